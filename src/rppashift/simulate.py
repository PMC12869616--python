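"""Synthetic RPPA datasets with known truth.

Emulates the statistical structure of the acute amyloid-beta / insulin
study design: 7 treatment groups x 3 replicates laid out across 4 RPPA
runs (untreated+insulin; Ab40 arms; Ab42 arms; vehicle alone), probe
variances following a mean-variance trend with scaled-inverse-chi-square
dispersion, per-sample quality (precision) factors, additive batch
offsets, invariant total-protein anchor probes, and treatment effects
realizing attenuation / reversal / saturation / no-effect scenarios.
Noise is Gaussian on the log2 scale; a heavy-tail contamination mixture
is available to exercise robust moderation. A single integer seed fully
determines the output for a fixed configuration.

Values are probe-level (the dilution-series interpolation performed by
an RPPA core is upstream and not modeled):

    y[p, j] = baseline_p + group_effect(p, group_j)
              + batch_offset(batch_j) + eps,   eps ~ N(0, sigma_p^2 / q_j).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import (
    TREATMENT_GROUPS,
    ExpressionMatrix,
    ProbeAnnotation,
    SampleTable,
)

__all__ = ["SimulationConfig", "make_scenario_effects", "generate_dataset", "write_dataset"]

SCENARIOS = (
    "null",
    "insulin_up",
    "insulin_down",
    "attenuated",
    "reversed",
    "saturated",
    "invariant_anchor",
    "batch_sensitive",
)

#: Run layout of the study: plates processed in tandem share a batch.
DEFAULT_BATCH_MAP = {
    "untreated": "run1",
    "insulin": "run1",
    "ab40": "run2",
    "ab40_insulin": "run2",
    "ab42": "run3",
    "ab42_insulin": "run3",
    "vehicle": "run4",
}


@dataclass
class SimulationConfig:
    """Study-shaped generator settings (all log2 units).

    Defaults mirror the study conditions: a 268-probe panel with 62
    phospho probes, seven treatments with three replicates each across
    four runs, a mild decreasing mean-variance trend around a prior
    variance of 0.003 (replicate sd ~0.055 log2, the precision regime in
    which a real panel yields a dozen-strong invariant set) with prior
    df 4, per-sample loading offsets (sd 0.15) that median centering is
    meant to remove, a 1.0-log2 insulin effect with attenuation factor
    0.3, and a -0.15 offset on the vehicle-only run (the kind of
    systematic displacement the batch diagnostics flag).
    """

    n_probes: int = 268
    n_phospho: int = 62
    n_replicates: int = 3
    groups: tuple = TREATMENT_GROUPS
    batch_map: dict = field(default_factory=lambda: dict(DEFAULT_BATCH_MAP))
    baseline_mean_range: tuple = (-2.0, 2.0)
    var_s0_2: float = 0.003
    var_d0: float | None = 4.0          # None -> variances exactly on the trend
    trend_slope: float = -0.25          # d log2(sigma^2) / d mean
    sample_quality_factors: dict = field(default_factory=dict)  # sample_id -> q
    batch_offsets: dict = field(default_factory=lambda: {
        "run1": 0.0, "run2": 0.0, "run3": 0.0, "run4": -0.15,
    })
    scenario_fractions: dict = field(default_factory=lambda: {
        "attenuated": 0.05,
        "reversed": 0.03,
        "saturated": 0.03,
        "insulin_up": 0.05,
        "insulin_down": 0.03,
        "invariant_anchor": 0.08,
        "batch_sensitive": 0.02,
    })
    effect_size_I: float = 1.0
    attenuation_factor: float = 0.3
    anchor_sd: float = 0.02
    batch_sensitive_sd: float = 0.2
    loading_offset_sd: float = 0.15
    heavy_tail_fraction: float = 0.0
    heavy_tail_var_factor: float = 9.0
    seed: int = 0

    def __post_init__(self) -> None:
        frac = sum(self.scenario_fractions.values())
        if frac > 1.0 + 1e-12:
            raise ValueError(f"scenario fractions sum to {frac:.3f} > 1")
        unknown = set(self.scenario_fractions) - set(SCENARIOS)
        if unknown:
            raise ValueError(f"unknown scenario(s): {sorted(unknown)}")
        if self.var_s0_2 <= 0 or self.anchor_sd <= 0:
            raise ValueError("variance parameters must be positive")

    def sample_ids(self) -> list:
        return [f"{g}_{r}" for g in self.groups for r in range(1, self.n_replicates + 1)]


def make_scenario_effects(
    scenario: str,
    effect_size_I: float = 1.0,
    attenuation_factor: float = 0.3,
) -> dict:
    """True per-group mean offsets (log2) for one probe's scenario.

    Scenarios are isoform-symmetric: both amyloid arms carry the same
    truth. ``saturated`` elevates the amyloid baseline to the stimulated
    level with no further insulin increment (L truth 0, S truth -effect).
    """
    e = effect_size_I
    f = attenuation_factor
    base = {g: 0.0 for g in TREATMENT_GROUPS}
    if scenario in ("null", "invariant_anchor", "batch_sensitive"):
        return base
    if scenario == "insulin_up":
        base.update(insulin=e, ab40_insulin=e, ab42_insulin=e)
    elif scenario == "insulin_down":
        base.update(insulin=-e, ab40_insulin=-e, ab42_insulin=-e)
    elif scenario == "attenuated":
        base.update(insulin=e, ab40_insulin=f * e, ab42_insulin=f * e)
    elif scenario == "reversed":
        base.update(insulin=e, ab40_insulin=-e, ab42_insulin=-e)
    elif scenario == "saturated":
        base.update(insulin=e, ab40=e, ab42=e, ab40_insulin=e, ab42_insulin=e)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return base


def _true_quartet(effects: dict, isoform: str) -> dict:
    ab = f"ab{isoform}"
    I = effects["insulin"] - effects["untreated"]
    Ia = effects[f"{ab}_insulin"] - effects[ab]
    return {"I": I, "Ia": Ia, "L": effects[f"{ab}_insulin"] - effects["insulin"],
            "S": Ia - I}


def _assign_scenarios(config: SimulationConfig, rng: np.random.Generator):
    """Deterministic probe -> scenario map honoring the phospho split.

    Insulin-response scenarios land on phospho probes (signaling nodes);
    anchors and batch-sensitive probes are total-protein.
    """
    n = config.n_probes
    counts = {s: int(round(f * n)) for s, f in config.scenario_fractions.items()}
    phospho_scen = [s for s in ("attenuated", "reversed", "saturated",
                                "insulin_up", "insulin_down") if counts.get(s)]
    total_scen = [s for s in ("invariant_anchor", "batch_sensitive") if counts.get(s)]
    phospho_ids = list(range(config.n_phospho))
    total_ids = list(range(config.n_phospho, n))
    rng.shuffle(phospho_ids)
    rng.shuffle(total_ids)
    scen = np.array(["null"] * n, dtype=object)
    pos = 0
    for s in phospho_scen:
        take = phospho_ids[pos:pos + counts[s]]
        if len(take) < counts[s]:
            raise ValueError("not enough phospho probes for the scenario fractions")
        scen[take] = s
        pos += counts[s]
    pos = 0
    for s in total_scen:
        take = total_ids[pos:pos + counts[s]]
        if len(take) < counts[s]:
            raise ValueError("not enough total-protein probes for the scenario fractions")
        scen[take] = s
        pos += counts[s]
    return scen


def generate_dataset(
    config: SimulationConfig = SimulationConfig(),
    seed: int | None = None,
):
    """Draw one dataset; returns (matrix, samples, annotation, truth).

    ``truth`` is a per-probe DataFrame with the scenario label and the
    true I / Ia / L / S contrast values (isoform-symmetric), sufficient
    to score every downstream call.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_probes
    groups = list(config.groups)
    sample_ids = config.sample_ids()
    sample_groups = [g for g in groups for _ in range(config.n_replicates)]
    probe_ids = [f"probe_{i + 1:04d}" for i in range(n)]

    scen = _assign_scenarios(config, rng)
    lo, hi = config.baseline_mean_range
    baseline = rng.uniform(lo, hi, size=n)
    mid = 0.5 * (lo + hi)

    # probe variances: trend value, then scaled-inverse-chi-square dispersion
    s0 = config.var_s0_2 * 2.0 ** (config.trend_slope * (baseline - mid))
    if config.var_d0 is None:
        sigma2 = s0
    else:
        sigma2 = s0 * config.var_d0 / rng.chisquare(config.var_d0, size=n)
    anchors = scen == "invariant_anchor"
    sigma2[anchors] = config.anchor_sd**2
    if config.heavy_tail_fraction > 0:
        contam = rng.random(n) < config.heavy_tail_fraction
        sigma2[contam & ~anchors] *= config.heavy_tail_var_factor

    # alternate the response direction within each scenario so the panel
    # stays direction-balanced (median centering then remains unbiased,
    # as it must be for the invariant-probe criterion to be meaningful)
    effects = np.zeros((n, len(groups)))
    truth_rows = []
    seen: dict = {}
    for i, s in enumerate(scen):
        sign = 1.0
        if s not in ("null", "invariant_anchor", "batch_sensitive"):
            k = seen.get(s, 0)
            seen[s] = k + 1
            sign = 1.0 if k % 2 == 0 else -1.0
        eff = make_scenario_effects(s, sign * config.effect_size_I,
                                    config.attenuation_factor)
        effects[i] = [eff[g] for g in groups]
        tq = _true_quartet(eff, "40")
        truth_rows.append({"probe_id": probe_ids[i], "scenario": s,
                           "true_sign": sign,
                           "true_sd": float(np.sqrt(sigma2[i])), **{
                               f"true_{k}": v for k, v in tq.items()}})

    offs = np.array([config.batch_offsets.get(config.batch_map[g], 0.0)
                     for g in sample_groups])
    probe_batch = np.zeros((n, len(sample_ids)))
    bs = scen == "batch_sensitive"
    if bs.any():
        batches = sorted(set(config.batch_map.values()))
        extra = rng.normal(0.0, config.batch_sensitive_sd, size=(int(bs.sum()), len(batches)))
        bidx = [batches.index(config.batch_map[g]) for g in sample_groups]
        probe_batch[bs] = extra[:, bidx]

    quality = np.array([config.sample_quality_factors.get(sid, 1.0)
                        for sid in sample_ids])
    if (quality <= 0).any():
        raise ValueError("sample quality factors must be positive")
    gidx = np.array([groups.index(g) for g in sample_groups])
    loading = (rng.normal(0.0, config.loading_offset_sd, size=len(sample_ids))
               if config.loading_offset_sd > 0 else np.zeros(len(sample_ids)))
    mean = (baseline[:, None] + effects[:, gidx] + offs[None, :] + probe_batch
            + loading[None, :])
    noise = rng.normal(size=(n, len(sample_ids)))
    values = mean + noise * np.sqrt(sigma2[:, None] / quality[None, :])

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"),
                     columns=sample_ids),
        scale="log2",
    )
    samples = SampleTable(pd.DataFrame({
        "sample_id": sample_ids,
        "group": sample_groups,
        "batch": [config.batch_map[g] for g in sample_groups],
        "replicate": [int(sid.rsplit("_", 1)[1]) for sid in sample_ids],
        "cf1": np.round(rng.uniform(0.8, 1.3, size=len(sample_ids)), 3),
        "cf2": np.round(rng.uniform(0.45, 1.1, size=len(sample_ids)), 3),
    }))
    annot = ProbeAnnotation(pd.DataFrame({
        "probe_id": probe_ids,
        "target_name": [f"protein_{i + 1:04d}" for i in range(n)],
        "phospho_site": ["S000" if i < config.n_phospho else "" for i in range(n)],
        "validated": True,
        "excluded": False,
        "context_tags": "endothelial",
    }))
    truth = pd.DataFrame(truth_rows).set_index("probe_id")
    return matrix, samples, annot, truth


def write_dataset(outdir, matrix, samples, annot, truth) -> None:
    """Write the four CSV artifacts of one simulated dataset."""
    from pathlib import Path

    from .data import write_expression_table

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression_table(matrix, out / "expression.csv")
    samples.data.to_csv(out / "samples.csv", index=False)
    annot_df = annot.data.reset_index().rename(columns={"index": "probe_id"})
    annot_df.to_csv(out / "probes.csv", index=False)
    truth.to_csv(out / "truth.csv")
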