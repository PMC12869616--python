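"""End-to-end orchestration: QC -> weights -> DE -> scores -> batch
diagnostics -> classification -> report bundle.

A single config (YAML or :class:`PipelineConfig`) drives the whole
analysis. Every number in the report bundle is recomputable by calling
the underlying module operations directly — the pipeline adds no math of
its own, only plumbing, logging and CSV serialization.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import batch as batchmod
from . import classify as classifymod
from . import linmod, qc, scoring
from .data import (
    ExpressionMatrix,
    ProbeAnnotation,
    SampleTable,
    filter_probes,
    flag_loading_outliers,
    median_center,
    read_expression_table,
    read_probe_annotation,
    read_sample_table,
)

__all__ = ["PipelineConfig", "PipelineResult", "parse_contrast", "run_pipeline",
           "DEFAULT_CONTRASTS", "QUARTET_CONTRASTS"]

log = logging.getLogger("rppashift")

#: The eight headline contrasts of the study (group-label expressions).
DEFAULT_CONTRASTS = {
    "vehicle_vs_untreated": "vehicle-untreated",
    "ab40_vs_vehicle": "ab40-vehicle",
    "ab42_vs_vehicle": "ab42-vehicle",
    "insulin_vs_untreated": "insulin-untreated",
    "ab40_insulin_shift": "(ab40_insulin-ab40)-(insulin-untreated)",
    "ab40ins_vs_insulin": "ab40_insulin-insulin",
    "ab42_insulin_shift": "(ab42_insulin-ab42)-(insulin-untreated)",
    "ab42ins_vs_insulin": "ab42_insulin-insulin",
}

#: Per-isoform contrast quartet (I, Ia, L, S) plus the baseline pair.
QUARTET_CONTRASTS = {
    "40": {
        "I": "insulin-untreated",
        "Ia": "ab40_insulin-ab40",
        "L": "ab40_insulin-insulin",
        "S": "(ab40_insulin-ab40)-(insulin-untreated)",
        "Av": "ab40-vehicle",
        "Au": "ab40-untreated",
    },
    "42": {
        "I": "insulin-untreated",
        "Ia": "ab42_insulin-ab42",
        "L": "ab42_insulin-insulin",
        "S": "(ab42_insulin-ab42)-(insulin-untreated)",
        "Av": "ab42-vehicle",
        "Au": "ab42-untreated",
    },
}

#: Within-batch two-group comparisons used for invariant-probe selection.
BATCH_CONTRASTS = {
    "run1": ("insulin", "untreated"),
    "run2": ("ab40_insulin", "ab40"),
    "run3": ("ab42_insulin", "ab42"),
}

_TOKEN = re.compile(r"[A-Za-z_][A-Za-z0-9_]*|[()+\-]")


def parse_contrast(expr: str, groups) -> dict:
    """Parse a group-label expression like
    ``(ab40_insulin-ab40)-(insulin-untreated)`` into coefficients.

    Supports group labels, ``+``, ``-`` and parentheses; coefficients of
    a difference contrast sum to zero by construction.
    """
    tokens = _TOKEN.findall(expr.replace(" ", ""))
    if "".join(tokens) != expr.replace(" ", ""):
        raise ValueError(f"cannot parse contrast expression {expr!r}")
    pos = 0

    def parse_sum() -> dict:
        nonlocal pos
        coeffs: dict = defaultdict(float)
        sign = 1.0
        while pos < len(tokens):
            tok = tokens[pos]
            if tok == "+":
                sign = 1.0
                pos += 1
            elif tok == "-":
                sign = -1.0
                pos += 1
            elif tok == "(":
                pos += 1
                sub = parse_sum()
                if pos >= len(tokens) or tokens[pos] != ")":
                    raise ValueError(f"unbalanced parentheses in {expr!r}")
                pos += 1
                for k, v in sub.items():
                    coeffs[k] += sign * v
                sign = 1.0
            elif tok == ")":
                break
            else:
                coeffs[tok] += sign
                pos += 1
                sign = 1.0
        return coeffs

    coeffs = parse_sum()
    if pos != len(tokens):
        raise ValueError(f"unbalanced parentheses in {expr!r}")
    unknown = [g for g in coeffs if g not in groups]
    if unknown:
        raise ValueError(f"contrast {expr!r} references unknown group(s): {unknown}")
    return {k: v for k, v in coeffs.items() if v != 0.0}


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run."""

    expression: str | None = None
    samples: str | None = None
    probes: str | None = None
    outdir: str = "rppashift_out"
    contrasts: dict = field(default_factory=lambda: dict(DEFAULT_CONTRASTS))
    context: str = "endothelial"
    fdr: float = 0.05
    invariant_bound: float = 0.1
    sensitivity_list: list = field(default_factory=list)
    weight_policy: str = "auto"          # auto | off | always
    weight_contrasts: list = field(default_factory=list)  # explicit overrides
    trend: bool = True
    robust: bool = True
    center_first: bool = False           # center before filtering (legacy order)
    robust_fdr: float = 0.001
    robust_fc: float = 1.5
    coherence_cutoff: float = qc.DEFAULT_COHERENCE_CUTOFF
    strict: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def digest(self) -> str:
        payload = {k: v for k, v in self.__dict__.items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResult:
    de: dict                  # contrast_id -> ContrastResult
    counts: pd.DataFrame      # Table-1-style per-contrast DE counts
    qc_reports: dict          # contrast_id -> PCAQCReport
    weights: dict             # contrast_id -> per-sample weights (Series)
    scores: pd.DataFrame      # probes x contrasts signed composite scores
    invariant: object         # InvariantSet
    shift_tables: dict        # "non_insulin"/"insulin" -> shift DataFrame
    overlaps: pd.DataFrame    # directional overlap counts
    calls: pd.DataFrame       # Table-2-style probe x isoform grid
    basal: pd.DataFrame       # probe x isoform basal-effect concordance
    quartets: dict            # isoform -> {name: ContrastResult}


def _fit_contrast(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    coeffs: dict,
    contrast_id: str,
    config: PipelineConfig,
    weights_out: dict,
    qc_out: dict,
):
    """Fit one contrast on the samples of its referenced groups."""
    groups = sorted(coeffs)
    sub = samples.samples_in_groups(groups)
    design = linmod.design_from_samples(sub, groups=groups)
    use_weights = config.weight_policy == "always" or contrast_id in config.weight_contrasts
    if config.weight_policy == "auto" and len(groups) == 2:
        report = qc.qc_contrast(matrix, sub, groups[0], groups[1],
                                contrast_id=contrast_id,
                                coherence_cutoff=config.coherence_cutoff)
        qc_out[contrast_id] = report
        if not report.coherent:
            use_weights = True
    if use_weights and config.weight_policy != "off":
        w, converged = linmod.estimate_sample_weights(matrix, design)
        if not converged:
            log.warning("weights for %s did not converge; using last iterate", contrast_id)
        design = linmod.design_from_samples(sub, groups=groups, weights=w)
        weights_out[contrast_id] = pd.Series(w, index=design.sample_ids)
    fit = linmod.fit_cellmeans(matrix, design)
    if fit.n_dropped_missing:
        log.info("%s: dropped %d probes with missing values", contrast_id,
                 fit.n_dropped_missing)
    mod = linmod.ebayes_moderate(fit, trend=config.trend, robust=config.robust)
    return linmod.apply_contrast(mod, coeffs, contrast_id=contrast_id)


def _quartet_results(matrix, samples, isoform, config, weights_out, qc_out):
    """Fit the I/Ia/L/S quartet from one 4-group model (so S = Ia - I
    holds exactly) plus the two baseline contrasts."""
    spec = QUARTET_CONTRASTS[isoform]
    quartet_groups = sorted({g for name in ("I", "Ia", "L", "S")
                             for g in parse_contrast(spec[name], samples.groups())})
    sub = samples.samples_in_groups(quartet_groups)
    cid = f"quartet_{isoform}"
    use_weights = config.weight_policy == "always" or cid in config.weight_contrasts
    design = linmod.design_from_samples(sub, groups=quartet_groups)
    if use_weights and config.weight_policy != "off":
        w, _ = linmod.estimate_sample_weights(matrix, design)
        design = linmod.design_from_samples(sub, groups=quartet_groups, weights=w)
        weights_out[cid] = pd.Series(w, index=design.sample_ids)
    fit = linmod.fit_cellmeans(matrix, design)
    mod = linmod.ebayes_moderate(fit, trend=config.trend, robust=config.robust)
    out = {}
    for name in ("I", "Ia", "L", "S"):
        coeffs = parse_contrast(spec[name], quartet_groups)
        out[name] = linmod.apply_contrast(mod, coeffs, contrast_id=f"{name}_{isoform}")
    for name in ("Av", "Au"):
        coeffs = parse_contrast(spec[name], samples.groups())
        out[name] = _fit_contrast(matrix, samples, coeffs, f"{name}_{isoform}",
                                  config, weights_out, qc_out)
    return out


def run_pipeline(config: PipelineConfig, inputs=None) -> PipelineResult:
    """Run the full analysis; returns the in-memory bundle and writes
    CSVs under ``config.outdir``.

    ``inputs`` may supply ``(matrix, samples, annot)`` directly (e.g.
    from the simulator); otherwise the config paths are read.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if inputs is not None:
        matrix, samples, annot = inputs
    else:
        if not (config.expression and config.samples and config.probes):
            raise ValueError("pipeline needs expression/samples/probes paths or in-memory inputs")
        matrix = read_expression_table(config.expression)
        samples = read_sample_table(config.samples)
        annot = read_probe_annotation(config.probes)
    samples = flag_loading_outliers(samples)
    if samples.data["qc_flag"].any():
        flagged = samples.data.loc[samples.data["qc_flag"], "sample_id"].tolist()
        log.warning("protein-loading outlier(s) flagged (kept): %s", flagged)

    # default order: filter on the analysis probe set, then center
    if config.center_first:
        matrix = filter_probes(median_center(matrix), annot, context=config.context)
    else:
        matrix = median_center(filter_probes(matrix, annot, context=config.context))
    log.info("analysis matrix: %d probes x %d samples", *matrix.shape)

    groups = samples.groups()
    qc_reports: dict = {}
    weights: dict = {}
    de: dict = {}
    for cid, expr in config.contrasts.items():
        try:
            coeffs = parse_contrast(expr, groups)
        except ValueError as err:
            raise ValueError(f"contrast {cid!r}: {err}") from err
        de[cid] = _fit_contrast(matrix, samples, coeffs, cid, config, weights, qc_reports)
        de[cid].table.to_csv(out / f"de_{cid}.csv")

    counts = pd.DataFrame(
        [
            {"contrast": cid, "up": u, "down": d, "total": t}
            for cid, (u, d, t) in (
                (cid, linmod.count_de(res, config.fdr)) for cid, res in de.items()
            )
        ]
    )
    counts.to_csv(out / "de_counts.csv", index=False)

    score_full, score_top = scoring.score_matrix(list(de.values()))
    score_full.to_csv(out / "scores.csv")
    score_top.to_csv(out / "scores_top.csv")

    # invariant probes from the three within-batch two-group fits
    batch_results = {}
    for run, (ga, gb) in BATCH_CONTRASTS.items():
        if ga in groups and gb in groups:
            coeffs = {ga: 1.0, gb: -1.0}
            batch_results[run] = _fit_contrast(matrix, samples, coeffs,
                                               f"batch_{run}", config, weights,
                                               qc_reports)
    invariant = batchmod.find_invariant_probes(
        batch_results, annot, sensitivity_list=config.sensitivity_list,
        bound=config.invariant_bound,
    )
    log.info("invariant probes: %d (excluded for amyloid sensitivity: %d)",
             len(invariant.probe_ids), len(invariant.excluded_for_ab_sensitivity))
    if config.strict and len(invariant.probe_ids) < 5:
        raise RuntimeError("strict mode: fewer than 5 invariant probes")

    shift_tables = {}
    non_insulin = [g for g in ("untreated", "ab40", "ab42", "vehicle") if g in groups]
    insulin_side = [g for g in ("insulin", "ab40_insulin", "ab42_insulin") if g in groups]
    if invariant.probe_ids:
        if len(non_insulin) >= 2:
            shift_tables["non_insulin"] = batchmod.shift_matrix(
                matrix, samples, invariant, non_insulin)
            shift_tables["non_insulin"].to_csv(out / "shift_non_insulin.csv", index=False)
        if len(insulin_side) >= 2:
            shift_tables["insulin"] = batchmod.shift_matrix(
                matrix, samples, invariant, insulin_side)
            shift_tables["insulin"].to_csv(out / "shift_insulin.csv", index=False)

    overlap_rows = []
    overlap_pairs = [(a, b) for a, b in (
        ("ab40_vs_vehicle", "ab42_vs_vehicle"),
    ) if a in de and b in de]
    for a, b in overlap_pairs:
        ov = linmod.directional_overlap(de[a], de[b], threshold=config.fdr)
        overlap_rows.append({"contrast_a": a, "contrast_b": b, **ov})
    overlaps = pd.DataFrame(overlap_rows)
    if len(overlaps):
        overlaps.to_csv(out / "overlaps.csv", index=False)

    # classification per isoform on probes with a significant base response
    rules = classifymod.RuleParams(alpha=config.fdr, robust_fdr=config.robust_fdr,
                                   robust_fc=config.robust_fc)
    quartets: dict = {}
    calls_by_isoform: dict = {}
    basal_cols: dict = {}
    for isoform in QUARTET_CONTRASTS:
        iso_groups = {g for name, expr in QUARTET_CONTRASTS[isoform].items()
                      for g in parse_contrast(expr, list(TREATMENT_SUPERSET))}
        if not iso_groups.issubset(set(groups)):
            continue
        qres = _quartet_results(matrix, samples, isoform, config, weights, qc_reports)
        quartets[isoform] = qres
        # basal concordance (perturbation alone vs vehicle and untreated)
        shared = qres["Av"].table.index.intersection(qres["Au"].table.index)
        basal_cols[f"ab{isoform}"] = pd.Series({
            p: classifymod.classify_basal(
                classifymod.ContrastStat(float(qres["Av"].table.loc[p, "lfc"]),
                                         float(qres["Av"].table.loc[p, "fdr"])),
                classifymod.ContrastStat(float(qres["Au"].table.loc[p, "lfc"]),
                                         float(qres["Au"].table.loc[p, "fdr"])),
                alpha=config.fdr)
            for p in shared})
        calls = []
        for p in qres["I"].table.index:
            stat = {name: classifymod.ContrastStat(
                float(qres[name].table.loc[p, "lfc"]),
                float(qres[name].table.loc[p, "fdr"])) for name in qres}
            if not (np.isfinite(stat["I"].fdr) and stat["I"].fdr < config.fdr):
                continue
            quartet = classifymod.ContrastQuartet(
                probe_id=p, I=stat["I"], Ia=stat["Ia"], L=stat["L"], S=stat["S"],
                baseline_av=stat["Av"], baseline_au=stat["Au"])
            calls.append(classifymod.classify_response(quartet, rules))
        calls_by_isoform[f"ab{isoform}"] = calls
    calls = classifymod.summarize_calls(calls_by_isoform) if calls_by_isoform else pd.DataFrame()
    if len(calls):
        calls.to_csv(out / "response_calls.csv")
    basal = pd.DataFrame(basal_cols)
    if len(basal):
        basal.index.name = "probe_id"
        basal.to_csv(out / "basal_calls.csv")

    qc_df = pd.DataFrame([
        {"contrast_id": r.contrast_id, "n_components_95": r.n_components_95,
         "mean_silhouette": r.mean_silhouette, "mahalanobis_2d": r.mahalanobis_2d,
         "coherent": r.coherent}
        for r in qc_reports.values()
    ])
    if len(qc_df):
        qc_df.to_csv(out / "qc_report.csv", index=False)

    from . import __version__

    (out / "run_log.json").write_text(json.dumps({
        "package_version": __version__,
        "config_hash": config.digest(),
        "n_probes": matrix.shape[0],
        "n_samples": matrix.shape[1],
        "n_invariant": len(invariant.probe_ids),
        "contrasts": list(de),
    }, indent=2))

    return PipelineResult(de=de, counts=counts, qc_reports=qc_reports,
                          weights=weights, scores=score_full, invariant=invariant,
                          shift_tables=shift_tables, overlaps=overlaps,
                          calls=calls, basal=basal, quartets=quartets)


# all groups any quartet expression may mention
TREATMENT_SUPERSET = (
    "untreated", "vehicle", "insulin", "ab40", "ab42", "ab40_insulin", "ab42_insulin",
)
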