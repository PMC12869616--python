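"""Qualitative calls of how a perturbation modulates a stimulus response.

Each probe's insulin response is summarized by a contrast quartet:

* ``I``  — insulin effect in unperturbed cells (insulin - untreated),
* ``Ia`` — insulin effect under the perturbation (perturbed+insulin - perturbed),
* ``L``  — final-level difference (perturbed+insulin - insulin),
* ``S``  — second-order shift, S = Ia - I.

An explicit, priority-ordered rule table converts the quartet (plus the
perturbation's baseline effects against vehicle and untreated) into one
of: no_effect, attenuation, robust_attenuation, augmentation, reversal,
or ambiguous, with an optional saturation_possible co-annotation when an
attenuation pattern co-occurs with an elevated baseline and no final-
level difference. The rules are direction-symmetric (negating every
fold change preserves the category) and overridable from a JSON file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ContrastStat",
    "ContrastQuartet",
    "RuleParams",
    "ResponseCall",
    "classify_response",
    "classify_basal",
    "summarize_calls",
]

CATEGORIES = (
    "no_effect",
    "attenuation",
    "robust_attenuation",
    "augmentation",
    "reversal",
    "saturation_possible",
    "ambiguous",
)


@dataclass(frozen=True)
class ContrastStat:
    lfc: float
    fdr: float


@dataclass(frozen=True)
class ContrastQuartet:
    probe_id: str
    I: ContrastStat
    Ia: ContrastStat
    L: ContrastStat
    S: ContrastStat
    baseline_av: ContrastStat | None = None  # perturbation - vehicle
    baseline_au: ContrastStat | None = None  # perturbation - untreated


@dataclass(frozen=True)
class RuleParams:
    """Thresholds of the decision rules.

    ``alpha`` gates significance; the robust tier requires FDR below
    ``robust_fdr`` and |fold change| above ``robust_fc`` on both the
    level (L) and shift (S) contrasts.
    """

    alpha: float = 0.05
    robust_fdr: float = 0.001
    robust_fc: float = 1.5

    @classmethod
    def from_json(cls, path) -> "RuleParams":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


@dataclass(frozen=True)
class ResponseCall:
    probe_id: str
    category: str
    rationale: str
    saturation_possible: bool = False

    @property
    def label(self) -> str:
        if self.saturation_possible:
            return f"{self.category}_or_saturation"
        return self.category


def _sig(c: ContrastStat, alpha: float) -> bool:
    return bool(np.isfinite(c.fdr) and c.fdr < alpha)


def classify_response(q: ContrastQuartet, params: RuleParams = RuleParams()) -> ResponseCall:
    """Apply the decision rules to one contrast quartet.

    Requires a significant base response ``I`` (probes without one belong
    to the basal-effect pathway, :func:`classify_basal`). Rules, in
    priority order:

    1. S not significant -> no_effect.
    2. S significant, opposite in sign to I:
       a. Ia significant and opposite to I -> reversal (the response
          flipped direction under the perturbation);
       b. else |Ia| < |I| -> attenuation, upgraded to robust_attenuation
          when both L and S clear the robust tier (FDR < 0.001 and
          |fold change| > 1.5);
       c. else -> ambiguous.
    3. S significant, same sign as I -> augmentation.
    4. An attenuation call where both baseline contrasts are significant
       in the direction of I and L is not significant additionally gets
       the saturation_possible co-annotation (the baseline may already
       sit at the stimulated level).
    """
    if not _sig(q.I, params.alpha):
        raise ValueError(
            f"probe {q.probe_id!r}: base response I is not significant "
            f"(fdr={q.I.fdr:.3g}); use classify_basal for basal effects"
        )
    s_i = np.sign(q.I.lfc)
    if not _sig(q.S, params.alpha):
        return ResponseCall(q.probe_id, "no_effect", "S_not_significant")
    s_s = np.sign(q.S.lfc)
    robust_lfc = float(np.log2(params.robust_fc))
    if s_s == -s_i:
        if _sig(q.Ia, params.alpha) and np.sign(q.Ia.lfc) == -s_i:
            return ResponseCall(q.probe_id, "reversal", "S_opposed_Ia_flipped")
        if abs(q.Ia.lfc) < abs(q.I.lfc):
            robust = (
                q.L.fdr < params.robust_fdr
                and q.S.fdr < params.robust_fdr
                and abs(q.L.lfc) > robust_lfc
                and abs(q.S.lfc) > robust_lfc
            )
            saturation = (
                q.baseline_av is not None
                and q.baseline_au is not None
                and _sig(q.baseline_av, params.alpha)
                and _sig(q.baseline_au, params.alpha)
                and np.sign(q.baseline_av.lfc) == s_i
                and np.sign(q.baseline_au.lfc) == s_i
                and not _sig(q.L, params.alpha)
            )
            cat = "robust_attenuation" if robust else "attenuation"
            rat = "S_opposed_Ia_shrunk" + ("_robust" if robust else "")
            return ResponseCall(q.probe_id, cat, rat, saturation_possible=saturation)
        return ResponseCall(q.probe_id, "ambiguous", "S_opposed_Ia_not_shrunk")
    if s_s == s_i:
        return ResponseCall(q.probe_id, "augmentation", "S_aligned_with_I")
    return ResponseCall(q.probe_id, "ambiguous", "S_zero_lfc")


def classify_basal(
    baseline_av: ContrastStat,
    baseline_au: ContrastStat,
    alpha: float = 0.05,
) -> str:
    """Consistency call for baseline perturbation effects.

    A probe counts as concordant only when both the perturbation-vs-
    vehicle and perturbation-vs-untreated contrasts are significant with
    agreeing sign; significant opposite signs are discordant; anything
    else is none.
    """
    a_sig, u_sig = _sig(baseline_av, alpha), _sig(baseline_au, alpha)
    if a_sig and u_sig:
        sa, su = np.sign(baseline_av.lfc), np.sign(baseline_au.lfc)
        if sa == su and sa != 0:
            return "concordant_up" if sa > 0 else "concordant_down"
        return "discordant"
    return "none"


def summarize_calls(calls: dict) -> pd.DataFrame:
    """Probe x isoform grid of category labels with rationale ids.

    ``calls`` maps isoform label -> list of ResponseCall; probes missing
    from an isoform get an empty cell.
    """
    probes: list = []
    for isoform_calls in calls.values():
        for c in isoform_calls:
            if c.probe_id not in probes:
                probes.append(c.probe_id)
    data = {}
    for isoform, isoform_calls in calls.items():
        by_probe = {c.probe_id: c for c in isoform_calls}
        data[isoform] = [
            by_probe[p].label if p in by_probe else "" for p in probes
        ]
        data[f"{isoform}_rule"] = [
            by_probe[p].rationale if p in by_probe else "" for p in probes
        ]
    return pd.DataFrame(data, index=pd.Index(probes, name="probe_id"))
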