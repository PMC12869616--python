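"""Composite effect-size / evidence scores via raised-cosine ramps.

A probe's differential-expression evidence is condensed into one bounded,
signed score: |log2 fold-change| and -log10(FDR) are each mapped through
a raised-cosine ramp to [0, 1], combined by geometric mean (so imbalance
between magnitude and statistical evidence is penalized), scaled to
[0, 100] and signed by the fold-change direction. The default knots put
the effect-size transition between fold changes of 1.1x and 1.5x and the
evidence transition between FDR 0.10 and 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ScoreParams", "CompositeScore", "raised_cosine", "composite_score", "score_matrix"]


@dataclass(frozen=True)
class ScoreParams:
    """Knots of the two ramps and the output scale."""

    lfc_a: float = float(np.log2(1.1))
    lfc_b: float = float(np.log2(1.5))
    fdr_a: float = 1.0   # -log10(0.10)
    fdr_b: float = 3.0   # -log10(0.001)
    scale: float = 100.0

    def __post_init__(self) -> None:
        if not (0 < self.lfc_a < self.lfc_b) or not (0 < self.fdr_a < self.fdr_b):
            raise ValueError("ramp knots must satisfy 0 < a < b")


@dataclass(frozen=True)
class CompositeScore:
    probe_id: str | None
    contrast_id: str | None
    signed_score: float
    lfc_component: float
    fdr_component: float


def raised_cosine(x, a: float, b: float):
    """Half-cosine ramp: 0 for x <= a, 1 for x >= b,
    0.5*(1 - cos(pi*(x-a)/(b-a))) in between. Continuous, nondecreasing."""
    if a >= b:
        raise ValueError("raised_cosine requires a < b")
    x = np.clip(np.asarray(x, dtype=float), a, b)
    out = 0.5 * (1.0 - np.cos(np.pi * (x - a) / (b - a)))
    return float(out) if out.ndim == 0 else out


def composite_score(
    lfc: float,
    fdr: float,
    params: ScoreParams = ScoreParams(),
    probe_id: str | None = None,
    contrast_id: str | None = None,
) -> CompositeScore:
    """Signed composite score for one (lfc, fdr) pair.

    An FDR of exactly 0 is treated as infinite evidence (component 1);
    either component at 0 annihilates the score, and the sign follows
    the fold-change direction.
    """
    if not (0.0 <= fdr <= 1.0):
        raise ValueError("fdr must lie in [0, 1]")
    lfc_c = raised_cosine(abs(lfc), params.lfc_a, params.lfc_b)
    neglog = np.inf if fdr == 0 else -np.log10(fdr)
    fdr_c = raised_cosine(neglog, params.fdr_a, params.fdr_b)
    mag = params.scale * float(np.sqrt(lfc_c * fdr_c))
    signed = float(np.sign(lfc)) * mag
    return CompositeScore(probe_id, contrast_id, signed, float(lfc_c), float(fdr_c))


def score_matrix(results, params: ScoreParams = ScoreParams(), top_n: int = 10):
    """Probes x contrasts table of signed scores.

    ``results`` is a list of ContrastResult (shared probe universe);
    returns ``(full, top)`` where ``top`` holds the ``top_n`` rows ranked
    by maximum |score| across contrasts, ties broken by probe_id.
    """
    cols = {}
    index = None
    for res in results:
        t = res.table
        if index is None:
            index = t.index
        else:
            index = index.intersection(t.index)
    for res in results:
        t = res.table.loc[index]
        scores = [
            composite_score(l, min(max(f, 0.0), 1.0), params).signed_score
            for l, f in zip(t["lfc"], t["fdr"])
        ]
        cols[res.contrast_id] = scores
    full = pd.DataFrame(cols, index=index)
    rank = full.abs().max(axis=1)
    order = sorted(full.index, key=lambda p: (-rank[p], str(p)))
    top = full.loc[order[:top_n]]
    return full, top
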