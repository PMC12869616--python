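"""Inter-batch shift diagnostics via invariant total-protein probes.

Treatment group is confounded with RPPA run (batch) in this design, so
batch health is monitored rather than modeled: total-protein probes whose
within-batch two-group 95% CI for log2 fold-change lies entirely inside
+/- 0.1 in every batch — and that have no plausible mechanism of acute
amyloid-beta sensitivity — form an invariant set. Differences of group
means over that set summarize each inter-batch comparison by a Wilcoxon
signed-rank p-value, median log2 fold-change, and (unscaled) MAD. A cell
is "notable" when p < 0.20 and |median| >= 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionMatrix, ProbeAnnotation, SampleTable
from .linmod import ContrastResult

__all__ = [
    "InvariantSet",
    "ShiftSummary",
    "find_invariant_probes",
    "wilcoxon_signed_rank",
    "interbatch_shift",
    "shift_matrix",
]

DEFAULT_CI_BOUND = 0.1
NOTABLE_P = 0.20
NOTABLE_MEDIAN = 0.01


@dataclass
class InvariantSet:
    probe_ids: list
    ci_table: pd.DataFrame  # rows probe, columns (batch, lfc/ci_low/ci_high)
    excluded_for_ab_sensitivity: list = field(default_factory=list)


@dataclass
class ShiftSummary:
    group_pair: tuple
    n_probes: int
    wilcoxon_p: float
    median_lfc: float
    mad: float

    @property
    def notable(self) -> bool:
        return self.wilcoxon_p < NOTABLE_P and abs(self.median_lfc) >= NOTABLE_MEDIAN


def find_invariant_probes(
    batch_results: dict,
    annot: ProbeAnnotation,
    sensitivity_list=(),
    bound: float = DEFAULT_CI_BOUND,
) -> InvariantSet:
    """Intersect the within-batch invariance criterion over all batches.

    ``batch_results`` maps batch label -> ContrastResult of that batch's
    two-group comparison. A probe qualifies when it is a total-protein
    probe, appears in every result with ci_low >= -bound and
    ci_high <= +bound (inclusive), and is not on the amyloid-sensitivity
    exclusion list.
    """
    for name, res in batch_results.items():
        for col in ("ci_low", "ci_high"):
            if col not in res.table.columns:
                raise ValueError(f"batch result {name!r} lacks column {col!r}")
    total = set(annot.total_protein_probes())
    sens = set(sensitivity_list)
    universe = None
    for res in batch_results.values():
        ids = set(res.table.index)
        universe = ids if universe is None else universe & ids
    rows = {}
    members, removed_sens = [], []
    for p in sorted(universe & total):
        ok = True
        for name, res in batch_results.items():
            r = res.table.loc[p]
            rows[(p, name)] = (r["lfc"], r["ci_low"], r["ci_high"])
            if not (r["ci_low"] >= -bound and r["ci_high"] <= bound):
                ok = False
        if ok:
            if p in sens:
                removed_sens.append(p)
            else:
                members.append(p)
    ci = pd.DataFrame.from_dict(rows, orient="index", columns=["lfc", "ci_low", "ci_high"])
    if len(ci):
        ci.index = pd.MultiIndex.from_tuples(ci.index, names=["probe_id", "batch"])
    return InvariantSet(probe_ids=members, ci_table=ci,
                        excluded_for_ab_sensitivity=removed_sens)


def wilcoxon_signed_rank(diffs, zero_method: str = "drop", exact_max_n: int = 25) -> float:
    """Two-sided Wilcoxon signed-rank p-value against a zero median.

    Zeros are dropped before ranking (classic treatment; ``zero_method=
    "pratt"`` keeps them in the ranking but not the statistic). Ties get
    midranks. For n <= ``exact_max_n`` the null distribution of W+ is
    enumerated exactly over all 2^n sign assignments (a subset-sum
    convolution over doubled ranks, so midranks stay exact); larger n
    uses the normal approximation with tie and continuity corrections.
    All differences zero returns p = 1.
    """
    d = np.asarray(diffs, dtype=float)
    if np.isnan(d).any():
        raise ValueError("differences must not contain NaN")
    if zero_method == "drop":
        d = d[d != 0]
        if d.size == 0:
            return 1.0
        ranks = stats.rankdata(np.abs(d))
    elif zero_method == "pratt":
        if np.all(d == 0):
            return 1.0
        ranks_all = stats.rankdata(np.abs(d))
        ranks = ranks_all[d != 0]
        d = d[d != 0]
    else:
        raise ValueError(f"unknown zero_method {zero_method!r}")
    n = d.size
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        # exact distribution over doubled ranks (integers even with midranks)
        r2 = np.rint(2 * ranks).astype(int)
        max_sum = int(r2.sum())
        counts = np.zeros(max_sum + 1)
        counts[0] = 1.0
        for r in r2:
            counts[r:] = counts[r:] + counts[:-r if r else None][: max_sum + 1 - r]
        counts /= counts.sum()
        w2 = int(np.rint(2 * w_plus))
        p_le = counts[: w2 + 1].sum()
        p_ge = counts[w2:].sum()
        return float(min(1.0, 2.0 * min(p_le, p_ge)))
    # normal approximation with tie correction and continuity correction
    mean = n * (n + 1) / 4.0
    tie_term = 0.0
    _, t_counts = np.unique(ranks, return_counts=True)
    tie_term = ((t_counts**3 - t_counts).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return 1.0
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def _group_means(matrix: ExpressionMatrix, samples: SampleTable, group: str,
                 probe_ids) -> pd.Series:
    ids = samples.data.loc[samples.data["group"] == group, "sample_id"]
    if ids.empty:
        raise ValueError(f"no samples in group {group!r}")
    return matrix.data.loc[list(probe_ids), list(ids)].mean(axis=1)


def interbatch_shift(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    invariants: InvariantSet,
    group_a: str,
    group_b: str,
) -> ShiftSummary:
    """Shift of group_a relative to group_b over the invariant probes.

    Uses per-probe differences of group means (A - B) on the (median-
    centered) expression matrix; reports the exact/approximate signed-
    rank p, the median difference, and the unscaled MAD about the median.
    """
    probes = invariants.probe_ids
    if len(probes) == 0:
        raise ValueError("invariant probe set is empty")
    if len(probes) < 5:
        warnings.warn(f"only {len(probes)} invariant probes; shift summaries are "
                      "unstable", stacklevel=2)
    diffs = (_group_means(matrix, samples, group_a, probes)
             - _group_means(matrix, samples, group_b, probes)).to_numpy()
    med = float(np.median(diffs))
    mad = float(np.median(np.abs(diffs - med)))
    p = wilcoxon_signed_rank(diffs)
    return ShiftSummary(group_pair=(group_a, group_b), n_probes=len(probes),
                        wilcoxon_p=p, median_lfc=med, mad=mad)


def shift_matrix(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    invariants: InvariantSet,
    group_list,
) -> pd.DataFrame:
    """All ordered pairwise shifts among ``group_list`` (row - column).

    Long-format table with columns row_group, col_group, n, p, median,
    mad, notable; the diagonal is marked ``self``. Medians are
    antisymmetric and p-values symmetric by construction.
    """
    groups = list(group_list)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    rows = []
    cache = {}
    for a, b in combinations(groups, 2):
        s = interbatch_shift(matrix, samples, invariants, a, b)
        cache[(a, b)] = s
        cache[(b, a)] = ShiftSummary((b, a), s.n_probes, s.wilcoxon_p,
                                     -s.median_lfc, s.mad)
    for a in groups:
        for b in groups:
            if a == b:
                rows.append({"row_group": a, "col_group": b, "n": len(invariants.probe_ids),
                             "p": np.nan, "median": 0.0, "mad": 0.0, "notable": False,
                             "self": True})
            else:
                s = cache[(a, b)]
                rows.append({"row_group": a, "col_group": b, "n": s.n_probes,
                             "p": s.wilcoxon_p, "median": s.median_lfc, "mad": s.mad,
                             "notable": s.notable, "self": False})
    return pd.DataFrame(rows)
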