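"""Moderated linear models for probe-level differential expression.

This is the statistical engine of the package: per-probe cell-means
linear models fit by (optionally weighted) least squares, empirical-Bayes
variance moderation with an intensity-dependent prior (mean-variance
trend) and robust hyperparameter estimation, arbitrary linear contrasts
over group means — including second-order difference-of-differences
contrasts — moderated t-statistics and confidence intervals, and
Benjamini-Hochberg FDR control per contrast.

Model
-----
For probe p with group means mu_g and per-sample precision weights w_j,

    y_pj = mu_{g(j)} + e_pj,   Var(e_pj) = sigma_p^2 / w_j.

The residual variances s_p^2 (d_p degrees of freedom) are shrunk toward a
prior s0^2(A_p) — a smooth function of average expression when the trend
is enabled — assuming the scaled-inverse-chi-square hierarchy

    s_p^2 | sigma_p^2 ~ sigma_p^2 chi^2_{d}/d,
    1/sigma_p^2       ~ chi^2_{d0} / (d0 s0^2),

giving the posterior variance

    s~_p^2 = (d0 s0^2(A_p) + d s_p^2) / (d0 + d)

and moderated t on d0 + d degrees of freedom. The hyperparameters
(d0, s0^2) are estimated by moment matching on log residual variances
(digamma/trigamma identities of the scaled-F distribution); the robust
option winsorizes the log-variance residuals before moment matching and
assigns outlying probes an individually reduced prior df.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .data import ExpressionMatrix, SampleTable

__all__ = [
    "DesignSpec",
    "CellMeansFit",
    "ModeratedFit",
    "ContrastResult",
    "design_from_samples",
    "fit_cellmeans",
    "estimate_sample_weights",
    "ebayes_moderate",
    "apply_contrast",
    "adjust_bh",
    "count_de",
    "directional_overlap",
]

#: Sentinel total-df cap when the prior df is infinite.
MAX_TOTAL_DF = 1e6


@dataclass
class DesignSpec:
    """Cell-means design: an ordered group list, a samples x groups 0/1
    incidence matrix, and per-sample positive precision weights."""

    groups: list
    incidence: np.ndarray  # samples x groups, one 1 per row
    sample_ids: list
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        inc = np.asarray(self.incidence, dtype=float)
        if not np.all(inc.sum(axis=1) == 1):
            raise ValueError("each sample must belong to exactly one group")
        n_per = inc.sum(axis=0)
        if (n_per < 2).any():
            low = [g for g, n in zip(self.groups, n_per) if n < 2]
            raise ValueError(f"every fitted group needs >= 2 samples; short: {low}")
        self.incidence = inc
        if self.weights is None:
            self.weights = np.ones(inc.shape[0])
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights <= 0).any():
            raise ValueError("weights must be positive")


def design_from_samples(samples: SampleTable, groups=None, weights=None) -> DesignSpec:
    """Build a cell-means design from a sample table (optionally
    restricted to ``groups``, in that order)."""
    df = samples.data
    if groups is None:
        groups = list(pd.unique(df["group"]))
    df = df[df["group"].isin(groups)]
    inc = np.zeros((len(df), len(groups)))
    for i, g in enumerate(df["group"]):
        inc[i, groups.index(g)] = 1.0
    w = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
    return DesignSpec(groups=list(groups), incidence=inc,
                      sample_ids=list(df["sample_id"]), weights=w)


@dataclass
class CellMeansFit:
    """Per-probe weighted-least-squares fit of the cell-means model."""

    groups: list
    probe_ids: list
    means: np.ndarray          # probes x groups
    s2: np.ndarray             # per-probe residual variance
    df_residual: int
    avg_expr: np.ndarray       # per-probe weighted mean expression
    group_weight_sums: np.ndarray  # sum of sample weights per group
    n_dropped_missing: int = 0


@dataclass
class ModeratedFit(CellMeansFit):
    """Cell-means fit augmented with empirical-Bayes moderation."""

    d0: np.ndarray = field(default_factory=lambda: np.array([]))   # per-probe prior df
    s0_2: np.ndarray = field(default_factory=lambda: np.array([])) # per-probe prior variance
    post_var: np.ndarray = field(default_factory=lambda: np.array([]))
    total_df: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class ContrastResult:
    """Per-probe estimates for one linear contrast over group means."""

    contrast_id: str
    coeffs: dict
    table: pd.DataFrame  # columns lfc, se, t, p, fdr, ci_low, ci_high, avg_expr

    @property
    def probe_ids(self) -> list:
        return list(self.table.index)


def fit_cellmeans(matrix: ExpressionMatrix, design: DesignSpec) -> CellMeansFit:
    """Weighted least squares of the cell-means model, probe by probe.

    Probes with any missing value among the design's samples are dropped
    from this fit (count recorded on the result).
    """
    if matrix.scale != "log2":
        raise ValueError("fit requires log2-scale expression")
    Y = matrix.subset_samples(design.sample_ids).data
    ok = ~Y.isna().any(axis=1)
    n_dropped = int((~ok).sum())
    Y = Y.loc[ok]
    y = Y.to_numpy(dtype=float)                       # probes x samples
    X = design.incidence                              # samples x groups
    w = design.weights
    n, g = X.shape
    d = n - g
    if d <= 0:
        raise ValueError(f"non-positive residual df: n={n}, groups={g}")
    Wg = (w[:, None] * X).sum(axis=0)                 # per-group weight sums
    means = (y * w[None, :]) @ X / Wg[None, :]        # probes x groups
    resid = y - means @ X.T
    s2 = (w[None, :] * resid**2).sum(axis=1) / d
    avg = (y * w[None, :]).sum(axis=1) / w.sum()
    return CellMeansFit(
        groups=list(design.groups),
        probe_ids=list(Y.index),
        means=means,
        s2=s2,
        df_residual=d,
        avg_expr=avg,
        group_weight_sums=Wg,
        n_dropped_missing=n_dropped,
    )


def estimate_sample_weights(
    matrix: ExpressionMatrix,
    design: DesignSpec,
    max_iter: int = 200,
    tol: float = 1e-3,
    clamp: tuple = (0.05, 20.0),
) -> tuple[np.ndarray, bool]:
    """Estimate per-sample precision weights (arrayWeights-style).

    Assumes sample j's residual variance is sigma_p^2 / w_j across all
    probes and iterates a moment-based fixed point: fit the cell-means
    model with current weights, compare each sample's leverage-corrected
    squared residuals against the probe variances, and divide its weight
    by the measured excess. Weights are normalized to geometric mean 1
    and clamped to ``clamp``.

    Returns ``(weights, converged)``; on non-convergence the last iterate
    is returned with ``converged=False``.
    """
    Y = matrix.subset_samples(design.sample_ids).data
    Y = Y.loc[~Y.isna().any(axis=1)]
    y = Y.to_numpy(dtype=float)
    if y.shape[0] < 50:
        import warnings

        warnings.warn(f"only {y.shape[0]} probes available for weight estimation; "
                      "estimates may be unstable", stacklevel=2)
    X = design.incidence
    n, g = X.shape
    d = n - g
    w = np.ones(n)
    converged = False
    for _ in range(max_iter):
        Wg = (w[:, None] * X).sum(axis=0)
        means = (y * w[None, :]) @ X / Wg[None, :]
        resid = y - means @ X.T
        s2 = (w[None, :] * resid**2).sum(axis=1) / d
        s2 = np.maximum(s2, 1e-12)
        h = np.einsum("ij,ij->i", X, w[:, None] * X / Wg[None, :])  # leverage per sample
        denom = np.maximum(1.0 - h, 1e-3)
        # excess variance factor of each sample relative to its weight;
        # damped update (exponent < 1) to avoid oscillation at small n
        v = (resid**2 / s2[:, None]).mean(axis=0) * w / denom
        new_w = w * np.maximum(v, 1e-8) ** -0.7
        new_w = np.clip(new_w, *clamp)
        new_w = new_w / np.exp(np.mean(np.log(new_w)))
        if np.max(np.abs(new_w - w)) < tol:
            w = new_w
            converged = True
            break
        w = new_w
    w = np.clip(w, *clamp)
    w = w / np.exp(np.mean(np.log(w)))
    return w, converged


# ---------------------------------------------------------------------------
# Empirical-Bayes moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def _winsor_attenuation(winsor: tuple) -> float:
    """Variance of a standard normal winsorized at the given quantiles,
    i.e. the factor by which winsorization deflates a unit variance."""
    lo, hi = stats.norm.ppf(winsor[0]), stats.norm.ppf(winsor[1])
    # E[W^2] with W = clip(Z, lo, hi); Z standard normal
    a, b = stats.norm.pdf(lo), stats.norm.pdf(hi)
    Fa, Fb = winsor[0], winsor[1]
    mid = (Fb - Fa) + lo * a - hi * b  # integral of z^2 phi(z) over [lo, hi]
    ew2 = mid + lo**2 * Fa + hi**2 * (1 - Fb)
    ew = -(b - a) + lo * Fa + hi * (1 - Fb)
    return float(ew2 - ew**2)


def _fit_f_dist(s2, d, covariate=None, winsor=None, trend_frac=0.4):
    """Moment-match a scaled F prior to observed residual variances.

    Returns (d0, s0_2 per probe, e_resid) where e_resid are the
    bias-corrected log-variance residuals about the prior trend.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    if covariate is not None:
        order = np.argsort(covariate)
        sm = lowess(e[ok], np.asarray(covariate)[ok], frac=trend_frac,
                    return_sorted=True)
        emean = np.interp(covariate, sm[:, 0], sm[:, 1])
    else:
        emean = np.full_like(e, e[ok].mean())
    r = e - emean
    r_fit = r[ok].copy()
    attenuation = 1.0
    if winsor is not None:
        lo, hi = np.quantile(r_fit, winsor)
        r_fit = np.clip(r_fit, lo, hi)
        # winsorized variance understates the true spread; divide by the
        # normal-theory attenuation at these quantiles so the moment
        # match stays (approximately) consistent
        attenuation = _winsor_attenuation(winsor)
    m = r_fit.size
    var_r = np.mean((r_fit - r_fit.mean())**2) * m / max(m - 1, 1) / attenuation
    evar = var_r - special.polygamma(1, d / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(float(evar))
        s0_2 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_2 = np.exp(emean)
    return d0, s0_2, r


def ebayes_moderate(
    fit: CellMeansFit,
    trend: bool = True,
    robust: bool = True,
    winsor: tuple = (0.05, 0.95),
    var_floor: float = 1e-9,
) -> ModeratedFit:
    """Shrink per-probe variances toward an empirical-Bayes prior.

    ``trend=True`` makes the prior variance a lowess function of average
    expression (RPPA variance is intensity-dependent); ``robust=True``
    winsorizes the log-variance residuals before moment matching and
    gives upper-tail outlier probes an individually reduced prior df so
    hypervariable probes are not over-shrunk.
    """
    n_probes = len(fit.probe_ids)
    if n_probes < 10:
        raise ValueError("empirical-Bayes moderation needs >= 10 probes")
    d = fit.df_residual
    s2 = np.maximum(fit.s2, 0.0)
    if np.allclose(s2, s2[0]):
        # degenerate: no variance dispersion -> infinite prior df
        d0 = np.full(n_probes, np.inf)
        s0_2 = np.full(n_probes, max(float(s2[0]), var_floor))
        post = s0_2.copy()
        total = np.full(n_probes, MAX_TOTAL_DF)
        return ModeratedFit(**fit.__dict__, d0=d0, s0_2=s0_2,
                            post_var=post, total_df=total)
    cov = fit.avg_expr if trend else None
    d0_scalar, s0_2, r = _fit_f_dist(
        s2, d, covariate=cov, winsor=winsor if robust else None
    )
    s0_2 = np.maximum(s0_2, var_floor)
    d0 = np.full(n_probes, d0_scalar)
    if robust and np.isfinite(d0_scalar):
        # outlying variances (above the winsorized upper tail) get a
        # smoothly reduced prior df so they retain their own variance
        hi = np.quantile(r, winsor[1])
        scale = np.sqrt(special.polygamma(1, d / 2.0) +
                        (special.polygamma(1, d0_scalar / 2.0)
                         if np.isfinite(d0_scalar) else 0.0))
        excess = np.maximum(r - hi, 0.0) / max(scale, 1e-6)
        d0 = d0_scalar * np.exp(-excess)
        d0 = np.maximum(d0, 0.1)
    with np.errstate(invalid="ignore"):
        post = np.where(
            np.isinf(d0),
            s0_2,
            (d0 * s0_2 + d * s2) / (d0 + d),
        )
    total = np.minimum(d0 + d, MAX_TOTAL_DF)
    return ModeratedFit(**fit.__dict__, d0=d0, s0_2=s0_2,
                        post_var=post, total_df=total)


def apply_contrast(
    modfit: ModeratedFit,
    coeffs: dict,
    contrast_id: str = "contrast",
    alpha: float = 0.05,
) -> ContrastResult:
    """Estimate a linear contrast c'mu with moderated inference.

    ``coeffs`` maps group label -> coefficient (unlisted groups get 0).
    Standard error is sqrt(post_var * sum_g c_g^2 / W_g); p-values and
    the (1 - alpha) CI use the t distribution on the moderated total df.
    """
    unknown = [g for g in coeffs if g not in modfit.groups]
    if unknown:
        raise ValueError(f"contrast {contrast_id!r} references unfitted group(s): {unknown}")
    c = np.array([coeffs.get(g, 0.0) for g in modfit.groups])
    lfc = modfit.means @ c
    unscaled = np.sqrt((c**2 / modfit.group_weight_sums).sum())
    se = np.sqrt(modfit.post_var) * unscaled
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, np.where(lfc == 0, 0.0, np.inf * np.sign(lfc)))
    p = 2.0 * stats.t.sf(np.abs(t), modfit.total_df)
    fdr = adjust_bh(p)
    tq = stats.t.ppf(1.0 - alpha / 2.0, modfit.total_df)
    table = pd.DataFrame(
        {
            "lfc": lfc,
            "se": se,
            "t": t,
            "p": p,
            "fdr": fdr,
            "ci_low": lfc - tq * se,
            "ci_high": lfc + tq * se,
            "avg_expr": modfit.avg_expr,
        },
        index=pd.Index(modfit.probe_ids, name="probe_id"),
    )
    return ContrastResult(contrast_id=contrast_id, coeffs=dict(coeffs), table=table)


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN-propagating)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        if ((p[ok] < 0) | (p[ok] > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def count_de(result: ContrastResult, threshold: float = 0.05) -> tuple[int, int, int]:
    """(n_up, n_down, n_total) at FDR < threshold; lfc exactly 0 counts
    as neither direction."""
    t = result.table
    sig = t["fdr"] < threshold
    n_up = int((sig & (t["lfc"] > 0)).sum())
    n_dn = int((sig & (t["lfc"] < 0)).sum())
    return n_up, n_dn, n_up + n_dn


def directional_overlap(
    res_a: ContrastResult,
    res_b: ContrastResult,
    threshold: float = 0.05,
) -> dict:
    """Partition two DE sets by sign agreement (Venn-style counts).

    Returns up_up, down_down, opposite, only_a, only_b over the shared
    probe universe (a disjoint universe is an error).
    """
    shared = res_a.table.index.intersection(res_b.table.index)
    if len(shared) == 0:
        raise ValueError("contrasts share no probes")
    a, b = res_a.table.loc[shared], res_b.table.loc[shared]
    de_a = set(shared[(a["fdr"] < threshold) & (a["lfc"] != 0)])
    de_b = set(shared[(b["fdr"] < threshold) & (b["lfc"] != 0)])
    both = de_a & de_b
    sign_a = np.sign(a["lfc"])
    sign_b = np.sign(b["lfc"])
    up_up = sum(1 for p in both if sign_a[p] > 0 and sign_b[p] > 0)
    dn_dn = sum(1 for p in both if sign_a[p] < 0 and sign_b[p] < 0)
    return {
        "up_up": up_up,
        "down_down": dn_dn,
        "opposite": len(both) - up_up - dn_dn,
        "only_a": len(de_a - de_b),
        "only_b": len(de_b - de_a),
        "n_a": len(de_a),
        "n_b": len(de_b),
    }
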