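"""Replicate-coherence QC for two-group contrasts.

Before differential expression, each two-group comparison is screened by
PCA: silhouette widths on the components explaining >= 95% of variance
quantify replicate clustering, and a Mahalanobis distance between group
centroids in two dimensions (pooled within-class covariance) quantifies
separation. A low-coherence verdict is what triggers sample precision
weights downstream — QC informs weighting, it never deletes samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_samples

from .data import ExpressionMatrix, SampleTable

__all__ = [
    "PCAQCReport",
    "group_pca",
    "components_for_threshold",
    "silhouette_widths",
    "mahalanobis_separation",
    "qc_contrast",
]

#: Mean-silhouette cutoff below which a contrast is flagged low-coherence.
DEFAULT_COHERENCE_CUTOFF = 0.25


@dataclass
class PCAQCReport:
    contrast_id: str
    n_components_95: int
    silhouette_per_sample: pd.Series
    mean_silhouette: float
    mahalanobis_2d: float
    coherent: bool


def group_pca(matrix: ExpressionMatrix, samples: SampleTable):
    """PCA of a two-group sample subset.

    Probes are centered across the subset (no unit-variance scaling); the
    decomposition is an SVD over the sample dimension with a deterministic
    sign convention (largest-magnitude probe loading positive).

    Returns
    -------
    scores : DataFrame (samples x components)
    fractions : ndarray of explained-variance fractions summing to 1
    """
    labels = samples.data["group"]
    counts = labels.value_counts()
    if len(counts) != 2 or (counts < 2).any():
        raise ValueError("group_pca requires exactly 2 groups with >= 2 samples each")
    X = matrix.subset_samples(samples.sample_ids).data.to_numpy(dtype=float).T
    if np.isnan(X).any():
        # probes with any missing value are dropped from the QC view
        X = X[:, ~np.isnan(X).any(axis=0)]
    X = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # drop numerically-null components
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    k = max(int((s > tol).sum()), 1)
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U * s
    total = (s**2).sum()
    fractions = s**2 / total if total > 0 else np.full(k, 1.0 / k)
    cols = [f"PC{j + 1}" for j in range(k)]
    return pd.DataFrame(scores, index=samples.sample_ids, columns=cols), fractions


def components_for_threshold(fractions, threshold: float = 0.95) -> int:
    """Smallest k whose cumulative explained-variance fraction >= threshold."""
    fr = np.asarray(fractions, dtype=float)
    if fr.size == 0:
        raise ValueError("empty explained-variance fractions")
    if (fr < 0).any():
        raise ValueError("fractions must be nonnegative")
    cum = np.cumsum(fr)
    hit = np.nonzero(cum >= threshold - 1e-12)[0]
    return int(hit[0]) + 1 if hit.size else fr.size


def silhouette_widths(scores, labels) -> pd.Series:
    """Classic silhouette widths s(i) = (b - a)/max(a, b), Euclidean.

    Degenerate 0/0 (all points coincident) is defined as 0; singleton
    groups get width 0 by convention.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    index = None
    if hasattr(labels, "index"):
        index = labels.index
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires two groups")
    if np.allclose(scores, scores[0]):
        widths = np.zeros(len(labels))
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            widths = silhouette_samples(scores, labels, metric="euclidean")
        widths = np.nan_to_num(widths, nan=0.0)
    return pd.Series(widths, index=index)


def mahalanobis_separation(scores2d, labels, eps_scale: float = 1e-8) -> float:
    """Mahalanobis distance between two group centroids in 2-D.

    Uses the pooled within-class covariance; a singular pooled covariance
    is ridge-regularized by ``eps_scale * trace/2 * I``.
    """
    X = np.asarray(scores2d, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("scores2d must be samples x 2")
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError("mahalanobis_separation requires exactly 2 groups")
    parts, means, dof = [], [], 0
    for g in uniq:
        Xg = X[labels == g]
        if Xg.shape[0] < 2:
            raise ValueError("each group needs >= 2 samples")
        means.append(Xg.mean(axis=0))
        parts.append((Xg - Xg.mean(axis=0)).T @ (Xg - Xg.mean(axis=0)))
        dof += Xg.shape[0] - 1
    S = (parts[0] + parts[1]) / dof
    if np.linalg.matrix_rank(S) < 2:
        S = S + eps_scale * max(np.trace(S) / 2.0, 1.0) * np.eye(2)
    diff = means[0] - means[1]
    return float(np.sqrt(diff @ np.linalg.solve(S, diff)))


def qc_contrast(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    group_a: str,
    group_b: str,
    contrast_id: str | None = None,
    variance_threshold: float = 0.95,
    coherence_cutoff: float = DEFAULT_COHERENCE_CUTOFF,
) -> PCAQCReport:
    """Full QC for one two-group contrast.

    Silhouette widths are computed on the PCs explaining >= 95% of
    variance; Mahalanobis separation on the first two PCs. The contrast
    is low-coherence (``coherent=False``) when the mean silhouette falls
    below the cutoff or any sample has a negative width.
    """
    sub = samples.samples_in_groups([group_a, group_b])
    scores, fractions = group_pca(matrix, sub)
    k = components_for_threshold(fractions, variance_threshold)
    labels = sub.data.set_index("sample_id")["group"].loc[scores.index]
    widths = silhouette_widths(scores.iloc[:, :k].to_numpy(), labels)
    widths.index = scores.index
    k2 = min(2, scores.shape[1])
    s2d = scores.iloc[:, :2].to_numpy() if k2 == 2 else np.column_stack(
        [scores.iloc[:, 0].to_numpy(), np.zeros(len(scores))]
    )
    maha = mahalanobis_separation(s2d, labels)
    mean_w = float(widths.mean())
    coherent = bool(mean_w >= coherence_cutoff and (widths >= 0).all())
    return PCAQCReport(
        contrast_id=contrast_id or f"{group_a}-{group_b}",
        n_components_95=k,
        silhouette_per_sample=widths,
        mean_silhouette=mean_w,
        mahalanobis_2d=maha,
        coherent=coherent,
    )
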