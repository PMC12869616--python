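# Methods

This note documents the models, estimators, conventions and design
choices behind `rppashift`, and what the synthetic-data generator does
and does not emulate.

## Data model and preprocessing

The analysis operates on probe-level log2 relative protein levels as
delivered by an RPPA core after dilution-series interpolation; the
interpolation itself (and slide quantification) is upstream and out of
scope. Internally everything is log2; linear-scale input is transformed
on read.

* **Loading outliers.** Samples with the cross-slide correction factor
  CF2 < 0.25 or > 2.5 (strict inequalities) are flagged, never removed.
* **Probe filtering.** Probes on a curated exclusion list are dropped
  unless a context tag re-admits them (e.g. pericyte-relevant probes in
  a pericyte analysis context). Filtering precedes median centering by
  default so centering is computed on the analysis probe set; a
  `center_first` switch reproduces the centering-first ordering.
* **Median centering.** Each sample's median over non-missing probes is
  subtracted (idempotent, exact). Centering removes per-sample loading
  offsets; note that it also exactly removes any batch shift that is
  *uniform across probes* — the inter-batch diagnostics therefore detect
  shifts that are differential across the panel, which is how real batch
  displacement manifests after normalization.
* **Missing values.** Probes with a missing value among a contrast's
  samples are dropped for that contrast only (count logged).

## Replicate-coherence QC

For each two-group contrast, PCA (probe-centered, SVD, deterministic
sign convention) yields scores and explained-variance fractions.
Silhouette widths are computed on the smallest k components reaching
95% cumulative variance (inclusive); the Mahalanobis distance between
group centroids uses the first two components and the pooled
within-class covariance (ridge `1e-8·trace/2·I` if singular; 0/0
silhouettes are defined as 0). A contrast is flagged low-coherence when
mean silhouette < 0.25 or any width is negative; under the `auto`
weight policy that flag triggers precision-weight estimation for that
contrast. The 0.25 cutoff is a package convention: coherence was
described qualitatively in the motivating design, so the numeric
threshold is an explicit, overridable reconstruction. QC never removes
samples.

## Moderated linear models

Per probe, a cell-means model is fit by weighted least squares. With
residual variance `s^2` on `d = n − g` df and average expression `A`:

* **Hyperparameters.** `e = log s^2 − digamma(d/2) + log(d/2)` is an
  unbiased estimate of `log sigma^2`. With the trend enabled, a lowess
  curve (span 0.4) of `e` on `A` provides the location; otherwise the
  mean. The residual variance of `e` beyond `trigamma(d/2)` equals
  `trigamma(d0/2)`, inverted by Newton iteration (tolerance 1e-8) to
  give the prior df `d0`; the prior variance is
  `s0^2(A) = exp(trend(A) + digamma(d0/2) − log(d0/2))`. This moment
  matching reproduces the standard empirical-Bayes estimator exactly
  (verified against Bioconductor limma to 1e-6 on shared fixtures in
  the non-trend case).
* **Robust option.** Log-variance residuals are winsorized at the
  (0.05, 0.95) quantiles before moment matching, divided by the
  normal-theory winsorization attenuation (≈0.831 at these quantiles)
  so the matched variance stays consistent; probes beyond the upper
  winsorization limit receive a smoothly reduced per-probe `d0`
  (`d0·exp(−excess/scale)`, floored at 0.1) so hypervariable probes are
  not over-shrunk. This is a deliberate simplification of the published
  robust empirical-Bayes procedure: it targets the upper tail only and
  uses a normal-theory correction rather than winsorized-F theory.
* **Degenerate case.** If all `s^2` are identical the prior df is
  infinite: posterior variance equals the prior and the total df is
  capped at 1e6 for t quantiles.
* **Posterior.** `s~^2 = (d0·s0^2 + d·s^2)/(d0 + d)`; contrasts
  `c'mu` get `se = s~·sqrt(Σ c_g^2 / W_g)` (`W_g` the group weight sum),
  two-sided p from t on `d0 + d`, and 95% CIs from the same quantile.
  BH adjustment is per contrast, NaN-propagating.
* **Precision weights.** An iterative moment scheme estimates per-sample
  variance factors: given current weights, each sample's
  leverage-corrected standardized squared residuals are averaged over
  probes, and the weight is divided by the measured excess (damped
  exponent 0.7 to avoid oscillation at n = 3; at most 200 iterations,
  convergence tolerance 1e-3 on the weights). Weights are clamped to
  [0.05, 20] and normalized to geometric mean 1; they are estimated per
  affected contrast on that contrast's samples only. This is a
  moment-based analogue of the likelihood-based array-weight estimator;
  on simulated data it recovers a 9-fold variance inflation as a weight
  below 0.5 and stays within [0.8, 1.25] for exchangeable samples.
* **Batch is not a covariate.** Group is confounded with run by design;
  primary contrasts are within-run or explicitly differenced (the
  second-order shift), and batch health is monitored by the invariant
  probes instead.

## Composite scores

Raised-cosine ramp `r(x; a, b) = 0.5(1 − cos(pi(x−a)/(b−a)))` clipped to
[a, b]: exactly 0 at and below `a`, 1 at and above `b`. Components are
`r(|lfc|; log2 1.1, log2 1.5)` and `r(−log10 fdr; 1, 3)`; FDR exactly
0.10 therefore scores 0, FDR = 0 counts as full evidence. The signed
score is `100·sqrt(lfc_comp · fdr_comp)` carrying the fold-change sign.
The half-cosine form is the standard raised-cosine transition; only the
knot pairs are prescribed by the motivating design. Ranking for the
top-N view uses max |score| across contrasts with probe-id tie-break.

## Invariant probes and batch shifts

A total-protein probe is invariant when its within-run two-group 95% CI
(moderated) is contained in ±0.1 log2 (inclusive endpoints) in all
three two-group runs, and it is absent from the user-supplied
acute-sensitivity exclusion list (empty by default — the curated list
is an input, not derivable here). Inter-run comparisons over the
invariant set use per-probe differences of group means: two-sided
Wilcoxon signed-rank p (zeros dropped, midranks for ties; exact
subset-sum enumeration of all 2^n sign assignments for n ≤ 25, normal
approximation with tie and continuity corrections above), the median
difference, and the unscaled MAD. A comparison is notable when
p < 0.20 and |median| ≥ 0.01. Identical profiles return p = 1 by
convention. Shift matrices report all ordered pairs (antisymmetric
medians, symmetric p).

Because moderation bounds the posterior variance below by
`d0·s0^2/(d0+d)`, the CI-containment criterion can only be met when the
panel's prior variance is small (moderated sd ≲ 0.05 at n = 3); in
noisier panels the invariant set is legitimately empty and the shift
diagnostics are skipped with a warning (an error in `--strict` mode).

## Response classifier

Rules are applied in priority order to the quartet (I, Ia, L, S), with
significance gate `alpha = 0.05` and a robust tier of FDR < 0.001 plus
|fold change| > 1.5 on both L and S (all overridable via a JSON rule
file):

1. base response I must be significant (otherwise the probe belongs to
   the basal-effect pathway, which classifies perturbation-only effects
   as concordant/discordant/none from the two baseline contrasts);
2. S not significant → `no_effect`;
3. S significant and opposed to I: Ia significant and opposed →
   `reversal`; else |Ia| < |I| → `attenuation` (upgraded to
   `robust_attenuation` on the robust tier); else `ambiguous`;
4. S significant and aligned with I → `augmentation`;
5. an attenuation call with both baseline contrasts significant in I's
   direction and no significant final-level difference additionally
   carries `saturation_possible` — a co-annotation, not an exclusive
   category, since an elevated baseline and a blunted response are
   observationally entangled at a single time point.

The rules are direction-symmetric: negating every fold change preserves
the category.

## Synthetic data

The generator draws
`y[p,j] = baseline_p + group_effect(p, group_j) + batch_offset(batch_j)
+ loading_j + eps`, `eps ~ N(0, sigma_p^2/q_j)` on the log2 scale, with:

* seven treatment arms × 3 replicates in the four-run layout
  (untreated+insulin; Aβ40 arms; Aβ42 arms; vehicle alone);
* probe variances from a scaled-inverse-chi-square around an
  intensity-dependent trend (`d0 = 4`, `s0^2 = 0.003` by default, i.e.
  replicate sd ≈ 0.055 — the precision regime in which a real panel
  yields a dozen-strong invariant set; slope −0.25 per log2 unit);
* per-sample loading offsets (sd 0.15) that median centering removes,
  and per-sample quality factors exercising the precision weights;
* additive batch offsets (default: −0.15 on the vehicle-only run, the
  kind of displacement the diagnostics are built to flag);
* probe scenarios with recorded truth: insulin responses of ±1.0 log2,
  attenuation to 0.3×, sign reversal, saturation (baseline at the
  stimulated level), low-noise invariant anchors (sd 0.02,
  total-protein), batch-sensitive probes, and nulls. Response
  directions alternate within each scenario so the panel stays
  direction-balanced — necessary for median centering to remain
  unbiased, and true to the mixed up/down responses of real signaling
  panels;
* an optional heavy-tail contamination mixture (9× variance) to
  exercise robust moderation.

A single integer seed fully determines the output. The generator does
**not** emulate dilution-series nonlinearity, spatial slide artifacts,
antibody cross-reactivity, or intensity-dependent (non-additive) batch
effects; passing tests therefore validate the statistical machinery
under the stated generative assumptions, not RPPA chemistry.

Two consequences of the generative model are worth knowing. A uniform
additive batch offset is removed exactly by median centering, so offset-
recovery checks measure shifts on the un-centered matrix. And median
centering itself injects a small shared per-sample noise (the sampling
error of a 268-probe median, sd ≈ 0.02 here), which mildly correlates
probes within a contrast — visible as seed-to-seed wobble in the
invariant-probe screen, exactly as in real normalized panels.

## Problem sizes and numerical conventions in the test suite

Calibration uses 20 independent null datasets of 500 probes (10,000
probe×replication draws) for type-I error (0.05 ± 0.01) and CI coverage
(95% ± 2%); hyperparameter recovery uses 200 probes; weight recovery
500 probes; classifier recovery ~216 scenario probes at replicate sd
0.15 (accuracy ≥ 90% per scenario, counting `robust_attenuation` as a
correct call for attenuated truth, since it is a sub-tier of
attenuation); exact Wilcoxon is checked against full 2^n enumeration
for n ≤ 10 and against scipy in tie-free cases. Probe identifiers are
case-sensitive opaque strings throughout; CI bound endpoints are
inclusive; lfc exactly 0 counts as neither up nor down.

## Known limitations

* The robust moderation is a documented simplification (upper-tail
  only, normal-theory winsorization correction); its `d0` is not
  numerically identical to the published robust estimator, though the
  non-robust path is.
* Precision weights use a moment scheme, not REML; with only 4 residual
  df per contrast their sampling error is substantial, which is why
  they are gated on the QC flag rather than always applied.
* The invariant-probe screen inherits the moderated prior: in
  high-noise panels it is empty by construction rather than by failure.
* Single-time-point designs cannot distinguish saturation from genuine
  attenuation; the classifier deliberately reports that ambiguity as a
  co-annotation instead of resolving it.
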