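import subprocess
import shutil

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rppashift as rs
from rppashift import linmod
from rppashift.linmod import (
    adjust_bh,
    apply_contrast,
    count_de,
    design_from_samples,
    directional_overlap,
    ebayes_moderate,
    estimate_sample_weights,
    fit_cellmeans,
)

from conftest import make_contrast_result


def _matrix(vals, n_samples=None):
    vals = np.asarray(vals, dtype=float)
    if vals.ndim == 1:
        vals = vals[None, :]
    return rs.ExpressionMatrix(pd.DataFrame(
        vals, index=[f"p{i}" for i in range(vals.shape[0])],
        columns=[f"s{i}" for i in range(vals.shape[1])]))


class TestFitCellMeans:
    def test_exact_means_and_zero_variance(self, two_group_samples):
        mat = _matrix([[1, 1, 1, 3, 3, 3]] * 12)
        design = design_from_samples(two_group_samples, groups=["a", "b"])
        fit = fit_cellmeans(mat, design)
        np.testing.assert_allclose(fit.means, [[1, 3]] * 12)
        np.testing.assert_allclose(fit.s2, 0.0, atol=1e-14)
        assert fit.df_residual == 4

    def test_weight_scale_invariance_of_means(self, small_matrix, two_group_samples):
        d1 = design_from_samples(two_group_samples, groups=["a", "b"])
        d2 = design_from_samples(two_group_samples, groups=["a", "b"],
                                 weights=np.full(6, 2.0))
        f1 = fit_cellmeans(small_matrix, d1)
        f2 = fit_cellmeans(small_matrix, d2)
        np.testing.assert_allclose(f1.means, f2.means, atol=1e-12)

    def test_means_match_weighted_average_oracle(self, rng, two_group_samples):
        vals = rng.normal(size=(30, 6))
        w = rng.uniform(0.5, 2.0, 6)
        design = design_from_samples(two_group_samples, groups=["a", "b"], weights=w)
        fit = fit_cellmeans(_matrix(vals), design)
        expect_a = (vals[:, :3] * w[:3]).sum(axis=1) / w[:3].sum()
        expect_b = (vals[:, 3:] * w[3:]).sum(axis=1) / w[3:].sum()
        np.testing.assert_allclose(fit.means[:, 0], expect_a, rtol=1e-10)
        np.testing.assert_allclose(fit.means[:, 1], expect_b, rtol=1e-10)


class TestModeration:
    def _fit(self, rng, n=60, sd=0.3):
        vals = rng.normal(0, sd, size=(n, 6)) + rng.uniform(-2, 2, n)[:, None]
        samples = rs.SampleTable(pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(6)],
            "group": ["a"] * 3 + ["b"] * 3, "batch": "x",
            "replicate": [1, 2, 3] * 2, "cf1": 1.0, "cf2": 1.0}))
        design = design_from_samples(samples, groups=["a", "b"])
        return fit_cellmeans(_matrix(vals), design)

    def test_zero_prior_df_recovers_classical_t(self, rng):
        fit = self._fit(rng)
        n = len(fit.probe_ids)
        mod = linmod.ModeratedFit(**fit.__dict__, d0=np.zeros(n),
                                  s0_2=np.full(n, 0.01),
                                  post_var=fit.s2.copy(),
                                  total_df=np.full(n, float(fit.df_residual)))
        res = apply_contrast(mod, {"b": 1, "a": -1})
        # classical two-sample pooled t per probe
        diff = fit.means[:, 1] - fit.means[:, 0]
        se = np.sqrt(fit.s2 * (1 / 3 + 1 / 3))
        t_classic = diff / se
        p_classic = 2 * stats.t.sf(np.abs(t_classic), fit.df_residual)
        np.testing.assert_allclose(res.table["t"].values, t_classic, atol=1e-10)
        np.testing.assert_allclose(res.table["p"].values, p_classic, atol=1e-10)

    def test_infinite_prior_df_collapses_to_prior_variance(self, rng):
        fit = self._fit(rng)
        fit.s2[:] = fit.s2[0]  # degenerate: all variances identical
        mod = ebayes_moderate(fit, trend=False, robust=False)
        assert np.isinf(mod.d0).all() or (mod.d0 > 1e4).all()
        np.testing.assert_allclose(mod.post_var, mod.s0_2, rtol=1e-9)

    def test_posterior_variance_is_convex_combination(self, rng):
        fit = self._fit(rng, n=120)
        mod = ebayes_moderate(fit, trend=True, robust=True)
        lo = np.minimum(fit.s2, mod.s0_2)
        hi = np.maximum(fit.s2, mod.s0_2)
        assert ((mod.post_var >= lo - 1e-12) & (mod.post_var <= hi + 1e-12)).all()
        # shrinkage identity
        expect = (mod.d0 * mod.s0_2 + fit.df_residual * fit.s2) / (mod.d0 + fit.df_residual)
        np.testing.assert_allclose(mod.post_var, expect, rtol=1e-9)

    def test_hyperparameter_recovery_from_known_hierarchy(self):
        # variances drawn from the scaled-inverse-chi-square model the
        # moderation assumes: d0 and s0^2 must be recovered
        rng = np.random.default_rng(42)
        n, d, d0_true, s0_true = 200, 4, 4.0, 0.02
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, n)
        s2 = sigma2 * rng.chisquare(d, n) / d
        d0_hat, s0_hat, _ = linmod._fit_f_dist(s2, d)
        assert 2.0 <= d0_hat <= 8.0
        assert s0_true / 1.5 <= np.median(s0_hat) <= s0_true * 1.5

    def test_matches_limma_oracle(self, rng, tmp_path):
        # independent oracle: Bioconductor limma on the same 80-probe fit
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng2 = np.random.default_rng(12345)
        y = rng2.normal(0, 0.3, size=(80, 6)) + rng2.uniform(-2, 2, 80)[:, None]
        ypath = tmp_path / "y.csv"
        pd.DataFrame(y, index=[f"p{i}" for i in range(80)],
                     columns=[f"s{i}" for i in range(6)]).to_csv(ypath)
        script = tmp_path / "limma.R"
        script.write_text(f"""
suppressMessages(library(limma))
y <- as.matrix(read.csv("{ypath}", row.names=1))
design <- model.matrix(~0+factor(rep(c("a","b"), each=3)))
colnames(design) <- c("a","b")
fit <- lmFit(y, design)
fit2 <- contrasts.fit(fit, makeContrasts(b-a, levels=design))
eb <- eBayes(fit2, trend=FALSE, robust=FALSE)
write.csv(data.frame(t=eb$t[,1], p=eb$p.value[,1], d0=eb$df.prior), "{tmp_path}/out.csv")
""")
        try:
            subprocess.run(["Rscript", str(script)], check=True, capture_output=True,
                           timeout=120)
        except (subprocess.CalledProcessError, subprocess.TimeoutExpired):
            pytest.skip("limma not runnable in this environment")
        ref = pd.read_csv(tmp_path / "out.csv", index_col=0)
        # refit on the exact same matrix
        samples = rs.SampleTable(pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(6)],
            "group": ["a"] * 3 + ["b"] * 3, "batch": "x",
            "replicate": [1, 2, 3] * 2, "cf1": 1.0, "cf2": 1.0}))
        design = design_from_samples(samples, groups=["a", "b"])
        fit2 = fit_cellmeans(_matrix(y), design)
        mod2 = ebayes_moderate(fit2, trend=False, robust=False)
        res2 = apply_contrast(mod2, {"b": 1, "a": -1})
        assert mod2.d0[0] == pytest.approx(ref["d0"].iloc[0], abs=1e-6)
        np.testing.assert_allclose(res2.table["t"].values, ref["t"].values, atol=1e-8)
        np.testing.assert_allclose(res2.table["p"].values, ref["p"].values, atol=1e-8)


class TestSampleWeights:
    def test_homoscedastic_weights_stay_near_one(self):
        cfg = rs.SimulationConfig(n_probes=500, n_phospho=100,
                                  scenario_fractions={}, batch_offsets={},
                                  loading_offset_sd=0.0, trend_slope=0.0)
        mat, samples, _, _ = rs.generate_dataset(cfg, seed=5)
        sub = samples.samples_in_groups(["insulin", "untreated"])
        design = design_from_samples(sub, groups=["insulin", "untreated"])
        w, _ = estimate_sample_weights(mat, design)
        assert (w >= 0.8).all() and (w <= 1.25).all()

    def test_noisy_sample_is_downweighted(self):
        cfg = rs.SimulationConfig(n_probes=500, n_phospho=100,
                                  scenario_fractions={}, batch_offsets={},
                                  loading_offset_sd=0.0, trend_slope=0.0,
                                  sample_quality_factors={"insulin_2": 1 / 9.0})
        mat, samples, _, _ = rs.generate_dataset(cfg, seed=6)
        sub = samples.samples_in_groups(["insulin", "untreated"])
        design = design_from_samples(sub, groups=["insulin", "untreated"])
        w, _ = estimate_sample_weights(mat, design)
        w = pd.Series(w, index=design.sample_ids)
        assert w["insulin_2"] < 0.5
        assert w.drop("insulin_2").min() > w["insulin_2"]

    def test_geometric_mean_is_one(self, small_matrix, two_group_samples):
        design = design_from_samples(two_group_samples, groups=["a", "b"])
        w, _ = estimate_sample_weights(small_matrix, design)
        assert np.exp(np.mean(np.log(w))) == pytest.approx(1.0, abs=1e-6)


class TestContrasts:
    def test_second_order_contrast_arithmetic(self):
        # group means (unt=0, ins=2, ab=0, ab_ins=1):
        # S = (ab_ins - ab) - (ins - unt) = 1 - 2 = -1
        groups = ["untreated", "insulin", "ab40", "ab40_insulin"]
        n = 12
        fit = linmod.CellMeansFit(
            groups=groups, probe_ids=[f"p{i}" for i in range(n)],
            means=np.tile([0.0, 2.0, 0.0, 1.0], (n, 1)),
            s2=np.full(n, 0.04), df_residual=8, avg_expr=np.zeros(n),
            group_weight_sums=np.full(4, 3.0))
        mod = linmod.ModeratedFit(**fit.__dict__, d0=np.zeros(n),
                                  s0_2=np.full(n, 0.04), post_var=fit.s2.copy(),
                                  total_df=np.full(n, 8.0))
        coeffs = {"ab40_insulin": 1, "ab40": -1, "insulin": -1, "untreated": 1}
        res = apply_contrast(mod, coeffs, "S")
        np.testing.assert_allclose(res.table["lfc"].values, -1.0)
        assert sum(coeffs.values()) == 0
        # balanced design closed-form se: sigma * sqrt(sum c^2 / 3)
        expect_se = 0.2 * np.sqrt(4 / 3)
        np.testing.assert_allclose(res.table["se"].values, expect_se, rtol=1e-12)

    def test_unknown_group_is_an_error(self, rng):
        fit = TestModeration()._fit(rng)
        mod = ebayes_moderate(fit, trend=False, robust=False)
        with pytest.raises(ValueError, match="nope"):
            apply_contrast(mod, {"nope": 1, "a": -1})

    def test_ci_brackets_estimate(self, rng):
        fit = TestModeration()._fit(rng)
        mod = ebayes_moderate(fit, trend=False, robust=False)
        res = apply_contrast(mod, {"b": 1, "a": -1})
        t = res.table
        assert ((t["ci_low"] <= t["lfc"]) & (t["lfc"] <= t["ci_high"])).all()
        assert (t["fdr"] >= t["p"] - 1e-15).all()


class TestBH:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_bh([0.03]), [0.03])

    def test_step_up_example(self):
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.04]),
                                   [0.03, 0.03, 0.04], rtol=1e-12)

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(adjust_bh([0.2, 0.2, 0.2]), [0.2] * 3)

    def test_nan_propagates_without_counting(self):
        out = adjust_bh([0.01, np.nan, 0.02, 0.04])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2, 3]], [0.03, 0.03, 0.04], rtol=1e-12)

    def test_pointwise_dominates_and_permutation_invariant(self, rng):
        p = rng.uniform(size=40)
        out = adjust_bh(p)
        assert (out >= p - 1e-15).all() and (out <= 1.0).all()
        perm = rng.permutation(40)
        np.testing.assert_allclose(adjust_bh(p[perm]), out[perm], rtol=1e-12)


class TestCountsAndOverlap:
    def test_empty_and_total_identity(self):
        res = make_contrast_result(["a", "b"], [1.0, -1.0], [0.5, 0.9])
        assert count_de(res) == (0, 0, 0)
        res2 = make_contrast_result(["a", "b", "c"], [1.0, -1.0, 0.0],
                                    [0.01, 0.01, 0.01])
        u, d, t = count_de(res2)
        assert (u, d) == (1, 1)
        assert t == u + d  # zero-lfc probe counts as neither

    def test_known_truth_simulation_recovers_up_count(self):
        cfg = rs.SimulationConfig(
            n_probes=210, n_phospho=60,
            scenario_fractions={"insulin_up": 10 / 210},
            batch_offsets={}, loading_offset_sd=0.0, trend_slope=0.0,
            var_s0_2=0.01, var_d0=None)
        mat, samples, _, truth = rs.generate_dataset(cfg, seed=3)
        sub = samples.samples_in_groups(["insulin", "untreated"])
        design = design_from_samples(sub, groups=["insulin", "untreated"])
        fit = fit_cellmeans(mat, design)
        mod = ebayes_moderate(fit, trend=False, robust=False)
        res = apply_contrast(mod, {"insulin": 1, "untreated": -1})
        u, d, t = count_de(res)
        n_true = int((truth["scenario"] == "insulin_up").sum())
        assert abs(t - n_true) <= 1

    def test_overlap_identical_and_negated(self):
        ids = [f"p{i}" for i in range(10)]
        lfc = np.linspace(-1, 1, 10)
        fdr = np.array([0.01] * 5 + [0.5] * 5)
        a = make_contrast_result(ids, lfc, fdr, "A")
        same = directional_overlap(a, a)
        n_de = int(((fdr < 0.05) & (lfc != 0)).sum())
        assert same["up_up"] + same["down_down"] == n_de
        assert same["opposite"] == 0
        b = make_contrast_result(ids, -lfc, fdr, "B")
        opp = directional_overlap(a, b)
        assert opp["opposite"] == n_de
        assert opp["up_up"] == opp["down_down"] == 0

    def test_overlap_matches_set_arithmetic(self, rng):
        ids = [f"p{i}" for i in range(50)]
        a = make_contrast_result(ids, rng.normal(size=50), rng.uniform(size=50), "A")
        b = make_contrast_result(ids, rng.normal(size=50), rng.uniform(size=50), "B")
        ov = directional_overlap(a, b)
        de_a = {p for p in ids if a.table.loc[p, "fdr"] < 0.05}
        de_b = {p for p in ids if b.table.loc[p, "fdr"] < 0.05}
        both = de_a & de_b
        up_up = sum(1 for p in both
                    if a.table.loc[p, "lfc"] > 0 and b.table.loc[p, "lfc"] > 0)
        assert ov["up_up"] == up_up
        assert ov["only_a"] == len(de_a - de_b)
        assert ov["only_b"] == len(de_b - de_a)

    def test_disjoint_universes_error(self):
        a = make_contrast_result(["x"], [1.0], [0.01])
        b = make_contrast_result(["y"], [1.0], [0.01])
        with pytest.raises(ValueError):
            directional_overlap(a, b)
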