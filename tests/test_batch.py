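from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rppashift as rs
from rppashift.batch import (
    find_invariant_probes,
    interbatch_shift,
    shift_matrix,
    wilcoxon_signed_rank,
)

from conftest import make_contrast_result


def _annot(probe_ids, phospho=()):
    return rs.ProbeAnnotation(pd.DataFrame({
        "probe_id": probe_ids,
        "target_name": probe_ids,
        "phospho_site": ["S1" if p in phospho else "" for p in probe_ids],
        "excluded": False,
    }))


def _batch_results(ci_by_probe):
    """ci_by_probe: probe -> list of 3 (lfc, lo, hi) tuples."""
    out = {}
    for b in range(3):
        ids = list(ci_by_probe)
        lfc = [ci_by_probe[p][b][0] for p in ids]
        lo = [ci_by_probe[p][b][1] for p in ids]
        hi = [ci_by_probe[p][b][2] for p in ids]
        out[f"run{b + 1}"] = make_contrast_result(
            ids, lfc, [0.5] * len(ids), f"run{b + 1}",
            ci_low=np.array(lo), ci_high=np.array(hi))
    return out


class TestInvariantSelection:
    def test_containment_in_all_batches_required(self):
        tight = [(0.0, -0.05, 0.05)] * 3
        loose = [(0.0, -0.05, 0.05)] * 2 + [(0.03, -0.05, 0.12)]
        res = _batch_results({"keep": tight, "drop": loose})
        inv = find_invariant_probes(res, _annot(["keep", "drop"]))
        assert inv.probe_ids == ["keep"]

    def test_bound_is_inclusive(self):
        res = _batch_results({"edge": [(0.0, -0.1, 0.1)] * 3})
        inv = find_invariant_probes(res, _annot(["edge"]))
        assert inv.probe_ids == ["edge"]

    def test_phospho_probes_never_qualify(self):
        res = _batch_results({"ph": [(0.0, -0.05, 0.05)] * 3})
        inv = find_invariant_probes(res, _annot(["ph"], phospho={"ph"}))
        assert inv.probe_ids == []

    def test_sensitivity_list_excludes_qualifying_probe(self):
        res = _batch_results({"amp": [(0.0, -0.05, 0.05)] * 3,
                              "ok": [(0.0, -0.05, 0.05)] * 3})
        inv = find_invariant_probes(res, _annot(["amp", "ok"]),
                                    sensitivity_list=["amp"])
        assert inv.probe_ids == ["ok"]
        assert inv.excluded_for_ab_sensitivity == ["amp"]

    def test_membership_monotone_in_bound(self, rng):
        ci = {}
        for i in range(40):
            tuples = []
            for _ in range(3):
                c = rng.normal(0, 0.05)
                h = rng.uniform(0.01, 0.1)
                tuples.append((c, c - h, c + h))
            ci[f"p{i:02d}"] = tuples
        res = _batch_results(ci)
        annot = _annot(list(ci))
        tight = set(find_invariant_probes(res, annot, bound=0.05).probe_ids)
        loose = set(find_invariant_probes(res, annot, bound=0.1).probe_ids)
        assert tight <= loose

    def test_missing_ci_columns_error(self):
        res = {"run1": make_contrast_result(["p"], [0.0], [0.5])}
        res["run1"].table.drop(columns=["ci_low"], inplace=True)
        with pytest.raises(ValueError, match="ci_low"):
            find_invariant_probes(res, _annot(["p"]))


class TestWilcoxon:
    def test_all_positive_n5(self):
        # all five signs positive: 2 of 32 assignments as extreme
        assert wilcoxon_signed_rank([0.02, 0.03, 0.05, 0.04, 0.06]) == pytest.approx(0.0625)

    def test_all_same_sign_n6(self):
        assert wilcoxon_signed_rank([-1, -2, -3, -4, -5, -6]) == pytest.approx(2 / 64)

    def test_single_nonzero_difference(self):
        assert wilcoxon_signed_rank([0.7]) == 1.0

    def test_symmetric_pairs_give_one(self):
        assert wilcoxon_signed_rank([-0.3, 0.3]) == 1.0

    def test_all_zero_returns_one(self):
        assert wilcoxon_signed_rank([0.0, 0.0]) == 1.0

    @pytest.mark.parametrize("n", range(3, 11))
    def test_matches_full_enumeration(self, n):
        rng = np.random.default_rng(n)
        d = rng.normal(0, 1, n)
        mask = rng.random(n) < 0.4
        d[mask] = np.round(d[mask], 1)  # induce ties (midranks)
        d = d[d != 0]
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        ws = [sum(r for r, s in zip(ranks, signs) if s)
              for signs in product([False, True], repeat=len(d))]
        ws = np.array(ws)
        p_le = np.mean(ws <= w_obs + 1e-9)
        p_ge = np.mean(ws >= w_obs - 1e-9)
        expect = min(1.0, 2 * min(p_le, p_ge))
        assert wilcoxon_signed_rank(d) == pytest.approx(expect, abs=1e-12)

    def test_agrees_with_scipy_without_ties(self):
        rng = np.random.default_rng(17)
        d = rng.normal(0, 1, 12)
        ours = wilcoxon_signed_rank(d)
        ref = stats.wilcoxon(d, alternative="two-sided", method="exact").pvalue
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_large_n_normal_approximation_is_close(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.2, 1, 60)
        p_approx = wilcoxon_signed_rank(d)
        ref = stats.wilcoxon(d, alternative="two-sided", correction=True,
                             method="approx").pvalue
        assert p_approx == pytest.approx(ref, rel=0.05)


class TestShifts:
    def _dataset(self, offset=0.0):
        cfg = rs.SimulationConfig(
            n_probes=400, n_phospho=62,
            scenario_fractions={"invariant_anchor": 0.2},
            batch_offsets={"run4": offset},
            loading_offset_sd=0.0, trend_slope=0.0,
            var_s0_2=0.0025, var_d0=None, anchor_sd=0.02)
        return rs.generate_dataset(cfg, seed=9)

    def _invariants(self, truth):
        ids = list(truth.index[truth["scenario"] == "invariant_anchor"])
        return rs.InvariantSet(probe_ids=ids, ci_table=pd.DataFrame())

    def test_identical_profiles_are_null(self):
        mat, samples, _, truth = self._dataset()
        inv = self._invariants(truth)
        df = mat.data.copy()
        df[[f"vehicle_{i}" for i in (1, 2, 3)]] = df[
            [f"untreated_{i}" for i in (1, 2, 3)]].values
        clone = rs.ExpressionMatrix(df)
        s = interbatch_shift(clone, samples, inv, "vehicle", "untreated")
        assert s.median_lfc == 0.0
        assert s.mad == 0.0
        assert s.wilcoxon_p == 1.0
        assert not s.notable

    def test_median_and_mad_by_hand(self):
        diffs = np.array([-1.0, 0.0, 1.0, 2.0, 4.0])
        med = np.median(diffs)
        mad = np.median(np.abs(diffs - med))
        assert med == 1.0 and mad == 1.0  # oracle for the unscaled MAD

    def test_injected_offset_recovered(self):
        mat, samples, _, truth = self._dataset(offset=-0.15)
        inv = self._invariants(truth)
        table = shift_matrix(mat, samples, inv,
                             ["untreated", "ab40", "ab42", "vehicle"])
        veh = table[(table.row_group == "vehicle") & ~table["self"]]
        assert np.allclose(veh["median"], -0.15, atol=0.03)
        assert veh["notable"].all()

    def test_antisymmetry_and_symmetric_p(self):
        mat, samples, _, truth = self._dataset(offset=-0.1)
        inv = self._invariants(truth)
        t = shift_matrix(mat, samples, inv, ["untreated", "vehicle"])
        t = t.set_index(["row_group", "col_group"])
        ab = t.loc[("untreated", "vehicle")]
        ba = t.loc[("vehicle", "untreated")]
        assert ab["median"] == -ba["median"]
        assert ab["p"] == ba["p"]

    def test_notable_flag_calibration_under_null(self):
        # no batch shifts: the notable flag should fire rarely
        mat, samples, _, truth = self._dataset(offset=0.0)
        inv = self._invariants(truth)
        t = shift_matrix(mat, samples, inv,
                         ["untreated", "ab40", "ab42", "vehicle"])
        off_diag = t[~t["self"]]
        assert off_diag["notable"].mean() <= 0.20

    def test_empty_invariant_set_is_an_error(self):
        mat, samples, _, _ = self._dataset()
        inv = rs.InvariantSet(probe_ids=[], ci_table=pd.DataFrame())
        with pytest.raises(ValueError):
            interbatch_shift(mat, samples, inv, "vehicle", "untreated")
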