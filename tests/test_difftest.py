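import numpy as np
import pandas as pd
import pytest
from scipy.stats import ttest_ind

from surfaceome import (
    GroupedMatrix,
    ImputationParams,
    SamParams,
    impute,
    preprocess,
    run_differential,
    sam_test,
)

from conftest import make_table


def grouped(values, groups, group_names=None):
    """GroupedMatrix from a 2-D array and a sample->group mapping."""
    df = pd.DataFrame(
        values,
        columns=list(groups),
        index=[f"P{i:04d}" for i in range(len(values))],
    )
    names = group_names or tuple(dict.fromkeys(groups.values()))
    return GroupedMatrix(df, dict(groups), tuple(names))


def six_samples(n, rng, loc1=30.0, loc2=30.0, sd=1.0):
    X = np.column_stack(
        [rng.normal(loc1, sd, (n, 3)), rng.normal(loc2, sd, (n, 3))]
    )
    groups = {f"a{i}": "g1" for i in range(3)} | {f"b{i}": "g2" for i in range(3)}
    return grouped(X, groups)


class TestPreprocess:
    def _table(self):
        exps = ("a1", "a2", "a3", "b1", "b2", "b3")
        rows = [
            # detected 3/3 in group1, 0/3 in group2
            ("P1", 100, 1, 1, [1e9] * 6, [1e9, 1e9, 1e9, 0, 0, 0], ""),
            # detected 2/3 in both groups
            ("P2", 100, 1, 1, [1e9] * 6, [1e9, 1e9, 0, 1e9, 1e9, 0], ""),
            # complete
            ("P3", 100, 1, 1, [1e9] * 6, [1e9] * 6, ""),
            # flagged: must vanish before any counting
            ("P4", 100, 1, 1, [1e9] * 6, [1e9] * 6, "reverse"),
        ]
        return make_table(rows, experiments=exps)

    def _groups(self):
        return {s: ("g1" if s.startswith("a") else "g2")
                for s in ("a1", "a2", "a3", "b1", "b2", "b3")}

    def test_one_group_rule_retains_half_detected(self):
        gm = preprocess(self._table(), self._groups(), min_valid=3)
        assert list(gm.data.index) == ["P1", "P3"]

    def test_all_group_rule_requires_both(self):
        gm = preprocess(self._table(), self._groups(), min_valid=3, require_in="all")
        assert list(gm.data.index) == ["P3"]

    def test_values_are_log2(self):
        gm = preprocess(self._table(), self._groups(), min_valid=3)
        assert gm.data.loc["P3", "a1"] == pytest.approx(np.log2(1e9))
        assert np.isnan(gm.data.loc["P1", "b1"])

    def test_missing_sample_named_in_error(self):
        groups = self._groups() | {"zz": "g1"}
        with pytest.raises(ValueError, match="zz"):
            preprocess(self._table(), groups)

    def test_needs_exactly_two_groups(self):
        groups = {s: g for s, g in self._groups().items()} | {"b3": "g3"}
        with pytest.raises(ValueError, match="2 groups"):
            preprocess(self._table(), groups)


class TestImpute:
    def test_complete_matrix_unchanged(self):
        rng = np.random.default_rng(0)
        gm = six_samples(50, rng)
        out = impute(gm, ImputationParams(seed=1))
        pd.testing.assert_frame_equal(out.data, gm.data)

    def test_same_seed_reproduces_bitwise(self):
        rng = np.random.default_rng(0)
        gm = six_samples(200, rng)
        gm.data.iloc[::5, 0] = np.nan
        a = impute(gm, ImputationParams(seed=7)).data
        b = impute(gm, ImputationParams(seed=7)).data
        pd.testing.assert_frame_equal(a, b)
        c = impute(gm, ImputationParams(seed=8)).data
        assert not a.equals(c)

    def test_observed_cells_untouched(self):
        rng = np.random.default_rng(0)
        gm = six_samples(100, rng)
        mask = gm.data.copy()
        gm.data.iloc[:30, 2] = np.nan
        out = impute(gm, ImputationParams(seed=3))
        obs = ~gm.data.isna()
        assert np.allclose(out.data.values[obs.values], mask.values[obs.values])

    def test_downshifted_mean_monte_carlo(self):
        # observed column: mean 30, sd 2 -> imputed mean ~ 30 - 1.8*2 = 26.4
        rng = np.random.default_rng(4)
        n_obs, n_miss = 10000, 10000
        col = np.concatenate([rng.normal(30, 2, n_obs), np.full(n_miss, np.nan)])
        X = np.column_stack([col, rng.normal(30, 2, n_obs + n_miss)])
        gm = grouped(X, {"s1": "g1", "s2": "g2"})
        out = impute(gm, ImputationParams(seed=5))
        imputed = out.data.iloc[n_obs:, 0]
        obs = pd.Series(col[:n_obs])
        expected = obs.mean() - 1.8 * obs.std(ddof=1)
        assert imputed.mean() == pytest.approx(expected, abs=0.1)
        assert imputed.mean() == pytest.approx(26.4, abs=0.1)
        assert imputed.std(ddof=1) == pytest.approx(0.3 * obs.std(ddof=1), rel=0.05)

    def test_column_with_one_observation_errors(self):
        X = np.array([[1.0, 1.0], [np.nan, 1.0], [np.nan, 1.0]])
        gm = grouped(X, {"s1": "g1", "s2": "g2"})
        with pytest.raises(ValueError, match="fewer than 2"):
            impute(gm)


class TestSamTest:
    def test_s0_zero_equals_classical_t(self):
        rng = np.random.default_rng(1)
        gm = six_samples(300, rng, loc1=30, loc2=29)
        res = sam_test(gm, SamParams(s0=0.0, fdr=0.05, seed=0))
        X = gm.data
        t_ref = ttest_ind(X.iloc[:, :3], X.iloc[:, 3:], axis=1, equal_var=True).statistic
        assert np.allclose(res.table["d"].values, t_ref, atol=1e-10)

    def test_swapping_groups_negates_d_same_calls(self):
        rng = np.random.default_rng(2)
        gm = six_samples(200, rng, loc1=31, loc2=30)
        swapped = GroupedMatrix(
            gm.data.copy(), dict(gm.groups), (gm.group_names[1], gm.group_names[0])
        )
        a = sam_test(gm, SamParams(s0=0.5, fdr=0.05, seed=0))
        b = sam_test(swapped, SamParams(s0=0.5, fdr=0.05, seed=0))
        assert np.allclose(a.table["d"].values, -b.table["d"].values)
        assert (a.table["significant"] == b.table["significant"]).all()
        sig = a.table[a.table["significant"]]
        assert set(sig["side"]) <= {"g1"}  # true shift is in group 1

    def test_location_shift_invariance(self):
        rng = np.random.default_rng(3)
        gm = six_samples(100, rng, loc1=31, loc2=30)
        shifted = GroupedMatrix(gm.data + 5.0, dict(gm.groups), gm.group_names)
        a = sam_test(gm, SamParams(seed=0))
        b = sam_test(shifted, SamParams(seed=0))
        assert np.allclose(a.table["d"].values, b.table["d"].values)

    def test_constant_data_yields_no_calls(self):
        X = np.full((50, 6), 30.0)
        X += np.arange(50)[:, None] * 0.001  # distinct rows, identical groups
        groups = {f"a{i}": "g1" for i in range(3)} | {f"b{i}": "g2" for i in range(3)}
        res = sam_test(grouped(X, groups), SamParams(s0=0.1, fdr=0.25, seed=0))
        assert res.table["significant"].sum() == 0
        assert res.cutoff is None

    def test_incomplete_matrix_rejected(self):
        rng = np.random.default_rng(4)
        gm = six_samples(10, rng)
        gm.data.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            sam_test(gm)

    def test_single_sample_groups_rejected(self):
        X = np.random.default_rng(0).normal(30, 1, (10, 2))
        gm = grouped(X, {"s1": "g1", "s2": "g2"})
        with pytest.raises(ValueError, match="2 samples"):
            sam_test(gm)

    def test_threshold_curve_symmetric_and_outside_calls(self):
        rng = np.random.default_rng(5)
        gm = six_samples(400, rng, loc1=33, loc2=30, sd=0.5)
        res = sam_test(gm, SamParams(s0=0.2, fdr=0.05, seed=0))
        assert res.table["significant"].sum() > 0
        curve = res.threshold_curve
        x = curve["difference"].values
        y = curve["neg_log10_p"].values
        assert np.allclose(sorted(x), sorted(-x))  # symmetric about 0
        assert np.allclose(y[: len(y) // 2][::-1], y[len(y) // 2:])

    def test_permutation_sampling_is_seeded(self):
        rng = np.random.default_rng(6)
        n = 14  # C(14,7) = 3432 > max_enumerate -> sampling path
        X = rng.normal(30, 1, (100, n))
        groups = {f"s{i}": ("g1" if i < 7 else "g2") for i in range(n)}
        gm = grouped(X, groups)
        a = sam_test(gm, SamParams(seed=11, n_permutations=50))
        b = sam_test(gm, SamParams(seed=11, n_permutations=50))
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.n_permutations_used == 50


class TestRunDifferential:
    def _spiked_table(self, seed=0):
        rng = np.random.default_rng(seed)
        exps = tuple(f"a{i}" for i in range(3)) + tuple(f"b{i}" for i in range(3))
        rows = []
        for i in range(120):
            base = 2.0 ** rng.normal(30, 1)
            shift = 8.0 if i < 10 else 1.0  # first 10 proteins 8-fold up in group1
            vals1 = base * shift * 2 ** rng.normal(0, 0.2, 3)
            vals2 = base * 2 ** rng.normal(0, 0.2, 3)
            lfq = list(vals1) + list(vals2)
            rows.append((f"P{i:04d}", 100, 1, 1, lfq, lfq, ""))
        return make_table(rows, experiments=exps), {
            e: ("g1" if e.startswith("a") else "g2") for e in exps
        }

    def test_recovers_planted_shifts_with_report(self):
        table, groups = self._spiked_table()
        res, report = run_differential(
            table, groups, sam=SamParams(s0=0.5, fdr=0.05, seed=1)
        )
        sig = set(res.table[res.table["significant"]].index)
        planted = {f"P{i:04d}" for i in range(10)}
        assert planted <= sig
        assert len(sig - planted) <= 2
        assert report["n_tested"] == 120
        assert report["sam"]["n_permutations_used"] == 18

    def test_missing_group_label_errors(self):
        table, groups = self._spiked_table()
        groups["nope"] = "g1"
        with pytest.raises(ValueError, match="nope"):
            run_differential(table, groups)

    def test_rerun_is_deterministic(self):
        table, groups = self._spiked_table()
        r1, _ = run_differential(table, groups, sam=SamParams(seed=2))
        r2, _ = run_differential(table, groups, sam=SamParams(seed=2))
        pd.testing.assert_frame_equal(r1.table, r2.table)
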