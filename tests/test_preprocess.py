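import math

import numpy as np
import pytest
from scipy import stats

from omicshape.model import Condition, ConfigurationError, OmicsLayer, Scale
from omicshape.preprocess import (
    FilterMode,
    ImputationParams,
    differential_test,
    filter_min_quantified,
    fold_change,
    impute_downshifted_normal,
    log2_transform,
)

from conftest import make_matrix


def _two_condition_matrix(values, n_tp=3, n_rep=2, scale=Scale.RAW):
    conds, tps, reps = [], [], []
    for c in ("N-", "N+"):
        for t in range(n_tp):
            for r in range(n_rep):
                conds.append(c)
                tps.append(3 * 2**t)
                reps.append(r + 1)
    return make_matrix(values, conds, tps, reps, scale=scale)


class TestLog2Transform:
    def test_values_and_missing_preserved(self):
        m = _two_condition_matrix([[8, 1, 4, np.nan, 2, 16, 8, 8, 8, 8, 8, 8]])
        out = log2_transform(m)
        assert out.scale is Scale.LOG2
        row = out.data.iloc[0].to_numpy()
        assert row[0] == 3.0 and row[1] == 0.0
        assert np.isnan(row[3])

    def test_nonpositive_cell_is_named(self):
        m = _two_condition_matrix([[8, 0.0, 4, 1, 2, 16, 8, 8, 8, 8, 8, 8]])
        m.data.iloc[0, 1] = 0.0
        with pytest.raises(ValueError, match="P1"):
            log2_transform(m)


class TestFilterMinQuantified:
    def test_counting_by_hand_sample_level(self):
        # per condition: 4 samples (2 tp x 2 rep); need ceil(0.5*4) = 2 present
        nan = np.nan
        values = [
            # kept: 2/4 in N-, 4/4 in N+
            [1, 1, nan, nan, 2, 2, 2, 2],
            # removed: 1/4 in N-
            [1, nan, nan, nan, 2, 2, 2, 2],
            # kept: complete
            [1, 1, 1, 1, 2, 2, 2, 2],
        ]
        m = _two_condition_matrix(values, n_tp=2)
        kept, report = filter_min_quantified(m, 0.5, FilterMode.SAMPLE_LEVEL)
        assert report.kept_ids == ["P1", "P3"]
        assert report.removed_ids == ["P2"]
        assert set(report.kept_ids) | set(report.removed_ids) == {"P1", "P2", "P3"}
        assert kept.entity_ids == ["P1", "P3"]

    def test_timepoint_level_counts_any_replicate(self):
        nan = np.nan
        # N- has 2 timepoints; one replicate present at each -> 2 quantified tps
        values = [[1, nan, nan, 1, 2, 2, 2, 2]]
        m = _two_condition_matrix(values, n_tp=2)
        _, report = filter_min_quantified(m, 1.0, FilterMode.TIMEPOINT_LEVEL)
        assert report.kept_ids == ["P1"]
        # sample-level at the same threshold removes it (2/4 < 4)
        _, report2 = filter_min_quantified(m, 1.0, FilterMode.SAMPLE_LEVEL)
        assert report2.removed_ids == ["P1"]

    def test_no_missing_keeps_everything(self):
        m = _two_condition_matrix(np.ones((5, 12)))
        kept, report = filter_min_quantified(m)
        assert kept.n_entities == 5 and report.removed_ids == []

    def test_monotone_in_min_fraction(self):
        rng = np.random.default_rng(7)
        values = rng.uniform(1, 2, size=(40, 12))
        values[rng.uniform(size=values.shape) < 0.4] = np.nan
        m = _two_condition_matrix(values)
        previous = None
        for frac in (1.0, 0.75, 0.5, 0.25):
            kept = set(filter_min_quantified(m, frac)[1].kept_ids)
            if previous is not None:
                assert previous <= kept  # lowering the bar never drops a keeper
            previous = kept

    def test_single_condition_is_configuration_error(self):
        m = make_matrix(np.ones((2, 2)), ["N-", "N-"], [3, 3], [1, 2])
        with pytest.raises(ConfigurationError):
            filter_min_quantified(m)


class TestImputation:
    def test_moment_recovery_monte_carlo(self):
        # one column with forced mean 20, sd 2 over present values, 1e5 missing
        rng = np.random.default_rng(11)
        present = rng.normal(20, 2, size=1000)
        present = 20 + 2 * (present - present.mean()) / present.std(ddof=1)
        col = np.concatenate([present, np.full(100_000, np.nan)])
        m = make_matrix(col[:, None], ["N-"], [3], [1], scale=Scale.LOG2)
        out = impute_downshifted_normal(m, ImputationParams(seed=5))
        imputed = out.data.to_numpy()[1000:, 0]
        assert imputed.mean() == pytest.approx(20 - 1.8 * 2, abs=0.02)
        assert imputed.std(ddof=1) == pytest.approx(0.3 * 2, abs=0.01)

    def test_only_missing_cells_change_and_determinism(self):
        rng = np.random.default_rng(3)
        values = rng.normal(20, 2, size=(30, 12))
        values[rng.uniform(size=values.shape) < 0.3] = np.nan
        m = _two_condition_matrix(values, scale=Scale.LOG2)
        mask = np.isnan(values)
        out1 = impute_downshifted_normal(m, ImputationParams(seed=9))
        out2 = impute_downshifted_normal(m, ImputationParams(seed=9))
        np.testing.assert_array_equal(out1.data.to_numpy(), out2.data.to_numpy())
        np.testing.assert_array_equal(
            out1.data.to_numpy()[~mask], values[~mask]
        )
        assert not np.isnan(out1.data.to_numpy()).any()

    def test_complete_column_returned_unchanged(self):
        values = np.arange(24, dtype=float).reshape(2, 12) + 1
        m = _two_condition_matrix(values, scale=Scale.LOG2)
        out = impute_downshifted_normal(m, ImputationParams(seed=0))
        np.testing.assert_array_equal(out.data.to_numpy(), values)

    def test_underpopulated_column_errors(self):
        values = np.full((3, 12), np.nan)
        values[0, :] = 1.0
        m = _two_condition_matrix(values, scale=Scale.LOG2)
        with pytest.raises(ValueError, match="< 2 present"):
            impute_downshifted_normal(m)


class TestFoldChange:
    def test_replicate_means_by_hand(self):
        # N- log2 {10,10,10} vs N+ {8,9,10} at one timepoint -> 1.0
        conds = ["N-"] * 3 + ["N+"] * 3
        m = make_matrix(
            [[10, 10, 10, 8, 9, 10]], conds, [3] * 6, [1, 2, 3, 1, 2, 3], scale=Scale.LOG2
        )
        fc = fold_change(m, OmicsLayer.PROTEIN)
        assert fc.data.loc["P1", 3.0] == pytest.approx(1.0)

    def test_identical_conditions_give_zero(self):
        rng = np.random.default_rng(1)
        half = rng.normal(size=(4, 6))
        values = np.hstack([half, half])
        m = _two_condition_matrix(values, scale=Scale.LOG2)
        fc = fold_change(m, OmicsLayer.PROTEIN)
        assert np.allclose(fc.data.to_numpy(), 0.0)

    def test_antisymmetry_under_condition_swap(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(5, 12))
        m = _two_condition_matrix(values, scale=Scale.LOG2)
        swapped_samples = [
            type(s)(
                Condition.N_PLUS if s.condition is Condition.N_MINUS else Condition.N_MINUS,
                s.timepoint_hours,
                s.replicate,
            )
            for s in m.samples
        ]
        m_swapped = make_matrix(
            values,
            [s.condition.value for s in swapped_samples],
            [s.timepoint_hours for s in swapped_samples],
            [s.replicate for s in swapped_samples],
            scale=Scale.LOG2,
        )
        fc = fold_change(m, OmicsLayer.PROTEIN)
        fc_swapped = fold_change(m_swapped, OmicsLayer.PROTEIN)
        np.testing.assert_allclose(fc.data.to_numpy(), -fc_swapped.data.to_numpy())

    def test_unshared_timepoint_excluded(self):
        conds = ["N-", "N-", "N-", "N+", "N+"]
        tps = [3, 6, 12, 3, 6]  # 12 h has no N+ sample
        m = make_matrix(np.ones((2, 5)), conds, tps, [1] * 5, scale=Scale.LOG2)
        fc = fold_change(m, OmicsLayer.PROTEIN)
        assert fc.timepoints == [3.0, 6.0]


class TestDifferentialTest:
    def test_welch_closed_form(self):
        # {1,2,3} vs {2,3,4}: t = -sqrt(3/2), p from t-dist with Welch df = 4
        conds = ["N-"] * 3 + ["N+"] * 3
        m = make_matrix(
            [[1, 2, 3, 2, 3, 4]], conds, [3] * 6, [1, 2, 3, 1, 2, 3], scale=Scale.LOG2
        )
        res = differential_test(m)[0]
        t_expected = -1.0 / math.sqrt(2.0 / 3.0)
        p_expected = 2 * stats.t.sf(abs(t_expected), df=4)
        assert res.t_statistic == pytest.approx(t_expected, abs=1e-12)
        assert res.p_value == pytest.approx(p_expected, abs=1e-12)
        assert res.p_value == pytest.approx(0.288, abs=5e-3)

    def test_zero_variance_conventions(self):
        conds = ["N-"] * 3 + ["N+"] * 3
        m = make_matrix(
            [[5, 5, 5, 5, 5, 5], [5, 5, 5, 7, 7, 7]],
            conds,
            [3] * 6,
            [1, 2, 3, 1, 2, 3],
            scale=Scale.LOG2,
        )
        res = differential_test(m)
        same, diff = res[0], res[1]
        assert same.p_value == 1.0 and same.t_statistic == 0.0
        assert diff.p_value == 0.0 and diff.significant

    def test_identical_small_pvalues_all_significant_after_bh(self):
        # m entities with identical group separation -> identical p < level
        rng = np.random.default_rng(0)
        n = 20
        base = np.array([0.0, 0.1, -0.1])
        rows = [np.concatenate([base, base + 5.0]) for _ in range(n)]
        conds = ["N-"] * 3 + ["N+"] * 3
        m = make_matrix(rows, conds, [3] * 6, [1, 2, 3, 1, 2, 3], scale=Scale.LOG2)
        res = differential_test(m, level=0.05)
        assert all(r.significant for r in res)
        assert all(0 <= r.q_value <= 1 for r in res)

    def test_bh_within_timepoint_matches_oracle(self):
        """BH step-up against a brute-force oracle on random p-vectors."""

        def bh_oracle(pvals, level):
            order = np.argsort(pvals)
            n = len(pvals)
            passed = [
                i for i in range(n) if pvals[order[i]] <= (i + 1) / n * level
            ]
            cut = max(passed) if passed else -1
            sig = np.zeros(n, dtype=bool)
            sig[order[: cut + 1]] = True
            return sig

        rng = np.random.default_rng(42)
        for trial in range(20):
            n = int(rng.integers(3, 50))
            # mixture of nulls and signal so some reject, some do not
            signal = rng.uniform(size=n) < 0.4
            rows = []
            for s in signal:
                shift = 4.0 if s else 0.0
                rows.append(
                    np.concatenate(
                        [rng.normal(0, 1, 3), rng.normal(shift, 1, 3)]
                    )
                )
            conds = ["N-"] * 3 + ["N+"] * 3
            m = make_matrix(
                rows, conds, [3] * 6, [1, 2, 3, 1, 2, 3], scale=Scale.LOG2
            )
            res = differential_test(m, level=0.05)
            pvals = np.array([r.p_value for r in res])
            expected = bh_oracle(pvals, 0.05)
            assert [r.significant for r in res] == expected.tolist()

    def test_pooled_mode_single_test_per_entity(self):
        rng = np.random.default_rng(4)
        m = _two_condition_matrix(rng.normal(size=(3, 12)), scale=Scale.LOG2)
        res = differential_test(m, pooled=True)
        assert len(res) == 3
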