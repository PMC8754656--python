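import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import reelscan as rs
from reelscan.depletion_calling import _fit_slopes


def make_pct(columns, tiles=None):
    cols = pd.MultiIndex.from_tuples(
        list(columns), names=["condition", "round", "replicate"]
    )
    df = pd.DataFrame(columns, dtype=float)
    df.columns = cols
    df = df / df.sum(axis=0)
    df.index = tiles or [f"S{i+1}" for i in range(len(df))]
    df.index.name = "tile_id"
    return rs.PercentageMatrix(fractions=df, pseudocount=0.0)


def full_pct(ne, buffer, rounds=(1, 4, 7, 10), reps=3, rng=None):
    """Build a percentage matrix from per-round per-tile target fractions,
    identical across replicates unless jittered."""
    cols = {}
    for r_i, r in enumerate(rounds):
        for rep in range(1, reps + 1):
            for cond, mat in (("NE", ne), ("buffer", buffer)):
                v = np.asarray(mat[r_i], dtype=float)
                if rng is not None:
                    v = v * rng.lognormal(0, 0.01, v.size)
                cols[(cond, r, rep)] = v
    return make_pct(cols)


class TestConditionMeans:
    def test_arithmetic_mean_over_replicates(self):
        pct = make_pct(
            {
                ("NE", 1, 1): [1, 9], ("NE", 1, 2): [2, 8], ("NE", 1, 3): [3, 7],
                ("buffer", 1, 1): [5, 5], ("buffer", 1, 2): [5, 5],
                ("buffer", 1, 3): [5, 5],
            }
        )
        means = rs.condition_means(pct)
        assert means[("NE", 1)].iloc[0] == pytest.approx(0.2)
        assert means[("buffer", 1)].iloc[0] == pytest.approx(0.5)

    def test_replicate_order_invariance(self, tiny_screen):
        _, _, _, cm, _ = tiny_screen
        pct = rs.to_percentages(cm)
        shuffled = rs.PercentageMatrix(
            fractions=pct.fractions.rename(
                columns={1: 3, 3: 1}, level="replicate"
            ),
            pseudocount=pct.pseudocount,
        )
        assert np.allclose(
            rs.condition_means(pct).to_numpy(),
            rs.condition_means(shuffled).to_numpy(),
        )

    def test_missing_cell_named_in_error(self):
        pct = make_pct(
            {("NE", 1, 1): [1, 2], ("NE", 1, 2): [1, 2],
             ("buffer", 1, 1): [1, 2], ("buffer", 1, 2): [1, 2]}
        )
        pct.fractions.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing replicate cell"):
            rs.condition_means(pct)


class TestRatioTrajectory:
    def test_equal_conditions_give_unit_ratios(self):
        pct = make_pct(
            {("NE", r, rep): [1, 2, 3] for r in (1, 4) for rep in (1, 2)}
            | {("buffer", r, rep): [1, 2, 3] for r in (1, 4) for rep in (1, 2)}
        )
        ratios = rs.ratio_trajectory(rs.condition_means(pct))
        assert np.allclose(ratios.to_numpy(), 1.0)

    def test_componentwise_division(self):
        means = pd.DataFrame(
            {
                ("NE", 1): [0.01], ("NE", 4): [0.008],
                ("NE", 7): [0.006], ("NE", 10): [0.004],
                ("buffer", 1): [0.01], ("buffer", 4): [0.01],
                ("buffer", 7): [0.01], ("buffer", 10): [0.01],
            }
        )
        means.columns = pd.MultiIndex.from_tuples(
            means.columns, names=["condition", "round"]
        )
        ratios = rs.ratio_trajectory(means)
        assert np.allclose(ratios.to_numpy(), [[1.0, 0.8, 0.6, 0.4]])

    def test_common_per_round_scaling_cancels(self):
        rng = np.random.default_rng(30)
        base = rng.random((5, 4)) + 0.1
        means = {}
        scaled = {}
        for j, r in enumerate((1, 4, 7, 10)):
            means[("NE", r)] = base[:, j] * 0.5
            means[("buffer", r)] = base[:, j]
            k = rng.uniform(0.5, 2)
            scaled[("NE", r)] = base[:, j] * 0.5 * k
            scaled[("buffer", r)] = base[:, j] * k
        def as_df(d):
            df = pd.DataFrame(d)
            df.columns = pd.MultiIndex.from_tuples(df.columns, names=["condition", "round"])
            return df
        assert np.allclose(
            rs.ratio_trajectory(as_df(means)).to_numpy(),
            rs.ratio_trajectory(as_df(scaled)).to_numpy(),
        )


class TestFitSlope:
    def test_flat_trajectory(self):
        assert rs.fit_slope([1, 1, 1, 1]) == 0.0

    def test_linear_decrease_closed_form(self):
        # OLS on x = (1,4,7,10): slope = sum((x-5.5)(y-ybar))/sum((x-5.5)^2)
        assert rs.fit_slope([1.0, 0.9, 0.8, 0.7]) == pytest.approx(-1 / 30, abs=1e-12)

    def test_reversal_negates_slope(self):
        y = [1.2, 0.7, 0.9, 0.4]
        assert rs.fit_slope(y[::-1]) == pytest.approx(-rs.fit_slope(y), abs=1e-12)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            rs.fit_slope([1.0, np.nan, 0.5, 0.2])

    @given(
        y=st.lists(
            st.floats(min_value=-10, max_value=10, allow_nan=False), min_size=4,
            max_size=4,
        )
    )
    def test_agrees_with_linregress(self, y):
        x = [1, 4, 7, 10]
        assert rs.fit_slope(y, x) == pytest.approx(
            stats.linregress(x, y).slope, abs=1e-12
        )

    def test_vectorized_slopes_match_scalar(self):
        rng = np.random.default_rng(31)
        y = rng.random((20, 4))
        df = pd.DataFrame(y, columns=[1, 4, 7, 10])
        vec = _fit_slopes(df, np.array([1.0, 4.0, 7.0, 10.0]))
        for i in range(20):
            assert vec.iloc[i] == pytest.approx(rs.fit_slope(y[i]), abs=1e-12)


class TestPerRoundTest:
    def test_identical_groups_degenerate_convention(self):
        assert rs.per_round_test([0.01] * 3, [0.01] * 3) == 1.0

    def test_pooled_t_hand_computed(self):
        # means 2 vs 5, pooled variance 1, se = sqrt(2/3), t = -3.674, df = 4
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        t_manual = (np.mean(a) - np.mean(b)) / np.sqrt(2 / 3)
        p_manual = 2 * stats.t.sf(abs(t_manual), df=4)
        p = rs.per_round_test(a, b)
        assert p == pytest.approx(p_manual, abs=1e-12)
        assert p == pytest.approx(0.0213, abs=5e-4)

    def test_two_sided_symmetry(self):
        a, b = [0.01, 0.02, 0.015], [0.03, 0.025, 0.04]
        assert rs.per_round_test(a, b) == pytest.approx(rs.per_round_test(b, a))

    def test_zero_variance_unequal_means_tends_to_zero(self):
        p = rs.per_round_test([0.01] * 3, [0.02] * 3)
        assert 0 < p < 1e-300

    def test_welch_option(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 6.0, 8.0]
        cfg = rs.CallingConfig(test="welch")
        assert rs.per_round_test(a, b, cfg) == pytest.approx(
            stats.ttest_ind(a, b, equal_var=False).pvalue
        )


class TestCallCandidates:
    def _records(self, slope, pvalues):
        return pd.DataFrame(
            {
                "slope": [slope],
                **{f"pvalue_{r}": [p] for r, p in zip((1, 4, 7, 10), pvalues)},
            },
            index=["S1"],
        )

    def test_negative_slope_all_significant_is_candidate(self):
        rec, summary = rs.call_candidates(
            self._records(-0.03, [0.01, 0.02, 0.03, 0.04])
        )
        assert rec["is_candidate"].iloc[0]
        assert summary == {"n_tested": 1, "n_slope_negative": 1, "n_candidates": 1}

    def test_one_round_failing_rejects(self):
        rec, _ = rs.call_candidates(self._records(-0.03, [0.01, 0.02, 0.06, 0.04]))
        assert not rec["is_candidate"].iloc[0]

    def test_positive_slope_rejects_despite_significance(self):
        rec, summary = rs.call_candidates(
            self._records(0.01, [0.001, 0.001, 0.001, 0.001])
        )
        assert not rec["is_candidate"].iloc[0]
        assert summary["n_slope_negative"] == 0


class TestRunDepletionCalling:
    def test_depleting_tile_called_others_not(self):
        # tile 1 depletes steadily; tiles 2-4 stay flat
        rng = np.random.default_rng(32)
        traj = [0.9, 0.7, 0.5, 0.3]
        ne = [[traj[j], 1, 1, 1] for j in range(4)]
        buf = [[1, 1, 1, 1]] * 4
        pct = full_pct(ne, buf, rng=rng)
        records, summary = rs.run_depletion_calling(pct)
        assert bool(records["is_candidate"].iloc[0])
        assert summary["n_candidates"] == 1
        assert records["slope"].iloc[0] < 0

    def test_calls_invariant_to_replicate_relabeling(self, tiny_screen):
        _, _, _, cm, _ = tiny_screen
        pct = rs.to_percentages(cm)
        rec1, _ = rs.run_depletion_calling(pct)
        relabeled = rs.PercentageMatrix(
            fractions=pct.fractions.rename(columns={1: 2, 2: 1}, level="replicate"),
            pseudocount=pct.pseudocount,
        )
        rec2, _ = rs.run_depletion_calling(relabeled)
        assert rec1["is_candidate"].equals(rec2["is_candidate"])

    def test_calls_invariant_to_uniform_depth_rescaling(self, tiny_screen):
        # deterministic limit: scaling every count by the same factor leaves
        # pseudocount-free percentages, hence calls, unchanged
        _, _, design, cm, _ = tiny_screen
        pct1 = rs.to_percentages(cm, pseudocount=0.0)
        scaled = rs.CountMatrix(
            counts=cm.counts * 10,
            design=rs.ScreenDesign(
                rounds_total=design.rounds_total,
                rounds_sequenced=design.rounds_sequenced,
                replicates=design.replicates,
                depth=design.depth * 10,
                pool_size=design.pool_size,
            ),
        )
        pct2 = rs.to_percentages(scaled, pseudocount=0.0)
        rec1, _ = rs.run_depletion_calling(pct1)
        rec2, _ = rs.run_depletion_calling(pct2)
        assert rec1["is_candidate"].equals(rec2["is_candidate"])
        assert np.allclose(rec1["slope"], rec2["slope"])

    def test_slope_x_choice_does_not_change_calls(self, tiny_screen):
        _, _, _, cm, _ = tiny_screen
        pct = rs.to_percentages(cm)
        rec_num, _ = rs.run_depletion_calling(
            pct, rs.CallingConfig(slope_x="round_number")
        )
        rec_idx, _ = rs.run_depletion_calling(
            pct, rs.CallingConfig(slope_x="round_index")
        )
        assert rec_num["is_candidate"].equals(rec_idx["is_candidate"])

    def test_missing_round_errors(self):
        pct = make_pct(
            {(c, 1, rep): [1, 2] for c in ("NE", "buffer") for rep in (1, 2)}
        )
        with pytest.raises(ValueError, match="rounds"):
            rs.run_depletion_calling(pct)


def test_validation_false_positive_rate():
    assert rs.validation_false_positive_rate(8, 10) == pytest.approx(0.2)
    assert rs.validation_false_positive_rate(10, 10) == 0.0
    with pytest.raises(ValueError):
        rs.validation_false_positive_rate(11, 10)
    with pytest.raises(ValueError):
        rs.validation_false_positive_rate(0, 0)
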