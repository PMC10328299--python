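"""Quantile/range construction, exact Wilcoxon vs enumeration, correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hopmat import (
    UndefinedStatisticError,
    classify_in_range,
    cohort_table,
    compare_timepoints,
    physiological_range,
    quantile,
    r_squared,
    score_agreement,
    session_summaries,
    spearman_rho,
    wilcoxon_signed_rank,
)


def quantile_oracle(values, q):
    """Sort-based linear interpolation at position (n-1) q / 100."""
    v = sorted(values)
    pos = (len(v) - 1) * q / 100.0
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    return v[lo] + (pos - lo) * (v[hi] - v[lo])


def wilcoxon_oracle(x, y):
    """Two-sided exact p by full enumeration of all 2^m sign assignments."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    sums = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=len(d))
    ]
    sums = np.array(sums)
    n = len(sums)
    p_le = np.sum(sums <= w_obs + 1e-9) / n
    p_ge = np.sum(sums >= w_obs - 1e-9) / n
    return min(1.0, 2 * min(p_le, p_ge))


class TestQuantile:
    def test_median_of_one_to_five(self):
        assert quantile([1, 2, 3, 4, 5], 50) == 3

    def test_interpolated_lower_tail(self):
        assert quantile(range(1, 41), 2.5) == pytest.approx(1.975)

    def test_extremes_are_min_and_max(self):
        values = [3.2, -1.0, 7.5]
        assert quantile(values, 0) == -1.0
        assert quantile(values, 100) == 7.5

    def test_agrees_with_sort_oracle_on_random_samples(self, rng):
        for _ in range(200):
            values = rng.normal(size=rng.integers(2, 60))
            q = float(rng.uniform(0, 100))
            assert quantile(values, q) == pytest.approx(quantile_oracle(values, q))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            quantile([], 50)


class TestPhysiologicalRange:
    def test_interval_covers_central_95_percent(self, rng):
        values = rng.normal(0, 0.14, size=160)
        prange = physiological_range(values, "ratio_force")
        _, fraction = classify_in_range(values, prange)
        assert fraction == pytest.approx(0.95, abs=0.015)

    def test_constant_input_degenerates_to_point(self):
        prange = physiological_range([0.1] * 50, "ratio_force")
        assert prange.lower == prange.upper == 0.1

    def test_small_sample_warns_but_computes(self):
        with pytest.warns(UserWarning, match="unstable"):
            prange = physiological_range([0.0, 1.0, 2.0], "ratio_pressure")
        assert prange.n_values == 3

    def test_outlier_moves_bound_at_most_one_interpolation_step(self, rng):
        values = np.sort(rng.normal(size=80))
        prange = physiological_range(values, "ratio_force")
        spiked = np.append(values, -100.0)
        prange2 = physiological_range(spiked, "ratio_force")
        # order-statistic argument: the 2.5th percentile index shifts < 1,
        # so the new bound stays within the adjacent original order stats
        pos = int(np.ceil((len(values) - 1) * 0.025))
        assert values[max(0, pos - 2)] <= prange2.lower <= values[pos + 1]
        assert prange2.lower <= prange.lower  # low outlier cannot raise it

    def test_boundary_value_counts_as_inside(self):
        prange = physiological_range(list(np.linspace(-1, 1, 81)), "ratio_force")
        flags, _ = classify_in_range([prange.lower, prange.upper], prange)
        assert flags.all()


class TestWilcoxon:
    def test_five_concordant_pairs_exact_p(self):
        res = wilcoxon_signed_rank([2, 3, 4, 5, 6], [1, 2, 3, 4, 5])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.0625)

    def test_identical_sequences_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert res.p_value == 1.0 and res.n == 0

    def test_exact_matches_full_enumeration_oracle(self, rng):
        for n in (5, 8, 12):
            for _ in range(5):
                x = rng.normal(size=n)
                y = rng.normal(size=n)
                res = wilcoxon_signed_rank(x, y, mode="exact")
                assert res.p_value == pytest.approx(wilcoxon_oracle(x, y), abs=1e-12)

    def test_exact_with_tied_differences_matches_oracle(self, rng):
        for _ in range(5):
            x = rng.integers(0, 4, size=10).astype(float)
            y = rng.integers(0, 4, size=10).astype(float)
            if np.all(x == y):
                continue
            res = wilcoxon_signed_rank(x, y, mode="exact")
            assert res.p_value == pytest.approx(wilcoxon_oracle(x, y), abs=1e-12)

    def test_exact_agrees_with_scipy_without_ties(self, rng):
        # independent cross-check against an established implementation
        x = rng.normal(size=14)
        y = rng.normal(size=14)
        res = wilcoxon_signed_rank(x, y, mode="exact")
        ref = sps.wilcoxon(x, y, mode="exact", alternative="two-sided")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_close_to_exact_at_m12(self, rng):
        for _ in range(10):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            exact = wilcoxon_signed_rank(x, y, mode="exact").p_value
            approx = wilcoxon_signed_rank(x, y, mode="normal_approximation").p_value
            assert abs(exact - approx) <= 0.02

    def test_auto_switches_to_approximation_for_large_n(self, rng):
        x = rng.normal(size=30)
        res = wilcoxon_signed_rank(x, x + rng.normal(size=30))
        assert res.method == "normal_approximation"


class TestCorrelations:
    def test_monotone_sequences(self):
        assert spearman_rho([1, 2, 3], [10, 20, 40]) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3], [5, 4, 3]) == pytest.approx(-1.0)

    def test_consistent_ties_preserve_perfect_correlation(self):
        assert spearman_rho([1, 2, 2, 3], [10, 20, 20, 40]) == pytest.approx(1.0)

    def test_constant_input_is_undefined_not_zero(self):
        with pytest.raises(UndefinedStatisticError):
            spearman_rho([1, 1, 1], [1, 2, 3])

    def test_r_squared_exact_linear_data(self):
        assert r_squared([1, 2, 3, 4], [3, 5, 7, 9]) == pytest.approx(1.0)

    def test_r_squared_matches_sse_sst_identity(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 1.9, 3.4, 3.6, 5.2])
        slope, intercept = np.polyfit(x, y, 1)
        sse = np.sum((y - (slope * x + intercept)) ** 2)
        sst = np.sum((y - y.mean()) ** 2)
        assert r_squared(x, y) == pytest.approx(1 - sse / sst)

    def test_r_squared_constant_x_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            r_squared([2, 2, 2], [1, 2, 3])


def _metrics_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["run_id", "animal_id", "session_id", "ratio_pressure", "ratio_force"],
    )


class TestSummariesAndTables:
    def test_single_run_session_has_undefined_sd(self):
        df = _metrics_frame([("k1", "r01", "d1", -0.1, -0.2)])
        out = session_summaries(df)
        assert out.loc[0, "mean_ratio_force"] == -0.2
        assert out.loc[0, "n_runs"] == 1
        assert np.isnan(out.loc[0, "sd_ratio_force"])

    def test_mean_of_symmetric_runs_is_zero(self):
        df = _metrics_frame(
            [(f"k{i}", "r01", "d1", v, v) for i, v in enumerate([-0.2, 0.0, 0.2])]
        )
        out = session_summaries(df)
        assert out.loc[0, "mean_ratio_pressure"] == pytest.approx(0.0)

    def test_rejected_runs_excluded(self):
        df = _metrics_frame(
            [("k1", "r01", "d1", 0.0, 0.0), ("k2", "r01", "d1", 0.9, 0.9)]
        )
        df["qc_accepted"] = [True, False]
        out = session_summaries(df)
        assert out.loc[0, "n_runs"] == 1

    def test_single_run_cohort_table_columns_all_equal(self):
        df = _metrics_frame([("k1", "r01", "d1", -0.1, -0.25)])
        out = cohort_table(session_summaries(df), df, ["d1"], "ratio_force")
        row = out.iloc[0]
        assert (
            row["single_min"] == row["single_max"] == row["single_mean"]
            == row["mean_min"] == row["mean_mean"] == -0.25
        )

    def test_pooled_preop_mean_range_narrower_than_daily(self, rng):
        # averaging each animal across days shrinks the mean-value range
        rows = []
        for a in range(12):
            offset = rng.normal(0, 0.03)
            for d in range(3):
                for k in range(5):
                    v = offset + rng.normal(0, 0.14)
                    rows.append((f"r{a}_{d}_{k}", f"r{a:02d}", f"preop_{d + 1}", v, v))
        df = _metrics_frame(rows)
        summaries = session_summaries(df)
        days = ["preop_1", "preop_2", "preop_3"]
        out = cohort_table(summaries, df, days, "ratio_force", preop_sessions=days)
        pooled = out[out["session"] == "preoperative_pooled"].iloc[0]
        daily_widths = (out.loc[: len(days) - 1, "mean_max"]
                        - out.loc[: len(days) - 1, "mean_min"])
        assert pooled["mean_max"] - pooled["mean_min"] < daily_widths.min()
        # pooled single-value columns pool all runs of all three days
        assert pooled["n_single"] == 180

    def test_empty_session_is_an_explicit_error(self):
        df = _metrics_frame([("k1", "r01", "d1", 0.0, 0.0)])
        with pytest.raises(ValueError, match="d2"):
            cohort_table(session_summaries(df), df, ["d1", "d2"], "ratio_force")


class TestCompareTimepoints:
    @staticmethod
    def _summaries(values_by_session):
        rows = []
        for sid, values in values_by_session.items():
            for i, v in enumerate(values):
                rows.append(
                    {
                        "animal_id": f"r{i:02d}",
                        "session_id": sid,
                        "n_runs": 3,
                        "mean_ratio_pressure": v,
                        "sd_ratio_pressure": 0.1,
                        "mean_ratio_force": v,
                        "sd_ratio_force": 0.1,
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_sessions_give_p_one(self):
        s = self._summaries({"a": [0.1, 0.2, 0.3], "b": [0.1, 0.2, 0.3]})
        with pytest.warns(UserWarning, match="degenerate"):
            out = compare_timepoints(s, [("a", "b")])
        assert (out["p_value"] == 1.0).all()

    def test_strong_shift_is_significant(self, rng):
        s = self._summaries(
            {"pre": rng.normal(0, 0.05, 12), "post": rng.normal(-0.8, 0.1, 12)}
        )
        out = compare_timepoints(s, [("pre", "post")])
        assert out["significant_0.01"].all()
        assert (out["method"] == "exact").all()

    def test_unpaired_animal_dropped_with_warning(self):
        s = self._summaries({"a": [0.1, 0.2, 0.3, 0.4], "b": [0.3, 0.2, 0.1]})
        with pytest.warns(UserWarning, match="unpaired"):
            out = compare_timepoints(s, [("a", "b")])
        assert (out["n_pairs"] <= 3).all()


class TestScoreAgreement:
    @staticmethod
    def _inputs(sign=1.0):
        scores = pd.DataFrame(
            {
                "animal_id": [f"r{i}" for i in range(8)],
                "session_id": ["w1"] * 8,
                "score": [0, 0, 1, 1, 2, 2, 3, 4],
            }
        )
        ratios = sign * np.array([-0.05, 0.0, -0.3, -0.35, -0.55, -0.6, -0.8, -0.97])
        summaries = pd.DataFrame(
            {
                "animal_id": [f"r{i}" for i in range(8)],
                "session_id": ["w1"] * 8,
                "n_runs": 3,
                "mean_ratio_pressure": ratios,
                "sd_ratio_pressure": 0.1,
                "mean_ratio_force": ratios,
                "sd_ratio_force": 0.1,
            }
        )
        return scores, summaries

    def test_monotone_offload_gives_strong_negative_rho(self):
        out = score_agreement(*self._inputs())
        assert out["ratio_force"]["rho"] < -0.9
        assert out["ratio_force"]["r_squared"] > 0.8
        bands = out["ratio_force"]["per_score"]
        assert bands.loc[bands["score"] == 4, "ratio_min"].iloc[0] == -0.97

    def test_flipping_limb_labels_flips_rho_sign(self):
        plus = score_agreement(*self._inputs(+1.0))
        minus = score_agreement(*self._inputs(-1.0))
        assert minus["ratio_force"]["rho"] == pytest.approx(
            -plus["ratio_force"]["rho"]
        )

    def test_constant_scores_surface_undefined_error(self):
        scores, summaries = self._inputs()
        scores["score"] = 2
        with pytest.raises(UndefinedStatisticError):
            score_agreement(scores, summaries)

    def test_disjoint_keys_error(self):
        scores, summaries = self._inputs()
        scores["session_id"] = "w2"
        with pytest.raises(ValueError, match="overlap"):
            score_agreement(scores, summaries)
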