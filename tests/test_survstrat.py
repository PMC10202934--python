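"""IHC classification, dichotomization, KM/log-rank stratification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oncomir.survstrat import (
    dichotomize,
    ihc_classify,
    km_logrank,
    scan_optimal_threshold,
    stratify_two_markers,
)
from oncomir.syndata import SimConfig, gen_survival_cohort


class TestIhcClassify:
    @pytest.mark.parametrize(
        "frac,expected",
        [(0.46, "low_neg"), (0.44, "positive"), (0.45, "low_neg"),
         (0.0, "positive"), (1.0, "low_neg")],
    )
    def test_inclusive_default(self, frac, expected):
        assert ihc_classify(frac) == expected

    def test_exclusive_flag(self):
        assert ihc_classify(0.45, inclusive=False) == "positive"

    @pytest.mark.parametrize("frac", [-0.1, 1.1])
    def test_out_of_range(self, frac):
        with pytest.raises(ValueError):
            ihc_classify(frac)


class TestDichotomize:
    def test_median_rule_ties_to_low(self):
        df = pd.DataFrame({"m": [1.0, 2.0, 3.0, 4.0]})
        labels = dichotomize(df, "m", rule="median")
        assert list(labels) == ["low", "low", "high", "high"]
        df5 = pd.DataFrame({"m": [1.0, 2.0, 3.0, 4.0, 5.0]})
        assert dichotomize(df5, "m")[2] == "low"  # value == median -> low

    def test_quantile_half_equals_median(self):
        df = pd.DataFrame({"m": np.arange(20, dtype=float)})
        assert (dichotomize(df, "m", rule="median")
                == dichotomize(df, "m", rule="quantile", q=0.5)).all()

    def test_fixed_cutoff_at_max_raises(self):
        df = pd.DataFrame({"m": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="split"):
            dichotomize(df, "m", rule="fixed", cutoff=3.0)

    def test_identical_values_raise(self):
        df = pd.DataFrame({"m": [2.0] * 5})
        with pytest.raises(ValueError):
            dichotomize(df, "m")


def _cohort(times, events, labels):
    return (
        pd.DataFrame({"dfs_time": times, "dfs_event": events}),
        pd.Series(labels),
    )


class TestKmLogrank:
    def test_identical_groups_give_null_statistic(self):
        times = [3.0, 5.0, 7.0, 9.0]
        events = [True, True, False, True]
        df, labels = _cohort(times * 2, events * 2, ["a"] * 4 + ["b"] * 4)
        res = km_logrank(df, labels)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_textbook_hand_computed_example(self):
        """Events at t=1,2 in group A, group B censored at t=3.

        By hand: O_A=2, E_A=1/2+1/3, V=1/4+2/9, chi2=(7/6)^2/(17/36)=49/17.
        """
        df, labels = _cohort([1.0, 2.0, 3.0, 3.0], [True, True, False, False],
                             ["A", "A", "B", "B"])
        res = km_logrank(df, labels)
        assert res.statistic == pytest.approx(49 / 17, abs=1e-9)
        assert res.p_value == pytest.approx(stats.chi2.sf(49 / 17, 1), abs=1e-9)

    def test_all_censored_flat_km(self):
        df, labels = _cohort([5.0, 6.0, 7.0, 8.0], [False] * 4, ["a", "a", "b", "b"])
        res = km_logrank(df, labels)
        for curve in res.km_curves.values():
            assert (curve["survival"] == 1.0).all()

    def test_km_invariants(self):
        coh = gen_survival_cohort(SimConfig(seed=4, n_patients=60))
        res = km_logrank(coh, coh["ihc_class"])
        for curve in res.km_curves.values():
            s = curve["survival"].to_numpy()
            assert s[0] == 1.0 or curve["time"].iloc[0] == 0.0
            assert (np.diff(s) <= 1e-12).all()  # non-increasing
            at_risk = curve["at_risk"].dropna().to_numpy()
            assert (np.diff(at_risk) <= 0).all()

    def test_empty_group_raises(self):
        df, labels = _cohort([1.0, 2.0], [True, True], ["a", "a"])
        with pytest.raises(ValueError, match="groups"):
            km_logrank(df, labels)

    def test_agrees_with_permutation_oracle(self):
        """Asymptotic log-rank p matches a label-permutation test at n=40."""
        rng = np.random.default_rng(12)
        n = 40
        times = np.r_[rng.exponential(10, n // 2), rng.exponential(16, n // 2)]
        events = rng.random(n) < 0.8
        labels = pd.Series(["a"] * (n // 2) + ["b"] * (n // 2))
        df = pd.DataFrame({"dfs_time": times, "dfs_event": events})
        observed = km_logrank(df, labels)
        count = 0
        n_perm = 2000
        for _ in range(n_perm):
            perm = pd.Series(rng.permutation(labels.to_numpy()))
            if km_logrank(df, perm).statistic >= observed.statistic:
                count += 1
        p_perm = (count + 1) / (n_perm + 1)
        # Monte-Carlo SE at p~0.1 with 2000 perms is ~0.007; allow 4 SE + asymptotic slack
        assert abs(p_perm - observed.p_value) < 0.05


class TestTwoMarkerStratification:
    def test_four_groups_and_contrast(self):
        cfg = SimConfig(seed=15, n_patients=400, survival_group_rule="marker_quadrant",
                        hazard_ratios={"high/high": 2.5})
        coh = gen_survival_cohort(cfg)
        res = stratify_two_markers(coh, "miR-21-5p", "miR-93-5p")
        assert set(res.labels.unique()) == {"high/high", "high/low", "low/high", "low/low"}
        assert res.p_value < 0.05
        assert res.contrasts["high/high_vs_rest"]["p_value"] < 0.05

    def test_degenerate_grouping_skips_contrasts(self):
        # marker_b constant except one value: dichotomize still works, but
        # engineered labels leave groups empty
        df = pd.DataFrame(
            {
                "dfs_time": [1.0, 2.0, 3.0, 4.0],
                "dfs_event": [True, True, True, True],
                "a": [1.0, 2.0, 3.0, 4.0],
                "b": [1.0, 2.0, 3.0, 4.0],
            }
        )
        res = stratify_two_markers(df, "a", "b")
        # perfectly correlated markers populate only high/high and low/low
        assert set(res.skipped) == {"high/low", "low/high"}
        assert "high/high_vs_rest" in res.contrasts


class TestScanOptimalThreshold:
    def test_recovers_planted_split(self):
        cfg = SimConfig(seed=31, n_patients=300, survival_group_rule="ihc",
                        ihc_split=0.45,
                        hazard_ratios={"positive": 1.0, "low_neg": 3.0})
        coh = gen_survival_cohort(cfg)
        grid = np.round(np.arange(0.15, 0.85, 0.05), 2)
        res = scan_optimal_threshold(coh, grid)
        assert abs(res["threshold"] - 0.45) <= 0.05 + 1e-9

    def test_null_profile_flagged_by_permutation(self):
        cfg = SimConfig(seed=32, n_patients=120, survival_group_rule="ihc",
                        hazard_ratios={"positive": 1.0, "low_neg": 1.0})
        coh = gen_survival_cohort(cfg)
        res = scan_optimal_threshold(
            coh, [0.25, 0.45, 0.65], n_permutations=200,
            rng=np.random.default_rng(0),
        )
        assert res["permutation_p"] > 0.05
        assert "optimistic" in res["note"]

    def test_single_point_grid(self):
        coh = gen_survival_cohort(SimConfig(seed=33, n_patients=50))
        res = scan_optimal_threshold(coh, [0.45])
        assert res["threshold"] == 0.45

    def test_degenerate_grid_points_skipped(self):
        coh = gen_survival_cohort(SimConfig(seed=34, n_patients=50))
        res = scan_optimal_threshold(coh, [0.0, 0.45])  # 0.0 -> everyone low_neg
        assert np.isnan(
            res["profile"].set_index("threshold").loc[0.0, "logrank_statistic"]
        )
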