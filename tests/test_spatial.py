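"""TMA pipeline: outlier filter, core summaries, ranking, stratification."""

import numpy as np
import pandas as pd
import pytest

from oncomir.spatial import (
    MIR21_COLUMN,
    CDK2AP1_COLUMN,
    compare_compartments,
    median_channels,
    merge_and_filter,
    rank_cores,
    reconstruct,
    stratify_and_test,
    summarize_cores,
)
from oncomir.syndata import SimConfig, gen_tma_cohort


def _toy_cells(n=200, seed=0, core_id="c1", mir21=None, cdk2ap1=None):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "core_id": core_id,
            "patient_id": "p1",
            "x": rng.random(n) * 100,
            "y": rng.random(n) * 100,
            "compartment": "tumor",
            MIR21_COLUMN: mir21 if mir21 is not None else rng.normal(100, 10, n),
            CDK2AP1_COLUMN: cdk2ap1 if cdk2ap1 is not None else rng.normal(120, 10, n),
        }
    )


class TestMergeAndFilter:
    def test_displaced_cell_is_excluded(self):
        """Brute-force z computation agrees on a 20-SD displacement."""
        cells = _toy_cells(500)
        x = cells[MIR21_COLUMN].to_numpy().copy()
        x[7] = x.mean() + 20 * x.std()
        cells[MIR21_COLUMN] = x
        out = merge_and_filter(cells)
        z = (x - x.mean()) / x.std()
        assert out["excluded"].iloc[7]
        assert (out["excluded"] == (np.abs(z) > 3)).all()

    def test_constant_channel_gives_no_exclusions(self):
        cells = _toy_cells(100, mir21=np.full(100, 50.0), cdk2ap1=np.full(100, 60.0))
        with pytest.warns(UserWarning, match="zero variance"):
            out = merge_and_filter(cells)
        assert not out["excluded"].any()

    def test_filtering_preserves_cell_count(self, small_tma_cells):
        out = merge_and_filter(small_tma_cells.copy())
        assert len(out) == len(small_tma_cells)

    def test_recovers_planted_outliers(self, small_tma_cells):
        out = merge_and_filter(small_tma_cells.copy())
        truth = small_tma_cells["truth_outlier"].to_numpy()
        assert out.loc[truth, "excluded"].all()
        assert out.loc[~truth, "excluded"].mean() < 0.01

    def test_inconsistent_headers_raise(self):
        a, b = _toy_cells(10), _toy_cells(10).drop(columns=[CDK2AP1_COLUMN])
        with pytest.raises(ValueError, match="headers"):
            merge_and_filter([a, b])

    def test_truth_columns_are_not_channels(self, small_tma_cells):
        assert not any(c.startswith("truth_") for c in median_channels(small_tma_cells))


class TestSummarizeCores:
    def test_min_tumor_cell_inclusion_boundary(self):
        cells = pd.concat(
            [_toy_cells(499, core_id="small"), _toy_cells(500, core_id="big")],
            ignore_index=True,
        )
        cells["excluded"] = False
        out = summarize_cores(cells, min_tumor_cells=500).set_index("core_id")
        assert not out.loc["small", "included"]
        assert out.loc["big", "included"]

    def test_constant_core_has_undefined_r(self):
        cells = _toy_cells(500, mir21=np.full(500, 100.0))
        cells["excluded"] = False
        out = summarize_cores(cells, min_tumor_cells=500)
        assert out["mir21_tumor"].iloc[0] == pytest.approx(100.0)
        assert np.isnan(out["pearson_r"].iloc[0])

    def test_three_cell_anticorrelated_core(self):
        cells = _toy_cells(3, mir21=np.array([1.0, 2.0, 3.0]),
                           cdk2ap1=np.array([3.0, 2.0, 1.0]))
        cells["excluded"] = False
        out = summarize_cores(cells, min_tumor_cells=3)
        assert out["pearson_r"].iloc[0] == pytest.approx(-1.0, abs=1e-12)

    def test_excluded_cells_do_not_contribute(self):
        cells = _toy_cells(600)
        cells["excluded"] = np.arange(600) < 150
        out = summarize_cores(cells, min_tumor_cells=500)
        assert out["n_tumor_cells"].iloc[0] == 450
        assert not out["included"].iloc[0]
        expected = cells.loc[~cells["excluded"], MIR21_COLUMN].mean()
        assert out["mir21_tumor"].iloc[0] == pytest.approx(expected)

    def test_pearson_matches_two_pass_oracle(self):
        """np-based r agrees with a naive two-pass oracle to 1e-12."""
        cells = _toy_cells(1000, seed=5)
        cells["excluded"] = False
        out = summarize_cores(cells, min_tumor_cells=10)
        x = cells[MIR21_COLUMN].to_numpy()
        y = cells[CDK2AP1_COLUMN].to_numpy()
        mx, my = x.mean(), y.mean()
        naive = ((x - mx) * (y - my)).sum() / np.sqrt(
            ((x - mx) ** 2).sum() * ((y - my) ** 2).sum()
        )
        assert out["pearson_r"].iloc[0] == pytest.approx(naive, abs=1e-12)


class TestRankCores:
    def _summary(self, rows):
        return pd.DataFrame(
            rows, columns=["core_id", "patient_id", "n_tumor_cells", "n_stroma_cells",
                           "mir21_tumor", "cdk2ap1_tumor", "pearson_r", "included"]
        )

    def test_inverse_pearson_order(self):
        summ = self._summary(
            [("a", "p", 600, 10, 1, 1, -0.8, True),
             ("b", "p", 600, 10, 1, 1, 0.1, True),
             ("c", "p", 600, 10, 1, 1, -0.2, True)]
        )
        assert list(rank_cores(summ)["core_id"]) == ["a", "c", "b"]

    def test_single_core_and_nan_last(self):
        summ = self._summary(
            [("a", "p", 600, 10, 1, 1, float("nan"), True),
             ("b", "p", 600, 10, 1, 1, 0.5, True)]
        )
        assert list(rank_cores(summ)["core_id"]) == ["b", "a"]
        single = self._summary([("only", "p", 600, 10, 1, 1, 0.0, True)])
        assert list(rank_cores(single)["core_id"]) == ["only"]

    def test_excluded_cores_never_ranked(self):
        summ = self._summary(
            [("a", "p", 100, 10, 1, 1, -0.9, False),
             ("b", "p", 600, 10, 1, 1, 0.5, True)]
        )
        assert list(rank_cores(summ)["core_id"]) == ["b"]


class TestCompareCompartments:
    def test_recovers_stroma_shift(self):
        cfg = SimConfig(seed=13, n_patients=15, cells_per_core_range=(400, 500),
                        stroma_mir21_shift=2.0, outlier_fraction=0.0)
        cells = gen_tma_cohort(cfg)
        cells["excluded"] = False
        res = compare_compartments(cells)
        assert abs(res["mean_ratio"] - 2.0) < 0.2
        assert res["p_value"] < 0.001

    def test_null_case(self):
        rng = np.random.default_rng(7)
        parts = []
        for i in range(10):
            core = _toy_cells(400, seed=int(rng.integers(2**31)), core_id=f"c{i}")
            core.loc[rng.choice(400, 200, replace=False), "compartment"] = "stroma"
            parts.append(core)
        res = compare_compartments(pd.concat(parts, ignore_index=True))
        assert abs(np.log2(res["mean_ratio"])) < 0.1
        assert res["p_value"] > 0.01

    def test_zero_stroma_signal_gives_zero_ratio(self):
        cells = _toy_cells(100)
        cells.loc[50:, "compartment"] = "stroma"
        cells.loc[50:, MIR21_COLUMN] = 0.0
        res = compare_compartments(cells)
        assert res["per_core"]["ratio"].iloc[0] == 0.0

    def test_missing_compartment_core_skipped(self):
        cells = _toy_cells(50)  # tumor only
        with pytest.warns(UserWarning, match="skipped"):
            res = compare_compartments(cells)
        assert res["n_cores"] == 0


class TestStratifyAndTest:
    def _summaries(self, mir21_values, cdk2ap1_values=None, included=True):
        n = len(mir21_values)
        return pd.DataFrame(
            {
                "core_id": [f"c{i}" for i in range(n)],
                "patient_id": [f"p{i // 3}" for i in range(n)],
                "n_tumor_cells": 600,
                "n_stroma_cells": 100,
                "mir21_tumor": mir21_values,
                "cdk2ap1_tumor": cdk2ap1_values if cdk2ap1_values is not None
                else np.arange(n, dtype=float),
                "pearson_r": -0.5,
                "included": included,
            }
        )

    def test_cutoff_boundary_rules(self):
        summ = self._summaries([151.0, 150.0, 149.0])
        res = stratify_and_test(summ)
        assert res.groups.to_dict() == {"c0": "high", "c1": "low", "c2": "low"}

    def test_empty_group_skipped_with_status(self):
        res = stratify_and_test(self._summaries([10.0, 20.0, 30.0]))
        assert res.status.startswith("skipped")
        assert np.isnan(res.p_value)

    def test_detects_planted_difference_unpaired(self):
        rng = np.random.default_rng(2)
        mir = np.r_[rng.normal(200, 10, 40), rng.normal(100, 10, 40)]
        cdk = np.r_[rng.normal(80, 5, 40), rng.normal(120, 5, 40)]
        res = stratify_and_test(self._summaries(mir, cdk))
        assert res.p_value < 1e-6
        assert res.mean_high < res.mean_low

    def test_patient_paired_mode(self):
        # each patient contributes one high and one low core; CDK2AP1 lower in high
        rows = []
        rng = np.random.default_rng(3)
        for i in range(12):
            rows.append((f"h{i}", f"p{i}", 200.0, 80 + rng.normal(0, 2)))
            rows.append((f"l{i}", f"p{i}", 100.0, 120 + rng.normal(0, 2)))
        summ = pd.DataFrame(rows, columns=["core_id", "patient_id", "mir21_tumor",
                                           "cdk2ap1_tumor"])
        summ["n_tumor_cells"], summ["n_stroma_cells"] = 600, 50
        summ["pearson_r"], summ["included"] = -0.4, True
        res = stratify_and_test(summ, pairing="patient_paired")
        assert res.n_pairs == 12
        assert res.p_value < 1e-8


class TestReconstruct:
    def test_empty_input_no_crash(self, tmp_path):
        out = tmp_path / "empty.png"
        reconstruct(_toy_cells(0), out)
        assert out.exists()

    def test_vector_output_byte_stable(self, tmp_path, small_tma_cells):
        sub = small_tma_cells[small_tma_cells["core_id"] == "P001-C1"]
        p1, p2 = tmp_path / "a.svg", tmp_path / "b.svg"
        reconstruct(sub, p1)
        reconstruct(sub, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_unknown_channel_lists_channels(self, tmp_path, small_tma_cells):
        with pytest.raises(ValueError, match="mir21_cytoplasm_median"):
            reconstruct(small_tma_cells.head(5), tmp_path / "x.png", channel="nope")

    def test_channel_coloring_writes_file(self, tmp_path, small_tma_cells):
        sub = small_tma_cells[small_tma_cells["core_id"] == "P001-C1"]
        out = tmp_path / "chan.png"
        reconstruct(sub, out, channel=MIR21_COLUMN)
        assert out.stat().st_size > 0
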