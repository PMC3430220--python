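"""Normalization, deviation statistics, correction runs and the pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sofmrbf import (
    CANONICAL_DESCRIPTORS,
    DescriptorTable,
    SOFMConfig,
    SPREAD_GRID,
    SyntheticSpec,
    deviation_stats,
    fit_normalization,
    generate,
    mad,
    run_correction,
    run_dft_sofm_rbfnn,
    spread_scan,
)

SELECTED_8 = ("dH_homo", "Q_Y", "Q_N", "N_X", "mu", "alpha", "E_HOMO", "E_LUMO")


class TestNormalization:
    def test_min_max_mapping(self, synthetic_default):
        table, _ = synthetic_default
        params = fit_normalization(table, ["dH_homo", "mu"])
        train = table.descriptor_matrix(["dH_homo", "mu"])[table.train_mask]
        mapped = params.apply(train)
        assert mapped.min() == pytest.approx(-1.0)
        assert mapped.max() == pytest.approx(1.0)
        mid = (params.minimum + params.maximum) / 2
        np.testing.assert_allclose(params.apply(mid[None, :]), 0.0, atol=1e-12)

    def test_out_of_range_values_are_not_clipped(self):
        import pandas as pd

        params = None
        frame = {
            "molecule_id": ["a", "b", "c"],
            "y_type": ["N"] * 3,
            "split": ["train", "train", "test"],
            "expt_bde": [30.0, 40.0, 50.0],
        }
        rng = np.random.default_rng(0)
        for name in CANONICAL_DESCRIPTORS:
            frame[name] = rng.normal(size=3)
        frame["mu"] = [0.0, 10.0, 20.0]  # test row far above the train range
        table = DescriptorTable(pd.DataFrame(frame))
        params = fit_normalization(table, ["mu"])
        assert params.apply(np.array([[20.0]]))[0, 0] == pytest.approx(3.0)
        assert params.apply(np.array([[0.0]]))[0, 0] == pytest.approx(-1.0)

    def test_constant_feature_maps_to_zero(self):
        import pandas as pd

        frame = {
            "molecule_id": ["a", "b"],
            "y_type": ["N"] * 2,
            "split": ["train", "train"],
            "expt_bde": [30.0, 40.0],
        }
        rng = np.random.default_rng(0)
        for name in CANONICAL_DESCRIPTORS:
            frame[name] = rng.normal(size=2)
        frame["N_X"] = [7.0, 7.0]
        table = DescriptorTable(pd.DataFrame(frame))
        params = fit_normalization(table, ["N_X"])
        assert params.constant_features == ("N_X",)
        assert params.apply(np.array([[7.0]]))[0, 0] == 0.0


class TestMad:
    def test_worked_example(self):
        assert mad(np.array([1.0, -1.0, 2.0])) == pytest.approx(4.0 / 3.0)

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            mad(np.array([]))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=20), st.integers(0, 100))
    def test_permutation_and_sign_flip_invariance(self, values, seed):
        v = np.asarray(values)
        rng = np.random.default_rng(seed)
        assert mad(-v) == pytest.approx(mad(v), rel=1e-12)
        assert mad(rng.permutation(v)) == pytest.approx(mad(v), rel=1e-12)


class TestDeviationStats:
    def test_single_value(self):
        s = deviation_stats(np.array([-2.3]))
        assert s.min == s.max == -2.3
        assert s.mad == pytest.approx(2.3)
        assert sum(s.counts) == 1

    def test_counts_conserved_and_bins_centered(self, rng):
        v = rng.normal(scale=5, size=200)
        s = deviation_stats(v, bin_width=1.0)
        assert sum(s.counts) == 200
        centers = (np.asarray(s.bin_edges[:-1]) + np.asarray(s.bin_edges[1:])) / 2
        np.testing.assert_allclose(centers, np.round(centers), atol=1e-9)

    def test_fixture_column_extremes(self, table1):
        s = deviation_stats(table1.deviations("b3lyp_631gd"))
        assert s.min == pytest.approx(-17.17)
        assert s.max == pytest.approx(7.91)

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            deviation_stats(np.array([1.0]), bin_width=0.0)


class TestRunCorrection:
    def test_training_rows_are_interpolated(self, synthetic_default):
        table, _ = synthetic_default
        for spread in (0.4, 0.8, 2.0):
            result = run_correction(table, SELECTED_8, spread)
            assert np.max(np.abs(result.deviations("train"))) <= 1e-6

    def test_molecule_order_is_irrelevant(self, synthetic_default):
        table, _ = synthetic_default
        base = run_correction(table, SELECTED_8, 0.8)
        perm = np.random.default_rng(0).permutation(len(table))
        shuffled_table = DescriptorTable(table.frame.iloc[perm].reset_index(drop=True))
        shuffled = run_correction(shuffled_table, SELECTED_8, 0.8)
        merged = base.frame.merge(shuffled.frame, on="molecule_id", suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["deviation_a"], merged["deviation_b"], atol=1e-7)

    def test_correction_strongly_reduces_systematic_bias(self, synthetic_batch):
        """Median corrected test MAD is well below the raw DFT test MAD."""
        ratios = []
        for table, _ in synthetic_batch:
            scan = spread_scan(table, SELECTED_8)
            corrected = run_correction(table, SELECTED_8, scan.best_spread)
            test = ~table.train_mask
            raw = table.descriptor_matrix(["dH_homo"])[:, 0] - table.expt_bde
            ratios.append(corrected.mad("test") / mad(raw[test]))
        assert np.median(ratios) < 0.5

    def test_residual_mode_agrees_on_training_rows(self, synthetic_default):
        table, _ = synthetic_default
        direct = run_correction(table, SELECTED_8, 0.8, target_mode="bde")
        residual = run_correction(table, SELECTED_8, 0.8, target_mode="residual")
        np.testing.assert_allclose(residual.deviations("train"), direct.deviations("train"), atol=1e-6)

    def test_too_few_train_rows_rejected(self, synthetic_default):
        table, _ = synthetic_default
        frame = table.frame.copy()
        frame["split"] = ["train"] * 2 + ["test"] * (len(frame) - 2)
        small = DescriptorTable(frame)
        run_correction(small, SELECTED_8, 0.8)  # 2 rows is the minimum
        frame2 = frame.copy()
        frame2["split"] = ["train"] + ["test"] * (len(frame2) - 1)
        with pytest.raises(Exception):
            DescriptorTable(frame2)


class TestSpreadScan:
    def test_grid_is_fifteen_spreads(self, synthetic_default):
        table, _ = synthetic_default
        scan = spread_scan(table, SELECTED_8)
        assert scan.spreads == tuple(round(0.2 * k, 1) for k in range(1, 16))
        assert len(SPREAD_GRID) == 15

    def test_best_spread_minimizes_test_mad(self, synthetic_default):
        table, _ = synthetic_default
        scan = spread_scan(table, SELECTED_8)
        best_idx = scan.spreads.index(scan.best_spread)
        assert scan.test_mads[best_idx] == min(scan.test_mads)
        assert all(scan.test_mads[best_idx] <= m for m in scan.test_mads)


class TestPipeline:
    def test_planted_structure_selects_eight_features(self, synthetic_default):
        table, truth = synthetic_default
        report = run_dft_sofm_rbfnn(table, SOFMConfig(seed=1))
        assert len(report.selection.chosen) == 8
        assert report.selection.partition == truth.partition

    def test_selection_does_not_destroy_accuracy(self, synthetic_batch):
        """DFT-SOFM-RBFNN test MAD stays within 1.5x of DFT-RBFNN's (median)."""
        ratios = []
        for seed, (table, _) in enumerate(synthetic_batch):
            report = run_dft_sofm_rbfnn(table, SOFMConfig(seed=seed))
            ratios.append(report.stats["dft_sofm_rbfnn"]["test"].mad / report.stats["dft_rbfnn"]["test"].mad)
        assert np.median(ratios) <= 1.5

    def test_report_is_reproducible(self, synthetic_default):
        table, _ = synthetic_default
        a = run_dft_sofm_rbfnn(table, SOFMConfig(seed=7)).to_json()
        b = run_dft_sofm_rbfnn(table, SOFMConfig(seed=7)).to_json()
        assert a == b
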