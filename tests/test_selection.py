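"""Tests of the four-step channel-selection workflow."""

import numpy as np
import pandas as pd
import pytest

from vocsense.errors import SelectionError
from vocsense.selection import (
    DEFAULT_ASSIGNMENTS,
    UNASSIGNED,
    SelectionConfig,
    assign_vocs,
    correlation_screen,
    knowledge_filter,
    pca_screen,
    run_selection,
)
from vocsense.simulate import SimulationConfig, simulate_run
from vocsense.timeseries import AlignedDataset, VOCMatrix


class TestKnowledgeFilter:
    def test_201_channels_reduce_to_129(self):
        kept = knowledge_filter(list(range(1, 202)))
        assert len(kept) == 129
        assert 18 in kept and 33 in kept and 160 in kept
        assert 32 not in kept and 161 not in kept

    def test_boundary_channels(self):
        assert knowledge_filter([18, 32, 33, 160, 161]) == [18, 33, 160]

    def test_no_exceptions(self):
        assert knowledge_filter([18, 40], exceptions=set()) == [40]

    def test_empty_result_raises(self):
        with pytest.raises(SelectionError):
            knowledge_filter([1, 2, 3])

    def test_inverted_bounds_raise(self):
        with pytest.raises(SelectionError):
            knowledge_filter([40], low=100, high=50)


class TestPcaScreen:
    def test_matches_covariance_eigendecomposition(self, rng):
        """Explained variances agree with a direct covariance eigen-solve."""
        X = rng.normal(size=(60, 50)) @ rng.normal(size=(50, 50))
        channels = list(range(1, 51))
        _, table, evr = pca_screen(X, channels, variance_target=1.0 - 1e-12)
        C = np.cov((X - X.mean(axis=0)).T, ddof=1)
        eigvals = np.sort(np.linalg.eigvalsh(C))[::-1]
        expected = eigvals / eigvals.sum()
        np.testing.assert_allclose(evr, expected[:evr.size], rtol=1e-8)
        # loading vectors match up to sign
        eigvals_full, eigvecs = np.linalg.eigh(C)
        order = np.argsort(eigvals_full)[::-1]
        for i in range(3):
            ours = table[f"pc{i + 1}_loading"].to_numpy()
            ref = eigvecs[:, order[i]]
            assert min(np.abs(ours - ref).max(), np.abs(ours + ref).max()) < 1e-8

    def test_planted_high_variance_channels_survive(self, rng):
        trend = np.sin(np.linspace(0, 3, 200)) * 50
        X = rng.normal(scale=0.5, size=(200, 20))
        X[:, 3] += trend
        X[:, 11] += 0.8 * trend
        survivors, _, _ = pca_screen(X, list(range(1, 21)))
        assert set(survivors) == {4, 12}

    def test_duplicated_channel_tie_symmetry(self, rng):
        X = rng.normal(size=(50, 5))
        X[:, 2] = X[:, 1]
        survivors, _, _ = pca_screen(X, [1, 2, 3, 4, 5])
        assert (2 in survivors) == (3 in survivors)

    def test_zero_threshold_keeps_everything(self, rng):
        X = rng.normal(size=(30, 6))
        survivors, _, _ = pca_screen(X, list(range(6)), importance_threshold=0.0)
        assert survivors == list(range(6))

    def test_constant_matrix_rejected(self):
        with pytest.raises(SelectionError, match="constant"):
            pca_screen(np.ones((10, 4)), [1, 2, 3, 4])


class TestAssignVocs:
    def test_default_table_names_the_six_known_vocs(self):
        out = assign_vocs([18, 33, 45, 47, 59, 63])
        assert out == DEFAULT_ASSIGNMENTS

    def test_unknown_channel_excluded(self):
        out = assign_vocs([18, 33, 99])
        assert out[99] == UNASSIGNED
        assert out[18] == "ammonia"

    def test_empty_input(self):
        assert assign_vocs([]) == {}


def make_aligned(vcd, channels_values: dict):
    t = np.arange(len(vcd), dtype=float) * 0.5
    data = {"time_days": t, "vcd": np.asarray(vcd, dtype=float),
            "viability": np.full(len(vcd), 95.0),
            "glucose": np.linspace(5, 0, len(vcd)),
            "lactate": np.linspace(0, 2, len(vcd))}
    cols = []
    for mz, values in channels_values.items():
        col = f"mz_{mz}"
        data[col] = np.asarray(values, dtype=float)
        cols.append(col)
    return AlignedDataset(pd.DataFrame(data), cols)


class TestCorrelationScreen:
    def test_identical_channel_has_unit_correlation(self):
        vcd = np.array([1.0, 2.0, 4.0, 6.5, 8.0])
        ds = make_aligned(vcd, {33: vcd})
        survivors, matrix = correlation_screen([ds], [33])
        assert survivors == [33]
        assert matrix.loc[33, "vcd"] == pytest.approx(1.0)

    def test_affine_invariance_with_sign_flip(self):
        vcd = np.array([1.0, 2.0, 4.0, 6.5, 8.0])
        ds = make_aligned(vcd, {33: -2.0 * vcd + 7.0})
        survivors, matrix = correlation_screen([ds], [33])
        # direct formula oracle
        x, y = -2.0 * vcd + 7.0, vcd
        r = np.corrcoef(x, y)[0, 1]
        assert matrix.loc[33, "vcd"] == pytest.approx(r) == pytest.approx(-1.0)
        assert survivors == [33]

    def test_iid_noise_rejected(self):
        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vcd = np.linspace(1, 8, 20)
            ds = make_aligned(vcd, {40: rng.normal(size=20)})
            survivors, _ = correlation_screen([ds], [40])
            rejections += (survivors == [])
        assert rejections >= 19

    def test_zero_variance_channel_reported_undefined(self):
        vcd = np.array([1.0, 2.0, 4.0])
        ds = make_aligned(vcd, {33: np.full(3, 5.0)})
        survivors, matrix = correlation_screen([ds], [33])
        assert survivors == []
        assert matrix.loc[33].isna().all()

    def test_needs_three_rows_per_run(self):
        vcd = np.array([1.0, 2.0])
        ds = make_aligned(vcd, {33: vcd})
        with pytest.raises(SelectionError):
            correlation_screen([ds], [33])


class TestRunSelection:
    def test_recovers_planted_channels(self, training_triplicate):
        report = run_selection(training_triplicate)
        assert report.step4_channels == [33, 59]
        report.validate_nesting()
        assert len(report.step1_channels) == 129

    def test_workflow_reduces_many_channels_to_few(self, training_triplicate):
        report = run_selection(training_triplicate)
        assert len(training_triplicate[0].voc.channels) >= 100
        assert len(report.step4_channels) <= 6
        assert set(report.step4_channels) >= {33, 59}

    def test_repeat_invocation_is_identical(self, training_triplicate):
        a = run_selection(training_triplicate)
        b = run_selection(training_triplicate)
        assert a.to_dict() == b.to_dict()

    def test_recovery_across_seeds(self):
        hits = 0
        for seed in range(10):
            runs = [simulate_run(SimulationConfig.batch(seed=1000 + 3 * seed + i))[0]
                    for i in range(3)]
            report = run_selection(runs)
            hits += (set(report.step4_channels) == {33, 59})
        assert hits >= 9

    def test_disjoint_channel_sets_rejected(self, training_triplicate):
        bad = training_triplicate[0]
        clipped = bad.voc.subset(bad.voc.channels[:-1])
        from vocsense.timeseries import CultivationRun
        mutant = CultivationRun("bad", clipped, bad.offline, bad.permittivity)
        with pytest.raises(SelectionError, match="differ"):
            run_selection([training_triplicate[1], mutant])

    def test_report_persists(self, tmp_path, training_triplicate):
        report = run_selection(training_triplicate)
        report.save(tmp_path)
        assert (tmp_path / "selection_report.json").exists()
        assert (tmp_path / "correlation_heatmap.csv").exists()
        assert (tmp_path / "loadings.csv").exists()
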