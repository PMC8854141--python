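"""Tests of metrics, smoothing, BR-LM training, CV and ensemble estimation."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vocsense.errors import VocSenseError
from vocsense.sensor import (
    EnsembleModel,
    NetModel,
    aggregate,
    estimate_with_ci,
    evaluate_on_runs,
    loo_batch_cv,
    moving_average,
    nrmse,
    train_brann,
)


class TestNrmse:
    def test_perfect_estimator(self):
        assert nrmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_computed_value(self):
        assert nrmse([1, 2, 3], [1, 2, 4]) == pytest.approx(100 * np.sqrt(1 / 3) / 2)

    def test_constant_bias_closed_form(self):
        y = np.array([2.0, 4.0, 6.0])
        assert nrmse(y, y + 0.5) == pytest.approx(100 * 0.5 / 4.0)

    def test_zero_mean_rejected(self):
        with pytest.raises(VocSenseError):
            nrmse([-1.0, 1.0], [0.0, 0.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(VocSenseError):
            nrmse([1.0, 2.0], [1.0])

    @given(st.floats(min_value=0.1, max_value=100.0))
    @settings(deadline=None, max_examples=25)
    def test_scale_invariance(self, c):
        y = np.array([1.0, 2.0, 5.0])
        y_hat = np.array([1.5, 1.8, 4.0])
        assert nrmse(c * y, c * y_hat) == pytest.approx(nrmse(y, y_hat))


def brute_moving_average(x, window):
    return np.array([np.mean(x[max(0, i - window + 1):i + 1]) for i in range(len(x))])


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        np.testing.assert_array_equal(moving_average(np.full(20, 3.0), 10), np.full(20, 3.0))

    def test_window_one_is_identity(self, rng):
        x = rng.normal(size=30)
        np.testing.assert_array_equal(moving_average(x, 1), x)

    @pytest.mark.parametrize("window", [2, 3, 10, 50])
    def test_matches_brute_force_loop(self, rng, window):
        x = rng.normal(size=64)
        np.testing.assert_allclose(moving_average(x, window),
                                   brute_moving_average(x, window), rtol=1e-12)

    def test_delayed_step_response(self):
        """A 0->1 step at scan 5: the window holds min(k-4, 10) ones out of
        min(k+1, 10) values, so the output ramps to 1 over one window."""
        x = np.concatenate([np.zeros(5), np.ones(20)])
        out = moving_average(x, 10)
        for k in range(5, 25):
            assert out[k] == pytest.approx(min(k - 4, 10) / min(k + 1, 10))
        np.testing.assert_array_equal(out[:5], 0.0)

    def test_output_inside_input_envelope(self, rng):
        x = rng.normal(size=100)
        out = moving_average(x, 7)
        assert out.min() >= x.min() - 1e-12
        assert out.max() <= x.max() + 1e-12

    def test_bad_window_rejected(self):
        with pytest.raises(VocSenseError):
            moving_average([1.0], 0)


class TestTrainBrann:
    def test_recovers_noiseless_linear_law(self, rng):
        X = rng.uniform(1, 5, size=(20, 1))
        y = 2.0 * X[:, 0]
        model = train_brann(X, y, seed=1)
        assert nrmse(y, model.predict(X)) < 1.0   # percent
        assert model.alpha > 0 and model.beta > 0

    def test_constant_target_reproduced(self, rng):
        X = rng.uniform(0, 5, size=(12, 2))
        model = train_brann(X, np.full(12, 3.0), seed=2)
        np.testing.assert_allclose(model.predict(X), 3.0, atol=1e-6)

    def test_multi_start_consistency(self, rng):
        X = rng.uniform(1, 5, size=(24, 2))
        y = X[:, 0] + 0.5 * X[:, 1]
        scores = [nrmse(y, train_brann(X, y, seed=s).predict(X)) for s in (11, 12)]
        assert max(scores) < 1.0

    def test_too_few_rows_rejected(self):
        with pytest.raises(VocSenseError, match="4"):
            train_brann(np.ones((3, 1)), np.ones(3))

    def test_non_finite_data_rejected(self):
        X = np.ones((5, 1))
        y = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        with pytest.raises(VocSenseError, match="finite"):
            train_brann(X, y)

    def test_architecture_bounds_enforced(self):
        X, y = np.ones((6, 1)), np.arange(6.0)
        from vocsense.errors import ConfigError
        with pytest.raises(ConfigError):
            train_brann(X, y, hidden=(12,))
        with pytest.raises(ConfigError):
            train_brann(X, y, hidden=(4, 4, 4, 4))


def linear_datasets(seeds, n=10, slope=2.0):
    out = []
    for s in seeds:
        rng = np.random.default_rng(s)
        X = rng.uniform(1, 5, size=(n, 1))
        out.append((f"run{s}", X, slope * X[:, 0]))
    return out


class TestLooBatchCV:
    def test_planted_law_gives_small_validation_error(self):
        results, best = loo_batch_cv(linear_datasets([1, 2, 3]), seed=0)
        assert best == (8,)
        for fold in results[0].folds:
            assert fold.val_nrmse < 1.0

    def test_identical_runs_give_identical_scores(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(1, 5, size=(10, 1))
        y = 2.0 * X[:, 0]
        results, _ = loo_batch_cv([("a", X, y), ("b", X, y)], seed=3)
        scores = [f.val_nrmse for f in results[0].folds]
        assert scores[0] == pytest.approx(scores[1], rel=1e-9)

    def test_single_candidate_architecture_wins(self):
        _, best = loo_batch_cv(linear_datasets([1, 2]), hidden_grid=[(8,)], seed=0)
        assert best == (8,)

    def test_needs_two_runs(self):
        with pytest.raises(VocSenseError):
            loo_batch_cv(linear_datasets([1]))


def constant_model(value: float, channels=(33, 59)) -> NetModel:
    """A degenerate network that predicts `value` everywhere."""
    n_in = len(channels)
    return NetModel(
        channels=list(channels), hidden=(2,),
        weights=[np.zeros((2, n_in)), np.zeros((1, 2))],
        biases=[np.zeros(2), np.zeros(1)],
        x_mean=np.zeros(n_in), x_scale=np.ones(n_in),
        y_mean=float(value), y_scale=1.0,
    )


class TestEnsemble:
    def test_two_member_worked_example(self):
        """Members at 10 and 14: mean 12, SD sqrt(8), CI 12 +/- 2.8284."""
        ensemble = aggregate([constant_model(10.0), constant_model(14.0)])
        X = np.ones((5, 2))
        est = estimate_with_ci(ensemble, np.arange(5.0), X)
        np.testing.assert_allclose(est.estimate, 12.0)
        np.testing.assert_allclose(est.sd, np.sqrt(8.0))
        np.testing.assert_allclose(est.ci_low, 12.0 - 2.8284, atol=1e-4)
        np.testing.assert_allclose(est.ci_high, 12.0 + 2.8284, atol=1e-4)

    def test_identical_members_collapse_ci(self):
        ensemble = aggregate([constant_model(7.0), constant_model(7.0)])
        est = estimate_with_ci(ensemble, np.arange(3.0), np.ones((3, 2)))
        np.testing.assert_array_equal(est.sd, 0.0)
        np.testing.assert_array_equal(est.ci_low, est.estimate)

    def test_single_member_sd_zero_with_notice(self, caplog):
        ensemble = aggregate([constant_model(9.0)])
        with caplog.at_level(logging.INFO):
            est = estimate_with_ci(ensemble, np.arange(3.0), np.ones((3, 2)))
        np.testing.assert_allclose(est.estimate, 9.0)
        np.testing.assert_array_equal(est.sd, 0.0)
        assert any("single" in rec.message.lower() for rec in caplog.records)

    def test_permutation_invariance(self):
        a = aggregate([constant_model(10.0), constant_model(14.0)])
        b = aggregate([constant_model(14.0), constant_model(10.0)])
        X = np.ones((4, 2))
        est_a = estimate_with_ci(a, np.arange(4.0), X)
        est_b = estimate_with_ci(b, np.arange(4.0), X)
        np.testing.assert_allclose(est_a.estimate, est_b.estimate)
        np.testing.assert_allclose(est_a.sd, est_b.sd)

    def test_mismatched_member_channels_rejected(self):
        from vocsense.errors import ConfigError
        with pytest.raises(ConfigError):
            aggregate([constant_model(1.0, (33, 59)), constant_model(1.0, (33, 45))])

    def test_persistence_round_trip(self, tmp_path):
        ensemble = aggregate([constant_model(10.0), constant_model(14.0)])
        ensemble.save(tmp_path / "model")
        back = EnsembleModel.load(tmp_path / "model")
        X = np.ones((3, 2))
        np.testing.assert_allclose(back.member_predictions(X),
                                   ensemble.member_predictions(X))


class TestEvaluateOnRuns:
    def test_biased_benchmark_matches_closed_form(self):
        """Capacitance trace at 1.5x true VCD: NRMSE = 50 * rms / mean."""
        from vocsense.timeseries import CultivationRun, Trace
        from conftest import noiseless_config
        from vocsense.simulate import simulate_run

        run, truth = simulate_run(noiseless_config(seed=8))
        biased = Trace(truth.time.copy(), 1.5 * truth.vcd_true / 0.63)
        run = CultivationRun(run.run_id, run.voc, run.offline, biased)
        member = train_brann(
            np.column_stack([np.interp(run.offline.time, run.voc.time,
                                       run.voc.channel_values(c)) for c in (33, 59)]),
            run.offline.vcd, channels=[33, 59], seed=3)
        report = evaluate_on_runs(aggregate([member]), [run])
        y = run.offline.vcd
        expected = 100 * 0.5 * np.sqrt(np.mean(y ** 2)) / np.mean(y)
        assert report.benchmark_nrmse_pct == pytest.approx(expected, rel=1e-9)
        assert report.nrmse_pct < report.benchmark_nrmse_pct
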