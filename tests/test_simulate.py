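"""Tests of the synthetic cultivation generator against independent oracles."""

import math

import numpy as np
import pytest

from vocsense.errors import ConfigError
from vocsense.simulate import (
    ChannelModel,
    SimulationConfig,
    SimulationTruth,
    emit_voc,
    growth_step,
    simulate_run,
)

from conftest import noiseless_config


def euler_oracle(cfg: SimulationConfig, dt: float):
    """Independent explicit-Euler forward integration of the same kinetics."""
    n = int(round(cfg.duration / dt))
    t_idx = None if cfg.transfection_time is None else int(round(cfg.transfection_time / dt))
    vcd, glc, lac = cfg.initial_vcd, cfg.initial_glucose, 0.0
    times, glcs = [0.0], [glc]
    for i in range(n):
        factor = cfg.post_transfection_mu_factor if (t_idx is not None and i >= t_idx) else 1.0
        mu = factor * cfg.monod_mu_max * glc / (cfg.monod_ks + glc) if glc > 0 else 0.0
        dx = mu * vcd * dt
        need = min(dx / cfg.yield_glc, glc)
        vcd += need * cfg.yield_glc
        glc -= need
        lac += cfg.lactate_yield * need
        if t_idx is not None and i + 1 == t_idx:
            vcd, glc, lac = vcd / 2, glc / 2 + cfg.fresh_glucose / 2, lac / 2
        times.append((i + 1) * dt)
        glcs.append(glc)
    return np.array(times), np.array(glcs)


class TestGrowthStep:
    def test_starvation_limit(self):
        cfg = SimulationConfig.batch()
        vcd, glc, lac, viab = growth_step((5.0, 0.0, 0.0, 90.0), cfg, 0.01)
        assert vcd == 5.0
        assert viab < 90.0

    def test_saturation_limit_matches_exponential(self):
        cfg = SimulationConfig.batch(monod_ks=1e-12, initial_glucose=100.0)
        dt = 0.005
        vcd, *_ = growth_step((1.0, 100.0, 0.0, 100.0), cfg, dt)
        assert vcd == pytest.approx(math.exp(cfg.monod_mu_max * dt), rel=1e-9)

    def test_local_error_shrinks_quadratically(self):
        """One coarse step vs a fine-step oracle: O(dt^2) local error."""
        cfg = SimulationConfig.batch()

        def fine(state, dt, substeps):
            for _ in range(substeps):
                state = growth_step(state, cfg, dt / substeps)
            return state

        state = (2.0, 3.0, 0.5, 100.0)
        errs = []
        for dt in (0.08, 0.04):
            coarse = growth_step(state, cfg, dt)
            ref = fine(state, dt, 512)
            errs.append(abs(coarse[0] - ref[0]))
        ratio = errs[0] / errs[1]
        assert 2.0 < ratio < 8.0   # halving dt cuts local error ~4x

    def test_negative_state_rejected(self):
        cfg = SimulationConfig.batch()
        with pytest.raises(ConfigError):
            growth_step((-1.0, 2.0, 0.0, 100.0), cfg, 0.01)
        with pytest.raises(ConfigError):
            growth_step((1.0, 2.0, 0.0, 100.0), cfg, 0.0)


class TestSimulateRun:
    def test_deterministic_for_fixed_seed(self):
        cfg = SimulationConfig.batch(seed=7)
        run_a, truth_a = simulate_run(cfg)
        run_b, truth_b = simulate_run(SimulationConfig.batch(seed=7))
        np.testing.assert_array_equal(run_a.voc.values, run_b.voc.values)
        np.testing.assert_array_equal(run_a.offline.vcd, run_b.offline.vcd)
        np.testing.assert_array_equal(run_a.permittivity.values, run_b.permittivity.values)
        np.testing.assert_array_equal(truth_a.vcd_true, truth_b.vcd_true)

    def test_noiseless_offline_equals_truth(self):
        run, truth = simulate_run(noiseless_config(seed=3))
        idx = np.searchsorted(truth.time, run.offline.time)
        np.testing.assert_array_equal(run.offline.vcd, truth.vcd_true[idx])
        np.testing.assert_array_equal(run.offline.glucose, truth.glucose_true[idx])

    def test_depletion_time_matches_fine_euler_oracle(self):
        cfg = SimulationConfig.batch(seed=1)
        _, truth = simulate_run(cfg)
        t, glc = euler_oracle(cfg, cfg.online_dt / 10)
        below = glc <= cfg.depletion_tolerance
        t_oracle = t[np.flatnonzero(~below[:-1] & below[1:])[0] + 1]
        assert len(truth.depletion_times) == 1
        assert abs(truth.depletion_times[0] - t_oracle) <= cfg.online_dt

    def test_transfection_dilution_arithmetic(self):
        cfg = noiseless_config(seed=5)
        cfg.duration = 9.0
        cfg.transfection_time = 3.7
        _, truth = simulate_run(cfg)
        i = int(round(3.7 / cfg.online_dt))
        # pre-dilution state: one kinetic step from the previous grid point
        pre = growth_step(
            (truth.vcd_true[i - 1], truth.glucose_true[i - 1],
             truth.lactate_true[i - 1], truth.viability_true[i - 1]),
            cfg, cfg.online_dt,
        )
        assert truth.vcd_true[i] == pytest.approx(pre[0] / 2, rel=1e-12)
        assert truth.glucose_true[i] == pytest.approx(
            pre[1] / 2 + cfg.fresh_glucose / 2, rel=1e-12)

    def test_truth_invariants(self, transfected_run):
        _, truth = transfected_run
        assert np.all(truth.vcd_true >= 0)
        assert np.all(truth.glucose_true >= 0)
        assert np.all(truth.lactate_true >= 0)
        dglc = np.diff(truth.glucose_true)
        i_tf = int(round(truth.transfection_time / (truth.time[1] - truth.time[0])))
        increases = np.flatnonzero(dglc > 1e-9) + 1
        assert list(increases) == [i_tf]   # glucose only rises at transfection
        for d in truth.depletion_times:
            i = np.searchsorted(truth.time, d)
            assert truth.glucose_true[i] <= 0.05
            assert truth.glucose_true[i - 1] > 0.05 or truth.glucose_true[i - 1] > 0

    @pytest.mark.parametrize("field,value", [
        ("duration", -1.0),
        ("online_dt", 0.0),
        ("transfection_time", 99.0),
        ("monod_mu_max", -0.1),
    ])
    def test_invalid_config_names_field(self, field, value):
        cfg = SimulationConfig.batch()
        setattr(cfg, field, value)
        with pytest.raises(ConfigError, match=field):
            simulate_run(cfg)


class TestEmitVoc:
    def test_zero_noise_planted_channel_is_affine_in_vcd(self):
        cfg = noiseless_config(seed=2)
        cfg.channel_spec[33] = ChannelModel("biomass", gain=4.0, offset=0.0, noise_sd=0.0)
        run, truth = simulate_run(cfg)
        np.testing.assert_allclose(run.voc.channel_values(33), 4.0 * truth.vcd_true,
                                   rtol=0, atol=1e-12)

    def test_burst_peak_matches_reported_scale(self):
        """Baseline 60 ppb with +185% bursts peaks near 170 ppb."""
        cfg = noiseless_config(seed=4)
        cfg.channel_spec[45] = ChannelModel("burst", baseline=60.0,
                                            relative_increase=1.85, noise_sd=0.0)
        run, truth = simulate_run(cfg)
        signal = run.voc.channel_values(45)
        pre = signal[run.voc.time < truth.depletion_times[0]]
        post = signal[run.voc.time >= truth.depletion_times[0]]
        assert np.all(pre == 60.0)
        assert post.max() == pytest.approx(60.0 * 2.85, rel=1e-12)   # ~170 ppb

    def test_informative_channels_track_sampled_vcd(self, batch_run):
        run, truth = batch_run
        for mz in truth.informative_channels:
            x = np.interp(run.offline.time, run.voc.time, run.voc.channel_values(mz))
            y = run.offline.vcd
            # direct Pearson formula as the oracle
            xm, ym = x - x.mean(), y - y.mean()
            r = np.sum(xm * ym) / np.sqrt(np.sum(xm ** 2) * np.sum(ym ** 2))
            assert r > 0.95

    def test_burst_channel_quiescent_before_depletion(self, batch_run):
        run, truth = batch_run
        signal = run.voc.channel_values(truth.burst_channel)
        pre = signal[run.voc.time < truth.depletion_times[0]]
        assert pre.std() / pre.mean() < 0.05

    def test_role_collision_rejected(self, batch_run):
        _, truth = batch_run
        clashing = SimulationTruth(
            time=truth.time, vcd_true=truth.vcd_true,
            viability_true=truth.viability_true, glucose_true=truth.glucose_true,
            lactate_true=truth.lactate_true, depletion_times=truth.depletion_times,
            informative_channels={33, 59}, burst_channel=33,
        )
        from vocsense.simulate import NoiseConfig, default_channel_spec
        with pytest.raises(ConfigError, match="role"):
            emit_voc(clashing, default_channel_spec(), NoiseConfig(), seed=0)
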