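"""Synthetic HEK 293 cultivation generator.

Produces ground truth plus noisy observables with the statistical structure
the downstream analysis assumes, so the whole pipeline is testable without
instrument data:

* batch growth kinetics — Monod-limited growth on glucose with lactate
  production during growth, lactate consumption as an alternative fuel after
  glucose depletion, and viability decline once both are exhausted;
* an optional transfection event — 1:1 dilution with fresh medium (viable
  cell density halves, glucose is replenished) at a configurable time;
* a PTR-MS VOC matrix — two biomass-correlated channels (default m/z 33 and
  59), a glucose-depletion burst channel (default m/z 45, a random telegraph
  wave riding on an elevated floor), growth-activity channels (m/z 47, 63),
  device-only channels below m/z 33 (except m/z 18), and a 0–4 ppb noise
  floor above m/z 160;
* a permittivity trace — proportional to viable cell density with a slow
  multiplicative bias (sinusoid + drift), a first-order response lag and a
  small drawdown shortly after each glucose depletion, emulating the
  capacitance probe's delayed drop/plateau response.

All randomness flows from a single integer seed; identical config + seed
gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .timeseries import (
    TIME_COLUMN,
    CultivationRun,
    OfflineTable,
    Trace,
    VOCMatrix,
)

DEFAULT_PERMITTIVITY_FACTOR = 0.63


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ChannelModel:
    """Emission model for one m/z channel.

    kind:
      ``biomass``  value = gain * vcd + offset           (soft-sensor inputs)
      ``burst``    telegraph bursts after glucose depletion over ``baseline``
      ``growth``   value = offset + gain * growth activity (d vcd / dt)
      ``device``   run-independent offset + noise (instrument background)
      ``floor``    near-zero noise floor
    """

    kind: str
    gain: float = 0.0
    offset: float = 0.0
    baseline: float = 0.0
    relative_increase: float = 1.85   # burst peak = baseline * (1 + this)
    floor_fraction: float = 0.35      # in-event elevated floor over baseline
    mean_hold: float = 0.02           # days; telegraph mean holding time
    onset_hold: float = 0.03          # days; sustained first wave at onset
    drift_amplitude: float = 0.0      # ppb; slow sinusoidal drift (m/z 18)
    drift_period: float = 3.0         # days
    noise_sd: float | None = None     # fractional; None -> global default

    _KINDS = ("biomass", "burst", "growth", "device", "floor")


def default_channel_spec() -> dict[int, ChannelModel]:
    """Channel models for the default simulated instrument.

    m/z 33 (methanol) and 59 (acetone) track biomass; m/z 45 (acetaldehyde)
    bursts at glucose depletion (~60 ppb baseline, +185% peaks); m/z 47
    (ethanol) and 63 (ethanethiol) follow growth activity with heavy noise;
    m/z 18 (ammonia) carries a slow device drift.
    """
    return {
        18: ChannelModel("device", offset=25.0, drift_amplitude=8.0, drift_period=3.0,
                         noise_sd=0.05),
        33: ChannelModel("biomass", gain=5.0, offset=20.0),
        45: ChannelModel("burst", baseline=60.0, relative_increase=1.85),
        47: ChannelModel("growth", gain=6.0, offset=10.0, noise_sd=0.10),
        59: ChannelModel("biomass", gain=12.0, offset=8.0),
        63: ChannelModel("growth", gain=2.5, offset=4.0, noise_sd=0.15),
    }


@dataclass
class NoiseConfig:
    """Observation-noise amplitudes (set every field to 0 for noiseless runs)."""

    voc_multiplicative_sd: float = 0.03       # fractional, per scan and channel
    offline_sd: dict[str, float] = field(default_factory=lambda: {
        "vcd": 0.15, "viability": 1.0, "glucose": 0.08, "lactate": 0.05, "titer": 0.02,
    })
    permittivity_sd: float = 0.01             # fractional


@dataclass
class PermittivityBiasConfig:
    """Slowly varying multiplicative bias + response model of the probe."""

    amplitude: float = 0.2      # fractional sinusoidal bias amplitude
    period: float = 8.0         # days
    drift: float = 0.02         # fractional bias per day
    lag_tau: float = 0.12       # days; first-order response lag
    dip_depth: float = 0.05     # fractional drawdown after depletion
    dip_lag: float = 0.25       # days from depletion to the drawdown centre
    dip_width: float = 0.05     # days (Gaussian sigma)


@dataclass
class SimulationConfig:
    """Full description of one simulated cultivation."""

    duration: float = 4.0                 # days
    online_dt: float = 0.005              # days between instrument scans
    offline_times: list[float] | None = None   # default: every 0.5 day
    transfection_time: float | None = None
    initial_vcd: float = 1.0              # 1e6 cells/mL
    initial_glucose: float = 5.0          # g/L
    fresh_glucose: float = 6.0            # g/L in the dilution medium
    monod_mu_max: float = 0.9             # 1/day
    monod_ks: float = 0.3                 # g/L
    yield_glc: float = 1.4                # (1e6 cells/mL) per (g/L glucose)
    lactate_yield: float = 0.6            # g lactate per g glucose consumed
    lactate_consumption_rate: float = 0.12   # (g/L)/day per (1e6 cells/mL)
    death_rate: float = 0.1               # 1/day once glucose and lactate gone
    post_transfection_mu_factor: float = 0.4
    depletion_tolerance: float = 0.05     # g/L; glucose below this = depleted
    max_mz: int = 201                     # channels emitted: m/z 1..max_mz
    channel_spec: dict[int, ChannelModel] = field(default_factory=default_channel_spec)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    permittivity_bias: PermittivityBiasConfig = field(default_factory=PermittivityBiasConfig)
    seed: int = 0

    def resolved_offline_times(self) -> np.ndarray:
        if self.offline_times is None:
            return np.arange(0.0, self.duration + 1e-9, 0.5)
        return np.asarray(self.offline_times, dtype=float)

    def validate(self) -> None:
        if not (self.duration > 0):
            raise ConfigError(f"duration: must be > 0, got {self.duration}")
        if not (self.online_dt > 0):
            raise ConfigError(f"online_dt: must be > 0, got {self.online_dt}")
        t_off = self.resolved_offline_times()
        if np.any(t_off < 0) or np.any(t_off > self.duration + 1e-12):
            raise ConfigError("offline_times: outside [0, duration]")
        if self.transfection_time is not None and not (
            0 < self.transfection_time < self.duration
        ):
            raise ConfigError(
                f"transfection_time: must lie in (0, duration), got {self.transfection_time}"
            )
        for name in (
            "initial_vcd", "initial_glucose", "fresh_glucose", "monod_mu_max",
            "monod_ks", "yield_glc", "lactate_yield", "lactate_consumption_rate",
            "death_rate", "post_transfection_mu_factor", "depletion_tolerance",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name}: must be non-negative, got {getattr(self, name)}")
        if self.yield_glc == 0:
            raise ConfigError("yield_glc: must be positive")
        if self.max_mz < 1:
            raise ConfigError(f"max_mz: must be >= 1, got {self.max_mz}")
        if self.noise.voc_multiplicative_sd < 0 or self.noise.permittivity_sd < 0:
            raise ConfigError("noise: standard deviations must be non-negative")
        if any(sd < 0 for sd in self.noise.offline_sd.values()):
            raise ConfigError("noise.offline_sd: standard deviations must be non-negative")
        for mz, model in self.channel_spec.items():
            if model.kind not in ChannelModel._KINDS:
                raise ConfigError(f"channel_spec[{mz}]: unknown kind {model.kind!r}")
        kinds = {}
        for mz, model in self.channel_spec.items():
            if mz in kinds and kinds[mz] != model.kind:
                raise ConfigError(f"channel_spec: m/z {mz} declared in two roles")
            kinds[mz] = model.kind

    # -- canonical study set-ups -------------------------------------------

    @classmethod
    def batch(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """4-day non-transfected batch culture (growth to ~8e6 cells/mL)."""
        params = dict(duration=4.0, transfection_time=None, initial_vcd=1.0,
                      initial_glucose=5.0)
        params.update(overrides)
        return cls(seed=seed, **params)

    @classmethod
    def transfected(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """4+5-day run: growth phase, 1:1 dilution + transfection at day 3.7."""
        params = dict(duration=9.0, transfection_time=3.7, initial_vcd=0.5,
                      initial_glucose=6.0)
        params.update(overrides)
        return cls(seed=seed, **params)


@dataclass
class SimulationTruth:
    """Ground truth of one simulated run (never fed to estimation stages)."""

    time: np.ndarray                # days, online grid
    vcd_true: np.ndarray            # 1e6 cells/mL
    viability_true: np.ndarray      # percent
    glucose_true: np.ndarray        # g/L
    lactate_true: np.ndarray        # g/L
    depletion_times: list[float]    # glucose-exhaustion instants
    informative_channels: set[int]  # biomass-correlated m/z planted
    burst_channel: int              # depletion-indicator m/z planted
    transfection_time: float | None = None


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

def growth_step(state, params, dt: float, mu_factor: float = 1.0):
    """Advance (vcd, glucose, lactate, viability) by one step of length dt.

    Growth follows Monod kinetics with an exponential per-step update
    (vcd multiplied by exp(mu dt), exact for frozen mu), glucose is consumed
    stoichiometrically at yield_glc, lactate is produced during growth and
    consumed as an alternative fuel after glucose depletion, and viability
    declines at death_rate once both carbon sources are exhausted.  All
    outputs are clipped at zero.
    """
    if dt <= 0:
        raise ConfigError(f"dt: must be > 0, got {dt}")
    vcd, glc, lac, viab = (float(v) for v in state)
    if min(vcd, glc, lac, viab) < 0:
        raise ConfigError("state: negative component")
    mu = 0.0
    if glc > 0:
        mu = mu_factor * params.monod_mu_max * glc / (params.monod_ks + glc)
    growth = vcd * (math.exp(mu * dt) - 1.0)
    need = growth / params.yield_glc
    if need > glc:                       # glucose runs out inside the step
        need = glc
        growth = glc * params.yield_glc
    vcd += growth
    glc -= need
    lac += params.lactate_yield * need
    if glc <= params.depletion_tolerance:
        lac = max(0.0, lac - params.lactate_consumption_rate * vcd * dt)
        if lac <= params.depletion_tolerance:
            viab *= math.exp(-params.death_rate * dt)
    return (max(vcd, 0.0), max(glc, 0.0), max(lac, 0.0), min(max(viab, 0.0), 100.0))


def _integrate(config: SimulationConfig):
    dt = config.online_dt
    n = int(round(config.duration / dt))
    time = np.arange(n + 1) * dt
    vcd = np.empty(n + 1)
    glc = np.empty(n + 1)
    lac = np.empty(n + 1)
    viab = np.empty(n + 1)
    state = (config.initial_vcd, config.initial_glucose, 0.0, 100.0)
    vcd[0], glc[0], lac[0], viab[0] = state
    t_idx = None
    if config.transfection_time is not None:
        t_idx = int(round(config.transfection_time / dt))
    for i in range(n):
        factor = 1.0
        if t_idx is not None and i >= t_idx:
            factor = config.post_transfection_mu_factor
        state = growth_step(state, config, dt, mu_factor=factor)
        if t_idx is not None and i + 1 == t_idx:
            # 1:1 dilution with fresh medium at transfection
            v, g, l, w = state
            state = (v / 2.0, g / 2.0 + config.fresh_glucose / 2.0, l / 2.0, w)
        vcd[i + 1], glc[i + 1], lac[i + 1], viab[i + 1] = state
    tol = config.depletion_tolerance
    below = glc <= tol
    crossings = np.flatnonzero(~below[:-1] & below[1:]) + 1
    depletion_times = [float(time[i]) for i in crossings]
    return time, vcd, glc, lac, viab, depletion_times


# ---------------------------------------------------------------------------
# VOC emission
# ---------------------------------------------------------------------------

def _burst_windows(truth: SimulationTruth) -> list[tuple[float, float]]:
    """Active fluctuation windows: from each depletion until replenishment/end."""
    end_of_run = float(truth.time[-1])
    windows = []
    for d in truth.depletion_times:
        end = end_of_run
        if truth.transfection_time is not None and truth.transfection_time > d:
            end = min(end, truth.transfection_time)
        windows.append((d, end))
    return windows


def _telegraph(rng: np.random.Generator, time: np.ndarray, mean_hold: float,
               onset_hold: float = 0.0) -> np.ndarray:
    """Random telegraph wave on the given grid, starting in the high state.

    The first (high) holding time is at least ``onset_hold``: the onset of
    the fluctuation phase is a sharp sustained rise, later waves alternate
    with exponential holding times.
    """
    span = time[-1] - time[0] if time.size else 0.0
    n_holds = max(8, int(4 * span / max(mean_hold, 1e-9)) + 8)
    holds = rng.exponential(mean_hold, size=n_holds)
    holds[0] = max(holds[0], onset_hold)
    edges = time[0] + np.cumsum(holds)
    # state flips at each edge; high on [t0, edge0), low on [edge0, edge1), ...
    seg = np.searchsorted(edges, time, side="right")
    return (seg % 2 == 0).astype(float)


def emit_voc(
    truth: SimulationTruth,
    channel_spec: dict[int, ChannelModel],
    noise: NoiseConfig,
    seed: int,
    max_mz: int = 201,
) -> VOCMatrix:
    """Render the VOC scan matrix for all channels m/z 1..max_mz.

    Channels without an explicit model follow position rules: below m/z 33
    they are device background, above m/z 160 a 0–4 ppb noise floor, and in
    between a quiet low-ppb floor.  Informative and burst roles must not
    collide on one channel.
    """
    roles: dict[int, str] = {}
    for mz in truth.informative_channels:
        roles[mz] = "biomass"
    b = truth.burst_channel
    if b in roles:
        raise ConfigError(
            f"channel_spec: m/z {b} declared in two roles (informative and burst)")
    roles[b] = "burst"
    for mz, model in channel_spec.items():
        if mz in roles and model.kind not in (roles[mz], "device", "growth"):
            if {model.kind, roles[mz]} == {"biomass", "burst"}:
                raise ConfigError(f"channel_spec: m/z {mz} declared in two roles")
    for mz, role in roles.items():
        model = channel_spec.get(mz)
        if model is not None and model.kind in ("biomass", "burst") and model.kind != role:
            raise ConfigError(f"channel_spec: m/z {mz} declared in two roles")

    rng = np.random.default_rng(seed)
    time = truth.time
    n = time.size
    dt = float(time[1] - time[0]) if n > 1 else 1.0
    activity = np.clip(np.gradient(truth.vcd_true, time), 0.0, None) if n > 1 else np.zeros(n)
    windows = _burst_windows(truth)
    channels = list(range(1, max_mz + 1))
    values = np.empty((n, len(channels)))

    for j, mz in enumerate(channels):
        model = channel_spec.get(mz)
        if model is None:
            if mz < 33:
                model = ChannelModel("device", offset=3.0 + (37 * mz) % 50)
            elif mz > 160:
                model = ChannelModel("floor", baseline=2.0)
            else:
                model = ChannelModel("floor", baseline=1.5)
        sd = noise.voc_multiplicative_sd if model.noise_sd is None else model.noise_sd
        if model.kind == "biomass":
            base = model.gain * truth.vcd_true + model.offset
            col = base * (1.0 + sd * rng.standard_normal(n))
        elif model.kind == "growth":
            base = model.offset + model.gain * activity
            col = base * (1.0 + sd * rng.standard_normal(n))
        elif model.kind == "burst":
            base = np.full(n, model.baseline)
            for start, end in windows:
                mask = (time >= start) & (time < end)
                if not np.any(mask):
                    continue
                wave = _telegraph(rng, time[mask], model.mean_hold, model.onset_hold)
                floor = model.baseline * (1.0 + model.floor_fraction)
                peak = model.baseline * (1.0 + model.relative_increase)
                base[mask] = floor + (peak - floor) * wave
            col = base * (1.0 + sd * rng.standard_normal(n))
        elif model.kind == "device":
            col = model.offset + (model.offset * sd + 1.0) * rng.standard_normal(n)
            if model.drift_amplitude:
                col = col + model.drift_amplitude * np.sin(
                    2 * np.pi * time / model.drift_period + 0.7 * mz
                )
        else:  # floor
            if mz > 160:
                col = rng.uniform(0.0, 4.0, size=n)
            else:
                col = model.baseline + 0.5 * rng.standard_normal(n)
        values[:, j] = np.clip(col, 0.0, None)
    return VOCMatrix(time, channels, values)


# ---------------------------------------------------------------------------
# Observables
# ---------------------------------------------------------------------------

def _sample_offline(config: SimulationConfig, truth: SimulationTruth,
                    rng: np.random.Generator) -> OfflineTable:
    dt = config.online_dt
    idx = np.clip(np.round(truth.time[0] + np.asarray(
        config.resolved_offline_times()) / dt).astype(int), 0, truth.time.size - 1)
    idx = np.unique(idx)
    t = truth.time[idx]
    sd = config.noise.offline_sd
    vcd = truth.vcd_true[idx] + sd.get("vcd", 0.0) * rng.standard_normal(idx.size)
    viab = truth.viability_true[idx] + sd.get("viability", 0.0) * rng.standard_normal(idx.size)
    glc = truth.glucose_true[idx] + sd.get("glucose", 0.0) * rng.standard_normal(idx.size)
    lac = truth.lactate_true[idx] + sd.get("lactate", 0.0) * rng.standard_normal(idx.size)
    titer = None
    if config.transfection_time is not None:
        rise = np.clip(t - config.transfection_time, 0.0, None)
        titer = (1.0 - np.exp(-rise / 1.5)) + sd.get("titer", 0.0) * rng.standard_normal(idx.size)
        titer = np.clip(titer, 0.0, None)
    return OfflineTable(
        time=t,
        vcd=np.clip(vcd, 0.0, None),
        viability=np.clip(viab, 0.0, 100.0),
        glucose=np.clip(glc, 0.0, None),
        lactate=np.clip(lac, 0.0, None),
        titer=titer,
    )


def _emit_permittivity(config: SimulationConfig, truth: SimulationTruth,
                       rng: np.random.Generator) -> Trace:
    bias_cfg = config.permittivity_bias
    time = truth.time
    dt = config.online_dt
    # first-order response lag
    lagged = np.empty_like(truth.vcd_true)
    lagged[0] = truth.vcd_true[0]
    alpha = min(1.0, dt / max(bias_cfg.lag_tau, 1e-9))
    for i in range(1, time.size):
        lagged[i] = lagged[i - 1] + alpha * (truth.vcd_true[i] - lagged[i - 1])
    # localized drawdown after each depletion (the probe's "small drop")
    for d in truth.depletion_times:
        centre = d + bias_cfg.dip_lag
        lagged = lagged * (1.0 - bias_cfg.dip_depth * np.exp(
            -0.5 * ((time - centre) / max(bias_cfg.dip_width, 1e-9)) ** 2))
    phase = rng.uniform(0.0, 2 * np.pi)
    bias = 1.0 + bias_cfg.amplitude * np.sin(
        2 * np.pi * time / bias_cfg.period + phase) + bias_cfg.drift * time
    noisy = lagged * bias * (1.0 + config.noise.permittivity_sd * rng.standard_normal(time.size))
    permittivity = np.clip(noisy, 0.0, None) / DEFAULT_PERMITTIVITY_FACTOR
    return Trace(time.copy(), permittivity)


# ---------------------------------------------------------------------------
# Top-level simulation
# ---------------------------------------------------------------------------

def simulate_run(config: SimulationConfig, run_id: str = "run") -> tuple[CultivationRun, SimulationTruth]:
    """Simulate one cultivation: returns noisy observables and ground truth."""
    config.validate()
    time, vcd, glc, lac, viab, depletion_times = _integrate(config)
    informative = {mz for mz, m in config.channel_spec.items() if m.kind == "biomass"}
    burst = [mz for mz, m in config.channel_spec.items() if m.kind == "burst"]
    truth = SimulationTruth(
        time=time, vcd_true=vcd, viability_true=viab, glucose_true=glc,
        lactate_true=lac, depletion_times=depletion_times,
        informative_channels=informative,
        burst_channel=burst[0] if burst else -1,
        transfection_time=config.transfection_time,
    )
    ss = np.random.SeedSequence(config.seed)
    seed_voc, seed_offline, seed_perm = (int(s.generate_state(1)[0] % (2**31))
                                         for s in ss.spawn(3))
    voc = emit_voc(truth, config.channel_spec, config.noise, seed_voc, config.max_mz)
    offline = _sample_offline(config, truth, np.random.default_rng(seed_offline))
    permittivity = _emit_permittivity(config, truth, np.random.default_rng(seed_perm))
    run = CultivationRun(
        run_id=run_id, voc=voc, offline=offline, permittivity=permittivity,
        transfection_time=config.transfection_time,
    )
    return run, truth


def save_truth(truth: SimulationTruth, directory) -> None:
    """Write the ground truth (kept separate from the observable tables)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        TIME_COLUMN: truth.time,
        "vcd_true": truth.vcd_true,
        "viability_true": truth.viability_true,
        "glucose_true": truth.glucose_true,
        "lactate_true": truth.lactate_true,
    }).to_csv(directory / "truth.csv", index=False)
    meta = {
        "depletion_times": [float(t) for t in truth.depletion_times],
        "informative_channels": sorted(int(c) for c in truth.informative_channels),
        "burst_channel": int(truth.burst_channel),
        "transfection_time": truth.transfection_time,
    }
    (directory / "truth.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
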