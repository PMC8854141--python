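"""Online glucose-depletion detection and sensor response comparison.

The m/z 45 (acetaldehyde) channel is quiet and steady while glucose is
available and starts to fluctuate in waves when the culture approaches
glucose exhaustion.  The detector tracks a robust rolling baseline (median,
with an MAD-derived spread) and opens a depletion event when the signal
exceeds ``baseline * (1 + rel_threshold)`` for ``k_consecutive`` scans; the
baseline is frozen at event opening so in-event bursts cannot inflate their
own reference.  An event resolves when the signal stays within
``baseline * (1 +/- rel_threshold / 2)`` for ``k_consecutive`` scans
(glucose re-addition restores the steady trend); otherwise it stays open to
the end of the stream.  Thresholding is purely relative, so detection times
are invariant to rescaling the series.

The capacitance probe answers the same question more slowly: its viable
cell density estimate shows a small drawdown after depletion and then a
plateau.  ``detect_capacitance_events`` finds both (running-maximum
drawdown, then a rolling-fit slope criterion), and ``compare_indicators``
tabulates the per-run response lags between the two sensors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import VocSenseError
from .sensor import moving_average
from .timeseries import CultivationRun, permittivity_to_vcd

DEFAULT_BURST_CHANNEL = 45


@dataclass
class DetectorConfig:
    rel_threshold: float = 0.5     # trigger above baseline * (1 + this)
    k_consecutive: int = 3         # scans to confirm trigger / resolution
    lookback: float = 0.5          # days of history for the rolling baseline
    warmup: float = 0.2            # days before the detector activates
    min_window_scans: int = 10


@dataclass
class DepletionEvent:
    """One detected onset of m/z 45 fluctuation."""

    detection_time: float
    baseline_level: float
    trigger_value: float
    relative_increase: float       # percent: 100 * (max - baseline) / baseline
    resolved_time: float | None = None

    def __post_init__(self) -> None:
        if not self.trigger_value > self.baseline_level:
            raise VocSenseError("DepletionEvent: trigger must exceed baseline")
        if self.resolved_time is not None and not self.resolved_time > self.detection_time:
            raise VocSenseError("DepletionEvent: resolution must follow detection")


@dataclass
class CapacitanceEvents:
    drop_time: float | None = None
    plateau_time: float | None = None

    def __post_init__(self) -> None:
        if (self.drop_time is not None and self.plateau_time is not None
                and self.plateau_time < self.drop_time):
            raise VocSenseError("CapacitanceEvents: plateau precedes drop")


def estimate_baseline(
    times: np.ndarray,
    values: np.ndarray,
    t_index: int,
    lookback: float = 0.5,
    min_window_scans: int = 10,
) -> tuple[float, float] | None:
    """Robust baseline at scan ``t_index`` from the trailing lookback window.

    Returns (level, spread) where level is the rolling median of the window
    ending at the scan and spread is the median absolute deviation scaled to
    a normal-sd equivalent (1.4826 * MAD), or None while the window holds
    fewer than ``min_window_scans`` scans (detector warm-up).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    t = times[t_index]
    window = values[(times > t - lookback) & (times <= t)]
    if window.size < min_window_scans:
        return None
    level = float(np.median(window))
    spread = float(1.4826 * np.median(np.abs(window - level)))
    return level, spread


def detect_depletion(
    times: np.ndarray,
    values: np.ndarray,
    config: DetectorConfig | None = None,
) -> list[DepletionEvent]:
    """Scan a burst-channel stream causally and return all depletion events.

    The decision at scan i uses only scans <= i, so replaying a truncated
    stream reproduces every event that lies inside the truncation.
    """
    cfg = config or DetectorConfig()
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape:
        raise VocSenseError("detect_depletion: time/value length mismatch")
    events: list[DepletionEvent] = []
    in_event = False
    streak = 0
    streak_start: int | None = None
    frozen: tuple[float, float] | None = None
    frozen_at_streak: tuple[float, float] | None = None
    event_open: dict | None = None
    resolve_streak = 0
    resolve_start: int | None = None
    t0 = times[0]

    for i in range(times.size):
        if not in_event:
            if times[i] - t0 < cfg.warmup:
                continue
            # baseline from scans strictly before the current one
            base = estimate_baseline(times, values, i - 1, cfg.lookback,
                                     cfg.min_window_scans) if i > 0 else None
            if base is None:
                continue
            level = base[0]
            if level <= 0:
                continue
            if values[i] > level * (1.0 + cfg.rel_threshold):
                if streak == 0:
                    streak_start = i
                    frozen_at_streak = base
                streak += 1
                if streak >= cfg.k_consecutive:
                    in_event = True
                    frozen = frozen_at_streak
                    event_open = {
                        "detection_index": streak_start,
                        "baseline": frozen[0],
                        "trigger": float(values[streak_start]),
                        "max": float(np.max(values[streak_start:i + 1])),
                    }
                    streak = 0
                    resolve_streak = 0
            else:
                streak = 0
        else:
            assert event_open is not None and frozen is not None
            event_open["max"] = max(event_open["max"], float(values[i]))
            b = event_open["baseline"]
            half = cfg.rel_threshold / 2.0
            if b * (1.0 - half) <= values[i] <= b * (1.0 + half):
                if resolve_streak == 0:
                    resolve_start = i
                resolve_streak += 1
                if resolve_streak >= cfg.k_consecutive:
                    events.append(DepletionEvent(
                        detection_time=float(times[event_open["detection_index"]]),
                        baseline_level=b,
                        trigger_value=event_open["trigger"],
                        relative_increase=100.0 * (event_open["max"] - b) / b,
                        resolved_time=float(times[resolve_start]),
                    ))
                    in_event = False
                    event_open = None
                    resolve_streak = 0
            else:
                resolve_streak = 0
    if in_event and event_open is not None:
        b = event_open["baseline"]
        events.append(DepletionEvent(
            detection_time=float(times[event_open["detection_index"]]),
            baseline_level=b,
            trigger_value=event_open["trigger"],
            relative_increase=100.0 * (event_open["max"] - b) / b,
            resolved_time=None,
        ))
    return events


def monitor_run(
    run: CultivationRun,
    channel: int = DEFAULT_BURST_CHANNEL,
    config: DetectorConfig | None = None,
) -> list[DepletionEvent]:
    """Run the depletion detector on one run's burst channel."""
    return detect_depletion(run.voc.time, run.voc.channel_values(channel), config)


# ---------------------------------------------------------------------------
# Capacitance probe events
# ---------------------------------------------------------------------------

@dataclass
class CapacitanceConfig:
    drop_frac: float = 0.02        # drawdown from running max that flags a drop
    plateau_slope: float = 0.02    # |slope| threshold, fraction of run-max per day
    window: float = 0.25           # days for the rolling linear fit
    smooth_scans: int = 10


def detect_capacitance_events(
    times: np.ndarray,
    vcd: np.ndarray,
    config: CapacitanceConfig | None = None,
) -> CapacitanceEvents:
    """Find the capacitance probe's post-depletion drop and plateau.

    drop_time: first scan where the smoothed trace falls at least
    ``drop_frac`` below its running maximum.  plateau_time: first later scan
    (or, without a drop, first scan past warm-up) where the slope of a
    least-squares line over the trailing ``window`` days stays below
    ``plateau_slope`` of the running maximum per day.
    """
    cfg = config or CapacitanceConfig()
    times = np.asarray(times, dtype=float)
    v = moving_average(np.asarray(vcd, dtype=float), cfg.smooth_scans)
    if times.size < 2 or times[-1] - times[0] <= cfg.window:
        raise VocSenseError("detect_capacitance_events: trace shorter than window")
    runmax = np.maximum.accumulate(v)
    drop_time = None
    positive = runmax > 0
    drawdown = np.zeros_like(v)
    drawdown[positive] = (runmax[positive] - v[positive]) / runmax[positive]
    past_warmup = times >= times[0] + cfg.window      # smoothing warm-up guard
    hits = np.flatnonzero((drawdown >= cfg.drop_frac) & past_warmup)
    if hits.size:
        drop_time = float(times[hits[0]])

    plateau_time = None
    start_t = times[0] + cfg.window
    if drop_time is not None:
        start_t = max(start_t, drop_time)
    for i in range(times.size):
        t = times[i]
        if t < start_t:
            continue
        mask = (times > t - cfg.window) & (times <= t)
        tt = times[mask]
        vv = v[mask]
        if tt.size < 3:
            continue
        slope = float(np.polyfit(tt, vv, 1)[0])
        limit = cfg.plateau_slope * max(runmax[i], 1e-12)
        if abs(slope) < limit:
            plateau_time = float(t)
            break
    if drop_time is not None and plateau_time is not None and plateau_time < drop_time:
        plateau_time = drop_time
    return CapacitanceEvents(drop_time=drop_time, plateau_time=plateau_time)


def capacitance_events_for_run(
    run: CultivationRun,
    config: CapacitanceConfig | None = None,
    permittivity_factor: float = 0.63,
) -> CapacitanceEvents:
    cap = permittivity_to_vcd(run.permittivity, permittivity_factor)
    return detect_capacitance_events(cap.time, cap.values, config)


# ---------------------------------------------------------------------------
# Indicator comparison
# ---------------------------------------------------------------------------

@dataclass
class IndicatorComparison:
    """Per-run response lags between the PTR-MS and capacitance indicators."""

    table: pd.DataFrame           # run, first_detection, drop, plateau, lags
    summary: pd.DataFrame         # min/median/max of the defined lags

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compare_indicators(
    per_run: list[tuple[str, list[DepletionEvent], CapacitanceEvents]],
) -> IndicatorComparison:
    """Tabulate drop and plateau lags of the capacitance probe per run.

    drop_lag = capacitance drop_time - first PTR-MS detection_time;
    plateau_lag = plateau_time - first detection_time.  Lags are NaN when
    either event is missing; the summary gives min/median/max over runs
    where the lag is defined.
    """
    rows = []
    for run_id, events, cap in per_run:
        first = min((e.detection_time for e in events), default=np.nan)
        drop = cap.drop_time if cap.drop_time is not None else np.nan
        plateau = cap.plateau_time if cap.plateau_time is not None else np.nan
        rows.append({
            "run": run_id,
            "first_detection": first,
            "drop_time": drop,
            "plateau_time": plateau,
            "drop_lag": drop - first,
            "plateau_lag": plateau - first,
            "n_events": len(events),
        })
    table = pd.DataFrame(rows)
    summary_rows = []
    for lag in ("drop_lag", "plateau_lag"):
        defined = table[lag].dropna()
        summary_rows.append({
            "lag": lag,
            "min": defined.min() if len(defined) else np.nan,
            "median": defined.median() if len(defined) else np.nan,
            "max": defined.max() if len(defined) else np.nan,
            "n": len(defined),
        })
    return IndicatorComparison(table=table, summary=pd.DataFrame(summary_rows))
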