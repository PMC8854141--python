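"""Tabular time-series containers, file IO and online/offline alignment.

Everything downstream works on three in-memory containers:

* :class:`VOCMatrix` — the dense PTR-MS scan matrix, one row per instrument
  scan, one column per integer m/z channel, values in ppb;
* :class:`OfflineTable` — the sparse offline analytics (viable cell density,
  viability, glucose, lactate, optionally a normalized titer);
* :class:`Trace` — a single online signal, here the permittivity probe.

Time is expressed in days from inoculation everywhere; the readers can
convert from hours or seconds on ingest.  The canonical on-disk format is
comma-separated UTF-8 text with a header row; a spreadsheet (.xlsx) dialect
is supported for the VOC matrix because instruments commonly export it.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import AlignmentError, ConfigError, FormatError

logger = logging.getLogger(__name__)

TIME_COLUMN = "time_days"
CHANNEL_PREFIX = "mz_"

_TIME_FACTORS = {"days": 1.0, "hours": 1.0 / 24.0, "seconds": 1.0 / 86400.0}


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 0:
        arr = arr.reshape(1)
    if not np.all(np.isfinite(arr)):
        raise ConfigError(f"{name}: values must be finite")
    return arr


def _check_strictly_increasing(time: np.ndarray, what: str) -> None:
    bad = np.flatnonzero(np.diff(time) <= 0)
    if bad.size:
        raise FormatError(f"{what}: time not strictly increasing at row {int(bad[0]) + 1}")


@dataclass
class VOCMatrix:
    """Dense online VOC time series: ppb per (scan time, integer m/z)."""

    time: np.ndarray                 # days, strictly increasing, shape (n,)
    channels: list[int]              # positive integer m/z, no duplicates
    values: np.ndarray               # ppb, shape (n, len(channels)), finite, >= 0

    def __post_init__(self) -> None:
        self.time = _as_float_array(self.time, "VOCMatrix.time")
        self.values = np.asarray(self.values, dtype=float)
        self.channels = [int(c) for c in self.channels]
        _check_strictly_increasing(self.time, "VOCMatrix")
        if len(set(self.channels)) != len(self.channels):
            raise FormatError("VOCMatrix: duplicate m/z channels")
        if any(c <= 0 for c in self.channels):
            raise FormatError("VOCMatrix: channels must be positive integers")
        if self.values.shape != (self.time.size, len(self.channels)):
            raise FormatError(
                f"VOCMatrix: values shape {self.values.shape} does not match "
                f"({self.time.size}, {len(self.channels)})"
            )
        if not np.all(np.isfinite(self.values)):
            raise FormatError("VOCMatrix: non-finite ppb values")
        if np.any(self.values < 0):
            raise FormatError("VOCMatrix: negative ppb values (clip on ingest)")

    @property
    def n_scans(self) -> int:
        return int(self.time.size)

    def channel_values(self, mz: int) -> np.ndarray:
        try:
            j = self.channels.index(int(mz))
        except ValueError:
            raise KeyError(f"channel m/z {mz} not present") from None
        return self.values[:, j]

    def subset(self, channels: Sequence[int]) -> "VOCMatrix":
        idx = [self.channels.index(int(c)) for c in channels]
        return VOCMatrix(self.time.copy(), [int(c) for c in channels], self.values[:, idx].copy())

    def to_frame(self) -> pd.DataFrame:
        data = {TIME_COLUMN: self.time}
        data.update({f"{CHANNEL_PREFIX}{c}": self.values[:, j]
                     for j, c in enumerate(self.channels)})
        return pd.DataFrame(data)


@dataclass
class OfflineTable:
    """Sparse offline analytics sampled during the cultivation."""

    time: np.ndarray                 # days, strictly increasing
    vcd: np.ndarray                  # 1e6 cells/mL
    viability: np.ndarray            # percent, within [0, 100]
    glucose: np.ndarray              # g/L
    lactate: np.ndarray              # g/L
    titer: np.ndarray | None = None  # normalized units, optional

    def __post_init__(self) -> None:
        self.time = _as_float_array(self.time, "OfflineTable.time")
        _check_strictly_increasing(self.time, "OfflineTable")
        for name in ("vcd", "viability", "glucose", "lactate"):
            arr = _as_float_array(getattr(self, name), f"OfflineTable.{name}")
            if arr.size != self.time.size:
                raise FormatError(f"OfflineTable.{name}: length mismatch with time")
            setattr(self, name, arr)
        if self.titer is not None:
            self.titer = _as_float_array(self.titer, "OfflineTable.titer")
            if self.titer.size != self.time.size:
                raise FormatError("OfflineTable.titer: length mismatch with time")
        if np.any((self.viability < 0) | (self.viability > 100)):
            raise FormatError("OfflineTable.viability: outside [0, 100]")
        for name in ("vcd", "glucose", "lactate"):
            if np.any(getattr(self, name) < 0):
                raise FormatError(f"OfflineTable.{name}: negative concentration")

    ANALYTES = ("vcd", "viability", "glucose", "lactate")

    def to_frame(self) -> pd.DataFrame:
        data = {TIME_COLUMN: self.time}
        for name in self.ANALYTES:
            data[name] = getattr(self, name)
        if self.titer is not None:
            data["titer"] = self.titer
        return pd.DataFrame(data)


@dataclass
class Trace:
    """A single online signal on its own time grid (e.g. permittivity)."""

    time: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.time = _as_float_array(self.time, "Trace.time")
        self.values = _as_float_array(self.values, "Trace.values")
        if self.values.size != self.time.size:
            raise FormatError("Trace: values length mismatch with time")
        _check_strictly_increasing(self.time, "Trace")


PermittivityTrace = Trace


@dataclass
class CultivationRun:
    """One cultivation: online VOC matrix + permittivity + offline table."""

    run_id: str
    voc: VOCMatrix
    offline: OfflineTable
    permittivity: Trace
    transfection_time: float | None = None

    def __post_init__(self) -> None:
        if self.transfection_time is not None:
            self.transfection_time = float(self.transfection_time)


@dataclass
class AlignedDataset:
    """Offline samples joined with interpolated online values.

    ``frame`` has one row per retained offline sample with the offline
    analytes, one ``mz_<c>`` column per VOC channel and, when a permittivity
    trace was supplied, a ``cap_vcd`` column with the capacitance-derived
    viable cell density.
    """

    frame: pd.DataFrame
    channel_columns: list[str] = field(default_factory=list)

    @property
    def channels(self) -> list[int]:
        return [int(c[len(CHANNEL_PREFIX):]) for c in self.channel_columns]

    def channel_values(self, mz: int) -> np.ndarray:
        return self.frame[f"{CHANNEL_PREFIX}{int(mz)}"].to_numpy()


# ---------------------------------------------------------------------------
# VOC matrix IO
# ---------------------------------------------------------------------------

def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        return dialect
    return "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"


def write_voc_table(matrix: VOCMatrix, path, dialect: str | None = None) -> None:
    """Write a VOC matrix; ``dialect`` is 'csv' or 'xlsx' (inferred from suffix)."""
    path = Path(path)
    frame = matrix.to_frame()
    if _infer_dialect(path, dialect) == "xlsx":
        frame.to_excel(path, index=False)
    else:
        frame.to_csv(path, index=False)


def read_voc_table(
    path,
    dialect: str | None = None,
    time_column: str = TIME_COLUMN,
    channel_prefix: str = CHANNEL_PREFIX,
    time_unit: str = "days",
    negative: str = "clip",
) -> VOCMatrix:
    """Read a VOC matrix from delimited text or a spreadsheet.

    The header must declare a time column (``time_column``) plus one column
    per integer m/z channel named ``<channel_prefix><int>``; channel order is
    preserved.  ``time_unit`` converts hours/seconds to days on ingest.
    Negative ppb values (possible after instrument baseline subtraction) are
    clipped to zero with a logged count by default, or rejected with
    ``negative='error'``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    if time_unit not in _TIME_FACTORS:
        raise ConfigError(f"time_unit: unknown unit {time_unit!r}")
    if negative not in ("clip", "error"):
        raise ConfigError(f"negative: must be 'clip' or 'error', got {negative!r}")
    if _infer_dialect(path, dialect) == "xlsx":
        frame = pd.read_excel(path, sheet_name=0)
    else:
        frame = pd.read_csv(path)
    if time_column not in frame.columns:
        raise FormatError(f"{path}: missing time column {time_column!r}")
    channels: list[int] = []
    cols: list[str] = []
    pattern = re.compile(re.escape(channel_prefix) + r"(\d+)$")
    for col in frame.columns:
        if col == time_column:
            continue
        m = pattern.match(str(col))
        if m is None:
            raise FormatError(f"{path}: column {col!r} is not a {channel_prefix}<int> channel header")
        channels.append(int(m.group(1)))
        cols.append(col)
    if not channels:
        raise FormatError(f"{path}: no channel columns found")
    time = frame[time_column].to_numpy(dtype=float) * _TIME_FACTORS[time_unit]
    bad = np.flatnonzero(np.diff(time) <= 0)
    if bad.size:
        raise FormatError(f"{path}: time not strictly increasing at row {int(bad[0]) + 1}")
    values = frame[cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise FormatError(f"{path}: non-finite ppb values")
    n_neg = int(np.count_nonzero(values < 0))
    if n_neg:
        if negative == "error":
            raise FormatError(f"{path}: {n_neg} negative ppb values")
        logger.warning("%s: clipped %d negative ppb values to zero", path, n_neg)
        values = np.clip(values, 0.0, None)
    return VOCMatrix(time, channels, values)


# ---------------------------------------------------------------------------
# Offline / permittivity IO
# ---------------------------------------------------------------------------

def write_offline_table(table: OfflineTable, path) -> None:
    table.to_frame().to_csv(Path(path), index=False)


def read_offline_table(path, time_unit: str = "days") -> OfflineTable:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    frame = pd.read_csv(path)
    for col in (TIME_COLUMN, *OfflineTable.ANALYTES):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    time = frame[TIME_COLUMN].to_numpy(dtype=float) * _TIME_FACTORS[time_unit]
    kwargs = {name: frame[name].to_numpy(dtype=float) for name in OfflineTable.ANALYTES}
    titer = frame["titer"].to_numpy(dtype=float) if "titer" in frame.columns else None
    return OfflineTable(time=time, titer=titer, **kwargs)


def write_trace(trace: Trace, path, value_column: str = "permittivity") -> None:
    pd.DataFrame({TIME_COLUMN: trace.time, value_column: trace.values}).to_csv(
        Path(path), index=False
    )


def read_trace(path, value_column: str = "permittivity", time_unit: str = "days") -> Trace:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    frame = pd.read_csv(path)
    for col in (TIME_COLUMN, value_column):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    time = frame[TIME_COLUMN].to_numpy(dtype=float) * _TIME_FACTORS[time_unit]
    return Trace(time, frame[value_column].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

def save_run(run: CultivationRun, directory) -> Path:
    """Persist a run as voc.csv / offline.csv / permittivity.csv + manifest.yaml."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_voc_table(run.voc, directory / "voc.csv")
    write_offline_table(run.offline, directory / "offline.csv")
    write_trace(run.permittivity, directory / "permittivity.csv")
    manifest = {
        "run_id": run.run_id,
        "voc": "voc.csv",
        "offline": "offline.csv",
        "permittivity": "permittivity.csv",
        "transfection_time": run.transfection_time,
    }
    manifest_path = directory / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
    return manifest_path


def load_run(manifest_path) -> CultivationRun:
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.yaml"
    if not manifest_path.exists():
        raise FormatError(f"{manifest_path}: no such manifest")
    manifest = yaml.safe_load(manifest_path.read_text())
    base = manifest_path.parent
    return CultivationRun(
        run_id=str(manifest.get("run_id", base.name)),
        voc=read_voc_table(base / manifest["voc"]),
        offline=read_offline_table(base / manifest["offline"]),
        permittivity=read_trace(base / manifest["permittivity"]),
        transfection_time=manifest.get("transfection_time"),
    )


# ---------------------------------------------------------------------------
# Permittivity conversion and alignment
# ---------------------------------------------------------------------------

def permittivity_to_vcd(trace: Trace, factor: float = 0.63) -> Trace:
    """Convert a permittivity trace to viable cell density.

    The capacitance probe's dielectric signal is proportional to viable cell
    volume; a cell-line-specific correlation factor maps it to viable cell
    density (default 0.63 for the HEK 293 line modelled here).
    """
    if not np.isfinite(factor) or factor <= 0:
        raise ConfigError(f"factor: must be positive, got {factor}")
    return Trace(trace.time.copy(), factor * trace.values)


def _interp(method: str, x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    if method == "linear":
        return np.interp(x, xp, fp)
    if method == "nearest":
        idx = np.searchsorted(xp, x)
        idx = np.clip(idx, 1, xp.size - 1)
        left = xp[idx - 1]
        right = xp[idx]
        choose_left = (x - left) <= (right - x)
        return np.where(choose_left, fp[idx - 1], fp[idx])
    raise ConfigError(f"method: unknown interpolation method {method!r}")


def align(
    voc: VOCMatrix,
    cap_vcd: Trace | None,
    offline: OfflineTable,
    method: str = "linear",
) -> AlignedDataset:
    """Join offline samples with interpolated online values.

    Every online channel (VOC channels and, when given, the
    permittivity-derived VCD) is evaluated at each offline sampling time by
    the chosen method (default: linear interpolation between bracketing
    scans).  Offline samples outside the common online span are dropped with
    a logged warning; an empty intersection raises :class:`AlignmentError`.
    """
    lo = voc.time[0]
    hi = voc.time[-1]
    if cap_vcd is not None:
        lo = max(lo, cap_vcd.time[0])
        hi = min(hi, cap_vcd.time[-1])
    if lo > hi:
        raise AlignmentError("online spans (VOC, permittivity) do not intersect")
    inside = (offline.time >= lo) & (offline.time <= hi)
    n_dropped = int(np.count_nonzero(~inside))
    if n_dropped:
        logger.warning(
            "align: dropped %d offline sample(s) outside online span [%.4f, %.4f] days",
            n_dropped, lo, hi,
        )
    if not np.any(inside):
        raise AlignmentError("no offline samples inside the online span")
    t = offline.time[inside]
    data: dict[str, np.ndarray] = {TIME_COLUMN: t}
    for name in OfflineTable.ANALYTES:
        data[name] = getattr(offline, name)[inside]
    if offline.titer is not None:
        data["titer"] = offline.titer[inside]
    channel_columns = []
    for j, c in enumerate(voc.channels):
        col = f"{CHANNEL_PREFIX}{c}"
        data[col] = _interp(method, t, voc.time, voc.values[:, j])
        channel_columns.append(col)
    if cap_vcd is not None:
        data["cap_vcd"] = _interp(method, t, cap_vcd.time, cap_vcd.values)
    return AlignedDataset(pd.DataFrame(data), channel_columns)
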