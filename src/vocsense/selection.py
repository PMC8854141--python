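"""Four-step reduction of the VOC matrix to soft-sensor input channels.

The workflow mirrors standard practice for screening spectral channels:

I.   knowledge filter — drop channels known to be device artefacts
     (below m/z 33 except m/z 18) or dead (above m/z 160);
II.  unsupervised screen — PCA on the pooled scan matrix; keep channels
     that carry a meaningful share of the retained components' variance;
III. assignment — map surviving channels to known VOCs via a lookup table;
     unassigned channels are excluded;
IV.  supervised screen — Pearson correlation of each remaining channel
     (aligned to offline sampling times, pooled over runs after per-run
     centering) against the offline analytes; keep channels whose best
     absolute correlation clears a threshold.

The four channel sets are nested by construction and reported together with
PCA loadings and the full channel x analyte correlation matrix (the data
behind the usual correlation heatmap).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import SelectionError
from .timeseries import (
    AlignedDataset,
    CultivationRun,
    VOCMatrix,
    align,
)

#: m/z -> most likely VOC, from the PTR-MS literature on cell culture off-gas.
DEFAULT_ASSIGNMENTS: dict[int, str] = {
    18: "ammonia",
    33: "methanol",
    45: "acetaldehyde",
    47: "ethanol",
    59: "acetone",
    63: "ethanethiol",
}

UNASSIGNED = "unassigned/excluded"

DEFAULT_ANALYTES = ("vcd", "viability", "glucose", "lactate")


@dataclass
class SelectionConfig:
    low: int = 33
    high: int = 160
    exceptions: frozenset[int] = frozenset({18})
    variance_target: float = 0.95
    importance_threshold: float | None = None   # None -> 1 / (2 * n_channels)
    scale_unit_variance: bool = False
    assignments: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_ASSIGNMENTS))
    analytes: tuple[str, ...] = DEFAULT_ANALYTES
    min_abs_r: float = 0.8


@dataclass
class SelectionReport:
    """Nested channel sets and diagnostics of the four-step workflow."""

    step1_channels: list[int]
    step2_channels: list[int]
    step2_loadings: pd.DataFrame          # per channel: importance + loadings
    explained_variance_ratio: list[float]
    step3_assignments: dict[int, str]
    step4_channels: list[int]
    correlation_matrix: pd.DataFrame      # channels x analytes, NaN = undefined

    def validate_nesting(self) -> None:
        s1, s2 = set(self.step1_channels), set(self.step2_channels)
        assigned = {c for c, n in self.step3_assignments.items() if n != UNASSIGNED}
        s4 = set(self.step4_channels)
        if not (s4 <= assigned <= s2 <= s1):
            raise SelectionError("selection report violates step nesting")

    def to_dict(self) -> dict:
        return {
            "step1_channels": [int(c) for c in self.step1_channels],
            "step2_channels": [int(c) for c in self.step2_channels],
            "explained_variance_ratio": [float(v) for v in self.explained_variance_ratio],
            "step3_assignments": {str(c): n for c, n in sorted(self.step3_assignments.items())},
            "step4_channels": [int(c) for c in self.step4_channels],
            "correlation_matrix": {
                str(c): {a: (None if not np.isfinite(v) else round(float(v), 12))
                         for a, v in row.items()}
                for c, row in self.correlation_matrix.iterrows()
            },
        }

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "selection_report.json").write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        self.correlation_matrix.to_csv(directory / "correlation_heatmap.csv",
                                       index_label="mz")
        self.step2_loadings.to_csv(directory / "loadings.csv", index_label="mz")


# ---------------------------------------------------------------------------
# Step I — knowledge filter
# ---------------------------------------------------------------------------

def knowledge_filter(
    voc: VOCMatrix | Sequence[int],
    low: int = 33,
    high: int = 160,
    exceptions: frozenset[int] | set[int] = frozenset({18}),
) -> list[int]:
    """Keep channels with low <= m/z <= high plus the listed exceptions.

    Defaults encode device knowledge: signals below m/z 33 originate from
    the instrument itself (except m/z 18), and above m/z 160 the device
    records no responses.
    """
    if low > high:
        raise SelectionError(f"knowledge_filter: low {low} > high {high}")
    channels = voc.channels if isinstance(voc, VOCMatrix) else [int(c) for c in voc]
    kept = [c for c in channels if (low <= c <= high) or c in set(exceptions)]
    if not kept:
        raise SelectionError("knowledge_filter: no channels survive")
    return kept


# ---------------------------------------------------------------------------
# Step II — PCA screen
# ---------------------------------------------------------------------------

def pca_screen(
    values: np.ndarray,
    channels: Sequence[int],
    variance_target: float = 0.95,
    importance_threshold: float | None = None,
    scale_unit_variance: bool = False,
) -> tuple[list[int], pd.DataFrame, np.ndarray]:
    """PCA-based channel screen on a (scans x channels) matrix.

    Channels are mean-centered over scans (optionally autoscaled);
    components are retained until their cumulative explained variance
    reaches ``variance_target``.  Each channel's importance is the
    explained-variance-weighted sum of its squared loadings over the
    retained components, normalized to sum 1 across channels; channels at
    or above ``importance_threshold`` (default 1/(2 * n_channels)) survive.

    Returns (surviving channels, per-channel loading table, explained
    variance ratios of the retained components).
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise SelectionError("pca_screen: need >= 2 scans and >= 2 channels")
    if len(channels) != X.shape[1]:
        raise SelectionError("pca_screen: channel list does not match matrix width")
    sd = X.std(axis=0)
    if np.all(sd == 0):
        raise SelectionError("pca_screen: all channels constant (degenerate input)")
    if scale_unit_variance:
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    n_comp = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_comp)
    pca.fit(X)
    evr = pca.explained_variance_ratio_
    k = int(np.searchsorted(np.cumsum(evr), variance_target) + 1)
    k = min(max(k, 1), evr.size)
    loadings = pca.components_[:k]                       # (k, n_channels)
    weighted = evr[:k, None] * loadings ** 2
    importance = weighted.sum(axis=0)
    total = importance.sum()
    if total > 0:
        importance = importance / total
    threshold = importance_threshold
    if threshold is None:
        threshold = 1.0 / (2.0 * len(channels))
    survivors = [int(c) for c, imp in zip(channels, importance) if imp >= threshold]
    table = pd.DataFrame(
        {"importance": importance,
         **{f"pc{i + 1}_loading": loadings[i] for i in range(k)}},
        index=pd.Index([int(c) for c in channels], name="mz"),
    )
    return survivors, table, evr[:k].copy()


# ---------------------------------------------------------------------------
# Step III — VOC assignment
# ---------------------------------------------------------------------------

def assign_vocs(
    channels: Sequence[int],
    assignment_table: dict[int, str] | None = None,
) -> dict[int, str]:
    """Annotate channels with known VOC names; unknown ones are excluded.

    The built-in table carries the six assignments supported by the PTR-MS
    cell-culture literature (ammonia, methanol, acetaldehyde, ethanol,
    acetone, ethanethiol).
    """
    table = DEFAULT_ASSIGNMENTS if assignment_table is None else assignment_table
    return {int(c): table.get(int(c), UNASSIGNED) for c in channels}


# ---------------------------------------------------------------------------
# Step IV — correlation screen
# ---------------------------------------------------------------------------

def correlation_screen(
    aligned: Sequence[AlignedDataset],
    channels: Sequence[int],
    analytes: Sequence[str] = DEFAULT_ANALYTES,
    min_abs_r: float = 0.8,
) -> tuple[list[int], pd.DataFrame]:
    """Pearson correlation of channels against offline analytes.

    Rows are pooled over runs after per-run mean-centering of both sides
    (between-run offsets would otherwise inflate correlations).  A channel
    survives if its maximum |r| over the analytes reaches ``min_abs_r``.
    Zero-variance channels or analytes yield undefined correlations
    (reported as NaN, never coerced to 0) and fail the screen.
    """
    datasets = list(aligned)
    if not datasets:
        raise SelectionError("correlation_screen: no aligned datasets")
    for ds in datasets:
        if len(ds.frame) < 3:
            raise SelectionError("correlation_screen: need >= 3 aligned rows per run")
    chan_cols = [f"mz_{int(c)}" for c in channels]
    pooled_x = {col: [] for col in chan_cols}
    pooled_y = {a: [] for a in analytes}
    for ds in datasets:
        for col in chan_cols:
            v = ds.frame[col].to_numpy(dtype=float)
            pooled_x[col].append(v - v.mean())
        for a in analytes:
            v = ds.frame[a].to_numpy(dtype=float)
            pooled_y[a].append(v - v.mean())
    xs = {col: np.concatenate(v) for col, v in pooled_x.items()}
    ys = {a: np.concatenate(v) for a, v in pooled_y.items()}
    matrix = pd.DataFrame(index=pd.Index([int(c) for c in channels], name="mz"),
                          columns=list(analytes), dtype=float)
    for c, col in zip(channels, chan_cols):
        x = xs[col]
        sx = float(np.sqrt(np.sum(x * x)))
        for a in analytes:
            y = ys[a]
            sy = float(np.sqrt(np.sum(y * y)))
            if sx == 0.0 or sy == 0.0:
                matrix.loc[int(c), a] = np.nan
            else:
                matrix.loc[int(c), a] = float(np.dot(x, y) / (sx * sy))
    best = matrix.abs().max(axis=1, skipna=True)
    survivors = [int(c) for c in channels
                 if np.isfinite(best.loc[int(c)]) and best.loc[int(c)] >= min_abs_r]
    return survivors, matrix


# ---------------------------------------------------------------------------
# Full workflow
# ---------------------------------------------------------------------------

def run_selection(
    runs: Sequence[CultivationRun],
    config: SelectionConfig | None = None,
) -> SelectionReport:
    """Execute steps I-IV on the pooled runs and return the nested report."""
    config = config or SelectionConfig()
    runs = list(runs)
    if not runs:
        raise SelectionError("run_selection: no runs given")
    ref = runs[0].voc.channels
    for run in runs[1:]:
        if run.voc.channels != ref:
            missing = set(ref).symmetric_difference(run.voc.channels)
            raise SelectionError(
                f"run_selection: channel sets differ between runs "
                f"({run.run_id}: mismatch on m/z {sorted(missing)[:8]})"
            )
    step1 = knowledge_filter(ref, config.low, config.high, config.exceptions)
    idx = [ref.index(c) for c in step1]
    pooled = np.vstack([run.voc.values[:, idx] for run in runs])
    step2, loadings, evr = pca_screen(
        pooled, step1, config.variance_target,
        config.importance_threshold, config.scale_unit_variance,
    )
    assignments = assign_vocs(step2, config.assignments)
    assigned = [c for c in step2 if assignments[c] != UNASSIGNED]
    if not assigned:
        raise SelectionError("run_selection: no channels survive VOC assignment")
    aligned = [align(run.voc.subset(assigned), None, run.offline) for run in runs]
    step4, corr = correlation_screen(aligned, assigned, config.analytes, config.min_abs_r)
    report = SelectionReport(
        step1_channels=step1,
        step2_channels=step2,
        step2_loadings=loadings,
        explained_variance_ratio=list(evr),
        step3_assignments=assignments,
        step4_channels=step4,
        correlation_matrix=corr,
    )
    report.validate_nesting()
    return report


def plot_heatmap(report: SelectionReport, path) -> None:
    """Render the channel x analyte correlation matrix as a heatmap image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    matrix = report.correlation_matrix.astype(float)
    fig, ax = plt.subplots(figsize=(6, 0.5 + 0.4 * len(matrix)))
    im = ax.imshow(matrix.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r", aspect="auto")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns)
    ax.set_yticks(range(len(matrix)), [f"m/z {c}" for c in matrix.index])
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
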