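"""Neural soft sensor for viable cell density from selected m/z channels.

The estimator is a small feed-forward network (1-3 hidden layers of 2-10
tanh units, linear output) trained by Levenberg-Marquardt with Bayesian
regularization: the objective ``beta * SSE + alpha * sum(w^2)`` is minimized
while ``alpha`` and ``beta`` are re-estimated from the evidence
approximation (MacKay updates) after every accepted step.  On the few dozen
offline biomass samples of a cultivation triplicate this controls
overfitting without a validation split.

Model selection uses leave-one-batch-out cross-validation (folds split by
cultivation, never by sample).  The deployed soft sensor is a bootstrap
aggregate: the best members from distinct folds are averaged; the member
spread at each scan gives a standard deviation (ddof-1 over members) and a
confidence band (estimate +/- SD).  A causal moving-average filter
(window 10 scans) smooths the aggregated output stream.

Accuracy is reported as NRMSE[%]: root-mean-square residual divided by the
mean of the measured values, times 100.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, EvaluationError, TrainingError, VocSenseError
from .timeseries import CultivationRun, Trace, align, permittivity_to_vcd

logger = logging.getLogger(__name__)

HIDDEN_UNIT_RANGE = (2, 10)
HIDDEN_LAYER_RANGE = (1, 3)
DEFAULT_HIDDEN = (8,)
DEFAULT_WINDOW = 10


# ---------------------------------------------------------------------------
# Metrics and smoothing
# ---------------------------------------------------------------------------

def nrmse(y, y_hat) -> float:
    """Normalized root-mean-square error in percent.

    ``100 * sqrt(mean((y - y_hat)^2)) / mean(y)``; undefined when the mean
    of the measured series is zero.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise VocSenseError(f"nrmse: length mismatch ({y.shape} vs {y_hat.shape})")
    if y.size < 1:
        raise VocSenseError("nrmse: empty series")
    mean = float(np.mean(y))
    if mean == 0.0:
        raise VocSenseError("nrmse: mean of measured series is zero")
    return float(100.0 * np.sqrt(np.mean((y - y_hat) ** 2)) / mean)


def moving_average(series, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Causal moving average: mean of the most recent min(t+1, window) values.

    The window expands during warm-up, so the filter is streaming-safe and
    introduces no look-ahead.
    """
    if window < 1:
        raise VocSenseError(f"moving_average: window must be >= 1, got {window}")
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise VocSenseError("moving_average: expected a 1-D series")
    n = x.size
    out = np.empty(n)
    head = min(window - 1, n)
    for i in range(head):                       # expanding warm-up
        out[i] = x[:i + 1].mean()
    if n >= window:
        sw = np.lib.stride_tricks.sliding_window_view(x, window)
        out[window - 1:] = sw.mean(axis=1)
    return out


# ---------------------------------------------------------------------------
# Network model
# ---------------------------------------------------------------------------

def _validate_arch(hidden: Sequence[int]) -> tuple[int, ...]:
    hidden = tuple(int(h) for h in hidden)
    lo_l, hi_l = HIDDEN_LAYER_RANGE
    lo_u, hi_u = HIDDEN_UNIT_RANGE
    if not (lo_l <= len(hidden) <= hi_l):
        raise ConfigError(f"hidden: layer count must be in [{lo_l}, {hi_l}], got {len(hidden)}")
    for h in hidden:
        if not (lo_u <= h <= hi_u):
            raise ConfigError(f"hidden: units per layer must be in [{lo_u}, {hi_u}], got {h}")
    return hidden


@dataclass
class NetModel:
    """One trained network with its normalization and training metadata."""

    channels: list[int]
    hidden: tuple[int, ...]
    weights: list[np.ndarray]       # per layer, shape (n_out, n_in)
    biases: list[np.ndarray]        # per layer, shape (n_out,)
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    seed: int = 0
    n_iter: int = 0
    alpha: float = float("nan")
    beta: float = float("nan")

    def __post_init__(self) -> None:
        self.hidden = _validate_arch(self.hidden)
        if np.any(self.x_scale <= 0) or self.y_scale <= 0:
            raise ConfigError("NetModel: normalization scales must be positive")
        sizes = [len(self.channels), *self.hidden, 1]
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape != (sizes[i + 1], sizes[i]) or b.shape != (sizes[i + 1],):
                raise ConfigError("NetModel: weight shapes do not match architecture")

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict viable cell density from raw (unnormalized) channel values."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        z = (X - self.x_mean) / self.x_scale
        a = z
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.tanh(a @ w.T + b)
        out = a @ self.weights[-1].T + self.biases[-1]
        return self.y_mean + self.y_scale * out[:, 0]

    def to_dict(self) -> dict:
        return {
            "channels": [int(c) for c in self.channels],
            "hidden": list(self.hidden),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean,
            "y_scale": self.y_scale,
            "seed": int(self.seed),
            "n_iter": int(self.n_iter),
            "alpha": self.alpha,
            "beta": self.beta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetModel":
        return cls(
            channels=[int(c) for c in d["channels"]],
            hidden=tuple(d["hidden"]),
            weights=[np.asarray(w, dtype=float) for w in d["weights"]],
            biases=[np.asarray(b, dtype=float) for b in d["biases"]],
            x_mean=np.asarray(d["x_mean"], dtype=float),
            x_scale=np.asarray(d["x_scale"], dtype=float),
            y_mean=float(d["y_mean"]),
            y_scale=float(d["y_scale"]),
            seed=int(d.get("seed", 0)),
            n_iter=int(d.get("n_iter", 0)),
            alpha=float(d.get("alpha", float("nan"))),
            beta=float(d.get("beta", float("nan"))),
        )


# ---------------------------------------------------------------------------
# Bayesian-regularized Levenberg-Marquardt training
# ---------------------------------------------------------------------------

def _init_params(sizes: list[int], rng: np.random.Generator) -> np.ndarray:
    parts = []
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        parts.append(rng.normal(0.0, 1.0 / np.sqrt(n_in), size=n_out * n_in))
        parts.append(np.zeros(n_out))
    return np.concatenate(parts)


def _unpack(p: np.ndarray, sizes: list[int]):
    weights, biases, k = [], [], 0
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        weights.append(p[k:k + n_out * n_in].reshape(n_out, n_in))
        k += n_out * n_in
        biases.append(p[k:k + n_out])
        k += n_out
    return weights, biases


def _forward_jacobian(p: np.ndarray, Z: np.ndarray, sizes: list[int]):
    """Network output and Jacobian d(output)/d(params) for each sample."""
    weights, biases = _unpack(p, sizes)
    acts = [Z]
    a = Z
    for w, b in zip(weights[:-1], biases[:-1]):
        a = np.tanh(a @ w.T + b)
        acts.append(a)
    out = (a @ weights[-1].T + biases[-1])[:, 0]

    n = Z.shape[0]
    J = np.empty((n, p.size))
    # delta at the output layer is 1 (linear unit); backpropagate through tanh
    deltas = [np.ones((n, 1))]
    for layer in range(len(weights) - 1, 0, -1):
        d_next = deltas[0]
        d = (d_next @ weights[layer]) * (1.0 - acts[layer] ** 2)
        deltas.insert(0, d)
    k = 0
    for layer, (w, b) in enumerate(zip(weights, biases)):
        d = deltas[layer]                     # (n, n_out)
        a_in = acts[layer]                    # (n, n_in)
        n_out, n_in = w.shape
        J[:, k:k + n_out * n_in] = (d[:, :, None] * a_in[:, None, :]).reshape(n, -1)
        k += n_out * n_in
        J[:, k:k + n_out] = d
        k += n_out
    return out, J


def train_brann(
    X: np.ndarray,
    y: np.ndarray,
    channels: Sequence[int] | None = None,
    hidden: Sequence[int] = DEFAULT_HIDDEN,
    seed: int = 0,
    max_iter: int = 500,
    n_restarts: int = 3,
    tol_objective: float = 1e-6,
    tol_hyper: float = 1e-4,
    patience: int = 10,
    mu_init: float = 5e-3,
    mu_cap: float = 1e10,
) -> NetModel:
    """Train one network by Levenberg-Marquardt with Bayesian regularization.

    Inputs and target are z-normalized with the training statistics (stored
    in the model).  After every accepted LM step the regularization
    hyperparameters are re-estimated by MacKay's evidence approximation:
    ``gamma = P - 2 alpha tr(H^-1)``, ``alpha = gamma / (2 Ew)``,
    ``beta = (N - gamma) / (2 Ed)``.  Training stops when the relative
    objective improvement stays below ``tol_objective`` for ``patience``
    iterations while the hyperparameters have settled (relative drift below
    ``tol_hyper``), or at ``max_iter``.  Several random restarts are run and
    the lowest final objective wins.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise VocSenseError("train_brann: X and y length mismatch")
    if X.shape[0] < 4:
        raise VocSenseError(f"train_brann: need >= 4 training rows, got {X.shape[0]}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise VocSenseError("train_brann: non-finite training data")
    hidden = _validate_arch(hidden)
    if channels is None:
        channels = list(range(X.shape[1]))

    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0)
    x_scale = np.where(x_scale > 0, x_scale, 1.0)
    y_mean = float(y.mean())
    y_scale = float(y.std())
    if y_scale <= 0:
        y_scale = 1.0
    Z = (X - x_mean) / x_scale
    t = (y - y_mean) / y_scale

    sizes = [X.shape[1], *hidden, 1]
    N = t.size
    master = np.random.SeedSequence(seed)
    best = None

    for restart_ss in master.spawn(max(1, n_restarts)):
        rng = np.random.default_rng(restart_ss)
        p = _init_params(sizes, rng)
        P = p.size
        alpha, beta = 1e-2, 1.0
        out, J = _forward_jacobian(p, Z, sizes)
        e = t - out
        Ed = float(e @ e)
        Ew = float(p @ p)
        F = beta * Ed + alpha * Ew
        mu = mu_init
        stall = 0
        hyper_settled = False
        it = 0
        while it < max_iter:
            it += 1
            A = beta * (J.T @ J) + (alpha + mu) * np.eye(P)
            g = beta * (J.T @ e) - alpha * p
            try:
                step = np.linalg.solve(A, g)
            except np.linalg.LinAlgError:
                mu *= 10.0
                if mu > mu_cap:
                    raise TrainingError("train_brann: damping cap reached on singular system")
                continue
            p_new = p + step
            out_new, J_new = _forward_jacobian(p_new, Z, sizes)
            e_new = t - out_new
            Ed_new = float(e_new @ e_new)
            Ew_new = float(p_new @ p_new)
            F_new = beta * Ed_new + alpha * Ew_new
            if F_new < F:
                rel = (F - F_new) / max(F, 1e-300)
                p, out, J, e, Ed, Ew = p_new, out_new, J_new, e_new, Ed_new, Ew_new
                mu = max(mu / 10.0, 1e-12)
                # MacKay evidence update of the hyperparameters
                try:
                    H = 2.0 * (beta * (J.T @ J) + alpha * np.eye(P))
                    tr_inv = float(np.trace(np.linalg.inv(H)))
                except np.linalg.LinAlgError:
                    tr_inv = 0.0
                gamma = P - 2.0 * alpha * tr_inv
                gamma = float(np.clip(gamma, 1e-6, P))
                alpha_new = gamma / max(2.0 * Ew, 1e-12)
                alpha_new = float(np.clip(alpha_new, 1e-9, 1e6))
                beta_new = (N - gamma) / max(2.0 * Ed, 1e-12) if N > gamma else beta
                beta_new = float(np.clip(beta_new, 1e-9, 1e9))
                drift = max(abs(alpha_new - alpha) / max(alpha, 1e-12),
                            abs(beta_new - beta) / max(beta, 1e-12))
                hyper_settled = drift < tol_hyper
                alpha, beta = alpha_new, beta_new
                F = beta * Ed + alpha * Ew
                stall = stall + 1 if rel < tol_objective else 0
            else:
                mu *= 10.0
                stall += 1
                if mu > mu_cap:
                    break  # steps have collapsed to zero; no further improvement
            if stall >= patience and hyper_settled:
                break
        if best is None or F < best[0]:
            best = (F, p, alpha, beta, it, int(restart_ss.generate_state(1)[0] % (2**31)))

    assert best is not None
    F, p, alpha, beta, n_iter, restart_seed = best
    weights, biases = _unpack(p, sizes)
    return NetModel(
        channels=[int(c) for c in channels], hidden=hidden,
        weights=[w.copy() for w in weights], biases=[b.copy() for b in biases],
        x_mean=x_mean, x_scale=x_scale, y_mean=y_mean, y_scale=y_scale,
        seed=int(seed), n_iter=int(n_iter), alpha=float(alpha), beta=float(beta),
    )


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    held_out: str
    model: NetModel
    val_nrmse: float
    train_nrmse: float


@dataclass
class CVResult:
    hidden: tuple[int, ...]
    folds: list[FoldResult]

    @property
    def mean_val_nrmse(self) -> float:
        return float(np.mean([f.val_nrmse for f in self.folds]))


def loo_batch_cv(
    datasets: Sequence[tuple[str, np.ndarray, np.ndarray]],
    hidden_grid: Sequence[Sequence[int]] = (DEFAULT_HIDDEN,),
    seed: int = 0,
    min_rows: int = 4,
    channels: Sequence[int] | None = None,
    **train_kwargs,
) -> tuple[list[CVResult], tuple[int, ...]]:
    """Leave-one-batch-out cross-validation over an architecture grid.

    ``datasets`` holds one (run_id, X, y) triple per cultivation.  For every
    architecture each run is held out once: the model trains on the pooled
    remaining runs and is scored by NRMSE on the held-out run.  The best
    architecture is the one with the lowest mean validation NRMSE.
    """
    datasets = list(datasets)
    if len(datasets) < 2:
        raise VocSenseError("loo_batch_cv: need >= 2 runs")
    ss = np.random.SeedSequence(seed)
    results: list[CVResult] = []
    for arch_i, hidden in enumerate(hidden_grid):
        hidden = _validate_arch(hidden)
        folds: list[FoldResult] = []
        # one init seed per architecture, shared across folds, so identical
        # folds produce identical models (restarts fan out inside train_brann)
        arch_seed = int(np.random.SeedSequence((seed, arch_i)).generate_state(1)[0]
                        % (2**31))
        for k, (run_id, X_val, y_val) in enumerate(datasets):
            X_tr = np.vstack([d[1] for i, d in enumerate(datasets) if i != k])
            y_tr = np.concatenate([d[2] for i, d in enumerate(datasets) if i != k])
            if X_tr.shape[0] < min_rows:
                logger.warning("loo_batch_cv: fold %s skipped (%d < %d training rows)",
                               run_id, X_tr.shape[0], min_rows)
                continue
            model = train_brann(X_tr, y_tr, channels=channels, hidden=hidden,
                                seed=arch_seed, **train_kwargs)
            folds.append(FoldResult(
                held_out=str(run_id), model=model,
                val_nrmse=nrmse(y_val, model.predict(X_val)),
                train_nrmse=nrmse(y_tr, model.predict(X_tr)),
            ))
        if not folds:
            raise VocSenseError("loo_batch_cv: all folds skipped")
        results.append(CVResult(hidden=hidden, folds=folds))
    best = min(results, key=lambda r: r.mean_val_nrmse)
    return results, best.hidden


# ---------------------------------------------------------------------------
# Aggregation and estimation
# ---------------------------------------------------------------------------

@dataclass
class EnsembleModel:
    """Bootstrap-aggregated soft sensor: member mean + spread-based CI."""

    members: list[NetModel]
    window: int = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        if not self.members:
            raise ConfigError("EnsembleModel: need >= 1 member")
        ref = self.members[0].channels
        for m in self.members[1:]:
            if m.channels != ref:
                raise ConfigError("EnsembleModel: members disagree on input channels")

    @property
    def channels(self) -> list[int]:
        return self.members[0].channels

    def member_predictions(self, X: np.ndarray) -> np.ndarray:
        return np.vstack([m.predict(X) for m in self.members])

    def save(self, path) -> None:
        path = Path(path)
        if path.is_dir() or path.suffix == "":
            path.mkdir(parents=True, exist_ok=True)
            path = path / "ensemble.json"
        payload = {"window": int(self.window),
                   "members": [m.to_dict() for m in self.members]}
        path.write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "EnsembleModel":
        path = Path(path)
        if path.is_dir():
            path = path / "ensemble.json"
        payload = json.loads(path.read_text())
        return cls(members=[NetModel.from_dict(d) for d in payload["members"]],
                   window=int(payload.get("window", DEFAULT_WINDOW)))


def aggregate(models: Sequence[NetModel], window: int = DEFAULT_WINDOW) -> EnsembleModel:
    """Bundle trained networks into the averaged (bagged) soft sensor."""
    return EnsembleModel(members=list(models), window=window)


def select_members(
    cv: CVResult,
    k: int = 2,
) -> list[NetModel]:
    """Pick the k fold models with the lowest validation NRMSE (distinct boots)."""
    ranked = sorted(cv.folds, key=lambda f: f.val_nrmse)
    if len(ranked) < k:
        k = len(ranked)
    return [f.model for f in ranked[:k]]


@dataclass
class EstimateTrace:
    """Smoothed ensemble estimate with member-spread uncertainty per scan."""

    time: np.ndarray
    estimate: np.ndarray     # 1e6 cells/mL, moving-average smoothed
    sd: np.ndarray           # member spread (ddof-1 over members)
    ci_low: np.ndarray
    ci_high: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_days": self.time, "estimate": self.estimate, "sd": self.sd,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
        })


def estimate_with_ci(
    ensemble: EnsembleModel,
    time: np.ndarray,
    X: np.ndarray,
    window: int | None = None,
) -> EstimateTrace:
    """Apply the ensemble to an online stream of channel values.

    Per scan t the estimate is the member mean, smoothed by the causal
    moving-average filter; the SD is the ddof-1 spread of the members around
    their mean (0, with a logged notice, for a single member); the
    confidence band is estimate +/- SD.
    """
    window = ensemble.window if window is None else window
    preds = ensemble.member_predictions(X)        # (n_members, n_scans)
    n = preds.shape[0]
    mean = preds.mean(axis=0)
    if n < 2:
        logger.info("estimate_with_ci: single-member ensemble, SD reported as 0")
        sd = np.zeros_like(mean)
    else:
        sd = np.sqrt(np.sum((mean - preds) ** 2, axis=0) / (n - 1))
    smoothed = moving_average(mean, window)
    return EstimateTrace(
        time=np.asarray(time, dtype=float), estimate=smoothed, sd=sd,
        ci_low=smoothed - sd, ci_high=smoothed + sd,
    )


def estimate_run(ensemble: EnsembleModel, run: CultivationRun,
                 window: int | None = None) -> EstimateTrace:
    """Estimate viable cell density over a whole run's VOC stream."""
    X = np.column_stack([run.voc.channel_values(c) for c in ensemble.channels])
    return estimate_with_ci(ensemble, run.voc.time, X, window)


# ---------------------------------------------------------------------------
# Evaluation against offline analytics
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    nrmse_pct: float             # soft sensor vs offline VCD, pooled runs
    benchmark_nrmse_pct: float | None   # capacitance-derived VCD, same samples
    scatter: pd.DataFrame        # run, time, measured, estimated, sd, benchmark


def evaluate_on_runs(
    ensemble: EnsembleModel,
    runs: Sequence[CultivationRun],
    window: int | None = None,
    permittivity_factor: float = 0.63,
) -> EvaluationReport:
    """Score the soft sensor (and the capacitance benchmark) on offline VCD.

    The smoothed ensemble estimate is linearly interpolated to the offline
    sampling times of every run and pooled; the same NRMSE is computed for
    the permittivity-derived VCD as the benchmark.
    """
    rows = []
    for run in runs:
        est = estimate_run(ensemble, run, window)
        off = run.offline
        inside = (off.time >= est.time[0]) & (off.time <= est.time[-1])
        if not np.any(inside):
            continue
        t = off.time[inside]
        measured = off.vcd[inside]
        estimated = np.interp(t, est.time, est.estimate)
        sd = np.interp(t, est.time, est.sd)
        cap = permittivity_to_vcd(run.permittivity, permittivity_factor)
        benchmark = np.interp(t, cap.time, cap.values)
        for row in zip([run.run_id] * t.size, t, measured, estimated, sd, benchmark):
            rows.append(row)
    if not rows:
        raise EvaluationError("evaluate_on_runs: no offline samples inside the online span")
    scatter = pd.DataFrame(rows, columns=["run", "time_days", "measured",
                                          "estimated", "sd", "benchmark"])
    return EvaluationReport(
        nrmse_pct=nrmse(scatter["measured"], scatter["estimated"]),
        benchmark_nrmse_pct=nrmse(scatter["measured"], scatter["benchmark"]),
        scatter=scatter,
    )


def aligned_training_data(
    runs: Sequence[CultivationRun],
    channels: Sequence[int],
) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Build (run_id, X, y) training triples from runs and selected channels."""
    datasets = []
    for run in runs:
        aligned = align(run.voc.subset(channels), None, run.offline)
        X = np.column_stack([aligned.channel_values(c) for c in channels])
        y = aligned.frame["vcd"].to_numpy(dtype=float)
        datasets.append((run.run_id, X, y))
    return datasets
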