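# Methods

This note documents the models, the synthetic study design, the numerical
choices and the known limitations of `vocsense`. Nothing here states a
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Synthetic cultivation model

The generator (`vocsense.simulate`) produces ground truth and noisy
observables for two canonical set-ups: a 4-day non-transfected batch run
and a 9-day transfected run (4-day growth, transfection at day 3.7, 5-day
production phase).

### Kinetics

State (X, S, L, V) = (viable cell density in 10⁶ cells/mL, glucose g/L,
lactate g/L, viability %) advances on the online grid (default
Δt = 0.005 day ≈ 7 min) by Monod-limited growth:

    mu = mu_max · S / (K_s + S)
    X ← X · exp(mu Δt)          (exponential per-step update, exact for frozen mu)
    S ← S − ΔX / Y_xs           (stoichiometric consumption, clipped at 0)
    L ← L + y_lac · ΔS_consumed
    after glucose depletion:  L ← L − q_lac · X · Δt   (lactate as alternative fuel)
    after both are exhausted: V ← V · exp(−k_d Δt)

The per-step growth factor uses the exponential integrator rather than the
first-order 1 + mu·Δt update so the step is exact in the
glucose-saturated limit; a fine-step explicit-Euler oracle in the tests
converges to the same trajectories (local error O(Δt²)). Transfection
applies exact 1:1 dilution: X, L halve, S ← S/2 + S_fresh/2, and the
post-transfection growth-rate factor (default 0.4) reflects transfection
stress. Glucose below 0.05 g/L counts as depleted — a tolerance that
avoids floating-point zero-crossing ambiguity; the near-depletion approach
is exponential with rate mu_max·X/(Y_xs·K_s) ≈ 17/day, so the crossing is
sharp.

Defaults — X₀ = 1.0 (batch) / 0.5 (transfected) ×10⁶ cells/mL,
S₀ = 5.0 / 6.0 g/L, S_fresh = 6 g/L, mu_max = 0.9 /day, K_s = 0.3 g/L,
Y_xs = 1.4 (10⁶ cells/mL)/(g/L), y_lac = 0.6, q_lac = 0.12 (g/L)/day per
10⁶ cells/mL, k_d = 0.1 /day — were chosen once so that the batch culture
depletes glucose around day 2.7 at a plateau of ~8×10⁶ cells/mL and the
transfected culture depletes shortly before transfection and again shortly
before day 6, reproducing the qualitative event structure of the
underlying study design. No published absolute glucose or biomass axis
values exist for these cultivations, so these are plausible HEK 293 batch
values, not measured ones.

### VOC emission

Per-channel models (`ChannelModel`):

* **biomass** (m/z 33 gain 5, offset 20; m/z 59 gain 12, offset 8):
  gain·X + offset, multiplicative Gaussian noise (default sd 3 %);
* **burst** (m/z 45, baseline 60 ppb, relative increase 185 %): steady
  baseline; from each depletion instant until glucose replenishment (or
  run end) a random telegraph wave with exponential holding times (mean
  0.02 day) rides on an elevated floor of 1.35× baseline, peaking at
  2.85× baseline ≈ 171 ppb. The first wave is sustained for at least
  0.03 day — the onset is a sharp collective metabolic response, and a
  detector needs a few consecutive scans to confirm any event. The
  elevated in-event floor (above the ±25 % resolution band of the default
  detector) encodes that the whole fluctuation phase sits above the steady
  trend, so one depletion episode is one event;
* **growth-activity** (m/z 47, 63): offset + gain·(dX/dt)₊ with heavy
  noise — channels that carry real variance (they survive the PCA screen)
  but correlate with no single offline analyte, as observed for the
  ethanol/ethanethiol channels;
* **device** (m/z < 33, plus m/z 18 with a slow sinusoidal drift):
  biology-independent offsets + noise;
* **floor** (m/z > 160): uniform 0–4 ppb; unplanted channels in 33–160 sit
  at a quiet ~1.5 ppb.

### Permittivity probe

The capacitance-derived VCD is X filtered by a first-order lag
(τ = 0.12 day), multiplied by a slowly varying bias
1 + A·sin(2πt/T + φ) + d·t (defaults A = 0.2, T = 8 day, d = 0.02/day,
φ random per run) and 1 % noise, with a localized 5 % Gaussian drawdown
0.25 day after each depletion (σ = 0.05 day) — the probe's delayed
drop/plateau response to growth cessation. The trace is stored as raw
permittivity (divided by the correlation factor 0.63) so that the standard
conversion reproduces the biased VCD estimate. The 20 % bias amplitude is
the default benchmark condition: the probe under- or over-estimates by up
to ~20 % depending on phase, which is what the soft sensor is compared
against.

### What the generator does not emulate

Real PTR-MS spectra carry correlated drift, fragmentation overlaps,
humidity effects and media-dependent channel assignments; offline
analytics have operator- and instrument-specific error structure; the
m/z 45 burst mechanism is imposed (tied to glucose only), not mechanistic
— the possible lactate-consumption contribution is deliberately not
modelled. Passing tests therefore demonstrate that the algorithms recover
planted structure under realistic noise, not that the specific channels or
error levels transfer to any particular instrument or cell line.

## Channel selection

PCA runs on the pooled, mean-centered scan matrix (centering only: all
channels share ppb units, and autoscaling would promote the flat noise
channels; a unit-variance flag exists). Components are retained to ≥ 95 %
cumulative explained variance. Channel importance is the
explained-variance-weighted sum of squared loadings over retained
components, normalized to sum 1; the survival threshold defaults to
1/(2·n_channels) — half the importance a channel would have if variance
were spread uniformly — and ties at the threshold are kept (inclusion is
cheap, later steps prune). The VOC assignment step is a declarative lookup
table (the six literature-supported assignments ship as the default), not
text mining. Correlations pool runs after per-run centering of both sides
so that between-run offsets cannot inflate r; zero-variance columns yield
undefined (NaN) correlations and fail the screen rather than being coerced
to 0.

## Soft sensor

Inputs and target are z-normalized with training-fold statistics only
(stored in the model; test runs reuse them). Training minimizes
F(w) = β·E_d + α·E_w by Levenberg–Marquardt (damping ×10 on reject, ÷10 on
accept, cap 10¹⁰) with MacKay evidence updates of (α, β) after every
accepted step. Stopping: relative objective decrease < 10⁻⁶ for 10
consecutive iterations while the hyperparameter drift is < 10⁻⁴, or 500
iterations (300 inside the pipeline), whichever comes first. Three random
restarts per fit; the lowest final objective wins. Initial weights are
N(0, 1/√fan_in), biases 0; all seeds fan out from one master seed via
`numpy.random.SeedSequence` and are recorded in the model metadata. Within
one cross-validation, the same initialization seed is shared across folds
(restarts still differ), so identical folds give identical models.

Cross-validation folds are whole cultivations. The held-out run is used
for scoring only — early stopping on the validation run would leak the
fold, so it is not done. The default architecture grid inside the pipeline
is the single (8,) setting found optimal by that search space; the full
2–10 × 1–3 grid remains available through `loo_batch_cv`.

The ensemble takes the k = 2 fold models with the lowest validation NRMSE
(necessarily from different boots, since each fold contributes one model).
The moving-average filter (causal, expanding during warm-up, window 10
scans) is applied to the aggregated mean stream only; the SD is the
ddof-1 spread of the raw member streams, and a single-member ensemble
reports SD = 0 with a logged notice. Estimates are linearly interpolated
to offline sampling times for scoring, since samples rarely coincide with
scans.

## Depletion detection

The baseline is the rolling median over a 0.5-day lookback window with an
MAD-derived spread; the detector is inactive until 0.2 day of history
exists (early signals are steady, and no event is expected near
inoculation). Triggering and resolution are purely relative (×1.5 to open,
within ×[0.75, 1.25] of the frozen baseline to close, 3 consecutive scans
each), so detection times are invariant to rescaling the series —
necessary because baselines differ ~3× between phases (~60 vs ~170 ppb).
The baseline is frozen at event opening so bursts cannot inflate their own
reference. Decisions at scan i use scans ≤ i only (causal); replaying a
truncated stream reproduces the contained events.

The capacitance drop uses a running-maximum drawdown (≥ 2 % of the
smoothed trace) rather than a derivative sign, which is robust to sensor
noise; detection is suppressed during the first fit-window (0.25 day) of
the trace where the smoothing warm-up makes drawdowns meaningless. The
plateau is the first later time where the least-squares slope over the
trailing 0.25-day window drops below 2 % of the running maximum per day.
Under the default 20 % bias the plateau can be masked in short batch runs
(the bias slope exceeds the threshold); such runs report an undefined
plateau lag rather than a guessed one.

## Pipeline problem sizes

The default end-to-end configuration — three 4-day training runs and three
9-day test runs at 0.005-day scan intervals (801/1801 scans × 201
channels), twice-daily offline sampling (9/19 samples per run), one
architecture, three restarts — was chosen as the smallest configuration
that reproduces the study's triplicate design; one full pipeline takes a
few seconds on one CPU, and the multi-seed recovery checks in the test
suite run in under a minute.

## Known limitations

* The Bayesian-regularization variant is the MacKay evidence
  approximation; other update schedules (e.g. full Hessian re-estimation
  per epoch) would give slightly different α/β trajectories.
* The exact rule by which PCA channel importance should be thresholded is
  a design choice (variance-weighted squared loadings with a 1/(2n)
  cutoff); other defensible rules select slightly different step-II sets,
  which is why the final selection rests on the supervised step IV.
* "First measurable peak" has no canonical quantitative definition; the
  k-consecutive relative-threshold rule is this package's
  operationalization, and its defaults are configuration, not claims.
* The NRMSE levels reached on synthetic data depend on the generator's
  noise settings and are not comparable to values measured on real
  cultivations.
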