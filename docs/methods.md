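# Methods

## The measurement problem

Small passerines in winter can drop their nocturnal skin temperature
(T<sub>s</sub>) several degrees below resting levels (shallow torpor),
saving energy at the cost of reduced alertness. A field experiment that
raises perceived predation risk during the daytime foraging period — and
reads the response out in the following night's torpor depth and duration —
needs a long chain of processing between the raw telemetry and the effect
estimates: transmitter calibration, gap-ridden time series on a 10-minute
grid, circadian segmentation, individual-specific torpor thresholds, and
repeated-measures models. This package implements that chain and ships a
synthetic study generator with planted ground truth so the chain can be
validated end-to-end by parameter recovery.

## Analysis pipeline

**Calibration.** Temperature-sensitive transmitters encode temperature in
the pulse interval (ms). Each transmitter's calibration table (≥ 5 distinct
points) is fitted with a least-squares cubic, T<sub>s</sub> = Σ cₖ pᵏ,
using a domain-scaled polynomial basis for numerical stability. The fit is
rejected unless strictly monotone over the calibrated range, because the
temperature–interval relation must be invertible; R² < 0.99 raises a
warning flag. Pulses more than 5 % of the calibrated span outside the
range become missing values rather than extrapolations — a cubic
extrapolated is unbounded and a single spurious pulse could fabricate a
torpor bout.

**Segmentation.** The rest-phase is 17:00–08:00 (next day), the
active-phase 07:00–17:00, daily medians use 08:00–17:00; all windows are
half-open `[start, end)`. The deliberate one-hour overlap at 07:00–08:00
means the morning hour contributes both to the night minimum and to the
lowest daily active reading; both windows are configurable. A bird-night is
keyed by the evening date and inherits that date's treatment condition,
because the manipulation is an active-phase exposure whose response is read
out in the following rest-phase. Missingness per night is counted as empty
grid slots against the full 90-slot window; nights missing more than 3 h
are excluded (`gap_gt_3h`) — this same rule absorbs truncated final nights
(e.g. transmitter battery failure), which need no special case. To limit
lingering responses, the first 2 days of any control block immediately
preceded by a treatment block are excluded (`carryover_day`); a leading
control block is untouched. Duplicate (bird, timestamp) rows collapse to
their median, which is robust to isolated mis-reads.

**Torpor metrics.** The normothermic baseline R<sub>i</sub> is the mean of
the lowest daily active-phase T<sub>s</sub> over retained control days
(days need more than 20 active samples to qualify, mirroring the median
rule); birds without a qualifying control day are flagged unusable and
dropped from night models. The torpor threshold is R<sub>i</sub> − 5 °C
(offset configurable). Nightly depth is the minimum rest-phase sample;
nightly duration is (number of non-missing samples strictly below the
threshold) × 10 min, contiguous or not. Ties at the threshold count as
normothermic — exact ties have probability zero in real data but the rule
must be deterministic. Missing samples contribute zero duration; no
interpolation across gaps (nights with large gaps are already excluded), a
conservative and simple choice. A bout-list accessor (onset/offset runs)
exists for inspection but the modeled quantity is total time below
threshold.

**Covariates.** Day records get the active-phase mean air temperature
(07:00–17:00, same date) and that date's maximum wind speed. Night records
get the 24-h mean from 07:00 of the preceding active-phase to 07:00 after
the rest-phase, and the wind maximum of the evening's calendar date (the
preceding foraging period). Weather windows require 90 % slot coverage,
otherwise the record is excluded with a reason. The treatment factor is
coded 0/1 with control as reference, so coefficients read as treatment
minus control.

**Mixed models.** Three REML linear mixed models (statsmodels `MixedLM`):
daily median active T<sub>s</sub> with a random intercept per individual;
nightly minimum T<sub>s</sub> and torpor duration with a random intercept
plus a random treatment slope per individual. Global fixed effects are
treatment, the response's air-temperature covariate, wind, body mass at
capture, and sex. Models are simplified by backward elimination: refit
after removing the non-protected term with the largest p ≥ 0.05 until all
remaining non-protected terms are significant. The treatment term is
protected — it is the effect under test and is reported regardless of
significance. p-values use the residual-df t approximation (df = n − k);
this is documented output metadata, and it is anticonservative for
between-individual terms (mass, sex) at 16 individuals, which inflates
their occasional false retention. Marginal/conditional R² follow the
variance-partition definition: var(Xβ) over var(Xβ) + mean(zᵢᵀΣzᵢ) + σ²,
with the random-effect variance added to the numerator for the conditional
value. If the random-slope model fails to converge it is refitted with a
random intercept only and the result carries a prominent flag — with 16
individuals, slope variances frequently sit on the boundary. Prediction
intervals come from a parametric bootstrap (default 1000 replicates):
responses are simulated from the fitted model, refitted, and predictions
collected at reference covariates (observed means) per condition, with a
paired treatment-minus-control contrast; percentile intervals;
deterministic given a seed; refit failures above 10 % raise a warning.

## Synthetic study generator

The default `paper-winter` scenario encodes the study conditions: 2 sites
× 8 birds (6 females, 10 males overall), 15 winter days in alternating
5-day control/playback blocks with opposing sequence per site, 10-min
sampling, daily air-temperature minima ≈ 2.5 ± 3.1 °C and maxima
≈ 17.2 ± 2.4 °C, daily maximum wind ≈ 32.2 ± 15.5 km/h floored at
11 km/h.

**Weather.** Air temperature follows half-cosine arcs between a drawn
daily minimum (06:00) and maximum (14:00) plus small AR(1) noise. The
analytic mean of this diel cycle is (min + max)/2 ≈ 9.85 °C over 24 h and
≈ 12.6 °C over 07:00–17:00; these two numbers are fixed in the config as
the references for all air-temperature slope terms, so planted condition
means are centred regardless of the weather realization.

**Birds.** Each bird gets a resting normothermic level R<sub>i</sub> ~
N(37.3, 1.2²) and an active plateau ~ N(39.6, 1.0²), correlated at 0.9 —
individuals with high resting set-points run warm all day, and the
correlation keeps the plateau safely above R<sub>i</sub> so the lowest
active-phase sample identifies R<sub>i</sub>. Nightly minima and durations
carry per-bird offsets (SD 0.8 °C and 1.0 h) plus night-level residuals
chosen so the total SDs equal the configured 1.5 °C and 2.3 h; the bird
level gives the night models a real random-intercept variance to estimate.

**Traces.** Each bird-day is piecewise smooth on the grid: a half-cosine
rewarming arc that sits exactly at R<sub>i</sub> at 07:00 and reaches the
day's plateau by 07:30 (rewarming in small passerines is fast, and a steep
arc leaves a single grid sample at R<sub>i</sub>, keeping the baseline
estimator nearly unbiased under measurement noise); a flat plateau shifted
by 0.17 °C/°C of daytime air temperature, −0.2 °C under playback, and
day-level jitter (SD 0.4 °C) representing behavioural variation; then an
evening decline after 17:00 into a trough. The planted nightly minimum is
drawn from N(30.0 + treatment·(−1.25) + 0.15·(Ta₂₄ − 9.85), 1.5²) and the
planted duration from N(3.8 + treatment·2.1 − 0.15·(Ta₂₄ − 9.85), 2.3²)
clipped to [0, 12] h — clipping (censoring) rather than resampling keeps
the censored mean of the control draw at ≈ 3.8 h. The planted treatment
effects (−1.25 °C, +2.1 h) sit between the raw condition differences and
the model-adjusted effects they are meant to reproduce, so a balanced
design can recover both within tolerance.

The trough is built to satisfy two construction identities exactly in the
noiseless trace: its minimum equals the planted minimum, and its
continuous time below R<sub>i</sub> − 5 °C equals the planted duration.
It descends from R<sub>i</sub> through 0.75-h half-cosine edges to a
sustained shelf placed at min(M + 1.0, θ − 0.4) °C — tracking the bout's
depth, since torpid birds sit near their minimum — holds the shelf for
whatever time closes the duration after accounting for the edges' closed
-form sub-threshold fractions, and carves a sharp 0.5-h cosine dip to the
planted minimum, centred on a grid point (00:30) so the noiseless sampled
minimum is exact. Short bouts that cannot fit the shelf geometry use a
single cosine dip whose width solves the same closed form. Durations that
cannot fit between 18:00 and 07:00 are truncated and flagged. Because the
depth and duration draws are independent, inconsistent pairs occur
(duration 0 with a sub-threshold minimum, or a positive duration with a
minimum above threshold); they are reconciled (minimum moved to just
above/below the threshold) and flagged `adjusted` (~2–5 % of nights).

Measurement is Gaussian noise (SD 0.3 °C), a hard physiological guard
band of 15–45 °C, and independent per-sample missingness: 25 % during
08:00–17:00 (birds forage out of receiver range) and 2 % otherwise. The
missingness mechanism of real data — contiguous out-of-range excursions —
is *not* modeled beyond the higher daytime rate. The simulation grid runs
from 07:00 of day 0 to midnight after the last day, so the final evening's
rest window is 8 h short and is removed by the ordinary > 3 h rule.

File bundles are plain CSV with ISO-8601 timestamps: one logger file per
site whose pulse intervals invert each transmitter's true cubic at the
measured temperature plus 0.05 ms timing jitter (receiver-grade
precision, ≈ 0.002 °C), calibration tables sampled exactly from the true
curves, metadata, schedule, weather, wind, the planted ground truth, and
the scenario YAML. Identical configurations give byte-identical bundles;
re-reading a bundle reproduces the in-memory temperatures to ~0.01 °C.

## What recovery tests do and do not show

The recovery suite (20 replicate studies by default) checks that condition
means of depth and duration, the two treatment coefficients, the daytime
air-temperature slope, and the baseline come back within 0.3 °C / 0.5 h /
0.05 °C·°C⁻¹ bands. Small systematic offsets remain by construction and
are worth knowing about: measured durations sit ~0.2 h below planted
values (2 % night missingness deletes sub-threshold samples, and the
noise-biased baseline lowers each bird's threshold by ~0.06 °C), measured
minima ~0.15–0.2 °C below (minimum of noisy samples), and the recovered
treatment coefficient for depth is attenuated by ~0.1 °C because
no-torpor nights are reconciled upward, far more often under control than
treatment. The same asymmetries exist in any thresholded analysis of noisy
telemetry; passing recovery here shows the pipeline is faithful to its
inputs, not that real birds meet the generator's simplifications (smooth
single-trough nights, independent missingness, linear weather effects, no
transmitter drift).

## Numerical and design notes

- Backward elimination can flip a term whose p-value sits exactly at 0.05
  under ~0.01 °C input perturbations (e.g. pulse quantization); derived
  night metrics themselves are stable to well below that.
- `MixedLM` occasionally fails to start with its default optimizer on
  degenerate inputs (zero variance components); the fitter falls back to
  Powell and conjugate-gradient before giving up.
- Everything random descends from a single integer seed through spawned
  `numpy` `SeedSequence` streams: per-bird draws are independent of bird
  count and ordering, and the file-emission jitter has its own fixed
  stream, so bundles are reproducible bit-for-bit.
- Known limitations: no transmitter drift or re-calibration over time, no
  bout-structure modeling (onset/offset analyses), no rainfall covariate,
  no spatial or roosting behaviour, and no energetic (metabolic-rate)
  interpretation of the temperature traces.
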