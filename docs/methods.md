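# Methods

`catrace` analyzes ROI-averaged fluorescence time series from synaptic
Ca²⁺ imaging: it converts raw intensities to ΔF/F or ratiometric ΔR/R,
detects spontaneous (quantal) and stimulus-evoked transients, fits their
rise and decay kinetics, summarizes stimulus trains, and pairs optical
events with simultaneously recorded miniature postsynaptic potentials
(mEPSPs). This note documents the models, the defaults and why they were
chosen, the numerical conventions, and what the synthetic benchmark does
and does not demonstrate.

## Units and conventions

Frames are 0-based; all times are milliseconds. Frame *k* maps to
`start_time + k · Δt` with `Δt = 1000 / frame_rate`. Fitted time
constants are always reported in ms; a fit performed in frames is
converted by multiplying by Δt. Raw intensities are arbitrary units;
normalized traces are dimensionless.

Input tables follow the Fiji "Multi Measure" export contract — a header
row of text labels over numeric rows, one time-or-frame column plus one
column per ROI — in CSV or XLSX. Non-finite cells are rejected, never
imputed, and errors cite spreadsheet coordinates. An explicit time
column must be uniformly sampled (jitter above 0.1% of the frame
interval is rejected); non-uniform acquisitions are out of scope. Cell
values are converted with Python's correctly rounded `float`, so a
write/read round trip of the table format is bit-identical.

## Baseline estimation and normalization

The time-varying baseline F₀(t) is a centered sliding-window statistic.
Two methods exist:

- **percentile** (default for ΔF/F): the linear-interpolation percentile
  (index `p/100 · (m−1)` of the sorted window) — the default window is
  101 frames and the 30th percentile;
- **lowest_fraction** (default for ΔR/R): the mean of the `⌈f·m⌉`
  smallest of the *m* window values, default f = 0.10 ("lowest 10%"
  reads as a set average rather than a quantile; the 10th percentile
  remains selectable).

Windows truncate at the array ends — no padding or reflection, so no
fabricated samples enter the baseline; edge baselines simply average
fewer frames. ΔF/F = (F − F₀)/F₀ requires F₀ > 0 and the
denormalization F = F₀·(1 + ΔF/F) is exact to rounding.

For dual-channel recordings the reference (Ca²⁺-insensitive) channel is
optionally smoothed with a centered truncated moving average *before*
division — smoothing the quotient's denominator, not the ratio — then
R(t) = F_sig/F_ref, R₀ by the lowest-fraction sliding baseline, and
ΔR/R = (R − R₀)/R₀. Because the ratio cancels any gain common to both
channels, a shared multiplicative bleach leaves ΔR/R identically zero.

One property of the percentile baseline matters downstream: on a
pure-noise trace, the 30th-percentile baseline sits 0.52 σ *below* the
noise mean, so the resulting ΔF/F trace is centered slightly above
zero. Detection thresholds quoted "n σ above baseline" should therefore
be referenced to the normalized trace's own median (see Detection).

Benchmark-mode helpers reproduce a dye-comparison analysis convention:
a linear photobleach trend is fitted by OLS to mean intensities of the
100 ms windows preceding each 1 Hz stimulus and subtracted (anchored at
the first window's center, leaving it unchanged; a divide-by-line
variant is available since "adjusting by the slope" is ambiguous), and a
constant-baseline ΔF/F uses F_rest = the mean over the half-open 100 ms
window before the first stimulus.

## Event detection

Candidates are strict local maxima (plateaus resolve to their first
frame) on the normalized trace. Three criteria filter them:

- **threshold** — minimum peak value (ΔF/F or ΔR/R units);
- **min_width** — minimum contiguous frames at or above half the peak's
  own height (width at half height; frames, convertible via Δt);
- **min_distance** — minimum inter-peak separation in ms; among peaks
  closer than this the larger survives, amplitude ties going to the
  earlier peak.

Manual rescue (`nearest_peak`) returns the local maximum nearest a
clicked time within a search radius (default 200 ms), ignoring the
threshold — its purpose is recovering missed events — with exact-tie
preference for the earlier peak. Amplitudes default to the trace value
at the peak (the baseline of a normalized trace is zero); a
local-base mode subtracts the minimum over a preceding span to remove
the pedestal of an unresolved earlier event.

**Operating point for quantal recordings.** For 60 s, 100 fps quantal
traces with transient amplitude ten times the ΔF/F noise σ, the
recommended settings are: threshold = trace median + 3 σ, min_width = 3
frames, min_distance = 140 ms. The median offset compensates the
percentile-baseline bias noted above; 140 ms covers the supra-threshold
span of a single transient (τ_decay 67 ms), which prevents noise bumps
on a decay tail registering as second events. With these settings the
synthetic benchmark measures ≈97% sensitivity at ≈3% false positives
under a ±50 ms tolerance (an event counts as detected when any
detection lies within 50 ms; a detection counts as false when no true
event does). The suppression distance trades sensitivity against
double-counting: events arriving closer than min_distance merge into
one detection, so at rate λ the sensitivity ceiling is roughly
1 − λ·min_distance.

## Kinetic fitting

**Decay.** y(t) = y_peak·e^(−t/τ), t from the peak, fitted by
unweighted Levenberg–Marquardt least squares initialized from the
log-linear closed form (stray non-positive samples are excluded from
the initialization only). The default window runs from the peak up to
(exclusive) the first sample below 10% of the peak, capped at 1,000 ms;
an explicit span overrides it. Segments that are not positive decaying
exponentials are flagged, not fitted. Iterations are capped at 200.

**Rise.** y(t) = A·(1 − e^(−(t−t₀)/τ)) over [onset, peak], where the
onset is the last pre-peak frame at or below 10% of the peak amplitude.
The foot t₀ is a *free* parameter bounded to at most one frame before
the onset sample, fitted by bounded trust-region least squares: with t₀
pinned to the detected onset, noise that places the onset a frame early
makes the window convex and drives τ to the degenerate linear limit.
A rise spanning fewer than 3 frames is flagged "unresolved" and τ is
reported as one frame interval — an upper bound, not an estimate. At
100 fps this makes rise constants of ~5 ms unmeasurable; the benchmark
treats them as sampling-limited.

**Benchmark rate form.** ΔF/F = A₀·e^(bt) with t in seconds; the
amplitude is the intercept A₀ and τ = 1000/(−b) ms. A fitted b ≥ 0 is
an error ("non-decaying segment").

**Sweep alignment.** Each sweep's first rise is the first post-stimulus
sample exceeding a threshold (default 2 σ of that sweep's pre-stimulus
segment); sweeps are shifted so that sample sits half a frame interval
after the stimulus (1.6475 ms at Δt = 3.295 ms) and averaged over their
overlap. Sweeps with no supra-threshold sample are excluded.

## Stimulus protocols and trains

A protocol is an ordered list of blocks (label, frequency, explicit
stimulus times); within a block, intervals must match 1000/frequency to
within a frame interval. Events are attributed to the nearest preceding
stimulus when the peak latency lies in (0, 100] ms (window
configurable); each stimulus claims at most one event — the nearest in
latency — and the rest stay unassigned. Assignment is idempotent.

Train summaries measure the first and final responses from the
pre-train baseline (mean over 100 ms before stimulus 1), each as the
peak within one inter-stimulus interval after its stimulus; the
facilitation index is final/first, and the post-train decay constant
comes from a 1,000 ms single-exponential fit after the final peak.
Baseline-referenced amplitudes include whatever summation pedestal the
preceding responses leave: with the 21.3 Hz / 17-stimulus protocol
(ISI 46.95 ms) the facilitation index matches the true gain ratio
within a few percent only when τ_decay is well below the ISI (the
benchmark uses τ_decay = 12 ms, tail ≈ 2%); for slower indicators a
trough-relative measure would be needed and is deliberately not the
default, matching the baseline-referenced convention.

## Paired optical–electrophysiology statistics

Events are paired by greedy globally-nearest matching: repeatedly pair
the unpaired cross-modal pair with smallest |Δt| ≤ tolerance (default
50 ms), ties toward the earlier ephys then optical event — deterministic
and order-independent, conserving both input counts. The detection
fraction is pairs/(pairs + unmatched ephys). Amplitude correspondence is
the Pearson r (and r²) of paired mV vs ΔF/F amplitudes, requiring ≥ 3
pairs and non-degenerate margins.

Active-zone matrices (AZ × stimulus peak responses) are compared with
paired two-tailed t-tests between every AZ pair, paired by stimulus
number; zero-variance pairs are excluded and reported as NaN. The
fraction significant at α = 0.05 is reported raw — no multiple-testing
correction by default, with Bonferroni and Benjamini–Hochberg options —
because the quantity of interest is the fraction itself, calibrated to
α under the null. Outlying AZs are flagged when their mean response
falls outside the pooled Q1–Q3 interquartile range (linear-interpolation
quartiles over all individual responses, the same convention as the
percentile baseline). Distributions are compared with the two-sample
Kolmogorov–Smirnov test (asymptotic p).

## Synthetic recordings

The generator exists to provide ground truth for every stage. A
transient is a unit-peak kernel: a saturating exponential rise over
3·τ_rise to the peak, then a pure exponential decay. This piecewise
form is exactly the pair of models the kinetics stage fits, a deliberate
choice: with a product-form kernel (rise times decay), the post-peak
segment is contaminated by the unsaturated rise term and a
decay-from-the-peak fit is biased high by 8–35% across the τ grid even
without noise — recovery tests would then measure model mismatch, not
estimator quality. The cost is a derivative kink at the peak that real
transients do not have.

Defaults emulate a 60 s widefield quantal recording at 100 fps from a
postsynaptic GCaMP8m-class sensor: baseline 100 AU; transients of peak
ΔF/F 0.58 with τ_rise 14 ms and τ_decay 67 ms arriving as a 0.5 Hz
Poisson process; additive Gaussian noise of σ = 5.8 AU (ΔF/F σ 0.058,
i.e. SNR 10, the same noise regime as the kinetics benchmark); and a
3% multiplicative exponential bleach over the acquisition (a linear
option exists for testing the bleach detrend). Evoked recordings place
one deterministic event per stimulus scaled by a per-stimulus gain;
dual-channel simulations give the reference its own baseline, noise and
bleach but no events. Matched-pair streams draw amplitudes from a
bivariate lognormal (geometric means 0.64 mV and 0.58 ΔF/F, log-sd 0.3,
correlation ρ on the log scale — amplitude-scale Pearson correlation
within ~0.01 of ρ at this spread), share event times up to ≤ 10 ms
jitter, and delete a dropout fraction of optical events. AZ matrices
are mean + i.i.d. Gaussian entries, default 30 AZs × 15 stimuli. All
generators are bit-reproducible under a fixed integer seed.

What the synthetic data does *not* contain: correlated (pink/drift)
noise, shot-noise variance scaling with intensity (a Poisson mode is a
possible extension), motion artifacts, overlapping multi-site events,
frame-rate jitter, or indicator nonlinearity (Hill binding,
saturation). Passing the benchmark therefore demonstrates correctness
of the estimators under the stated model, not performance on arbitrary
real recordings.

## Benchmark problem sizes

The acceptance script (`scripts/acceptance.py`) runs: 300 random traces
for the baseline oracle; 60 seeds per (τ_rise, τ_decay) cell for
kinetics recovery (median signed error reported); 60 quantal traces for
the detection operating point; 150 replicates of 300 pairs for the
detection fraction and 300 replicates at each (ρ, n) ∈ {(0.46, 283),
(0.73, 298), (0.81, 216)} for correlation recovery; and 1,000 null
30 × 15 matrices for type-I calibration. The pytest acceptance suite
uses 1,000 oracle traces, 100 seeds per kinetics cell and 100 detection
traces. These sizes put Monte-Carlo standard errors well inside each
check's tolerance.

## Known limitations

- Rise constants at or below half a frame interval are reported only as
  upper bounds; decay fits assume a mono-exponential return to baseline.
- Heavily overlapping transients are not deconvolved; min_distance
  suppression merges events closer than the suppression span.
- The greedy event matcher is not guaranteed maximum-cardinality on
  adversarial inputs (it is on realistically sparse streams).
- The AZ pairwise p-value matrix is reported without dependence
  correction across pairs sharing a row; only the per-pair level is
  calibrated.
- The benchmark-mode decay fit window follows the dye-comparison
  convention of 147 samples of 3.295 ms starting 14.828 ms after the
  stimulus.
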