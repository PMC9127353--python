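# Methods

## Model and assumptions

The package treats a drinking record as a cumulative-volume signal V(t)
sampled uniformly at fs (default 1000 Hz). Drinking speed is v(t) = dV/dt
(ml/s). A suck is a unimodal speed pulse; the silent gaps between pulses
(offset-to-onset pauses) form the interval sample. Pauses are assumed to
come from two latent classes — within-burst inter-suck intervals (ISIs)
and between-burst inter-burst intervals (IBIs) — that are approximately
lognormal, so their pooled natural-log values follow a two-component
Gaussian mixture. The burst–pause criterion (PC) is the interval value at
which the two weighted component densities are equal: below it a pause is
more probably an ISI, at or above it more probably an IBI. No assumption
is made about the physiological mechanism that sets pause lengths; the
classes are statistical constructs read off the pooled distribution.

Intervals are defined pause-based (offset-to-onset), not peak-to-peak:
the population's modal ISI of ~0.97 s would be impossible peak-to-peak
under the 1 s minimum peak spacing used by detection.

## Detection parameters

| parameter | default | unit | role |
|---|---|---|---|
| `fs` | 1000 | Hz | sampling rate of the device |
| `cutoff_hz` | 10 | Hz | conditioning low-pass (see below) |
| `artifact_speed` | 20 | ml/s | \|speed\| above this is a sensor artifact |
| `min_amplitude` | 0.5 | ml/s | speed below this is zeroed (noise floor) |
| `min_peak_distance_s` | 1 | s | minimum spacing between suck peaks |
| `min_suck_size_ml` | 1 | ml | smaller pulses are discarded as noise |

The artifact, amplitude, spacing and size thresholds are the suggested
device settings. The conditioning cutoff deliberately is not the suggested
0.5 Hz: that value belongs to the *visual QC* view of cumulative volume
(`qc-plot`, `VIZ_CUTOFF_HZ`), where heavy smoothing is desirable. A
zero-phase Butterworth at 0.5 Hz has a rise time of roughly 1.3 s and
merges speed pulses separated by second-scale pauses, so no pause-resolved
event detection can operate behind it (we verified numerically that a
0.97 s pause measures as ~0 s through it). The detection default of 10 Hz
passes the suck band (pulse content of a sub-second suck lies below
~5 Hz) while suppressing sample-scale sensor noise.

Two detection conventions matter downstream:

- **Onsets/offsets at floored zeros.** A suck's onset and offset are the
  nearest samples where the floored speed is zero. The amplitude floor
  therefore hides each pulse's sub-threshold tails: every measured pause
  exceeds the true silent gap by the two flanking floor-crossing times
  (for a raised-cosine pulse of width d and peak A, t_cross =
  d/(2π)·arccos(1 − 2·0.5/A); ~35 ms per side for typical pulses), plus
  the conditioning filter's rise width. Suck sizes correspondingly lose
  the tail area below the floor (≲ 0.05 ml per suck). The tests bound the
  round-trip error by these analytic quantities rather than by zero.
- **Artifact repair before flooring.** Super-threshold excursions are
  extended to their flanking zero crossings and bridged linearly; if a
  run touches the signal edge the nearest retained value is used, and if
  extension would swallow the entire (single-lobe) signal only the
  super-threshold run itself is bridged.

QC flags a measurement as interference when > 1% of samples are
artifact-repaired or cumulative volume drops by > 5 ml; both thresholds
are package choices standing in for a visual exclusion step.

## Mixture fit and criterion

The EM implementation is deliberately in-package: the reproducibility
contract (initialisation, tolerance, floor, restart policy) is part of
the method. Per restart, component means start at evenly spaced sample
quantiles with seeded Gaussian jitter (sd = 0.1 × sample sd), standard
deviations at the sample sd, weights uniform; iteration stops when the
log-likelihood improves by < 1e-8 or after 500 iterations; standard
deviations are floored at 1e-3 log-seconds so duplicated interval values
cannot collapse a component. The best of 10 restarts (by log-likelihood)
is reported, together with the full per-iteration likelihood history
(asserted non-decreasing in the tests). `sklearn.mixture.GaussianMixture`
is used in the test suite as an independent cross-check of the fitted
optimum, never as the implementation.

Model order is chosen by AIC with p = 3k − 1 free parameters (k means,
k sds, k − 1 weights); ties break toward the smaller k. "The two dominant
components" means the two largest mixing weights; a `selection="peak"`
switch uses peak density height instead.

The PC solves w₁φ(x; μ₁, σ₁) = w₂φ(x; μ₂, σ₂) via the quadratic in x from
the log densities; with equal σ the equation is linear. Exactly one root
can lie strictly between the means (the weighted left density is strictly
decreasing and the right one strictly increasing there); if none does,
the components are not separated enough and an error is raised rather
than a criterion invented. For k > 2 every local minimum of the full
mixture density between consecutive component means is reported as a
candidate criterion alongside the dominant-pair intersection. Note that a
two-component mixture density need not have an interior local minimum at
all even when the weighted component densities cross — with the default
simulator spreads (below) it does not — which is why the pairwise
intersection, not the mixture minimum, defines the PC.

## Survival verification

Each candidate criterion extracts the interval set below it; all values
are fully observed events (extraction truncates the set, not the
observation window), so the Kaplan–Meier estimate equals the empirical
survival function — the product-limit machinery (via `lifelines`) is kept
so that censored designs remain possible. The omnibus log-rank test spans
the finite-criterion groups. The KM median is the smallest event time
with S(t) ≤ 0.5, and the median quotient is 100·median/PC to the nearest
integer percent. "Residuals" are per-group interval histograms in 0.25 s
bins from zero; the comparison of these counts across criteria is left to
the reader of the plot/CSV.

The per-measurement AIC report (`aic_per_measurement`) truncates the
ratio at the second decimal (not rounds), matching the convention of the
reference values this report format follows.

## Simulator

The generator emulates the pooled structure of human drinkometer data:
log-domain pause mixture with means −0.0325 (ISI, mode ~0.97 s) and
1.1460 (IBI, mode ~3.15 s), spreads 0.45/0.55 and ISI weight 0.70; the
spreads and weight are package defaults — the data behind the modal
values do not pin them (the printed peak densities would pin the spreads
only under an additional assumption about whether plotted curves are
weight-scaled). Sucks per burst are geometric with mean 1/(1 − 0.70), so
the realized ISI fraction matches the mixture weight in expectation.
Sucks are raised-cosine speed pulses of 0.8 s moving 3.8 ± 0.5 ml
(clipped to [2.0, 5.5] ml: always detectable, never artifact-like), and
pauses are floored at 0.25 s as a refractory period. The floor sits 3σ
into the ISI log-tail (resampling ~0.1% of draws) deliberately: a harder
floor truncates the ISI component's left tail and measurably distorts
the EM decomposition, and it also guarantees peak spacings above the 1 s
minimum so detection never merges clean pulses. Optional white Gaussian
volume noise and ~100 ms biphasic ±60 ml/s artifact excursions complete
the rendering. `true_intersection` always refers to the untruncated
generating components.

What the simulator does **not** emulate: drift and slow baseline changes
of the sensor, serially correlated pause sequences, within-meal
satiation trends (pause lengthening over the meal), suck-shape
variability beyond size, and the device's calibration channels. Passing
round-trip tests therefore demonstrate correctness of the pipeline's
logic under the stated generative model, not robustness to every
real-device pathology.

## Test and problem sizes

The pooled interval count used throughout is n = 1671. At this size, with
the default component overlap, the derived intersection has an intrinsic
per-seed sampling spread of ~0.1 log-seconds; recovery is therefore
asserted on the across-seed mean (20 seeds), which isolates pipeline bias
(measured ≈ −0.03 log-seconds, dominated by the amplitude-floor pause
widening described above) from estimator noise. Full-pipeline runs use
450 bursts (~1500 pauses, ~an hour of signal at 1000 Hz) per seed.

## Known limitations

- A PC derived on pooled data is suboptimal for individual participants;
  per-participant fits need more intervals than short meals provide
  (bootstrapping is a possible remedy but is out of scope).
- No censoring support in the survival verification (by design).
- The TDMS adapter reads a single mapped volume channel and ignores the
  `.info`/`.tdms_index` companions, whose layout is undocumented; it
  requires the optional `npTDMS` dependency.
- The microstructure table implements a representative parameter roster
  (sucks, bursts, sizes, durations, ISI/IBI means); site-specific rosters
  can extend `PARAMETER_COLUMNS`.
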