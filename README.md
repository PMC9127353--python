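# drinkometer

Burst–pause criterion derivation (BPCD) and microstructure analysis for
drinkometer recordings of human ingestive behavior.

A drinkometer records the cumulative volume (ml) of a liquid meal at high
sampling rate (nominally 1000 Hz). Ingestion is organized on two time
scales: individual **sucks**, and **bursts** — clusters of sucks separated
by longer pauses. Suck-level ("PC-independent") parameters such as suck
count and size can be computed directly, but burst-level ("PC-dependent")
parameters require a **burst–pause criterion (PC)**: the pause duration
that separates inter-suck intervals (ISIs) from inter-burst intervals
(IBIs). Because drinking behavior varies strongly between people, the PC
should be derived from the data rather than fixed by convention.

## The method

1. **Detection.** The volume signal is low-pass filtered (zero-phase
   4th-order Butterworth), differentiated to a speed signal (ml/s),
   repaired for sensor artifacts (|speed| > 20 ml/s excursions deleted and
   bridged linearly), and floored (speed < 0.5 ml/s set to 0). Sucks are
   speed peaks ≥ 0.5 ml/s, at least 1 s apart, with integrated size
   ≥ 1 ml; the pauses between consecutive sucks form the interval sample.
2. **Mixture model.** The pooled pauses x₁…xₙ are log-transformed and
   modelled as a univariate Gaussian mixture
   f(x) = Σₖ wₖ φ(x; μₖ, σₖ), fitted by EM. The number of components is
   chosen by the Akaike information criterion, AIC = 2p − 2 ln L with
   p = 3k − 1; two components (ISIs and IBIs) are expected.
3. **Criterion.** The PC is the point where the two dominant weighted
   component densities intersect, w₁φ(x; μ₁, σ₁) = w₂φ(x; μ₂, σ₂) — the
   log-domain solution of a quadratic — back-transformed to seconds:
   PC = exp(x*). Intervals < PC are ISIs; intervals ≥ PC are IBIs.
4. **Verification.** Kaplan–Meier survival curves of the ISI sets
   extracted under candidate criteria are compared with a log-rank test,
   and each curve's median is expressed as a percentage of its criterion
   (a well-chosen PC splits its ISI set near 50%).
5. **Tables.** A chosen PC segments sucks into bursts and yields
   per-measurement macro-/microstructure parameter tables.

A simulator generates synthetic traces with known ground truth (lognormal
ISI/IBI mixture calibrated to log-modes −0.0325 and 1.1460, i.e. ~0.97 s
and ~3.15 s), so every stage is testable without device data.

## Worked example

```sh
drinkometer simulate --seed 11 --n-bursts 60 --noise-sd 0.02 \
    --out trace.csv --truth truth.json
drinkometer extract-isis --trace trace.csv --out intervals.csv
drinkometer fit-gmm --input intervals.csv --kmax 5 --restarts 10 --seed 11 \
    --out fit.json
drinkometer derive-pc --fit fit.json --out pc.json
drinkometer km-verify --input intervals.csv --pcs 1.34,3.15,5.13 --all \
    --out km.json
drinkometer extract-tables --trace trace.csv --pc 2.20 --out params.csv
```

prints

```
wrote trace.csv (175 sucks, 60 bursts)
INFO drinkometer: trace: 175 sucks, 174 intervals
chosen k = 2 (AIC 315.4); wrote fit.json
PC = 2.20 s (log_e 0.7883); wrote pc.json
log-rank chi2=86.80 df=2 p=1.42e-19; wrote km.json
wrote params.csv (1 measurements)
```

Reading the output: the simulated meal contains 175 sucks in 60 bursts;
detection recovers all of them and extracts the 174 pauses between
consecutive sucks. The AIC selects two mixture components, as expected for
a sample that pools ISIs and IBIs, and the weighted component densities
intersect at 2.20 s — the derived criterion for this recording (the
generating mixture's analytic intersection is 2.03 s; a single ~170-pause
measurement estimates it with sampling noise). The log-rank test confirms
that ISI sets extracted under different criteria have clearly different
survival distributions. `params.csv` holds one row per measurement: here
175 sucks totalling 667.3 ml over 462.9 s, mean suck size 3.81 ml, mean
ISI 1.16 s, and — under PC = 2.20 s — 52 bursts of on average 3.37 sucks,
12.8 ml and 5.05 s, separated by a mean IBI of 3.92 s.

Every subcommand writes a JSON provenance record (resolved configuration,
seed, SHA-256 of the inputs) next to its outputs.

## Layout

- `src/drinkometer/signal_io.py` — trace/interval I/O, CSV dialects, TDMS adapter
- `src/drinkometer/detection.py` — filtering, artifact repair, suck detection
- `src/drinkometer/bpcd.py` — log-domain GMM (EM), AIC selection, PC derivation
- `src/drinkometer/survival.py` — Kaplan–Meier verification, log-rank, residual bins
- `src/drinkometer/microstructure.py` — burst segmentation, parameter tables
- `src/drinkometer/simulate.py` — ground-truth trace/interval generator
- `src/drinkometer/cli.py` — the `drinkometer` command
- `docs/methods.md` — model assumptions, parameter choices, limitations
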