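# Methods

This note documents the models, parameter choices and numerical
conventions behind `emowave`, and what the synthetic validation does and
does not demonstrate about real recordings.

## Radar signal model and simulation

The simulator generates raw ADC cubes (channels × fast-time × slow-time)
for point-reflector scenes. Each reflector at range `R` contributes, per
chirp,

    A · exp(j·(2π f_IF t_fast + 4π R(t_slow)/λ)),

with `f_IF = S·2R₀/c` evaluated at the reflector's *nominal* range. This
is the small-displacement (stop-and-hop) approximation: sub-millimetre
chest motion moves the beat tone by ~10⁻⁴ of a range bin, so to excellent
accuracy only the slow-time carrier phase carries the motion. The
approximation is what makes the phase-fidelity invariant exact: for a
noiseless single-target scene the fused unwrapped phase equals
`4πR(t)/λ` up to an additive constant to better than 10⁻⁶ rad (measured:
~10⁻¹³).

The speed of light is fixed at `c = 3×10⁸ m/s` (the radar-engineering
convention), giving λ = 5.000 mm at 60 GHz and a range resolution of
`c/(2·B_sampled)` = 0.0451 m for the default configuration — `B_sampled`
being the bandwidth swept during the 50 µs ADC capture window, not the
full chirp bandwidth.

Chest motion is modelled as a sinusoidal superposition: baseline range
R₀ (default 0.7 m, inside the 0.6–0.9 m seating range), respiration
(default 0.25 Hz, 3 mm) with optional harmonics, heartbeat (default
1.2 Hz, 0.1 mm), plus optional ramp-and-hold motion artifacts. The 12
virtual channels observe the identical reflector return with independent
complex Gaussian noise (default relative SD 0.1 per sample — a free
parameter documented here, not a claim about the study hardware).
Clutter reflectors are strictly static; amplitudes are constant over
slow time (no RCS fluctuation); I/Q data are generated complex-valued,
so there are no real-sampling image frequencies.

## Extraction chain conventions

* Fast-time FFT: rectangular window, no zero-padding. Range bins are
  0-based; bin `b` covers `[b·Δr, (b+1)·Δr)`.
* MTI: per-bin slow-time mean subtraction; linear and variance-preserving
  by construction.
* Bin selection: top-K (K = 5) mean-amplitude bins inside a 0.3–1.5 m
  search window (covers the seating range with margin and keeps residual
  clutter bins out of the top-K; widen the window for the full-span
  behaviour). Amplitude ties break toward the nearer bin.
* Phase: complex argument per selected bin, unwrapped so successive
  steps lie in (−π, π]; weighted fusion with amplitude-proportional
  weights that always sum to one (bins containing an exactly-zero sample
  have undefined phase and are dropped, with weight renormalization).
* Selection and fusion run independently per channel; the per-channel
  fused phases are then averaged.
* First difference leaves length N−1; filtered outputs keep that length.
* Band-pass filters: Butterworth, orders 4 (respiration) and 6
  (heartbeat) as passed to the design routine, applied forward–backward
  (`sosfiltfilt`), so the outputs are zero-phase — phase distortion would
  corrupt beat timing — at the cost of doubling the effective order.
  The same zero-phase convention applies to the PPG, GSR and SNR filters.

## Physiological channels

PPG: 0.6–5 Hz 4th-order band-pass → least-squares linear detrend →
centered 0.1 s (20-sample at 200 Hz) moving average with edge truncation
(shorter effective window at the boundaries; this avoids phase lag, and
the boundaries lie outside the analysis windows anyway).

GSR: the sensor reports resistance in 100–2500 kΩ; conductance is
`G [µS] = 1000 / R [kΩ]` (an exact involution; 100 kΩ ↦ 10 µS), then a
3rd-order 1 Hz low-pass. The synthetic generator superimposes unit-peak
bi-exponential conductance responses on a tonic level and inverts back
to resistance, clipping to the sensor range.

The synthetic PPG is a fixed two-lobe template (systolic Gaussian at
0.30 T, dicrotic bump at 0.60 T) with multiplicative beat-interval
jitter; only rate and jitter vary because nothing downstream uses pulse
morphology beyond band content. True systolic-peak times are carried in
the signal metadata as detector ground truth.

## Validation metrics

Band-split SNR low/high-passes the record at a cutoff (15 Hz for PPG,
1 Hz for GSR; 3rd-order zero-phase Butterworth on both sides — the
high-side order is not separately specified anywhere, so the GSR order
is reused) and reports `10·log₁₀(M_signal/M_noise)` of the mean squares;
exactly zero noise power returns +inf as a distinct sentinel.

Dominant frequency is the magnitude-spectrum argmax on a zero-padded
grid no coarser than 0.005 Hz, searched inside 0.8–2.0 Hz for heart rate
(the design band 1.0–1.8 Hz with margin) and 0.1–0.5 Hz for respiration,
over the whole record (no sub-window). Heart-rate agreement reports the
per-trial absolute errors plus MAE, median, SD and mean relative error.

## Features

Per 5-second window over the final 60 s of a trial (12 windows, no
overlap; windowing requires the record to be at least one sample longer
than the tail because the differenced vital sign loses one sample):

* mmWave (32): mean and SD of the vital sign; mean |Δ¹| and |Δ²| of the
  vital sign and of its variance-normalized copy; NSI; HFD; mean
  periodogram PSD of the respiration waveform in 0–0.1 / 0.1–0.2 /
  0.2–0.3 / 0.3–0.4 Hz and of the heartbeat waveform in 1.0–1.3 /
  1.3–1.6 / 1.6–1.8 Hz; mean instantaneous frequency and amplitude of
  the first four IMFs; nine HRV features.
* PPG (28): the same minus the four respiration PSD bands.
* GSR (24): median/mean/SD/min/max/normalized-range of the conductance,
  its first and its second derivative (18), plus median/mean/SD/max/min/
  range of the 0–2 Hz periodogram PSD (6).

Conventions chosen where the definitions are open:

* **Beat detection** — prominence-based peak picking (threshold: half the
  5th–95th percentile span) with a 0.45 s refractory period, isolated
  behind one function so a template-matching segmenter can be dropped in.
* **HRV** — nine statistics of the NN intervals; SD1 is the RMS Poincaré
  distance perpendicular to the identity line, which equals RMSSD/√2
  identically (asserted as a cross-feature test). HRVTi uses the
  conventional 1/128 s histogram bin. Windows with fewer than 3 NN
  intervals carry the trial-level HRV (computed over the whole 60 s
  tail) forward, since 5 s windows can contain too few beats for
  SDNN/pNN50 to be meaningful.
* **NSI** — SD of the 10 per-segment means of the variance-normalized
  signal (zero-variance input → 0).
* **HFD** — Higuchi curve-length regression with kmax = 10.
* **PSD** — raw periodogram, rectangular window, zero-padded to a grid of
  at most 0.025 Hz: the raw grid of a 5-s window (0.2 Hz) would leave
  0.1-Hz-wide bands empty.
* **HHT** — in-package empirical mode decomposition (cubic-spline
  envelopes with mirrored edge extrema, Cauchy-type stopping threshold
  0.2, ≤64 siftings); instantaneous frequency/amplitude from the
  analytic signal with 5% edge trimming; missing IMFs report 0 with the
  missing-flag convention.

## Ratings and labels

CV = sample SD / mean (n−1 SD throughout; this reproduces the published
mean per-clip CVs 0.26/0.32/0.29 at 2 d.p. from the per-clip summary
table). Spearman ρ is computed as Pearson correlation of average ranks —
the tie-aware form discrete 1–9 ratings require — with a two-sided
t-approximation p-value helper. Quadrant boundaries assign
coordinate = center to the "low" half (display only; threshold-5 trials
are excluded from labels anyway). Binarization: rating < 5 → low,
> 5 → high, = 5 → excluded; each labeled trial contributes 12
window-level samples to the class distribution.

## Classification baseline

Per participant and scale: trials with definite labels are split
window-wise (first ⌈0.75 n⌉ windows train — 9 of 12 — remainder test),
Z-scored with training-set statistics only (zero-SD features map to 0),
and classified by an RBF SVM. Grid search covers C = 10⁻⁵…10⁵ (11
values) × γ = 10⁻⁴…10 (6 values) — the unique geometric sequences with
those endpoints and counts — selected by stratified 5-fold CV accuracy
on the training set (the selection protocol is not otherwise specified;
CV avoids test-set leakage, which may shift absolute accuracies), with
seeded fold shuffling for bit-reproducibility. Reported: accuracy,
balanced accuracy (mean per-class recall), F1 of the "high" class
(binary convention) plus macro-F1.

## What the synthetic validation shows — and limitations

Passing tests demonstrate that the implementation is internally
consistent (oracle identities, round trips, determinism) and that the
chain recovers known simulation parameters. The generators emulate
band structure, periodicity and noise, not real morphology: sinusoidal
breathing, a fixed PPG template, point-reflector chests. Results on real
recordings will differ (body motion, posture change, extended targets).

**Respiratory-harmonic interference.** Mean cancellation is applied
before phase extraction, as the chain defines. For a single moving
phasor `z = exp(jφ)` this subtracts the phasor's own slow-time mean
`m ≈ J₀(a)` (modulation index `a = 4π·A_resp/λ` ≈ 7.5 for 3 mm
respiration), and `arg(z − m)` then carries a ripple of order |J₀(a)| ≈
0.27 rad concentrated at exact multiples of the respiration rate. With a
0.1 mm cardiac amplitude (0.13 rad phase line) and first-difference
weighting, such a harmonic can outweigh the heartbeat peak for the
slowest heart rates: on the 16-cell rate grid, respiration is recovered
in 16/16 cells within ±0.02 Hz but heart rate in 12/16 within ±1.2 bpm,
the four misses being exact respiration harmonics. Perfectly periodic
synthetic breathing concentrates all harmonic energy into sharp lines —
the worst case; real breathing spreads it. Extracting phase from the
raw (non-cancelled) matrix removes the effect entirely in simulation,
but the cancellation-first order is kept as the method's definition.
This is the known dominant error mechanism for radar heart-rate
estimation with this class of pipeline.

Problem sizes used by the default validation runs: 60–65 s trials at the
full 12-channel configuration for end-to-end checks, a 16-cell rate grid
with one seeded noise realization per cell, 6 synthetic trials for
heart-rate agreement, and reduced configurations (1–2 channels, 64
fast-time samples) for unit-level oracles.
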