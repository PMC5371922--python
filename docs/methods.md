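# Methods

This note documents the models, conventions and numerical choices behind
`pcgkit`, and what the synthetic validation does and does not show.

## Signal model of the synthetic generator

The generator (`pcgkit.synth`) renders what the downstream pipeline
assumes about newborn PCG:

* **Cycles.** Quasi-periodic S1 events starting 0.2 s into the recording,
  cycle length `60/HR` with uniform ±`hr_jitter_pct`% jitter per cycle
  (default heart rate 140 bpm, jitter 2%).  S2 falls at
  `systole_fraction` (default 0.4) of each cycle, so systole is shorter
  than diastole, as required by the interval-based labeling rule.
* **Heart sounds.** Gaussian-windowed cosines: S1 at 40 Hz over 80 ms and
  unit amplitude; S2 at 65 Hz over 60 ms at 0.7 relative amplitude.  The
  ±3σ envelope spans the nominal duration and the cosine phase puts the
  energy maximum exactly at the annotated event time.  Both tones sit
  inside the pipeline's 20–100 Hz analysis band — the standard PCG-phantom
  choice.
* **Murmurs.** Hann-windowed bursts of band-limited Gaussian noise in the
  90–180 Hz band.  Turbulent-flow murmurs are clinically higher-pitched
  than the valve-closure transients; this choice also means the
  segmentation wavelet (centered near 50 Hz) barely responds to the
  murmur, while the 20–100 Hz Butterworth filter still passes the lower
  part of the murmur band, leaving discriminative energy in the filtered
  signal.  Pathological murmurs fill the full systolic or diastolic
  interval at the configured relative amplitude; innocent murmurs cover
  only the early half of systole at 0.4× that amplitude, encoding the
  clinical picture of soft, short, early-systolic innocent murmurs.
  Recordings are labeled pathological iff the murmur kind is
  pathological.
* **Noise.** The clean signal is peak-normalized to 1, then white noise
  (70% of the noise power) and <10 Hz baseline wander (30%) are added at
  the configured SNR (default 20 dB; `inf` gives a noise-free recording).
  Dataset generation derives per-recording seeds from one master seed and
  randomizes heart rate (±8%) and SNR (±3 dB) across subjects.

**What this does not emulate:** respiration-synchronized S2 splitting,
third/fourth heart sounds, crying and handling artifacts, sensor-contact
dropouts, and real murmur spectro-temporal structure (synthetic murmurs
are stationary filtered noise).  Passing tests on this generator shows
the pipeline's stages are correct and internally consistent under the
stated signal model — not that clinical-grade performance transfers to
real newborn recordings.

## De-noising

3rd-order Butterworth band-pass, 20/100 Hz cutoffs, applied
forward-backward (`sosfiltfilt`).  Zero-phase application is a deliberate
choice: a causal pass would delay the 50 Hz envelope by several
milliseconds and bias event times.  The single-pass design magnitude is
−3 dB at both cutoffs (the Butterworth definition); the two-pass
application doubles stop-band attenuation.  Amplitude is peak-normalized
after filtering so the 0.1 wavelet detection threshold is dimensionless.
Spectrogram QC uses a Hann window with 50% overlap, the usual
leakage/variance trade-off.

## Segmentation

The analysis wavelet is the complex Gaussian (Gabor) wavelet
`ψ(t) = C·e^{−jωt}·e^{−t²}` evaluated at `t/scale`.  The published form
leaves ω and the dilation open, so both are parameters; the default
(ω = 5, scale = ω/(2π·50 Hz) ≈ 15.9 ms) centers the passband at 50 Hz —
the midpoint of the analysis band — with a bandwidth that responds
strongly to both S1 (40 Hz) and S2 (65 Hz) but negligibly above ~90 Hz.
The coefficient magnitude is max-normalized; "zero-crossing" peak
localization is implemented as zero-crossings of the first difference of
that envelope, i.e. local-maximum localization.  Peaks below 0.1 are
discarded and peaks closer than 0.06 s (shorter than any plausible
newborn systole) are merged keeping the larger, suppressing
double-detections on split sounds.

S1/S2 assignment uses the alternating interval rule with a majority vote:
the parity whose intervals are shorter on average opens systoles (S1).
If the two parities differ by less than 5% of the mean interval the
pattern is declared ambiguous and segmentation fails for that recording
rather than guessing.  Cycles are cut S1-to-S1; a cycle whose systole is
not shorter than its diastole contradicts the labeling rule and is
dropped with a warning.

## Cycle selection

DTW uses |aᵢ − bⱼ| as the local cost (the 1-D instance of the Euclidean
metric), the {(1,0),(0,1),(1,1)} step set, and reports accumulated cost ÷
path length.  Cycles are peak-normalized and Fourier-resampled to 256
samples before comparison; without a common scale and length a single
absolute threshold across cycles would be meaningless.  The default
constraint is a Sakoe-Chiba band of 10% of the length; the unconstrained
and Itakura (slope 1/2…2) variants are selectable, and infeasible windows
raise errors rather than returning partial alignments.  The inner dynamic
program is JIT-compiled (numba); path recovery backtracks the filled cost
matrix with a deterministic diagonal-first tie-break.

Representative selection is a greedy cover: the DTW medoid of the
uncovered cycles (minimal summed distance, lowest index on ties) becomes
the next "pattern cycle" and covers everything within the threshold
(default 0.005, per-step, on normalized cycles).  Exact minimal covers
are verified against brute force only on small test instances; greedy is
the production path.  With realistic noise the 0.005 threshold is strict
enough that most cycles become their own representatives — the
selection then degrades gracefully to using all cycles, weighted
equally, rather than discarding information.

## Features

Per representative cycle: max |x|; sum of positive samples; population
variance; Shannon energy `−(1/N)Σx²ln x²` with `0·ln 0 := 0` (nonnegative
for |x| ≤ 1, emphasizing mid-intensity content such as murmur energy).

The bispectrum uses the direct estimator: mean-removed, Hann-windowed
segments (default 256 samples, 50% overlap), averaged
`X(f₁)X(f₂)X*(f₁+f₂)` on the grid 0…N/2 in each axis; it is symmetric in
(f₁, f₂) by construction and scales cubically with amplitude.  The
third-order Wigner distribution is reduced to its diagonal frequency
slice: for the analytic signal z, the lag kernel
`z(t+τ)²·z*(t−2τ)` is Hann-windowed over τ (128 lags, hop 16) and
Fourier-transformed; a tone at f₀ concentrates at 4f₀ under this kernel,
so the frequency axis is rescaled by 1/4.  The windowed (pseudo) form
trades frequency resolution for stability, and zero-padding at the edges
preserves time-shift covariance away from the boundaries.

Each polyspectrum magnitude is summarized by mean, max, normalized
entropy `−Σpᵢln pᵢ / ln K`, and `Σ log(1+|·|)` — four scalars chosen to
capture overall level, peakedness and spectral concentration with a
fixed, documented dimensionality (12 features total).  Recording-level
vectors are the representative-cycle features averaged with weights equal
to the number of cycles each representative covers, which makes the
result invariant to cycle ordering.

## Classification and evaluation

Soft-margin linear SVM (default regularization C = 1.0); the hard-margin
primal is recovered as C grows but fails on non-separable data, so slack
is the default.  Features are z-standardized with parameters fit on the
training split only and stored in the model, making prediction
self-contained.  A decision value of exactly zero is classified +1
(healthy) — an arbitrary but documented and tested tie rule.

Cross-validation uses seeded stratified folds built by per-class
round-robin dealing with the second class offset by k/2 folds; this keeps
both near-equal fold sizes overall (58+58 with k = 8 gives four folds of
15 and four of 14) and 7–8 members of each class per fold.  ROC/AUC are
computed from the pooled out-of-fold decision values by a threshold sweep
over distinct values; tied scores traverse a single ROC segment, making
the trapezoidal area exactly the pairwise concordance probability (ties
counted ½).  +1 (healthy) is the positive class.

## Problem sizes

The synthetic validation cohort is 58 + 58 recordings of 8 s at 4 kHz
(the acquisition-rate 44 kHz path is exercised separately through the
resampler, since the analysis band ends at 100 Hz), segmentation-recovery
checks use 20 recordings, and DTW/AUC oracle equivalence is enumerated on
series of length ≤ 6 and datasets of ≤ 12 points where exhaustive
enumeration is exact.

## Known limitations

* The interval-based S1/S2 rule assumes systole < diastole throughout;
  tachycardic recordings where the two approach equality trigger the
  ambiguity error instead of labeling.
* Loud broadband murmurs overlapping the wavelet passband could insert
  spurious peaks; the pipeline isolates such failures per recording
  rather than correcting them.
* The 0.005 DTW coverage threshold is a convention on normalized,
  length-256 cycles and per-step cost; raw-amplitude or total-cost
  interpretations would need a different threshold.
* Feature summarization of the polyspectra (four scalars each) is a
  design choice of this package; other functionals may discriminate
  differently on real data.
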