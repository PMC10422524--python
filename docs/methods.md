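# Methods

## Signal model

Breathing moves the chest wall approximately sinusoidally,
x(t) = x_max·sin(2π f_resp t + φ₀), with x_max of a few millimetres and
f_resp in the 0.08–1 Hz band (resting adults mostly below 0.4 Hz).  A
continuous-wave radar tone of wavelength λ acquires the two-way phase
modulation 4π x(t)/λ; the corresponding instantaneous Doppler frequency is
f_D(t) = (2/λ)·v(t) with v = dx/dt.  An FCCW radar transmits `n_tones`
(default 32) simultaneous tones spanning bandwidth `BW` (default 60 MHz)
around a carrier (default 1.3 GHz); an inverse DFT across the tones
resolves echoes into range bins of extent ΔR = c/(2·BW).  Multipath
reflections place several echoes of the same person in different bins, each
with its own strength and motion coupling (the projection of chest motion
on the path direction); each bin is analysed as an independent observation.

Assumptions: a single (or no) breathing source per scene; motion amplitude
small enough that the echo stays in its bin; clutter static up to a slow
drift; noise complex, white and Gaussian.

## Detection chain

1. **Decomposition** (`ranging`): unitary inverse DFT across tones
   (1/√N both directions) so per-sample energy is conserved; bins 1..5 are
   kept (bin 0 holds direct leakage; N/2 is the aliasing limit).  Each
   sub-signal is high-pass filtered: 4th-order Butterworth, 0.04 Hz cutoff,
   applied forward–backward (`sosfiltfilt`) for zero phase.  Even
   (mirror) padding with pad length 3·fs/cutoff is used; odd padding would
   inject a step of twice the endpoint value into the extension, and the
   filter's ~25 s settling time would carry that transient deep into a
   one-minute record.
2. **Band spectrum** (`timefreq`): FFT magnitude of the complex series on
   [0.08, 1] Hz; `f_fft` is the band argmax (ties to the lowest
   frequency, matching the tendency of drift residue to capture the band
   edge).  The prominence ratio compares the peak power with the mean
   power of the remaining band points; a noiseless line would divide by
   zero, so the residual is floored at 10⁻¹² of the peak (≈120 dB cap).
3. **CWT ridge** (`timefreq`): complex Morlet (`cmor1.5-1.0`) on a uniform
   grid of 75 frequencies (0.0125 Hz spacing) over [0.08, 1] Hz.
   Coefficients are rescaled to the L1 (amplitude) convention — a unit
   sinusoid responds identically at every analysis frequency — so
   magnitudes are comparable across the band; with L2-type scaling the
   ridge of pure noise piles up at the low end of the band, which
   contradicts how empty-scene measurements behave (their ridge wanders
   broadly, its mean near the band middle).  Per time column, interior
   local maxima are scored by a peak factor PF = topographic prominence /
   column median; the ridge takes the maximum-PF peak, falling back to the
   column maximum when no interior peak exists.  The exact peak-scoring
   rule is a design choice of this package; prominence was chosen over raw
   height to suppress broad noise pedestals.  Cone-of-influence columns
   are retained (a small bias source at the record edges).
4. **Features** (`features`): nine per observation — PR(f_fft) [dB],
   std(f_cwt) [Hz, population divisor N], f_fft, f_cwt_mean, f_cwt_mode
   [Hz], TD_cwt_mean, TD_cwt_mode (fraction of time the ridge stays within
   ±0.05 Hz of its mean/mode; the fixed 0.1 Hz window matches the typical
   ridge spread when breathing is present), and Δf(fft, cwt_mean),
   Δf(fft, cwt_mode) = |a−b|/((a+b)/2) (fractions; a rendering layer may
   multiply by 100).  The ridge mode is taken over the discrete CWT grid
   values with ties to the lower frequency.  All nine features are
   invariant to positive rescaling of the sub-signal.
5. **Selection** (`selection`): one-way ANOVA per feature (F = MSG/MSE with
   dfG = 1, dfE = N₀+N₁−2; score −ln p computed from the log survival
   function so that huge F remains finite and sortable, capped at 745
   where double precision underflows and flagged as infinite).  MRMR uses
   plug-in mutual information in nats: continuous columns are discretized
   into ⌈√n/2⌉ equal-frequency bins (≤16); columns with few distinct
   values are used exactly.  Redundancy averages I(u, z) over the other
   features with the full-set 1/M normalization; ranking is by descending
   MIQ = V/W with stable ties.  The estimator is deterministic and
   documented; absolute MIQ values are estimator-dependent and only the
   ranking should be compared across implementations.
6. **Classifier** (`svm`): soft-margin linear SVM (C = 1, equal class
   costs) on features standardized by the training mean and standard
   deviation, exported in the (μ, σ, β, s, b) score parameterization with
   s = 1; the bundled reference models carry their published s.  The sign
   convention is fixed throughout: f(x) < 0 ⇒ "with person".  A score of
   exactly 0 is classified "without person" with a boundary warning.
   Cross-validation uses seeded random equal-size folds; folds are redrawn
   (with a warning) if a training split loses a class.  The default random
   split places sub-signals of one measurement in different folds — the
   per-measurement grouping is available to callers via the feature
   table's `measurement_id`.

The `LifeDetectionSVM` / `LifeDetectionResults` pair packages steps 5–6 in
a model/results interface: construction from a feature table, `fit()`
returning the fitted hyperplane plus both rankings, and methods for
prediction, evaluation (with per-group false rates, e.g. by 5 dB
prominence-ratio bins or body position) and subset-accuracy curves.

## Scene simulator

`simulate` generates labelled measurements tone-by-tone.  A path at range
bin r contributes amplitude·exp(−j2πir/N)·exp(j(4π/λᵢ)·coupling·x(t)) on
tone i, with per-tone wavelengths λᵢ = c/fᵢ (physically consistent; at
60 MHz/1.3 GHz the per-tone spread is negligible for reporting, where the
carrier λ is used).  Added to this are static clutter per bin, a
random-walk drift low-passed below 0.04 Hz whose level follows each bin's
clutter strength (drift is slow variation of the static reflections, so it
is strongest at near range, where bin 1 carries a boosted direct-leakage
residue), complex white noise, optional raised-cosine transient
disturbances on selected bins (brief body movement), and optional
stationary narrowband interference — a constant-envelope tone with slow
phase noise at 0.5–1 Hz, the signature of machinery or structural
vibration, typically faster than resting breathing.

Default study conditions (`SceneSampler`): slow-time rate fs = 20 Hz
(≥20× the 1 Hz band edge), T = 60 s, f_resp ~ U(0.15, 0.4) Hz with a
fractional slow rate wander of 2–12 % (human breathing is not strictly
constant), x_max ~ U(3, 9) mm, per-bin couplings |c| ∈ [0.4, 1] with a 6 %
chance of a nearly perpendicular path, echo strengths decaying with range,
disturbances in 40 % of scenes and interference in 35 % of empty (12 % of
occupied) scenes.  Noise, drift, interference and disturbance levels were
calibrated once so that the per-class feature moments of a synthetic
ensemble reproduce the reported laboratory feature table (occupied PR
mean ≈ 15 dB vs ≈ 10–12 dB empty; occupied TD_cwt_mode ≈ 0.7 with large
spread; empty ridge mean near the band middle; empty-class Δf near 1) and
the overall classification difficulty sits in the mid-90 % accuracy range
rather than at a synthetic ceiling.  Body positions are sampled at
20/10/10/40/20 % (sitting, right/left lateral, supine, prone) as metadata.

What the simulator does *not* emulate: real rubble electromagnetics
(frequency-dependent attenuation, interface reflections), antenna
patterns, heartbeat or body micro-motion, multiple persons, non-Gaussian
impulsive noise, and any coupling between body position and detectability
(position is metadata only).  Passing synthetic tests therefore
demonstrates the correctness and the qualitative robustness of the chain,
not field performance.

## Test and acceptance problem sizes

The shared synthetic dataset used by the ensemble and classification tests
is 200 + 200 scenes (2000 range observations); parameter recovery uses 50
clean scenes; the ANOVA-vs-t² oracle uses 1000 random small datasets.
These sizes give stable class statistics while keeping the default test
run in the minutes range.

## Known limitations

* The per-time peak factor is this package's own definition; ridge
  statistics (especially of noise-only scenes) depend on it and on the CWT
  normalization, so absolute feature moments differ between
  implementations even on identical data.
* The MI estimator's binning makes MIQ values comparable only within one
  run of this package.
* The bundled reference models carry two-decimal parameters; recomputed
  scores therefore deviate from their published values by up to ~0.1.
* Range-bin index is not calibrated to physical depth (the in-rubble
  propagation speed is unknown by design).
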