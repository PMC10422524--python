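# bioradar

Automatic life detection from ground-penetrating rescue bioradar signals.

After an earthquake, a bioradar lowered onto the rubble can detect a trapped
survivor by the Doppler phase modulation that breathing-induced chest motion
(millimetres, 0.08–1 Hz) imprints on reflected RF waves.  The practical
question for a first responder is binary — *is someone there?* — and must be
answered automatically, robustly against multipath, drift, low SNR and brief
movement artefacts.  This package implements a complete detection chain for
frequency-comb continuous-wave (FCCW) measurements, together with a
physics-based scene simulator so that every stage can be exercised and
validated without laboratory data.

## Method

A measurement is a complex matrix of 32 comb tones (≈60 MHz bandwidth at
1.3 GHz) over one minute of slow time.  The chain is:

1. **Range decomposition** — a unitary inverse DFT across tones splits the
   echo into range bins; each bin's complex slow-time series is treated as
   an independent "virtual scene" observation (bins 1–5 by default), then
   high-pass filtered at 0.04 Hz.
2. **Spectral analysis** — the FFT magnitude spectrum restricted to
   [0.08, 1] Hz yields the peak frequency `f_fft` and its prominence ratio

       PR(f_fft) = 10 log10( X²max / [(Σ|X(k)|² − X²max)/(L−1)] )   [dB],

   and an analytic-Morlet CWT yields the per-time ridge `f_cwt[n]`, the
   frequency of the most prominent spectral peak at each instant.
3. **Nine features** per observation: PR(f_fft), std(f_cwt), f_fft,
   mean/mode of f_cwt, the normalized durations TD_cwt_mean/TD_cwt_mode the
   ridge spends within ±0.05 Hz of its mean/mode, and the normalized
   disagreements Δf(fft, cwt_mean), Δf(fft, cwt_mode) with
   Δf(a, b) = |a − b| / ((a + b)/2).
4. **Feature selection** — one-way ANOVA (score −ln p of the upper-tail F
   probability) and minimum-redundancy-maximum-relevance
   (MIQ = I(u; y) / mean I(u; z)) rank the features; cross-validated
   accuracy of growing subsets selects a compact set.
5. **Classification** — a linear SVM with equal misclassification costs.
   With training moments μ, σ, weights β, kernel scale s and bias b the
   score of an observation x is

       f(x) = ((x − μ)/σ) · β / s + b,     f(x) < 0 ⇒ "with person".

A bundled pre-trained model (`reference_model(dim)` for 2, 3 or 4 features,
trained on a 2165-observation laboratory dataset) ships with the package.

## Worked example

```python
import bioradar as br

# score a known feature row with the bundled 4-feature model
model = br.reference_model(4)
x = {"PR_ffft_db": 17.83, "f_cwt_mean_hz": 0.34,
     "TD_cwt_mode": 0.70, "dF_fft_cwt_mean": 0.11}
print("f(x) =", round(br.lsvm_score(model, x), 3))   # f(x) = -3.51
print(br.lsvm_predict(model, x)[0])                  # with_person

# simulate a labelled dataset, extract features, fit and inspect
measurements, manifest = br.generate_dataset(n_with=30, n_without=30, seed=7)
table = br.feature_table(measurements)
results = br.LifeDetectionSVM.from_dataframe(table).fit(seed=7)
print(results.summary())
```

The summary printed by the last line:

```
Life-detection linear SVM
============================================================
observations: 300   features (model): 4
C = 1.0   kernel scale s = 1   bias b = -0.03071

hyperplane (standardized features):
  PR_ffft_db         mu=  13.0926  sigma=  4.3479  beta=  0.1516
  f_cwt_mean_hz      mu=   0.3684  sigma=  0.1301  beta=  0.7184
  TD_cwt_mode        mu=   0.6213  sigma=  0.3363  beta= -1.4624
  dF_fft_cwt_mean    mu=   0.6220  sigma=  0.5967  beta=  0.4732

feature rankings (1 = most significant):
  ANOVA: TD_cwt_mean, std_fcwt_hz, TD_cwt_mode, dF_fft_cwt_mean, ...
  MRMR:  TD_cwt_mean, TD_cwt_mode, std_fcwt_hz, dF_fft_cwt_mean, ...

training-set ACC=0.937  FNR=0.073  FPR=0.053  (TP=139 FP=8 TN=142 FN=11)
decision rule: f(x) < 0 => "with person"
```

The score −3.51 is well below the f(x) = 0 decision boundary, a confident
positive detection.  On the synthetic data, 60 one-minute scenes give 300
range observations; the fitted hyperplane classifies them with 93.7 %
training accuracy, and the duration/spread features of the CWT ridge
dominate both rankings.

A command-line pipeline wraps the same library:

```bash
bioradar simulate --n-with 50 --n-without 50 --seed 1 --out data/
bioradar extract --in data/ --out features.csv
bioradar rank --features features.csv
bioradar train --features features.csv --dims 4 --out model.json
bioradar predict --model model.json --features features.csv --out pred.csv
bioradar run --n-with 60 --n-without 60 --seed 7 --out artifacts/   # everything
```

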