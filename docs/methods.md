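# Methods

`hrvrisk` implements a complete short-term (5-minute) heart-rate-variability
(HRV) analysis chain for two-class cardiovascular-risk prognosis: ECG beat
detection, ectopic-interval removal, four families of HRV features,
distribution-free feature selection, and three classifier schemes. This note
records the models, the parameter choices that matter, the numerical
conventions, and what the synthetic validation does and does not establish.

## Signal model and preprocessing

**R-peak detection.** The detector is Pan-Tompkins fed by a wavelet detail
pre-filter: the ECG is decomposed with the Haar wavelet to level *L*
(default 4), the approximation is discarded, and the trace is rebuilt from
detail levels 1..*L* only. This removes baseline drift while keeping the QRS
band; at low *L* only the top octave survives, which at ordinary sampling
rates (e.g. 250 Hz) removes most QRS energy too — the level sweep exposed by
`detect_r_peaks(level=...)` exists to study exactly this trade-off. The
Pan-Tompkins chain is zero-phase throughout (forward-backward 5–15 Hz
band-pass, centred derivative, squaring, 150 ms centred moving-window
integration) so fiducials stay time-aligned; an adaptive dual threshold with
a 200 ms refractory period and RR-gap search-back accepts beats, and each
fiducial is refined to the raw-signal maximum within ±50 ms. Beat scoring
uses greedy one-to-one matching within ±50 ms: Se = TP/(TP+FN),
Ac = TP/(TP+FN+FP), both in percent.

**Ectopic removal.** NN intervals are screened with the generalized extreme
studentized deviate (Rosner) procedure: up to `k_max` candidates (default
⌈0.05·N⌉) are peeled off by the Grubbs statistic R = max|x−x̄|/s (sample-sd
convention), each compared to its t-distribution critical value at
`alpha = 0.05`; the declared outlier count is the largest iteration whose
statistic exceeds its critical value. Removed intervals are dropped, never
interpolated — interpolation would fabricate beat-to-beat structure that the
entropy and Poincaré measures are designed to detect.

## Feature families

**Time domain (7).** meanNN, SDNN, RMSSD, pNN50, MIRR (interquartile range),
MDARR (median |ΔNN|), SDSD. pNN50 counts successive differences *strictly*
greater than 50 ms, normalized by the N−1 differences (the Task-Force
convention); quartiles use linear interpolation; SDNN/SDSD use the sample
(n−1) convention. All are in ms except the dimensionless pNN50.

**Frequency domain (6).** The tachogram is cubic-spline resampled at 4 Hz,
detrended by smoothness priors (trend = (I + λ²D₂ᵀD₂)⁻¹z with the
second-difference operator D₂, λ = 500 — the customary value in the HRV
software literature, passing the entire LF band essentially intact), and
modelled as AR(16) by the covariance (least-squares) method. The spectrum
σ²/f_s/|1+Σaₖe^(−i2πfk/f_s)|² is evaluated on 1024 points and integrated by
trapezoid over VLF [0, 0.04), LF [0.04, 0.15), HF [0.15, 0.4] Hz (half-open
partition so band powers are additive). NLF = 100·LF/(LF+HF), NHF its
complement, LF/HF the sympathovagal-balance ratio (missing when HF = 0).
Parametric estimation is preferred over the periodogram because 5-minute
records are short; the periodogram appears only as a test oracle.

**Multi-resolution (124).** Full wavelet-packet tree of the mean-subtracted,
un-resampled NN series (beat-index domain): Daubechies-4, periodization,
level 5 → 62 nodes over levels 1–5. Each node emits its mean squared
coefficient (energy) and the Shannon entropy of its normalized squared
coefficients (natural log, 0·ln 0 ≡ 0). Periodization keeps the transform
orthogonal, so every full level carries the exact signal energy — the basis
of the conservation tests. PCA (covariance eigendecomposition, deterministic
sign convention: the largest-magnitude loading of each component is made
positive) is available to reduce this redundant block; both the raw node
features and PC projections can feed selection.

**Nonlinear (13).** Poincaré map (xₙ, xₙ₊₁) rotated by π/4:
SD1 = population sd across the identity line, SD2 = along it, giving the
exact identities SD1² = SDSD²_pop/2, SD2² = 2·SDNN²_pop − SDSD²_pop/2 used
as tests. Histogram widths (NN, width, length) are ranges rounded up to
whole bins of 7.8125 ms (1/128 s, the conventional HRV bin); `bin_ms = 0`
disables binning. ApEn (self-matches included) and SmEn (excluded) use
Chebyshev distance with m = 1..4 and tolerance r = k·SD, default k = 0.2
(upper end of the recommended 0.1–0.2 range; better match-count stability on
~400-beat series). SmEn is reported missing (NaN) when no template pairs
match — the correct behaviour for short records at large m rather than an
infinite value.

## Selection and classification

Features are screened per family-ordered column with the two-sample KS test
(D = sup|ECDF difference|, asymptotic p at effective size n_a·n_b/(n_a+n_b);
45 per group is well inside the asymptotic regime — measured type-I rate
≈ 0.04–0.05 at α = 0.05). Two levels: α = 0.05 marks significance,
α = 0.01 admits a feature to the classifier pool; the top-k (default 5) by
ascending p are selected, ties broken by column order. No multiple-testing
correction is applied by default, matching common practice in this
literature; the chi-square/KS normality screen documents why
distribution-free testing is used at all.

MinMax normalization is fitted on the training split only and applied
unchanged to the test split (test values may leave [0, 1]); fitting on all
data before splitting leaks test information, so the leak-free protocol is
the default.

Three schemes, all with risk = positive class and threshold 0.5:

* **MLP** (5-200-1): tanh hidden layer, logistic output, trained by
  Levenberg-Marquardt on squared error. The LM step is solved in the sample
  dimension via (JᵀJ+λI)⁻¹Jᵀe = Jᵀ(JJᵀ+λI)⁻¹e, which makes 1400-parameter
  networks on 60-record training sets cheap. Validation-based early stopping
  (stop after 6 consecutive validation-error rises) is available via
  `val_fraction` but defaults off: on cohorts this small a hidden validation
  split costs more in variance than it saves in overfitting, and training on
  the full split keeps the capacity behaviour and determinism transparent.
* **RBF network** (5-3-1): k-means centers (scikit-learn, seeded), Gaussian
  width of each center = distance to its nearest other center (its influence
  radius), linear readout by least squares.
* **SVM**: soft-margin SVC with linear, polynomial or RBF kernel. The linear
  machine uses C = 1; for the kernel machines a small grid
  (C ∈ {0.1, 1, 10, 100} × degree ∈ {2, 3} or γ ∈ {0.01, 0.1, 1}) is scored
  by seeded 3-fold CV on the training split. Support-vector counts are
  reported.

Evaluation: stratified 2/3–1/3 split (a 45+45 cohort gives 30+30 train,
15+15 test), confusion matrix, Se/Sp/Pp/Np/Ac in percent, ROC by threshold
sweep and trapezoid AUC (equal to the Mann-Whitney U statistic normalized by
n₊·n₋). `repeats > 1` re-splits with derived seeds and reports one result
per repeat.

## Synthetic cohort

`generate_rr` samples RRₙ = base + A_LF·sin(2πf_LF·tₙ) +
A_HF·sin(2πf_HF·tₙ+φ) + ε at the cumulative beat times (a point-process
sampling of the modulations), clipped to [300, 2000] ms. Defaults: 300 s
records, base 800 ms (75 bpm), A_LF = 30 ms at 0.1 Hz, A_HF = 20 ms at
0.2 Hz (respiratory sinus arrhythmia at 12 breaths/min), ε ~ N(0, 10 ms) —
giving a normal-class SDNN near 27 ms, comfortably physiological. The risk
class multiplies all three variability sources by `risk_scaling`
(default 0.5), the reduced-variability phenotype that dominates clinical
risk signatures; an `erratic` mode instead inflates noise and injects
ectopic-like spikes to exercise the outlier filter. `generate_ecg` renders a
series as a sum-of-Gaussians PQRST template at the beat times, returning the
exact R-apex sample indices, plus optional noise, 0.3 Hz baseline wander and
a sinusoidal respiration channel.

What this generator does *not* emulate: real QRS morphology and its
between-subject variation, nonstationary autonomic tone, true ectopy
physiology, measurement artefact structure, or overlap between clinical
classes. The default two-class effect (variability halved) is deliberately
strong, so near-perfect classification accuracies on synthetic cohorts
demonstrate that the pipeline *recovers a planted effect*, not that clinical
discrimination of this quality is attainable. The null cohort (identical
class parameters) provides the complementary control: selection at the
chance rate and test accuracy near 50%.

## Validation design and problem sizes

Every numerical primitive is tested against an independent oracle: ApEn/SmEn
against direct template counting, the KS statistic against a pooled-ECDF
scan, AUC against the rank-statistic identity, SD1/SD2 against their
closed forms, AR band power against the variance of white noise, and
wavelet energies against per-level conservation. The end-to-end checks use
the default cohort conditions (45+45 records, 300 s, risk_scaling 0.5) over
ten seeds; the R-peak round trip uses 120 s records at 250 Hz over ten
seeds, sizes chosen to keep the whole suite under a minute of feature
extraction per cohort while preserving the stated study conditions.

## Known limitations

* The asymptotic KS p-value is slightly conservative below ~20 samples per
  group; exact small-sample p-values are out of scope.
* The breathing-rate check (dominant respiration frequency in
  [0.05, 0.7] Hz; valid iff within 12 ± 3 breaths/min and stable to
  2 breaths/min across 60 s windows) flags records as advisory-only — it
  never drops them, since invalidity is a protocol judgement, not a data
  error.
* The AR covariance method can be ill-conditioned on pathologically short
  or constant tachograms; this raises a conditioning error naming the record
  rather than returning garbage.
* No vendor binary formats (PowerLab native), WFDB/EDF readers, long-term
  (24 h) indexes, DFA/Lyapunov measures, or GUI.
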