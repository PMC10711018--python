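# Methods

`spirodesat` re-implements, as a tested pipeline, an intraoperative-
spirometry analysis for predicting immediate postoperative desaturation
(SpO₂ < 95% in the post-anesthesia care unit despite a facial oxygen
mask) in patients undergoing laparoscopic or robot-assisted lower
abdominal surgery.  Because no patient-level dataset is public, the
package ships a synthetic cohort generator that reproduces the signal
structure and group-level effect directions the method assumes; every
downstream stage is validated on that generator plus independent
brute-force references.

## Signals and the position problem

Three ventilator channels are analyzed at 15 Hz: peak inspiratory
pressure (PIP, one plateau value held per breath), airway pressure (AWP,
continuous across inspiration and expiration) and lung volume (VOL).
Pneumoperitoneum plus the steep Trendelenburg position markedly raises
PIP, so the patient's position can be segmented from the PIP channel
alone.

### Segmentation rule base

The PIP channel is Gaussian-smoothed with σ = 60 s × f_s (= 900 samples
at 15 Hz; kernel truncated at 4σ, reflect padding) and then min-max
scaled to [0, 1] — smoothing before scaling, in that order.  Four rules
locate the two sections on the smoothed, normalized series:

* **Supine start** — first sample ≥ 0.3 whose successive per-sample
  differences stay ≤ 0.1 for the next 5 minutes.  "Successive
  difference" is read as the first difference of the smoothed normalized
  series, the only series available at this stage.
* **Supine end** — first later sample exceeding 0.7.  A single crossing
  suffices; the sustained check belongs to the next rule, and a second
  debounce would double-count.
* **Trendelenburg start** — first sample opening a run that stays ≥ 0.7
  for 5 minutes.
* **Trendelenburg end** — first pair of two *adjacent* samples below
  0.5 after the start (record end if none).  The alternative reading —
  two successive decreases crossing 0.5 — was considered and rejected in
  favour of the literal adjacent-samples reading.

Only the centred 80% of each section is analyzed further: a section of
L samples keeps ⌊0.8 L⌋ samples with ⌈(L − ⌊0.8 L⌋)/2⌉ dropped from the
head.  The trim is applied to *both* sections.  All rule scans are O(n)
(cumulative-sum sliding windows), since records are hours of 15 Hz data.

Because the smoothing kernel is 60 s wide, detected boundaries shift by
up to roughly 2σ; the boundary-recovery tests therefore use a 120 s
tolerance, which noise-free synthetic cases meet with a wide margin.

## Windowing

Each trimmed section is divided into 20 windows of 2000 samples
(≈ 133.3 s).  The stride follows
`(section length − window size) / number of windows`, floored per start
index so that exactly 20 full windows exist for any section of at least
2000 samples (a 2000-sample section yields 20 identical windows).
Sections longer than 400,000 samples instead spread the windows
maximally, `(L − w)/(n − 1)`, so the last window ends at the section
end.  Every per-window statistic is averaged across the 20 windows;
windows where a statistic is undefined are excluded from the average
rather than zero-filled, to avoid biasing means.

## The 176-feature registry

Four families, in fixed order:

1. **Demographics (4)** — sex, age, weight, height.
2. **Signal properties (44)** — per channel × position (6 combinations):
   mean, median, SD, skewness, excess kurtosis, and two outlier
   statistics — the per-window *count* of samples with |z| > 3 (z
   against the window's own mean/SD) and the count outside the 1.5×IQR
   fences — plus the two section lengths in samples.  Skewness and
   kurtosis are defined as 0 for zero-variance windows.  The exact
   composition of this family is a committed reconstruction: it
   reproduces the documented family total and every individually named
   feature, but individual definitions beyond the named ones are this
   package's choices.
3. **Correlations (20)** — five metrics (Pearson, Spearman, Kendall
   tau-b, band-averaged magnitude-squared coherence, path-normalized
   DTW) on (a) AWP vs VOL window pairs within each position and (b)
   Supine window *i* vs Trendelenburg window *i* for AWP and VOL.
   PIP carries no correlation or peak features: it is a per-breath
   plateau, not a periodic waveform.  Zero-variance windows map the
   three correlation coefficients to 0 by convention; coherence and DTW
   remain defined.
4. **Peak variability (108)** — HRV-style statistics transplanted to
   breath timescales, per AWP/VOL × position (4 combinations), 27 each:
   16 on the peak-interval series (mean, median, SDNN-analog,
   RMSSD-analog, SDSD, CV, min, max, range, NNxx count and proportion
   with the 50 ms HRV constant rescaled to 0.5 s, and total/LF/HF
   spectral power with LF/HF and normalized LF) and 11 on the
   peak-value series (the same time-domain block with a 0.5-unit
   successive-difference threshold).  Intervals are measured in samples;
   spectral bands are physical (LF 0.01–0.05 Hz, HF 0.05–0.5 Hz) on the
   interval tachogram resampled to a uniform 4 Hz grid.  SDNN/SD use
   ddof = 1.  Windows with fewer than 3 detected peaks are treated as
   missing; a combination with no usable window at all is an error.

Peak detection uses local maxima with a 2 s minimum separation and a
prominence floor of 10% of the window's amplitude range — enough to
suppress noise ripples while keeping every breath peak of the simulated
morphology.

DTW uses the classic symmetric step pattern with absolute-difference
local cost, normalized by the optimal warping path's length;
predecessor ties prefer the diagonal, then the vertical step, making the
path length deterministic.  The kernel is numba-compiled;  the test
suite checks it against a pure-Python full-table reference to 1e−9.
Coherence is Welch-estimated (Hann, 256-sample segments, 50% overlap)
and averaged over the 0.05–1 Hz respiratory band.

## Selection and classifiers

Cases are split into training and held-out sets stratified by label
(fraction 42/207), with 5-fold stratified CV on the training rows.  All
selection statistics and scaling constants are computed on training rows
only; the `FeatureMatrix` records any read of test rows so the suite can
assert the absence of leakage.

* **Filter methods** — chi-square (on training-min-max-scaled features),
  ANOVA F, and mutual information; top-k with k = 10 by default.
* **Wrapper methods** — sequential floating forward/backward selection
  (SFFS/SBFS) scored by mean CV AUROC of a configurable estimator, with
  conditional exclusion/inclusion steps accepted only when they improve
  the best score recorded for that subset size; candidate ties break by
  registry order.  On small toys SFFS is verified to match exhaustive
  subset enumeration.

Five classifiers are compared: random forest, XGBoost, LightGBM, KNN
(K = 5) and RBF-SVM, the latter two behind an in-fold standardizer.
Hyperparameters are committed defaults chosen to limit overfitting
(shallow trees, a few hundred estimators); they are exposed through
`make_model` overrides.  The winner is the model with the highest mean
CV AUROC.  The default pipeline scores the wrapper search with the KNN
model, which makes a full 176-feature floating search affordable on one
CPU; any of the five models can be configured instead.

## The Desaturation Prediction Index

The wrapper's selected set is reduced by a LASSO linear fit on
standardized training features, with the penalty chosen by 5-fold CV
under the one-standard-error rule (the sparser choice within one SE of
the CV optimum; if it zeroes everything on a very small cohort the CV
optimum is used instead).  Coefficients below 1e−10 in magnitude count
as zero, since coordinate descent leaves O(eps) residues on dropped
collinear features.  The survivors enter an ordinary-least-squares
regression of the 0/1 label on the *raw* feature values — a linear
probability model, so the index

DPI = c₀ + Σⱼ cⱼ·Fⱼ

can be evaluated at the bedside without standardization constants.  The
intercept is retained internally and reported separately.  Diagnostics:
AUROC in tie-corrected rank (Mann–Whitney) form, a seeded percentile
bootstrap 95% CI (2000 resamples by default; the CI construction method
is a package choice), a one-sided permutation test of AUROC > 0.5, and
an accuracy/sensitivity/specificity/PPV table over thresholds 0.0–1.0
in steps of 0.1 (positive call at score ≥ threshold; empty denominators
reported as missing).

Group comparisons are gated on normality: Shapiro–Wilk per group at the
stringent α = 0.01 (small samples over-reject normality), then Student's
independent t-test if both groups pass, otherwise a two-sided
Mann–Whitney U.  The pipeline emits this table both for train-vs-test
distribution checks and for normal-vs-desaturation comparisons of the
selected features.

## Synthetic cohort generator

The generator is first-class, tested code, not a fixture.  Each case
concatenates five phases — pre-incision noise, Supine ventilation,
a 60 s linear transition ramp, Trendelenburg/pneumoperitoneum, and a
post phase — with defaults of 120 / 900 / 60 / 1200 / 120 s.  (Real
surgeries last ≥ 1.5 h; the committed desk-scale durations satisfy every
rule constraint — both analyzed phases ≥ 600 s — while keeping a
207-case cohort tractable.)  Breath morphology is a raised-cosine AWP
rise to the breath's PIP with a short plateau and exponential decay to
PEEP, and a raised-cosine VOL inflation hitting the tidal volume exactly
at end-inspiration (giving the peak detector unambiguous maxima)
followed by exponential deflation.  The PIP channel holds each breath's
peak value constant across the breath.  Gaussian noise is added per
channel; AWP/VOL are clipped at zero.

A single latent severity s ~ N(0, 1) couples the planted effects:

| quantity | value at severity s | group defaults (s = ∓1) |
|---|---|---|
| Supine PIP level (cmH₂O) | 15.2 + 0.5 s | 14.7 / 15.7 |
| Trendelenburg multiplier | 1.955 + 0.155 s | 1.80 / 2.11 |
| tidal amplitude (mL) | 666 + 44.5 s | ≈ Supine VOL median 119 / 136 |
| breath-period jitter SD (s) | 1.75 + 0.35 s | 1.4 / 2.1 |

These constants were calibrated once so that group-typical profiles
reproduce the clinically reported feature levels and directions —
higher Supine mean PIP, higher Supine median VOL and higher
Trendelenburg mean AWP (≈ 10.8 vs 12.6 cmH₂O with PEEP 5) in the
desaturation group.  The label is drawn from a logistic model on s
(slope 1.5, intercept −0.83, fixed numerically so the population
prevalence is ≈ 36%, i.e. 74 desaturation cases in 207).  Cohort
construction screens cheap (profile, label) draws until both label
buckets are filled, then synthesizes signals only for accepted cases, so
requested group counts are exact while the feature–label association
stays stochastic.

The normalized-PIP geometry is guaranteed by construction: with a
pre-incision baseline of 2 cmH₂O, the smoothed normalized Supine plateau
falls in [0.3, 0.7) and the Trendelenburg plateau at 1.0, so every
generated case satisfies the rule base; profile validation rejects
parameter combinations that would not.

**What the generator does not emulate:** real waveform morphology
(no public raw-signal reference exists, so the breath shapes are
documented stand-ins), ventilator pressure-limit behaviour, SpO₂
dynamics, measurement dropouts, and any demographics–outcome
association (demographics are drawn independently of severity).
Passing tests therefore demonstrate that the machinery recovers planted
structure of this kind — not that the clinical effect sizes or the
published AUROCs (which require the real cohort) are reproduced.

## Numerical and scale choices

* Fractional window strides floor per start index; deterministic.
* Constant windows: skewness/kurtosis 0, outlier counts 0, rank
  correlations 0.
* AUROC rank form is tie-corrected; it matches trapezoidal ROC
  integration to 1e−12.
* One pipeline seed fans out (via `SeedSequence.spawn`) to cohort
  screening, per-case signal synthesis, the train/test split, CV folds,
  model seeds and bootstrap/permutation draws; reruns with the same
  configuration are byte-identical, and artifact files embed the seed
  plus a configuration hash.
* Problem sizes used by the validation suite: boundary recovery over 25
  noise-free cases; planted-index recovery over 50 replicates of a
  400-case feature-level design (5 informative + 5 noise features,
  logistic link, slope 2.0); byte-identity of reruns demonstrated on a
  22-case cohort with 640 s analyzed phases in addition to a single
  full 207-case run.

## Known limitations

* The composition of the 44- and 108-feature families beyond the
  individually documented features is a reconstruction; alternative
  layouts with the same totals exist.
* The per-window |z| > 3 outlier count is bounded by the window length,
  so its absolute scale is not comparable to implementations that sum
  (rather than average) across windows.
* Interval statistics are reported in samples; multiply by 1/f_s for
  seconds.
* SFFS is a heuristic; optimality is verified only on small instances.
* The linear probability model can produce DPI values outside [0, 1];
  the threshold grid nevertheless spans 0–1 by convention.
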