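# Methods

`sleepsci` turns staged overnight polysomnography into a fixed vector of
sleep-EEG features and fits cross-validated Elastic-Net indices of
cognitive performance on top of it. This note documents the models and
procedures, the parameters that matter, what the synthetic-data generator
does and does not emulate, and the numerical choices made where the design
was genuinely open.

## Signal pipeline

**Analysis form.** All EEG is brought to 200 Hz (polyphase resampling with
anti-alias filtering; recordings below 100 Hz are rejected because the
sigma band would sit too close to Nyquist) and band-pass filtered
0.1–20 Hz. Epochs are 30 s, subdivided into fifteen 2-s subepochs; epoch k
spans samples [k·30·fs, (k+1)·30·fs), 0-based, aligned to the hypnogram.

**Zero-phase filtering.** Every "zero-phase band-pass" in the pipeline
applies the *squared magnitude response* of a 4th-order Butterworth filter
in the frequency domain, after odd-reflection padding (3/f_low seconds per
side). This realizes exactly the amplitude response of a forward-backward
recursive pass, but is symmetric under time reversal to machine precision
and has no start-up transients. A recursive forward-backward
implementation was rejected on numerical grounds: with a 0.1-Hz corner at
fs = 200 the filter's poles sit at |p| ≈ 0.9988 and round-off breaks time
symmetry at the 10⁻² level, which contaminates sub-hertz event morphology.

**Artifact mask.** A deliberately simple stand-in for production artifact
removal: an epoch/channel is excluded when any |sample| exceeds
`amp_thresh_uv` (default 500 µV) or the signal is flat longer than
`flat_sec` (default 5 s). Masked epochs never enter any feature average.
Both thresholds are config keys.

**ECG correction (optional).** The ECG trace is zero-phase filtered
0.3–40 Hz; R peaks are detected as excursions more than 4 scaled-MAD above
the median, at least 0.3 s apart. The QRS-locked average waveform (±0.2 s)
is subtracted from each EEG channel at every beat. The template is only
subtracted when it exceeds three times its own averaging noise floor
(channel SD / √beats), so uncontaminated channels pass through bit-exact.
If no physiologically plausible beat sequence is found (< 20 bpm
equivalent), the recording is returned unchanged with a warning.

## Feature set

The per-night feature vector concatenates, in fixed order:

1. **Macrostructure (10).** TST, WASO, SE = TST/TTB, TTB, sleep latency,
   REM latency, and %TST in N1/N2/N3/R, computed by epoch counting within
   the lights-off/lights-on interval (0.5 min per epoch). REM latency is
   measured from lights-off by default (a config flag switches to the
   sleep-onset convention). A night with no sleep reports TST = 0, SE = 0
   and missing latencies; a night with no REM reports missing REM latency
   and %R — missingness is an expected state, imputed at the cohort level.
   SE is defined as TST over time in bed, the standard convention.

2. **Spindle / coupling / slow-oscillation block (42).** 21 features per
   central channel (see detectors below): spindle AMP, DENS, DUR, FFT,
   FWHM, NOSC, SYMM2; coupling COUPL_ANGLE, COUPL_MAG, COUPL_OVERLAP,
   COUPL_PV; SO count, SO_AMP, SO_DUR, SO_NEG_DUR, SO_POS_DUR, SO_RATE and
   the four phase slopes. This block always comes from the central
   channels, also in the all-electrode and ablation sets.

3. **Waveform + frequency block (160 per region).** Per stage (W, N1, N2,
   N3, R): line length (mean |successive difference|) and Pearson kurtosis
   per channel (2 × 5 × 2 = 20); relative delta/theta/alpha power and the
   delta/theta, delta/alpha, theta/alpha absolute-power ratios, each
   summarized as {p95, min, mean, sd} across the 15 subepochs of an epoch
   and then averaged over the stage's clean epochs (60 + 60); and the
   Pearson kurtosis of the pooled per-subepoch absolute band-power series
   for delta/theta/alpha/sigma ("spectrogram kurtosis", 20). Waveform
   features are per channel while frequency features average the region's
   two channels — the only split consistent with 160 features per region.

Totals: 212 for a single region plus the central event block, 532 with
all three regions. Electrode sets: `central`, `frontal`, `occipital`
(212 each) and `all` (532).

**Spectral estimation.** Hann-tapered periodograms per 2-s subepoch;
band power is the PSD sum over half-open bins [lo, hi); bands are delta
0.5–4, theta 4–8, alpha 8–12, sigma 11–15 Hz. Relative power is normalized
by total power in 0.5–20 Hz, matching the analysis band (for a flat
spectrum the relative delta power is 3.5/19.5 ≈ 0.179, which the tests
check). Kurtosis is the Pearson convention m₄/m₂² (normal → 3); since
kurtosis is scale-invariant the raw/standardized choice is immaterial.
The subepoch sd uses ddof = 1; p95 uses linear interpolation between order
statistics. All relative powers, ratios and kurtoses are invariant under
amplitude scaling of the recording; line length scales linearly (tested
exactly with a factor of 2, which is lossless in binary floating point).

## Event detectors

Both detectors operate on artifact-free N2/N3 samples and use only
data-relative thresholds, so they are amplitude-scale invariant.

**Slow oscillations.** Band-pass 0.2–4.5 Hz; candidates are intervals
between consecutive positive-to-negative zero-crossings lasting 0.8–2 s
with a negative-then-positive phase geometry. Candidates whose
negative-peak magnitude and peak-to-peak amplitude *strictly* exceed the
respective medians over all duration-qualified candidates become events.
The strict inequality means a perfectly homogeneous candidate pool yields
nothing — the rule finds what stands out from its own night. Morphology:
the four slopes connect zero-crossings to the adjacent extrema
(negative-going slopes are negative by construction). A 3-Hz rhythm can
never qualify (cycle length 1/3 s).

**Spindles.** The production reference for spindle scoring is an external
package; this detector is a transparent envelope-threshold method whose
contract is the per-night feature vector, not event-for-event equality
with any reference. Band-pass 11–15 Hz, analytic-signal magnitude smoothed
with a 0.1-s moving average; events are runs above mean + k·sd (k = 1.5)
of the N2/N3 envelope, gaps under 0.25 s merged, durations confined to
0.5–3 s (short runs dropped, long runs truncated around the envelope
peak). Per event: amplitude = max peak-to-peak of the band-passed segment;
mean frequency = (n_zc − 1)/(2·span) over the zero-crossing span, the
unbiased zero-crossing rate (the naive count-over-duration form is biased
by partial edge periods); FWHM of the envelope; NOSC = ⌊n_zc/2⌋; and
SYMM2 = 2·|peak position fraction − ½| ∈ [0, 1], the folded symmetry of
the envelope peak. Because the threshold trims an event's quiet flanks,
NOSC tracks frequency × detected duration, not the full underlying burst.
k, smoothing, merge gap and duration bounds are config keys.

**Coupling.** SO phase is the analytic phase of the 0.2–4.5 Hz filtered
signal. A spindle overlaps an SO when its envelope peak falls inside the
SO's zero-crossing span. Over the n overlapping spindles with phases φ_k:
COUPL_ANGLE = arg Σe^{iφ}, COUPL_MAG = |Σe^{iφ}|/n (the intra-trial phase
clustering magnitude), COUPL_OVERLAP = n, COUPL_PV = exp(−nR²), the
asymptotic Rayleigh p-value without small-sample correction. Under a von
Mises(μ, κ) phase law the ITPC converges to I₁(κ)/I₀(κ); the tests check
κ = 2 against the Bessel ratio and p-value uniformity under the uniform
null.

## Cohort modelling

**Imputation.** Missing-stage features are filled by K nearest neighbours
(K = 10): distances are root-mean-square differences over mutually
observed, z-scored features (count-normalized so pairs with few shared
features are not favoured), and a missing value becomes the mean of the
feature over the K nearest donors that observed it. Inside
cross-validation the imputer is fitted on the training fold only and test
rows are imputed from training donors.

**Index models.** For each target (a cognitive score, or chronological age
for the brain-age comparator) a nested ten-fold cross-validated Elastic
Net: the outer folds are a seeded random partition (150 subjects → folds
of 15, training sets of 135); within each outer training set an inner
ten-fold CV picks the penalty strength and L1 mixing weight by mean
squared error over a glmnet-style grid (mixing ∈ {0.1, 0.5, 0.7, 0.9,
0.95, 1.0}; 50 log-spaced penalties spanning four decades below the
data-derived maximum). Features are z-scored with outer-training-fold
statistics before the inner search; re-standardizing inside every inner
fold would cost roughly an order of magnitude more compute for a
negligible change, and the held-out fold is untouched either way. The
selected pair is refit on the full outer training set and predicts the
held-out fold, so every subject receives exactly one held-out prediction;
reported r and MAE use those predictions only. The intercept is fitted and
the target left in its natural units, so a score is directly
interpretable: intercept + coefficients · z(features). A deployable model
refits on all subjects with the hyperparameters most often selected across
folds.

**Brain-age comparator.** The same protocol restricted to the waveform +
frequency domains (160 central columns), predicting age; the index is
held-out predicted age minus chronological age, near zero on average by
construction.

**Evaluation battery.** Pearson r with t-distribution p; Fisher r-to-z
comparison of two correlations using the independent-samples form
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)) — the standard
two-correlation comparison even when the indices share subjects, where it
is conservative about dependence; a dependent-correlation variant is out
of scope. Tertile discriminability: a rank-based low/medium/high split
(remainder distributed low→high, ties stable), Cuzick's trend test with
mid-ranks and tie-corrected variance (for two groups it reduces exactly to
the normal-approximation Wilcoxon rank-sum), and the low-vs-high AUC in
the Mann–Whitney form with the medium tertile excluded. Goodness of fit of
an EEG-only submodel against a full model adding age, education and sex
uses a Gaussian likelihood-ratio test: deviance = n·log(RSS_sub/RSS_full),
χ² with 3 df. Applying a χ² LRT to penalized fits is statistically
heterodox — penalization breaks exact nesting — so the deviance is floored
at zero with a warning when the richer model fits worse; calibration under
the null is verified by simulation with unpenalized refits. No
multiple-comparison correction is applied anywhere, by design: the battery
estimates effect sizes per target.

## Synthetic polysomnography

The generator exists so that every stage of the pipeline can be validated
against known ground truth; its defaults are the package's study
conditions and were fixed once, before the test suite was frozen.

**Hypnogram.** First-order Markov chain over {W, N1, N2, N3, R} at 30-s
resolution. The default transition matrix has stationary proportions of
roughly 14% W, 9% N1, 46% N2, 15% N3, 16% R — of sleep time: 10/53/18/19%
for N1/N2/N3/R, a plausible middle-aged clinical night — and mixes fast
enough that a 10,000-epoch chain matches the eigenvector distribution
within ±3%.

**Background EEG.** Gaussian noise shaped to 1/f^α per stage (α from 1.0
in wake to 1.7 in N3) with multiplicative band boosts (alpha in wake,
theta in N1/N2/REM, 1.5–4 Hz delta in N2/N3), scaled to stage-specific RMS
(15–25 µV). Power below 1.5 Hz is deliberately rolled off: in this
generator the sub-hertz content of deep sleep comes from discrete injected
events, which keeps the SO detector's data-relative thresholds
interpretable against the injection list. Two channels per region share a
common source (correlation 0.8 by default). Per-epoch segments are
overlap-added with complementary sin/cos power ramps (0.5 s) so stage
transitions are continuous — hard joins would masquerade as
slow-oscillation-sized swings after 0.2-Hz high-pass filtering.

**Events.** Counts are deterministic — round(density × stage minutes) —
and spread evenly over the stage's epochs; no event crosses an epoch
boundary, and the injection list *is* the ground truth. Spindles are
Hann-windowed sinusoids (frequency ~N(13.5, 0.6) Hz clipped to
11.5–14.5, duration U(0.9, 1.5) s, peak amplitude ~N(34, 4) µV, floor 25)
at 2.5/min of N2 and 1/min of N3; the amplitude floor keeps every injected
event at envelope SNR ≥ 3, the regime the detector benchmark addresses —
weaker spindles fragment under any 0.1-s envelope and are not scoreable
events. Slow oscillations are single-cycle biphasic waves (duration
U(1.0, 1.4) s, negative peak ~N(110, 8) µV, floor 90) at 5/min of N3 and
1/min of N2, accompanied by sub-criterion "decoy" delta waves (30–45% of
the SO amplitude, 1.25 per SO): because the median rule keeps the top
half of the candidate pool, a night needs a realistic population of
smaller delta waves for recall and precision to be simultaneously
meaningful — exactly the large-vs-small cycle structure of the detector's
defining example. Coupled spindles (50% by default) are centred at an SO
phase drawn from von Mises(μ = 0 — the depolarized up-state — κ = 2);
κ = 0 recovers no coupling. An optional ECG channel carries a QRS train
(~65 bpm) that can leak into the EEG for testing the correction.

Under these defaults the detectors score recall and precision ≥ 0.9
(typically ≥ 0.95) against the injection lists at ±0.25-s tolerance.

**What the generator does not emulate.** No apnea/arousal events, no
body-movement or electrode-pop artifacts beyond what the mask thresholds
target, no neural-mass dynamics, no frontal slow-spindle class, no
night-to-night variability. Passing tests therefore demonstrate that the
pipeline measures what it claims on signals with known structure — not
that the detectors rival clinical scoring on real recordings.

**Cohorts.** Feature vectors are standard normal with a block-correlation
structure (blocks = feature domains/stages, within-block correlation 0.3)
plus optional linear age effects; scores follow y = β₀ + Xβ + ε with
ε ~ N(0, σ²), so the attainable correlation
r* = √(Var(Xβ)/(Var(Xβ)+σ²)) is known in closed form (and verified
against Monte-Carlo draws). A target r* can be requested directly; σ is
then solved for. The default score signal is a deliberately minimal
two-feature contrast (N3 delta/theta ratio and spindle density — the two
features most consistently tied to cognition): at n = 150 the realized
attainable correlation of a draw already fluctuates with SD ≈ 0.045, and
denser signals at the same r* push per-coefficient detectability below
what any estimator can recover, which would make r* an asymptote rather
than a benchmark. A separate ten-coefficient configuration
(`SUPPORT_BETAS`) serves the feature-support recovery study at r* = 0.8.
Demographics: age ~N(48.8, 17.7²), 56% female, education ~N(16.5, 3²)
clipped to 8–24 years.

## Problem sizes used in validation

The bundled validation runs use 1-hour nights (120 epochs) for feature
extraction and detector benchmarks, 150-subject feature-level cohorts for
the modelling protocol (10 seeds for the recovery study), and 2,000
simulations for test-calibration studies; these sizes give stable
statistics while keeping a full run in minutes. The CLI writes full
synthetic EDF nights for a configurable number of subjects (default 2) and
model-ready feature tables for the rest; a 150-subject set of full-night
EDFs would be several gigabytes and adds nothing to the composition
contract.

## Known limitations

* The spindle detector is a stand-in: its FFT/FWHM/NOSC/SYMM2 definitions
  are self-consistent but not certified against any external scorer.
* The artifact mask is a threshold rule, not a production artifact-removal
  method.
* The LRT on penalized fits inherits the heterodoxy discussed above.
* The lights-off/on convention of real exports varies; markers default to
  the first/last epoch and must be supplied when known, and sleep-latency
  semantics depend on them.
* Linear models only; possible non-linear feature–cognition relationships
  are out of scope.
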