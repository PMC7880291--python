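# Methods

## Experimental designs

The generator reproduces two session layouts of a single-trial audiovisual
localization task with five speaker positions at −23.2°…23.2° (11.6°
spacing) and six audiovisual discrepancies ΔVA ∈ {±11.6°, ±23.2°, ±34.8°}
(the colocated and extreme conditions are excluded).  The long-term (LT)
session has three consecutive leftward blocks (ΔVA < 0) followed by three
rightward blocks, 72 AV trials per block; the short-term (ST) session has
five blocks of 72 AV trials with all six ΔVA interleaved.  Every AV trial
is immediately followed by an auditory-only (A) trial; visual (V) catch
trials (72 in LT, 55 in ST) are inserted only after A trials so they never
break an AV→A pair.  Each ΔVA is repeated 72 (LT) / 60 (ST) times.

Choices where the layout is under-determined:

* AV stimulus pairs are drawn by sampling ΔVA uniformly from the block's
  allowed set and then the auditory position uniformly among speakers for
  which the implied visual position is also a speaker.  This reproduces
  the intended ΔVA marginals; it also means the auditory position is
  *not* independent of ΔVA (large discrepancies force off-center sounds),
  a constraint inherent to any bounded speaker array (see "Known
  limitations").
* The 72 repeats per ΔVA in LT are split equally, 24 per block, across
  the three blocks of the matching sign.
* V trials occupy distinct, uniformly drawn AV→A slots within each block.
* The LT session always runs leftward blocks first; direction order only
  relabels signs.

## Behavioral generator

Responses are drawn per trial (ε ~ N(0, σ²), σ = `sigma_resp`, default
4°; a per-subject constant offset ~ N(0, `sigma_subj`²) models
idiosyncratic localization bias):

* AV: R = A + b_ve_sqrt·ss(ΔVA) + b_ve_lin·ΔVA + ε, with ss the signed
  square root.
* A:  R = A + b_vae_sqrt·ss(ΔVA_prev) + b_vae_lin·ΔVA_prev +
  b_resp·R_AV_prev + c_t + ε.
* V:  R = V + ε.

The carryover term multiplies the *raw* previous response, so the A-trial
model is exactly the regression later fitted to it and parameter-recovery
studies are well defined.  The cumulative state c_t relaxes toward the
current block sign, c_k = c_{k−1} + rate·(±target − c_{k−1}), reset at the
leftward/rightward break and held at 0 in ST — the simplest dynamics with
a saturating buildup.  Defaults (b_ve_sqrt = 2.06, b_ve_lin = 0.02,
b_vae_sqrt = 0.89, b_vae_lin = −0.06, b_resp = 0.026) are of the magnitude
typical for this paradigm class: a strong, saturating visual capture in AV
trials and an aftereffect roughly half a degree per unit signed-root
discrepancy.

## Epoch generator

Epochs span −0.8 … 0.65 s around stimulus onset at 150 Hz.  Each encoded
variable v ∈ {ΔVA side, response side, sound side} owns a fixed unit-norm
random spatial pattern a_v and a Gaussian temporal envelope (defaults:
ΔVA at 250 ms, response at 300 ms, sound at 135 ms; SD 50 ms).  A trial's
data are Σ_v snr·g_v·a_v·s_v(t) + noise, where g_v = ±1 is the trial's
binary value plus N(0, `amp_jitter`²) single-trial amplitude jitter, and
the noise is spatially mixed white noise band-passed 2–40 Hz (fourth-order
zero-phase Butterworth) and normalized to unit RMS, so `snr` is a
pattern-to-noise amplitude ratio.  Two ground-truth couplings create the
links the analyses must detect:

* `coupling` (degrees per amplitude unit) adds the AV trial's single-trial
  ΔVA-pattern amplitude to the paired A trial's response — the
  neurobehavioral link (vae ~ LDA-ΔVA).
* `sound_bias` shifts the A-trial sound-pattern amplitude by the sign of
  the preceding ΔVA — the "recalibrated sound representation" probed by
  the LDA-sound ~ ΔVA_prev models.

Patterns are shared across a subject's two sessions by default (the same
brain), and can be drawn independently per session to model
paradigm-specific generators.

## Analysis chain

* **Biases.** ve = R_AV − A_AV per AV trial; vae = R_A − mean(R_A | same
  sound position, subject, paradigm), so constant per-location offsets
  cancel.  Mixed models are Gaussian with identity link, ML-fitted
  (statsmodels MixedLM), paradigm coded 0/1 with LT as reference,
  random intercept per subject only.  When the random-intercept variance
  collapses to the boundary (inevitable for vae, whose centering removes
  subject offsets), the fit degenerates to OLS and the OLS likelihood and
  standard errors are used — they are the exact ML quantities at that
  boundary.  BIC = −2·logLik + k·ln(n) with k = fixed effects + 2
  variances.
* **Binned time courses.** A-trial biases are ordered within each
  sign-constant run (LT halves sign-aligned by negating leftward-half
  values; ST whole session) and averaged in 36 bins of 5 (LT) / 9 (ST)
  trials.  These bin counts do not tile the runs exactly (216 and 360
  trials respectively); trials beyond bins × increment are dropped, and
  both numbers are exposed as parameters.  CIs are hybrid (basic)
  bootstrap over subjects, 199 resamples.
* **Decoding.** Features per window are the 6-sample channel means
  (channel-concatenation of raw samples is available as an option).
  rLDA: w ∝ Σ_reg⁻¹(μ_R − μ_L), Σ_reg = (1−λ)Σ̂_pooled + λ(trΣ̂/d)I,
  λ = 0.1; positive decision values mean "right".  AUC per window is the
  mean over six stratified folds of the held-out rank-statistic AUC
  (midranks for ties).  Forward models are per-window correlations of
  decision values with windowed channel data, normalized to unit maximum
  absolute value.
* **Neurobehavioral models.** Threefold stratified CV repeated 30 times
  (fold seeds derived deterministically from seed × subject × repeat);
  held-out decision values are z-scored within fold before the regression
  so β1 is comparable across windows, folds and paradigms.  Cross-paradigm
  models train fold classifiers on the source session and apply each to
  all destination trials, averaging fold regressions (fold-then-average).
  Group inference: one-sample t across subjects per window; effect size
  Cohen's d = mean/SD.  The conjunction of the two cross-directions is the
  per-window signed minimum; windows where the two t values disagree in
  sign are flagged, since the minimum is then the negative value.
* **Cluster statistics.** Per-subject chance-centered time courses
  (AUC − 0.5, or raw betas) have their signs flipped per subject as a
  whole (preserving temporal autocorrelation), 3000 randomizations.
  Group statistic: mean for AUC (first-level threshold = 99th percentile
  of the pooled randomized values, one-sided), t for betas (two-sided
  parametric threshold at p = 0.01, e.g. t_crit = 2.88 for 19 subjects).
  Clusters are temporal runs of ≥ 4 supra-threshold windows scored by the
  summed statistic; p = (1 + #{null max |mass| ≥ |mass|}) / (1 + n_rand),
  never zero, floor 1/3001.

## Validation studies and problem sizes

`ventrilab.validation` packages the end-to-end checks run by the test
suite, the acceptance script, and `analysis/05_calibration.py`.  Sizes are
chosen so a full pass completes in minutes on one core; the scientific
conditions (designs, trial counts, model structure, analysis settings) are
never reduced:

* Bias-model recovery: 19-subject cohorts, both paradigms, cumulative
  state off (so the generating model is exactly the fitted Eq-2 form),
  60–100 replicate cohorts; per-term 95% CI coverage must be ≥ 90% and
  the carryover model must win on BIC in every replicate.
* Decoder null: 50 single-subject ST runs at snr = 0, 8 channels; per
  window the mean AUC must stay in [0.47, 0.53].
* Signal recovery: one subject at snr = 4, 16 channels; AUC > 0.95
  throughout the ±1 SD envelope window and forward-model/ground-truth
  correlation > 0.95.
* Link recovery: 12 ST subjects, snr 1.5, coupling 0.3, 5 CV repeats;
  every significant Eq-3 cluster must contain the generating 250 ms
  latency.  Null calibration: 100 fully-null runs (couplings and
  behavioral ΔVA terms zero), 8 subjects, 2 repeats; ≤ 5% may produce a
  cluster at α = 0.05.
* Cross-paradigm dissociation: 10 subjects per scenario; shared patterns
  must give a significant conjunction cluster, session-specific patterns
  significant within-paradigm clusters only.
* Permutation machinery: p floor 1/3001 on a constant effect; exact
  enumeration of all 2⁸ sign flips matches the Monte-Carlo p within
  sampling error; family-wise error over 300–400 fully-null pipeline runs
  (12 subjects, 1 repeat) inside the binomial 95% band around 0.05.

In the null-calibration configurations the behavioral ΔVA and carryover
terms are switched off together with the neural coupling: with them on,
the decoded discrepancy genuinely predicts the aftereffect through
behavior alone, which is a true effect rather than a false positive.

## What the generator does and does not emulate

It emulates the designs exactly, the bias structure of behavior, the
band-limited spatially correlated background activity, latency-specific
binary spatial codes with single-trial amplitude variability, and a causal
single-trial path from neural amplitude to behavior.  It does not emulate
volume conduction from realistic sources, non-stationary artifacts, eye
movements, evoked components unrelated to the coded variables, or graded
(parametric) neural tuning — decoding here is genuinely binary.  Passing
tests therefore certify the statistical machinery and its calibration,
not claims about real neural data.

## Known limitations

* Because the speaker array is bounded, large |ΔVA| forces off-center
  sounds: the sign of the AV response correlates with ΔVA by design.  A
  decoder trained on response side therefore partially loads on the ΔVA
  pattern, and a weak "response" link to the aftereffect can appear in
  the generator even when only the ΔVA pattern is coupled.  The
  response-specificity check is accordingly run at the construction level
  (labels shuffled against epochs) rather than on the raw generator.
* The mixed model is random-intercept only; slopes are not modelled.
* Window-level inference is one-dimensional (time); no channel × time
  clustering.
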