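# Methods

## The experimental model

The pipeline analyses a monocular, lateralized face-presentation design.
Each trial shows two faces bilaterally (7° eccentric); one may be fearful
(left or right), or both neutral. Under monocular viewing the lateralized
fearful face stimulates exactly one hemiretina of the viewing eye: for a
left viewing eye, a left-field face projects to the nasal hemiretina and a
right-field face to the temporal hemiretina; a right viewing eye mirrors
this. Because the nasal hemiretina projects more strongly to the superior
colliculus, a naso-temporal processing asymmetry is read as engagement of
the subcortical route, and its dependence on spatial frequency (SF) is the
scientific question the statistic addresses.

Three SF blocks are run — broadband (BSF), low-pass (< 8 cycles/image) and
high-pass (> 32 cpi) — of 330 trials each: 110 per trial type (neutral,
fear-left, fear-right), of which 10 per type are fixation-colour-change
catch trials. Removing the catch trials leaves 100 usable trials per
condition, 300 per block, 900 in total. (The catch rate is exactly 10/110 ≈
9.1%; this is the only rate consistent with those usable counts.)

## The hemiretinal difference statistic

Per subject, per SF band, on fearful-face trials only (neutral-only trials
have no lateralized fearful face and are excluded by construction):

1. condition-average ERPs are pooled over left (PO7, P7, P9) and right
   (PO8, P8, P10) parietal electrodes;
2. the N2pc difference waveform is contra − ipsi with respect to the
   fearful face's field (left field → right-pool − left-pool), labelled
   with the stimulated hemiretina via the viewing-eye mapping;
3. the hemiretinal difference waveform is nasal-N2pc − temporal-N2pc.

The construction is eye-agnostic: relabelling the viewing eye while
mirroring presentation fields leaves the result unchanged, which is what
makes eye counterbalancing across subjects collapsible.

Statistics run on mean amplitudes over four fixed windows — 75–100 (P1.1),
115–125 (P1.2), 155–170 (N170) and 205–245 ms (EPN) — as one-way
repeated-measures ANOVAs over SF, with a follow-up 2 (hemiretina) × 3 (SF)
ANOVA on the N2pc window means to localize any asymmetry.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis assumes,
with known ground truth:

* **Components.** Pooled-parietal activity is a sum of Gaussian bumps —
  P1 (+4 µV, 110 ms, width 15 ms), N170 (−4 µV, 170 ms, 15 ms), EPN
  (+2.5 µV, 250 ms, 35 ms) — chosen to bracket the latency ranges the
  peak detector searches. The EPN is simulated as a positive deflection
  whose magnitude is *reduced* in "more negative" conditions, matching the
  sign convention of positive printed means.
* **Lateralized asymmetry.** A bump with the N170 shape is added only to
  the pool contralateral to the fearful face, with amplitude a(sf,
  hemiretina). **Calibration convention:** `a` is expressed in 155–170 ms
  *window-mean* units — the bump is scaled so the expected window mean of
  the contra−ipsi contrast equals `a` exactly, using the
  jitter-convolved expected shape (a Gaussian of width w jittered by
  N(0, j²) has expectation a Gaussian of width √(w²+j²) scaled by
  w/√(w²+j²)). This makes the noise-free hemiretinal difference equal `a`
  in that window to machine precision and makes recovery unbiased under
  latency jitter. Defaults: a(BSF, nasal) = −0.9 µV, all else 0.
* **Noise.** Per-channel 1/f-power ("pink") noise, 2 µV SD, normalized
  analytically so the ensemble SD is exact (averaging k trials gives SD
  exactly 2/√k). Per-trial Gaussian latency jitter, SD 5 ms, shifts all
  bumps together. Per-subject asymmetry offsets, SD 0.5 µV, drawn
  independently per (sf, hemiretina) cell, give the RM ANOVA a realistic
  subject × condition error term.
* **Artifacts.** With probability 0.02 a trial receives either a
  saccade-like 130 µV eye-channel step (100–300 ms long) or a 160 µV,
  15 ms muscle burst on one EEG channel — both band-limited enough to
  survive the 0.1–40 Hz filter so the threshold rejection stage has real
  work to do.
* **Behaviour.** Hits and false alarms are binomial per emotion × SF cell
  (catch trials are the signal trials: 10 per neutral cell, 20 per fear
  cell). Defaults p_hit = 0.91 (neutral) / 0.89 (fear), p_fa = 0.01 were
  chosen so the d′ distribution reproduces the study-level pattern —
  overall mean near 5 with a heavy upper tail from ceiling cells hitting
  the substitution rule, and higher d′ for neutral than fearful trials
  (the small neutral cells reach a perfect hit rate more often, which is
  itself part of the emulated effect). RTs are shifted-lognormal with cell
  means 1.46–1.48 s and a 10 ms fear slowdown.

Not modelled: scalp topography and volume conduction (the montage is the
six analysis electrodes plus one eye channel), spatial noise correlation
between pool members, eyeblink ICA components, and any trial-history
structure. Passing tests therefore demonstrate correctness of the
*analysis* under the assumed signal model, not robustness to every
real-EEG pathology.

A fast path (`simulate_condition_averages`) draws subject condition
averages from the exact distribution of an n-trial average (expected
template + pool-level pink noise with SD σ/√(3n)); it shares the waveform
code with the per-trial simulator and is what the replicated power and
type-I simulations use, keeping hundreds of replicates to seconds. The
full per-trial path (simulate → filter → baseline → reject → average) is
exercised by the pipeline itself.

## Stimulus preparation

Face-like 512×512 grayscale images are generated procedurally (smooth head
blob and shading for low-SF content; hard-edged eyes, brows, mouth and
fine texture for high-SF content; expression widens eye/mouth apertures).
SF filtering is a radial Butterworth amplitude gain in the 2-D frequency
domain: lowpass G(f) = 1/√(1+(f/fc)^(2n)), highpass G(f) =
1/√(1+(fc/f)^(2n)) with G(0) = 0 exactly, n = 2, f in cycles/image on the
pre-crop frame. Conditions are then luminance/contrast equated by linear
mean/SD matching over visible pixels (chosen over histogram matching for
invertibility and testability), and cropped to a vertical ellipse of
337 × 256.12 px via a binary alpha mask. Cycles-per-degree conversions
depend on viewing geometry and are reported only as documentation; all
computation is in cpi.

## Preprocessing and measurement choices

* **Filtering.** Zero-phase IIR: 2nd-order Butterworth high-pass at
  0.1 Hz, 10th-order Butterworth low-pass at 40 Hz, 50 Hz IIR notch
  (Q = 30), all forward–backward. The low-pass order keeps passband ripple
  below 1 dB through 35 Hz after the two passes double the attenuation.
  The high-pass uses Gustafsson initial conditions (reflective padding
  leaks multi-second edge transients into short records) with an explicit
  mean subtraction, since the stage's DC gain is zero by design.
* **Downsampling** (1024 → 512 Hz) is polyphase FIR with line-extension
  padding: linear phase, exact unit DC gain, no edge transients.
* **Epochs** span −100..600 ms at 512 Hz (359 samples); baseline
  correction subtracts the per-channel mean over [−100, 0) ms.
* **Rejection** applies after filtering and baseline correction (matching
  the listed processing order): a trial is dropped if |eye| > 60 µV, else
  if any EEG channel exceeds ±100 µV ("exceeded" read as strict
  inequality). Rejection is monotone in the thresholds and logged with a
  reason per trial.
* **Peak detection.** "First maximum / first minimum / second maximum" is
  realized as ordered windowed extrema: P1 = max in 60–160 ms, N170 = min
  in [max(P1 latency, 120), 230] ms, EPN = max in [max(N170 latency, 200),
  320] ms; ties break to the earliest sample. Amplitude is the mean over
  peak ± 5 ms (P1, N170) or ± 15 ms (EPN). Windows are config-overridable.
  The "semi-automatic" escape hatch is machine-readable flags
  (`review:flat`, `review:edge`) — never an interactive prompt.
* **Window means** use inclusive endpoints; fractional-ms endpoints round
  to the nearest sample of the 512 Hz grid. All latencies are grid times.

## Statistics

`rm_anova` performs the complete sums-of-squares decomposition of a
balanced fully-within design (subject, every effect, every effect ×
subject term) via inclusion–exclusion over marginal means; F uses the
effect × subject interaction as its error term, partial η² =
SS_effect/(SS_effect+SS_error). No sphericity correction is applied by
default — the reported dfs are the integer df1 = Π(levels−1), df2 =
df1·(n−1) — with Greenhouse–Geisser (orthonormal-contrast ε) as an option.
Degenerate inputs (zero error variance with a nonzero effect) raise; if
both effect and error are numerically zero, F is defined as 0. Post hocs
are paired t-tests with Bonferroni correction (p_bonf = min(1, m·p));
Cohen's d defaults to the d_z convention (mean of differences / SD of
differences), with d_av available — published d values under unclear
conventions are deliberately not used as reference points. The RT ANOVA
runs on subject-level cell means; a trial-level option exists for fidelity
to designs that report trial-level dfs, but is flagged as statistically
inappropriate.

## Problem sizes and reproducibility

Default study scale is 36 subjects (viewing eye counterbalanced 18/18) ×
990 trials. A full per-trial pipeline run completes in ~20 s; replicated
simulations (200-replicate power/recovery, 500-replicate null calibration)
use the exact fast path and finish in seconds. All randomness flows from a
single master seed through `numpy.random.SeedSequence` spawning; a run is
byte-reproducible from its YAML config, and the run directory carries
SHA-256 checksums of every output.

## Known limitations

* The 7-channel synthetic montage makes 64-channel re-referencing and
  topographic interpolation moot; the preprocessing surface documents the
  hook but the default chain omits them, and ICA-based eyeblink removal is
  out of scope (threshold rejection stands in).
* Peak "amplitude" here is a windowed mean around the detected extremum;
  jackknife or fractional-area latency estimators are not provided.
* The equating step matches first and second moments only; full SHINE-style
  histogram matching is a non-goal.
* d′ uses the fixed substitution constants for extreme rates rather than a
  log-linear correction, by design.
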