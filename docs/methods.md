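# Methods

`mscausal` is an end-to-end in-silico study of multisensory causal
inference: it synthesizes visual and vestibular motion inputs, trains a
small two-stream feedforward network to estimate self-motion (cue fusion),
scene motion (cue scission) and a binary common-cause decision, and then
interrogates the trained network with the single-unit and psychophysical
analyses standard in the visual–vestibular integration literature.  This
note documents the model, the synthetic data, the numerical choices, and
the known limitations.

## The task and the labels

Each trial pairs a visual velocity vector and a vestibular velocity vector,
four axes each: horizontal (x), vertical (y), motion-in-depth (z) and roll
rotation (r), all in pixels/frame.  The eight components are drawn i.i.d.
uniform on ±4 pixels/frame.  Per axis the network must report

- **fusion** `(v_vis + v_vest)/2` — the integrated self-motion estimate,
- **scission** `v_vis − v_vest` — the scene-motion estimate (sign
  convention: visual minus vestibular; configurable), and
- **causal** `1{|v_vis − v_vest| > m}` — "two events", where `m` is the
  per-axis median absolute cue difference over the whole dataset.  For the
  uniform training distribution `m = 8 − 4√2 ≈ 2.343` analytically.

## Visual stimuli

**Texture sequences (training).**  Each example renders six 64×64 frames
(32×32 in the reduced preset) from a procedurally generated grayscale scene
with a 1/f amplitude spectrum — the defining second-order statistic of
natural images, which is what a convolutional front end adapts to.  Scenes
are synthesized in the Fourier domain and are therefore periodic; rendering
wraps seamlessly, so any velocity is supported without border artifacts.  A
directory of user-supplied photographs can be substituted (`wrap=False`),
in which case the source must contain the crop plus motion margin and a
helpful error is raised otherwise.

Motion is an affine flow `v(p) = (vx, vy) + k·(p − c) + ω×(p − c)` about
the patch center `c`, applied cumulatively frame to frame and sampled by
inverse warping with bilinear interpolation.  The radial gain `k` and
angular rate `ω` follow the midpoint-speed convention: the stated `vz`/`vr`
is the image speed at half the distance from the focal point to the image
edge, so `k = vz/(S/4)` and `ω = vr/(S/4)` for image size `S`.  The focal
point of the combined field is its stationary point and is therefore set by
the translational component, as it is for egomotion optic flow.  Under
strong contraction the warp minifies the source; frames are sampled from
pre-blurred copies of the scene (mip levels chosen by the per-frame
minification) to bound aliasing.  Because each frame is sampled from the
high-resolution periodic source, expansion interpolates existing values
rather than inventing detail — the same motivation as initializing a zoom
sequence at a down-sampled resolution.

**Dot kinematograms (testing).**  Test stimuli are 50 Gaussian dots
(diameter 6 px, SD 1.2 px, black or white at random) on a midgray (0)
background, moving at 4 px/frame by default.  Coherent dots follow the same
affine flow (their speed scales linearly with distance from the focal
point); incoherent dots move at the dot speed in directions redrawn every
frame — the standard random-direction coherence algorithm.  Dots leaving
the image, or reaching the focal point under contraction, are repositioned
uniformly at random, conserving the dot count.  Motion coherence is the
visual-reliability manipulation used by the behavioral experiments.

## Vestibular encoding

Each axis is a 32-unit Gaussian population code with preferred velocities
evenly spaced on ±8 and unit peak response.  The tuning width σ is the
reliability handle: drawn uniformly from [1, 8] per axis per training
example, fixed per condition in the experiments (σ = 6 for the
cue-weighting task, σ = 2 for the decision-bias task).  Zero-mean Gaussian
noise (SD 0.3 during training) is added *fresh on every presentation*; this
matters, because trial-to-trial vestibular variability is what drives the
ROC analyses and the decision-bias phenomenon.  Velocities beyond ±8
saturate at the grid edge and trigger a warning.

## Network

Two streams converge on a multisensory layer (names follow the cortical
areas they are modeled after):

- **V1**: 64 kernels of 12×12×6 convolved (valid, no padding) over the
  x–y–t volume, collapsing the six frames; rectified linear. 53×53 maps,
  179,776 units, 55,360 learnable parameters.
- **pooling**: 2×2, stride 2, ceil-mode (53→27).  The connection count of
  the next layer (46,656 per downstream unit = 64·27²) pins only the pooled
  output size; max pooling is the default and average pooling is available
  (`Architecture.pool_mode`).
- **MT**: dense 46,656→64, rectified (2,986,048 parameters).
- **PIVC**: dense 128→12 on the flattened vestibular input, rectified
  (1,548 parameters).
- **MSTd**: dense 76→64, rectified, with one offset per *input* (64 visual
  + 12 vestibular), giving 4,940 parameters.  This input-offset
  parameterization is what the 4,940-parameter count implies.
- **output**: dense 64→12: eight linear regression units (fusion ×4,
  scission ×4) and four sigmoid causal units (780 parameters).

The forward pass and backpropagation are implemented directly in NumPy
(im2col convolution, argmax-routed pooling gradients); correctness is
checked against central finite differences in the test suite.  Convolution
uses cross-correlation orientation (no kernel flip).

**Initialization.**  Three schemes are provided.  The literal reference scheme
(`"zero_fc"`) — convolutional kernels N(0, 0.001), every other weight and all
offsets zero — gives identically zero gradient to every pre-output layer
(no symmetry breaking) and cannot train as written; it is retained for
reference.  `"small_random"` draws all weights N(0, 0.001), which breaks
symmetry but attenuates both signal and gradient by ~10⁻³ per layer.  The
default for actual runs is `"he"`: Gaussian weights with SD √(2/fan-in)
(√(1/fan-in) at the output), zero offsets — the standard choice for
rectified networks and the only one of the three that converges in
practical time.

## Training

Plain minibatch gradient descent (no momentum, no adaptivity, no
regularization): batches of 32 drawn without replacement each epoch,
constant learning rate, 75/25 train/test split with disjoint example IDs.
The loss is

    1.0 · [ MSE(fusion) + 0.5 · MSE(scission) ] + 0.2 · BCE(causal)

with MSE/BCE averaged over axes and batch.  The 0.5 scission factor
compensates for the scission target range being twice the fusion range;
note that under an uninformed zero predictor E[scission²] = 4·E[fusion²]
(32/3 vs 8/3), so halving narrows the imbalance to 2:1 rather than
removing it.  The causal units output sigmoid values but are trained
against binary labels and read out at the 0.5 boundary.

Two presets:

- **full** — 64×64 inputs, 64 kernels, 64,000 examples, 50 epochs,
  lr 1·10⁻⁴, 5 replicates.  This is the reference protocol; at NumPy speed
  on one CPU it is a multi-hour run.
- **desk** — 32×32 inputs, 16 kernels, 8,000 examples, 15 epochs,
  lr 2·10⁻², 5 replicates (fewer are used where runtime is tight).  All
  analyses in the test suite and the acceptance script run under this
  preset.  The learning rate is raised because the reduced run has ~27×
  fewer SGD updates than the full protocol; 2·10⁻² is the largest rate
  that remains stable at this scale (3·10⁻² and above diverge), chosen
  once from a rate scan.

**What the reduced preset does and does not reproduce.**  At desk scale
the held-out regression correlations reach r ≈ 0.9 (they are
generalization-limited: the preset has 6,000 unique training scenes, and
test loss plateaus while training loss keeps falling) and causal accuracy
stays close to chance after 15 epochs, climbing slowly with further
training.  The causal decision needs rectification-folded |Δv| features in
the multisensory layer; these emerge slowly under the 0.2-weighted
binary-cross-entropy gradient, long after the regression objectives have
shaped the layer, so the representation for near-reference accuracy forms
only after far more SGD updates than the reduced budget provides.  The
qualitative phenomena (congruent/opposite unit structure, weight
organization, cue weighting, decision bias) emerge already at desk scale;
the headline accuracy figure does not.

## Unit characterization

Heading direction combines x and z: θ = 0° is straight-ahead
motion-in-depth, 90° rightward motion; `decode_polar` uses
`arctan2(vx, vz)`-ordering to match.  Single-cue conditions input the
excluded cue as zeros.  Vestibular tuning width defaults to σ = 6 with
SD-0.3 noise during characterization (matching the cue-weighting task);
visual trials use fresh dot placements, and tuning curves average 64
repeats by default.

- **Broad tuning**: 10 headings at 36° spacing; sinusoid fit
  `a·sin(θ − θ_pref) + b` by linear least squares (a ≥ 0 by convention;
  constant responses give a = 0 and an undefined preferred direction).
  The preferred-direction-difference histogram includes only strongly
  tuned units (amplitude above the per-cue median for both cues), binned
  at 30°.
- **Fine sweep**: 10 log-spaced directions, five magnitudes from 2° to 36°
  mirrored about zero (the inner endpoint is a package choice; the
  literature states only the count and the outer bound).  The congruency
  index is the product of the per-cue Pearson correlations between
  per-trial response and heading; units with both correlations significant
  (two-sided p < 0.05, t-approximation) are congruent (CI > 0) or opposite
  (CI < 0), otherwise intermediate.
- **Neurometric thresholds**: for each signed direction the ROC area
  between the unit's response distribution at +θ and its own distribution
  at −θ (the anti-unit); the neurometric function is fitted with a
  cumulative Gaussian by least squares and the threshold is its SD (84%
  point).  100 trials per direction by default.  Optimal-integration
  prediction: σ_pred² = σ_vest²·σ_vis²/(σ_vest² + σ_vis²), which never
  exceeds either single-cue threshold.  Non-convergent or saturated fits
  are flagged unresolvable, matching the exclusion of untuned units.
- **Per-axis classification**: seven evenly spaced speeds on ±4 per cue in
  isolation; the per-cue response–speed correlations are multiplied and
  classified exactly like the congruency index.  Each unit's preferred cue
  velocity (speed of maximal mean response) feeds the weight-binning and
  preference-offset analyses.
- **Weights, lesions, asymmetry**: class-level summaries use the signed
  mean weight to the causal units and mean |weight| to fusion/scission
  units, pooled over axes.  Artificial lesions zero all units outside the
  decoded class; estimate maps cover the 31×31 grid of visual × vestibular
  velocities on ±4 (961 cells), normalized by their maximum absolute
  value.  Cue-sensitivity asymmetry is the normalized amplitude difference
  ||a_vis| − |a_vest||/(|a_vis| + |a_vest|) from the broad-tuning fits (no
  canonical formula exists; the raw difference is available).  For
  heading-based classes the relevant output weight is the mean |weight|
  over the x and z axes, the axes that compose heading.

## Behavioral experiments

**Cue weighting.**  Seven test directions on ±14°; vestibular-only,
visual-only at coherence 1.0 and 0.6, and combined conditions with
conflicts of 0 and ±9° (each cue offset by half the conflict in opposite
directions, so the cue average equals the test direction).  128 trials per
direction; a trial is "rightward" when the fusion x-estimate exceeds zero
(no decision noise, lapse rate 0).  Choice proportions are fitted with a
maximum-likelihood cumulative Gaussian (Nelder–Mead on the binomial
likelihood); PSE = mean, threshold = SD; perfectly separated data are
clipped at 1/(2n) and flagged.  The PSE-vs-conflict slope measures cue
dominance: negative slope = visual dominance (the PSE follows the visual
offset), positive = vestibular.

**Decision bias.**  Vestibular input encodes zero x-velocity (σ = 2) with
SD-0.8 noise; visual input is a coherent dot field at ±2.343 px/frame (the
learned one/two-event boundary), 2,560 trials per sign.  Trials are
grouped by the network's own causal decision; because the separation sits
at the boundary, vestibular noise swings roughly half the trials to each
decision.  Reported: mean self- and scene-motion estimates per group
(signed toward the visual cue), estimate histograms, and the mean 32-unit
vestibular input per group, whose population vector shifts toward the
visual sign on one-event trials.

**Statistics.**  Bootstrap percentile CIs (50,000 iterations by default;
smaller counts are used inside tests where noted) and Pearson correlations
throughout.  Replicate ensembles (5 networks at full scale) are averaged;
runtime-constrained analyses use fewer replicates and say so.

## Known limitations

- The synthetic 1/f scenes reproduce the amplitude spectrum of natural
  images but not their phase structure (edges, occlusions), object
  content, or luminance distribution; conclusions about adaptation to
  higher-order natural statistics are outside what these stimuli can show.
- No photoreceptor/retinal model, no yaw/pitch rotations, no spatially
  localized object motion, no temporal dynamics of vestibular transduction
  (the population code is velocity-labelled).
- The reduced preset reproduces the qualitative unit-level and behavioral
  phenomena but not the full-scale accuracy figures (see Training above).
- Pooling type and edge handling, the inner endpoint of the log-spaced
  sweep, and the asymmetry formula are package choices where the
  literature pins only the surrounding constraints; all are exposed as
  configuration.
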