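# mscausal

**Multisensory causal inference in a two-stream neural network.**

When you move through the world you receive two independent estimates of
your own motion: optic flow on the retina and inertial signals from the
vestibular organs.  The brain must decide, moment to moment, whether the
two signals were caused by the *same* event (you are moving — integrate
them) or by *different* events (the scene is also moving — separate them).
This is the problem of causal inference, and macaque area MSTd — where
visual and vestibular self-motion signals converge, and where "congruent"
and "opposite" multisensory neurons live — is its presumed neural locus.

`mscausal` is a complete in-silico version of that problem, for
computational neuroscientists who want a transparent model system:

- **Stimulus synthesis** — six-frame optic-flow movies (translation,
  expansion/contraction, roll) rendered from procedurally generated
  1/f-noise scenes with exact velocity ground truth, plus random-dot
  kinematograms with a motion-coherence (reliability) manipulation.
- **Vestibular encoding** — four 32-unit Gaussian population codes
  (preferred velocities on ±8, tuning width σ ∈ [1, 8], fresh additive
  noise per presentation).
- **The network** — V1 (3-D convolution, 64@12×12×6) → pooling → MT (dense
  64) for vision; PIVC (dense 12) for the vestibular code; both converge
  on MSTd (dense 64), read out by 8 linear regression units and 4 sigmoid
  decision units.  Forward pass *and* backpropagation are pure NumPy.
- **Training** — per axis, fusion = cue average (self-motion), scission =
  cue difference (scene motion), causal = 1 if |Δv| exceeds the dataset
  median (≈ 8 − 4√2 ≈ 2.34 for the uniform ±4 px/frame training
  distribution); composite loss `MSE(fusion) + 0.5·MSE(scission) +
  0.2·BCE(causal)`, plain minibatch SGD.
- **Analyses** — heading-tuning curves and sinusoid fits, congruency-index
  classification (CI = r_vestibular × r_visual), ROC neurometric
  thresholds vs the optimal-integration prediction
  σ_pred² = σ_vest²σ_vis²/(σ_vest²+σ_vis²), connection-weight summaries,
  artificial lesions, reliability-based cue weighting (PSE shifts under
  ±9° cue conflict), and the causal-inference decision-bias experiment.

See `docs/methods.md` for the full model description and the design
choices.

## Worked example

Train a reduced-scale ("desk": 32×32 inputs, 16 kernels, 8,000 examples,
15 epochs) network and inspect it:

```python
import numpy as np
from mscausal import training, network
from mscausal import characterization as chz

cfg = training.desk_config(seed=202)
dataset = training.generate_dataset(cfg.n_examples, cfg.seed, cfg.arch)
params, history = training.train(cfg, dataset)
print(history[["epoch", "train_loss", "min_r", "acc_causal_mean"]].tail(3))
```

```
    epoch  train_loss     min_r  acc_causal_mean
12     12    1.138602  0.896308         0.533000
13     13    1.125564  0.913971         0.537625
14     14    1.087846  0.858909         0.536125
```

After 15 reduced-scale epochs the eight regression outputs track the true
self- and scene-motion velocities with held-out Pearson r ≈ 0.86–0.92
(`min_r` is the worst of the eight), and the binary causal decisions are
above chance (53–55% vs 50%) and still improving — at this scale the
network has the integration/separation estimates but only the beginnings
of the decision representation (see `docs/methods.md` for why, and what
the full-scale protocol adds).

Classify the multisensory units and look at the emergent structure:

```python
rng = np.random.default_rng(77)
ccfg = chz.CharacterizationConfig()
fine = chz.fine_directions()
curves = {cue: chz.measure_tuning(params, cue, fine, 64, rng, ccfg)
          for cue in ("vestibular", "visual")}
classes = chz.congruency_index(curves["vestibular"], curves["visual"])
print(classes["unit_class"].value_counts().to_dict())
```

```
{'intermediate': 41, 'opposite': 13, 'congruent': 10}
```

Congruent units (same preferred direction for both cues) and opposite
units (opposed preferred directions) emerge from training alone — the
hallmark cell types of macaque MSTd — and the package's weight, lesion,
cue-weighting and decision-bias analyses then show congruent units
supporting integration (self-motion) and opposite units supporting
separation (scene motion) and the two-events decision.  (With longer
training the population sharpens further; the distribution of
visual-vestibular preferred-direction differences becomes bimodal at 0°
and 180°, as in cortex.)

A command-line interface wraps the same functionality:

```sh
mscausal train --preset desk --seed 1 --out runs/demo
mscausal experiment cue-weighting --checkpoint runs/demo/replicate0 --seed 2 --out runs/demo
mscausal study --preset desk --replicates 2 --seed 1 --out runs/study
```

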