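"""Dataset construction, composite loss, and minibatch SGD training.

Each training example pairs a rendered six-frame visual motion sequence with
a noiseless vestibular tuning profile (noise is redrawn on every
presentation).  The eight velocity components (visual and vestibular, four
axes each) are drawn independently and uniformly from +/-4 pixels/frame.

Labels per axis:

* **fusion** = (v_visual + v_vestibular) / 2   (self-motion when integrated)
* **scission** = v_visual - v_vestibular       (scene motion)
* **causal** = 1 iff |v_visual - v_vestibular| exceeds the per-axis median
  absolute difference over the whole dataset (analytically 8 - 4*sqrt(2)
  ~ 2.34 for the uniform training distribution), i.e. 1 = "two events".

The loss is ``w_reg * [MSE(fusion) + 0.5 * MSE(scission)] + w_bin *
BCE(causal)`` with ``w_reg = 1.0`` and ``w_bin = 0.2``; halving the scission
term equates the potential loss of the two regression tasks (the scission
target range is twice the fusion range).  Optimization is plain minibatch
gradient descent: ``w <- w - alpha * <dL/dw>`` with a constant learning
rate, batches of 32 drawn without replacement each epoch.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import network, stimuli, vestibular
from .network import Architecture, DESK_ARCH, FULL_ARCH, NetworkParams

ANALYTIC_MEDIAN_DIFF = 8.0 - 4.0 * np.sqrt(2.0)  # median |U1 - U2|, U ~ U(-4, 4)


@dataclass
class Dataset:
    """In-memory paired visual/vestibular dataset with ground truth."""

    visual: np.ndarray  # (N, H, W, T) float32, rendered sequences
    vest_profile: np.ndarray  # (N, 4, 32) float32, noiseless tuning
    vis_v: np.ndarray  # (N, 4) visual velocities
    vest_v: np.ndarray  # (N, 4) vestibular velocities
    sigma: np.ndarray  # (N, 4) vestibular tuning widths
    ids: np.ndarray  # (N,) example identifiers

    def __len__(self):
        return len(self.ids)

    def vest_input(self, rng: np.random.Generator, noise_sd: float, idx=None):
        """Noisy 128-value vestibular inputs for one presentation."""
        prof = self.vest_profile if idx is None else self.vest_profile[idx]
        flat = prof.reshape(prof.shape[0], -1)
        if noise_sd <= 0:
            return flat
        return flat + rng.normal(0.0, noise_sd, size=flat.shape).astype(np.float32)


def generate_dataset(
    n: int,
    seed: int,
    arch: Architecture = FULL_ARCH,
    scene_size: int | None = None,
) -> Dataset:
    """Generate ``n`` visual-vestibular training pairs.

    Every example gets its own procedurally generated periodic 1/f scene
    image; vestibular tuning widths are drawn uniformly from [1, 8] per axis
    and fixed per example (noise is added later, per presentation).
    """
    if n < 1:
        raise ValueError("dataset must contain at least one example")
    rng = np.random.default_rng(seed)
    size = arch.image_size
    scene_size = scene_size or 4 * size
    visual = np.empty((n, size, size, arch.n_frames), dtype=np.float32)
    vest_profile = np.empty((n, network.N_AXES, arch.vest_units), dtype=np.float32)
    vis_v = np.empty((n, 4))
    vest_v = np.empty((n, 4))
    sigmas = np.empty((n, 4))
    scene_seeds = rng.integers(0, 2**31 - 1, size=n)
    for i in range(n):
        vis, vest = stimuli.sample_motion_pair(rng)
        scene = stimuli.generate_scene_image(int(scene_seeds[i]), scene_size)
        visual[i] = stimuli.render_texture_sequence(scene, vis, out_size=size)
        sig = vestibular.sample_sigma(rng)
        vest_profile[i] = np.stack(
            [
                vestibular.tuning_profile(mu, s, arch.vest_units)
                for mu, s in zip(vest.as_array(), sig)
            ]
        )
        vis_v[i] = vis.as_array()
        vest_v[i] = vest.as_array()
        sigmas[i] = sig
    return Dataset(
        visual=visual,
        vest_profile=vest_profile,
        vis_v=vis_v,
        vest_v=vest_v,
        sigma=sigmas,
        ids=np.arange(n),
    )


def compute_causal_thresholds(vis_v: np.ndarray, vest_v: np.ndarray) -> np.ndarray:
    """Per-axis median absolute visual-vestibular velocity difference."""
    vis_v = np.atleast_2d(vis_v)
    vest_v = np.atleast_2d(vest_v)
    if len(vis_v) == 0:
        raise ValueError("cannot compute thresholds on an empty dataset")
    return np.median(np.abs(vis_v - vest_v), axis=0)


@dataclass
class LabelSet:
    fusion: np.ndarray  # (..., 4)
    scission: np.ndarray  # (..., 4)
    causal: np.ndarray  # (..., 4) binary, 1 = two events


def make_labels(
    vis_v, vest_v, thresholds, scission_sign: float = 1.0
) -> LabelSet:
    """Build fusion/scission/causal labels from a velocity pair.

    ``scission_sign=+1`` gives scene motion as visual minus vestibular (the
    default); ``-1`` flips the convention.
    """
    vis_v = np.asarray(vis_v, dtype=float)
    vest_v = np.asarray(vest_v, dtype=float)
    diff = vis_v - vest_v
    return LabelSet(
        fusion=(vis_v + vest_v) / 2.0,
        scission=scission_sign * diff,
        causal=(np.abs(diff) > np.asarray(thresholds)).astype(float),
    )


@dataclass
class TrainConfig:
    """Training hyperparameters.  Defaults are the full-scale protocol."""

    learning_rate: float = 1.0e-4
    batch_size: int = 32
    epochs: int = 50
    loss_weight_regression: float = 1.0
    loss_weight_binary: float = 0.2
    scission_loss_factor: float = 0.5
    train_fraction: float = 0.75
    seed: int = 0
    n_replicates: int = 5
    n_examples: int = 64_000
    noise_sd: float = vestibular.TRAIN_NOISE_SD
    scission_sign: float = 1.0
    init_scheme: str = "he"
    arch: Architecture = FULL_ARCH


def desk_config(seed: int = 0, **overrides) -> TrainConfig:
    """Reduced-scale preset: 16 kernels, 32x32 inputs, 8,000 examples,
    15 epochs.  All emergent-property analyses run under this preset.

    The learning rate is raised to 2e-2: with roughly 27x fewer SGD updates
    than the full protocol, the full-scale rate leaves the optimization far
    from convergence, and 2e-2 is the largest rate that remains stable at
    this scale.
    """
    cfg = TrainConfig(
        seed=seed, arch=DESK_ARCH, n_examples=8000, epochs=15, learning_rate=2e-2
    )
    return replace(cfg, **overrides)


def composite_loss(
    fusion, scission, causal, labels: LabelSet, config: TrainConfig
) -> dict[str, float]:
    """Composite loss and its components, averaged over axes and batch."""
    causal = np.asarray(causal)
    if (causal <= 0).any() or (causal >= 1).any():
        raise ValueError("causal outputs must be strictly in (0, 1) (post-sigmoid)")
    mse_f = float(np.mean((fusion - labels.fusion) ** 2))
    mse_s = float(np.mean((scission - labels.scission) ** 2))
    bce = float(
        np.mean(
            -labels.causal * np.log(causal) - (1 - labels.causal) * np.log1p(-causal)
        )
    )
    total = (
        config.loss_weight_regression * (mse_f + config.scission_loss_factor * mse_s)
        + config.loss_weight_binary * bce
    )
    return {"total": total, "mse_fusion": mse_f, "mse_scission": mse_s, "bce": bce}


def split_dataset(dataset: Dataset, config: TrainConfig):
    """Disjoint train/test index split (75/25 by default), seeded."""
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(len(dataset))
    n_train = int(round(config.train_fraction * len(dataset)))
    return perm[:n_train], perm[n_train:]


def _output_grad(acts, labels: LabelSet, config: TrainConfig) -> np.ndarray:
    """d(loss)/d(pre-activation outputs), batch-averaged; shape (B, 12)."""
    b = acts.fusion.shape[0]
    scale = 1.0 / (network.N_AXES * b)
    d = np.empty((b, network.N_OUTPUTS), dtype=np.float32)
    wr = config.loss_weight_regression
    d[:, :4] = wr * 2.0 * (acts.fusion - labels.fusion) * scale
    d[:, 4:8] = (
        wr * config.scission_loss_factor * 2.0 * (acts.scission - labels.scission) * scale
    )
    d[:, 8:] = config.loss_weight_binary * (acts.causal - labels.causal) * scale
    return d


def evaluate(
    params: NetworkParams,
    dataset: Dataset,
    idx,
    thresholds,
    config: TrainConfig,
    rng: np.random.Generator,
    batch_size: int = 256,
) -> dict:
    """Held-out metrics: per-output Pearson r and causal accuracy.

    Causal outputs are binarized at 0.5.  Accuracy is reported per axis,
    axis-averaged, and pooled over all four decisions.
    """
    idx = np.asarray(idx)
    fus = np.empty((len(idx), 4))
    sci = np.empty((len(idx), 4))
    cau = np.empty((len(idx), 4))
    for lo in range(0, len(idx), batch_size):
        sel = idx[lo : lo + batch_size]
        vest_in = dataset.vest_input(rng, config.noise_sd, sel)
        acts = network.forward(params, dataset.visual[sel], vest_in)
        fus[lo : lo + batch_size] = acts.fusion
        sci[lo : lo + batch_size] = acts.scission
        cau[lo : lo + batch_size] = acts.causal
    labels = make_labels(
        dataset.vis_v[idx], dataset.vest_v[idx], thresholds, config.scission_sign
    )
    metrics = {}
    axes = "xyzr"
    for i, ax in enumerate(axes):
        metrics[f"r_fusion_{ax}"] = _safe_pearson(fus[:, i], labels.fusion[:, i])
        metrics[f"r_scission_{ax}"] = _safe_pearson(sci[:, i], labels.scission[:, i])
    decisions = (cau > 0.5).astype(float)
    correct = decisions == labels.causal
    for i, ax in enumerate(axes):
        metrics[f"acc_causal_{ax}"] = float(correct[:, i].mean())
    metrics["acc_causal_mean"] = float(correct.mean(axis=0).mean())
    metrics["acc_causal_pooled"] = float(correct.mean())
    metrics["min_r"] = min(
        v for k, v in metrics.items() if k.startswith("r_")
    )
    loss = composite_loss(
        fus, sci, np.clip(cau, 1e-7, 1 - 1e-7), labels, config
    )
    metrics["test_loss"] = loss["total"]
    return metrics


def _safe_pearson(a, b) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b)[0])


def train(
    config: TrainConfig,
    dataset: Dataset,
    checkpoint_dir=None,
    verbose: bool = False,
) -> tuple[NetworkParams, pd.DataFrame]:
    """Train one network; returns final parameters and per-epoch history.

    The history records train/test loss, the eight held-out Pearson
    correlations, and causal accuracy after every epoch.  If
    ``checkpoint_dir`` is given, a checkpoint is saved per epoch.
    """
    rng = np.random.default_rng(config.seed)
    params = network.init_network(
        int(rng.integers(2**31 - 1)), config.init_scheme, config.arch
    )
    thresholds = compute_causal_thresholds(dataset.vis_v, dataset.vest_v)
    train_idx, test_idx = split_dataset(dataset, config)
    assert not np.intersect1d(dataset.ids[train_idx], dataset.ids[test_idx]).size
    all_labels = make_labels(
        dataset.vis_v, dataset.vest_v, thresholds, config.scission_sign
    )
    history = []
    t0 = time.time()
    for epoch in range(config.epochs):
        order = rng.permutation(train_idx)
        epoch_loss = 0.0
        n_batches = 0
        for lo in range(0, len(order), config.batch_size):
            sel = order[lo : lo + config.batch_size]
            vest_in = dataset.vest_input(rng, config.noise_sd, sel)
            acts, cache = network._forward_full(params, dataset.visual[sel], vest_in)
            labels = LabelSet(
                fusion=all_labels.fusion[sel],
                scission=all_labels.scission[sel],
                causal=all_labels.causal[sel],
            )
            loss = composite_loss(
                acts.fusion, acts.scission,
                np.clip(acts.causal, 1e-7, 1 - 1e-7), labels, config,
            )
            if not np.isfinite(loss["total"]):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches} "
                    f"(examples {sel[:5]}...): {loss}"
                )
            grads = network.backward(params, cache, _output_grad(acts, labels, config))
            for name, grad in grads.items():
                arr = getattr(params, name)
                arr -= config.learning_rate * grad.astype(arr.dtype)
            epoch_loss += loss["total"]
            n_batches += 1
        metrics = evaluate(params, dataset, test_idx, thresholds, config, rng)
        metrics["epoch"] = epoch
        metrics["train_loss"] = epoch_loss / max(n_batches, 1)
        metrics["seconds"] = time.time() - t0
        history.append(metrics)
        if verbose:
            print(
                f"epoch {epoch:3d}  train {metrics['train_loss']:.4f}  "
                f"test {metrics['test_loss']:.4f}  min r {metrics['min_r']:.3f}  "
                f"acc {metrics['acc_causal_mean']:.3f}"
            )
        if checkpoint_dir is not None:
            network.save_params(
                f"{checkpoint_dir}/epoch{epoch:03d}",
                params,
                meta={"epoch": epoch, "seed": config.seed},
            )
    return params, pd.DataFrame(history)


def train_ensemble(
    config: TrainConfig, dataset: Dataset, verbose: bool = False
) -> list[tuple[NetworkParams, pd.DataFrame]]:
    """Train ``config.n_replicates`` networks on the same dataset.

    Replicates differ in initialization, batch order and noise draws
    (seeded from ``config.seed``); reported analysis quantities are averaged
    over the ensemble.
    """
    out = []
    for rep in range(config.n_replicates):
        cfg = replace(config, seed=config.seed + 1000 * rep + 1)
        out.append(train(cfg, dataset, verbose=verbose))
    return out
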