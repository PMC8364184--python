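"""Two-stream feedforward network for visual-vestibular motion estimation.

Architecture (full scale)::

    visual 64x64x6 --conv 64@12x12x6--> V1 64x53x53 --2x2 pool--> 64x27x27
        --dense--> MT 64 --+
                           +--> MSTd 64 --> 8 regression + 4 sigmoid outputs
    vestibular 4x32 --dense--> PIVC 12 --+

All hidden layers are rectified linear.  The eight regression outputs are the
per-axis *fusion* (self-motion: average of the two cues) and *scission*
(scene motion: visual minus vestibular) velocity estimates; the four sigmoid
outputs are per-axis causal-inference decisions (1 = the cues came from two
different events).

The forward pass and backpropagation are implemented directly in NumPy
(im2col convolution); gradients are verified against finite differences in
the test suite.  There is no automatic differentiation dependency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

N_AXES = 4
N_OUTPUTS = 3 * N_AXES  # 4 fusion + 4 scission + 4 causal


@dataclass(frozen=True)
class Architecture:
    """Structural hyperparameters; the defaults are the full-scale network."""

    image_size: int = 64
    n_frames: int = 6
    kernel_size: int = 12
    n_kernels: int = 64
    mt_units: int = 64
    pivc_units: int = 12
    mstd_units: int = 64
    vest_units: int = 32
    pool: int = 2
    pool_mode: str = "max"  # "max" or "avg"

    @property
    def conv_out(self) -> int:
        return self.image_size - self.kernel_size + 1

    @property
    def pooled(self) -> int:
        return -(-self.conv_out // self.pool)  # ceil division (ceil-mode pooling)

    @property
    def mt_in(self) -> int:
        return self.n_kernels * self.pooled**2

    @property
    def vest_in(self) -> int:
        return N_AXES * self.vest_units

    @property
    def mstd_in(self) -> int:
        return self.mt_units + self.pivc_units


FULL_ARCH = Architecture()
#: reduced-scale architecture used by the desk preset (see training module)
DESK_ARCH = Architecture(image_size=32, n_kernels=16)


@dataclass
class NetworkParams:
    """All learnable parameters.

    The MSTd layer carries one offset per *input* (64 visual + 12 vestibular)
    added before the weight matrix, rather than per-output offsets; the other
    dense layers use conventional per-output offsets.
    """

    arch: Architecture
    v1_kernels: np.ndarray  # (K, kh, kw, T)
    v1_offsets: np.ndarray  # (K,)
    mt_w: np.ndarray  # (mt_in, mt_units)
    mt_b: np.ndarray  # (mt_units,)
    pivc_w: np.ndarray  # (vest_in, pivc_units)
    pivc_b: np.ndarray  # (pivc_units,)
    mstd_w: np.ndarray  # (mstd_in, mstd_units)
    mstd_in_offsets: np.ndarray  # (mstd_in,)
    out_w: np.ndarray  # (mstd_units, 12)
    out_b: np.ndarray  # (12,)

    ARRAY_FIELDS = (
        "v1_kernels", "v1_offsets", "mt_w", "mt_b", "pivc_w", "pivc_b",
        "mstd_w", "mstd_in_offsets", "out_w", "out_b",
    )

    def arrays(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in self.ARRAY_FIELDS}

    def copy(self) -> "NetworkParams":
        return NetworkParams(self.arch, **{k: v.copy() for k, v in self.arrays().items()})


@dataclass
class LayerActivations:
    v1: np.ndarray  # (B, oh, ow, K)
    pooled: np.ndarray  # (B, ph, pw, K)
    mt: np.ndarray  # (B, mt_units)
    pivc: np.ndarray  # (B, pivc_units)
    mstd: np.ndarray  # (B, mstd_units)
    fusion: np.ndarray  # (B, 4)
    scission: np.ndarray  # (B, 4)
    causal: np.ndarray  # (B, 4), in (0, 1)


def init_network(
    seed: int, scheme: str = "he", arch: Architecture = FULL_ARCH
) -> NetworkParams:
    """Initialize parameters.

    Schemes:

    * ``"he"`` (default) — Gaussian weights with SD ``sqrt(2 / fan_in)`` for
      the rectified layers and ``sqrt(1 / fan_in)`` for the output layer,
      offsets zero.  This is the scheme used for actual training runs.
    * ``"small_random"`` — every weight ~ Normal(0, 0.001), offsets zero.
    * ``"zero_fc"`` — convolutional kernels ~ Normal(0, 0.001); every other
      weight and all offsets exactly zero.  Note that under backpropagation
      this scheme leaves all pre-output layers with identically zero
      gradient (no symmetry breaking), so it cannot train as written; it is
      retained for reference.
    """
    if scheme not in ("he", "small_random", "zero_fc"):
        raise ValueError(f"unknown init scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    a = arch
    kshape = (a.n_kernels, a.kernel_size, a.kernel_size, a.n_frames)

    def w(shape, fan_in, gain=2.0):
        if scheme == "he":
            sd = np.sqrt(gain / fan_in)
        else:
            sd = 0.001
        return rng.normal(0.0, sd, size=shape).astype(np.float32)

    fan_conv = a.kernel_size**2 * a.n_frames
    params = NetworkParams(
        arch=a,
        v1_kernels=w(kshape, fan_conv),
        v1_offsets=np.zeros(a.n_kernels, dtype=np.float32),
        mt_w=w((a.mt_in, a.mt_units), a.mt_in),
        mt_b=np.zeros(a.mt_units, dtype=np.float32),
        pivc_w=w((a.vest_in, a.pivc_units), a.vest_in),
        pivc_b=np.zeros(a.pivc_units, dtype=np.float32),
        mstd_w=w((a.mstd_in, a.mstd_units), a.mstd_in),
        mstd_in_offsets=np.zeros(a.mstd_in, dtype=np.float32),
        out_w=w((a.mstd_units, N_OUTPUTS), a.mstd_units, gain=1.0),
        out_b=np.zeros(N_OUTPUTS, dtype=np.float32),
    )
    if scheme == "zero_fc":
        for name in params.ARRAY_FIELDS:
            if name != "v1_kernels":
                getattr(params, name)[:] = 0.0
    return params


def count_parameters(params: NetworkParams) -> dict[str, int]:
    """Exact learnable-parameter counts per layer (offsets included)."""
    counts = {
        "V1": params.v1_kernels.size + params.v1_offsets.size,
        "MT": params.mt_w.size + params.mt_b.size,
        "PIVC": params.pivc_w.size + params.pivc_b.size,
        "MSTd": params.mstd_w.size + params.mstd_in_offsets.size,
        "output": params.out_w.size + params.out_b.size,
    }
    counts["total"] = sum(counts.values())
    return counts


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _im2col(visual: np.ndarray, arch: Architecture) -> np.ndarray:
    """(B, H, W, T) -> (B*oh*ow, kh*kw*T) patch matrix."""
    k, t = arch.kernel_size, arch.n_frames
    win = sliding_window_view(visual, (k, k, t), axis=(1, 2, 3))
    b, oh, ow = win.shape[0], win.shape[1], win.shape[2]
    return np.ascontiguousarray(win).reshape(b * oh * ow, k * k * t)


def _pool_forward(v1: np.ndarray, arch: Architecture):
    """Ceil-mode pooling.  Returns (pooled, argmax windows) for backward."""
    b, oh, ow, kk = v1.shape
    p = arch.pool
    ph, pw = arch.pooled, arch.pooled
    pad_h, pad_w = ph * p - oh, pw * p - ow
    fill = -np.inf if arch.pool_mode == "max" else np.nan
    x = np.pad(v1, ((0, 0), (0, pad_h), (0, pad_w), (0, 0)), constant_values=fill)
    x = x.reshape(b, ph, p, pw, p, kk).transpose(0, 1, 3, 2, 4, 5)
    x = np.ascontiguousarray(x).reshape(b, ph, pw, p * p, kk)
    if arch.pool_mode == "max":
        idx = np.argmax(x, axis=3)
        pooled = np.take_along_axis(x, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        return pooled, idx
    pooled = np.nanmean(x, axis=3)
    return pooled, None


def _pool_backward(d_pooled: np.ndarray, idx, v1_shape, arch: Architecture):
    b, oh, ow, kk = v1_shape
    p = arch.pool
    ph = pw = arch.pooled
    d = np.zeros((b, ph, pw, p * p, kk), dtype=d_pooled.dtype)
    if arch.pool_mode == "max":
        np.put_along_axis(d, idx[:, :, :, None, :], d_pooled[:, :, :, None, :], axis=3)
    else:
        # count of non-padded cells per window
        hv = np.minimum(p, oh - np.arange(ph) * p)
        wv = np.minimum(p, ow - np.arange(pw) * p)
        counts = (hv[:, None] * wv[None, :]).astype(d.dtype)
        d[:] = (d_pooled / counts[None, :, :, None])[:, :, :, None, :]
    d = d.reshape(b, ph, pw, p, p, kk).transpose(0, 1, 3, 2, 4, 5)
    d = d.reshape(b, ph * p, pw * p, kk)
    return d[:, :oh, :ow, :]


def _forward_full(params: NetworkParams, visual, vest, mstd_mask=None):
    """Batched forward pass keeping every intermediate needed for backprop."""
    a = params.arch
    visual = np.asarray(visual, dtype=np.float32)
    vest = np.asarray(vest, dtype=np.float32)
    squeeze = visual.ndim == 3
    if squeeze:
        visual = visual[None]
        vest = vest.reshape(1, -1)
    else:
        vest = vest.reshape(visual.shape[0], -1)
    if visual.shape[1:] != (a.image_size, a.image_size, a.n_frames):
        raise ValueError(
            f"visual input shape {visual.shape[1:]} does not match the "
            f"architecture ({a.image_size}, {a.image_size}, {a.n_frames})"
        )
    if vest.shape[1] != a.vest_in:
        raise ValueError(
            f"vestibular input has {vest.shape[1]} values; expected {a.vest_in}"
        )
    b = visual.shape[0]
    oh = ow = a.conv_out

    cols = _im2col(visual, a)
    kmat = params.v1_kernels.reshape(a.n_kernels, -1).T  # (kh*kw*T, K)
    v1_pre = (cols @ kmat).reshape(b, oh, ow, a.n_kernels) + params.v1_offsets
    v1 = np.maximum(v1_pre, 0.0)
    pooled, pool_idx = _pool_forward(v1, a)
    pooled_flat = pooled.reshape(b, -1)
    mt_pre = pooled_flat @ params.mt_w + params.mt_b
    mt = np.maximum(mt_pre, 0.0)
    pivc_pre = vest @ params.pivc_w + params.pivc_b
    pivc = np.maximum(pivc_pre, 0.0)
    z = np.concatenate([mt, pivc], axis=1) + params.mstd_in_offsets
    mstd_pre = z @ params.mstd_w
    mstd = np.maximum(mstd_pre, 0.0)
    if mstd_mask is not None:
        mstd = mstd * mstd_mask
    out = mstd @ params.out_w + params.out_b
    acts = LayerActivations(
        v1=v1, pooled=pooled, mt=mt, pivc=pivc, mstd=mstd,
        fusion=out[:, :N_AXES],
        scission=out[:, N_AXES : 2 * N_AXES],
        causal=_sigmoid(out[:, 2 * N_AXES :]),
    )
    cache = dict(
        cols=cols, v1=v1, pool_idx=pool_idx, pooled_flat=pooled_flat,
        mt=mt, pivc=pivc, vest=vest, z=z, mstd=mstd, b=b, squeeze=squeeze,
    )
    return acts, cache


def _squeeze_acts(acts: LayerActivations) -> LayerActivations:
    return LayerActivations(**{k: v[0] for k, v in acts.__dict__.items()})


def forward(params: NetworkParams, visual, vestibular) -> LayerActivations:
    """Run the network on one stimulus or a batch.

    ``visual``: array ``(H, W, 6)`` or ``(B, H, W, 6)``; ``vestibular``: a
    :class:`~mscausal.vestibular.VestibularActivity`, a ``(4, 32)`` array, or
    a batch ``(B, 128)``.  Single inputs return unbatched activations.
    """
    vest = getattr(vestibular, "activity", vestibular)
    acts, cache = _forward_full(params, visual, np.asarray(vest))
    return _squeeze_acts(acts) if cache["squeeze"] else acts


def lesion_forward(
    params: NetworkParams, visual, vestibular, silenced_mstd_units
) -> LayerActivations:
    """Forward pass with the listed MSTd units clamped to zero activity."""
    a = params.arch
    silenced = np.asarray(list(silenced_mstd_units), dtype=int)
    if silenced.size and (silenced.min() < 0 or silenced.max() >= a.mstd_units):
        raise ValueError(f"silenced unit indices out of range [0, {a.mstd_units})")
    mask = np.ones(a.mstd_units, dtype=np.float32)
    mask[silenced] = 0.0
    vest = getattr(vestibular, "activity", vestibular)
    acts, cache = _forward_full(params, visual, np.asarray(vest), mstd_mask=mask)
    return _squeeze_acts(acts) if cache["squeeze"] else acts


def backward(params: NetworkParams, cache, d_out: np.ndarray) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss given d(loss)/d(pre-activation outputs).

    ``d_out`` has shape ``(B, 12)``: the first 8 columns differentiate with
    respect to the linear regression outputs, the last 4 with respect to the
    causal pre-sigmoid activations.  Returns a dict keyed like
    ``NetworkParams.ARRAY_FIELDS``.
    """
    a = params.arch
    mstd, z, mt, pivc = cache["mstd"], cache["z"], cache["mt"], cache["pivc"]
    g = {}
    g["out_w"] = mstd.T @ d_out
    g["out_b"] = d_out.sum(axis=0)
    d_mstd = d_out @ params.out_w.T
    d_mstd_pre = d_mstd * (mstd > 0)
    g["mstd_w"] = z.T @ d_mstd_pre
    d_z = d_mstd_pre @ params.mstd_w.T
    g["mstd_in_offsets"] = d_z.sum(axis=0)
    d_mt = d_z[:, : a.mt_units] * (mt > 0)
    d_pivc = d_z[:, a.mt_units :] * (pivc > 0)
    g["pivc_w"] = cache["vest"].T @ d_pivc
    g["pivc_b"] = d_pivc.sum(axis=0)
    g["mt_w"] = cache["pooled_flat"].T @ d_mt
    g["mt_b"] = d_mt.sum(axis=0)
    d_pooled = (d_mt @ params.mt_w.T).reshape(-1, a.pooled, a.pooled, a.n_kernels)
    v1 = cache["v1"]
    d_v1 = _pool_backward(d_pooled, cache["pool_idx"], v1.shape, a)
    d_v1_pre = d_v1 * (v1 > 0)
    d_flat = d_v1_pre.reshape(-1, a.n_kernels)
    g["v1_offsets"] = d_flat.sum(axis=0)
    dk = cache["cols"].T @ d_flat  # (kh*kw*T, K)
    g["v1_kernels"] = dk.T.reshape(params.v1_kernels.shape)
    return g


def save_params(path, params: NetworkParams, meta: dict | None = None) -> None:
    """Save a checkpoint as an .npz archive plus a JSON sidecar."""
    path = str(path)
    np.savez(path if path.endswith(".npz") else path + ".npz", **params.arrays())
    side = dict(params.arch.__dict__)
    side["param_counts"] = count_parameters(params)
    if meta:
        side.update(meta)
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json", "w") as fh:
        json.dump(side, fh, indent=1, default=str)


def load_params(path) -> NetworkParams:
    """Load a checkpoint, validating the parameter-count invariants."""
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    with np.load(path) as data:
        arrays = {k: data[k] for k in NetworkParams.ARRAY_FIELDS}
    base = path[:-4]
    with open(base + ".json") as fh:
        side = json.load(fh)
    arch = Architecture(
        **{k: side[k] for k in Architecture.__dataclass_fields__ if k in side}
    )
    params = NetworkParams(arch=arch, **arrays)
    counts = count_parameters(params)
    stored = side.get("param_counts")
    if stored is not None and {k: int(v) for k, v in stored.items()} != counts:
        raise ValueError(f"checkpoint parameter counts {stored} != {counts}")
    expected = {
        "V1": arch.n_kernels * (arch.kernel_size**2 * arch.n_frames + 1),
        "MT": arch.mt_in * arch.mt_units + arch.mt_units,
        "PIVC": arch.vest_in * arch.pivc_units + arch.pivc_units,
        "MSTd": arch.mstd_in * arch.mstd_units + arch.mstd_in,
    }
    for layer, n in expected.items():
        if counts[layer] != n:
            raise ValueError(f"{layer} parameter count {counts[layer]} != {n}")
    return params
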