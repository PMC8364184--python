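"""Synthesis of visual motion stimuli with exact velocity ground truth.

Two stimulus families are provided:

* **Texture sequences** — a square patch cropped from a grayscale scene image
  is translated, zoomed and rotated over six frames.  Scene images are either
  procedurally generated 1/f noise (natural-image-like amplitude spectrum) or
  supplied by the user.
* **Dot kinematograms** — Gaussian dots on a midgray background, with a
  motion-coherence manipulation, used as test stimuli for trained networks.

Velocity conventions
--------------------
A :class:`MotionSpec` holds four velocity components in pixels/frame:
``vx`` (rightward), ``vy`` (downward), ``vz`` (radial; positive = expansion)
and ``vr`` (rotational; positive = clockwise with y pointing down).  Radial
and rotational flow speeds grow linearly with distance from the focal point;
the stated ``vz``/``vr`` is the image speed at *half* the distance from the
focal point to the image edge (midpoint-speed convention).  The focal point
is the stationary point of the combined flow field, so it is displaced from
the image center by the translational velocity.

Coordinates: image origin top-left, x rightward (columns), y downward (rows),
0-based pixel indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.fft import fft2, fftfreq, ifft2
from scipy import ndimage

logger = logging.getLogger(__name__)

N_FRAMES = 6
#: training velocities are drawn uniformly from +/- this bound (pixels/frame)
VELOCITY_RANGE = 4.0


@dataclass(frozen=True)
class MotionSpec:
    """Ground-truth velocity 4-vector in pixels/frame (midpoint convention)."""

    vx: float = 0.0
    vy: float = 0.0
    vz: float = 0.0
    vr: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.vx, self.vy, self.vz, self.vr], dtype=float)

    @staticmethod
    def from_array(v) -> "MotionSpec":
        vx, vy, vz, vr = np.asarray(v, dtype=float)
        return MotionSpec(vx, vy, vz, vr)

    def negated(self) -> "MotionSpec":
        return MotionSpec(-self.vx, -self.vy, -self.vz, -self.vr)


@dataclass(frozen=True)
class DotFieldSpec:
    """Random-dot kinematogram parameters.

    ``dot_diameter`` limits the rendered footprint of each Gaussian dot;
    ``dot_sd`` is the Gaussian SD.  ``coherence`` is the fraction of dots
    carrying the signal motion; the rest move at ``dot_speed`` in random
    directions redrawn every frame.
    """

    n_dots: int = 50
    dot_speed: float = 4.0
    coherence: float = 1.0
    dot_diameter: float = 6.0
    dot_sd: float = 1.2

    def __post_init__(self):
        if not 0.0 <= self.coherence <= 1.0:
            raise ValueError(f"coherence must be in [0, 1], got {self.coherence}")
        if self.n_dots < 1:
            raise ValueError("n_dots must be positive")


def generate_scene_image(seed: int, size: int = 128) -> np.ndarray:
    """Generate a grayscale scene image with a ~1/f amplitude spectrum.

    The image is synthesized in the Fourier domain (white Gaussian phase
    spectrum, amplitude scaled by 1/f) and is therefore periodic: it tiles
    seamlessly, which lets motion rendering wrap content around the edges.
    Intensities are rescaled to [-1, 1].  Deterministic per ``seed``.
    """
    if size < 16:
        raise ValueError(f"scene image size must be >= 16, got {size}")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((size, size))
    fx = fftfreq(size)[None, :]
    fy = fftfreq(size)[:, None]
    f = np.hypot(fx, fy)
    f[0, 0] = np.inf  # zero out the DC component
    spectrum = fft2(white) / f
    img = np.real(ifft2(spectrum))
    lo, hi = img.min(), img.max()
    img = 2.0 * (img - lo) / (hi - lo) - 1.0
    return img.astype(np.float32)


def _flow_params(motion: MotionSpec, out_size: int):
    """Per-frame affine flow: scale factor, rotation angle, translation."""
    half_radius = out_size / 4.0  # midpoint between focal point and edge
    k = motion.vz / half_radius  # relative expansion per frame
    omega = motion.vr / half_radius  # radians per frame
    return 1.0 + k, omega, np.array([motion.vx, motion.vy])


def _inverse_affine(scale, omega, trans):
    """Inverse of p -> c + scale*R(omega) @ (p - c) + trans, about origin c."""
    c, s = np.cos(omega), np.sin(omega)
    rot = np.array([[c, -s], [s, c]])
    a = scale * rot
    a_inv = np.linalg.inv(a)
    return a_inv, -a_inv @ trans


def render_texture_sequence(
    image: np.ndarray,
    motion: MotionSpec,
    out_size: int = 64,
    wrap: bool = True,
) -> np.ndarray:
    """Render a six-frame motion sequence from a scene image.

    The patch content moves under the affine flow field
    ``v(p) = (vx, vy) + k (p - c) + omega x (p - c)`` where ``c`` is the
    patch center, ``k = vz / (out_size/4)`` and ``omega = vr / (out_size/4)``
    (midpoint-speed convention).  Each frame is sampled from the source image
    by composing the inverse per-frame affine map, with bilinear
    interpolation; under strong contraction the source is pre-blurred
    (mip levels) to limit aliasing.

    With ``wrap=True`` (the default, correct for generated periodic scenes)
    sampling wraps around the source.  With ``wrap=False`` (user-supplied
    photographs) the source must be large enough that every sampled
    coordinate stays inside it, otherwise a ``ValueError`` explains the
    required size.

    Returns an array of shape ``(out_size, out_size, 6)`` in [-1, 1].
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2:
        raise ValueError("scene image must be 2-D grayscale")
    if image.std() == 0:
        logger.warning("rendering from a constant-intensity scene image")

    scale, omega, trans = _flow_params(motion, out_size)
    if scale <= 0:
        raise ValueError(f"contraction too strong: per-frame scale {scale} <= 0")
    a_inv, b_inv = _inverse_affine(scale, omega, trans)

    src_h, src_w = image.shape
    c_src = np.array([(src_w - 1) / 2.0, (src_h - 1) / 2.0])
    # output pixel grid centered on the source center
    xs = np.arange(out_size) - (out_size - 1) / 2.0
    gx, gy = np.meshgrid(xs, xs)  # gx: x offsets, gy: y offsets
    pts = np.stack([gx.ravel(), gy.ravel()])  # (2, out_size**2), about center

    mips: dict[int, np.ndarray] = {0: image}
    frames = np.empty((out_size, out_size, N_FRAMES), dtype=np.float32)
    cur = pts.copy()
    for t in range(N_FRAMES):
        if t > 0:
            cur = a_inv @ cur + b_inv[:, None]
        # minification of this frame relative to the source sets the blur level
        minif = max(scale ** -t, 1.0)
        level = min(int(np.round(np.log2(minif))), 5)
        if level not in mips:
            mips[level] = ndimage.gaussian_filter(
                image, sigma=0.6 * (2**level), mode="wrap"
            )
        coords = cur + c_src[:, None]  # (x, y) source coordinates
        if not wrap:
            lo = coords.min(axis=1)
            hi = coords.max(axis=1)
            if lo.min() < 0 or hi[0] > src_w - 1 or hi[1] > src_h - 1:
                need = int(np.ceil(2 * np.abs(cur).max() + 2))
                raise ValueError(
                    f"scene image of size {image.shape} is too small for a "
                    f"{out_size}px crop under motion {motion}; provide an image "
                    f"of at least {need}x{need} pixels (or use wrap=True for "
                    "periodic scenes)"
                )
        frame = ndimage.map_coordinates(
            mips[level],
            [coords[1], coords[0]],  # row (y), col (x)
            order=1,
            mode="grid-wrap" if wrap else "nearest",
        )
        frames[:, :, t] = frame.reshape(out_size, out_size)
    return np.clip(frames, -1.0, 1.0)


def _render_dots(frame_shape, positions, polarity, diameter, sd):
    """Draw Gaussian dots at continuous positions onto a zero background."""
    h, w = frame_shape
    img = np.zeros((h, w), dtype=np.float32)
    r = diameter / 2.0
    ri = int(np.ceil(r))
    for (px, py), pol in zip(positions, polarity):
        x0, x1 = int(np.floor(px - ri)), int(np.ceil(px + ri))
        y0, y1 = int(np.floor(py - ri)), int(np.ceil(py + ri))
        xs = np.arange(max(x0, 0), min(x1 + 1, w))
        ys = np.arange(max(y0, 0), min(y1 + 1, h))
        if xs.size == 0 or ys.size == 0:
            continue
        dx = xs[None, :] - px
        dy = ys[:, None] - py
        d2 = dx**2 + dy**2
        g = np.exp(-d2 / (2.0 * sd**2))
        g[d2 > r**2] = 0.0
        img[np.ix_(ys, xs)] += pol * g
    return np.clip(img, -1.0, 1.0)


def render_dot_sequence(
    spec: DotFieldSpec,
    motion: MotionSpec,
    seed,
    out_size: int = 64,
    return_positions: bool = False,
):
    """Render a six-frame random-dot kinematogram.

    Coherent dots follow the :class:`MotionSpec` flow field (radial and
    rotational speed scale linearly with distance from the focal point);
    incoherent dots move at ``spec.dot_speed`` in directions redrawn each
    frame.  Dots leaving the image, or reaching the focal point under
    contraction, are repositioned uniformly at random, so the dot count is
    conserved.  ``seed`` may be an int or a :class:`numpy.random.Generator`.

    With ``return_positions=True`` also returns the per-frame dot centers
    (array ``(6, n_dots, 2)``, columns x, y) and the coherent-dot mask.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = spec.n_dots
    pos = rng.uniform(0, out_size, size=(n, 2))  # columns: x, y
    polarity = rng.choice([-1.0, 1.0], size=n)
    n_coh = int(round(spec.coherence * n))
    is_coh = np.zeros(n, dtype=bool)
    is_coh[rng.permutation(n)[:n_coh]] = True

    scale, omega, trans = _flow_params(motion, out_size)
    c = np.array([(out_size - 1) / 2.0, (out_size - 1) / 2.0])
    cth, sth = np.cos(omega), np.sin(omega)
    rot = np.array([[cth, -sth], [sth, cth]])
    a = scale * rot
    # focal point: fixed point of p -> c + A(p - c) + t (when it exists)
    focal = None
    if not np.allclose(a, np.eye(2)):
        focal = c + np.linalg.solve(np.eye(2) - a, trans)

    frames = np.empty((out_size, out_size, N_FRAMES), dtype=np.float32)
    trajectory = np.empty((N_FRAMES, n, 2))
    for t in range(N_FRAMES):
        frames[:, :, t] = _render_dots(
            (out_size, out_size), pos, polarity, spec.dot_diameter, spec.dot_sd
        )
        trajectory[t] = pos
        if t == N_FRAMES - 1:
            break
        new = pos.copy()
        if is_coh.any():
            p = pos[is_coh]
            new[is_coh] = c + (a @ (p - c).T).T + trans
        if (~is_coh).any():
            theta = rng.uniform(0, 2 * np.pi, size=(~is_coh).sum())
            step = spec.dot_speed * np.stack([np.cos(theta), np.sin(theta)], axis=1)
            new[~is_coh] = pos[~is_coh] + step
        out = (new < 0).any(axis=1) | (new >= out_size).any(axis=1)
        if scale < 1.0 and focal is not None:
            out |= np.hypot(*(new - focal).T) < 0.5
        if out.any():
            new[out] = rng.uniform(0, out_size, size=(out.sum(), 2))
        pos = new
    if return_positions:
        return frames, trajectory, is_coh
    return frames


def sample_motion_pair(rng: np.random.Generator) -> tuple[MotionSpec, MotionSpec]:
    """Draw an independent (visual, vestibular) velocity pair.

    All eight components are i.i.d. uniform on +/- ``VELOCITY_RANGE``
    pixels/frame, matching the training distribution.
    """
    v = rng.uniform(-VELOCITY_RANGE, VELOCITY_RANGE, size=8)
    return MotionSpec.from_array(v[:4]), MotionSpec.from_array(v[4:])


def radial_amplitude_slope(image: np.ndarray) -> float:
    """Log-log slope of the radially averaged amplitude spectrum.

    Natural images (and the generated scenes) have slopes near -1.
    """
    img = np.asarray(image, dtype=float)
    amp = np.abs(fft2(img - img.mean()))
    size = img.shape[0]
    fx = fftfreq(size)[None, :]
    fy = fftfreq(img.shape[0])[:, None]
    f = np.hypot(fx, fy).ravel()
    a = amp.ravel()
    mask = (f > 0) & (f <= 0.5)
    bins = np.logspace(np.log10(f[mask].min()), np.log10(0.5), 20)
    idx = np.digitize(f[mask], bins)
    fm, am = [], []
    for i in range(1, len(bins)):
        sel = idx == i
        if sel.sum() >= 2:
            fm.append(f[mask][sel].mean())
            am.append(a[mask][sel].mean())
    slope = np.polyfit(np.log(fm), np.log(am), 1)[0]
    return float(slope)
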