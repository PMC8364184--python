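"""Gaussian population-code encoding of vestibular velocity signals.

Each of the four velocity axes (x, y, z, r) is represented by 32 units with
preferred velocities evenly spaced on [-8, 8].  The noiseless response of
unit *i* on an axis with stimulus velocity ``mu`` and tuning width ``sigma``
is the unit-peak Gaussian ``exp(-(x_i - mu)^2 / (2 sigma^2))``.  Gaussian
noise (SD 0.3 during training) is added on every presentation; the tuning
width is the reliability handle used by the behavioral experiments (narrow
sigma = reliable vestibular signal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .stimuli import MotionSpec

N_UNITS = 32
GRID_HALF_RANGE = 8.0
#: preferred velocities: 32 evenly spaced values between +/-8
PREFERRED_VELOCITIES = np.linspace(-GRID_HALF_RANGE, GRID_HALF_RANGE, N_UNITS)
SIGMA_RANGE = (1.0, 8.0)
TRAIN_NOISE_SD = 0.3


@dataclass
class VestibularActivity:
    """Population activity for the four axes (shape ``(4, 32)``)."""

    activity: np.ndarray
    sigma: np.ndarray  # tuning width per axis
    preferred_velocities: np.ndarray = None

    def __post_init__(self):
        if self.preferred_velocities is None:
            self.preferred_velocities = PREFERRED_VELOCITIES

    def flat(self) -> np.ndarray:
        """The 128-value input vector fed to the network."""
        return self.activity.reshape(-1)


def preferred_grid(n_units: int = N_UNITS) -> np.ndarray:
    """Evenly spaced preferred velocities on [-8, 8]."""
    return np.linspace(-GRID_HALF_RANGE, GRID_HALF_RANGE, n_units)


def tuning_profile(mu: float, sigma: float, n_units: int = N_UNITS) -> np.ndarray:
    """Noiseless Gaussian population profile, peak value 1 at x = mu."""
    grid = PREFERRED_VELOCITIES if n_units == N_UNITS else preferred_grid(n_units)
    return np.exp(-((grid - mu) ** 2) / (2.0 * sigma**2))


def encode(
    motion: MotionSpec,
    sigma_per_axis,
    noise_sd: float = TRAIN_NOISE_SD,
    rng: np.random.Generator | None = None,
    n_units: int = N_UNITS,
) -> VestibularActivity:
    """Encode a velocity 4-vector as four noisy Gaussian population codes.

    ``sigma_per_axis`` may be a scalar or a length-4 sequence, each in
    [1, 8].  Fresh noise is drawn on every call.  Velocities outside the
    +/-8 preferred-velocity grid trigger a warning (the code saturates at
    the grid edge) but are encoded anyway.
    """
    sigma = np.broadcast_to(np.asarray(sigma_per_axis, dtype=float), (4,)).copy()
    if (sigma < SIGMA_RANGE[0]).any() or (sigma > SIGMA_RANGE[1]).any():
        raise ValueError(f"sigma must be within {SIGMA_RANGE}, got {sigma}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    mu = motion.as_array()
    if (np.abs(mu) > GRID_HALF_RANGE).any():
        warnings.warn(
            f"velocity {mu} exceeds the +/-{GRID_HALF_RANGE} preferred-velocity "
            "grid; the population code saturates at the edge",
            stacklevel=2,
        )
    grid = preferred_grid(n_units)
    act = np.exp(
        -((grid[None, :] - mu[:, None]) ** 2) / (2.0 * sigma[:, None] ** 2)
    )
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        act = act + rng.normal(0.0, noise_sd, size=act.shape)
    return VestibularActivity(activity=act, sigma=sigma, preferred_velocities=grid)


def sample_sigma(rng: np.random.Generator, n_axes: int = 4) -> np.ndarray:
    """Draw per-axis tuning widths uniformly from [1, 8]."""
    return rng.uniform(*SIGMA_RANGE, size=n_axes)


def population_vector(activity: np.ndarray) -> np.ndarray:
    """Activity-weighted mean preferred velocity per axis.

    A simple decoder used for sanity checks and for summarizing the
    vestibular input in the decision-bias analysis.  Negative activities
    (possible after additive noise) are clipped at zero before weighting.
    """
    act = np.clip(np.atleast_2d(activity), 0.0, None)
    grid = preferred_grid(act.shape[-1])
    w = act.sum(axis=-1)
    w[w == 0] = np.nan
    return (act @ grid) / w
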