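"""Bootstrap confidence intervals and correlation helpers."""

from __future__ import annotations

import numpy as np
from scipy import stats

N_BOOT = 50_000


def bootstrap_ci(
    values,
    n_boot: int = N_BOOT,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    statistic=np.mean,
) -> tuple[float, float]:
    """Percentile bootstrap CI for a statistic of a 1-D sample."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        return (np.nan, np.nan)
    if rng is None:
        rng = np.random.default_rng()
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    if statistic is np.mean:
        boot = values[idx].mean(axis=1)
    else:
        boot = np.array([statistic(values[i]) for i in idx])
    lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def bootstrap_corr_ci(
    x,
    y,
    n_boot: int = N_BOOT,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for a Pearson correlation (paired resampling)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        return (np.nan, np.nan)
    if rng is None:
        rng = np.random.default_rng()
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    xs, ys = x[idx], y[idx]
    xs = xs - xs.mean(axis=1, keepdims=True)
    ys = ys - ys.mean(axis=1, keepdims=True)
    denom = np.sqrt((xs**2).sum(axis=1) * (ys**2).sum(axis=1))
    denom[denom == 0] = np.nan
    r = (xs * ys).sum(axis=1) / denom
    lo, hi = np.nanpercentile(r, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def pearson(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p-value; (nan, nan) on degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return (np.nan, np.nan)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def roc_area(pos, neg) -> float:
    """Area under the ROC curve separating two response samples.

    Equivalent to the Mann-Whitney U statistic scaled to [0, 1]: the
    probability that a random draw from ``pos`` exceeds one from ``neg``,
    counting ties as one half.
    """
    pos = np.asarray(pos, dtype=float)[:, None]
    neg = np.asarray(neg, dtype=float)[None, :]
    return float(np.mean((pos > neg) + 0.5 * (pos == neg)))
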