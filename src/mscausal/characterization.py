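"""Characterization of multisensory (MSTd-layer) units in a trained network.

The analyses mirror the standard single-unit toolkit of the visual-vestibular
integration literature:

* heading tuning curves under vestibular-only, visual-only and combined
  stimulation, with sinusoidal fits to extract preferred direction and
  tuning amplitude;
* congruent / opposite / intermediate classification via the congruency
  index (product of the per-cue Pearson correlations between response and
  heading over a fine sweep around straight ahead);
* neurometric thresholds from ROC analysis of a unit versus its anti-unit,
  compared with the maximum-likelihood (optimal integration) prediction
  ``sigma_pred^2 = sigma_vest^2 sigma_vis^2 / (sigma_vest^2 + sigma_vis^2)``;
* connection-weight summaries, artificial lesion decoding, and correlations
  between cue-sensitivity asymmetry and cross-task weights.

Heading direction combines motion-in-depth and lateral velocity: 0 deg is
straight-ahead motion-in-depth and 90 deg is motion directly to the right.
In single-cue conditions the excluded cue is input as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from . import network, stimuli, vestibular
from .network import NetworkParams
from .stats import pearson, roc_area
from .stimuli import DotFieldSpec, MotionSpec

AXES = "xyzr"


# ---------------------------------------------------------------------------
# polar decoding and heading geometry


def decode_polar(vx, vy):
    """Velocity components -> (speed, direction).

    Direction uses ``arctan2(vx, vy)`` (note the argument order), so 0 deg
    lies on the +y axis of the pair and angles are in (-180, 180].  For the
    (x, z) pair this makes 0 deg straight ahead and +90 deg rightward.
    The zero vector decodes to (0, 0) by convention.
    """
    vx = np.asarray(vx, dtype=float)
    vy = np.asarray(vy, dtype=float)
    rho = np.hypot(vx, vy)
    phi = np.degrees(np.arctan2(vx, vy))
    return rho, phi


def heading_to_motion(theta_deg: float, speed: float = 4.0) -> MotionSpec:
    """Heading angle -> velocity 4-vector.

    0 deg is straight-ahead motion-in-depth (pure vz), 90 deg is motion
    directly to the right (pure vx).
    """
    th = np.radians(theta_deg)
    return MotionSpec(vx=speed * np.sin(th), vy=0.0, vz=speed * np.cos(th), vr=0.0)


# ---------------------------------------------------------------------------
# stimulus batteries


@dataclass
class CharacterizationConfig:
    """Shared measurement parameters for the unit-level analyses."""

    speed: float = 4.0  # cue speed, pixels/frame
    sigma: float = 6.0  # vestibular tuning width during testing
    noise_sd: float = 0.3  # vestibular additive noise per trial
    dots: DotFieldSpec = field(default_factory=DotFieldSpec)
    n_trials_tuning: int = 64  # repeats for tuning curves (replicability)
    n_trials_roc: int = 100  # repeats per direction for ROC analysis
    broad_directions: int = 10  # evenly spaced over [0, 360)
    fine_inner: float = 2.0  # inner magnitude of the log-spaced sweep (deg)
    fine_outer: float = 36.0  # outer magnitude (deg)
    n_speeds: int = 7  # speed sweep for per-axis classification
    map_steps: int = 35  # heading grid for the activity map (+/-90 deg)
    lesion_steps: int = 31  # velocity grid for lesion decoding (+/-4)
    map_trials: int = 8
    batch: int = 256


def broad_directions(n: int = 10) -> np.ndarray:
    """Evenly spaced headings from 0 deg, full circle, endpoint excluded."""
    return np.arange(n) * (360.0 / n)


def fine_directions(inner: float = 2.0, outer: float = 36.0, n: int = 10) -> np.ndarray:
    """Log-spaced discrimination sweep: n/2 magnitudes mirrored about zero."""
    mags = np.geomspace(inner, outer, n // 2)
    return np.sort(np.concatenate([-mags, mags]))


def _batched_forward(params, visual, vest, batch, lesion_mask=None):
    outs = []
    for lo in range(0, len(visual), batch):
        acts, _ = network._forward_full(
            params, visual[lo : lo + batch], vest[lo : lo + batch],
            mstd_mask=lesion_mask,
        )
        outs.append(acts)
    return LayerStack(
        mstd=np.concatenate([a.mstd for a in outs]),
        fusion=np.concatenate([a.fusion for a in outs]),
        scission=np.concatenate([a.scission for a in outs]),
        causal=np.concatenate([a.causal for a in outs]),
    )


@dataclass
class LayerStack:
    mstd: np.ndarray
    fusion: np.ndarray
    scission: np.ndarray
    causal: np.ndarray


def _cue_inputs(motion_list, cue, cfg: CharacterizationConfig, rng, arch):
    """Render visual frames and vestibular vectors for a list of motions.

    ``cue`` selects which stream carries signal; the excluded cue is input
    as zeros.
    """
    n = len(motion_list)
    size = arch.image_size
    visual = np.zeros((n, size, size, arch.n_frames), dtype=np.float32)
    vest = np.zeros((n, network.N_AXES * arch.vest_units), dtype=np.float32)
    for i, m in enumerate(motion_list):
        if cue in ("visual", "combined"):
            visual[i] = stimuli.render_dot_sequence(cfg.dots, m, rng, out_size=size)
        if cue in ("vestibular", "combined"):
            vest[i] = vestibular.encode(
                m, cfg.sigma, noise_sd=cfg.noise_sd, rng=rng,
                n_units=arch.vest_units,
            ).flat()
    return visual, vest


@dataclass
class TuningCurve:
    """Per-direction MSTd responses for one cue condition."""

    cue: str
    directions: np.ndarray  # (n_dir,)
    responses: np.ndarray  # (n_dir, n_trials, n_units)

    @property
    def mean(self) -> np.ndarray:
        return self.responses.mean(axis=1)

    @property
    def sd(self) -> np.ndarray:
        return self.responses.std(axis=1, ddof=1)


def measure_tuning(
    params: NetworkParams,
    cue: str,
    directions,
    n_trials: int,
    rng: np.random.Generator,
    cfg: CharacterizationConfig | None = None,
) -> TuningCurve:
    """Measure MSTd responses to headings under one cue condition.

    Trial-to-trial variability comes from dot placement seeds (visual) and
    additive vestibular noise.  Responses are averaged downstream; the raw
    per-trial responses are kept for ROC analysis.
    """
    if cue not in ("vestibular", "visual", "combined"):
        raise ValueError(f"unknown cue condition {cue!r}")
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2 (response SD is undefined)")
    cfg = cfg or CharacterizationConfig()
    directions = np.asarray(directions, dtype=float)
    motions = [heading_to_motion(d, cfg.speed) for d in directions]
    arch = params.arch
    resp = np.empty((len(directions), n_trials, arch.mstd_units), dtype=np.float32)
    for t in range(n_trials):
        visual, vest = _cue_inputs(motions, cue, cfg, rng, arch)
        stack = _batched_forward(params, visual, vest, cfg.batch)
        resp[:, t, :] = stack.mstd
    return TuningCurve(cue=cue, directions=directions, responses=resp)


# ---------------------------------------------------------------------------
# sinusoidal tuning fits


def fit_sinusoid(directions_deg, responses) -> tuple[float, float, float]:
    """Least-squares fit of ``y = a sin(x - x_pref) + b`` (360-deg period).

    Returns ``(a, x_pref_deg, b)`` with ``a >= 0`` (the sign is absorbed
    into the phase).  A constant response gives ``a = 0`` and ``x_pref``
    NaN (undefined).
    """
    x = np.radians(np.asarray(directions_deg, dtype=float))
    y = np.asarray(responses, dtype=float)
    if len(np.unique(np.round(x, 9))) < 4:
        raise ValueError("need >= 4 distinct directions for a sinusoid fit")
    design = np.column_stack([np.sin(x), np.cos(x), np.ones_like(x)])
    (A, B, b), *_ = np.linalg.lstsq(design, y, rcond=None)
    a = float(np.hypot(A, B))
    if a < 1e-12:
        return 0.0, np.nan, float(b)
    # a sin(x - p) = a cos(p) sin(x) - a sin(p) cos(x)
    x_pref = float(np.degrees(np.arctan2(-B, A))) % 360.0
    return a, x_pref, float(b)


def fit_all_sinusoids(curve: TuningCurve) -> pd.DataFrame:
    """Sinusoid fits for every unit of a tuning curve."""
    rows = []
    mean = curve.mean
    for u in range(mean.shape[1]):
        a, x_pref, b = fit_sinusoid(curve.directions, mean[:, u])
        rows.append({"unit": u, "cue": curve.cue, "amplitude": a,
                     "x_pref": x_pref, "offset": b})
    return pd.DataFrame(rows)


def circular_difference(a_deg, b_deg) -> np.ndarray:
    """Absolute circular difference in degrees, in [0, 180]."""
    d = np.abs(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)) % 360.0
    return np.minimum(d, 360.0 - d)


def preferred_difference_histogram(
    fits_visual: pd.DataFrame,
    fits_vestibular: pd.DataFrame,
    bin_width: float = 30.0,
) -> pd.DataFrame:
    """Histogram of |preferred visual - vestibular| direction differences.

    Only strongly tuned units are included: fitted amplitude above the
    median across all units, required for both cues.  Returns the bin edges
    and counts (bins span [0, 180]).
    """
    vis = fits_visual.set_index("unit")
    ves = fits_vestibular.set_index("unit")
    strong = (vis["amplitude"] > vis["amplitude"].median()) & (
        ves["amplitude"] > ves["amplitude"].median()
    )
    ok = strong & vis["x_pref"].notna() & ves["x_pref"].notna()
    delta = circular_difference(vis.loc[ok, "x_pref"], ves.loc[ok, "x_pref"])
    edges = np.arange(0.0, 180.0 + bin_width, bin_width)
    counts, _ = np.histogram(delta, bins=edges)
    return pd.DataFrame(
        {"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts}
    ).assign(n_units=int(ok.sum()))


# ---------------------------------------------------------------------------
# congruency classification


def classify_from_correlations(r1, p1, r2, p2, alpha: float = 0.05) -> str:
    ci = r1 * r2
    if np.isnan(ci):
        return "intermediate"
    if p1 < alpha and p2 < alpha:
        return "congruent" if ci > 0 else "opposite"
    return "intermediate"


def congruency_index(
    vest_curve: TuningCurve, vis_curve: TuningCurve, alpha: float = 0.05
) -> pd.DataFrame:
    """Congruency index per unit over the fine discrimination sweep.

    For each single-cue condition the Pearson correlation between per-trial
    response and heading is computed; the congruency index is their product.
    Units with both correlations significant are classed congruent (CI > 0)
    or opposite (CI < 0); all others are intermediate.  Zero-variance
    responses give an intermediate class with ``degenerate=True``.
    """
    rows = []
    for u in range(vest_curve.responses.shape[2]):
        out = {"unit": u}
        rs = {}
        degenerate = False
        for name, curve in (("vestibular", vest_curve), ("visual", vis_curve)):
            resp = curve.responses[:, :, u]
            x = np.repeat(curve.directions, resp.shape[1])
            r, p = pearson(x, resp.ravel())
            if np.isnan(r):
                degenerate = True
            rs[name] = (r, p)
            out[f"r_{name}"], out[f"p_{name}"] = r, p
        out["congruency_index"] = rs["vestibular"][0] * rs["visual"][0]
        out["unit_class"] = classify_from_correlations(
            *rs["vestibular"], *rs["visual"], alpha=alpha
        )
        out["degenerate"] = degenerate
        rows.append(out)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# neurometric thresholds and optimal integration


def predicted_threshold(sigma_vest: float, sigma_vis: float) -> float:
    """Maximum-likelihood combined-cue threshold from single-cue thresholds."""
    v2, w2 = sigma_vest**2, sigma_vis**2
    return float(np.sqrt(v2 * w2 / (v2 + w2)))


def _cumulative_gaussian(x, mu, sigma):
    from scipy.special import ndtr

    return ndtr((x - mu) / sigma)


def fit_neurometric(directions, roc_areas) -> tuple[float, float, bool]:
    """Fit a cumulative Gaussian to ROC area vs signed direction.

    Returns ``(mu, sigma, converged)``; the threshold is the fitted SD (the
    84% point of the neurometric function).
    """
    x = np.asarray(directions, dtype=float)
    y = np.asarray(roc_areas, dtype=float)
    span = x.max() - x.min()
    try:
        popt, _ = optimize.curve_fit(
            _cumulative_gaussian, x, y,
            p0=[0.0, span / 4],
            bounds=([x.min(), 1e-3], [x.max(), 50 * span]),
            maxfev=5000,
        )
    except RuntimeError:
        return np.nan, np.nan, False
    mu, sigma = popt
    converged = sigma < 10 * span  # saturated fits are unresolvable
    return float(mu), float(sigma), bool(converged)


def neurometric_curve(curve: TuningCurve) -> np.ndarray:
    """ROC area per (signed direction, unit): unit versus its anti-unit.

    The anti-unit response distribution at +theta is the unit's own
    distribution at -theta, so the area at direction theta measures how
    separable the +theta and -theta responses are.
    """
    dirs = curve.directions
    n_dir, _, n_units = curve.responses.shape
    areas = np.full((n_dir, n_units), np.nan)
    for i, d in enumerate(dirs):
        j = int(np.argmin(np.abs(dirs + d)))
        for u in range(n_units):
            areas[i, u] = roc_area(
                curve.responses[i, :, u], curve.responses[j, :, u]
            )
    return areas


def neurometric_thresholds(
    curves: dict[str, TuningCurve],
) -> pd.DataFrame:
    """Per-unit neurometric thresholds for each cue condition.

    ``curves`` maps condition name (vestibular / visual / combined) to a
    fine-sweep tuning curve.  Adds the optimal-integration prediction and
    the combined/predicted ratio.  Units whose sigmoid fit does not
    converge get NaN thresholds (untuned units are unresolvable).
    """
    n_units = next(iter(curves.values())).responses.shape[2]
    thr = {}
    for cond, curve in curves.items():
        areas = neurometric_curve(curve)
        vals = np.full(n_units, np.nan)
        for u in range(n_units):
            _, sigma, ok = fit_neurometric(curve.directions, areas[:, u])
            if ok:
                vals[u] = sigma
        thr[cond] = vals
    df = pd.DataFrame({"unit": np.arange(n_units)})
    for cond, vals in thr.items():
        df[f"sigma_{cond}"] = vals
    if {"vestibular", "visual"} <= set(thr):
        df["sigma_predicted"] = [
            predicted_threshold(v, w) if np.isfinite(v) and np.isfinite(w) else np.nan
            for v, w in zip(thr["vestibular"], thr["visual"])
        ]
        if "combined" in thr:
            df["threshold_ratio"] = df["sigma_combined"] / df["sigma_predicted"]
    return df


# ---------------------------------------------------------------------------
# per-axis speed-based classification


def speed_sweep(
    params: NetworkParams,
    axis: int,
    cue: str,
    speeds,
    n_trials: int,
    rng: np.random.Generator,
    cfg: CharacterizationConfig,
) -> np.ndarray:
    """MSTd responses (n_speeds, n_trials, n_units) to motion along one axis."""
    motions = []
    for v in speeds:
        vec = np.zeros(4)
        vec[axis] = v
        motions.append(MotionSpec.from_array(vec))
    arch = params.arch
    resp = np.empty((len(speeds), n_trials, arch.mstd_units), dtype=np.float32)
    for t in range(n_trials):
        visual, vest = _cue_inputs(motions, cue, cfg, rng, arch)
        stack = _batched_forward(params, visual, vest, cfg.batch)
        resp[:, t, :] = stack.mstd
    return resp


def speed_congruency_classification(
    params: NetworkParams,
    axis: int,
    rng: np.random.Generator,
    cfg: CharacterizationConfig | None = None,
    n_trials: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify units per velocity axis from speed sweeps of each cue.

    Seven evenly spaced speeds between +/-4 pixels/frame are presented per
    cue in isolation; the per-cue Pearson correlations between response and
    speed are multiplied and used exactly like the congruency index.  Also
    records each unit's preferred cue velocity (speed of maximal mean
    response per cue), used by the weight-binning and asymmetry analyses.
    """
    cfg = cfg or CharacterizationConfig()
    n_trials = n_trials or cfg.n_trials_tuning
    speeds = np.linspace(-stimuli.VELOCITY_RANGE, stimuli.VELOCITY_RANGE, cfg.n_speeds)
    rows = []
    resp = {
        cue: speed_sweep(params, axis, cue, speeds, n_trials, rng, cfg)
        for cue in ("vestibular", "visual")
    }
    for u in range(params.arch.mstd_units):
        out = {"unit": u, "axis": AXES[axis]}
        rs = {}
        for cue in ("vestibular", "visual"):
            r_u = resp[cue][:, :, u]
            r, p = pearson(np.repeat(speeds, r_u.shape[1]), r_u.ravel())
            rs[cue] = (r, p)
            out[f"r_{cue}"], out[f"p_{cue}"] = r, p
            mean = r_u.mean(axis=1)
            out[f"pref_speed_{cue}"] = (
                float(speeds[np.argmax(mean)]) if mean.std() > 0 else np.nan
            )
        out["congruency_index"] = rs["vestibular"][0] * rs["visual"][0]
        out["unit_class"] = classify_from_correlations(
            *rs["vestibular"], *rs["visual"], alpha=alpha
        )
        rows.append(out)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# population activity map


def congruent_opposite_activity_map(
    params: NetworkParams,
    classes: pd.DataFrame,
    rng: np.random.Generator,
    cfg: CharacterizationConfig | None = None,
) -> dict:
    """Mean congruent minus mean opposite response over a heading grid.

    The grid spans all combinations of visual and vestibular headings in
    +/-90 deg (``cfg.map_steps`` each).  ``classes`` must be a heading-based
    congruency table with a ``unit_class`` column; an empty class is an
    error.
    """
    cfg = cfg or CharacterizationConfig()
    cong = classes.loc[classes["unit_class"] == "congruent", "unit"].to_numpy()
    oppo = classes.loc[classes["unit_class"] == "opposite", "unit"].to_numpy()
    for name, members in (("congruent", cong), ("opposite", oppo)):
        if members.size == 0:
            raise ValueError(f"no units classified as {name}; cannot build map")
    headings = np.linspace(-90.0, 90.0, cfg.map_steps)
    arch = params.arch
    size = arch.image_size
    n_h = len(headings)
    acc = np.zeros((n_h, n_h, arch.mstd_units))
    for _ in range(cfg.map_trials):
        # render one visual stimulus per visual heading, reuse across
        # vestibular headings within the trial
        visual_bank = np.stack(
            [
                stimuli.render_dot_sequence(
                    cfg.dots, heading_to_motion(h, cfg.speed), rng, out_size=size
                )
                for h in headings
            ]
        )
        vest_bank = np.stack(
            [
                vestibular.encode(
                    heading_to_motion(h, cfg.speed), cfg.sigma, cfg.noise_sd, rng,
                    n_units=arch.vest_units,
                ).flat()
                for h in headings
            ]
        )
        vi = np.repeat(np.arange(n_h), n_h)
        ve = np.tile(np.arange(n_h), n_h)
        stack = _batched_forward(
            params, visual_bank[vi], vest_bank[ve], cfg.batch
        )
        acc += stack.mstd.reshape(n_h, n_h, -1)
    acc /= cfg.map_trials
    diff = acc[:, :, cong].mean(axis=2) - acc[:, :, oppo].mean(axis=2)
    return {
        "visual_headings": headings,
        "vestibular_headings": headings,
        "difference_map": diff,
        "n_congruent": cong.size,
        "n_opposite": oppo.size,
    }


# ---------------------------------------------------------------------------
# weight summaries


def weight_summaries(params: NetworkParams, classes: pd.DataFrame) -> dict:
    """Connection-weight summaries for congruent vs opposite units.

    ``classes`` is a per-axis classification table (from
    :func:`speed_congruency_classification`, possibly concatenated over
    axes).  For each classified (unit, axis) pair the relevant output
    weights are the unit's weights to that axis's fusion, scission and
    causal output; results are pooled across axes.

    Returns per-(unit, axis) rows plus class-level means: signed weight to
    the causal units, absolute weight to fusion and scission units, and
    absolute weights binned by preferred cue velocity.
    """
    rows = []
    for _, rec in classes.iterrows():
        if rec["unit_class"] not in ("congruent", "opposite"):
            continue
        u = int(rec["unit"])
        ax = AXES.index(rec["axis"])
        rows.append(
            {
                "unit": u,
                "axis": rec["axis"],
                "unit_class": rec["unit_class"],
                "w_fusion": float(params.out_w[u, ax]),
                "w_scission": float(params.out_w[u, 4 + ax]),
                "w_causal": float(params.out_w[u, 8 + ax]),
                "pref_speed_visual": rec.get("pref_speed_visual", np.nan),
                "pref_speed_vestibular": rec.get("pref_speed_vestibular", np.nan),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        summary = pd.DataFrame()
    else:
        summary = (
            table.assign(
                abs_w_fusion=table["w_fusion"].abs(),
                abs_w_scission=table["w_scission"].abs(),
            )
            .groupby("unit_class")[["w_causal", "abs_w_fusion", "abs_w_scission"]]
            .mean()
        )
    return {"table": table, "summary": summary}


# ---------------------------------------------------------------------------
# artificial lesions


def lesion_decoding_experiment(
    params: NetworkParams,
    classes: pd.DataFrame,
    axis: int,
    rng: np.random.Generator,
    cfg: CharacterizationConfig | None = None,
) -> dict:
    """Decode velocity maps from all / congruent-only / opposite-only units.

    Fusion and scission estimates for one axis are measured over the full
    grid of visual x vestibular velocities in +/-4 (``cfg.lesion_steps``
    linear steps, 31 -> 961 estimates).  Decoding from one class lesions
    (zeroes) every unit outside it.  Each map is also normalized by its
    maximum absolute value; the difference map is normalized opposite minus
    normalized congruent.
    """
    cfg = cfg or CharacterizationConfig()
    ax_classes = classes[classes["axis"] == AXES[axis]]
    cong = ax_classes.loc[ax_classes["unit_class"] == "congruent", "unit"].to_numpy()
    oppo = ax_classes.loc[ax_classes["unit_class"] == "opposite", "unit"].to_numpy()
    all_units = np.arange(params.arch.mstd_units)
    lesions = {
        "all": np.array([], dtype=int),
        "congruent": np.setdiff1d(all_units, cong),
        "opposite": np.setdiff1d(all_units, oppo),
    }
    vels = np.linspace(-stimuli.VELOCITY_RANGE, stimuli.VELOCITY_RANGE, cfg.lesion_steps)
    arch = params.arch
    size = arch.image_size
    n_v = len(vels)

    maps = {("fusion", k): np.zeros((n_v, n_v)) for k in lesions}
    maps.update({("scission", k): np.zeros((n_v, n_v)) for k in lesions})
    for _ in range(cfg.map_trials):
        visual_bank = np.empty((n_v, size, size, arch.n_frames), dtype=np.float32)
        vest_bank = np.empty((n_v, network.N_AXES * arch.vest_units), dtype=np.float32)
        for i, v in enumerate(vels):
            vec = np.zeros(4)
            vec[axis] = v
            m = MotionSpec.from_array(vec)
            visual_bank[i] = stimuli.render_dot_sequence(cfg.dots, m, rng, out_size=size)
            vest_bank[i] = vestibular.encode(
                m, cfg.sigma, cfg.noise_sd, rng, n_units=arch.vest_units
            ).flat()
        vi = np.repeat(np.arange(n_v), n_v)
        ve = np.tile(np.arange(n_v), n_v)
        for name, silenced in lesions.items():
            mask = np.ones(arch.mstd_units, dtype=np.float32)
            mask[silenced] = 0.0
            stack = _batched_forward(
                params, visual_bank[vi], vest_bank[ve], cfg.batch, lesion_mask=mask
            )
            maps[("fusion", name)] += stack.fusion[:, axis].reshape(n_v, n_v)
            maps[("scission", name)] += stack.scission[:, axis].reshape(n_v, n_v)
    for key in maps:
        maps[key] /= cfg.map_trials

    amplitudes = {k: float(np.abs(m).max()) for k, m in maps.items()}
    normalized = {
        k: m / amplitudes[k] if amplitudes[k] > 0 else m for k, m in maps.items()
    }
    diffs = {
        est: normalized[(est, "opposite")] - normalized[(est, "congruent")]
        for est in ("fusion", "scission")
    }
    return {
        "velocities": vels,
        "maps": maps,
        "amplitudes": amplitudes,
        "normalized": normalized,
        "difference": diffs,
        "n_cells": n_v * n_v,
    }


# ---------------------------------------------------------------------------
# asymmetry correlations


def cue_sensitivity_asymmetry(
    fits_visual: pd.DataFrame, fits_vestibular: pd.DataFrame
) -> pd.Series:
    """Normalized amplitude asymmetry ||a_vis| - |a_vest|| / (|a_vis| + |a_vest|)."""
    a_vis = fits_visual.set_index("unit")["amplitude"].abs()
    a_ves = fits_vestibular.set_index("unit")["amplitude"].abs()
    denom = a_vis + a_ves
    asym = (a_vis - a_ves).abs() / denom.where(denom > 0)
    return asym.rename("asymmetry")


def asymmetry_correlations(
    params: NetworkParams,
    heading_classes: pd.DataFrame,
    fits_visual: pd.DataFrame,
    fits_vestibular: pd.DataFrame,
    speed_classes: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
    n_boot: int = 2000,
) -> pd.DataFrame:
    """Correlations between cue asymmetry / preference offsets and weights.

    * congruent units: asymmetry vs |weight to the scission outputs|
    * opposite units: asymmetry vs |weight to the fusion outputs|
    * congruent units: |preferred visual - vestibular velocity| (from the
      per-axis speed sweeps) vs |weight to the scission outputs|

    Weight magnitudes for the heading-based analyses are the mean absolute
    weight over the x and z axes (the axes that compose heading direction).
    Classes with fewer than 3 units give NaN (undefined) correlations.
    """
    from .stats import bootstrap_corr_ci

    asym = cue_sensitivity_asymmetry(fits_visual, fits_vestibular)
    w_sci = np.abs(params.out_w[:, [4 + 0, 4 + 2]]).mean(axis=1)  # x, z scission
    w_fus = np.abs(params.out_w[:, [0, 2]]).mean(axis=1)  # x, z fusion
    cong = heading_classes.loc[
        heading_classes["unit_class"] == "congruent", "unit"
    ].to_numpy()
    oppo = heading_classes.loc[
        heading_classes["unit_class"] == "opposite", "unit"
    ].to_numpy()

    rows = []

    def corr_row(name, x, y):
        if len(x) < 3:
            rows.append({"correlation": name, "r": np.nan, "p": np.nan,
                         "ci_lo": np.nan, "ci_hi": np.nan, "n": len(x)})
            return
        r, p = pearson(x, y)
        lo, hi = bootstrap_corr_ci(x, y, n_boot=n_boot, rng=rng)
        rows.append({"correlation": name, "r": r, "p": p,
                     "ci_lo": lo, "ci_hi": hi, "n": len(x)})

    corr_row("congruent_asymmetry_vs_scission", asym.loc[cong].to_numpy(), w_sci[cong])
    corr_row("opposite_asymmetry_vs_fusion", asym.loc[oppo].to_numpy(), w_fus[oppo])

    if speed_classes is not None:
        sc = speed_classes[speed_classes["unit_class"] == "congruent"]
        dpref = (
            sc["pref_speed_visual"] - sc["pref_speed_vestibular"]
        ).abs().to_numpy()
        w = np.array(
            [
                np.abs(params.out_w[int(u), 4 + AXES.index(ax)])
                for u, ax in zip(sc["unit"], sc["axis"])
            ]
        )
        ok = np.isfinite(dpref)
        corr_row("congruent_dpref_vs_scission", dpref[ok], w[ok])
    return pd.DataFrame(rows)
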