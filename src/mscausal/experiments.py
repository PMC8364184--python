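"""Network psychophysics: cue weighting, decision bias, and study orchestration.

Two behavioral experiments are run on trained networks:

* **Reliability-based cue weighting** — heading discrimination around
  straight ahead with visual (dot-field) and vestibular cues at seven test
  directions in +/-14 deg.  Visual reliability is manipulated via motion
  coherence (100% vs 60%); cue-conflict conditions offset the two cues in
  opposite directions (+/-9 deg total) around the test direction.  The
  proportion of rightward self-motion estimates per direction is fitted
  with a cumulative Gaussian; the PSE shift under conflict measures which
  cue dominates.
* **Causal-inference decision bias** — the vestibular cue signals zero
  velocity (tuning width 2, additive noise SD 0.8) while the visual cue
  moves at +/-2.34 pixels/frame along x (the learned one/two-event
  boundary).  Trials are grouped by the network's own causal decision;
  self-motion estimates are more visually biased on one-event trials, and
  the vestibular population input itself predicts the decision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr

from . import characterization as chz
from . import network, stimuli, training, vestibular
from .network import NetworkParams
from .stats import bootstrap_ci
from .stimuli import DotFieldSpec
from .training import ANALYTIC_MEDIAN_DIFF


# ---------------------------------------------------------------------------
# psychometric fitting


@dataclass
class PsychometricFit:
    pse: float  # mean of the cumulative Gaussian (deg)
    threshold: float  # SD of the cumulative Gaussian (deg)
    converged: bool
    flagged: str = ""


def fit_psychometric(directions, prop_right, n_trials: int) -> PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian fit to choice proportions.

    ``prop_right`` are proportions of rightward choices out of ``n_trials``
    per direction.  Perfectly separated data are fitted after clipping the
    proportions to ``[eps, 1 - eps]`` with ``eps = 1 / (2 n_trials)`` and
    flagged.  A flat response profile leaves the PSE undefined (NaN).
    """
    x = np.asarray(directions, dtype=float)
    p = np.asarray(prop_right, dtype=float)
    if len(x) < 4:
        raise ValueError("need >= 4 directions for a psychometric fit")
    flagged = ""
    if np.ptp(p) == 0:
        return PsychometricFit(np.nan, np.nan, False, "flat-response")
    eps = 1.0 / (2.0 * n_trials)
    if ((p <= 0) | (p >= 1)).any():
        flagged = "clipped"
    p = np.clip(p, eps, 1.0 - eps)
    k = np.round(p * n_trials)

    def nll(theta):
        mu, log_sigma = theta
        q = np.clip(ndtr((x - mu) / np.exp(log_sigma)), 1e-9, 1 - 1e-9)
        return -np.sum(k * np.log(q) + (n_trials - k) * np.log1p(-q))

    span = x.max() - x.min()
    best = None
    for s0 in (span / 4, span):
        res = optimize.minimize(
            nll, [np.median(x), np.log(s0)], method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    mu, sigma = best.x[0], float(np.exp(best.x[1]))
    if sigma < 0.05 * span:
        flagged = (flagged + " near-degenerate").strip()
    return PsychometricFit(float(mu), sigma, bool(best.success), flagged)


# ---------------------------------------------------------------------------
# reliability-based cue weighting


@dataclass
class CueWeightingConfig:
    directions: np.ndarray = field(
        default_factory=lambda: np.linspace(-14.0, 14.0, 7)
    )
    conflicts: tuple = (0.0, 9.0, -9.0)  # visual minus vestibular offset (deg)
    coherences: tuple = (1.0, 0.6)  # high / low visual reliability
    n_trials: int = 128
    speed: float = 4.0
    sigma: float = 6.0  # vestibular tuning width for this task
    noise_sd: float = 0.3
    dots: DotFieldSpec = field(default_factory=DotFieldSpec)
    batch: int = 256


def _zeros_inputs(n, arch):
    visual = np.zeros((n, arch.image_size, arch.image_size, arch.n_frames), np.float32)
    vest = np.zeros((n, network.N_AXES * arch.vest_units), np.float32)
    return visual, vest


def cue_weighting_experiment(
    params: NetworkParams,
    rng: np.random.Generator,
    cfg: CueWeightingConfig | None = None,
) -> dict:
    """Run the cue-weighting task; returns trial proportions and fits.

    Conditions: vestibular-only, visual-only at each coherence, and combined
    at each coherence x conflict.  In conflict conditions the visual cue is
    offset by +conflict/2 and the vestibular cue by -conflict/2 so their
    average equals the test direction.  A trial is classed rightward when
    the fusion x-estimate exceeds zero.  Single-cue conditions input the
    excluded cue as zeros.
    """
    cfg = cfg or CueWeightingConfig()
    arch = params.arch
    conditions = [("vestibular", None, 0.0)]
    for coh in cfg.coherences:
        conditions.append(("visual", coh, 0.0))
    for coh in cfg.coherences:
        for conf in cfg.conflicts:
            conditions.append(("combined", coh, conf))

    rows = []
    for cond, coh, conflict in conditions:
        dots = replace(cfg.dots, coherence=coh if coh is not None else 1.0)
        for d in cfg.directions:
            visual, vest = _zeros_inputs(cfg.n_trials, arch)
            vis_dir = d + conflict / 2.0
            ves_dir = d - conflict / 2.0
            for t in range(cfg.n_trials):
                if cond in ("visual", "combined"):
                    visual[t] = stimuli.render_dot_sequence(
                        dots,
                        chz.heading_to_motion(vis_dir, cfg.speed),
                        rng,
                        out_size=arch.image_size,
                    )
                if cond in ("vestibular", "combined"):
                    vest[t] = vestibular.encode(
                        chz.heading_to_motion(ves_dir, cfg.speed),
                        cfg.sigma,
                        cfg.noise_sd,
                        rng,
                        n_units=arch.vest_units,
                    ).flat()
            stack = chz._batched_forward(params, visual, vest, cfg.batch)
            rightward = stack.fusion[:, 0] > 0.0
            rows.append(
                {
                    "condition": cond,
                    "coherence": coh,
                    "conflict": conflict,
                    "direction": d,
                    "prop_right": float(rightward.mean()),
                    "n_trials": cfg.n_trials,
                }
            )
    trials = pd.DataFrame(rows)
    fits = []
    for (cond, coh, conf), grp in trials.groupby(
        ["condition", "coherence", "conflict"], dropna=False
    ):
        fit = fit_psychometric(
            grp["direction"].to_numpy(), grp["prop_right"].to_numpy(), cfg.n_trials
        )
        fits.append(
            {
                "condition": cond,
                "coherence": coh,
                "conflict": conf,
                "pse": fit.pse,
                "threshold": fit.threshold,
                "converged": fit.converged,
                "flagged": fit.flagged,
            }
        )
    return {"trials": trials, "fits": pd.DataFrame(fits)}


def pse_shift_summary(fits: pd.DataFrame) -> pd.DataFrame:
    """Per-coherence PSE shift with conflict: d(PSE)/d(conflict).

    A positive slope means the point of subjective equality follows the
    visual cue's offset (visual dominance); a negative slope means
    vestibular dominance.
    """
    rows = []
    comb = fits[fits["condition"] == "combined"]
    for coh, grp in comb.groupby("coherence"):
        grp = grp.dropna(subset=["pse"])
        if len(grp) < 2:
            rows.append({"coherence": coh, "pse_slope": np.nan})
            continue
        slope = np.polyfit(grp["conflict"], grp["pse"], 1)[0]
        rows.append({"coherence": coh, "pse_slope": float(slope)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# causal-inference decision bias


@dataclass
class DecisionBiasConfig:
    visual_velocity: float = ANALYTIC_MEDIAN_DIFF  # ~2.34 px/frame, the boundary
    n_trials: int = 2560  # per visual velocity sign
    sigma: float = 2.0  # vestibular tuning width
    noise_sd: float = 0.8  # vestibular additive noise
    dots: DotFieldSpec = field(default_factory=DotFieldSpec)
    batch: int = 256
    n_boot: int = 2000


def decision_bias_experiment(
    params: NetworkParams,
    rng: np.random.Generator,
    cfg: DecisionBiasConfig | None = None,
) -> dict:
    """Group motion estimates by the network's own causal decision.

    The vestibular input encodes zero x-velocity; the visual input is a
    coherent dot field at +/-``visual_velocity`` along x.  Because the cue
    separation sits at the learned one/two-event boundary, vestibular noise
    swings the decision trial by trial.  Returns per-trial records, group
    means with bootstrap CIs, and the average vestibular population input
    per decision group.
    """
    cfg = cfg or DecisionBiasConfig()
    arch = params.arch
    records = []
    vest_traces = {}
    for sign in (+1.0, -1.0):
        v_vis = sign * cfg.visual_velocity
        motion = stimuli.MotionSpec(vx=v_vis)
        visual = np.empty(
            (cfg.n_trials, arch.image_size, arch.image_size, arch.n_frames), np.float32
        )
        vest = np.empty((cfg.n_trials, network.N_AXES * arch.vest_units), np.float32)
        for t in range(cfg.n_trials):
            visual[t] = stimuli.render_dot_sequence(
                cfg.dots, motion, rng, out_size=arch.image_size
            )
            vest[t] = vestibular.encode(
                stimuli.MotionSpec(), cfg.sigma, cfg.noise_sd, rng,
                n_units=arch.vest_units,
            ).flat()
        stack = chz._batched_forward(params, visual, vest, cfg.batch)
        decision = (stack.causal[:, 0] > 0.5).astype(int) + 1  # 1 or 2 events
        for t in range(cfg.n_trials):
            records.append(
                {
                    "visual_velocity": v_vis,
                    "fusion_x": float(stack.fusion[t, 0]),
                    "scission_x": float(stack.scission[t, 0]),
                    "decision": int(decision[t]),
                }
            )
        vest_x = vest[:, : arch.vest_units]  # x-axis population (32 units)
        for dec in (1, 2):
            key = (sign, dec)
            sel = decision == dec
            vest_traces[key] = (
                vest_x[sel].mean(axis=0) if sel.any() else np.full(arch.vest_units, np.nan)
            )
            if not sel.any():
                import warnings

                warnings.warn(
                    f"decision group {dec} empty for visual velocity {v_vis}",
                    stacklevel=2,
                )
    trials = pd.DataFrame(records)
    # bias toward the visual sign: estimate * sign(visual velocity)
    trials["fusion_toward_visual"] = trials["fusion_x"] * np.sign(
        trials["visual_velocity"]
    )
    trials["scission_toward_visual"] = trials["scission_x"] * np.sign(
        trials["visual_velocity"]
    )
    groups = []
    for dec, grp in trials.groupby("decision"):
        for col in ("fusion_toward_visual", "scission_toward_visual"):
            lo, hi = bootstrap_ci(grp[col].to_numpy(), n_boot=cfg.n_boot, rng=rng)
            groups.append(
                {
                    "decision": dec,
                    "measure": col,
                    "mean": float(grp[col].mean()),
                    "ci_lo": lo,
                    "ci_hi": hi,
                    "n": len(grp),
                }
            )
    return {
        "trials": trials,
        "group_means": pd.DataFrame(groups),
        "vestibular_traces": vest_traces,
        "two_event_fraction": float((trials["decision"] == 2).mean()),
    }


def vestibular_trace_shift(result: dict) -> float:
    """Population-vector shift (toward the visual sign) of one-event minus
    two-event mean vestibular input, averaged over the two visual signs."""
    shifts = []
    for sign in (+1.0, -1.0):
        pv = {
            dec: vestibular.population_vector(result["vestibular_traces"][(sign, dec)])[0]
            for dec in (1, 2)
        }
        shifts.append(sign * (pv[1] - pv[2]))
    return float(np.mean(shifts))


# ---------------------------------------------------------------------------
# full-study orchestration


def run_study(
    out_dir,
    config: training.TrainConfig | None = None,
    char_cfg: chz.CharacterizationConfig | None = None,
    seed: int = 0,
    verbose: bool = False,
) -> dict:
    """End-to-end study: data, training, characterization, experiments.

    Stages are checkpointed under ``out_dir``: trained replicate networks
    are stored as .npz checkpoints and reloaded on rerun, so analyses can be
    repeated without retraining.  All tables are written as CSV and a
    summary as JSON plus a markdown report.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or training.desk_config(seed=seed)
    char_cfg = char_cfg or chz.CharacterizationConfig()
    stage = "dataset"
    try:
        dataset = training.generate_dataset(config.n_examples, config.seed, config.arch)
        stage = "training"
        ensemble = []
        for rep in range(config.n_replicates):
            ckpt = out / f"replicate{rep}"
            hist_path = out / f"history_rep{rep}.csv"
            cfg_rep = replace(config, seed=config.seed + 1000 * rep + 1)
            if (ckpt.with_suffix(".npz")).exists():
                params = network.load_params(ckpt)
                history = pd.read_csv(hist_path) if hist_path.exists() else None
            else:
                params, history = training.train(cfg_rep, dataset, verbose=verbose)
                network.save_params(str(ckpt), params, meta={"replicate": rep})
                history.to_csv(hist_path, index=False)
            ensemble.append((params, history))

        stage = "characterization"
        summary: dict = {"config": {"n_replicates": config.n_replicates,
                                    "n_examples": config.n_examples,
                                    "epochs": config.epochs,
                                    "seed": config.seed}}
        rng = np.random.default_rng(seed + 17)
        all_hist = pd.concat(
            [h.assign(replicate=i) for i, (_, h) in enumerate(ensemble) if h is not None]
        )
        all_hist.to_csv(out / "history.csv", index=False)
        final = all_hist.groupby("replicate").tail(1)
        summary["min_r"] = float(final["min_r"].mean())
        summary["causal_accuracy_pct"] = float(final["acc_causal_mean"].mean() * 100)

        char_rows, corr_rows, weight_rows = [], [], []
        first_res = None
        for rep, (params, _) in enumerate(ensemble):
            res = characterize_network(params, rng, char_cfg)
            if first_res is None:
                first_res = res
            res["congruency"].assign(replicate=rep).pipe(char_rows.append)
            res["asymmetry"].assign(replicate=rep).pipe(corr_rows.append)
            res["weights"]["table"].assign(replicate=rep).pipe(weight_rows.append)
        pd.concat(char_rows).to_csv(out / "unit_congruency.csv", index=False)
        pd.concat(corr_rows).to_csv(out / "asymmetry_correlations.csv", index=False)
        pd.concat(weight_rows).to_csv(out / "weights.csv", index=False)

        stage = "experiments"
        cw = cue_weighting_experiment(ensemble[0][0], rng)
        cw["trials"].to_csv(out / "cue_weighting_trials.csv", index=False)
        cw["fits"].to_csv(out / "cue_weighting_fits.csv", index=False)
        db = decision_bias_experiment(ensemble[0][0], rng)
        db["group_means"].to_csv(out / "decision_bias_groups.csv", index=False)
        summary["two_event_fraction"] = db["two_event_fraction"]

        stage = "figures"
        from . import figures

        figures.plot_history(all_hist, out / "fig_history.png")
        figures.plot_pref_difference_histogram(
            first_res["pref_diff_histogram"], out / "fig_pref_differences.png"
        )
        lesion = chz.lesion_decoding_experiment(
            ensemble[0][0], first_res["speed_classes"], 0, rng, char_cfg
        )
        figures.plot_lesion_maps(lesion, out / "fig_lesion_maps.png")
        figures.plot_psychometrics(
            cw["trials"], cw["fits"], out / "fig_cue_weighting.png"
        )
        figures.plot_decision_bias(db, out / "fig_decision_bias.png")

        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        _write_report(out, summary)
        return summary
    except Exception as err:  # noqa: BLE001
        raise RuntimeError(
            f"study failed at stage {stage!r}; artifacts under {out}"
        ) from err


def characterize_network(
    params: NetworkParams, rng: np.random.Generator, cfg: chz.CharacterizationConfig
) -> dict:
    """Run the full unit-characterization battery on one network."""
    fine = chz.fine_directions(cfg.fine_inner, cfg.fine_outer)
    fine_curves = {
        cue: chz.measure_tuning(params, cue, fine, cfg.n_trials_roc, rng, cfg)
        for cue in ("vestibular", "visual", "combined")
    }
    congruency = chz.congruency_index(fine_curves["vestibular"], fine_curves["visual"])
    thresholds = chz.neurometric_thresholds(fine_curves)
    broad = chz.broad_directions(cfg.broad_directions)
    broad_curves = {
        cue: chz.measure_tuning(params, cue, broad, cfg.n_trials_tuning, rng, cfg)
        for cue in ("vestibular", "visual")
    }
    fits = {cue: chz.fit_all_sinusoids(c) for cue, c in broad_curves.items()}
    hist = chz.preferred_difference_histogram(fits["visual"], fits["vestibular"])
    speed_classes = pd.concat(
        [
            chz.speed_congruency_classification(params, ax, rng, cfg, n_trials=16)
            for ax in range(4)
        ]
    )
    weights = chz.weight_summaries(params, speed_classes)
    asym = chz.asymmetry_correlations(
        params, congruency, fits["visual"], fits["vestibular"], speed_classes, rng
    )
    return {
        "congruency": congruency,
        "thresholds": thresholds,
        "tuning_fits": fits,
        "pref_diff_histogram": hist,
        "speed_classes": speed_classes,
        "weights": weights,
        "asymmetry": asym,
    }


def _write_report(out: Path, summary: dict) -> None:
    lines = [
        "# Study report",
        "",
        f"Replicates: {summary['config']['n_replicates']}, "
        f"examples: {summary['config']['n_examples']}, "
        f"epochs: {summary['config']['epochs']}",
        "",
        f"- held-out minimum Pearson r over the eight regression outputs: "
        f"{summary['min_r']:.3f}",
        f"- causal-inference accuracy (axis-averaged): "
        f"{summary['causal_accuracy_pct']:.1f}%",
        f"- two-event fraction at the decision boundary: "
        f"{summary.get('two_event_fraction', float('nan')):.2f}",
        "",
        "Tables: history.csv, unit_congruency.csv, weights.csv, "
        "asymmetry_correlations.csv, cue_weighting_fits.csv, "
        "decision_bias_groups.csv",
    ]
    (out / "report.md").write_text("\n".join(lines))
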