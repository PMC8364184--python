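"""Study figures: training history, unit structure, behavioral panels."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_history(history: pd.DataFrame, path) -> None:
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2))
    for rep, grp in history.groupby(history.get("replicate", 0)):
        axes[0].plot(grp["epoch"], grp["train_loss"], label=f"train r{rep}")
        axes[0].plot(grp["epoch"], grp["test_loss"], "--", label=f"test r{rep}")
        axes[1].plot(grp["epoch"], grp["min_r"])
        axes[2].plot(grp["epoch"], 100 * grp["acc_causal_mean"])
    axes[0].set(xlabel="epoch", ylabel="loss")
    axes[0].legend(fontsize=6)
    axes[1].set(xlabel="epoch", ylabel="held-out min Pearson r", ylim=(0, 1))
    axes[2].axhline(50, color="gray", lw=0.5)
    axes[2].set(xlabel="epoch", ylabel="causal accuracy (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pref_difference_histogram(hist: pd.DataFrame, path) -> None:
    fig, ax = plt.subplots(figsize=(4, 3))
    centers = (hist["bin_lo"] + hist["bin_hi"]) / 2
    ax.bar(centers, hist["count"], width=0.9 * (hist["bin_hi"] - hist["bin_lo"]))
    ax.set(
        xlabel="|preferred visual - vestibular direction| (deg)",
        ylabel="number of units",
        xticks=[0, 45, 90, 135, 180],
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_activity_map(amap: dict, path) -> None:
    fig, ax = plt.subplots(figsize=(4.2, 3.6))
    d = amap["difference_map"]
    lim = np.abs(d).max() or 1.0
    im = ax.imshow(
        d, origin="lower", cmap="RdBu_r", vmin=-lim, vmax=lim,
        extent=[amap["vestibular_headings"][0], amap["vestibular_headings"][-1],
                amap["visual_headings"][0], amap["visual_headings"][-1]],
    )
    fig.colorbar(im, ax=ax, label="congruent - opposite activity")
    ax.set(xlabel="vestibular heading (deg)", ylabel="visual heading (deg)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_lesion_maps(lesion: dict, path) -> None:
    conds = ("all", "congruent", "opposite")
    fig, axes = plt.subplots(2, 4, figsize=(12, 5.6))
    vels = lesion["velocities"]
    ext = [vels[0], vels[-1], vels[0], vels[-1]]
    for row, est in enumerate(("fusion", "scission")):
        for col, cond in enumerate(conds):
            m = lesion["normalized"][(est, cond)]
            im = axes[row, col].imshow(
                m, origin="lower", cmap="RdBu_r", vmin=-1, vmax=1, extent=ext
            )
            axes[row, col].set_title(
                f"{est} from {cond}\n(amplitude {lesion['amplitudes'][(est, cond)]:.2f})",
                fontsize=8,
            )
        dm = lesion["difference"][est]
        axes[row, 3].imshow(
            dm, origin="lower", cmap="RdBu_r",
            vmin=-np.abs(dm).max() or -1, vmax=np.abs(dm).max() or 1, extent=ext,
        )
        axes[row, 3].set_title(f"{est}: opposite - congruent", fontsize=8)
    for ax in axes.ravel():
        ax.set(xlabel="vestibular velocity", ylabel="visual velocity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_psychometrics(trials: pd.DataFrame, fits: pd.DataFrame, path) -> None:
    from scipy.special import ndtr

    comb = trials[trials["condition"] == "combined"]
    cohs = sorted(comb["coherence"].dropna().unique(), reverse=True)
    fig, axes = plt.subplots(1, len(cohs), figsize=(4 * len(cohs), 3.2), squeeze=False)
    for ax, coh in zip(axes[0], cohs):
        for conflict, grp in comb[comb["coherence"] == coh].groupby("conflict"):
            ax.plot(grp["direction"], grp["prop_right"], "o", ms=3,
                    label=f"conflict {conflict:+.0f} deg")
            fit = fits[
                (fits["condition"] == "combined")
                & (fits["coherence"] == coh)
                & (fits["conflict"] == conflict)
            ]
            if len(fit) and np.isfinite(fit["pse"].iloc[0]):
                x = np.linspace(-14, 14, 100)
                ax.plot(
                    x, ndtr((x - fit["pse"].iloc[0]) / fit["threshold"].iloc[0]),
                    lw=1,
                )
        ax.axhline(0.5, color="gray", lw=0.5)
        ax.set(title=f"coherence {coh:.0%}", xlabel="test direction (deg)",
               ylabel="proportion rightward", ylim=(-0.02, 1.02))
        ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_decision_bias(result: dict, path) -> None:
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.2))
    trials = result["trials"]
    for dec, color in ((1, "tab:green"), (2, "tab:purple")):
        sel = trials[trials["decision"] == dec]
        axes[0].hist(sel["fusion_toward_visual"], bins=40, alpha=0.6,
                     color=color, label=f"{dec} event(s)")
        axes[1].hist(sel["scission_toward_visual"], bins=40, alpha=0.6, color=color)
    axes[0].set(xlabel="self-motion estimate (toward visual)", ylabel="trials")
    axes[0].legend(fontsize=7)
    axes[1].set(xlabel="scene-motion estimate (toward visual)")
    for (sign, dec), trace in result["vestibular_traces"].items():
        if sign > 0 and np.isfinite(trace).all():
            n = len(trace)
            grid = np.linspace(-8, 8, n)
            axes[2].plot(grid, trace, label=f"{dec} event(s)",
                         color="tab:green" if dec == 1 else "tab:purple")
    axes[2].axvline(0, color="gray", lw=0.5)
    axes[2].set(xlabel="preferred velocity", ylabel="mean vestibular input")
    axes[2].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
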