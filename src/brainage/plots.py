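"""Matplotlib figures: BAG trajectories and effect-size bars per window."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_bag_trajectories", "plot_effect_sizes"]

_PNG_METADATA = {"Software": "brainage"}  # keep output byte-stable across runs


def plot_bag_trajectories(window_summary: pd.DataFrame, path: str | Path) -> None:
    """Mean ± SEM of patient and control BAG across windows, one panel per modality.

    Expects columns: modality, duration_lo, mean_bag_patients, sem_bag_patients,
    mean_bag_controls, sem_bag_controls.
    """
    modalities = list(window_summary["modality"].unique())
    fig, axes = plt.subplots(1, len(modalities), figsize=(5 * len(modalities), 4),
                             sharey=True, squeeze=False)
    for ax, modality in zip(axes[0], modalities):
        sub = window_summary[window_summary["modality"] == modality]
        x = sub["duration_lo"]
        for group, color in (("patients", "tab:red"), ("controls", "tab:blue")):
            mean = sub[f"mean_bag_{group}"]
            sem = sub[f"sem_bag_{group}"]
            ax.plot(x, mean, color=color, label=group)
            ax.fill_between(x, mean - sem, mean + sem, color=color, alpha=0.25)
        ax.set_title(modality)
        ax.set_xlabel("illness duration window start (years)")
        ax.axhline(0.0, color="grey", lw=0.5)
    axes[0][0].set_ylabel("brain-age gap (years)")
    axes[0][0].legend()
    fig.tight_layout()
    fig.savefig(path, metadata=_PNG_METADATA)
    plt.close(fig)


def plot_effect_sizes(results: pd.DataFrame, path: str | Path) -> None:
    """Partial eta squared per window, one bar panel per modality.

    Expects columns: modality, window_label, partial_eta_sq, significant.
    """
    modalities = list(results["modality"].unique())
    fig, axes = plt.subplots(len(modalities), 1,
                             figsize=(10, 2.8 * len(modalities)),
                             sharex=False, squeeze=False)
    for ax, modality in zip(axes[:, 0], modalities):
        sub = results[results["modality"] == modality]
        colors = ["tab:orange" if s else "tab:gray" for s in sub["significant"]]
        ax.bar(range(len(sub)), sub["partial_eta_sq"], color=colors)
        ax.set_xticks(range(len(sub)))
        ax.set_xticklabels(sub["window_label"], rotation=90, fontsize=7)
        ax.set_ylabel("partial η²")
        ax.set_title(modality)
    axes[-1, 0].set_xlabel("illness duration window")
    fig.tight_layout()
    fig.savefig(path, metadata=_PNG_METADATA)
    plt.close(fig)
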