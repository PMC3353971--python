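"""Diagnostic plots for study outputs (power curves, SDI histograms, shape scatter)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_power_curves(power_df: pd.DataFrame, path) -> None:
    """Power vs expected pattern size, one panel per test variant."""
    variants = [v for v in power_df["variant"].unique() if v != "aggregate"]
    fig, axes = plt.subplots(1, len(variants), figsize=(4 * len(variants), 3.2), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, variant in zip(axes, variants):
        sub = power_df[power_df["variant"] == variant]
        for process, grp in sub.groupby("process"):
            grp = grp.sort_values("expected_n")
            ax.plot(grp["expected_n"], grp["power"], marker="o", label=process)
        ax.set_xscale("log", base=2)
        ax.set_xlabel("expected points per nucleus")
        ax.set_title(variant.replace("_", " "))
        ax.set_ylim(0, 1)
    axes[0].set_ylabel("rejection fraction")
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)


def plot_sdi_histogram(values: Sequence[float], path, title: str = "SDI") -> None:
    """Histogram of SDI values; uniform height means consistency with CSR."""
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.hist(np.asarray(values), bins=10, range=(0, 1), edgecolor="black")
    ax.axhline(len(list(values)) / 10, color="gray", linestyle="--", linewidth=1)
    ax.set_xlabel("SDI")
    ax.set_ylabel("nuclei")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)


def plot_shape_heterogeneity(report: pd.DataFrame, path) -> None:
    """Scatter of max-chord cubed against volume, coloured by shape class."""
    fig, ax = plt.subplots(figsize=(4, 3.5))
    for cls, grp in report.groupby("class"):
        ax.scatter(grp["volume"], grp["max_chord_cubed"], s=12, label=cls)
    ax.set_xlabel("volume")
    ax.set_ylabel("max chord$^3$")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=150)
    plt.close(fig)
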