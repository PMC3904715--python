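"""Small report figures (matplotlib, Agg-safe)."""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_method_comparison", "plot_section_counts"]


def plot_method_comparison(report: dict, path: Optional[str] = None):
    """Bar chart of the 3D disector vs 2D profile-count per-cell estimates,
    with the generator truth as a reference line."""
    fig, ax = plt.subplots(figsize=(4, 4))
    vals = [report["n_per_cell_3d"], report["n_per_cell_2d"]]
    ax.bar(["3D disector", "2D profiles"], vals, color=["white", "0.4"],
           edgecolor="black")
    truth = report.get("true_mean_particles_per_cell")
    if truth is not None:
        ax.axhline(truth, color="tab:red", ls="--", lw=1,
                   label=f"generator truth ({truth:.0f})")
        ax.legend(frameon=False)
    ax.set_ylabel("chloroplasts per cell")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_section_counts(report: dict, path: Optional[str] = None):
    """Per-section profile counts of the model-cell experiment with the
    mean and the true particle number."""
    counts = np.asarray(report["per_section_counts"])
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(counts, lw=0.8, color="0.3")
    ax.axhline(report["mean_profiles_per_section"], color="tab:blue",
               label=f"mean {report['mean_profiles_per_section']:.1f}")
    ax.axhline(report["true_n"], color="tab:red", ls="--",
               label=f"true n = {report['true_n']}")
    ax.set_xlabel("section")
    ax.set_ylabel("profiles")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
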