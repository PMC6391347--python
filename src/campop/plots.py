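"""Basic matplotlib figures for the standard reports.

Optional: importable only when matplotlib is installed (``pip install
campop[plot]``). Each function returns the Axes so callers can restyle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_chromosome_density(summary: pd.DataFrame, ax=None):
    """Bar chart of per-chromosome SNP counts with density annotations."""
    ax = _axes(ax)
    ax.bar(summary.index.astype(str), summary["n_snps"], color="#4477aa")
    ax.set_xlabel("chromosome")
    ax.set_ylabel("SNP count")
    for x, (_, row) in enumerate(summary.iterrows()):
        if np.isfinite(row.get("density_kb", np.nan)):
            ax.text(x, row["n_snps"], f"{row['density_kb']:.0f}",
                    ha="center", va="bottom", fontsize=7)
    return ax


def plot_diversity_histogram(values, bin_width: float = 0.05, ax=None,
                             label: str = "gene diversity"):
    """Fixed-width histogram of a per-locus statistic starting at 0."""
    ax = _axes(ax)
    values = np.asarray(list(values), dtype=float)
    edges = np.arange(0, values.max() + bin_width, bin_width)
    ax.hist(values, bins=edges, color="#66ccee", edgecolor="black")
    ax.set_xlabel(label)
    ax.set_ylabel("SNP count")
    return ax


def plot_pcoa(result, pop_labels=None, ax=None):
    """Scatter of the first two principal coordinates, colored by population."""
    ax = _axes(ax)
    coords = result.coordinates
    if pop_labels is None:
        ax.scatter(coords[:, 0], coords[:, 1], s=12)
    else:
        pop_labels = np.asarray(pop_labels)
        for pop in pd.unique(pop_labels):
            sel = pop_labels == pop
            ax.scatter(coords[sel, 0], coords[sel, 1], s=12, label=str(pop))
        ax.legend()
    ax.set_xlabel(f"axis 1 ({result.pct_variance[0]:.1f}%)")
    if coords.shape[1] > 1 and len(result.pct_variance) > 1:
        ax.set_ylabel(f"axis 2 ({result.pct_variance[1]:.1f}%)")
    return ax


def plot_structure_bars(q_mean: np.ndarray, sample_order=None, ax=None):
    """Stacked admixture-proportion bars, one per individual."""
    ax = _axes(ax)
    q = np.asarray(q_mean, dtype=float)
    if sample_order is not None:
        q = q[np.asarray(sample_order)]
    bottom = np.zeros(q.shape[0])
    x = np.arange(q.shape[0])
    for c in range(q.shape[1]):
        ax.bar(x, q[:, c], bottom=bottom, width=1.0)
        bottom += q[:, c]
    ax.set_xlim(-0.5, q.shape[0] - 0.5)
    ax.set_ylim(0, 1)
    ax.set_ylabel("admixture proportion")
    ax.set_xlabel("individual")
    return ax
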