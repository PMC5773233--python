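"""Manhattan and QQ panels for window selections.

Thin matplotlib wrappers over :func:`omimgwas.enrichment_stats.manhattan_data`
and :func:`omimgwas.enrichment_stats.qq_data`; both write PNG or SVG
depending on the output suffix.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .enrichment_stats import QQData, manhattan_data, qq_data
from .window_mapping import WindowSelection

__all__ = ["plot_manhattan", "plot_qq"]


def plot_manhattan(
    selection: WindowSelection,
    path: str | Path,
    nominal_alpha: float = 0.05,
    experiment_wise: float | None = None,
) -> Path:
    """Scatter of -log10 p by cumulative genome position with guide lines."""
    table, meta = manhattan_data(selection, nominal_alpha, experiment_wise)
    fig, ax = plt.subplots(figsize=(9, 3.2))
    for i, (chrom, sub) in enumerate(table.groupby("chr", sort=False)):
        ax.scatter(sub["cum_pos"], sub["neglog10_p"], s=6,
                   color=["#30557f", "#8ab0d9"][i % 2], linewidths=0)
    for level, style in (
        (meta["nominal_alpha"], ":"),
        (meta["experiment_wise_threshold"], "--"),
    ):
        ax.axhline(-np.log10(level), color="firebrick", linestyle=style, linewidth=1)
    ax.set_xlabel("cumulative genome position (bp)")
    ax.set_ylabel(r"$-\log_{10}\,P$")
    ax.set_title(f"{meta['n_variants']} variants in candidate-gene windows")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_qq(data: QQData | WindowSelection, path: str | Path) -> Path:
    """Observed vs expected -log10 p with the 95% null envelope shaded."""
    if isinstance(data, WindowSelection):
        data = qq_data(data.global_variants["p"].to_numpy())
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.fill_between(
        data.neglog10_expected,
        data.neglog10_lower,
        data.neglog10_upper,
        color="0.85",
        label="95% null envelope",
    )
    ax.plot(data.neglog10_expected, data.neglog10_expected, color="0.4", linewidth=1)
    ax.scatter(
        data.neglog10_expected,
        data.neglog10_observed,
        s=8,
        color="#30557f",
        linewidths=0,
    )
    ax.set_xlabel(r"expected $-\log_{10}\,P$")
    ax.set_ylabel(r"observed $-\log_{10}\,P$")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
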