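"""Figures: divergence profile, density tracks, expression heatmap."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

_SF_COLORS = {"Copia": "#2e7d32", "RLC": "#2e7d32",
              "Gypsy": "#e65100", "RLG": "#e65100",
              "NA": "#455a64", "RXX-NA": "#455a64"}


def plot_divergence_profile(hists: dict[str, np.ndarray], edges: np.ndarray,
                            path: str | Path) -> None:
    """Per-superfamily histogram of LTR-pair K2P distances."""
    fig, ax = plt.subplots(figsize=(7, 4))
    centers = (edges[:-1] + edges[1:]) / 2
    for sf in sorted(hists):
        ax.plot(centers, hists[sf], drawstyle="steps-mid",
                color=_SF_COLORS.get(sf, "gray"), label=sf)
    ax.set_xlabel("K2P distance between LTRs (substitutions/site)")
    ax.set_ylabel("elements")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_density_tracks(densities, path: str | Path,
                        tracks=("Copia", "Gypsy", "NA", "genes")) -> None:
    """Linear per-scaffold density tracks (features per Mb)."""
    scaffolds = sorted({w.scaffold for w in densities})
    fig, axes = plt.subplots(len(scaffolds), 1,
                             figsize=(8, 2.2 * len(scaffolds)),
                             squeeze=False)
    for ax, scf in zip(axes[:, 0], scaffolds):
        wins = [w for w in densities if w.scaffold == scf]
        x = [(w.start + w.end) / 2e6 for w in wins]
        for track in tracks:
            ax.plot(x, [w.density(track) for w in wins],
                    color=_SF_COLORS.get(track, "black"), label=track)
        ax.set_title(scf, fontsize=9)
        ax.set_ylabel("per Mb")
    axes[-1, 0].set_xlabel("position (Mb)")
    axes[0, 0].legend(frameon=False, fontsize=8, ncol=len(tracks))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_expression_heatmap(normalized: pd.DataFrame, path: str | Path,
                            log: bool = True) -> None:
    """Elements x tissues heatmap of normalized expression, rows ordered by
    hierarchical clustering (correlation linkage)."""
    from scipy.cluster.hierarchy import leaves_list, linkage

    data = normalized.to_numpy(dtype=float)
    if log:
        data = np.log2(data + 1.0)
    order = np.arange(data.shape[0])
    if data.shape[0] > 2:
        order = leaves_list(linkage(data, method="average"))
    fig, ax = plt.subplots(
        figsize=(1 + 0.5 * data.shape[1], 1 + 0.16 * data.shape[0]))
    im = ax.imshow(data[order], aspect="auto", cmap="viridis")
    ax.set_xticks(range(data.shape[1]),
                  [str(c) for c in normalized.columns], rotation=60,
                  ha="right", fontsize=7)
    ax.set_yticks(range(data.shape[0]),
                  [str(normalized.index[i]) for i in order], fontsize=5)
    fig.colorbar(im, ax=ax, label="log2(normalized + 1)" if log else
                 "normalized")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
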