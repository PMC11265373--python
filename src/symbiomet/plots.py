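"""Minimal figure helpers (presence/absence heatmap, rarefaction curves)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def presence_absence_heatmap(matrix: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(max(4, matrix.shape[1] * 0.15), max(3, matrix.shape[0] * 0.25)))
    ax.imshow(matrix.to_numpy(), aspect="auto", cmap="Greys", interpolation="nearest")
    ax.set_yticks(range(len(matrix.index)), matrix.index, fontsize=6)
    ax.set_xlabel("gene cluster family")
    ax.set_ylabel("strain")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def rarefaction_curves(rarefaction: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for group, sub in rarefaction.groupby("group"):
        ax.plot(sub["n_strains"], sub["expected_richness"], marker="o", label=str(group))
    ax.set_xlabel("strains sampled")
    ax.set_ylabel("expected family richness")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
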