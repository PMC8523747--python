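"""Static diagnostic plots: QQ, volcano, and the directionality curve."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["qq_plot", "volcano_plot", "directionality_plot"]


def qq_plot(p_values, path, title: str = "") -> None:
    """Observed vs expected -log10 P under the global null."""
    p = np.sort(np.asarray(p_values, dtype=float))
    n = len(p)
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(p)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(expected, observed, ".", ms=2, color="steelblue")
    lim = max(expected.max(), observed.max())
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    ax.set_xlabel("expected -log10 P")
    ax.set_ylabel("observed -log10 P")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def volcano_plot(ewas_table: pd.DataFrame, path, cutoff: float | None = None, title: str = "") -> None:
    """Effect estimate vs -log10 P; directional significant sites colored."""
    est = ewas_table["estimate"].to_numpy()
    logp = -np.log10(ewas_table["p"].to_numpy())
    fig, ax = plt.subplots(figsize=(5, 4.5))
    ax.plot(est, logp, ".", ms=2, color="grey", alpha=0.5)
    if cutoff is not None:
        sig = ewas_table["p"] <= cutoff
        hyper = sig & (ewas_table["direction"] == 1)
        hypo = sig & (ewas_table["direction"] == -1)
        ax.plot(est[hyper], logp[hyper], ".", ms=3, color="crimson")
        ax.plot(est[hypo], logp[hypo], ".", ms=3, color="royalblue")
        ax.axhline(-np.log10(cutoff), ls="--", lw=0.8, color="k")
    ax.set_xlabel("effect estimate (M units)")
    ax.set_ylabel("-log10 P")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def directionality_plot(curve: pd.DataFrame, path, min_proportion: float = 0.95, cutoff: float | None = None) -> None:
    """Directional proportion as a function of the P-value cutoff."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(-np.log10(curve["cutoff"]), curve["proportion"], color="crimson", lw=1)
    ax.axhline(min_proportion, ls="--", lw=0.8, color="k")
    if cutoff is not None:
        ax.axvline(-np.log10(cutoff), ls="--", lw=0.8, color="k")
    ax.set_xlabel("-log10 P cutoff")
    ax.set_ylabel("proportion directional")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
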