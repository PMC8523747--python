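"""Directionality-based significance-threshold selection.

Rather than a fixed genome-wide threshold, the significance cutoff is the
largest P value below which (inclusively) at least a given proportion of
sites — 95% by default — share the direction of interest.  When no cutoff
reaches that purity (as in small, noisy cohorts), the top-K most significant
directional sites are taken instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HyperSet",
    "directionality_curve",
    "select_threshold",
    "select_hyper_set",
]


@dataclass
class HyperSet:
    """A directional significant-site set with its selection provenance."""

    probes: pd.Index
    direction: int  # +1 hyper, -1 hypo
    rule: str  # "proportion_threshold" or "top_k"
    cutoff: float | None = None
    k: int | None = None
    source: str = ""

    def __len__(self) -> int:
        return len(self.probes)


def _validated(ewas_table: pd.DataFrame, direction: int) -> pd.DataFrame:
    if len(ewas_table) == 0:
        raise ValueError("empty EWAS table")
    if direction not in (+1, -1):
        raise ValueError("direction must be +1 or -1")
    return ewas_table


def directionality_curve(ewas_table: pd.DataFrame, direction: int = +1) -> pd.DataFrame:
    """Proportion of directional sites among sites with P <= cutoff.

    Evaluated at every distinct observed P value (ties pooled), returned in
    increasing cutoff order with columns cutoff, n_sites, n_directional,
    proportion.
    """
    tab = _validated(ewas_table, direction)
    order = np.argsort(tab["p"].to_numpy(), kind="stable")
    p_sorted = tab["p"].to_numpy()[order]
    match = (tab["direction"].to_numpy()[order] == direction).astype(int)
    cum_total = np.arange(1, len(p_sorted) + 1)
    cum_match = np.cumsum(match)
    # keep the last row of each tie block so counts are inclusive of ties
    is_last = np.ones(len(p_sorted), dtype=bool)
    is_last[:-1] = p_sorted[:-1] != p_sorted[1:]
    return pd.DataFrame(
        {
            "cutoff": p_sorted[is_last],
            "n_sites": cum_total[is_last],
            "n_directional": cum_match[is_last],
            "proportion": cum_match[is_last] / cum_total[is_last],
        }
    ).reset_index(drop=True)


def select_threshold(
    ewas_table: pd.DataFrame, direction: int = +1, min_proportion: float = 0.95
) -> float | None:
    """Largest observed P value c with directional proportion >= min_proportion
    among sites at P <= c; None when no cutoff qualifies."""
    curve = directionality_curve(ewas_table, direction)
    ok = curve["proportion"].to_numpy() >= min_proportion
    if not ok.any():
        return None
    return float(curve["cutoff"].to_numpy()[np.flatnonzero(ok)[-1]])


def select_hyper_set(
    ewas_table: pd.DataFrame,
    direction: int = +1,
    min_proportion: float = 0.95,
    fallback_k: int = 2000,
    source: str = "",
) -> HyperSet:
    """Directional significant-site set by the proportion rule, else top-K.

    When a qualifying cutoff exists the set is all directional sites with
    P <= cutoff; otherwise the ``fallback_k`` smallest-P directional sites
    (rule recorded as ``top_k``).
    """
    tab = _validated(ewas_table, direction)
    cutoff = select_threshold(tab, direction, min_proportion)
    directional = tab[tab["direction"] == direction]
    if cutoff is not None:
        members = directional.index[directional["p"] <= cutoff]
        return HyperSet(members, direction, "proportion_threshold", cutoff, None, source)
    if fallback_k > len(directional):
        warnings.warn(
            f"top-k fallback requested k={fallback_k} but only "
            f"{len(directional)} directional sites exist; taking all",
            stacklevel=2,
        )
        fallback_k = len(directional)
    members = directional["p"].nsmallest(fallback_k, keep="all").index
    return HyperSet(members, direction, "top_k", None, int(fallback_k), source)
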