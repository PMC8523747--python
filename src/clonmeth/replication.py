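"""Cross-cohort concordance of directional site sets and 2x2 association tests.

The dichotomous association test follows the classical dispatch rule:
Pearson chi-square (without continuity correction) unless any expected cell
count is below five, in which case Fisher's exact test is used.  Two-sided
Fisher P values use the point-probability method (sum of hypergeometric
tables no more probable than the observed one).  P values that underflow
are reported as the bound 1e-300 rather than zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from clonmeth.siteselect import HyperSet

__all__ = [
    "TwoByTwo",
    "chi_square_2x2",
    "fisher_exact_2x2",
    "expected_counts",
    "dispatch_2x2",
    "direction_concordance",
    "concordance_test",
    "set_overlap_report",
]

P_FLOOR = 1e-300


@dataclass
class TwoByTwo:
    """Integer 2x2 contingency table with axis labels."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("row1", "row2")
    col_labels: tuple[str, str] = ("col1", "col2")

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("cell counts must be non-negative integers")

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def _as_array(table) -> np.ndarray:
    if isinstance(table, TwoByTwo):
        return table.to_array()
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    return arr


def _zero_margin(arr: np.ndarray) -> bool:
    return bool((arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any())


def expected_counts(table) -> np.ndarray:
    """Expected cell counts under independence (row * column / total)."""
    arr = _as_array(table)
    n = arr.sum()
    if n == 0:
        return np.zeros((2, 2))
    return np.outer(arr.sum(axis=1), arr.sum(axis=0)) / n


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square without continuity correction; (statistic, P)."""
    arr = _as_array(table)
    if _zero_margin(arr):
        warnings.warn("zero margin in 2x2 table; returning P = 1", stacklevel=2)
        return 0.0, 1.0
    stat, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), float(max(p, P_FLOOR))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact P (point-probability method)."""
    arr = _as_array(table)
    if _zero_margin(arr):
        warnings.warn("zero margin in 2x2 table; returning P = 1", stacklevel=2)
        return 1.0
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(max(p, P_FLOOR))


def dispatch_2x2(table) -> tuple[str, float, float]:
    """Apply the expected-count-5 rule; returns (method, statistic, P).

    statistic is NaN for the Fisher branch.
    """
    arr = _as_array(table)
    if _zero_margin(arr) or (expected_counts(arr) < 5).any():
        return "fisher", float("nan"), fisher_exact_2x2(arr)
    stat, p = chi_square_2x2(arr)
    return "chi2", stat, p


# ---------------------------------------------------------------------------
# concordance


def _member_probes(site_set) -> pd.Index:
    if isinstance(site_set, HyperSet):
        return pd.Index(site_set.probes)
    return pd.Index(site_set)


def _set_direction(site_set, direction: int | None) -> int:
    if direction is not None:
        return direction
    if isinstance(site_set, HyperSet):
        return site_set.direction
    raise ValueError("direction required when site_set is a plain probe list")


def direction_concordance(
    site_set, target_ewas: pd.DataFrame, direction: int | None = None
) -> tuple[int, int, float]:
    """How many of a source cohort's sites keep their direction elsewhere.

    Returns (n_available, n_concordant, fraction); members absent from the
    target cohort (e.g. removed by its QC) are dropped from both numerator
    and denominator.
    """
    direction = _set_direction(site_set, direction)
    members = _member_probes(site_set)
    available = members.intersection(target_ewas.index)
    if len(available) == 0:
        warnings.warn("no member probes available in the target cohort", stacklevel=2)
        return 0, 0, float("nan")
    n_conc = int((target_ewas.loc[available, "direction"] == direction).sum())
    return len(available), n_conc, n_conc / len(available)


def concordance_test(
    site_set, target_ewas: pd.DataFrame, direction: int | None = None
) -> tuple[TwoByTwo, str, float]:
    """2x2 test of set membership against directional sign in a target cohort.

    Rows: probe in set / not in set (among the target's probes); columns:
    direction-positive (matching ``direction``) / not.  The test is
    dispatched by the expected-count rule.
    """
    direction = _set_direction(site_set, direction)
    members = _member_probes(site_set).intersection(target_ewas.index)
    in_set = target_ewas.index.isin(members)
    pos = (target_ewas["direction"] == direction).to_numpy()
    table = TwoByTwo(
        int((in_set & pos).sum()),
        int((in_set & ~pos).sum()),
        int((~in_set & pos).sum()),
        int((~in_set & ~pos).sum()),
        row_labels=("in_set", "out_of_set"),
        col_labels=("directional", "other"),
    )
    method, _, p = dispatch_2x2(table)
    return table, method, p


def set_overlap_report(
    ewas_a: pd.DataFrame,
    ewas_b: pd.DataFrame,
    sig_a: pd.Index | None = None,
    sig_b: pd.Index | None = None,
) -> pd.DataFrame:
    """Quadrant counts of shared probes by sign in two cohorts.

    Rows are the four (sign in A, sign in B) quadrants; when significance
    sets are given, per-quadrant counts of doubly significant probes are
    added (volcano-margin summaries).
    """
    shared = ewas_a.index.intersection(ewas_b.index)
    da = ewas_a.loc[shared, "direction"].to_numpy()
    db = ewas_b.loc[shared, "direction"].to_numpy()
    rows = []
    for sa in (+1, -1):
        for sb in (+1, -1):
            mask = (da == sa) & (db == sb)
            row = {"sign_a": sa, "sign_b": sb, "n": int(mask.sum())}
            if sig_a is not None and sig_b is not None:
                both = shared[mask].isin(sig_a) & shared[mask].isin(sig_b)
                row["n_both_significant"] = int(both.sum())
            rows.append(row)
    return pd.DataFrame(rows)
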