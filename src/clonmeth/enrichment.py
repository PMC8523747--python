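"""Chromatin-state / CpG-island composition enrichment and GREAT-style tests.

Region-to-gene assignment follows the "basal plus extension" regulatory
domain model: every gene owns a strand-aware basal window around its TSS
(5 kb upstream / 1 kb downstream by default) extended in both directions up
to 1 Mb, stopping early at the nearest neighboring basal domain.  Term
enrichment combines a region-level binomial test (does the selected site
set fall inside a term's domain union more often than its genome-coverage
fraction predicts?) with a gene-level hypergeometric test on genes hit by
at least one selected site.  Both are Bonferroni-corrected over terms.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from clonmeth.replication import dispatch_2x2

__all__ = [
    "annotate_sites",
    "composition_enrichment",
    "build_regulatory_domains",
    "domain_coverage_fraction",
    "great_binomial",
    "gene_hypergeometric",
    "great_enrichment",
    "enhancer_specificity_compare",
]

ENHANCER_STATES = ("EnhA", "EnhG")


# ---------------------------------------------------------------------------
# interval annotation


def _bed_trees(bed: pd.DataFrame) -> dict[str, IntervalTree]:
    """IntervalTree per chromosome from a BED frame (0-based half-open).

    Overlapping segments (malformed segmentations) are resolved
    first-interval-wins after sorting, with a warning.
    """
    trees: dict[str, IntervalTree] = {}
    bed = bed.sort_values(["chrom", "start", "end"], kind="stable")
    overlap_warned = False
    for chrom, grp in bed.groupby("chrom", sort=False):
        tree = IntervalTree()
        last_end = -1
        for start, end, name in zip(grp["start"], grp["end"], grp["name"]):
            if start < last_end and not overlap_warned:
                warnings.warn(
                    "overlapping intervals in segmentation; first interval wins",
                    stacklevel=3,
                )
                overlap_warned = True
            tree.addi(int(start), int(end), name)
            last_end = max(last_end, int(end))
        trees[str(chrom)] = tree
    return trees


def annotate_sites(
    sites: pd.DataFrame,
    chromhmm_bed: pd.DataFrame,
    island_map: pd.Series | None = None,
) -> pd.DataFrame:
    """Assign each 1-bp site its chromatin state (and island relation).

    ``sites`` needs columns chrom and pos (1-based); ``chromhmm_bed`` needs
    chrom/start/end/name with 0-based half-open intervals.  A position p
    (1-based) falls in interval [start, end) iff start <= p-1 < end; sites
    outside every interval get a missing state with a warning.
    """
    trees = _bed_trees(chromhmm_bed)
    states = []
    n_missing = 0
    for chrom, pos in zip(sites["chrom"].astype(str), sites["pos"].astype(int)):
        tree = trees.get(chrom)
        hits = sorted(tree[pos - 1]) if tree is not None else []
        if not hits:
            states.append(None)
            n_missing += 1
        else:
            states.append(hits[0].data)
    if n_missing:
        warnings.warn(f"{n_missing} sites outside the segmentation", stacklevel=2)
    out = pd.DataFrame({"state": states}, index=sites.index)
    if island_map is not None:
        out["island_relation"] = island_map.reindex(sites.index)
    return out


# ---------------------------------------------------------------------------
# composition enrichment


def composition_enrichment(
    hyper_probes: Sequence[str],
    all_sites: pd.DataFrame,
    category_field: str,
) -> pd.DataFrame:
    """Per-category 2x2 enrichment of a site set against the background.

    For each level of ``category_field`` in ``all_sites`` (indexed by probe),
    tests (in set vs not) x (in category vs not) with the chi-square/Fisher
    dispatcher and reports within-set and background proportions and their
    ratio.  Background = sites not in the set.
    """
    hyper_probes = pd.Index(hyper_probes)
    in_set = all_sites.index.isin(hyper_probes)
    cats = all_sites[category_field]
    n_set = int(in_set.sum())
    n_bg = int((~in_set).sum())
    rows = []
    for level in pd.unique(cats.dropna()):
        in_cat = (cats == level).to_numpy()
        a = int((in_set & in_cat).sum())
        b = n_set - a
        c = int((~in_set & in_cat).sum())
        d = n_bg - c
        method, _, p = dispatch_2x2([[a, b], [c, d]])
        prop_set = a / n_set if n_set else float("nan")
        prop_bg = c / n_bg if n_bg else float("nan")
        rows.append(
            {
                "category": level,
                "n_set": a,
                "set_size": n_set,
                "n_background": c,
                "background_size": n_bg,
                "prop_set": prop_set,
                "prop_background": prop_bg,
                "ratio": prop_set / prop_bg if prop_bg else float("inf"),
                "method": method,
                "p": p,
            }
        )
    out = pd.DataFrame(rows).sort_values("p", kind="stable").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# regulatory domains (basal plus extension)


def build_regulatory_domains(
    tss_table: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_extension: int = 1_000_000,
) -> pd.DataFrame:
    """Strand-aware basal-plus-extension regulatory domains per gene.

    ``tss_table`` needs columns gene, chrom, tss (1-based position), strand
    (+/-).  Returns a frame indexed by gene with 0-based half-open
    domain_start/domain_end plus the basal window, clipped to chromosome
    bounds.  Extensions stop at the nearest neighboring basal domain.
    """
    tab = tss_table.copy()
    tss0 = tab["tss"].astype(int) - 1  # 0-based TSS coordinate
    plus = tab["strand"].astype(str) == "+"
    basal_start = np.where(plus, tss0 - basal_up, tss0 - basal_down + 1)
    basal_end = np.where(plus, tss0 + basal_down, tss0 + basal_up + 1)
    tab["basal_start"] = basal_start
    tab["basal_end"] = basal_end
    tab["tss0"] = tss0

    out = []
    for chrom, grp in tab.groupby("chrom", sort=False):
        size = int(chrom_sizes[str(chrom)])
        grp = grp.sort_values("tss0", kind="stable")
        bs = np.clip(grp["basal_start"].to_numpy(), 0, size)
        be = np.clip(grp["basal_end"].to_numpy(), 0, size)
        t0 = grp["tss0"].to_numpy()
        # running extremes of neighboring basal domains
        prev_end = np.concatenate([[0], np.maximum.accumulate(be)[:-1]])
        next_start = np.concatenate(
            [np.minimum.accumulate(bs[::-1])[::-1][1:], [size]]
        )
        dom_start = np.minimum(bs, np.maximum(t0 - max_extension, prev_end))
        dom_end = np.maximum(be, np.minimum(t0 + max_extension, next_start))
        dom_start = np.clip(dom_start, 0, size)
        dom_end = np.clip(dom_end, 0, size)
        for g, c, s, e, b1, b2 in zip(
            grp["gene"], grp["chrom"], dom_start, dom_end, bs, be
        ):
            out.append(
                {
                    "gene": g,
                    "chrom": c,
                    "domain_start": int(s),
                    "domain_end": int(e),
                    "basal_start": int(b1),
                    "basal_end": int(b2),
                }
            )
    return pd.DataFrame(out).set_index("gene")


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _domain_union(domains: pd.DataFrame, genes: Sequence[str]) -> dict[str, list]:
    union: dict[str, list] = {}
    present = domains.index.intersection(pd.Index(genes))
    for _, row in domains.loc[present].iterrows():
        union.setdefault(str(row["chrom"]), []).append(
            (int(row["domain_start"]), int(row["domain_end"]))
        )
    return {c: _merge_intervals(v) for c, v in union.items()}


def domain_coverage_fraction(
    domains: pd.DataFrame, genes: Sequence[str], chrom_sizes: Mapping[str, int]
) -> float:
    """Fraction of the genome covered by the union of the genes' domains."""
    union = _domain_union(domains, genes)
    covered = sum(e - s for ivs in union.values() for s, e in ivs)
    total = sum(int(v) for v in chrom_sizes.values())
    return covered / total


def _sites_in_union(sites: pd.DataFrame, union: dict[str, list]) -> np.ndarray:
    hits = np.zeros(len(sites), dtype=bool)
    for i, (chrom, pos) in enumerate(
        zip(sites["chrom"].astype(str), sites["pos"].astype(int))
    ):
        for s, e in union.get(chrom, ()):
            if s <= pos - 1 < e:
                hits[i] = True
                break
    return hits


def great_binomial(
    selected_sites: pd.DataFrame,
    term_to_genes: Mapping[str, Sequence[str]],
    domains: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
) -> pd.DataFrame:
    """Region-level binomial enrichment test per term.

    Each selected site is a 1-bp region; for term t with genome-coverage
    fraction p_t of its domain union, P = upper-tail Binomial(n sites, p_t)
    at the observed in-domain count.  Bonferroni over terms.
    """
    n = len(selected_sites)
    rows = []
    for term, genes in term_to_genes.items():
        union = _domain_union(domains, genes)
        p_t = domain_coverage_fraction(domains, genes, chrom_sizes)
        k = int(_sites_in_union(selected_sites, union).sum())
        p = float(stats.binom.sf(k - 1, n, p_t)) if n else 1.0
        rows.append(
            {
                "term": term,
                "n_hits": k,
                "n_sites": n,
                "coverage_fraction": p_t,
                "fold": (k / n) / p_t if (n and p_t) else float("nan"),
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(1.0, out["p"] * len(out))
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def gene_hypergeometric(
    selected_sites: pd.DataFrame,
    term_to_genes: Mapping[str, Sequence[str]],
    domains: pd.DataFrame,
) -> pd.DataFrame:
    """Gene-level hypergeometric enrichment test per term.

    A gene is "hit" when at least one selected site lies in its regulatory
    domain; the upper-tail hypergeometric compares term-annotated hit genes
    against the gene universe.  Bonferroni over terms.
    """
    hit_genes = set()
    for gene, row in domains.iterrows():
        chrom = str(row["chrom"])
        s, e = int(row["domain_start"]), int(row["domain_end"])
        on_chrom = selected_sites["chrom"].astype(str) == chrom
        pos0 = selected_sites.loc[on_chrom, "pos"].astype(int) - 1
        if ((pos0 >= s) & (pos0 < e)).any():
            hit_genes.add(gene)
    N = len(domains)
    n_hit = len(hit_genes)
    rows = []
    for term, genes in term_to_genes.items():
        term_genes = set(genes) & set(domains.index)
        K = len(term_genes)
        k = len(term_genes & hit_genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n_hit)) if K else 1.0
        rows.append(
            {"term": term, "n_term_genes": K, "n_hit_genes": n_hit, "n_term_hits": k, "p": p}
        )
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(1.0, out["p"] * len(out))
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def great_enrichment(
    selected_sites: pd.DataFrame,
    term_to_genes: Mapping[str, Sequence[str]],
    domains: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Combined region-binomial + gene-hypergeometric enrichment.

    A term is called enriched when Bonferroni-corrected P < alpha in BOTH
    tests.
    """
    binom = great_binomial(selected_sites, term_to_genes, domains, chrom_sizes)
    hyper = gene_hypergeometric(selected_sites, term_to_genes, domains)
    merged = binom.merge(hyper, on="term", suffixes=("_binomial", "_hypergeom"))
    merged["enriched"] = (merged["p_bonferroni_binomial"] < alpha) & (
        merged["p_bonferroni_hypergeom"] < alpha
    )
    return merged.sort_values("p_binomial", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# cell-type-specific enhancer comparison


def enhancer_specificity_compare(
    ewas_table: pd.DataFrame,
    annotation: pd.DataFrame,
    celltype_a: str,
    celltype_b: str,
    enhancer_states: Sequence[str] = ENHANCER_STATES,
    equal_var: bool = False,
) -> dict:
    """Compare scaled effect sizes at A-specific vs B-specific enhancers.

    "A-specific" probes are enhancer-state in cell type A's segmentation
    (column ``state_<A>`` of ``annotation``) and not in B's.  Effect
    estimates are z-scaled over all probes in the table; the group contrast
    is a two-sided t test (Welch by default) with normal-approximation 95%
    CIs on the group means.
    """
    shared = ewas_table.index.intersection(annotation.index)
    eff = ewas_table.loc[shared, "estimate"].to_numpy(dtype=float)
    scaled = (eff - eff.mean()) / eff.std(ddof=1)
    in_a = annotation.loc[shared, f"state_{celltype_a}"].isin(enhancer_states).to_numpy()
    in_b = annotation.loc[shared, f"state_{celltype_b}"].isin(enhancer_states).to_numpy()
    grp_a = scaled[in_a & ~in_b]
    grp_b = scaled[in_b & ~in_a]
    if len(grp_a) < 2 or len(grp_b) < 2:
        raise ValueError("need at least two probes per enhancer-specific group")
    t, p = stats.ttest_ind(grp_a, grp_b, equal_var=equal_var)

    def _ci(x: np.ndarray) -> tuple[float, float]:
        half = 1.959963984540054 * x.std(ddof=1) / np.sqrt(len(x))
        return float(x.mean() - half), float(x.mean() + half)

    return {
        "mean_a": float(grp_a.mean()),
        "ci_a": _ci(grp_a),
        "n_a": int(len(grp_a)),
        "mean_b": float(grp_b.mean()),
        "ci_b": _ci(grp_b),
        "n_b": int(len(grp_b)),
        "t": float(t),
        "p": float(p),
    }
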