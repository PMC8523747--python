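"""Synthetic cohorts with planted mutation-methylation effects.

The generator emulates the structure of an elderly-twin CHIP cohort and its
replication cohorts: per-probe beta values arise as cell-fraction-weighted
mixtures of cell-type reference profiles; TET2/DNMT3A carriers receive an
additive M-scale shift at "affected" probes proportional to their variant
allele frequency (clone size); twin pairs share a Gaussian pair intercept;
batches add probe-level shifts; and affected probes concentrate in
enhancer-annotated, CpG-poor regions.  Planted truth is recorded per probe
so downstream recovery can be scored exactly.

Defaults are calibrated for the recovery experiments the package's analyses
are validated on: 120 samples (45 twin pairs + 30 singletons), ~1/3 TET2
carriers, VAF ~ U(0.1, 0.5), an M-scale VAF slope of 5/3 (carrier mean
shift of 0.5 M units), residual noise SD 0.25 M units, ~1% of probes
affected with 10:1 enhancer bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from clonmeth.motifs import PWM, RankedRegions, pwm_from_consensus
from clonmeth.preprocess import MethylationCohort, RawArray, beta_to_m, m_to_beta

__all__ = [
    "CHROMHMM_STATES",
    "SimDesign",
    "make_annotation",
    "make_reference_profiles",
    "simulate_cohort",
    "simulate_motif_regions",
    "simulate_variant_calls",
    "simulate_raw_array",
    "make_pwm_set",
]

CHROMHMM_STATES = (
    "TssA",
    "TssAFlnk",
    "TxFlnk",
    "Tx",
    "TxWk",
    "EnhG",
    "EnhA",
    "ZNF_Rpts",
    "Het",
    "TssBiv",
    "BivFlnk",
    "EnhBiv",
    "ReprPC",
    "ReprPCWk",
    "Quies",
)

# monocyte-like genome composition of the 15 states
DEFAULT_STATE_PROPORTIONS = {
    "TssA": 0.02,
    "TssAFlnk": 0.02,
    "TxFlnk": 0.01,
    "Tx": 0.08,
    "TxWk": 0.12,
    "EnhG": 0.02,
    "EnhA": 0.06,
    "ZNF_Rpts": 0.01,
    "Het": 0.05,
    "TssBiv": 0.01,
    "BivFlnk": 0.01,
    "EnhBiv": 0.01,
    "ReprPC": 0.04,
    "ReprPCWk": 0.06,
    "Quies": 0.48,
}

DEFAULT_CELL_TYPES = ("granulocyte", "monocyte", "CD4T", "B")
ISLAND_RELATIONS = ("island", "shore", "shelf", "open_sea")

# island-relation composition conditional on the chromatin state class:
# promoters sit in islands, enhancers in CpG-poor open sea
_TSS_STATES = {"TssA", "TssAFlnk", "TssBiv", "BivFlnk"}
_ENH_STATES = {"EnhA", "EnhG", "EnhBiv"}
_ISLAND_PROBS = {
    "tss": (0.65, 0.20, 0.05, 0.10),
    "enh": (0.05, 0.15, 0.12, 0.68),
    "other": (0.28, 0.22, 0.10, 0.40),
}


def _default_affected() -> dict:
    return {
        "TET2": {"EnhA": 0.06, "EnhG": 0.06, "default": 0.006},
        "DNMT3A": {"EnhA": 0.008, "EnhG": 0.008, "default": 0.0008},
    }


@dataclass
class SimDesign:
    """Parameters of one simulated cohort.

    ``effect_model`` maps gene -> M-value shift per unit VAF at affected
    probes (positive = hypermethylation); ``affected_fraction_by_state``
    maps gene -> {chromatin state: probability a probe is affected}, with a
    ``default`` key for unlisted states.  ``vaf_distribution`` is the
    uniform support (lo, hi) of carrier VAFs, bounded inside (0.02, 0.6).
    """

    seed: int
    n_pairs: int = 45
    n_singletons: int = 30
    n_probes: int = 20_000
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES
    mutation_rates: Mapping[str, float] = field(
        default_factory=lambda: {"TET2": 1.0 / 3.0, "DNMT3A": 0.15}
    )
    vaf_distribution: tuple[float, float] = (0.10, 0.50)
    effect_model: Mapping[str, float] = field(
        default_factory=lambda: {"TET2": 5.0 / 3.0, "DNMT3A": -5.0 / 3.0}
    )
    affected_fraction_by_state: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_affected
    )
    noise_sd: float = 0.25
    twin_sd: float | None = None  # defaults to 0.5 * noise_sd
    n_batches: int = 2
    batch_sd: float = 0.10
    monocyte_bump: float = 0.03
    cell_fraction_base: Mapping[str, float] = field(
        default_factory=lambda: {"granulocyte": 0.60, "monocyte": 0.08, "CD4T": 0.22, "B": 0.10}
    )
    cell_fraction_concentration: float = 150.0

    def __post_init__(self) -> None:
        for gene, rate in self.mutation_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"mutation rate for {gene} outside [0, 1]")
        lo, hi = self.vaf_distribution
        if not (0.02 <= lo < hi <= 0.60):
            raise ValueError("VAF support must lie inside (0.02, 0.6)")
        for gene, by_state in self.affected_fraction_by_state.items():
            for state, frac in by_state.items():
                if not 0.0 <= frac <= 1.0:
                    raise ValueError(f"affected fraction {gene}/{state} outside [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def n_samples(self) -> int:
        return 2 * self.n_pairs + self.n_singletons

    @property
    def pair_sd(self) -> float:
        return 0.5 * self.noise_sd if self.twin_sd is None else self.twin_sd


# ---------------------------------------------------------------------------
# annotation


def _segment_genome(
    rng: np.random.Generator,
    genome_length: int,
    proportions: np.ndarray,
    mean_segment: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Random tiling of [0, genome_length) into state-labelled segments.

    Returns (boundaries including 0 and genome_length, state index per
    segment); segments are non-overlapping by construction.
    """
    n_seg = max(2, genome_length // mean_segment)
    cuts = np.sort(rng.choice(np.arange(1, genome_length), size=n_seg - 1, replace=False))
    bounds = np.concatenate([[0], cuts, [genome_length]])
    states = rng.choice(len(proportions), size=n_seg, p=proportions)
    return bounds, states


def make_annotation(
    n_probes: int,
    genome_length: int | None = None,
    state_proportions: Mapping[str, float] | None = None,
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES,
    seed: int = 0,
    chrom: str = "chr1",
    mean_segment: int = 1000,
    n_genes: int | None = None,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], pd.DataFrame]:
    """Probe manifest plus per-cell-type chromatin segmentations and a TSS table.

    Returns (annotation, beds, tss): ``annotation`` is indexed by probe id
    with chrom, pos (1-based), island_relation and one ``state_<celltype>``
    column per cell type; ``beds`` maps cell type to a BED frame (0-based
    half-open, non-overlapping, tiling the genome); ``tss`` has gene, chrom,
    tss (1-based), strand.
    """
    rng = np.random.default_rng(seed)
    if genome_length is None:
        genome_length = 1000 * n_probes
    if n_probes > genome_length:
        raise ValueError("n_probes exceeds genome capacity")
    props = dict(DEFAULT_STATE_PROPORTIONS if state_proportions is None else state_proportions)
    if set(props) != set(CHROMHMM_STATES):
        raise ValueError("state_proportions must cover exactly the 15 states")
    pvec = np.array([props[s] for s in CHROMHMM_STATES], dtype=float)
    if abs(pvec.sum() - 1.0) > 1e-6:
        raise ValueError("state proportions must sum to 1")

    positions = np.sort(rng.choice(genome_length, size=n_probes, replace=False)) + 1
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    ann = pd.DataFrame({"chrom": chrom, "pos": positions}, index=pd.Index(probe_ids, name="probe"))

    beds: dict[str, pd.DataFrame] = {}
    for ct in cell_types:
        bounds, states = _segment_genome(rng, genome_length, pvec, mean_segment)
        beds[ct] = pd.DataFrame(
            {
                "chrom": chrom,
                "start": bounds[:-1],
                "end": bounds[1:],
                "name": [CHROMHMM_STATES[s] for s in states],
            }
        )
        seg_of_probe = np.searchsorted(bounds, positions - 1, side="right") - 1
        ann[f"state_{ct}"] = [CHROMHMM_STATES[s] for s in states[seg_of_probe]]

    ref_ct = "monocyte" if "monocyte" in cell_types else cell_types[0]
    ref_states = ann[f"state_{ref_ct}"]
    klass = np.where(
        ref_states.isin(_TSS_STATES), "tss", np.where(ref_states.isin(_ENH_STATES), "enh", "other")
    )
    island = np.empty(n_probes, dtype=object)
    for kl, probs in _ISLAND_PROBS.items():
        mask = klass == kl
        island[mask] = rng.choice(ISLAND_RELATIONS, size=int(mask.sum()), p=probs)
    ann["island_relation"] = island

    if n_genes is None:
        n_genes = max(20, n_probes // 20)
    tss_pos = np.sort(rng.choice(genome_length, size=n_genes, replace=False)) + 1
    tss = pd.DataFrame(
        {
            "gene": [f"G{i:05d}" for i in range(n_genes)],
            "chrom": chrom,
            "tss": tss_pos,
            "strand": rng.choice(["+", "-"], size=n_genes),
        }
    )
    return ann, beds, tss


# ---------------------------------------------------------------------------
# reference profiles


_ISLAND_BETA_PARAMS = {
    "island": (1.5, 15.0),
    "shore": (4.0, 6.0),
    "shelf": (8.0, 4.0),
    "open_sea": (15.0, 3.0),
}


def make_reference_profiles(
    annotation: pd.DataFrame,
    cell_types: Sequence[str] = DEFAULT_CELL_TYPES,
    seed: int = 0,
    n_markers_per_type: int = 25,
    celltype_sd: float = 0.2,
) -> tuple[pd.DataFrame, pd.Index]:
    """Reference beta profiles (cell types x probes) plus marker probes.

    Baseline methylation follows the CpG-island relation (islands low, open
    sea high) with small cell-type-specific M-scale deviations.  For each
    cell type a disjoint block of marker probes is set to beta 0.9 in that
    type and 0.1 in all others, so every pair of cell types differs by
    |delta beta| >= 0.5 at some markers and deconvolution is identifiable.
    """
    cell_types = list(cell_types)
    if len(cell_types) != len(set(cell_types)):
        raise ValueError("duplicate cell types requested (non-identifiable)")
    if len(cell_types) < 2:
        raise ValueError("need at least two cell types")
    rng = np.random.default_rng(seed)
    n_probes = len(annotation)
    if n_markers_per_type * len(cell_types) > n_probes:
        raise ValueError("too few probes for the requested marker blocks")

    base = np.empty(n_probes)
    rel = annotation["island_relation"].to_numpy()
    for relation, (a, b) in _ISLAND_BETA_PARAMS.items():
        mask = rel == relation
        base[mask] = rng.beta(a, b, size=int(mask.sum()))
    base = np.clip(base, 0.01, 0.99)

    base_m = beta_to_m(base)
    profiles = np.vstack(
        [base_m + rng.normal(0.0, celltype_sd, size=n_probes) for _ in cell_types]
    )
    profiles = m_to_beta(profiles)

    marker_idx = rng.choice(n_probes, size=n_markers_per_type * len(cell_types), replace=False)
    for k, _ in enumerate(cell_types):
        block = marker_idx[k * n_markers_per_type : (k + 1) * n_markers_per_type]
        profiles[:, block] = 0.1
        profiles[k, block] = 0.9
    out = pd.DataFrame(profiles, index=pd.Index(cell_types, name="cell_type"), columns=annotation.index)
    return out, annotation.index[np.sort(marker_idx)]


# ---------------------------------------------------------------------------
# cohort simulation


def _draw_affected(
    rng: np.random.Generator, states: pd.Series, by_state: Mapping[str, float]
) -> np.ndarray:
    default = by_state.get("default", 0.0)
    probs = states.map(lambda s: by_state.get(s, default)).to_numpy(dtype=float)
    return rng.random(len(states)) < probs


def simulate_cohort(
    design: SimDesign,
    annotation: pd.DataFrame,
    references: pd.DataFrame,
    ref_celltype: str | None = None,
    truth: pd.DataFrame | None = None,
) -> tuple[MethylationCohort, pd.DataFrame]:
    """Simulate a twin cohort with planted mutation effects.

    Returns (cohort, truth) where ``truth`` is indexed by probe with
    per-gene affected flags and planted M-per-VAF effect sizes plus the
    chromatin state and island relation used for planting.  Passing the
    ``truth`` table of a previous run reuses its affected sites, so
    replication cohorts share the same mutation-target loci (the targets
    are a property of the biology, not of the cohort).
    """
    probes = annotation.index
    if len(probes.difference(references.columns)):
        raise ValueError("reference profiles do not cover all probes")
    rng = np.random.default_rng(design.seed)
    n = design.n_samples
    cell_types = list(references.index)

    sample_ids = [f"S{i:04d}" for i in range(n)]
    pair_ids: list = []
    ages = np.empty(n)
    sexes = np.empty(n, dtype=object)
    for j in range(design.n_pairs):
        age = rng.integers(70, 91)
        sex = rng.choice(["F", "M"])
        for _ in range(2):
            pair_ids.append(f"pair{j:03d}")
            ages[len(pair_ids) - 1] = age
            sexes[len(pair_ids) - 1] = sex
    for _ in range(design.n_singletons):
        pair_ids.append(None)
        ages[len(pair_ids) - 1] = rng.integers(70, 91)
        sexes[len(pair_ids) - 1] = rng.choice(["F", "M"])
    batches = rng.choice([f"batch{k}" for k in range(design.n_batches)], size=n)

    meta = pd.DataFrame(
        {"age": ages, "sex": sexes, "batch": batches, "pair": pair_ids},
        index=pd.Index(sample_ids, name="sample"),
    )
    lo, hi = design.vaf_distribution
    for gene, rate in design.mutation_rates.items():
        carrier = rng.random(n) < rate
        vaf = np.where(carrier, rng.uniform(lo, hi, size=n), np.nan)
        meta[f"mut_{gene}"] = carrier.astype(int)
        meta[f"vaf_{gene}"] = vaf

    ref_ct = ref_celltype or ("monocyte" if "monocyte" in annotation.columns.str.replace("state_", "").tolist() else None)
    state_col = f"state_{ref_ct}" if ref_ct else [c for c in annotation.columns if c.startswith("state_")][0]
    states = annotation[state_col]

    if truth is None:
        truth = pd.DataFrame(index=probes)
        truth["state"] = states
        truth["island_relation"] = annotation["island_relation"]
        for gene in design.mutation_rates:
            by_state = design.affected_fraction_by_state.get(gene, {})
            affected = _draw_affected(rng, states, by_state)
            truth[f"affected_{gene}"] = affected
            truth[f"effect_{gene}"] = np.where(
                affected, design.effect_model.get(gene, 0.0), 0.0
            )
    else:
        if not truth.index.equals(probes):
            raise ValueError("provided truth table does not match the probe set")
        truth = truth.copy()

    # cell fractions: Dirichlet around the base composition, monocyte bump
    # for TET2 carriers
    alpha = np.array(
        [design.cell_fraction_base.get(ct, 1.0 / len(cell_types)) for ct in cell_types]
    )
    alpha = alpha / alpha.sum() * design.cell_fraction_concentration
    fractions = rng.dirichlet(alpha, size=n)
    if "monocyte" in cell_types and "mut_TET2" in meta:
        mono = cell_types.index("monocyte")
        carriers = meta["mut_TET2"].to_numpy(dtype=bool)
        fractions[carriers, mono] += design.monocyte_bump
        fractions[carriers] /= fractions[carriers].sum(axis=1, keepdims=True)
    frac_df = pd.DataFrame(fractions, index=meta.index, columns=cell_types)

    R = references.loc[:, probes].to_numpy(dtype=float)
    M = beta_to_m(fractions @ R)

    # twin-pair random intercept, drawn per (pair, probe): co-twins share a
    # probe-specific deviation, matching the per-CpG random-intercept model
    pair_series = pd.Series(pair_ids, index=meta.index)
    for pid, members in pair_series.dropna().groupby(pair_series.dropna()).groups.items():
        M[meta.index.get_indexer(members)] += rng.normal(0.0, design.pair_sd, size=len(probes))

    # per-(batch, probe) shifts
    for b in np.unique(batches):
        shift = rng.normal(0.0, design.batch_sd, size=len(probes))
        M[batches == b] += shift

    # planted mutation effects, proportional to clone size
    for gene in design.mutation_rates:
        slope = design.effect_model.get(gene, 0.0)
        affected = truth[f"affected_{gene}"].to_numpy()
        carriers = meta[f"mut_{gene}"].to_numpy(dtype=bool)
        if slope and affected.any() and carriers.any():
            vaf = meta.loc[carriers, f"vaf_{gene}"].to_numpy(dtype=float)
            M[np.ix_(carriers, affected)] += slope * vaf[:, None]

    if design.noise_sd > 0:
        M += rng.normal(0.0, design.noise_sd, size=M.shape)

    beta = pd.DataFrame(m_to_beta(M), index=meta.index, columns=probes)
    cohort = MethylationCohort(beta, meta, frac_df)
    return cohort, truth


# ---------------------------------------------------------------------------
# companion fixtures


def simulate_variant_calls(
    cohort: MethylationCohort, seed: int = 0, n_artifacts: int = 20
) -> pd.DataFrame:
    """Variant-call table for the cohort's planted mutations plus artifacts.

    True calls carry the metadata VAFs with negligible population MAF;
    artifact rows exercise each exclusion rule (sub-threshold VAF, common
    germline MAF, and twin-concordant near-heterozygous VAF).
    """
    rng = np.random.default_rng(seed)
    rows = []
    meta = cohort.samples
    genes = [c.removeprefix("mut_") for c in meta.columns if c.startswith("mut_")]
    for sample, row in meta.iterrows():
        for gene in genes:
            if row[f"mut_{gene}"]:
                rows.append(
                    {
                        "sample": sample,
                        "gene": gene,
                        "vaf": row[f"vaf_{gene}"],
                        "maf": float(rng.uniform(0, 0.001)),
                        "twin_concordant": False,
                    }
                )
    kinds = ["low_vaf", "common", "germline"]
    for i in range(n_artifacts):
        sample = rng.choice(meta.index)
        kind = kinds[i % 3]
        rows.append(
            {
                "sample": sample,
                "gene": "ARTIFACT",
                "vaf": float(rng.uniform(0.002, 0.019))
                if kind == "low_vaf"
                else float(rng.uniform(0.40, 0.60)),
                "maf": float(rng.uniform(0.02, 0.4)) if kind == "common" else 0.0,
                "twin_concordant": kind == "germline",
            }
        )
    return pd.DataFrame(rows)


def simulate_raw_array(
    cohort: MethylationCohort,
    seed: int = 0,
    p_fail: float = 0.0005,
    p_low_bead: float = 0.0005,
    p_zero: float = 0.0002,
) -> RawArray:
    """Wrap a cohort's betas with plausible detection/bead-count QC channels."""
    rng = np.random.default_rng(seed)
    shape = cohort.beta.shape
    detection = pd.DataFrame(
        np.where(rng.random(shape) < p_fail, rng.uniform(0.02, 0.5, shape), rng.uniform(0, 0.005, shape)),
        index=cohort.beta.index,
        columns=cohort.beta.columns,
    )
    beads = pd.DataFrame(
        np.where(rng.random(shape) < p_low_bead, rng.integers(0, 3, shape), rng.poisson(12, shape) + 3),
        index=cohort.beta.index,
        columns=cohort.beta.columns,
    )
    zero = pd.DataFrame(
        rng.random(shape) < p_zero, index=cohort.beta.index, columns=cohort.beta.columns
    )
    return RawArray(cohort.beta, detection, beads, zero)


# ---------------------------------------------------------------------------
# motif regions


def make_pwm_set(
    n_motifs: int = 5,
    length: int = 8,
    seed: int = 0,
    families: Sequence[str] | None = None,
    p: float = 0.85,
) -> list[PWM]:
    """Random informative PWMs with optional family labels (cycled)."""
    rng = np.random.default_rng(seed)
    pwms = []
    for i in range(n_motifs):
        consensus = "".join(rng.choice(list("ACGT"), size=length))
        fam = families[i % len(families)] if families else None
        pwms.append(pwm_from_consensus(f"TF{i + 1:03d}", consensus, p=p, family=fam))
    return pwms


def simulate_motif_regions(
    pwm: PWM,
    n_regions: int,
    region_length: int = 200,
    planted_top_fraction: float = 0.2,
    consensus_mutation_rate: float = 0.0,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
) -> tuple[RankedRegions, np.ndarray]:
    """Ranked background regions with the PWM's consensus planted on top.

    The consensus (each base independently mutated with probability
    ``consensus_mutation_rate``) is embedded at a random offset in the top
    ``round(planted_top_fraction * n_regions)`` regions of the descending
    ranking; all other sequence is background.  Returns (regions, truth)
    with ``truth`` flagging planted regions in rank order.
    """
    if not 0.0 <= planted_top_fraction <= 1.0:
        raise ValueError("planted_top_fraction must lie in [0, 1]")
    if region_length < len(pwm):
        raise ValueError("region_length shorter than the motif")
    rng = np.random.default_rng(seed)
    bg = np.asarray(background, dtype=float)
    bg = bg / bg.sum()
    n_planted = int(round(planted_top_fraction * n_regions))
    scores = np.sort(rng.normal(size=n_regions))[::-1]
    bases = np.array(list("ACGT"))
    seqs = []
    truth = np.zeros(n_regions, dtype=bool)
    consensus = pwm.consensus
    for i in range(n_regions):
        seq = rng.choice(bases, size=region_length, p=bg)
        if i < n_planted:
            motif = list(consensus)
            for k in range(len(motif)):
                if rng.random() < consensus_mutation_rate:
                    motif[k] = rng.choice([b for b in "ACGT" if b != motif[k]])
            off = rng.integers(0, region_length - len(motif) + 1)
            seq[off : off + len(motif)] = list(motif)
            truth[i] = True
        seqs.append("".join(seq))
    regions = RankedRegions([f"R{i:05d}" for i in range(n_regions)], seqs, scores)
    return regions, truth
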