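"""PWM scanning of ranked 200 bp regions and partition-maximized enrichment.

Each transcription-factor motif is scored against every region by the
maximum log-odds over all window positions on both strands; a region is a
"hit" when that score is non-negative (the motif model is at least as
likely as the background).  Enrichment of hits among highly ranked
(most-hypermethylated) regions is found by partition maximization: for
every rank cut i, a one-sided Fisher exact test on the (top-i vs rest) x
(hit vs miss) table, taking the minimum P over cuts and correcting the
result (E value) for the number of motifs and partitions tested.  A motif
is called enriched when E < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from pyfaidx import Fasta
from scipy import stats

from clonmeth.replication import fisher_exact_2x2

__all__ = [
    "PWM",
    "RankedRegions",
    "read_meme",
    "write_meme",
    "pwm_from_consensus",
    "log_odds",
    "score_region",
    "score_regions",
    "extract_regions",
    "composite_score",
    "ame_partition_fisher",
    "family_enrichment",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES + "N")}
_COMPLEMENT = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N->N


@dataclass
class PWM:
    """Position probability matrix over A, C, G, T.

    ``matrix`` has shape (length, 4) with rows summing to one;
    ``background`` holds the 0-order background nucleotide frequencies.
    """

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    family: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (length, 4)")
        if (self.matrix < 0).any():
            raise ValueError("PWM probabilities must be non-negative")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


@dataclass
class RankedRegions:
    """Fixed-length sequences ordered by decreasing hypermethylation score."""

    ids: list
    sequences: list
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if np.isnan(self.scores).any():
            raise ValueError("ranking scores contain NaN")
        if len(self.ids) != len(self.sequences) or len(self.ids) != len(self.scores):
            raise ValueError("ids, sequences and scores must align")
        bad = set("".join(self.sequences).upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"sequences contain invalid characters: {sorted(bad)}")
        order = np.argsort(-self.scores, kind="stable")
        self.ids = [self.ids[i] for i in order]
        self.sequences = [self.sequences[i].upper() for i in order]
        self.scores = self.scores[order]

    def __len__(self) -> int:
        return len(self.ids)


# ---------------------------------------------------------------------------
# MEME-minimal I/O


def read_meme(path, family_map: Mapping[str, str] | None = None) -> list[PWM]:
    """Parse a MEME-minimal motif file into PWMs.

    A missing background line defaults to uniform frequencies.  Optional
    ``family_map`` assigns family labels (e.g. ETS, C/EBP) by motif name.
    """
    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
        out = []
        for mot in records:
            counts = np.array(
                [[mot.counts[b][i] for b in BASES] for i in range(mot.length)],
                dtype=float,
            )
            probs = counts / counts.sum(axis=1, keepdims=True)
            bg = np.array([mot.background.get(b, 0.25) for b in BASES], dtype=float)
            name = mot.name
            fam = family_map.get(name) if family_map else None
            out.append(PWM(name, probs, bg, fam))
    return out


def write_meme(pwms: Sequence[PWM], path) -> None:
    """Write PWMs in MEME-minimal format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.5f}" for b, f in zip(BASES, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(pwm)} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def pwm_from_consensus(
    name: str,
    consensus: str,
    p: float = 0.85,
    family: str | None = None,
    background: np.ndarray | None = None,
) -> PWM:
    """Informative PWM putting probability ``p`` on each consensus base."""
    consensus = consensus.upper()
    off = (1.0 - p) / 3.0
    mat = np.full((len(consensus), 4), off)
    for i, base in enumerate(consensus):
        mat[i, _BASE_INDEX[base]] = p
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return PWM(name, mat, bg, family)


# ---------------------------------------------------------------------------
# scanning


def log_odds(pwm: PWM, pseudocount: float = 1e-3) -> np.ndarray:
    """Log-odds score matrix of shape (length, 5); the N column scores 0.

    score[l, b] = log2((p[l, b] + pseudocount) / background[b]).
    """
    with np.errstate(divide="ignore"):
        lo = np.log2((pwm.matrix + pseudocount) / pwm.background[None, :])
    return np.hstack([lo, np.zeros((len(pwm), 1))])


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[ch] for ch in seq.upper()], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - guarded by RankedRegions
        raise ValueError(f"invalid base {exc}") from exc


def _reverse_complement_matrix(lo: np.ndarray) -> np.ndarray:
    return lo[::-1, _COMPLEMENT]


def score_region(seq: str, lo: np.ndarray) -> float:
    """Max log-odds over all window positions on both strands."""
    idx = _encode(seq)
    L = lo.shape[0]
    if len(idx) < L:
        return float("-inf")
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)  # (n_win, L)
    pos = np.arange(L)
    fwd = lo[pos, windows].sum(axis=1)
    rc = _reverse_complement_matrix(lo)
    rev = rc[pos, windows].sum(axis=1)
    return float(max(fwd.max(), rev.max()))


def score_regions(sequences: Sequence[str], pwm: PWM, pseudocount: float = 1e-3):
    lo = log_odds(pwm, pseudocount)
    return np.array([score_region(s, lo) for s in sequences])


# ---------------------------------------------------------------------------
# region extraction and ranking


def extract_regions(
    sites: pd.DataFrame, fasta_path, flank: int = 100, score_col: str = "score"
) -> RankedRegions:
    """Fixed-width regions centered on CpG sites, ranked by a score column.

    ``sites`` needs chrom, pos (1-based) and ``score_col``.  The region is
    [pos - flank, pos + flank) on the reference strand (2*flank bp); regions
    running off a contig end are clipped with a warning.
    """
    fasta = Fasta(str(fasta_path))
    seqs, ids, scores = [], [], []
    n_clipped = 0
    for probe, row in sites.iterrows():
        chrom = str(row["chrom"])
        pos0 = int(row["pos"]) - 1
        contig_len = len(fasta[chrom])
        start = pos0 - flank
        end = pos0 + flank
        if start < 0 or end > contig_len:
            n_clipped += 1
            start = max(start, 0)
            end = min(end, contig_len)
        seqs.append(str(fasta[chrom][start:end]).upper())
        ids.append(probe)
        scores.append(float(row[score_col]))
    if n_clipped:
        warnings.warn(f"{n_clipped} regions clipped at contig bounds", stacklevel=2)
    return RankedRegions(ids, seqs, np.array(scores))


def composite_score(effects_a, effects_b) -> np.ndarray:
    """Average of z-normalized effect estimates from two analyses.

    Combines two per-site effect measures (e.g. the mutation-status and the
    clone-size regressions) into one hypermethylation ranking score.
    """
    a = np.asarray(effects_a, dtype=float)
    b = np.asarray(effects_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("effect vectors must have equal length")

    def _z(x: np.ndarray) -> np.ndarray:
        sd = x.std(ddof=1)
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    return 0.5 * (_z(a) + _z(b))


# ---------------------------------------------------------------------------
# partition-maximized enrichment


def _partition_grid(n: int, max_partitions: int = 1000) -> np.ndarray:
    if n - 1 <= max_partitions:
        return np.arange(1, n)
    return np.unique(np.linspace(1, n - 1, max_partitions).astype(int))


def ame_partition_fisher(
    ranked_regions: RankedRegions,
    pwm_set: Sequence[PWM],
    hit_threshold: float = 0.0,
    pseudocount: float = 1e-3,
    max_partitions: int = 1000,
    correct_partitions: bool = True,
    e_max: float = 0.05,
) -> pd.DataFrame:
    """Ranked motif enrichment by partition-maximized Fisher exact test.

    For each motif, regions are hits when their max log-odds >= the
    threshold (0 bits: motif at least as likely as background).  At every
    partition cut i the one-sided Fisher P for over-representation of hits
    among the top i regions is computed; the minimum over cuts, corrected
    for the number of motifs (and, by default, partitions) tested, is the
    E value.  Motifs longer than the regions are skipped with a warning.
    """
    n = len(ranked_regions)
    if n < 2:
        raise ValueError("need at least two regions")
    cuts = _partition_grid(n, max_partitions)
    usable = []
    for pwm in pwm_set:
        if len(pwm) > min(len(s) for s in ranked_regions.sequences):
            warnings.warn(f"motif {pwm.name} longer than regions; skipped", stacklevel=2)
            continue
        usable.append(pwm)
    n_tests = len(usable) * (len(cuts) if correct_partitions else 1)
    rows = []
    for pwm in usable:
        scores = score_regions(ranked_regions.sequences, pwm, pseudocount)
        hits = scores >= hit_threshold
        K = int(hits.sum())
        # one-sided enrichment P at each cut from the hypergeometric tail
        a = np.cumsum(hits)[cuts - 1]  # hits among top i
        pvals = stats.hypergeom.sf(a - 1, n, K, cuts)
        best = int(np.argmin(pvals))
        p_star = float(max(pvals[best], 1e-300))
        evalue = min(1.0, p_star * n_tests)
        rows.append(
            {
                "motif": pwm.name,
                "family": pwm.family,
                "n_hits": K,
                "best_partition": int(cuts[best]),
                "p": p_star,
                "evalue": evalue,
                "enriched": evalue < e_max,
                "hit_threshold": hit_threshold,
            }
        )
    return pd.DataFrame(rows)


def family_enrichment(
    results: pd.DataFrame, family_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Per-family 2x2 Fisher test of enriched-motif counts vs other motifs.

    ``results`` is the output of :func:`ame_partition_fisher`; families come
    from its ``family`` column or from ``family_map``.  Degenerate margins
    (a family covering all motifs, or no enriched motif anywhere) give
    P = 1 with a warning.
    """
    res = results.copy()
    if family_map is not None:
        res["family"] = res["motif"].map(family_map)
    rows = []
    enriched = res["enriched"].to_numpy(dtype=bool)
    families = pd.unique(res["family"].dropna()) if "family" in res else []
    if len(families) == 0:
        warnings.warn("no family labels available", stacklevel=2)
        return pd.DataFrame(
            columns=["family", "n_enriched", "n_total", "proportion", "p"]
        )
    for fam in families:
        in_fam = (res["family"] == fam).to_numpy()
        a = int((in_fam & enriched).sum())
        b = int((in_fam & ~enriched).sum())
        c = int((~in_fam & enriched).sum())
        d = int((~in_fam & ~enriched).sum())
        p = fisher_exact_2x2([[a, b], [c, d]])
        rows.append(
            {
                "family": fam,
                "n_enriched": a,
                "n_total": a + b,
                "proportion": a / (a + b) if a + b else float("nan"),
                "p": p,
            }
        )
    return pd.DataFrame(rows).sort_values("p", kind="stable").reset_index(drop=True)
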