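"""Probe-level QC, beta/M transforms, cell deconvolution, and variant filtering.

The QC rules mirror standard Illumina methylation-array practice: probes are
dropped if any sample shows zero signal or fewer than three beads, if the
per-probe detection call rate falls below 0.95, if they target a sex
chromosome, or if they appear on cross-reactive / SNP-affected exclusion
lists.  Samples with overall call rate below the same threshold are removed
before probe-level rates are computed.

Cell-type deconvolution follows the reference-based (Houseman-style)
constrained-projection formulation: per sample, non-negative cell fractions
summing to at most one are fit by least squares against reference profiles
restricted to cell-type-discriminative probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

SEX_CHROMS = {"chrX", "chrY", "X", "Y"}

__all__ = [
    "RawArray",
    "MethylationCohort",
    "QCReport",
    "beta_to_m",
    "m_to_beta",
    "filter_probes",
    "estimate_cell_fractions",
    "pca_outlier_screen",
    "batch_center",
    "filter_variant_calls",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class RawArray:
    """Pre-QC array data: beta values plus per-(sample, probe) QC channels.

    All frames are samples x probes with identical index/columns.
    """

    beta: pd.DataFrame
    detection_p: pd.DataFrame
    bead_count: pd.DataFrame
    zero_signal: pd.DataFrame

    def __post_init__(self) -> None:
        shape = self.beta.shape
        for name in ("detection_p", "bead_count", "zero_signal"):
            other = getattr(self, name)
            if other.shape != shape:
                raise ValueError(f"{name} shape {other.shape} != beta shape {shape}")
            if not other.index.equals(self.beta.index) or not other.columns.equals(
                self.beta.columns
            ):
                raise ValueError(f"{name} index/columns differ from beta")


@dataclass
class MethylationCohort:
    """Post-QC methylation data with sample metadata.

    ``beta`` is samples x probes in (0, 1).  ``samples`` is indexed by sample
    id and carries age, sex, batch, nullable twin-pair id, per-gene mutation
    flags (``mut_<GENE>``) and VAFs (``vaf_<GENE>``).  ``cell_fractions`` is
    samples x cell types (estimated or, for simulated cohorts, true).
    """

    beta: pd.DataFrame
    samples: pd.DataFrame
    cell_fractions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.beta.index.equals(self.samples.index):
            raise ValueError("beta rows and sample metadata index differ")
        if self.cell_fractions is not None and not self.cell_fractions.index.equals(
            self.beta.index
        ):
            raise ValueError("cell_fractions index differs from beta rows")

    @property
    def m(self) -> pd.DataFrame:
        """M values, log2(beta / (1 - beta))."""
        return beta_to_m(self.beta)

    @property
    def n_samples(self) -> int:
        return self.beta.shape[0]

    @property
    def probes(self) -> pd.Index:
        return self.beta.columns

    def subset_probes(self, probes: Iterable[str]) -> "MethylationCohort":
        probes = pd.Index(probes)
        return MethylationCohort(
            self.beta.loc[:, probes], self.samples, self.cell_fractions
        )

    def subset_samples(self, samples: Iterable[str]) -> "MethylationCohort":
        samples = pd.Index(samples)
        cf = None if self.cell_fractions is None else self.cell_fractions.loc[samples]
        return MethylationCohort(self.beta.loc[samples], self.samples.loc[samples], cf)


@dataclass
class QCReport:
    """Per-rule exclusion counts from :func:`filter_probes`."""

    n_probes_in: int
    n_probes_out: int
    n_samples_dropped: int
    dropped_samples: list = field(default_factory=list)
    excluded_by_rule: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# transforms


def beta_to_m(beta, eps: float = 1e-6):
    """log2-logit transform of beta values; boundary values clipped to eps."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    arr = np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)
    m = np.log2(arr / (1.0 - arr))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index)
    return m


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2^M / (1 + 2^M)."""
    arr = np.asarray(m, dtype=float)
    # numerically stable logistic in base 2
    beta = np.where(arr >= 0, 1.0 / (1.0 + 2.0 ** (-arr)), 2.0**arr / (1.0 + 2.0**arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(beta, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(beta, index=m.index)
    return beta


# ---------------------------------------------------------------------------
# probe QC


def filter_probes(
    raw: RawArray,
    probe_annotation: pd.DataFrame,
    cross_reactive_list: Iterable[str] = (),
    snp_probe_list: Iterable[str] = (),
    detection_p_max: float = 0.01,
    min_beads: int = 3,
    min_call_rate: float = 0.95,
) -> tuple[pd.Index, QCReport]:
    """Apply probe-level QC rules; returns (surviving probes, report).

    A probe survives iff it has no zero-signal sample, no sample with fewer
    than ``min_beads`` beads, per-probe call rate >= ``min_call_rate`` (a
    probe-sample call fails when detection P > ``detection_p_max``), maps to
    an autosome in ``probe_annotation`` (``chrom`` column), and is absent
    from both exclusion lists.  Samples whose overall call rate is below
    ``min_call_rate`` are dropped before probe-level rates are computed.
    """
    probes = raw.beta.columns
    missing = probes.difference(probe_annotation.index)
    if len(missing):
        raise ValueError(f"{len(missing)} probes absent from the manifest")

    detected = raw.detection_p.to_numpy() <= detection_p_max
    sample_call_rate = detected.mean(axis=1)
    keep_samples = sample_call_rate >= min_call_rate
    dropped_samples = list(raw.beta.index[~keep_samples])

    detected = detected[keep_samples]
    zero_sig = raw.zero_signal.to_numpy()[keep_samples]
    beads = raw.bead_count.to_numpy()[keep_samples]

    fail_zero = zero_sig.any(axis=0)
    fail_beads = (beads < min_beads).any(axis=0)
    probe_call_rate = detected.mean(axis=0) if detected.shape[0] else np.ones(len(probes))
    fail_callrate = probe_call_rate < min_call_rate
    chrom = probe_annotation.loc[probes, "chrom"].astype(str)
    fail_sex = chrom.isin(SEX_CHROMS).to_numpy()
    fail_xreact = probes.isin(pd.Index(cross_reactive_list))
    fail_snp = probes.isin(pd.Index(snp_probe_list))

    fail_any = fail_zero | fail_beads | fail_callrate | fail_sex | fail_xreact | fail_snp
    survivors = probes[~fail_any]
    if len(survivors) == 0:
        raise ValueError("no probes survive QC")

    report = QCReport(
        n_probes_in=len(probes),
        n_probes_out=len(survivors),
        n_samples_dropped=len(dropped_samples),
        dropped_samples=dropped_samples,
        excluded_by_rule={
            "zero_signal": int(fail_zero.sum()),
            "low_bead_count": int(fail_beads.sum()),
            "low_call_rate": int(fail_callrate.sum()),
            "sex_chromosome": int(fail_sex.sum()),
            "cross_reactive": int(np.sum(fail_xreact)),
            "snp_affected": int(np.sum(fail_snp)),
        },
    )
    return survivors, report


# ---------------------------------------------------------------------------
# cell-type deconvolution


def _ls_sum_constrained(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """min ||A f - b||^2 s.t. f >= 0 and sum(f) <= 1, by active-set on both
    the non-negativity bounds and the simplex face."""
    from scipy.optimize import nnls

    f, _ = nnls(A, b)
    if f.sum() <= 1.0 + 1e-12:
        return f
    # the sum constraint is active: solve equality-constrained LS on the
    # free set, dropping variables that go negative
    k = A.shape[1]
    free = np.ones(k, dtype=bool)
    for _ in range(2 * k + 1):
        Af = A[:, free]
        nf = Af.shape[1]
        kkt = np.zeros((nf + 1, nf + 1))
        kkt[:nf, :nf] = 2.0 * Af.T @ Af
        kkt[:nf, nf] = 1.0
        kkt[nf, :nf] = 1.0
        rhs = np.concatenate([2.0 * Af.T @ b, [1.0]])
        sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
        f_free = sol[:nf]
        if (f_free >= -1e-12).all():
            f = np.zeros(k)
            f[free] = np.clip(f_free, 0.0, None)
            return f
        worst = np.argmin(f_free)
        free[np.flatnonzero(free)[worst]] = False
        if not free.any():
            return np.zeros(k)
    return np.zeros(k)


def estimate_cell_fractions(
    beta: pd.DataFrame,
    reference_profiles: pd.DataFrame,
    discriminative_probes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Constrained-projection deconvolution of cell-type fractions.

    ``beta`` is samples x probes; ``reference_profiles`` is cell types x
    probes.  Per sample, solves ``min ||beta_s - F' ref||^2`` subject to
    ``F >= 0`` and ``sum(F) <= 1``, restricted to ``discriminative_probes``
    (all shared probes when None).  Residual fraction mass 1 - sum(F) is
    left implicit (unexplained cell types).
    """
    if reference_profiles.shape[0] < 2:
        raise ValueError("need at least two reference cell types")
    if discriminative_probes is None:
        probes = reference_profiles.columns.intersection(beta.columns)
    else:
        probes = pd.Index(discriminative_probes)
        if len(probes.difference(beta.columns)) or len(
            probes.difference(reference_profiles.columns)
        ):
            raise ValueError("discriminative probes missing from beta or references")
    A = reference_profiles.loc[:, probes].to_numpy(dtype=float).T  # probes x cells
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("reference profiles are rank-deficient (non-identifiable)")
    B = beta.loc[:, probes].to_numpy(dtype=float)
    out = np.vstack([_ls_sum_constrained(A, B[i]) for i in range(B.shape[0])])
    return pd.DataFrame(out, index=beta.index, columns=reference_profiles.index)


# ---------------------------------------------------------------------------
# outlier screening and batch centering


def pca_outlier_screen(
    M: pd.DataFrame, n_components: int = 7, z_max: float = 6.0
) -> tuple[pd.Series, pd.DataFrame]:
    """Flag samples that are outliers in the leading principal components.

    Scores on the first ``n_components`` PCs of the centered M matrix are
    robust-standardized (median / 1.4826*MAD per component); a sample is
    flagged when any |z| exceeds ``z_max``.  Returns (flags, scores); removal
    is left to the caller.
    """
    n_samples = M.shape[0]
    if n_samples < n_components:
        raise ValueError("need at least as many samples as components")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(M.to_numpy(dtype=float) - M.to_numpy(dtype=float).mean(0))
    med = np.median(scores, axis=0)
    mad = np.median(np.abs(scores - med), axis=0) * 1.4826
    mad = np.where(mad < 1e-12, 1e-12, mad)
    z = (scores - med) / mad
    if np.isinf(z_max):
        flags = np.zeros(n_samples, dtype=bool)
    else:
        flags = (np.abs(z) > z_max).any(axis=1)
    score_df = pd.DataFrame(
        scores, index=M.index, columns=[f"PC{i + 1}" for i in range(n_components)]
    )
    return pd.Series(flags, index=M.index, name="pca_outlier"), score_df


def batch_center(M: pd.DataFrame, batch_ids: Sequence) -> pd.DataFrame:
    """Per probe, shift each batch's mean to the global mean.

    Within-batch variances are unchanged; this is a documented, deliberately
    simple mean-centering stand-in for heavier plate-correction schemes.
    """
    batches = pd.Series(np.asarray(batch_ids), index=M.index)
    global_mean = M.mean(axis=0)
    batch_means = M.groupby(batches).transform("mean")
    return M - batch_means + global_mean


# ---------------------------------------------------------------------------
# variant-call filtering


def filter_variant_calls(
    calls: pd.DataFrame,
    vaf_min: float = 0.02,
    maf_max: float = 0.01,
    germline_band: tuple[float, float] = (0.40, 0.60),
) -> pd.DataFrame:
    """Filter candidate somatic calls down to credible CHIP mutations.

    Keeps a call iff VAF >= ``vaf_min`` (small subclones below the reliable
    detection limit are dropped), population MAF <= ``maf_max`` (common
    germline polymorphisms are dropped), and NOT (VAF inside
    ``germline_band`` AND concordant between co-twins) — twin-shared
    near-heterozygous variants are rare germline variants, not somatic.

    ``calls`` must have columns sample, gene, vaf, maf, twin_concordant.
    """
    vaf = calls["vaf"].to_numpy(dtype=float)
    maf = calls["maf"].to_numpy(dtype=float)
    conc = calls["twin_concordant"].to_numpy(dtype=bool)
    lo, hi = germline_band
    if np.any((vaf < 0) | (vaf > 1)) or np.any((maf < 0) | (maf > 1)):
        raise ValueError("vaf and maf must lie in [0, 1]")
    germline_like = (vaf >= lo) & (vaf <= hi) & conc
    keep = (vaf >= vaf_min) & (maf <= maf_max) & ~germline_like
    return calls.loc[keep]
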