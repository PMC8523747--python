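"""Per-CpG association models with twin structure.

The primary model is a linear mixed model per CpG site,

    M_ij = x_ij' beta + b_j + e_ij,   b_j ~ N(0, s2_pair),  e_ij ~ N(0, s2_e),

with a shared random intercept b_j for the two members of twin pair j
(singletons form their own group).  The model is fit by REML, profiling the
likelihood over the single variance ratio theta = s2_pair / s2_e.  Because
every group has at most two members, rotating each pair into sum and
difference components diagonalizes the marginal covariance: the difference
component has unit variance, the sum component variance 1 + 2*theta, and
singletons 1 + theta.  The restricted likelihood at any theta then reduces
to weighted Gram-matrix arithmetic, which we exploit to run the profile
search vectorized across all probes at once (golden-section on log theta in
[-12, 12], with an explicit comparison against the theta = 0 boundary).

The Wald test on the exposure coefficient uses a t reference with residual
degrees of freedom n - rank(X).  This avoids Satterthwaite machinery and is
mildly conservative for strongly between-pair contrasts; downstream
site-selection logic depends only on signs and ranks.

Unpaired cohorts use ordinary least squares per probe, optionally with
limma-style empirical-Bayes variance moderation (off by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from clonmeth.preprocess import MethylationCohort

__all__ = [
    "DesignSpec",
    "fit_cpg_mixed",
    "fit_cpg_ols",
    "mixed_model_batch",
    "ols_batch",
    "run_ewas",
    "genomic_inflation",
    "vaf_direction_check",
    "moderate_variances",
]

P_FLOOR = 1e-300  # underflow sentinel bound; reported P values stay in (0, 1]

_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


@dataclass
class DesignSpec:
    """Specification of one epigenome-wide analysis.

    ``exposure`` names a sample-metadata column: a 0/1 mutation flag
    (``mut_<GENE>``) or a continuous VAF column.  For binary exposures the
    comparison group is restricted to samples carrying none of the mutation
    flags in ``exclude_other_chip`` (exposed samples are always kept), so a
    TET2 analysis contrasts TET2-mutated with mutation-free samples.
    """

    exposure: str
    covariates: Sequence[str] = ("age", "sex", "batch")
    use_cell_fractions: bool = True
    n_pcs: int = 0
    grouping: str | None = "pair"
    exclude_other_chip: Sequence[str] = field(default_factory=tuple)
    moderated: bool = False


# ---------------------------------------------------------------------------
# mixed-model core


def _pair_structure(pair_ids: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """Split sample indices into complete pairs (m x 2) and singletons."""
    groups: dict = {}
    n = len(pair_ids)
    for i, pid in enumerate(pair_ids):
        if pid is None or (isinstance(pid, float) and np.isnan(pid)) or pid == "":
            continue
        groups.setdefault(pid, []).append(i)
    for pid, members in groups.items():
        if len(members) > 2:
            raise ValueError(f"pair id {pid!r} groups {len(members)} > 2 samples")
    pairs = [m for m in groups.values() if len(m) == 2]
    paired = {i for m in pairs for i in m}
    singles = np.array([i for i in range(n) if i not in paired], dtype=int)
    pairs_arr = np.array(pairs, dtype=int).reshape(-1, 2)
    return pairs_arr, singles


class _ProfileREML:
    """Precomputed sufficient statistics for batched profile-REML.

    Y is (n, P) outcomes, X is (n, p).  All theta-dependent quantities are
    weighted combinations of three Gram blocks (pair sums, pair differences,
    singletons), so evaluating the restricted deviance at a per-probe vector
    of theta values costs one batched p x p solve.
    """

    def __init__(self, Y: np.ndarray, X: np.ndarray, pair_ids: Sequence):
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if np.linalg.matrix_rank(X) < p:
            raise ValueError("design matrix X is rank deficient")
        pairs, singles = _pair_structure(pair_ids)
        self.n, self.p = n, p
        self.m_pairs = len(pairs)
        self.n_singles = len(singles)
        self.P = Y.shape[1]

        inv_sqrt2 = 1.0 / np.sqrt(2.0)
        if len(pairs):
            Xs = (X[pairs[:, 0]] + X[pairs[:, 1]]) * inv_sqrt2
            Xd = (X[pairs[:, 0]] - X[pairs[:, 1]]) * inv_sqrt2
            Ys = (Y[pairs[:, 0]] + Y[pairs[:, 1]]) * inv_sqrt2
            Yd = (Y[pairs[:, 0]] - Y[pairs[:, 1]]) * inv_sqrt2
        else:
            Xs = np.zeros((0, p))
            Xd = np.zeros((0, p))
            Ys = np.zeros((0, self.P))
            Yd = np.zeros((0, self.P))
        Xg, Yg = X[singles], Y[singles]

        self.A_s, self.A_d, self.A_g = Xs.T @ Xs, Xd.T @ Xd, Xg.T @ Xg
        self.b_s, self.b_d, self.b_g = Xs.T @ Ys, Xd.T @ Yd, Xg.T @ Yg  # (p, P)
        self.c_s = (Ys**2).sum(axis=0)
        self.c_d = (Yd**2).sum(axis=0)
        self.c_g = (Yg**2).sum(axis=0)

    def _assemble(self, theta: np.ndarray):
        """Weighted Gram pieces at per-probe theta; returns (XtX, Xty, yty)."""
        w1 = 1.0 / (1.0 + 2.0 * theta)
        w3 = 1.0 / (1.0 + theta)
        XtX = (
            w1[:, None, None] * self.A_s
            + self.A_d[None, :, :]
            + w3[:, None, None] * self.A_g
        )
        Xty = w1[:, None] * self.b_s.T + self.b_d.T + w3[:, None] * self.b_g.T
        yty = w1 * self.c_s + self.c_d + w3 * self.c_g
        return XtX, Xty, yty

    def solve(self, theta: np.ndarray):
        XtX, Xty, yty = self._assemble(theta)
        beta = np.linalg.solve(XtX, Xty[..., None])[..., 0]
        rss = np.maximum(yty - np.einsum("ij,ij->i", beta, Xty), 1e-300)
        return XtX, beta, rss

    def deviance(self, theta: np.ndarray) -> np.ndarray:
        """-2 restricted log-likelihood up to a constant, profiled over s2_e."""
        XtX, _, rss = self.solve(theta)
        _, logdet_xtx = np.linalg.slogdet(XtX)
        logdet_v = self.m_pairs * np.log1p(2.0 * theta) + self.n_singles * np.log1p(theta)
        return (self.n - self.p) * np.log(rss) + logdet_v + logdet_xtx

    def optimize(self, lo: float = -12.0, hi: float = 12.0, n_iter: int = 50):
        """Vectorized golden-section search for theta-hat on the log scale.

        Returns (theta_hat, boundary) where boundary flags probes whose REML
        criterion is minimized at theta = 0.
        """
        P = self.P
        a = np.full(P, lo)
        b = np.full(P, hi)
        c = b - _INVPHI * (b - a)
        d = a + _INVPHI * (b - a)
        fc = self.deviance(np.exp(c))
        fd = self.deviance(np.exp(d))
        for _ in range(n_iter):
            left = fc < fd
            b_new = np.where(left, d, b)
            a_new = np.where(left, a, c)
            c_new = np.where(left, b_new - _INVPHI * (b_new - a_new), d)
            d_new = np.where(left, c, a_new + _INVPHI * (b_new - a_new))
            x_eval = np.where(left, c_new, d_new)
            f_eval = self.deviance(np.exp(x_eval))
            fc_old = fc
            fc = np.where(left, f_eval, fd)
            fd = np.where(left, fc_old, f_eval)
            a, b, c, d = a_new, b_new, c_new, d_new
        theta = np.exp(0.5 * (a + b))
        dev_hat = self.deviance(theta)
        dev_zero = self.deviance(np.zeros(P))
        boundary = dev_zero <= dev_hat + 1e-10
        theta = np.where(boundary, 0.0, theta)
        return theta, boundary

    def _h_terms(self, theta: np.ndarray, coef_index: int):
        """(g, rss, logdet terms) needed for the Satterthwaite machinery.

        g(theta) = [X' V*(theta)^-1 X]^-1 at the exposure coefficient;
        h(theta) = log|V*| + log|X'V*^-1 X|.
        """
        XtX, _, rss = self.solve(theta)
        inv = np.linalg.inv(XtX)
        g = inv[:, coef_index, coef_index]
        _, logdet_xtx = np.linalg.slogdet(XtX)
        h = (
            self.m_pairs * np.log1p(2.0 * theta)
            + self.n_singles * np.log1p(theta)
            + logdet_xtx
        )
        return g, rss, h

    def satterthwaite_df(self, theta: np.ndarray, coef_index: int) -> np.ndarray:
        """Per-probe Satterthwaite degrees of freedom for the Wald t test.

        The variance of the squared SE, f(sigma2, theta) = sigma2 * g(theta),
        is obtained by the delta method from the REML information of
        (sigma2, theta); df = 2 f^2 / Var(f).  Probes at the theta = 0
        boundary fall back to the residual df n - p.
        """
        df_resid = float(self.n - self.p)
        g0, sigma2, g_prime, i_ss, i_st, i_tt, det = self._theta_info(theta, coef_index)
        # Var(f) with grad f = (g, sigma2 * g'), A = inverse information
        a11, a12, a22 = i_tt / det, -i_st / det, i_ss / det
        var_f = g0**2 * a11 + 2 * g0 * sigma2 * g_prime * a12 + (sigma2 * g_prime) ** 2 * a22
        f = sigma2 * g0
        with np.errstate(divide="ignore", invalid="ignore"):
            df = 2.0 * f**2 / var_f
        df = np.where((theta <= 0) | ~np.isfinite(df), df_resid, df)
        return np.clip(df, 1.0, df_resid)

    def _theta_info(self, theta: np.ndarray, coef_index: int):
        """Inverse-information variance of theta-hat (delta method pieces)."""
        df_resid = float(self.n - self.p)
        delta = np.maximum(1e-4, 1e-3 * theta)
        g0, rss0, h0 = self._h_terms(theta, coef_index)
        gp, rssp, hp = self._h_terms(theta + delta, coef_index)
        gm, rssm, hm = self._h_terms(np.maximum(theta - delta, 0.0), coef_index)
        step = theta + delta - np.maximum(theta - delta, 0.0)
        sigma2 = rss0 / df_resid
        g_prime = (gp - gm) / step
        r_prime = (rssp - rssm) / step
        h_dd = (hp - 2 * h0 + hm) / (0.5 * step) ** 2
        r_dd = (rssp - 2 * rss0 + rssm) / (0.5 * step) ** 2
        # REML information (negative Hessian) of (sigma2, theta) at the optimum
        i_ss = df_resid / (2.0 * sigma2**2)
        i_st = -r_prime / (2.0 * sigma2**2)
        i_tt = 0.5 * (h_dd + r_dd / sigma2)
        det = np.maximum(i_ss * i_tt - i_st**2, 1e-300)
        return g0, sigma2, g_prime, i_ss, i_st, i_tt, det

    def kr_variance_inflation(self, theta: np.ndarray, coef_index: int) -> np.ndarray:
        """Kackar-Harville / Kenward-Roger inflation of the exposure variance.

        For V = sigma2 (I + theta ZZ') the sigma2- and cross-derivative
        terms of the adjustment vanish identically; the surviving theta
        term is 2 Var(theta_hat) [G^-1 (C - B G^-1 B) G^-1] at the exposure
        coefficient, with G, B, C weighted Gram blocks of the rotated
        design.
        """
        w1 = 1.0 / (1.0 + 2.0 * theta)
        w3 = 1.0 / (1.0 + theta)
        G = (
            w1[:, None, None] * self.A_s
            + self.A_d[None, :, :]
            + w3[:, None, None] * self.A_g
        )
        B = 2.0 * w1[:, None, None] ** 2 * self.A_s + w3[:, None, None] ** 2 * self.A_g
        C = 4.0 * w1[:, None, None] ** 3 * self.A_s + w3[:, None, None] ** 3 * self.A_g
        Ginv = np.linalg.inv(G)
        inner = C - B @ Ginv @ B
        adj = (Ginv @ inner @ Ginv)[:, coef_index, coef_index]
        _, _, _, i_ss, _, _, det = self._theta_info(theta, coef_index)
        var_theta = i_ss / det  # (theta, theta) element of the inverse info
        base = Ginv[:, coef_index, coef_index]
        with np.errstate(divide="ignore", invalid="ignore"):
            inflation = 1.0 + 2.0 * var_theta * adj / base
        return np.where(theta > 0, np.maximum(inflation, 1.0), 1.0)

    def wald(
        self,
        theta: np.ndarray,
        coef_index: int,
        satterthwaite: bool = True,
        kenward_roger: bool = True,
    ):
        """Estimates, SEs and two-sided t P values at fixed per-probe theta.

        ``kenward_roger`` applies the small-sample variance inflation that
        accounts for the estimation uncertainty in theta; ``satterthwaite``
        replaces the fixed residual df n - rank(X) with per-probe
        Satterthwaite degrees of freedom.
        """
        XtX, beta, rss = self.solve(theta)
        df_resid = self.n - self.p
        sigma2 = rss / df_resid
        inv = np.linalg.inv(XtX)
        var_beta = sigma2 * inv[:, coef_index, coef_index]
        if kenward_roger:
            var_beta = var_beta * self.kr_variance_inflation(theta, coef_index)
        se = np.sqrt(var_beta)
        est = beta[:, coef_index]
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = est / se
        df = self.satterthwaite_df(theta, coef_index) if satterthwaite else df_resid
        pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
        pvals = np.clip(pvals, P_FLOOR, 1.0)
        return est, se, tstat, pvals, sigma2, df


def mixed_model_batch(
    Y, X, pair_ids, coef_index: int = 1, satterthwaite: bool = True
) -> pd.DataFrame:
    """Fit the twin random-intercept model to every column of ``Y``.

    ``Y``: (n, P) outcome matrix (one column per probe); ``X``: (n, p)
    design with full column rank; ``coef_index``: exposure column of X.
    Returns a DataFrame with estimate, se, stat, p, direction, theta, df,
    boundary (True when the pair variance is estimated at zero).  Wald P
    values use Satterthwaite degrees of freedom by default (the plugged-in
    variance ratio is otherwise mildly anticonservative); pass
    ``satterthwaite=False`` for the fixed residual df n - rank(X).
    """
    prof = _ProfileREML(np.asarray(Y, dtype=float), X, pair_ids)
    theta, boundary = prof.optimize()
    est, se, tstat, pvals, _, df = prof.wald(theta, coef_index, satterthwaite)
    return pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "stat": tstat,
            "p": pvals,
            "direction": np.sign(est).astype(int),
            "theta": theta,
            "df": np.broadcast_to(df, est.shape).astype(float),
            "boundary": boundary,
        }
    )


def fit_cpg_mixed(y, X, pair_ids, coef_index: int = 1):
    """Single-probe twin mixed model; returns (estimate, se, p).

    Non-convergence / degenerate fits surface as NaN results rather than an
    exception so that genome-wide loops can continue.
    """
    try:
        res = mixed_model_batch(np.asarray(y, dtype=float)[:, None], X, pair_ids, coef_index)
    except np.linalg.LinAlgError:
        return np.nan, np.nan, np.nan
    row = res.iloc[0]
    return float(row["estimate"]), float(row["se"]), float(row["p"])


# ---------------------------------------------------------------------------
# OLS


def ols_batch(Y, X, coef_index: int = 1, moderated: bool = False) -> pd.DataFrame:
    """Per-probe least squares for every column of ``Y``.

    With ``moderated=True``, residual variances are shrunk toward a common
    prior (empirical-Bayes moderated t statistics in the limma style).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix X is rank deficient")
    df = n - p
    XtX = X.T @ X
    XtY = X.T @ Y
    beta = np.linalg.solve(XtX, XtY)  # (p, P)
    resid = Y - X @ beta
    rss = (resid**2).sum(axis=0)
    s2 = rss / max(df, 1)
    inv_jj = np.linalg.inv(XtX)[coef_index, coef_index]
    est = beta[coef_index]
    if moderated:
        s2_post, df_total = moderate_variances(s2, df)
        se = np.sqrt(s2_post * inv_jj)
        t_df = df_total
    else:
        se = np.sqrt(s2 * inv_jj)
        t_df = df
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, est / se, np.sign(est) * np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), t_df)
    pvals = np.clip(pvals, P_FLOOR, 1.0)
    return pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "stat": tstat,
            "p": pvals,
            "direction": np.sign(est).astype(int),
        }
    )


def fit_cpg_ols(y, X, coef_index: int = 1):
    """Single-probe OLS; returns (estimate, se, p)."""
    res = ols_batch(np.asarray(y, dtype=float)[:, None], X, coef_index)
    row = res.iloc[0]
    return float(row["estimate"]), float(row["se"]), float(row["p"])


def moderate_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of residual variances.

    Fits a scaled inverse-chi-square prior (s0^2, d0) to the observed
    variances by moment matching on log s^2 and returns the posterior
    variances (d0 s0^2 + df s^2) / (d0 + df) with total df d0 + df.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    target = max(np.var(e, ddof=1) - special.polygamma(1, df / 2.0), 1e-8)
    # invert trigamma(d0/2) = target by Newton on the log scale
    x = 0.5 + 1.0 / target
    for _ in range(50):
        f = special.polygamma(1, x) - target
        fp = special.polygamma(2, x)
        step = f / fp
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < 1e-10 * abs(x):
            x = x_new
            break
        x = x_new
    d0 = 2.0 * x
    s0_2 = np.exp(e_mean + special.digamma(x) - np.log(x))
    s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
    return s2_post, df + d0


# ---------------------------------------------------------------------------
# cohort-level drivers


def _compute_pcs(M: np.ndarray, k: int) -> np.ndarray:
    """Leading principal-component scores of the centered M matrix."""
    centered = M - M.mean(axis=0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    return u[:, :k] * s[:k]


def build_design_matrix(
    cohort: MethylationCohort, design: DesignSpec, samples: pd.Index
) -> tuple[pd.DataFrame, np.ndarray]:
    """Assemble the fixed-effects design for the selected samples.

    Columns: intercept, exposure, requested covariates (categorical ones
    dummy-coded dropping the first level), cell fractions, leading PCs of
    the analysis M matrix.  Returns (X, pair id array).
    """
    meta = cohort.samples.loc[samples]
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(samples))}
    cols[design.exposure] = meta[design.exposure].to_numpy(dtype=float)
    for cov in design.covariates:
        vals = meta[cov]
        if vals.dtype.kind in "biufc":
            cols[cov] = vals.to_numpy(dtype=float)
        else:
            dummies = pd.get_dummies(vals.astype(str), prefix=cov, drop_first=True)
            for name in dummies.columns:
                cols[name] = dummies[name].to_numpy(dtype=float)
    if design.use_cell_fractions and cohort.cell_fractions is not None:
        cf = cohort.cell_fractions.loc[samples]
        for name in cf.columns:
            cols[f"frac_{name}"] = cf[name].to_numpy(dtype=float)
    if design.n_pcs > 0:
        pcs = _compute_pcs(cohort.m.loc[samples].to_numpy(dtype=float), design.n_pcs)
        for i in range(pcs.shape[1]):
            cols[f"PC{i + 1}"] = pcs[:, i]
    X = pd.DataFrame(cols, index=samples)
    # drop constant / collinear covariate columns (never the exposure)
    keep = []
    for j, name in enumerate(X.columns):
        if name in ("intercept", design.exposure):
            keep.append(name)
            continue
        trial = X[keep + [name]].to_numpy(dtype=float)
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            keep.append(name)
    X = X[keep]
    if design.grouping is not None:
        pair_ids = meta[design.grouping].to_numpy(dtype=object)
    else:
        pair_ids = np.array([None] * len(samples), dtype=object)
    return X, pair_ids


def select_analysis_samples(cohort: MethylationCohort, design: DesignSpec) -> pd.Index:
    """Exposed samples plus controls free of the excluded mutations."""
    meta = cohort.samples
    exposure = meta[design.exposure]
    if design.exposure.startswith("mut_"):
        exposed = exposure.astype(bool)
        clean = pd.Series(True, index=meta.index)
        for col in design.exclude_other_chip:
            clean &= ~meta[col].astype(bool)
        keep = exposed | (clean & ~exposed)
        n_exposed = int(exposed[keep].sum())
        n_control = int((~exposed[keep]).sum())
        if min(n_exposed, n_control) < 2:
            raise ValueError("fewer than 2 samples in an exposure group")
        return meta.index[keep]
    return meta.index[exposure.notna()]


def run_ewas(cohort: MethylationCohort, design: DesignSpec) -> pd.DataFrame:
    """Epigenome-wide association scan; one row per probe.

    Returns a DataFrame indexed by probe id with columns estimate (M-value
    scale), se, stat, p, direction, and — for the mixed model — theta and
    boundary.
    """
    samples = select_analysis_samples(cohort, design)
    X, pair_ids = build_design_matrix(cohort, design, samples)
    Y = cohort.m.loc[samples].to_numpy(dtype=float)
    coef_index = int(X.columns.get_loc(design.exposure))
    if design.grouping is not None:
        table = mixed_model_batch(Y, X.to_numpy(dtype=float), pair_ids, coef_index)
    else:
        table = ols_batch(
            Y, X.to_numpy(dtype=float), coef_index, moderated=design.moderated
        )
    table.index = cohort.probes
    table.index.name = "probe"
    return table


def genomic_inflation(p_values) -> float:
    """Genomic inflation factor: observed / expected median 1-df chi-square.

    lambda > 1 indicates widespread signal or confounding across probes.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0 or np.any((p <= 0) | (p > 1)):
        raise ValueError("P values must lie in (0, 1]")
    chi_obs = np.median(stats.chi2.isf(p, df=1))
    return float(chi_obs / stats.chi2.isf(0.5, df=1))


def vaf_direction_check(
    M: pd.DataFrame,
    sites: Sequence[str],
    vaf: Sequence[float],
    covariates: np.ndarray | None = None,
    pair_ids: Sequence | None = None,
) -> tuple[int, int, float]:
    """Count sites whose methylation rises with clone size.

    Regresses each site's M values on VAF (plus optional covariate columns),
    using the twin mixed model when ``pair_ids`` is given, and returns
    (n_positive, n_total, fraction) for the sign of the VAF coefficient.
    """
    sites = [s for s in sites if s in M.columns]
    if not sites:
        return 0, 0, float("nan")
    vaf = np.asarray(vaf, dtype=float)
    n = len(vaf)
    parts = [np.ones((n, 1)), vaf[:, None]]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        parts.append(cov)
    X = np.hstack(parts)
    Y = M.loc[:, sites].to_numpy(dtype=float)
    if pair_ids is not None:
        table = mixed_model_batch(Y, X, pair_ids, coef_index=1)
    else:
        table = ols_batch(Y, X, coef_index=1)
    n_pos = int((table["estimate"] > 0).sum())
    return n_pos, len(sites), n_pos / len(sites)
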