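"""Elastic-net logistic prediction of mutation status from methylation.

The penalized log-likelihood

    min over (b0, beta) of  -loglik / n + lam * [ (1 - alpha)/2 ||beta||_2^2
                                                 + alpha ||beta||_1 ]

is minimized by iteratively reweighted least squares with cyclic coordinate
descent on the penalized weighted quadratic approximation (the glmnet
algorithm), warm-started along a descending lambda path.  The intercept is
never penalized.  A step-halving safeguard makes the penalized objective
monotone non-increasing across outer iterations.

Out-of-sample evaluation uses leave-one-out cross-validation: for each held
out sample, an inner stratified k-fold CV on the remaining samples picks
lambda by minimum mean binomial deviance, the model is refit at that lambda
and the held-out probability recorded.  Features are standardized inside
each training set only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from numba import njit
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "FitSpec",
    "PredictionReport",
    "enet_logistic_fit",
    "enet_objective",
    "lambda_grid",
    "enet_path",
    "cv_lambda",
    "loocv_predict",
    "confusion_metrics",
    "prob_vs_clone_size",
]


@dataclass
class FitSpec:
    """Tunables of the elastic-net fit and its cross-validation."""

    alpha: float = 0.5  # L1/L2 mixing; 1 = lasso, 0 = ridge
    n_lambda: int = 30
    lambda_min_ratio: float = 1e-3
    n_folds: int = 10
    tol: float = 1e-7
    max_iter: int = 200
    standardize: bool = True
    cutoff: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


@dataclass
class PredictionReport:
    """Per-sample out-of-fold probabilities and confusion metrics."""

    probabilities: np.ndarray
    labels: np.ndarray
    predicted: np.ndarray
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    chosen_lambdas: np.ndarray = field(default_factory=lambda: np.array([]))


# ---------------------------------------------------------------------------
# core solver


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    ex = np.exp(eta[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def enet_objective(
    X: np.ndarray, y: np.ndarray, b0: float, beta: np.ndarray, alpha: float, lam: float
) -> float:
    """Penalized negative log-likelihood per sample."""
    eta = b0 + X @ beta
    # -loglik = sum(log(1 + e^eta) - y*eta), computed stably
    nll = np.sum(np.logaddexp(0.0, eta) - y * eta) / len(y)
    penalty = lam * ((1.0 - alpha) * 0.5 * beta @ beta + alpha * np.abs(beta).sum())
    return float(nll + penalty)


@njit(cache=False)
def _cd_quadratic_numba(X, w, z, b0, beta, alpha, lam, tol, max_sweeps):
    """Cyclic coordinate descent on the penalized weighted least squares."""
    n, p = X.shape
    wx2 = np.zeros(p)
    for j in range(p):
        acc = 0.0
        for i in range(n):
            acc += w[i] * X[i, j] * X[i, j]
        wx2[j] = acc / n
    r = z - b0 - X @ beta
    wsum = w.sum()
    g = lam * alpha
    for _ in range(max_sweeps):
        max_delta = 0.0
        db0 = 0.0
        for i in range(n):
            db0 += w[i] * r[i]
        db0 /= wsum
        b0 += db0
        for i in range(n):
            r[i] -= db0
        max_delta = abs(db0)
        for j in range(p):
            bj = beta[j]
            rho = 0.0
            for i in range(n):
                rho += w[i] * X[i, j] * r[i]
            rho = rho / n + wx2[j] * bj
            if rho > g:
                bj_new = (rho - g) / (wx2[j] + lam * (1.0 - alpha))
            elif rho < -g:
                bj_new = (rho + g) / (wx2[j] + lam * (1.0 - alpha))
            else:
                bj_new = 0.0
            if bj_new != bj:
                diff = bj - bj_new
                for i in range(n):
                    r[i] += X[i, j] * diff
                beta[j] = bj_new
                d = abs(diff) * np.sqrt(wx2[j])
                if d > max_delta:
                    max_delta = d
        if max_delta < tol:
            break
    return b0


def _cd_quadratic(
    X: np.ndarray,
    w: np.ndarray,
    z: np.ndarray,
    b0: float,
    beta: np.ndarray,
    alpha: float,
    lam: float,
    tol: float,
    max_sweeps: int = 1000,
) -> tuple[float, np.ndarray]:
    X = np.ascontiguousarray(X, dtype=np.float64)
    b0 = _cd_quadratic_numba(
        X,
        np.ascontiguousarray(w, dtype=np.float64),
        np.ascontiguousarray(z, dtype=np.float64),
        float(b0),
        beta,
        float(alpha),
        float(lam),
        float(tol),
        max_sweeps,
    )
    return float(b0), beta


def enet_logistic_fit(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    spec: FitSpec | None = None,
    warm: tuple[float, np.ndarray] | None = None,
) -> tuple[float, np.ndarray]:
    """Fit one penalized logistic regression; returns (intercept, coefficients).

    Raises on non-convergence at ``spec.max_iter`` outer IRLS iterations.
    ``X`` is used as passed (standardize beforehand if desired).
    """
    spec = spec or FitSpec(alpha=alpha)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    n, p = X.shape
    if warm is not None:
        b0, beta = warm[0], warm[1].copy()
    else:
        ybar = np.clip(y.mean(), 1e-6, 1 - 1e-6)
        b0, beta = float(np.log(ybar / (1 - ybar))), np.zeros(p)
    obj = enet_objective(X, y, b0, beta, alpha, lam)
    for it in range(spec.max_iter):
        eta = b0 + X @ beta
        mu = _sigmoid(eta)
        w = np.clip(mu * (1.0 - mu), 1e-5, None)
        z = eta + (y - mu) / w
        b0_new, beta_new = _cd_quadratic(
            X, w, z, b0, beta.copy(), alpha, lam, spec.tol
        )
        obj_new = enet_objective(X, y, b0_new, beta_new, alpha, lam)
        # step-halving safeguard keeps the objective monotone
        step = 1.0
        while obj_new > obj + 1e-12 and step > 1e-6:
            step *= 0.5
            b0_try = b0 + step * (b0_new - b0)
            beta_try = beta + step * (beta_new - beta)
            obj_try = enet_objective(X, y, b0_try, beta_try, alpha, lam)
            if obj_try <= obj:
                b0_new, beta_new, obj_new = b0_try, beta_try, obj_try
                break
        converged = (
            abs(obj - obj_new) < spec.tol * (abs(obj) + spec.tol)
            and np.max(np.abs(beta_new - beta), initial=abs(b0_new - b0)) < 1e2
        )
        b0, beta, obj = b0_new, beta_new, obj_new
        if converged:
            return b0, beta
    raise RuntimeError(
        f"elastic net did not converge in {spec.max_iter} IRLS iterations "
        f"(lam={lam:.3g}, alpha={alpha}, last objective {obj:.6g})"
    )


def lambda_grid(X: np.ndarray, y: np.ndarray, spec: FitSpec) -> np.ndarray:
    """Descending log-spaced lambda path from the smallest all-zero lambda."""
    n = len(y)
    alpha_eff = max(spec.alpha, 1e-3)
    lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / (n * alpha_eff)
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * spec.lambda_min_ratio, spec.n_lambda)


def enet_path(
    X: np.ndarray, y: np.ndarray, lambdas: np.ndarray, spec: FitSpec
) -> list[tuple[float, np.ndarray]]:
    """Warm-started fits along a descending lambda path."""
    fits: list[tuple[float, np.ndarray]] = []
    warm = None
    for lam in lambdas:
        b0, beta = enet_logistic_fit(X, y, spec.alpha, lam, spec, warm)
        warm = (b0, beta)
        fits.append((b0, beta.copy()))
    return fits


def _standardize_train(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (X - mean) / sd, mean, sd


def _deviance(y: np.ndarray, prob: np.ndarray) -> float:
    prob = np.clip(prob, 1e-10, 1 - 1e-10)
    return float(-2.0 * np.sum(y * np.log(prob) + (1 - y) * np.log(1 - prob)))


def cv_lambda(
    X: np.ndarray, y: np.ndarray, spec: FitSpec, seed: int
) -> tuple[float, np.ndarray]:
    """Pick lambda by minimum mean k-fold binomial deviance (lambda-min rule)."""
    lambdas = lambda_grid(X, y, spec)
    n_folds = min(spec.n_folds, int(y.sum()), int((1 - y).sum()))
    if n_folds < 2:
        raise ValueError("insufficient samples per class for inner CV folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    dev = np.zeros(len(lambdas))
    for train_idx, val_idx in skf.split(X, y):
        Xt, mean, sd = _standardize_train(X[train_idx])
        Xv = (X[val_idx] - mean) / sd
        fits = enet_path(Xt, y[train_idx], lambdas, spec)
        for k, (b0, beta) in enumerate(fits):
            prob = _sigmoid(b0 + Xv @ beta)
            dev[k] += _deviance(y[val_idx], prob)
    return float(lambdas[int(np.argmin(dev))]), lambdas


def loocv_predict(X, y, spec: FitSpec | None = None) -> PredictionReport:
    """Leave-one-out cross-validated mutation-status probabilities.

    For each sample, the inner CV / refit / predict cycle runs on the other
    n - 1 samples; standardization parameters come from the training set
    only.  Labels are assigned at ``spec.cutoff`` (ties classified positive).
    """
    spec = spec or FitSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10 or y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("too few samples (or class members) for LOOCV")
    probs = np.zeros(n)
    chosen = np.zeros(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, ytr = X[mask], y[mask]
        lam, _ = cv_lambda(Xtr, ytr, spec, seed=spec.seed + i)
        if spec.standardize:
            Xs, mean, sd = _standardize_train(Xtr)
            xi = (X[i] - mean) / sd
        else:
            Xs, xi = Xtr, X[i]
        b0, beta = enet_logistic_fit(Xs, ytr, spec.alpha, lam, spec)
        probs[i] = _sigmoid(np.atleast_1d(b0 + xi @ beta))[0]
        chosen[i] = lam
    metrics = confusion_metrics(probs, y, spec.cutoff)
    return PredictionReport(
        probabilities=probs,
        labels=y.astype(int),
        predicted=(probs >= spec.cutoff).astype(int),
        chosen_lambdas=chosen,
        **metrics,
    )


def confusion_metrics(probabilities, labels, cutoff: float = 0.5) -> dict:
    """Confusion counts and sensitivity/specificity at a probability cutoff.

    Probabilities exactly at the cutoff classify positive.
    """
    prob = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    pred = prob >= cutoff
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    tn = int((~pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return {
        "tp": tp,
        "fp": fp,
        "tn": tn,
        "fn": fn,
        "sensitivity": sens,
        "specificity": spec,
    }


def prob_vs_clone_size(probabilities, vaf, carrier_mask) -> tuple[float, float]:
    """Association of predicted probability with clone size among carriers.

    Linear regression of out-of-fold probability on VAF restricted to
    mutation carriers; returns (slope, two-sided P).
    """
    prob = np.asarray(probabilities, dtype=float)
    vaf = np.asarray(vaf, dtype=float)
    mask = np.asarray(carrier_mask, dtype=bool)
    if mask.sum() < 3:
        raise ValueError("need at least three carriers")
    Xc = sm.add_constant(vaf[mask])
    fit = sm.OLS(prob[mask], Xc).fit()
    return float(fit.params[1]), float(fit.pvalues[1])
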