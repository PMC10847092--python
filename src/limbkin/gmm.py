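"""Gaussian mixture model clustering with EM, BIC/ICL model selection, and
95% confidence ellipses.

The mixture has full, unequal per-component covariances (the component
distributions are not constrained to share shape or volume). Criteria follow
the lower-is-better convention:

    BIC = -2 log L + n_params ln n
    ICL = BIC + 2 EN,   EN = -sum_i sum_k z_ik ln z_ik

where z_ik are the posterior responsibilities, so ICL >= BIC with equality
for a perfectly hard partition. For d = 2 with full unequal covariances
n_params = 6K - 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import chi2

logger = logging.getLogger("limbkin")

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class MixtureModel:
    """A fitted K-component Gaussian mixture in d dimensions."""

    K: int
    weights: np.ndarray          # (K,)
    means: np.ndarray            # (K, d)
    covariances: np.ndarray      # (K, d, d)
    responsibilities: np.ndarray  # (n, K)
    log_likelihood: float
    n_iter: int
    log_likelihood_path: np.ndarray = field(repr=False, default=None)

    @property
    def n_params(self) -> int:
        d = self.means.shape[1]
        per_comp = d + d * (d + 1) // 2
        return self.K * per_comp + (self.K - 1)

    @property
    def hard_labels(self) -> np.ndarray:
        # argmax breaks responsibility ties toward the lowest component index
        return np.argmax(self.responsibilities, axis=1)


@dataclass
class Ellipse:
    """Confidence ellipse of one Gaussian component."""

    center: np.ndarray
    axes: np.ndarray      # semi-axis lengths, descending
    rotation: float       # degrees, orientation of the leading axis
    level: float


# ---------------------------------------------------------------------------
# EM internals


def _log_gauss(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = X.shape[1]
    L = np.linalg.cholesky(cov)
    sol = np.linalg.solve(L, (X - mean).T)
    maha = np.sum(sol ** 2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (d * _LOG_2PI + logdet + maha)


def _kmeanspp_centers(X: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: spread initial centers proportionally to squared
    distance from the nearest chosen center."""
    n = len(X)
    centers = [X[rng.integers(n)]]
    for _ in range(1, K):
        d2 = np.min(
            [np.sum((X - c) ** 2, axis=1) for c in centers], axis=0)
        total = d2.sum()
        if total <= 0:
            centers.append(X[rng.integers(n)])
            continue
        centers.append(X[rng.choice(n, p=d2 / total)])
    return np.array(centers)


def _em_single(X: np.ndarray, K: int, rng: np.random.Generator,
               tol: float, max_iter: int, reg: float) -> MixtureModel | None:
    n, d = X.shape
    centers = _kmeanspp_centers(X, K, rng)
    # initial hard assignment to the nearest center
    dist = np.linalg.norm(X[:, None, :] - centers[None], axis=2)
    resp = np.zeros((n, K))
    resp[np.arange(n), dist.argmin(axis=1)] = 1.0

    data_scale = np.trace(np.cov(X.T, bias=True).reshape(d, d)) / d if n > 1 else 1.0
    floor = max(reg * data_scale, 1e-12)

    weights = means = covs = None
    ll_prev = -np.inf
    ll_path = []
    for it in range(max_iter):
        # M step
        nk = resp.sum(axis=0) + 1e-300
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        covs = np.empty((K, d, d))
        for k in range(K):
            diff = X - means[k]
            covs[k] = (resp[:, k][:, None] * diff).T @ diff / nk[k]
            # ridge only on near-singularity, so healthy fits stay exact ML
            if np.linalg.eigvalsh(covs[k])[0] < floor:
                covs[k].flat[:: d + 1] += floor
            if np.linalg.det(covs[k]) < (floor ** d) * 1e-3:
                return None  # component collapsed; caller restarts
        # E step
        log_prob = np.column_stack(
            [np.log(weights[k]) + _log_gauss(X, means[k], covs[k])
             for k in range(K)])
        ll_norm = logsumexp(log_prob, axis=1)
        ll = float(ll_norm.sum())
        resp = np.exp(log_prob - ll_norm[:, None])
        ll_path.append(ll)
        if it > 0 and abs(ll - ll_prev) <= tol * (abs(ll_prev) + 1e-12):
            break
        ll_prev = ll
    return MixtureModel(K=K, weights=weights, means=means, covariances=covs,
                        responsibilities=resp, log_likelihood=ll,
                        n_iter=len(ll_path),
                        log_likelihood_path=np.array(ll_path))


def fit_em(features: np.ndarray, K: int, seed: int = 0, n_restarts: int = 10,
           tol: float = 1e-8, max_iter: int = 500,
           reg: float = 1e-6) -> MixtureModel:
    """Fit a K-component full-covariance Gaussian mixture by EM.

    Runs ``n_restarts`` EM runs from k-means++-style initializations and
    returns the run with the highest final log-likelihood. Within each run
    the log-likelihood is non-decreasing (EM guarantee). Covariances receive
    a trace-scaled ridge of ``reg`` for numerical stability; a run whose
    component covariance nearly collapses is restarted with a stronger ridge,
    and an error is raised only if every restart collapses.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be an (n, d) array")
    n = len(X)
    if n < K:
        raise ValueError(f"n = {n} samples cannot support K = {K} components")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")

    root = np.random.default_rng(seed)
    best = None
    for r in range(max(1, n_restarts)):
        rng = np.random.default_rng(root.integers(2 ** 31))
        model = _em_single(X, K, rng, tol, max_iter, reg)
        if model is None:
            model = _em_single(X, K, rng, tol, max_iter, reg * 1e3)
        if model is None:
            continue
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    if best is None:
        raise ValueError(
            f"EM failed: all {n_restarts} restarts collapsed a component")
    return best


# ---------------------------------------------------------------------------
# Criteria


def bic(model: MixtureModel, n: int) -> float:
    """Bayesian information criterion, lower is better."""
    if n <= 0:
        raise ValueError("n must be positive")
    return -2.0 * model.log_likelihood + model.n_params * np.log(n)


def entropy_of_assignment(model: MixtureModel) -> float:
    """EN = -sum z ln z over all responsibilities, with 0 ln 0 = 0."""
    z = model.responsibilities
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(z > 0, z * np.log(z), 0.0)
    return float(-term.sum())


def icl(model: MixtureModel, n: int) -> float:
    """Integrated complete-data likelihood criterion: BIC plus twice the
    assignment entropy; lower is better, and ICL >= BIC always."""
    return bic(model, n) + 2.0 * entropy_of_assignment(model)


def select_model(features: np.ndarray, K_range=range(4, 8), seed: int = 0,
                 n_restarts: int = 10, tol: float = 1e-8,
                 max_iter: int = 500) -> tuple[MixtureModel, pd.DataFrame]:
    """Fit every K in ``K_range`` and select the model with the lowest BIC.

    Returns the selected model plus a selection table (columns K, BIC, ICL,
    log_likelihood). When BIC and ICL disagree on the best K the
    disagreement is logged for the analyst — the final call on substantive
    validity of a clustering is a human judgment this function cannot make.
    """
    K_list = list(K_range)
    if not K_list:
        raise ValueError("K_range is empty")
    X = np.asarray(features, dtype=float)
    rows, models = [], {}
    for K in K_list:
        model = fit_em(X, K, seed=seed, n_restarts=n_restarts, tol=tol,
                       max_iter=max_iter)
        models[K] = model
        rows.append((K, bic(model, len(X)), icl(model, len(X)),
                     model.log_likelihood))
    table = pd.DataFrame(rows, columns=["K", "BIC", "ICL", "log_likelihood"])
    best_bic = int(table.loc[table["BIC"].idxmin(), "K"])
    best_icl = int(table.loc[table["ICL"].idxmin(), "K"])
    if best_bic != best_icl:
        logger.warning("BIC selects K=%d but ICL selects K=%d; returning the "
                       "BIC choice — review the selection table", best_bic,
                       best_icl)
    return models[best_bic], table


# ---------------------------------------------------------------------------
# Confidence ellipses


def confidence_ellipse(mean: np.ndarray, covariance: np.ndarray,
                       level: float = 0.95) -> Ellipse:
    """Confidence ellipse of a 2-D Gaussian at the given coverage level.

    Semi-axes are sqrt(chi2_2(level) * eigenvalues) of the covariance;
    rotation is the angle of the leading eigenvector in degrees.
    """
    mean = np.asarray(mean, dtype=float)
    covariance = np.asarray(covariance, dtype=float)
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    eigvals, eigvecs = np.linalg.eigh(covariance)
    if np.any(eigvals <= 0):
        raise ValueError("covariance must be positive definite")
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    scale = chi2.ppf(level, df=2)
    axes = np.sqrt(scale * eigvals)
    rotation = float(np.degrees(np.arctan2(eigvecs[1, 0], eigvecs[0, 0])))
    return Ellipse(center=mean, axes=axes, rotation=rotation, level=level)


def ellipse_table(model: MixtureModel, level: float = 0.95) -> pd.DataFrame:
    """Per-component ellipse parameters for plotting cluster scatter."""
    rows = []
    for k in range(model.K):
        e = confidence_ellipse(model.means[k], model.covariances[k], level)
        rows.append((k + 1, e.center[0], e.center[1], e.axes[0], e.axes[1],
                     e.rotation, level))
    return pd.DataFrame(rows, columns=["component", "center_x", "center_y",
                                       "semi_major", "semi_minor",
                                       "rotation_deg", "level"])
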