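"""Chemometric baselines: PLSR and PCA(>=95%)+SVR.

PLSR (single-response NIPALS via scikit-learn) serves as the linear
reference; the number of latent variables is chosen by minimizing RMSE on
the validation partition.  The kernel baseline reduces the standardized
spectra with PCA retaining the smallest number of components whose
cumulative explained variance exceeds 95%, then fits epsilon-insensitive
SVR whose kernel, box constraint C and epsilon are tuned by a seeded
Gaussian-process expected-improvement search against validation RMSE (a
plain seeded random search is available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.svm import SVR
from scipy.stats import norm as _norm

__all__ = [
    "BaselineError",
    "PLSModel",
    "PCABasis",
    "SVRModel",
    "SearchResult",
    "DEFAULT_SVR_SPACE",
    "fit_plsr",
    "select_latent_variables",
    "fit_pca_95",
    "fit_svr",
    "bayes_opt_svr",
]


class BaselineError(ValueError):
    """Domain error raised by the baseline models."""


_KERNEL_MAP = {
    "linear": "linear",
    "polynomial": "poly",
    "gaussian": "rbf",
    "sigmoid": "sigmoid",
}


# --------------------------------------------------------------------------
# PLSR
# --------------------------------------------------------------------------


@dataclass
class PLSModel:
    """Fitted PLSR model; prediction is affine in the (standardized) input."""

    n_latent: int
    _pls: PLSRegression

    @property
    def coef_(self) -> np.ndarray:
        return np.ravel(self._pls.coef_)

    @property
    def intercept_(self) -> float:
        return float(np.ravel(self._pls.intercept_)[0])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.ravel(self._pls.predict(np.asarray(X, dtype=float)))


def fit_plsr(X: np.ndarray, y: np.ndarray, n_latent: int) -> PLSModel:
    """Fit single-response PLSR with ``n_latent`` latent variables."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if not (1 <= n_latent <= max_rank):
        raise BaselineError(
            f"n_latent must be in [1, {max_rank}] for X of shape {X.shape}"
        )
    pls = PLSRegression(n_components=n_latent, scale=False)
    pls.fit(X, y)
    return PLSModel(n_latent=n_latent, _pls=pls)


def _rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    d = np.asarray(y, dtype=float) - np.asarray(yhat, dtype=float)
    return float(np.sqrt(np.mean(d * d)))


def select_latent_variables(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    max_lv: int = 60,
    return_scores: bool = False,
):
    """Number of latent variables minimizing validation RMSE (tie -> fewer)."""
    if max_lv < 1:
        raise BaselineError("max_lv must be >= 1")
    cap = min(max_lv, X_train.shape[0] - 1, X_train.shape[1])
    scores = np.empty(cap)
    for k in range(1, cap + 1):
        model = fit_plsr(X_train, y_train, k)
        scores[k - 1] = _rmse(y_val, model.predict(X_val))
    best = int(np.argmin(scores)) + 1   # argmin returns first minimum -> fewer LVs
    if return_scores:
        return best, scores
    return best


# --------------------------------------------------------------------------
# PCA + SVR
# --------------------------------------------------------------------------


@dataclass
class PCABasis:
    """Training-mean-centred PCA basis truncated at >95% explained variance."""

    components: np.ndarray            # (retained, n_features)
    explained_variance_ratio: np.ndarray
    retained: int
    mean: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) @ self.components.T


def fit_pca_95(X: np.ndarray, threshold: float = 0.95) -> PCABasis:
    """PCA keeping the smallest k with cumulative explained variance > threshold."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise BaselineError("need at least two samples")
    if np.ptp(X) == 0.0:
        raise BaselineError("degenerate all-equal data")
    pca = PCA(svd_solver="full")
    pca.fit(X)
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    retained = int(np.searchsorted(cum, threshold, side="right")) + 1
    retained = min(retained, len(evr))
    return PCABasis(
        components=pca.components_[:retained].copy(),
        explained_variance_ratio=evr.copy(),
        retained=retained,
        mean=pca.mean_.copy(),
    )


@dataclass
class SVRModel:
    """Fitted epsilon-insensitive SVR with its hyperparameters."""

    kernel: str
    C: float
    epsilon: float
    _svr: SVR

    @property
    def dual_coef_(self) -> np.ndarray:
        return np.ravel(self._svr.dual_coef_)

    @property
    def intercept_(self) -> float:
        return float(np.ravel(self._svr.intercept_)[0])

    def predict(self, Z: np.ndarray) -> np.ndarray:
        return np.ravel(self._svr.predict(np.asarray(Z, dtype=float)))


def fit_svr(
    Z: np.ndarray,
    y: np.ndarray,
    kernel: str = "linear",
    C: float = 1.0,
    epsilon: float = 0.1,
    **kernel_params,
) -> SVRModel:
    """Fit SVR; kernels: linear, polynomial, gaussian, sigmoid."""
    if kernel not in _KERNEL_MAP:
        raise BaselineError(f"unknown kernel {kernel!r}")
    if C <= 0 or epsilon < 0:
        raise BaselineError("need C > 0 and epsilon >= 0")
    # cap libsvm iterations: near-separable data at large C can otherwise
    # stall the hyperparameter search
    kernel_params.setdefault("max_iter", 200_000)
    svr = SVR(kernel=_KERNEL_MAP[kernel], C=C, epsilon=epsilon, **kernel_params)
    svr.fit(np.asarray(Z, dtype=float), np.asarray(y, dtype=float))
    return SVRModel(kernel=kernel, C=C, epsilon=epsilon, _svr=svr)


# --------------------------------------------------------------------------
# Bayesian hyperparameter search
# --------------------------------------------------------------------------

DEFAULT_SVR_SPACE = {
    "kernels": ("linear", "polynomial", "gaussian", "sigmoid"),
    "log10_C": (-3.0, 3.0),
    "log10_epsilon": (-3.0, 0.0),
}


@dataclass
class SearchResult:
    """Evaluated configurations, their validation RMSEs, and the incumbent."""

    configs: list[dict]
    scores: list[float]
    best_config: dict = field(init=False)
    best_score: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.configs:
            raise BaselineError("empty search result")
        i = int(np.argmin(self.scores))
        self.best_config = self.configs[i]
        self.best_score = float(self.scores[i])


def _expected_improvement(mu, sigma, best):
    sigma = np.maximum(sigma, 1e-12)
    z = (best - mu) / sigma
    return sigma * (z * _norm.cdf(z) + _norm.pdf(z))


def bayes_opt_svr(
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    space: dict | None = None,
    budget: int = 40,
    seed: int = 0,
    method: str = "gp",
) -> SearchResult:
    """Tune SVR hyperparameters against validation RMSE.

    The budget is spread over the kernels in the space; per kernel, a few
    seeded random points initialize a Gaussian-process surrogate over
    (log10 C, log10 epsilon) and subsequent points maximize expected
    improvement over a random candidate pool.  ``method='random'`` gives a
    plain seeded random search over the same space.  Deterministic given
    ``seed``.
    """
    if budget < 1:
        raise BaselineError("budget must be >= 1")
    space = dict(DEFAULT_SVR_SPACE if space is None else space)
    kernels = tuple(space["kernels"])
    if not kernels:
        raise BaselineError("empty search space")
    Ztr, ytr = train
    Zval, yval = val
    rng = np.random.default_rng(seed)

    def evaluate(kernel, logC, logE):
        model = fit_svr(Ztr, ytr, kernel=kernel, C=10.0 ** logC,
                        epsilon=10.0 ** logE)
        return _rmse(yval, model.predict(Zval))

    lC, uC = space["log10_C"]
    lE, uE = space["log10_epsilon"]
    per_kernel = [budget // len(kernels)] * len(kernels)
    for i in range(budget - sum(per_kernel)):
        per_kernel[i] += 1

    configs: list[dict] = []
    scores: list[float] = []
    for kernel, n_evals in zip(kernels, per_kernel):
        if n_evals == 0:
            continue
        pts: list[tuple[float, float]] = []
        vals: list[float] = []
        n_init = min(max(4, n_evals // 4), n_evals)
        for _ in range(n_init):
            pts.append((rng.uniform(lC, uC), rng.uniform(lE, uE)))
        for p in pts:
            vals.append(evaluate(kernel, *p))
        while len(pts) < n_evals:
            if method == "gp":
                X = np.array(pts)
                yv = np.array(vals)
                gp = GaussianProcessRegressor(
                    kernel=Matern(length_scale=[1.0, 1.0], nu=2.5),
                    alpha=1e-6, normalize_y=True, random_state=0,
                )
                gp.fit(X, yv)
                cand = np.column_stack([
                    rng.uniform(lC, uC, 256), rng.uniform(lE, uE, 256)
                ])
                mu, sd = gp.predict(cand, return_std=True)
                ei = _expected_improvement(mu, sd, yv.min())
                nxt = tuple(cand[int(np.argmax(ei))])
            else:
                nxt = (rng.uniform(lC, uC), rng.uniform(lE, uE))
            pts.append(nxt)
            vals.append(evaluate(kernel, *nxt))
        for p, v in zip(pts, vals):
            configs.append({"kernel": kernel, "C": 10.0 ** p[0],
                            "epsilon": 10.0 ** p[1]})
            scores.append(v)
    return SearchResult(configs=configs, scores=scores)
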