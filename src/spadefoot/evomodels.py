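"""Maximum-likelihood fitting of single-trait evolutionary models.

Three nested Gaussian models of continuous-trait evolution on a fixed
chronogram are fitted by ML and compared by AIC:

* **BM** — Brownian motion; tip covariance is the shared-path matrix
  ``sigma^2 V``; parameters ``(mu, sigma^2)``.
* **LAMBDA** — Pagel's lambda; off-diagonals of ``V`` shrunk by
  ``lambda in [0, 1]``; parameters ``(mu, sigma^2, lambda)``.
* **OU** — single-optimum Ornstein-Uhlenbeck with pull ``alpha > 0``;
  parameters ``(mu, sigma^2, alpha)``.

For any fixed covariance shape ``V(theta)`` the mean and rate have closed
ML forms (GLS mean, ML divisor *n*), so fitting reduces to a bounded 1-D
profile-likelihood search over the shape parameter.  Models within 4 AIC
units are treated as comparably supported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .tree import PhyloCov, TimeTree, lambda_scale, ou_scale, phylo_covariance

__all__ = [
    "EvoModelFit",
    "ModelComparison",
    "mvn_loglik",
    "fit_bm",
    "fit_lambda",
    "fit_ou",
    "model_table",
    "AIC_SUPPORT_THRESHOLD",
    "DEFAULT_OU_SEED",
]

#: AIC difference below which competing models are considered comparably supported.
AIC_SUPPORT_THRESHOLD = 4.0

#: Default seed for the OU restart scheme.
DEFAULT_OU_SEED = 20140506

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class EvoModelFit:
    """ML fit of one trait under one model.

    ``shape`` holds lambda (LAMBDA), alpha (OU) or ``None`` (BM).  A constant
    trait is flagged ``degenerate`` with ``sigma2 = 0`` and infinite
    log-likelihood rather than raising.
    """

    model: str
    mu: float
    sigma2: float
    shape: float | None
    loglik: float
    n_params: int
    n: int
    degenerate: bool = False
    aic: float = field(init=False)

    def __post_init__(self) -> None:
        self.aic = -2.0 * self.loglik + 2.0 * self.n_params


@dataclass
class ModelComparison:
    """The three fits for one trait with AIC differences and the supported set."""

    fits: dict[str, EvoModelFit]
    delta_aic: dict[str, float] = field(init=False)
    preferred: list[str] = field(init=False)

    def __post_init__(self) -> None:
        best = min(f.aic for f in self.fits.values())
        self.delta_aic = {m: f.aic - best for m, f in self.fits.items()}
        self.preferred = [
            m for m, d in self.delta_aic.items() if d < AIC_SUPPORT_THRESHOLD
        ]


def _chol(V: np.ndarray):
    """Cholesky factor of V, retrying once with a tiny jitter."""
    try:
        return cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        pass
    jitter = 1e-10 * np.trace(V) / len(V)
    try:
        return cho_factor(V + jitter * np.eye(len(V)), lower=True)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "covariance matrix is singular even after jitter; check for "
            "duplicate tips or zero-length terminal branches"
        ) from e


def _align(y, tree: TimeTree) -> tuple[np.ndarray, list[str]]:
    """Coerce a trait to an array aligned with the tree's tips.

    A pandas Series is aligned by label with missing values dropped; a bare
    array is assumed to already be in tip order.
    """
    if isinstance(y, pd.Series):
        y = y.dropna()
        missing = [t for t in y.index if t not in set(tree.tips)]
        if missing:
            raise KeyError(f"trait labels not in tree: {missing}")
        labels = [t for t in tree.tips if t in set(y.index)]
        return y.loc[labels].to_numpy(dtype=float), labels
    arr = np.asarray(y, dtype=float)
    if arr.shape != (tree.n_tips,):
        raise ValueError(
            f"trait length {arr.shape} does not match the {tree.n_tips}-tip tree"
        )
    return arr, list(tree.tips)


def mvn_loglik(y: np.ndarray, cov: PhyloCov, mu: float, sigma2: float) -> float:
    """Log-density of ``y ~ N(mu 1, sigma2 V)`` via Cholesky factorization."""
    y = np.asarray(y, dtype=float)
    n = cov.n
    if y.shape != (n,):
        raise ValueError(f"y has length {y.shape}, expected {n}")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    c = _chol(cov.V)
    logdet_V = 2.0 * np.sum(np.log(np.diag(c[0])))
    r = y - mu
    quad = float(r @ cho_solve(c, r))
    return -0.5 * (n * _LOG2PI + n * math.log(sigma2) + logdet_V + quad / sigma2)


def _profile_fit(y: np.ndarray, V: np.ndarray) -> tuple[float, float, float]:
    """Closed-form ML ``(mu, sigma2, loglik)`` for ``y ~ N(mu 1, sigma2 V)``.

    mu is the GLS mean, sigma2 uses the ML divisor n.
    """
    n = len(y)
    c = _chol(V)
    ones = np.ones(n)
    Vi1 = cho_solve(c, ones)
    mu = float(ones @ cho_solve(c, y) / (ones @ Vi1))
    r = y - mu
    sigma2 = float(r @ cho_solve(c, r)) / n
    if sigma2 <= 0:
        return mu, 0.0, math.inf
    logdet_V = 2.0 * np.sum(np.log(np.diag(c[0])))
    loglik = -0.5 * (n * _LOG2PI + n * math.log(sigma2) + logdet_V + n)
    return mu, sigma2, loglik


def _check_input(y: np.ndarray) -> bool:
    """Return True if the trait is degenerate (constant)."""
    if len(y) < 3:
        raise ValueError("need at least 3 non-missing trait values")
    return bool(np.ptp(y) == 0.0)


def fit_bm(y, tree: TimeTree) -> EvoModelFit:
    """Brownian-motion fit; closed form, 2 parameters (mu, sigma2)."""
    yv, labels = _align(y, tree)
    if _check_input(yv):
        return EvoModelFit("BM", float(yv[0]), 0.0, None, math.inf, 2, len(yv), True)
    V = phylo_covariance(tree).subset(labels).V
    mu, sigma2, ll = _profile_fit(yv, V)
    return EvoModelFit("BM", mu, sigma2, None, ll, 2, len(yv))


def fit_lambda(y, tree: TimeTree, xatol: float = 1e-8) -> EvoModelFit:
    """Pagel's-lambda fit: bounded 1-D profile search of lambda on [0, 1].

    The interior optimum from Brent search is compared against both
    endpoints, so boundary estimates (0 or 1) are returned exactly.
    """
    yv, labels = _align(y, tree)
    if _check_input(yv):
        return EvoModelFit(
            "LAMBDA", float(yv[0]), 0.0, None, math.inf, 3, len(yv), True
        )
    cov = phylo_covariance(tree).subset(labels)

    def nll(lam: float) -> float:
        return -_profile_fit(yv, lambda_scale(cov, lam).V)[2]

    res = optimize.minimize_scalar(
        nll, bounds=(0.0, 1.0), method="bounded", options={"xatol": xatol}
    )
    candidates = [(nll(0.0), 0.0), (nll(1.0), 1.0), (res.fun, float(res.x))]
    best_nll, lam_hat = min(candidates, key=lambda t: t[0])
    mu, sigma2, ll = _profile_fit(yv, lambda_scale(cov, lam_hat).V)
    return EvoModelFit("LAMBDA", mu, sigma2, lam_hat, ll, 3, len(yv))


def fit_ou(
    y,
    tree: TimeTree,
    n_restarts: int = 10,
    seed: int = DEFAULT_OU_SEED,
) -> EvoModelFit:
    """Single-optimum OU fit by restarted profile search over alpha.

    ``n_restarts`` L-BFGS-B searches over log(alpha) start from random
    log-uniform points in ``[1e-4 / T, 100 / T]`` (T the tree depth); the
    fit with the minimum deviance (-2 log-likelihood) is returned.  The
    restart scheme is deterministic given ``seed``.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    yv, labels = _align(y, tree)
    if _check_input(yv):
        return EvoModelFit("OU", float(yv[0]), 0.0, None, math.inf, 3, len(yv), True)
    T = tree.depth
    lo, hi = math.log(1e-4 / T), math.log(100.0 / T)
    sub = set(labels)
    idx = [i for i, t in enumerate(tree.tips) if t in sub]

    def nll(log_alpha: float) -> float:
        alpha = math.exp(np.clip(log_alpha, lo, hi))
        V = ou_scale(tree, alpha).V[np.ix_(idx, idx)]
        return -_profile_fit(yv, V)[2]

    rng = np.random.default_rng(seed)
    starts = rng.uniform(lo, hi, size=n_restarts)
    results, failures = [], []
    for x0 in starts:
        try:
            res = optimize.minimize(
                lambda v: nll(v[0]),
                x0=[x0],
                method="L-BFGS-B",
                bounds=[(lo, hi)],
            )
            if np.isfinite(res.fun):
                results.append((res.fun, float(res.x[0])))
            else:
                failures.append((x0, "non-finite objective"))
        except Exception as e:  # pragma: no cover - defensive
            failures.append((x0, str(e)))
    if not results:
        raise RuntimeError(
            "all OU restarts failed to converge; per-restart diagnostics: "
            f"{failures}"
        )
    _, log_alpha_hat = min(results, key=lambda t: t[0])
    alpha_hat = math.exp(log_alpha_hat)
    V = ou_scale(tree, alpha_hat).V[np.ix_(idx, idx)]
    mu, sigma2, ll = _profile_fit(yv, V)
    return EvoModelFit("OU", mu, sigma2, alpha_hat, ll, 3, len(yv))


def model_table(
    y,
    tree: TimeTree,
    n_restarts: int = 10,
    seed: int = DEFAULT_OU_SEED,
) -> ModelComparison:
    """Fit BM, OU and LAMBDA to one trait and compare by AIC."""
    fits = {
        "BM": fit_bm(y, tree),
        "OU": fit_ou(y, tree, n_restarts=n_restarts, seed=seed),
        "LAMBDA": fit_lambda(y, tree),
    }
    return ModelComparison(fits)
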