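"""Closed-form model evidence for fixed sets of design columns.

Model: y = X beta + eps with eps ~ N(0, sigma^2 I), the conjugate prior
beta | sigma^2 ~ N(0, sigma^2 lambda^2 Sigma) and p(sigma^2) ∝ 1/sigma^2.
Integrating beta and sigma^2 out gives, up to a constant shared by every
model on the same data,

    log p(y | gamma) = -1/2 log|lambda^2 Sigma|
                       -1/2 log|X'X + (lambda^2 Sigma)^{-1}|
                       -(n/2) log Q(gamma),

where Q(gamma) = y'y - y'X (X'X + (lambda^2 Sigma)^{-1})^{-1} X'y is the
residual sum of squares of regressing the augmented response (y; 0_k) on the
augmented design (X; lambda^{-1} C) with C'C = Sigma^{-1}.  A single QR of the
augmented design yields both the determinant (from |diag R|) and Q, and all
arithmetic stays in log space — with n in the hundreds Q^{-n/2} would
underflow otherwise.

Only posterior *ratios* are ever needed by the sampler, so the shared
constant is never evaluated.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import cholesky, solve_triangular

__all__ = [
    "PriorSpec",
    "ModelEvidence",
    "ModelState",
    "build_sigma",
    "log_marginal_likelihood",
    "log_marginal_likelihood_normal_eq",
    "log_model_posterior",
    "make_snp_log_posterior",
    "exhaustive_posterior",
    "marginals_from_exhaustive",
    "count_model_space",
]


@dataclass
class PriorSpec:
    """Prior configuration for the screen.

    Parameters
    ----------
    lam : float
        Scale of the effect prior (flatness); the study default is 1.0,
        matching effect sizes of order one.
    sigma_structure : {"identity", "exchangeable"}
        Prior correlation structure among active effects.  "exchangeable"
        puts correlation ``rho`` within each gene block.
    rho : float
        Within-block prior correlation, in [0, 1).
    m : int
        Number of active factors in every model.
    model_prior : {"uniform", "size_penalized"}
        "uniform" gives every model the same prior probability;
        "size_penalized" weights a model with k regression parameters by
        exp(-k/2) (a BIC-style penalty used in gene mode, where k varies).
    bic_log_n : bool
        If True the penalty becomes exp(-(k/2) log n), the textbook BIC
        scaling; off by default.
    """

    lam: float = 1.0
    sigma_structure: str = "identity"
    rho: float = 0.0
    m: int = 10
    model_prior: str = "uniform"
    bic_log_n: bool = False

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.sigma_structure not in ("identity", "exchangeable"):
            raise ValueError(f"unknown sigma structure {self.sigma_structure!r}")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1) for a positive-definite prior")
        if self.m < 1:
            raise ValueError("model size m must be positive")
        if self.model_prior not in ("uniform", "size_penalized"):
            raise ValueError(f"unknown model prior {self.model_prior!r}")


@dataclass
class ModelEvidence:
    """Evidence of one model, up to a shared additive constant.

    ``log_marginal = log_det_penalty - (n/2) * log(q_gamma) + const(n)``.
    """

    log_marginal: float
    q_gamma: float
    log_det_penalty: float
    k: int
    n: int

    def to_dict(self) -> dict:
        return {
            "log_marginal": self.log_marginal,
            "q_gamma": self.q_gamma,
            "log_det_penalty": self.log_det_penalty,
            "k": self.k,
            "n": self.n,
        }


@dataclass(frozen=True)
class ModelState:
    """A model: the sorted set of active factor indices."""

    active: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "active", tuple(sorted(self.active)))

    def gamma(self, p: int) -> np.ndarray:
        g = np.zeros(p, dtype=np.int8)
        g[list(self.active)] = 1
        return g

    @property
    def m(self) -> int:
        return len(self.active)


def build_sigma(
    k: int,
    structure: str = "identity",
    rho: float = 0.0,
    block_sizes: Sequence[int] | None = None,
) -> np.ndarray:
    """Prior correlation matrix Sigma for k effects.

    "identity" returns I_k.  "exchangeable" returns a block-diagonal matrix
    with 1 on the diagonal and ``rho`` within each block (one block per gene);
    cross-block entries are zero.
    """
    if structure == "identity":
        return np.eye(k)
    if structure != "exchangeable":
        raise ValueError(f"unknown sigma structure {structure!r}")
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must lie in [0, 1); rho >= 1 makes the prior singular")
    if block_sizes is None:
        block_sizes = [k]
    if sum(block_sizes) != k:
        raise ValueError("block sizes must sum to k")
    sigma = np.zeros((k, k))
    start = 0
    for b in block_sizes:
        sigma[start : start + b, start : start + b] = rho
        start += b
    np.fill_diagonal(sigma, 1.0)
    return sigma


def _sigma_inv_sqrt(sigma: np.ndarray) -> tuple[np.ndarray, float]:
    """Return C with C'C = Sigma^{-1} and log|Sigma|."""
    try:
        L = cholesky(sigma, lower=True, check_finite=False)
    except np.linalg.LinAlgError as exc:
        raise ValueError("sigma is not symmetric positive definite") from exc
    log_det_sigma = 2.0 * float(np.sum(np.log(np.diag(L))))
    C = solve_triangular(L, np.eye(sigma.shape[0]), lower=True, check_finite=False)
    return C, log_det_sigma


def log_marginal_likelihood(
    y: np.ndarray,
    X: np.ndarray,
    prior: PriorSpec,
    sigma: np.ndarray | None = None,
) -> ModelEvidence:
    """Log marginal likelihood of centred response ``y`` given columns ``X``.

    Computed through the augmented regression: one QR of
    ``[X; lambda^{-1} C]`` (with ``C'C = Sigma^{-1}``) yields both
    ``|X'X + (lambda^2 Sigma)^{-1}|`` and Q(gamma).  The prior keeps the
    augmented design full rank, so duplicate or all-zero columns are allowed
    (a zero column triggers a warning, not an error).
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if n == 0 or k == 0:
        raise ValueError("need at least one observation and one column")
    if y.shape[0] != n:
        raise ValueError("y and X have incompatible shapes")
    yty = float(y @ y)
    if yty == 0.0:
        raise ValueError("response is identically zero")

    lam = prior.lam
    if sigma is None:
        C = np.eye(k)
        log_det_sigma = 0.0
    else:
        sigma = np.asarray(sigma, dtype=float)
        if sigma.shape != (k, k):
            raise ValueError("sigma shape does not match column count")
        C, log_det_sigma = _sigma_inv_sqrt(sigma)

    if not np.einsum("ij,ij->j", X, X).all():
        warnings.warn(
            "design contains an all-zero column; the prior keeps the model "
            "well posed",
            stacklevel=2,
        )

    Xa = np.empty((n + k, k))
    Xa[:n] = X
    Xa[n:] = C / lam
    R = np.linalg.qr(Xa, mode="r")
    # X'X + (lam^2 Sigma)^{-1} = R'R; its log-determinant from |diag R|
    log_det_M = 2.0 * float(np.sum(np.log(np.abs(np.diag(R)))))
    # Q = y'y - z'z with z = R^{-T} X'y  (the augmented rows contribute 0 to X'y)
    z = solve_triangular(R, X.T @ y, trans="T", lower=False, check_finite=False)
    q_gamma = yty - float(z @ z)
    # guard against cancellation on (near-)perfect fits
    q_gamma = max(q_gamma, np.finfo(float).tiny)

    log_det_lam2_sigma = 2.0 * k * math.log(lam) + log_det_sigma
    log_det_penalty = -0.5 * log_det_M - 0.5 * log_det_lam2_sigma
    log_marginal = log_det_penalty - 0.5 * n * math.log(q_gamma)
    return ModelEvidence(log_marginal, q_gamma, log_det_penalty, k, n)


def log_marginal_likelihood_normal_eq(
    y: np.ndarray,
    X: np.ndarray,
    prior: PriorSpec,
    sigma: np.ndarray | None = None,
) -> ModelEvidence:
    """Same quantity via explicit normal equations (cross-check route)."""
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    lam = prior.lam
    sig = np.eye(k) if sigma is None else np.asarray(sigma, dtype=float)
    prior_prec = np.linalg.inv(lam**2 * sig)
    M = X.T @ X + prior_prec
    sign, log_det_M = np.linalg.slogdet(M)
    if sign <= 0:
        raise ValueError("normal-equations matrix not positive definite")
    Xty = X.T @ y
    q_gamma = float(y @ y - Xty @ np.linalg.solve(M, Xty))
    q_gamma = max(q_gamma, np.finfo(float).tiny)
    _, log_det_sigma = np.linalg.slogdet(sig)
    log_det_penalty = -0.5 * log_det_M - 0.5 * (2 * k * math.log(lam) + log_det_sigma)
    log_marginal = log_det_penalty - 0.5 * n * math.log(q_gamma)
    return ModelEvidence(log_marginal, q_gamma, log_det_penalty, k, n)


def log_model_posterior(evidence: ModelEvidence, prior: PriorSpec) -> float:
    """Unnormalised log posterior: evidence plus the log model prior.

    Uniform prior adds a constant (dropped).  The size-penalised prior adds
    -k/2 (or -(k/2) log n when ``bic_log_n``), with k the number of design
    columns — the beta dimension.
    """
    if prior.model_prior == "uniform":
        return evidence.log_marginal
    penalty = 0.5 * evidence.k
    if prior.bic_log_n:
        penalty *= math.log(evidence.n)
    return evidence.log_marginal - penalty


def make_snp_log_posterior(
    X_centered: np.ndarray, y_centered: np.ndarray, prior: PriorSpec
) -> Callable[[tuple[int, ...]], float]:
    """Closure mapping an active-variant index tuple to its log posterior.

    SNP mode: Sigma is the identity and every model has k = m columns, so the
    model prior contributes the same constant to every model either way.
    """
    X_centered = np.asarray(X_centered, dtype=float)
    y_centered = np.asarray(y_centered, dtype=float).ravel()

    def log_post(active: tuple[int, ...]) -> float:
        X = X_centered[:, list(active)]
        ev = log_marginal_likelihood(y_centered, X, prior, sigma=None)
        return log_model_posterior(ev, prior)

    return log_post


def count_model_space(p: int, m: int) -> int:
    """Exact number of models with m of p factors active: C(p, m)."""
    if m < 0 or p < 0:
        raise ValueError("p and m must be non-negative")
    if m > p:
        raise ValueError(f"m={m} exceeds p={p}")
    return math.comb(p, m)


def exhaustive_posterior(
    y: np.ndarray,
    design_provider: Callable[[tuple[int, ...]], np.ndarray | tuple],
    p: int,
    m: int,
    prior: PriorSpec,
    cap: int = 10**6,
) -> tuple[list[tuple[int, ...]], np.ndarray]:
    """Enumerate all C(p, m) models and return normalised posteriors.

    ``design_provider(active)`` returns the design matrix for a model, or a
    ``(design, block_sizes)`` pair when the exchangeable prior needs gene
    blocks.  Refuses (with advice to use MCMC) when C(p, m) exceeds ``cap``.
    """
    n_models = count_model_space(p, m)
    if n_models > cap:
        raise ValueError(
            f"model space has {n_models} models (> cap {cap}); "
            "use the Metropolis-Hastings sampler instead"
        )
    models: list[tuple[int, ...]] = []
    log_posts = np.empty(n_models)
    for i, combo in enumerate(itertools.combinations(range(p), m)):
        out = design_provider(combo)
        if isinstance(out, tuple):
            X, block_sizes = out
            sigma = build_sigma(X.shape[1], prior.sigma_structure, prior.rho, block_sizes)
        else:
            X = out
            sigma = None
            if prior.sigma_structure == "exchangeable":
                sigma = build_sigma(X.shape[1], "exchangeable", prior.rho)
        ev = log_marginal_likelihood(y, X, prior, sigma)
        log_posts[i] = log_model_posterior(ev, prior)
        models.append(combo)
    log_posts -= log_posts.max()
    probs = np.exp(log_posts)
    probs /= probs.sum()
    return models, probs


def marginals_from_exhaustive(
    models: Sequence[tuple[int, ...]], probs: np.ndarray, p: int
) -> np.ndarray:
    """Per-factor marginal inclusion probabilities from an enumerated space."""
    marg = np.zeros(p)
    for combo, pr in zip(models, probs):
        marg[list(combo)] += pr
    return marg
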