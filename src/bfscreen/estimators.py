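"""scikit-learn style screening estimators.

:class:`SnpScreen` and :class:`GeneScreen` are feature selectors: ``fit(X, y)``
runs the Metropolis-Hastings screen and stores per-factor marginal inclusion
probabilities; ``transform`` keeps the columns of the top-``m`` factors, so
the estimators compose with sklearn pipelines and model selection.

``y`` is expected to be covariate-residualised already (see
:func:`bfscreen.residualize.residualize`); both X columns and y are centred
internally, matching the intercept-free variant models.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .bayes import PriorSpec, make_snp_log_posterior
from .genes import make_gene_log_posterior_from_arrays
from .mcmc import convergence_check, marginal_inclusion, run_chain

__all__ = ["SnpScreen", "GeneScreen", "screen_snps", "screen_genes"]


def _chain_seeds(random_state, n_chains: int) -> list[int]:
    if random_state is None:
        random_state = int(np.random.SeedSequence().generate_state(1)[0] & 0x7FFFFFFF)
    seeds = [int(random_state)]
    ss = np.random.SeedSequence(int(random_state))
    for child in ss.spawn(n_chains - 1):
        seeds.append(int(child.generate_state(1)[0] & 0x7FFFFFFF))
    return seeds


class _BaseScreen(SelectorMixin, BaseEstimator):
    def _run_chains(self, log_post, p: int, m: int):
        seeds = _chain_seeds(self.random_state, self.n_chains)
        chains = [
            run_chain(
                log_post,
                p=p,
                m=m,
                n_iter=self.n_iter,
                burn_in=self.burn_in,
                seed=s,
                audit_path=self.audit_path if i == 0 else None,
            )
            for i, s in enumerate(seeds)
        ]
        summaries = [marginal_inclusion(c, p) for c in chains]
        self.chain_ = chains[0]
        self.chains_ = chains
        self.summaries_ = summaries
        self.summary_ = summaries[0]
        self.inclusion_probabilities_ = summaries[0].probabilities
        self.acceptance_rate_ = chains[0].acceptance_rate
        if len(summaries) > 1:
            self.convergence_correlation_ = convergence_check(
                summaries[0], summaries[1]
            )
        return summaries[0]


class SnpScreen(_BaseScreen):
    """Bayesian screen treating every column of X as a candidate factor.

    Every model holds exactly ``m`` active columns; the conjugate prior
    beta | sigma^2 ~ N(0, sigma^2 lam^2 I) and p(sigma^2) ∝ 1/sigma^2 gives
    each model a closed-form evidence, and a swap-proposal Metropolis-
    Hastings chain estimates per-column marginal inclusion probabilities.

    Parameters
    ----------
    m : int, default=10
        Number of active factors in every model.
    lam : float, default=1.0
        Prior effect scale; 1.0 suits effects of order one.
    model_prior : {"uniform", "size_penalized"}, default="uniform"
        With fixed-size SNP models both choices coincide (k is constant).
    n_iter, burn_in : int
        Chain length after burn-in, and burn-in length.
    n_chains : {1, 2}, default=1
        With 2, an independent chain is run and the Pearson correlation of
        the two inclusion vectors is stored as a convergence diagnostic.
    random_state : int or None
        Seed for the sampler (first chain uses it directly).

    Attributes
    ----------
    inclusion_probabilities_ : ndarray of shape (n_features,)
        Marginal posterior inclusion probability per column; sums to ``m``.
    summary_ : InclusionSummary
    chain_ : Chain
    acceptance_rate_ : float
    convergence_correlation_ : float, only when ``n_chains == 2``.
    """

    def __init__(
        self,
        m: int = 10,
        lam: float = 1.0,
        model_prior: str = "uniform",
        n_iter: int = 100_000,
        burn_in: int = 1_000,
        n_chains: int = 1,
        random_state: int | None = None,
        audit_path=None,
    ):
        self.m = m
        self.lam = lam
        self.model_prior = model_prior
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.n_chains = n_chains
        self.random_state = random_state
        self.audit_path = audit_path

    def fit(self, X, y):
        X, y = validate_data(self, X, y, dtype=float, y_numeric=True)
        p = X.shape[1]
        if not 0 < self.m < p:
            raise ValueError(f"need 0 < m < n_features (m={self.m}, p={p})")
        Xc = X - X.mean(axis=0, keepdims=True)
        yc = y - y.mean()
        prior = PriorSpec(
            lam=self.lam,
            sigma_structure="identity",
            m=self.m,
            model_prior=self.model_prior,
        )
        log_post = make_snp_log_posterior(Xc, yc, prior)
        self._run_chains(log_post, p, self.m)
        order = self.summary_.ranking()
        mask = np.zeros(p, dtype=bool)
        mask[order[: self.m]] = True
        self.support_mask_ = mask
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_mask_


class GeneScreen(_BaseScreen):
    """Bayesian screen treating groups of columns (genes) as factors.

    All variants of a gene enter and leave the model together, so the
    parameter count k varies with the active genes; the size-penalised model
    prior exp(-k/2) counteracts the resulting bias toward variant-rich genes.

    ``fit(X, y, groups=...)`` takes one gene label per column.  ``transform``
    keeps the columns of the top-``m`` genes.

    Attributes
    ----------
    gene_ids_ : list of str
        Sorted gene labels; index order of the gene factors.
    inclusion_probabilities_ : ndarray of shape (n_genes,)
        Marginal posterior inclusion probability per gene; sums to ``m``.
    """

    def __init__(
        self,
        m: int = 3,
        lam: float = 1.0,
        sigma: str = "identity",
        rho: float = 0.1,
        model_prior: str = "size_penalized",
        n_iter: int = 10_000,
        burn_in: int = 1_000,
        n_chains: int = 1,
        random_state: int | None = None,
        audit_path=None,
    ):
        self.m = m
        self.lam = lam
        self.sigma = sigma
        self.rho = rho
        self.model_prior = model_prior
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.n_chains = n_chains
        self.random_state = random_state
        self.audit_path = audit_path

    def fit(self, X, y, groups=None):
        X, y = validate_data(self, X, y, dtype=float, y_numeric=True)
        if groups is None:
            raise ValueError("GeneScreen.fit requires groups= (gene label per column)")
        groups = np.asarray(groups)
        if groups.shape[0] != X.shape[1]:
            raise ValueError("groups must give one gene label per column")
        gene_ids = sorted(str(g) for g in set(groups.tolist()))
        n_genes = len(gene_ids)
        if not 0 < self.m < n_genes:
            raise ValueError(f"need 0 < m < n_genes (m={self.m}, genes={n_genes})")
        gene_cols = [
            np.flatnonzero(groups.astype(str) == g) for g in gene_ids
        ]
        Xc = X - X.mean(axis=0, keepdims=True)
        yc = y - y.mean()
        prior = PriorSpec(
            lam=self.lam,
            sigma_structure=self.sigma,
            rho=self.rho if self.sigma == "exchangeable" else 0.0,
            m=self.m,
            model_prior=self.model_prior,
        )
        log_post = make_gene_log_posterior_from_arrays(Xc, yc, prior, gene_cols)
        self._run_chains(log_post, n_genes, self.m)
        self.gene_ids_ = gene_ids
        for s in self.summaries_:
            s.factor_ids = list(gene_ids)
        order = self.summary_.ranking()
        top_genes = set(order[: self.m])
        mask = np.zeros(X.shape[1], dtype=bool)
        for gi in top_genes:
            mask[gene_cols[gi]] = True
        self.support_mask_ = mask
        self.gene_sizes_ = {g: len(c) for g, c in zip(gene_ids, gene_cols)}
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.support_mask_


# ---------------------------------------------------------------------------
# thin wrappers over the estimators, working on the domain containers


def screen_snps(
    genotypes,
    response,
    m: int = 10,
    lam: float = 1.0,
    n_iter: int = 100_000,
    burn_in: int = 1_000,
    n_chains: int = 1,
    seed: int = 0,
    audit_path=None,
):
    """SNP-level screen on a GenotypeMatrix and a residualised response.

    Returns the fitted :class:`SnpScreen`; its ``summary_`` carries the
    variant ids.
    """
    est = SnpScreen(
        m=m,
        lam=lam,
        n_iter=n_iter,
        burn_in=burn_in,
        n_chains=n_chains,
        random_state=seed,
        audit_path=audit_path,
    )
    est.fit(genotypes.values, np.asarray(response, dtype=float))
    for s in est.summaries_:
        s.factor_ids = list(genotypes.variant_ids)
    return est


def screen_genes(
    genotypes,
    gene_map,
    response,
    m: int = 3,
    lam: float = 1.0,
    sigma: str = "identity",
    rho: float = 0.1,
    model_prior: str = "size_penalized",
    n_iter: int = 10_000,
    burn_in: int = 1_000,
    n_chains: int = 1,
    seed: int = 0,
    audit_path=None,
):
    """Gene-level screen on a GenotypeMatrix, GeneMap and residualised response."""
    missing = [v for v in genotypes.variant_ids if v not in gene_map.assignment]
    if missing:
        raise ValueError(
            f"{len(missing)} variant(s) missing from the gene map "
            f"(first: {missing[0]!r})"
        )
    groups = [gene_map.assignment[v] for v in genotypes.variant_ids]
    est = GeneScreen(
        m=m,
        lam=lam,
        sigma=sigma,
        rho=rho,
        model_prior=model_prior,
        n_iter=n_iter,
        burn_in=burn_in,
        n_chains=n_chains,
        random_state=seed,
        audit_path=audit_path,
    )
    est.fit(genotypes.values, np.asarray(response, dtype=float), groups=groups)
    return est
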