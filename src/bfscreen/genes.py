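"""Gene-as-factor screening.

A gene factor forces all of its variants in and out of the model together:
the design for an active gene set is the concatenation of the centred
minor-allele-count columns of every variant in every active gene.  Because
gene sizes differ, the number of regression parameters k varies across
models, and the size-penalised prior exp(-k/2) corrects the bias toward
large genes (imperfectly — it is known to overshoot toward small genes,
which is reproduced here deliberately).

Gene-level inference can also be derived from a SNP-level run by averaging
the marginal posterior of a gene's variants and comparing with the per-variant
prior m/p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .bayes import (
    PriorSpec,
    build_sigma,
    log_marginal_likelihood,
    log_model_posterior,
)
from .io import GeneMap, GenotypeMatrix
from .mcmc import InclusionSummary, run_chain

__all__ = [
    "GeneModelDesign",
    "build_gene_design",
    "make_gene_log_posterior",
    "make_gene_log_posterior_from_arrays",
    "gene_summary_from_snp_run",
    "run_gene_screen",
]


@dataclass
class GeneModelDesign:
    """Centred design for a set of active genes.

    Column blocks are ordered by gene id, variants in map order within each
    block; ``k`` (the total column count) feeds the size-penalised prior.
    """

    active_genes: tuple[str, ...]
    columns: np.ndarray
    k: int
    block_sizes: list[int]


def _gene_column_index(
    gene_map: GeneMap, genotypes: GenotypeMatrix
) -> dict[str, list[int]]:
    col_of = {v: j for j, v in enumerate(genotypes.variant_ids)}
    unmapped = [v for v in genotypes.variant_ids if v not in gene_map.assignment]
    if unmapped:
        raise ValueError(
            f"{len(unmapped)} genotyped variant(s) missing from the gene map "
            f"(first: {unmapped[0]!r}); gene-level mode requires full coverage"
        )
    index: dict[str, list[int]] = {}
    for variant, gene in gene_map.assignment.items():
        if variant in col_of:
            index.setdefault(gene, []).append(col_of[variant])
    for gene in index:
        index[gene].sort()
    return index


def build_gene_design(
    active_genes: Sequence[str],
    gene_map: GeneMap,
    genotypes: GenotypeMatrix,
) -> GeneModelDesign:
    """Centred design whose columns are all variants of the active genes."""
    index = _gene_column_index(gene_map, genotypes)
    genes = tuple(sorted(active_genes))
    cols: list[int] = []
    block_sizes: list[int] = []
    for gene in genes:
        if gene not in index:
            raise ValueError(f"unknown gene {gene!r}")
        cols.extend(index[gene])
        block_sizes.append(len(index[gene]))
    X = genotypes.values[:, cols].astype(float)
    X -= X.mean(axis=0, keepdims=True)
    return GeneModelDesign(
        active_genes=genes, columns=X, k=X.shape[1], block_sizes=block_sizes
    )


def make_gene_log_posterior_from_arrays(
    X_centered: np.ndarray,
    y_centered: np.ndarray,
    prior: PriorSpec,
    gene_cols: Sequence[np.ndarray],
) -> Callable[[tuple[int, ...]], float]:
    """Closure over a centred matrix and per-gene column-index blocks."""
    Xc = np.asarray(X_centered, dtype=float)
    y = np.asarray(y_centered, dtype=float).ravel()
    gene_cols = [np.asarray(c, dtype=int) for c in gene_cols]

    def log_post(active: tuple[int, ...]) -> float:
        blocks = [gene_cols[i] for i in active]
        cols = np.concatenate(blocks)
        X = Xc[:, cols]
        if prior.sigma_structure == "exchangeable":
            sigma = build_sigma(
                X.shape[1], "exchangeable", prior.rho, [len(b) for b in blocks]
            )
        else:
            sigma = None
        ev = log_marginal_likelihood(y, X, prior, sigma)
        return log_model_posterior(ev, prior)

    return log_post


def make_gene_log_posterior(
    genotypes: GenotypeMatrix,
    gene_map: GeneMap,
    y_centered: np.ndarray,
    prior: PriorSpec,
    gene_ids: Sequence[str],
) -> Callable[[tuple[int, ...]], float]:
    """Closure mapping an active-gene index tuple to its log posterior.

    ``gene_ids`` fixes the index order of the gene factors.  The centred
    genotype matrix is precomputed once; per model only a column gather and
    one QR are needed.
    """
    index = _gene_column_index(gene_map, genotypes)
    missing = [g for g in gene_ids if g not in index]
    if missing:
        raise ValueError(f"gene(s) without genotyped variants: {missing[:5]}")
    Xc = genotypes.values.astype(float)
    Xc = Xc - Xc.mean(axis=0, keepdims=True)
    gene_cols = [np.asarray(index[g], dtype=int) for g in gene_ids]
    return make_gene_log_posterior_from_arrays(Xc, y_centered, prior, gene_cols)


def gene_summary_from_snp_run(
    snp_summary: InclusionSummary,
    gene_map: GeneMap,
    m: int | None = None,
    p: int | None = None,
) -> pd.DataFrame:
    """Gene-level posterior/prior ratios derived from a SNP-level run.

    Per gene: mean marginal posterior over its variants, divided by the
    per-variant prior inclusion probability m/p (the uniform-model-prior
    value).  Genes whose variants were not summarised are excluded with a
    warning.
    """
    m = snp_summary.m if m is None else m
    p = snp_summary.p if p is None else p
    prior_per_variant = m / p
    post = dict(zip(snp_summary.factor_ids, snp_summary.probabilities))
    rows = []
    skipped = []
    for gene in gene_map.genes:
        variants = [v for v in gene_map.variants_of(gene) if v in post]
        if not variants:
            skipped.append(gene)
            continue
        mean_post = float(np.mean([post[v] for v in variants]))
        rows.append(
            {
                "gene_id": gene,
                "n_variants": len(variants),
                "mean_marginal_posterior": mean_post,
                "posterior_prior_ratio": mean_post / prior_per_variant,
            }
        )
    if skipped:
        warnings.warn(
            f"{len(skipped)} gene(s) had no summarised variants and were "
            f"excluded (first: {skipped[0]!r})",
            stacklevel=2,
        )
    return pd.DataFrame(rows).sort_values(
        "posterior_prior_ratio", ascending=False, ignore_index=True
    )


def run_gene_screen(
    genotypes: GenotypeMatrix,
    gene_map: GeneMap,
    response: np.ndarray,
    prior: PriorSpec,
    n_iter: int = 10_000,
    burn_in: int = 1_000,
    seed: int = 0,
    audit_path=None,
):
    """Metropolis-Hastings screen over gene sets of size ``prior.m``.

    Returns an (InclusionSummary over genes, Chain) pair.  The response
    should already be covariate-residualised; it is centred here.
    """
    gene_ids = gene_map.genes
    n_genes = len(gene_ids)
    if prior.m >= n_genes:
        raise ValueError(f"model size m={prior.m} must be below gene count {n_genes}")
    y = np.asarray(response, dtype=float).ravel()
    y = y - y.mean()
    log_post = make_gene_log_posterior(genotypes, gene_map, y, prior, gene_ids)
    chain = run_chain(
        log_post,
        p=n_genes,
        m=prior.m,
        n_iter=n_iter,
        burn_in=burn_in,
        seed=seed,
        audit_path=audit_path,
    )
    from .mcmc import marginal_inclusion

    summary = marginal_inclusion(chain, n_genes, factor_ids=gene_ids)
    return summary, chain
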