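"""Synthetic mini-exome study generator with known ground truth.

Emulates the structure of the GAW17-style design the screen targets: ~697
unrelated individuals, many genes with highly variable variant counts, a
rare-skewed minor-allele-frequency spectrum, a handful of causal variants
clustered in a few genes with effects spanning 0.13-1.35, three covariates
(Smoke, Age, Sex) and an optional causal-gene x smoking interaction.

What it does NOT emulate: linkage disequilibrium from real haplotypes
(independent binomial sites by default; an optional Gaussian-copula
within-gene LD block generator is provided for robustness experiments),
population structure, pedigrees, or the actual GAW17 trait model.

The trait decomposes exactly as genetic + covariate + interaction + noise;
the decomposition is kept in :class:`SyntheticTruth` so tests can check
recovery against the generative truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .io import GeneMap, GenotypeMatrix, PhenoTable

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SimulatedStudy",
    "default_config",
    "paper_scale_config",
    "simulate_genotypes",
    "simulate_trait",
    "simulate_replicate",
]

#: default causal architecture: effects spanning the declared range, paired
#: with MAFs running from common (0.25) to very rare (0.002), grouped into
#: four causal genes.
_DEFAULT_EFFECTS = (1.35, 0.9, 0.7, 0.55, 0.5, 0.4, 0.3, 0.2, 0.15, 0.13)
_DEFAULT_MAFS = (0.25, 0.15, 0.10, 0.08, 0.07, 0.02, 0.01, 0.005, 0.003, 0.002)
_DEFAULT_ASSIGNMENT = (0, 0, 0, 1, 1, 1, 2, 2, 3, 3)


@dataclass
class SyntheticConfig:
    """Study-design knobs for the generator.

    Defaults describe the standard small replicate: 697 individuals, 200
    genes (~1,000 variants), 10 causal variants in 4 genes, unit noise.
    """

    n_individuals: int = 697
    n_genes: int = 200
    gene_size_mean: float = 5.0  # geometric; highly variable counts
    max_gene_size: int = 40
    maf_beta_a: float = 0.3  # Beta(a, b) * 0.5: rare-skewed spectrum
    maf_beta_b: float = 3.0
    causal_effects: tuple = _DEFAULT_EFFECTS
    causal_mafs: tuple = _DEFAULT_MAFS
    causal_gene_assignment: tuple = _DEFAULT_ASSIGNMENT
    effect_range: tuple = (0.13, 1.35)
    smoke_prevalence: float = 0.25
    sex_fraction: float = 0.5
    age_range: tuple = (20, 80)
    smoke_effect: float = 0.3
    age_effect: float = 0.01
    sex_effect: float = 0.2
    interaction_gene: int | None = None  # causal-gene slot, e.g. 0
    interaction_multiplier: float = 0.0
    noise_sd: float = 1.0
    ld_within_gene: float = 0.0  # Gaussian-copula haplotype correlation

    def __post_init__(self) -> None:
        lo, hi = self.effect_range
        for e in self.causal_effects:
            if not lo <= abs(e) <= hi:
                raise ValueError(
                    f"causal effect {e} outside declared range [{lo}, {hi}]"
                )
        if len(self.causal_effects) != len(self.causal_mafs) or len(
            self.causal_effects
        ) != len(self.causal_gene_assignment):
            raise ValueError("causal effect/MAF/gene lists must have equal length")
        for f in self.causal_mafs:
            if not 0 < f <= 0.5:
                raise ValueError("causal MAFs must lie in (0, 0.5]")
        if not 0 <= self.ld_within_gene < 1:
            raise ValueError("ld_within_gene must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    @property
    def n_causal_genes(self) -> int:
        return len(set(self.causal_gene_assignment))


def default_config(**overrides) -> SyntheticConfig:
    """The standard small replicate (n=697, ~1,000 variants, 200 genes)."""
    return SyntheticConfig(**overrides)


def paper_scale_config(**overrides) -> SyntheticConfig:
    """Full-scale preset: 3,205 genes (~24,500 variants), 39 causal in 9 genes.

    Intended for manual runs; far too slow for routine testing.
    """
    sizes = (11, 7, 5, 4, 3, 3, 3, 2, 1)  # 39 causal variants over 9 genes
    assignment = tuple(g for g, s in enumerate(sizes) for _ in range(s))
    effects = tuple(np.round(np.geomspace(1.35, 0.13, 39), 4))
    mafs = tuple(np.round(np.geomspace(0.25, 0.002, 39), 6))
    params = dict(
        n_genes=3205,
        gene_size_mean=7.6,
        causal_effects=effects,
        causal_mafs=mafs,
        causal_gene_assignment=assignment,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


@dataclass
class SyntheticTruth:
    """Generative ground truth for one replicate."""

    causal_effects: dict[str, float]
    causal_genes: list[str]
    parts: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def causal_variants(self) -> set[str]:
        return set(self.causal_effects)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "causal_effects": self.causal_effects,
            "causal_genes": self.causal_genes,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class SimulatedStudy:
    genotypes: GenotypeMatrix
    gene_map: GeneMap
    pheno: PhenoTable
    truth: SyntheticTruth
    mafs: np.ndarray


def _draw_gene_sizes(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    p_geom = 1.0 / config.gene_size_mean
    sizes = rng.geometric(p_geom, size=config.n_genes)
    sizes = np.minimum(sizes, config.max_gene_size)
    # causal genes must hold their assigned causal variants
    counts = np.bincount(
        np.asarray(config.causal_gene_assignment, dtype=int),
        minlength=config.n_causal_genes,
    )
    for g, c in enumerate(counts):
        sizes[g] = max(sizes[g], c)
    return sizes


def _ld_block_genotypes(
    n: int, mafs: np.ndarray, r: float, rng: np.random.Generator
) -> np.ndarray:
    """Within-gene LD via a shared latent factor on each of two haplotypes."""
    k = mafs.shape[0]
    thresholds = norm.ppf(mafs)
    g = np.zeros((n, k), dtype=np.int8)
    for _ in range(2):  # two haplotypes per individual
        shared = rng.standard_normal((n, 1))
        noise = rng.standard_normal((n, k))
        z = np.sqrt(r) * shared + np.sqrt(1 - r) * noise
        g += (z < thresholds).astype(np.int8)
    return g


def simulate_genotypes(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[GenotypeMatrix, GeneMap, list[tuple[str, str, float, float]]]:
    """Draw genotypes and the gene map; returns the causal-variant table too.

    Each variant's MAF comes from the rare-skewed Beta spectrum except the
    causal variants, whose MAFs are fixed by the config (the first variants
    of the first causal genes).  Genotypes are binomial(2, MAF) per site, or
    LD-correlated within genes when ``ld_within_gene`` > 0.

    Returns ``(genotypes, gene_map, causal_table)`` where the causal table
    rows are (variant_id, gene_id, effect, maf).
    """
    n = config.n_individuals
    sizes = _draw_gene_sizes(config, rng)
    gene_ids = [f"G{g:04d}" for g in range(config.n_genes)]

    min_maf = 1.0 / (2 * n)
    variant_ids: list[str] = []
    assignment: dict[str, str] = {}
    mafs_list: list[float] = []
    causal_table: list[tuple[str, str, float, float]] = []

    causal_by_gene: dict[int, list[tuple[float, float]]] = {}
    for eff, maf, g in zip(
        config.causal_effects, config.causal_mafs, config.causal_gene_assignment
    ):
        causal_by_gene.setdefault(g, []).append((eff, maf))

    for g, size in enumerate(sizes):
        gid = gene_ids[g]
        causal_here = causal_by_gene.get(g, [])
        for j in range(size):
            vid = f"{gid}_v{j:02d}"
            variant_ids.append(vid)
            assignment[vid] = gid
            if j < len(causal_here):
                eff, maf = causal_here[j]
                mafs_list.append(maf)
                causal_table.append((vid, gid, eff, maf))
            else:
                maf = 0.5 * float(rng.beta(config.maf_beta_a, config.maf_beta_b))
                mafs_list.append(max(min_maf, min(0.5, maf)))

    mafs = np.asarray(mafs_list)
    if config.ld_within_gene > 0:
        blocks = []
        start = 0
        for size in sizes:
            blocks.append(
                _ld_block_genotypes(
                    n, mafs[start : start + size], config.ld_within_gene, rng
                )
            )
            start += size
        values = np.concatenate(blocks, axis=1)
    else:
        values = rng.binomial(2, mafs, size=(n, mafs.shape[0])).astype(np.int8)

    individual_ids = [f"I{i:04d}" for i in range(n)]
    gm = GenotypeMatrix(values, variant_ids, individual_ids)
    gene_map = GeneMap(assignment=assignment)
    return gm, gene_map, causal_table


def simulate_trait(
    genotypes: GenotypeMatrix,
    causal_table: list[tuple[str, str, float, float]],
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[PhenoTable, SyntheticTruth]:
    """Build the quantitative trait from genotypes plus covariates and noise.

    trait = sum_j effect_j * g_j + covariate part + optional interaction
    (smoking x causal-gene minor-allele burden x multiplier) + N(0, noise_sd^2).
    """
    n = genotypes.n_individuals
    col_of = {v: j for j, v in enumerate(genotypes.variant_ids)}
    missing = [v for v, *_ in causal_table if v not in col_of]
    if missing:
        raise ValueError(f"causal variant(s) absent from genotypes: {missing[:5]}")

    genetic = np.zeros(n)
    for vid, _gid, eff, _maf in causal_table:
        genetic += eff * genotypes.values[:, col_of[vid]]

    smoke = rng.binomial(1, config.smoke_prevalence, size=n).astype(float)
    age = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n).astype(
        float
    )
    sex = rng.binomial(1, config.sex_fraction, size=n).astype(float)
    covariate_part = (
        config.smoke_effect * smoke + config.age_effect * age + config.sex_effect * sex
    )

    interaction_part = np.zeros(n)
    if config.interaction_gene is not None and config.interaction_multiplier != 0:
        target = f"G{config.interaction_gene:04d}"
        burden = np.zeros(n)
        for vid, gid, _eff, _maf in causal_table:
            if gid == target:
                burden += genotypes.values[:, col_of[vid]]
        interaction_part = config.interaction_multiplier * smoke * burden

    noise = config.noise_sd * rng.standard_normal(n)
    trait = genetic + covariate_part + interaction_part + noise

    import pandas as pd

    pheno = PhenoTable(
        trait=trait,
        covariates=pd.DataFrame({"Smoke": smoke, "Age": age, "Sex": sex}),
        individual_ids=list(genotypes.individual_ids),
    )
    truth = SyntheticTruth(
        causal_effects={vid: eff for vid, _g, eff, _m in causal_table},
        causal_genes=sorted({gid for _v, gid, _e, _m in causal_table}),
        parts={
            "genetic": genetic,
            "covariate": covariate_part,
            "interaction": interaction_part,
            "noise": noise,
        },
    )
    return pheno, truth


def simulate_replicate(config: SyntheticConfig | None = None, seed: int = 0) -> SimulatedStudy:
    """One complete replicate: genotypes, gene map, phenotypes, truth."""
    if config is None:
        config = default_config()
    rng = np.random.default_rng(seed)
    genotypes, gene_map, causal_table = simulate_genotypes(config, rng)
    pheno, truth = simulate_trait(genotypes, causal_table, config, rng)
    from .io import compute_maf

    return SimulatedStudy(
        genotypes=genotypes,
        gene_map=gene_map,
        pheno=pheno,
        truth=truth,
        mafs=compute_maf(genotypes),
    )
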