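"""Genotype, phenotype and gene-map input/output.

Genotypes are held as minor-allele counts (0/1/2) per individual x variant.
"Minor" is decided per site from the sample allele frequency at load time,
which makes the representation canonical: swapping REF/ALT labels in a VCF
does not change the loaded matrix.  Missing genotypes are a hard error —
no silent imputation.

Text formats are deliberately plain:

* genotype TSV: header row of variant IDs, first column ``individual_id``;
* gene-map TSV: columns ``variant_id``, ``gene_id``;
* phenotype TSV: columns ``individual_id``, ``trait``, then covariates.

Rows are reconciled by ``individual_id``, never by position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "GeneMap",
    "PhenoTable",
    "load_genotypes",
    "load_gene_map",
    "load_phenotypes",
    "write_genotypes_tsv",
    "write_gene_map_tsv",
    "write_phenotypes_tsv",
    "compute_maf",
    "center_columns",
]


@dataclass
class GenotypeMatrix:
    """n_individuals x p_variants matrix of minor-allele counts.

    Attributes
    ----------
    values : ndarray of shape (n_individuals, p_variants), integer
        Entries are in {0, 1, 2}.
    variant_ids : list of str
        Unique variant identifiers, one per column.
    individual_ids : list of str
        Unique individual identifiers, one per row.
    """

    values: np.ndarray
    variant_ids: list[str]
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D matrix")
        n, p = self.values.shape
        if n < 2:
            raise ValueError("need at least 2 individuals")
        if len(self.variant_ids) != p:
            raise ValueError("variant_ids length does not match column count")
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match row count")
        if len(set(self.variant_ids)) != p:
            raise ValueError("variant_ids must be distinct")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual_ids must be distinct")
        vals = self.values
        if not np.isin(vals, (0, 1, 2)).all():
            raise ValueError("genotype entries must all be 0, 1 or 2")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def p_variants(self) -> int:
        return self.values.shape[1]


@dataclass
class GeneMap:
    """Assignment of every variant to exactly one gene."""

    assignment: dict[str, str]
    gene_sizes: dict[str, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        sizes: dict[str, int] = {}
        for gene in self.assignment.values():
            sizes[gene] = sizes.get(gene, 0) + 1
        if self.gene_sizes is None:
            self.gene_sizes = sizes
        elif self.gene_sizes != sizes:
            raise ValueError("gene_sizes inconsistent with assignment")

    @property
    def genes(self) -> list[str]:
        return sorted(self.gene_sizes)

    def variants_of(self, gene_id: str) -> list[str]:
        return [v for v, g in self.assignment.items() if g == gene_id]


@dataclass
class PhenoTable:
    """Quantitative trait plus covariates for the genotyped individuals."""

    trait: np.ndarray
    covariates: pd.DataFrame
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.trait = np.asarray(self.trait, dtype=float)
        n = self.trait.shape[0]
        if len(self.individual_ids) != n or len(self.covariates) != n:
            raise ValueError("trait, covariates and individual_ids lengths differ")
        if np.isnan(self.trait).any():
            raise ValueError("missing values in trait")
        if self.covariates.isna().any().any():
            raise ValueError("missing values in covariates")


# ---------------------------------------------------------------------------
# loaders


def load_genotypes(path: str | Path, format: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix of minor-allele counts from TSV or VCF.

    For VCF input the minor allele is determined per site from the sample
    allele frequency; when the ALT frequency is exactly 0.5 the ALT allele
    counts as minor (deterministic tie rule).  Multiallelic sites and missing
    genotypes raise errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _load_tsv(path)
    if format == "vcf":
        return _load_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _load_tsv(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"malformed genotype TSV {path}: {exc}") from exc
    if df.isna().any().any():
        bad = df.columns[df.isna().any()][0]
        raise ValueError(f"missing genotype in column {bad!r} of {path}")
    try:
        values = df.to_numpy(dtype=np.int64)
    except ValueError as exc:
        raise ValueError(f"non-integer genotype entry in {path}: {exc}") from exc
    return GenotypeMatrix(
        values=values.astype(np.int8),
        variant_ids=[str(c) for c in df.columns],
        individual_ids=[str(i) for i in df.index],
    )


def _load_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    reader = VCF(str(path))
    individual_ids = list(reader.samples)
    n = len(individual_ids)
    columns: list[np.ndarray] = []
    variant_ids: list[str] = []
    for line_no, v in enumerate(reader, start=1):
        if len(v.ALT) != 1:
            raise ValueError(
                f"multiallelic site {v.CHROM}:{v.POS} in {path} "
                "(split or filter upstream)"
            )
        alt_counts = np.zeros(n, dtype=np.int64)
        for i, gt in enumerate(v.genotypes):
            a0, a1 = gt[0], gt[1]
            if a0 < 0 or a1 < 0:
                raise ValueError(
                    f"missing genotype for sample {individual_ids[i]!r} at "
                    f"{v.CHROM}:{v.POS} in {path}"
                )
            alt_counts[i] = (a0 == 1) + (a1 == 1)
        alt_freq = alt_counts.sum() / (2 * n)
        # ALT is minor on ties at 0.5
        minor = alt_counts if alt_freq <= 0.5 else 2 - alt_counts
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        variant_ids.append(vid)
        columns.append(minor.astype(np.int8))
    if not columns:
        raise ValueError(f"no biallelic records in {path}")
    values = np.column_stack(columns)
    return GenotypeMatrix(values, variant_ids, individual_ids)


def load_gene_map(path: str | Path) -> GeneMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("variant_id", "gene_id"):
        if col not in df.columns:
            raise ValueError(f"gene map {path} lacks column {col!r}")
    if df["variant_id"].duplicated().any():
        dup = df.loc[df["variant_id"].duplicated(), "variant_id"].iloc[0]
        raise ValueError(f"variant {dup!r} mapped to more than one gene")
    return GeneMap(assignment=dict(zip(df["variant_id"], df["gene_id"])))


def load_phenotypes(
    path: str | Path,
    individual_ids: Sequence[str],
    covariates: Iterable[str] = ("Smoke", "Age", "Sex"),
) -> PhenoTable:
    """Read trait + covariates and align rows to ``individual_ids``."""
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    if "individual_id" not in df.columns or "trait" not in df.columns:
        raise ValueError(f"phenotype TSV {path} needs individual_id and trait columns")
    df = df.set_index("individual_id")
    missing = set(individual_ids) - set(df.index)
    if missing:
        raise ValueError(f"phenotypes missing for individuals {sorted(missing)[:5]}")
    df = df.loc[list(individual_ids)]
    cov_cols = [c for c in covariates if c]
    absent = [c for c in cov_cols if c not in df.columns]
    if absent:
        raise ValueError(f"covariate column(s) {absent} not in {path}")
    return PhenoTable(
        trait=df["trait"].to_numpy(dtype=float),
        covariates=df[cov_cols].astype(float).reset_index(drop=True),
        individual_ids=list(individual_ids),
    )


# ---------------------------------------------------------------------------
# writers


def write_genotypes_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(g.values, index=g.individual_ids, columns=g.variant_ids)
    df.index.name = "individual_id"
    df.to_csv(path, sep="\t")


def write_gene_map_tsv(gene_map: GeneMap, path: str | Path) -> None:
    df = pd.DataFrame(
        sorted(gene_map.assignment.items()), columns=["variant_id", "gene_id"]
    )
    df.to_csv(path, sep="\t", index=False)


def write_phenotypes_tsv(pheno: PhenoTable, path: str | Path) -> None:
    df = pheno.covariates.copy()
    df.insert(0, "trait", pheno.trait)
    df.insert(0, "individual_id", pheno.individual_ids)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# derived quantities


def compute_maf(g: GenotypeMatrix) -> np.ndarray:
    """Minor-allele frequency per variant: copies / (2 * n_individuals)."""
    n = g.n_individuals
    maf = g.values.sum(axis=0) / (2.0 * n)
    if (maf > 0.5).any():
        warnings.warn(
            "some columns have allele frequency > 0.5; input is not coded "
            "as minor-allele counts",
            stacklevel=2,
        )
    return maf


def center_columns(g: GenotypeMatrix | np.ndarray, selection: Sequence[int]) -> np.ndarray:
    """Mean-centred design columns for the selected variants, in order."""
    selection = list(selection)
    if len(selection) == 0:
        raise ValueError("empty variant selection")
    values = g.values if isinstance(g, GenotypeMatrix) else np.asarray(g)
    cols = values[:, selection].astype(float)
    cols -= cols.mean(axis=0, keepdims=True)
    return cols
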