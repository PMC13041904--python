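"""Pseudo-bulking: per-cell-type donor aggregation, filters, normalization.

Cell types qualify for mapping when enough donors contribute enough cells
(default: >= 40 donors with >= 5 cells each); genes qualify when expressed
in at least 10% of all cells.  Qualifying counts are sum-aggregated to a
gene x donor matrix per cell type, library-normalised per donor
(counts-per-10k, log1p) and then rank inverse-normal transformed per gene
across donors, which makes the downstream linear model's null exact.
Covariates are donor age, genotype PCs (on LD-pruned standardized dosages)
and per-cell-type expression PCs standing in for latent expression factors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse
from scipy.stats import norm, rankdata

from .simdata import CellTable, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class PseudobulkSet:
    """Per-cell-type gene x donor matrices (raw sums and normalized)."""

    raw: dict[str, pd.DataFrame] = field(default_factory=dict)
    normalized: dict[str, pd.DataFrame] = field(default_factory=dict)
    qualifying_donors: dict[str, list[str]] = field(default_factory=dict)
    qualifying_genes: list[str] = field(default_factory=list)

    @property
    def cell_types(self) -> list[str]:
        return list(self.raw)


@dataclass
class CovariateSet:
    """Donor-level covariates: age, genotype PCs, per-cell-type expression PCs."""

    age: pd.Series
    genotype_pcs: pd.DataFrame  # donors x k
    expression_factors: dict[str, pd.DataFrame]  # cell type -> donors x m

    def design(self, cell_type: str, donors: list[str]) -> pd.DataFrame:
        """Column-centered covariate matrix for one cell type's donors."""
        parts = [self.age.loc[donors].rename("age").to_frame()]
        if self.genotype_pcs.shape[1]:
            parts.append(self.genotype_pcs.loc[donors])
        ef = self.expression_factors.get(cell_type)
        if ef is not None and ef.shape[1]:
            parts.append(ef.loc[donors])
        mat = pd.concat(parts, axis=1)
        return mat - mat.mean(axis=0)


def qualify_cell_types(
    cells: CellTable, min_donors: int = 40, min_cells: int = 5
) -> dict[str, list[str]]:
    """Cell types with >= ``min_donors`` donors each contributing >= ``min_cells``.

    Returns a mapping cell type -> sorted qualifying donor list.
    """
    if cells.n_cells == 0:
        raise ValueError("empty CellTable")
    counts = cells.cells.groupby(["cell_type", "donor"], observed=True).size()
    out: dict[str, list[str]] = {}
    for ct, per_donor in counts.groupby(level=0, observed=True):
        donors = sorted(per_donor[per_donor >= min_cells].index.get_level_values(1))
        if len(donors) >= min_donors:
            out[str(ct)] = donors
    return out


def filter_genes(cells: CellTable, min_fraction: float = 0.10) -> list[str]:
    """Genes with a nonzero count in at least ``min_fraction`` of all cells."""
    nnz_per_gene = np.asarray((cells.counts > 0).sum(axis=1)).ravel()
    keep = nnz_per_gene >= min_fraction * cells.n_cells
    genes = list(cells.genes.loc[keep, "gene_id"])
    if not genes:
        warnings.warn("gene expression filter removed every gene", stacklevel=2)
    return genes


def aggregate(
    cells: CellTable,
    qualifying: dict[str, list[str]] | None = None,
    genes: list[str] | None = None,
    min_donors: int = 40,
    min_cells: int = 5,
    min_fraction: float = 0.10,
) -> PseudobulkSet:
    """Sum per-cell counts to gene x donor matrices for qualifying cell types."""
    if qualifying is None:
        qualifying = qualify_cell_types(cells, min_donors, min_cells)
    if genes is None:
        genes = filter_genes(cells, min_fraction)
    gene_idx = cells.genes.set_index("gene_id").index.get_indexer(genes)
    counts = cells.counts.tocsc()

    pb = PseudobulkSet(qualifying_genes=list(genes))
    for ct, donors in qualifying.items():
        mask = (cells.cells["cell_type"] == ct).to_numpy() & cells.cells[
            "donor"
        ].isin(donors).to_numpy()
        cols = np.flatnonzero(mask)
        donor_codes = pd.Categorical(
            cells.cells.loc[mask, "donor"], categories=donors
        ).codes
        # indicator (cells-of-type x donors) matrix; counts @ indicator = sums
        ind = scipy.sparse.csr_matrix(
            (np.ones(len(cols)), (np.arange(len(cols)), donor_codes)),
            shape=(len(cols), len(donors)),
        )
        sums = np.asarray((counts[:, cols] @ ind).todense())[gene_idx, :]
        pb.raw[ct] = pd.DataFrame(sums.astype(int), index=genes, columns=donors)
        pb.qualifying_donors[ct] = list(donors)
    return pb


def _rank_int(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform with offset (r - 0.5) / n."""
    ranks = rankdata(values, method="average")
    return norm.ppf((ranks - 0.5) / len(values))


def pseudobulk_normalize(raw: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """Library-normalise per donor (CP10k, log1p) then per-gene rank-INT.

    Donors with a zero library are dropped with a warning.  The output has,
    per gene, mean ~0 and unit normal marginals; donor rank order within a
    gene is preserved from the library-normalised values.
    """
    libsize = raw.sum(axis=0)
    if (libsize == 0).any():
        bad = list(libsize.index[libsize == 0])
        warnings.warn(f"dropping zero-library donors: {bad}", stacklevel=2)
        raw = raw.loc[:, libsize > 0]
        libsize = libsize[libsize > 0]
    lognorm = np.log1p(raw / libsize.to_numpy()[None, :] * scale)
    out = lognorm.apply(lambda r: _rank_int(r.to_numpy()), axis=1, result_type="expand")
    out.columns = lognorm.columns
    return out


def _pca_scores(mat: np.ndarray, k: int, label: str) -> np.ndarray:
    """Top-k PC scores (rows = samples), columns orthogonal."""
    centered = mat - mat.mean(axis=0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if len(s) else 0
    if k > rank:
        warnings.warn(
            f"requested {k} {label} PCs but rank is {rank}; truncating",
            stacklevel=3,
        )
        k = rank
    return u[:, :k] * s[:k]


def build_covariates(
    pb: PseudobulkSet,
    genotypes: GenotypeMatrix,
    age: pd.Series,
    n_gpcs: int = 3,
    n_factors: int | dict[str, int] = 5,
    ld_prune_kwargs: dict | None = None,
) -> CovariateSet:
    """Genotype PCs on LD-pruned dosages plus per-cell-type expression PCs."""
    from .annotate import ld_prune

    kept = ld_prune(genotypes, **(ld_prune_kwargs or {}))
    keep_idx = genotypes.variants.index[
        genotypes.variants["variant_id"].isin(kept)
    ].to_numpy()
    dos = genotypes.dosages[:, keep_idx]
    sd = dos.std(axis=0)
    dos = (dos - dos.mean(axis=0))[:, sd > 0] / sd[sd > 0]
    gpcs = _pca_scores(dos, n_gpcs, "genotype")
    gpc_df = pd.DataFrame(
        gpcs, index=genotypes.donors, columns=[f"gPC{i+1}" for i in range(gpcs.shape[1])]
    )

    factors: dict[str, pd.DataFrame] = {}
    for ct, norm_mat in pb.normalized.items():
        m = n_factors[ct] if isinstance(n_factors, dict) else n_factors
        scores = (
            _pca_scores(norm_mat.to_numpy().T, m, "expression")
            if m > 0
            else np.empty((norm_mat.shape[1], 0))
        )
        factors[ct] = pd.DataFrame(
            scores,
            index=norm_mat.columns,
            columns=[f"PF{i+1}" for i in range(scores.shape[1])],
        )
    return CovariateSet(age=age, genotype_pcs=gpc_df, expression_factors=factors)


def normalize_all(pb: PseudobulkSet) -> PseudobulkSet:
    """Fill ``pb.normalized`` for every cell type in place (and return it)."""
    for ct, raw in pb.raw.items():
        pb.normalized[ct] = pseudobulk_normalize(raw)
    return pb


def optimize_factor_count(
    pb: PseudobulkSet,
    genotypes: GenotypeMatrix,
    age: pd.Series,
    tss: pd.DataFrame,
    grid: list[int],
    plateau_tol: float = 0.02,
    n_gpcs: int = 3,
    n_perm: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict[str, int]:
    """Pick the expression-factor count per cell type by eGene discovery.

    Runs eGene discovery at each grid value and returns, per cell type, the
    smallest count whose discovery is within ``plateau_tol`` of the grid
    maximum (the plateau rule used for covariate optimization).
    """
    from .ciseqtl import map_cell_type

    if not grid:
        raise ValueError("factor-count grid must be nonempty")
    counts: dict[str, dict[int, int]] = {ct: {} for ct in pb.cell_types}
    for m in grid:
        cov = build_covariates(pb, genotypes, age, n_gpcs=n_gpcs, n_factors=m)
        for ct in pb.cell_types:
            egenes = map_cell_type(
                pb.normalized[ct], genotypes, cov.design(ct, pb.qualifying_donors[ct]),
                tss, n_perm=n_perm, seed=seed,
            )
            counts[ct][m] = int((egenes["q_value"] < alpha).sum())
    chosen = {}
    for ct, by_m in counts.items():
        best = max(by_m.values())
        ok = [m for m in sorted(grid) if by_m[m] >= (1 - plateau_tol) * best]
        chosen[ct] = ok[0]
        logger.info("cell type %s: factor counts %s -> chose %d", ct, by_m, chosen[ct])
    return chosen
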