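"""Synthetic single-cell eQTL cohorts with ground truth.

The generator emulates the data structure the downstream analyses assume: a
cohort of unrelated donors genotyped at variants organised in LD blocks
(Hardy-Weinberg equilibrium within variant, tunable within-block r2), and a
per-cell UMI count matrix in which each gene's counts follow a negative
binomial whose log-mean combines a gene baseline, a cis allelic effect that
may be global, category-shared, cell-type-specific or null, a
pseudotime-dependent (dynamic) allelic effect, a donor random intercept and
a per-cell library size factor.  Every injected effect is recorded in a
:class:`SimTruth` table so parameter-recovery tests can score the pipeline.

The LD model is a latent multivariate normal per haplotype, thresholded at
the allele-frequency quantile; summing two haplotypes yields HWE genotypes
with block-wise correlation close to the latent ``ld_rho``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse
from scipy.stats import norm

from . import io as _io

# (name, category) pool used to label simulated cell types; the trajectory
# branch (AT2 -> Alveolar Transitional -> AT1) comes first so small
# configurations still exercise the dynamic-eQTL machinery.
_CELL_TYPE_POOL = [
    ("AT2", "epithelial"),
    ("Alveolar macrophage", "immune"),
    ("AT1", "epithelial"),
    ("CD4 T", "immune"),
    ("Fibroblast", "stromal"),
    ("Capillary EC", "endothelial"),
    ("Alveolar Transitional", "epithelial"),
    ("NK", "immune"),
    ("Pericyte", "stromal"),
    ("Arterial EC", "endothelial"),
    ("Club", "epithelial"),
    ("CD8 T", "immune"),
    ("Smooth muscle", "stromal"),
    ("Venous EC", "endothelial"),
    ("Ciliated", "epithelial"),
    ("B cell", "immune"),
    ("Basal", "epithelial"),
    ("Monocyte", "immune"),
    ("Lymphatic EC", "endothelial"),
    ("Mesothelial", "stromal"),
]

_TRAJECTORY_CELL_TYPES = ("AT2", "Alveolar Transitional", "AT1")

DEFAULT_EFFECT_GRID = [
    (1.0, "global"),
    (1.0, "category"),
    (1.0, "specific"),
    (0.15, "dynamic"),
    (0.0, "null"),
    (0.0, "null"),
]


def default_cell_types(n: int) -> list[tuple[str, str]]:
    """Return ``n`` (cell type, category) labels from the built-in pool."""
    out = []
    for i in range(n):
        name, cat = _CELL_TYPE_POOL[i % len(_CELL_TYPE_POOL)]
        if i >= len(_CELL_TYPE_POOL):
            name = f"{name} {i // len(_CELL_TYPE_POOL) + 1}"
        out.append((name, cat))
    return out


@dataclass
class SimConfig:
    """Parameters of a synthetic cohort.

    ``cells_per_donor_per_type`` is the (mean, dispersion) of a negative
    binomial for the number of cells each donor contributes to each cell
    type.  ``effect_grid`` is cycled over genes; each entry is
    (log-scale effect size, sharing pattern) with pattern one of
    ``global | category | specific | null | dynamic``.  For ``dynamic`` the
    effect size is the per-quantile interaction slope.
    """

    n_donors: int = 120
    n_variants: int = 200
    n_genes: int = 120
    n_cell_types: int = 3
    cells_per_donor_per_type: tuple[float, float] = (30.0, 3.0)
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.5
    effect_grid: list[tuple[float, str]] = field(
        default_factory=lambda: list(DEFAULT_EFFECT_GRID)
    )
    nb_dispersion: float = 2.0
    donor_sd: float = 0.3
    pseudotime_model: str = "uniform"
    pseudotime_max: float = 30.0
    pt_infinite_frac: float = 0.0
    n_quantiles: int = 6
    variant_spacing: int = 50_000
    chrom: str = "1"
    base_log_mean: float = np.log(0.5)
    base_log_sd: float = 0.5
    size_factor_sd: float = 0.4
    dosage_noise_sd: float = 0.0
    age_range: tuple[float, float] = (40.0, 75.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_donors", "n_variants", "n_genes", "n_cell_types"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must be in [0, 1)")
        if self.n_variants < self.ld_block_size:
            raise ValueError("n_variants must be >= ld_block_size")
        if self.pseudotime_model not in ("uniform", "bimodal"):
            raise ValueError("pseudotime_model must be 'uniform' or 'bimodal'")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")

    def cell_types(self) -> list[tuple[str, str]]:
        return default_cell_types(self.n_cell_types)

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class GenotypeMatrix:
    """Donor x variant dosage matrix with variant metadata."""

    dosages: np.ndarray  # (n_donors, n_variants), alt-allele dosage
    variants: pd.DataFrame  # variant_id, chrom, pos, ref, alt, maf, impq
    donors: list[str]

    @property
    def n_donors(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def subset_variants(self, mask) -> "GenotypeMatrix":
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            variants=self.variants.iloc[idx].reset_index(drop=True),
            donors=self.donors,
        )


@dataclass
class CellTable:
    """Per-cell counts (gene x cell, sparse) plus cell and gene metadata.

    ``cells`` columns: cell_id, donor, cell_type, n_umi, pct_mito,
    pseudotime (NaN outside the trajectory branch, +inf allowed).
    ``genes`` columns: gene_id, chrom, tss, strand.
    """

    counts: scipy.sparse.csr_matrix
    genes: pd.DataFrame
    cells: pd.DataFrame

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


@dataclass
class SimTruth:
    """Injected effects: one row per (gene, variant, cell type)."""

    effects: pd.DataFrame  # gene_id, variant_id, cell_type, true_beta,
    # true_interaction_slope, sharing_pattern

    def for_gene(self, gene_id: str) -> pd.DataFrame:
        return self.effects[self.effects["gene_id"] == gene_id]


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw HWE genotypes in LD blocks via a thresholded latent MVN.

    Each haplotype's latent vector within a block is equicorrelated with
    correlation ``ld_rho``; the allele is 1 where the latent value falls
    below the MAF quantile.  Dosage = sum of the two haplotypes; optional
    Gaussian dosage noise (clipped to [0, 2]) emulates imputation.
    """
    rng = _child_rngs(config.seed, 4)[0]
    n, m = config.n_donors, config.n_variants
    mafs = rng.uniform(*config.maf_range, size=m)
    thresholds = norm.ppf(mafs)

    dosages = np.zeros((n, m))
    sqrt_rho = np.sqrt(config.ld_rho)
    sqrt_1mrho = np.sqrt(1 - config.ld_rho)
    for start in range(0, m, config.ld_block_size):
        stop = min(start + config.ld_block_size, m)
        width = stop - start
        for _hap in range(2):
            shared = rng.standard_normal((n, 1))
            latent = sqrt_rho * shared + sqrt_1mrho * rng.standard_normal((n, width))
            dosages[:, start:stop] += latent < thresholds[start:stop]

    if config.dosage_noise_sd > 0:
        dosages = np.clip(
            dosages + rng.normal(0, config.dosage_noise_sd, size=dosages.shape),
            0.0,
            2.0,
        )

    pos = (np.arange(m) + 1) * config.variant_spacing
    p_emp = dosages.mean(axis=0) / 2.0
    variants = pd.DataFrame(
        dict(
            variant_id=[f"var{j:05d}" for j in range(m)],
            chrom=config.chrom,
            pos=pos,
            ref="A",
            alt="G",
            maf=np.minimum(p_emp, 1 - p_emp),
            maf_true=mafs,
            impq=1.0,
        )
    )
    donors = [f"donor{i:04d}" for i in range(n)]
    return GenotypeMatrix(dosages=dosages, variants=variants, donors=donors)


def _assign_effects(config: SimConfig, rng: np.random.Generator):
    """Cycle the effect grid over genes and resolve per-cell-type betas."""
    cell_types = config.cell_types()
    names = [ct for ct, _ in cell_types]
    cats = {ct: cat for ct, cat in cell_types}
    n_ct = len(names)

    causal_idx = (np.arange(config.n_genes) * config.n_variants) // config.n_genes
    records = []
    beta = np.zeros((config.n_genes, n_ct))
    slope = np.zeros((config.n_genes, n_ct))
    traj = [ct for ct in names if ct in _TRAJECTORY_CELL_TYPES] or names[:1]

    for g in range(config.n_genes):
        size, pattern = config.effect_grid[g % len(config.effect_grid)]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        eff = sign * size
        if pattern == "global":
            beta[g, :] = eff
        elif pattern == "category":
            target_cat = cats[names[rng.integers(n_ct)]]
            for k, ct in enumerate(names):
                if cats[ct] == target_cat:
                    beta[g, k] = eff
        elif pattern == "specific":
            beta[g, rng.integers(n_ct)] = eff
        elif pattern == "dynamic":
            for k, ct in enumerate(names):
                if ct in traj:
                    slope[g, k] = eff
        elif pattern == "null":
            pass
        else:
            raise ValueError(f"unknown sharing pattern {pattern!r}")
        for k, ct in enumerate(names):
            records.append(
                dict(
                    gene_id=f"gene{g:05d}",
                    variant_id=f"var{causal_idx[g]:05d}",
                    cell_type=ct,
                    true_beta=beta[g, k],
                    true_interaction_slope=slope[g, k],
                    sharing_pattern=pattern,
                )
            )
    truth = pd.DataFrame(records)
    return causal_idx, beta, slope, truth


def equal_count_quantiles(values: np.ndarray, q: int) -> np.ndarray:
    """Rank finite values into ``q`` equal-count bins (1..q; 0 = unassigned).

    Ties and order are resolved by stable argsort, so bin sizes differ by at
    most one.  Non-finite values (NaN or +inf) get bin 0.
    """
    values = np.asarray(values, dtype=float)
    out = np.zeros(len(values), dtype=int)
    finite = np.isfinite(values)
    n = int(finite.sum())
    if n == 0:
        return out
    order = np.argsort(values[finite], kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    out[finite] = (ranks * q) // n + 1
    return out


def _draw_pseudotime(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if config.pseudotime_model == "uniform":
        pt = rng.uniform(0, config.pseudotime_max, size=n)
    else:  # bimodal: early and late states along the trajectory
        comp = rng.random(n) < 0.5
        pt = np.where(
            comp,
            rng.normal(0.25 * config.pseudotime_max, 0.1 * config.pseudotime_max, n),
            rng.normal(0.75 * config.pseudotime_max, 0.1 * config.pseudotime_max, n),
        )
        pt = np.clip(pt, 0, config.pseudotime_max)
    if config.pt_infinite_frac > 0:
        pt[rng.random(n) < config.pt_infinite_frac] = np.inf
    return pt


def simulate_cells(
    config: SimConfig, genotypes: GenotypeMatrix
) -> tuple[CellTable, SimTruth]:
    """Draw per-cell NB counts under the injected cis and dynamic effects.

    log-mean for gene g in cell c of donor d:
        base_g + beta[g, ct(c)] * dosage[d, v(g)]
               + slope[g, ct(c)] * cq(c) * dosage[d, v(g)]
               + donor_intercept[g, d] + log(size_factor_c)
    where cq is the pseudotime quantile centered at its mid value, and
    counts ~ NB(mean, dispersion ``nb_dispersion``) via gamma-Poisson.
    """
    if genotypes.n_donors != config.n_donors:
        raise ValueError("genotype donors do not match config.n_donors")
    rngs = _child_rngs(config.seed, 4)
    rng_fx, rng_cells, rng_counts = rngs[1], rngs[2], rngs[3]

    causal_idx, beta, slope, truth = _assign_effects(config, rng_fx)
    cell_types = config.cell_types()
    names = [ct for ct, _ in cell_types]

    # per-donor per-type cell numbers ~ NB(mean, dispersion)
    mean_c, disp_c = config.cells_per_donor_per_type
    lam = rng_cells.gamma(disp_c, mean_c / disp_c, size=(config.n_donors, len(names)))
    n_cells_mat = rng_cells.poisson(lam)

    donor_idx = np.repeat(
        np.tile(np.arange(config.n_donors), len(names)), n_cells_mat.T.ravel()
    )
    ct_idx = np.repeat(np.arange(len(names)), n_cells_mat.sum(axis=0))
    n_cells = len(donor_idx)

    size_factor = rng_cells.lognormal(0.0, config.size_factor_sd, size=n_cells)
    pct_mito = rng_cells.beta(2.0, 48.0, size=n_cells)

    pseudotime = np.full(n_cells, np.nan)
    traj_mask = np.isin(
        np.array(names)[ct_idx], [ct for ct in names if ct in _TRAJECTORY_CELL_TYPES]
    )
    pseudotime[traj_mask] = _draw_pseudotime(config, int(traj_mask.sum()), rng_cells)

    qbin = equal_count_quantiles(pseudotime, config.n_quantiles)
    cq = np.where(qbin > 0, qbin - (config.n_quantiles + 1) / 2.0, 0.0)

    base = rng_fx.normal(config.base_log_mean, config.base_log_sd, size=config.n_genes)
    donor_int = rng_fx.normal(0.0, config.donor_sd, size=(config.n_genes, config.n_donors))

    dos_cell = genotypes.dosages[donor_idx, :]  # (n_cells, n_variants)
    log_sf = np.log(size_factor)
    theta = config.nb_dispersion

    blocks = []
    chunk = max(1, min(config.n_genes, int(4e7 / max(n_cells, 1))))
    for g0 in range(0, config.n_genes, chunk):
        g1 = min(g0 + chunk, config.n_genes)
        gg = np.arange(g0, g1)
        dos = dos_cell[:, causal_idx[gg]].T  # (chunk, n_cells)
        eta = (
            base[gg, None]
            + beta[gg][:, ct_idx] * dos
            + slope[gg][:, ct_idx] * cq[None, :] * dos
            + donor_int[gg][:, donor_idx]
            + log_sf[None, :]
        )
        mu = np.exp(eta)
        lam_g = rng_counts.gamma(theta, mu / theta)
        blocks.append(scipy.sparse.csr_matrix(rng_counts.poisson(lam_g)))
    counts = scipy.sparse.vstack(blocks, format="csr")

    donors = np.array(genotypes.donors)
    cells_df = pd.DataFrame(
        dict(
            cell_id=[f"cell{i:06d}" for i in range(n_cells)],
            donor=donors[donor_idx],
            cell_type=np.array(names)[ct_idx],
            n_umi=np.asarray(counts.sum(axis=0)).ravel().astype(int),
            pct_mito=pct_mito,
            pseudotime=pseudotime,
        )
    )
    tss_offset = 1000
    genes_df = pd.DataFrame(
        dict(
            gene_id=[f"gene{g:05d}" for g in range(config.n_genes)],
            chrom=config.chrom,
            tss=genotypes.variants["pos"].to_numpy()[causal_idx] + tss_offset,
            strand=np.where(np.arange(config.n_genes) % 2 == 0, "+", "-"),
        )
    )
    return CellTable(counts=counts, genes=genes_df, cells=cells_df), SimTruth(truth)


def donor_ages(config: SimConfig) -> pd.Series:
    """Donor ages drawn uniformly from ``age_range`` (deterministic in seed)."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[4])
    ages = rng.uniform(*config.age_range, size=config.n_donors)
    return pd.Series(ages, index=[f"donor{i:04d}" for i in range(config.n_donors)], name="age")


_STATE_LABELS = [
    "TssA", "TssAFlnk", "TxFlnk", "Tx", "TxWk", "EnhG", "Enh", "ZNF/Rpts",
    "Het", "TssBiv", "BivFlnk", "EnhBiv", "ReprPC", "ReprPCWk", "Quies",
]


def synthetic_state_track(
    genotypes: GenotypeMatrix, tile: int = 2000
) -> pd.DataFrame:
    """Tile the synthetic chromosome with cycling chromatin-state labels."""
    end = int(genotypes.variants["pos"].max()) + tile
    starts = np.arange(0, end, tile)
    labels = [_STATE_LABELS[i % len(_STATE_LABELS)] for i in range(len(starts))]
    return pd.DataFrame(
        dict(
            chrom=genotypes.variants["chrom"].iloc[0],
            start=starts,
            end=starts + tile,
            label=labels,
        )
    )


def write_fixture(
    out_dir: str,
    genotypes: GenotypeMatrix,
    cells: CellTable,
    truth: SimTruth,
) -> dict[str, str]:
    """Write the cohort as plain-text files; returns the path map."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "genotypes.vcf"),
        "counts_dir": out_dir,
        "tss": os.path.join(out_dir, "tss.tsv"),
        "states_bed": os.path.join(out_dir, "states.bed"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    _io.write_vcf(paths["vcf"], genotypes)
    _io.write_counts_mtx(out_dir, cells)
    _io.write_tss_table(paths["tss"], cells.genes)
    _io.write_bed(paths["states_bed"], synthetic_state_track(genotypes))
    truth.effects.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def read_fixture(out_dir: str) -> tuple[GenotypeMatrix, CellTable, SimTruth]:
    geno = _io.read_vcf(os.path.join(out_dir, "genotypes.vcf"))
    cells = _io.read_counts_mtx(out_dir)
    truth = SimTruth(
        pd.read_csv(
            os.path.join(out_dir, "truth.tsv"), sep="\t",
            keep_default_na=False, na_values=[""],
        )
    )
    return geno, cells, truth
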