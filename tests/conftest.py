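import numpy as np
import pandas as pd
import pytest
import scipy.sparse

from scqtl import simdata


@pytest.fixture(scope="session")
def small_cohort():
    """80-donor, 2-cell-type cohort with the default effect grid."""
    cfg = simdata.SimConfig(
        n_donors=80,
        n_variants=60,
        n_genes=30,
        n_cell_types=2,
        cells_per_donor_per_type=(20, 3),
        seed=11,
    )
    geno = simdata.simulate_genotypes(cfg)
    cells, truth = simdata.simulate_cells(cfg, geno)
    return cfg, geno, cells, truth


def make_cell_table(spec: list[tuple[str, str, int]], n_genes: int = 5, seed: int = 0):
    """Build a CellTable from (donor, cell_type, n_cells) triplets."""
    rng = np.random.default_rng(seed)
    donors, cts = [], []
    for donor, ct, n in spec:
        donors += [donor] * n
        cts += [ct] * n
    n_cells = len(donors)
    counts = scipy.sparse.csr_matrix(
        rng.poisson(2.0, size=(n_genes, n_cells)).astype(np.int64)
    )
    cells_df = pd.DataFrame(
        dict(
            cell_id=[f"c{i}" for i in range(n_cells)],
            donor=donors,
            cell_type=cts,
            n_umi=np.asarray(counts.sum(axis=0)).ravel(),
            pct_mito=0.05,
            pseudotime=np.nan,
        )
    )
    genes_df = pd.DataFrame(
        dict(
            gene_id=[f"g{i}" for i in range(n_genes)],
            chrom="1",
            tss=np.arange(n_genes) * 1000 + 500,
            strand="+",
        )
    )
    return simdata.CellTable(counts=counts, genes=genes_df, cells=cells_df)
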