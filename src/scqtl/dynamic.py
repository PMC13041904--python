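"""Cell-state-interacting (dynamic) eQTLs along a pseudotime trajectory.

Cells of the trajectory branch are split into Q equal-count pseudotime
quantiles (default 6; cells with infinite pseudotime are removed).  For
each candidate (gene, variant) pair, per-cell UMI counts are fitted with a
negative-binomial mixed-effects model: fixed effects genotype, quantile
(ordinal 1..Q treated as continuous, centered), genotype x quantile
interaction and cell/donor covariates (percent-mito, expression PCs,
genotype PCs, age), a log(nUMI) offset and a donor random intercept.  The
Wald test on the interaction coefficient, BH-corrected across pairs,
flags dynamic eQTLs.  Per-quantile allelic effects refit the model within
each quantile without the interaction, and a weighted linear/quadratic
regression of those effects on the quantile index classifies the
trajectory shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .nbglmm import NbglmmResult, fit_nb_glmm
from .simdata import CellTable, GenotypeMatrix, equal_count_quantiles

logger = logging.getLogger(__name__)


@dataclass
class StateAssignment:
    """Per-cell pseudotime quantile (1..Q; 0 = removed / non-trajectory)."""

    quantile: pd.Series  # indexed by cell_id
    q: int

    def centered(self) -> pd.Series:
        c = self.quantile.astype(float) - (self.q + 1) / 2.0
        c[self.quantile == 0] = np.nan
        return c


def assign_quantiles(
    cells: CellTable,
    trajectory_cell_types: list[str] | None = None,
    q: int = 6,
) -> StateAssignment:
    """Equal-count pseudotime quantiles over the trajectory branch.

    Cells outside the branch, or with non-finite pseudotime, get quantile 0.
    Invariant to monotone transformations of pseudotime (rank-based).
    """
    meta = cells.cells
    mask = np.ones(len(meta), dtype=bool)
    if trajectory_cell_types is not None:
        mask &= meta["cell_type"].isin(trajectory_cell_types).to_numpy()
    pt = np.where(mask, meta["pseudotime"].to_numpy(dtype=float), np.nan)
    n_finite = int(np.isfinite(pt).sum())
    if n_finite < q:
        raise ValueError(f"only {n_finite} finite-pseudotime cells for {q} quantiles")
    bins = equal_count_quantiles(pt, q)
    return StateAssignment(pd.Series(bins, index=meta["cell_id"].to_numpy()), q)


def expression_pcs(
    cells: CellTable, cell_mask: np.ndarray, n_pcs: int = 6, scale: float = 1e4
) -> np.ndarray:
    """Top PCs of library-normalised log1p cell-level expression."""
    sub = cells.counts[:, cell_mask].astype(float)
    lib = np.asarray(sub.sum(axis=0)).ravel()
    lib[lib == 0] = 1.0
    lognorm = np.log1p(sub.multiply(scale / lib).toarray() if scipy.sparse.issparse(sub) else sub / lib * scale)
    centered = lognorm.T - lognorm.mean(axis=1)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    k = min(n_pcs, (s > s[0] * 1e-12).sum())
    return u[:, :k] * s[:k]


def build_cell_design(
    cells: CellTable,
    assignment: StateAssignment,
    age: pd.Series | None = None,
    gpcs: pd.DataFrame | None = None,
    n_exp_pcs: int = 6,
) -> dict:
    """Shared per-cell design pieces for all interaction fits.

    Returns cell mask (quantile > 0), centered quantile, covariate matrix
    (pct_mito, expPCs, gPCs, age), offset log(nUMI) and donor labels.
    """
    meta = cells.cells
    mask = (assignment.quantile.loc[meta["cell_id"]].to_numpy() > 0)
    qc = assignment.centered().loc[meta["cell_id"]].to_numpy()[mask]
    covs = [meta.loc[mask, "pct_mito"].to_numpy()[:, None]]
    names = ["pct_mito"]
    if n_exp_pcs > 0:
        pcs = expression_pcs(cells, mask, n_exp_pcs)
        covs.append(pcs)
        names += [f"expPC{i+1}" for i in range(pcs.shape[1])]
    donors = meta.loc[mask, "donor"].to_numpy()
    if gpcs is not None:
        covs.append(gpcs.loc[donors].to_numpy())
        names += list(gpcs.columns)
    if age is not None:
        covs.append(age.loc[donors].to_numpy()[:, None])
        names += ["age"]
    cov = np.column_stack(covs)
    cov = cov - cov.mean(axis=0)
    n_umi = meta.loc[mask, "n_umi"].to_numpy(dtype=float)
    return dict(
        mask=mask,
        quantile_centered=qc,
        covariates=cov,
        covariate_names=names,
        offset=np.log(np.maximum(n_umi, 1.0)),
        donors=donors,
    )


def fit_interaction(
    y: np.ndarray,
    dosage: np.ndarray,
    design: dict,
    re_mode: str = "aghq",
) -> dict:
    """Wald test of the genotype x quantile interaction for one pair."""
    qc = design["quantile_centered"]
    x = np.column_stack(
        [
            np.ones(len(y)),
            dosage,
            qc,
            dosage * qc,
            design["covariates"],
        ]
    )
    names = ["intercept", "dosage", "quantile", "dosage:quantile"] + design[
        "covariate_names"
    ]
    try:
        res = fit_nb_glmm(
            y, x, design["offset"], design["donors"], names=names, re_mode=re_mode
        )
    except (ValueError, np.linalg.LinAlgError) as err:
        logger.warning("interaction fit failed: %s", err)
        return dict(
            beta_interaction=np.nan, se_interaction=np.nan, p_interaction=np.nan,
            converged=False, result=None,
        )
    b, s, p = res.wald("dosage:quantile")
    if not res.converged or not np.isfinite(s):
        p = np.nan
    return dict(
        beta_interaction=b, se_interaction=s, p_interaction=p,
        converged=res.converged, result=res,
    )


def per_quantile_effects(
    y: np.ndarray,
    dosage: np.ndarray,
    design: dict,
    assignment_values: np.ndarray,
    re_mode: str = "aghq",
    min_cells: int = 50,
) -> pd.DataFrame:
    """Per-quantile allelic effect: the NB model refit within each bin.

    ``assignment_values``: quantile (1..Q) per masked cell.  Bins below
    ``min_cells`` cells, or with no dosage variation (e.g. no alternative
    allele carriers), yield missing estimates.
    """
    q_max = int(assignment_values.max())
    rows = []
    for q in range(1, q_max + 1):
        sel = assignment_values == q
        beta_q, se_q = np.nan, np.nan
        if sel.sum() < min_cells:
            logger.info("quantile %d: %d cells < %d, skipped", q, sel.sum(), min_cells)
        elif np.var(dosage[sel]) < 1e-12:
            logger.info("quantile %d: no dosage variation, skipped", q)
        else:
            cov = design["covariates"][sel]
            keep = cov.std(axis=0) > 1e-12
            x = np.column_stack([np.ones(sel.sum()), dosage[sel], cov[:, keep]])
            try:
                res = fit_nb_glmm(
                    y[sel], x, design["offset"][sel], design["donors"][sel],
                    names=["intercept", "dosage"] + [n for n, k in zip(design["covariate_names"], keep) if k],
                    re_mode=re_mode,
                )
                beta_q, se_q, _ = res.wald("dosage")
            except (ValueError, np.linalg.LinAlgError) as err:
                logger.info("quantile %d fit failed: %s", q, err)
        rows.append(dict(quantile=q, beta_q=beta_q, se_q=se_q, n_cells=int(sel.sum())))
    return pd.DataFrame(rows)


def classify_trend(
    beta_q: np.ndarray, se_q: np.ndarray, alpha: float = 0.05
) -> dict:
    """Weighted linear/quadratic fits of per-quantile effects on quantile.

    Weights 1/se^2.  Classes: 'linear' (only the linear slope significant),
    'quadratic' (only the q^2 coefficient), 'both', or 'none'.
    """
    beta_q = np.asarray(beta_q, dtype=float)
    se_q = np.asarray(se_q, dtype=float)
    qs = np.arange(1, len(beta_q) + 1, dtype=float)
    ok = np.isfinite(beta_q) & np.isfinite(se_q) & (se_q > 0)
    if ok.sum() < 4:
        return dict(trend_class="none", p_linear=np.nan, p_quadratic=np.nan, flagged=True)
    w = 1.0 / se_q[ok] ** 2
    qv, bv = qs[ok], beta_q[ok]
    lin = sm.WLS(bv, sm.add_constant(qv), weights=w).fit()
    p_linear = float(lin.pvalues[1])
    quad_design = np.column_stack([np.ones(ok.sum()), qv, qv**2])
    quad = sm.WLS(bv, quad_design, weights=w).fit()
    p_quadratic = float(quad.pvalues[2])
    is_l, is_q = p_linear < alpha, p_quadratic < alpha
    cls = "both" if (is_l and is_q) else "linear" if is_l else "quadratic" if is_q else "none"
    return dict(trend_class=cls, p_linear=p_linear, p_quadratic=p_quadratic, flagged=False)


def test_interactions(
    pairs: pd.DataFrame,
    cells: CellTable,
    genotypes: GenotypeMatrix,
    assignment: StateAssignment,
    age: pd.Series | None = None,
    gpcs: pd.DataFrame | None = None,
    n_exp_pcs: int = 6,
    re_mode: str = "aghq",
    fdr_alpha: float = 0.05,
    with_quantile_effects: bool = False,
    min_cells_per_quantile: int = 50,
) -> pd.DataFrame:
    """Run the interaction test over a (gene_id, variant_id) pair list.

    Returns one row per pair with interaction statistics, BH FDR, and —
    when ``with_quantile_effects`` — per-quantile effects and trend class.
    """
    design = build_cell_design(cells, assignment, age=age, gpcs=gpcs, n_exp_pcs=n_exp_pcs)
    mask = design["mask"]
    gene_idx = cells.genes.set_index("gene_id")
    var_idx = genotypes.variants.set_index("variant_id")
    donor_pos = {d: i for i, d in enumerate(genotypes.donors)}
    dcodes = np.array([donor_pos[d] for d in design["donors"]])
    qvals = assignment.quantile.loc[cells.cells["cell_id"]].to_numpy()[mask]

    counts = cells.counts.tocsr()
    rows = []
    for rec in pairs.itertuples():
        gi = gene_idx.index.get_loc(rec.gene_id)
        vj = var_idx.index.get_loc(rec.variant_id)
        y = np.asarray(counts[gi, :].todense()).ravel()[mask]
        dos = genotypes.dosages[dcodes, vj]
        fit = fit_interaction(y, dos, design, re_mode=re_mode)
        row = dict(gene_id=rec.gene_id, variant_id=rec.variant_id, **{
            k: fit[k] for k in ("beta_interaction", "se_interaction", "p_interaction", "converged")
        })
        if with_quantile_effects:
            pq = per_quantile_effects(
                y, dos, design, qvals, re_mode=re_mode, min_cells=min_cells_per_quantile
            )
            trend = classify_trend(pq["beta_q"].to_numpy(), pq["se_q"].to_numpy())
            for q, b, s in zip(pq["quantile"], pq["beta_q"], pq["se_q"]):
                row[f"beta_q{q}"] = b
                row[f"se_q{q}"] = s
            row.update(
                trend_class=trend["trend_class"],
                p_linear=trend["p_linear"],
                p_quadratic=trend["p_quadratic"],
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    pvals = out["p_interaction"].to_numpy()
    fdr = np.full(len(out), np.nan)
    ok = np.isfinite(pvals)
    if ok.any():
        fdr[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    out["fdr"] = fdr
    out["is_dynamic"] = out["fdr"] < fdr_alpha
    return out


def regulon_trends(
    activity: pd.DataFrame,
    assignment: StateAssignment,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Linear/quadratic regression of per-cell regulon activity on quantile.

    ``activity``: regulon x cell matrix (columns = cell_ids).  Constant
    activity gives p = 1 and a flag.
    """
    q = assignment.quantile.reindex(activity.columns).to_numpy()
    keep = q > 0
    qv = q[keep].astype(float)
    rows = []
    for regulon, act in activity.iterrows():
        a = act.to_numpy(dtype=float)[keep]
        if np.var(a) < 1e-24:
            rows.append(
                dict(regulon_id=regulon, p_linear=1.0, p_quadratic=1.0,
                     significant=False, flagged=True,
                     **{f"mean_q{int(k)}": float(a[qv == k].mean()) for k in np.unique(qv)})
            )
            continue
        lin = sm.OLS(a, sm.add_constant(qv)).fit()
        quad = sm.OLS(a, np.column_stack([np.ones(len(qv)), qv, qv**2])).fit()
        p_l, p_q = float(lin.pvalues[1]), float(quad.pvalues[2])
        rows.append(
            dict(
                regulon_id=regulon,
                p_linear=p_l,
                p_quadratic=p_q,
                quadratic_coef=float(quad.params[2]),
                significant=(p_l < alpha) or (p_q < alpha),
                flagged=False,
                **{f"mean_q{int(k)}": float(a[qv == k].mean()) for k in np.unique(qv)},
            )
        )
    return pd.DataFrame(rows)


def overlap_summary(gene_lists: dict[str, list[str] | set[str]]) -> pd.DataFrame:
    """Pairwise intersection counts (and gene sets) between named lists."""
    names = list(gene_lists)
    sets = {k: set(v) for k, v in gene_lists.items()}
    rows = []
    for i, a in enumerate(names):
        for b in names[i:]:
            inter = sorted(sets[a] & sets[b])
            rows.append(
                dict(list_a=a, list_b=b, n_a=len(sets[a]), n_b=len(sets[b]),
                     n_overlap=len(inter), overlap=",".join(inter))
            )
    return pd.DataFrame(rows)
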