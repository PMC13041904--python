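"""GWAS integration: ABF colocalization and TWAS.

Colocalization follows the single-causal-variant approximate-Bayes-factor
scheme: per variant and trait, the Wakefield log-ABF is

    lABF = 1/2 log(V / (V + W)) + z^2 W / (2 (V + W)),

with V = se^2 and prior effect variance W ((0.15 sdY)^2 for quantitative
traits, 0.2^2 on the log-odds scale for case-control).  Hypothesis sums
H0..H4 accumulate in log space with priors p1, p2 (one-trait association)
and p12 (shared variant); PP.H4 >= 0.7 flags a colocalized locus.

TWAS trains cis-variant weight models per gene (top-SNP, ridge as a BLUP
surrogate, lasso, elastic net) with k-fold cross-validation, keeps genes
whose expression is cis-predictable (permutation p of the cross-validated
R^2 and the CV correlation test both < 0.05), and tests the weighted GWAS
z-score z = w'z / sqrt(w'Rw) against the in-sample LD matrix R.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from sklearn.linear_model import ElasticNet, Lasso, Ridge
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- harmonize

def harmonize(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Align two summary-stat frames on variant id and allele orientation.

    Frames need columns variant_id, a1 (effect allele), a2, beta, se.
    Swapped alleles in ``b`` flip its beta; mismatched allele pairs drop.
    Returns a merged frame with suffixes _1 / _2.
    """
    merged = a.merge(b, on="variant_id", suffixes=("_1", "_2"))
    same = (merged["a1_1"] == merged["a1_2"]) & (merged["a2_1"] == merged["a2_2"])
    flipped = (merged["a1_1"] == merged["a2_2"]) & (merged["a2_1"] == merged["a1_2"])
    merged.loc[flipped, "beta_2"] *= -1
    merged.loc[flipped, ["a1_2", "a2_2"]] = merged.loc[flipped, ["a2_2", "a1_2"]].to_numpy()
    bad = ~(same | flipped)
    if bad.any():
        logger.info("dropping %d variants with mismatched alleles", int(bad.sum()))
    return merged[~bad].reset_index(drop=True)


def define_loci(
    gwas: pd.DataFrame,
    top_snps: pd.DataFrame,
    eqtl: pd.DataFrame,
    window: int = 100_000,
) -> list[dict]:
    """Per GWAS top SNP, variants within +/- window shared with the eQTL stats.

    ``top_snps`` needs variant_id, chrom, pos.  Loci with no shared variant
    are dropped (logged).  Boundary is inclusive.
    """
    shared_ids = set(gwas["variant_id"]) & set(eqtl["variant_id"])
    loci = []
    for snp in top_snps.itertuples():
        in_win = gwas[
            (gwas["chrom"].astype(str) == str(snp.chrom))
            & (np.abs(gwas["pos"] - snp.pos) <= window)
        ]
        ids = [v for v in in_win["variant_id"] if v in shared_ids]
        if not ids:
            logger.info("locus %s: no shared eQTL variant, dropped", snp.variant_id)
            continue
        loci.append(dict(locus_id=snp.variant_id, variant_ids=ids))
    return loci


# -------------------------------------------------------------------- coloc

def estimate_sdy(se: np.ndarray, maf: np.ndarray, n: float) -> float:
    """coloc's sdY estimator from the identity var(beta) ~ sdY^2/(2 n maf (1-maf))."""
    vbeta = np.asarray(se, dtype=float) ** 2
    oneover = 1.0 / vbeta
    nvx = 2.0 * n * np.asarray(maf) * (1 - np.asarray(maf))
    cf = float((nvx * oneover).sum() / (oneover**2).sum())
    if cf <= 0:
        logger.warning("sdY estimate non-positive; falling back to 1.0")
        return 1.0
    return float(np.sqrt(cf))


def wakefield_labf(beta: np.ndarray, se: np.ndarray, w: float) -> np.ndarray:
    v = np.asarray(se, dtype=float) ** 2
    z2 = (np.asarray(beta, dtype=float) / se) ** 2
    r = w / (v + w)
    return 0.5 * (np.log1p(-r) + z2 * r)


def _prior_w(trait_type: str, sdy: float | None) -> float:
    if trait_type == "cc":
        return 0.2**2
    return (0.15 * (sdy if sdy is not None else 1.0)) ** 2


@dataclass
class ColocResult:
    locus_id: str
    n_variants: int
    pp: dict[str, float]
    top_shared_variant: str | None

    @property
    def pp_h4(self) -> float:
        return self.pp["PP.H4"]


def coloc_abf(
    locus: pd.DataFrame,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    trait1_type: str = "quant",
    trait2_type: str = "quant",
    sdy1: float | None = None,
    sdy2: float | None = None,
    n1: float | None = None,
    n2: float | None = None,
    locus_id: str = "locus",
) -> ColocResult:
    """ABF colocalization on one locus.

    ``locus`` columns: variant_id, beta_1, se_1, beta_2, se_2 and optionally
    maf (used with n1/n2 to estimate sdY for quantitative traits).
    Non-finite rows are dropped.  PP.H4 is invariant to trait order.
    """
    cols = ["beta_1", "se_1", "beta_2", "se_2"]
    finite = np.isfinite(locus[cols].to_numpy(dtype=float)).all(axis=1) & (
        locus["se_1"].to_numpy() > 0
    ) & (locus["se_2"].to_numpy() > 0)
    if (~finite).any():
        logger.info("dropping %d non-finite variants from locus", int((~finite).sum()))
    loc = locus[finite]
    if len(loc) == 0:
        raise ValueError("no usable variants in locus")

    if trait1_type == "quant" and sdy1 is None and n1 is not None and "maf" in loc:
        sdy1 = estimate_sdy(loc["se_1"].to_numpy(), loc["maf"].to_numpy(), n1)
    if trait2_type == "quant" and sdy2 is None and n2 is not None and "maf" in loc:
        sdy2 = estimate_sdy(loc["se_2"].to_numpy(), loc["maf"].to_numpy(), n2)

    l1 = wakefield_labf(loc["beta_1"].to_numpy(), loc["se_1"].to_numpy(), _prior_w(trait1_type, sdy1))
    l2 = wakefield_labf(loc["beta_2"].to_numpy(), loc["se_2"].to_numpy(), _prior_w(trait2_type, sdy2))

    with np.errstate(divide="ignore"):
        lp1, lp2, lp12 = np.log(p1), np.log(p2), np.log(p12)
    s1, s2, s12 = logsumexp(l1), logsumexp(l2), logsumexp(l1 + l2)
    lh = np.empty(5)
    lh[0] = 0.0
    lh[1] = lp1 + s1
    lh[2] = lp2 + s2
    # sum over i != j = (sum_i)(sum_j) - sum_i (i == j), in log space
    both = s1 + s2
    if len(loc) > 1 and both > s12:
        lh[3] = lp1 + lp2 + both + np.log1p(-np.exp(s12 - both))
    else:
        lh[3] = -np.inf
    lh[4] = lp12 + s12
    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    top = loc["variant_id"].to_numpy()[np.argmax(l1 + l2)]
    return ColocResult(
        locus_id=locus_id,
        n_variants=len(loc),
        pp={f"PP.H{i}": float(pp[i]) for i in range(5)},
        top_shared_variant=str(top),
    )


# --------------------------------------------------------------------- twas

@dataclass
class TwasModel:
    gene_id: str
    cell_type: str
    variant_ids: list[str]
    weights: np.ndarray
    model_type: str
    cv_r2: float
    cv_p: float
    heritability_p: float
    retained: bool
    cv_r2_by_model: dict[str, float] = field(default_factory=dict)


def _kfold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    idx = rng.permutation(n)
    return [idx[i::k] for i in range(k)]


_RIDGE_GRID = np.geomspace(1e-2, 1e3, 10)
_LASSO_GRID = np.geomspace(1e-3, 1.0, 10)


def _fit_family(xtr, ytr, family: str):
    """Best in-family estimator by a small internal grid on training R^2."""
    if family == "top-snp":
        r = xtr.T @ ytr / len(ytr)
        j = int(np.argmax(np.abs(r)))
        w = np.zeros(xtr.shape[1])
        denom = float(xtr[:, j] @ xtr[:, j])
        w[j] = float(xtr[:, j] @ ytr) / denom if denom > 0 else 0.0
        return ("top-snp", w)
    models = {
        "ridge": [Ridge(alpha=a) for a in _RIDGE_GRID],
        "lasso": [Lasso(alpha=a, max_iter=5000) for a in _LASSO_GRID],
        "elastic-net": [ElasticNet(alpha=a, l1_ratio=0.5, max_iter=5000) for a in _LASSO_GRID],
    }[family]
    best_w, best_score = None, -np.inf
    for est in models:
        est.fit(xtr, ytr)
        pred = xtr @ est.coef_
        score = -np.sum((ytr - pred) ** 2)
        if score > best_score:
            best_score, best_w = score, est.coef_.copy()
    return (family, best_w)


def _cv_r2(x, y, family, folds) -> tuple[float, np.ndarray]:
    pred = np.zeros(len(y))
    for hold in folds:
        train = np.setdiff1d(np.arange(len(y)), hold)
        _, w = _fit_family(x[train], y[train], family)
        pred[hold] = x[hold] @ w
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1 - float(((y - pred) ** 2).sum()) / ss_tot if ss_tot > 0 else -np.inf
    return r2, pred


def train_weights(
    gene_id: str,
    cis_dosages: np.ndarray,
    phenotype: np.ndarray,
    variant_ids: list[str],
    cell_type: str = "",
    k_folds: int = 5,
    seed: int = 0,
    n_perm_h2: int = 100,
    families: tuple[str, ...] = ("top-snp", "ridge", "lasso", "elastic-net"),
) -> TwasModel | None:
    """Cross-validated cis prediction weights for one gene.

    ``cis_dosages`` are standardized internally; ``phenotype`` should
    already have covariates regressed out.  The family with the best
    cross-validated R^2 wins; the cis-heritability filter is a permutation
    test on that family's cv R^2 (set ``n_perm_h2=0`` to skip).  Returns
    None when no family predicts at all (all cv_r2 <= 0).
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(cis_dosages, dtype=float)
    sd = x.std(axis=0)
    keep = sd > 1e-12
    x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    ids = [v for v, k in zip(variant_ids, keep) if k]
    y = np.asarray(phenotype, dtype=float)
    y = y - y.mean()
    folds = _kfold_indices(len(y), k_folds, rng)

    scores, preds = {}, {}
    for fam in families:
        scores[fam], preds[fam] = _cv_r2(x, y, fam, folds)
    best = max(scores, key=scores.get)
    if scores[best] <= 0:
        logger.info("gene %s: no model with positive cv R^2, dropped", gene_id)
        return None

    r, cv_p = stats.pearsonr(preds[best], y)
    cv_p = cv_p / 2 if r > 0 else 1 - cv_p / 2  # one-sided: prediction helps

    if n_perm_h2 > 0:
        exceed = 0
        for _ in range(n_perm_h2):
            yp = rng.permutation(y)
            r2p, _ = _cv_r2(x, yp, best, folds)
            exceed += r2p >= scores[best]
        h2_p = (1 + exceed) / (1 + n_perm_h2)
    else:
        h2_p = np.nan

    _, w = _fit_family(x, y, best)
    if not np.any(w != 0):
        logger.info("gene %s: all-zero weights, dropped", gene_id)
        return None
    retained = (cv_p < 0.05) and (not np.isfinite(h2_p) or h2_p < 0.05)
    return TwasModel(
        gene_id=gene_id,
        cell_type=cell_type,
        variant_ids=ids,
        weights=w,
        model_type=best,
        cv_r2=scores[best],
        cv_p=float(cv_p),
        heritability_p=float(h2_p),
        retained=bool(retained),
        cv_r2_by_model=scores,
    )


def ld_matrix(dosages: np.ndarray) -> np.ndarray:
    """In-sample variant correlation matrix from reference dosages."""
    x = np.asarray(dosages, dtype=float)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    xs = (x - x.mean(axis=0)) / sd
    return (xs.T @ xs) / x.shape[0]


def twas_associate(
    model: TwasModel,
    gwas_z: pd.Series,
    ld: np.ndarray | pd.DataFrame,
    epsilon: float = 0.01,
) -> dict:
    """Weighted-z TWAS test: z = w'z / sqrt(w' R w) with R PSD-regularized."""
    if isinstance(ld, pd.DataFrame):
        ld = ld.loc[model.variant_ids, model.variant_ids].to_numpy()
    z = gwas_z.loc[model.variant_ids].to_numpy(dtype=float)
    w = model.weights
    r = (1 - epsilon) * np.asarray(ld) + epsilon * np.eye(len(w))
    denom = float(w @ r @ w)
    if denom <= 0:
        logger.warning("gene %s: non-positive w'Rw, result missing", model.gene_id)
        return dict(gene_id=model.gene_id, cell_type=model.cell_type, z=np.nan, p=np.nan)
    zt = float(w @ z) / np.sqrt(denom)
    return dict(
        gene_id=model.gene_id,
        cell_type=model.cell_type,
        z=zt,
        p=float(2 * stats.norm.sf(abs(zt))),
    )


def twas_fdr(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """BH FDR across genes within each cell type."""
    out = results.copy()
    out["fdr"] = np.nan
    for ct, sub in out.groupby("cell_type"):
        ok = sub["p"].notna()
        if ok.any():
            out.loc[sub.index[ok], "fdr"] = multipletests(
                sub.loc[ok, "p"], method="fdr_bh"
            )[1]
    out["significant"] = out["fdr"] < alpha
    return out
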