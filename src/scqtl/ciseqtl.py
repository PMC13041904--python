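"""Per-cell-type cis-eQTL mapping.

Nominal pass: for each gene, every variant within +/- 1 Mb of the TSS is
tested by OLS of the rank-normalised pseudobulk phenotype on alt-allele
dosage with donor covariates.  Implemented via Frisch-Waugh projection
(phenotype and dosages residualized against the covariates once), which
reproduces full-design OLS exactly with df = n_donors - (n_covariates + 2).

Gene-level multiplicity: the phenotype residuals are permuted across donors
and, per permutation, the minimum cis p-value recorded; a Beta distribution
fitted to those minima by maximum likelihood converts the nominal top p
into a gene-level adjusted p (the beta approximation).  Storey q-values
over the adjusted p-values call eGenes at q < 0.05.

A negative-binomial GLM pass on raw pseudobulk counts with a library-size
offset is provided as an alternative mapper for sparse cell types.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .simdata import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class VariantFilter:
    """Inclusion filter: imputation quality, MAF, and the cis window (bp)."""

    min_maf: float = 0.05
    min_impq: float = 0.3
    cis_window: int = 1_000_000

    def apply(self, variants: pd.DataFrame) -> np.ndarray:
        """Boolean mask over the variant table."""
        return (
            (variants["maf"].to_numpy() > self.min_maf)
            & (variants["impq"].to_numpy() > self.min_impq)
        )


def residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residuals of y (columns) after OLS on [1, covariates]."""
    n = y.shape[0]
    design = np.column_stack([np.ones(n), covariates])
    q, _ = np.linalg.qr(design)
    return y - q @ (q.T @ y)


def _check_covariates(n: int, covariates: np.ndarray) -> np.ndarray:
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[0] != n:
        covariates = covariates.T
    design = np.column_stack([np.ones(n), covariates])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate design")
    return covariates


def cis_mask(
    variants: pd.DataFrame, chrom: str, tss: int, window: int
) -> np.ndarray:
    """Variants within +/- window bp of the TSS (inclusive boundary)."""
    return (
        (variants["chrom"].astype(str).to_numpy() == str(chrom))
        & (np.abs(variants["pos"].to_numpy() - tss) <= window)
    )


def nominal_pass(
    pheno: pd.DataFrame,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | np.ndarray,
    tss: pd.DataFrame,
    vfilter: VariantFilter | None = None,
) -> pd.DataFrame:
    """All cis (gene, variant) OLS associations for one cell type.

    ``pheno``: genes x donors normalized matrix; ``tss``: gene_id, chrom,
    tss[, strand].  Returns one row per tested pair with beta, se, t_stat,
    p_nominal, tss_distance and maf.
    """
    vfilter = vfilter or VariantFilter()
    donors = list(pheno.columns)
    didx = [genotypes.donors.index(d) for d in donors]
    dos_all = genotypes.dosages[didx, :]
    n = len(donors)

    cov = _check_covariates(n, np.asarray(covariates, dtype=float))
    k = cov.shape[1]
    df = n - (k + 2)
    if df < 1:
        raise ValueError("need at least 2 more donors than covariates")

    keep = vfilter.apply(genotypes.variants)
    tss_map = tss.set_index("gene_id")

    ydat = residualize(pheno.to_numpy().T, cov)  # donors x genes
    xres = residualize(dos_all, cov)
    xss = (xres**2).sum(axis=0)

    out = []
    variants = genotypes.variants
    pos = variants["pos"].to_numpy()
    for gi, gene in enumerate(pheno.index):
        if gene not in tss_map.index:
            continue
        grow = tss_map.loc[gene]
        mask = keep & cis_mask(variants, grow["chrom"], int(grow["tss"]), vfilter.cis_window)
        vidx = np.flatnonzero(mask)
        if len(vidx) == 0:
            continue
        poly = xss[vidx] > 1e-12
        if not poly.all():
            logger.info(
                "gene %s: skipping %d monomorphic-in-sample variants",
                gene, int((~poly).sum()),
            )
            vidx = vidx[poly]
            if len(vidx) == 0:
                continue
        y = ydat[:, gi]
        yss = float(y @ y)
        xy = xres[:, vidx].T @ y
        beta = xy / xss[vidx]
        rss = np.maximum(yss - beta * xy, 0.0)
        sigma2 = rss / df
        se = np.sqrt(sigma2 / xss[vidx])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, 0.0)
        p = 2 * stats.t.sf(np.abs(t), df)
        out.append(
            pd.DataFrame(
                dict(
                    gene_id=gene,
                    variant_id=variants["variant_id"].to_numpy()[vidx],
                    tss_distance=pos[vidx] - int(grow["tss"]),
                    beta=beta,
                    se=se,
                    t_stat=t,
                    p_nominal=p,
                    maf=variants["maf"].to_numpy()[vidx],
                )
            )
        )
    if not out:
        return pd.DataFrame(
            columns=[
                "gene_id", "variant_id", "tss_distance", "beta", "se",
                "t_stat", "p_nominal", "maf",
            ]
        )
    return pd.concat(out, ignore_index=True)


def fit_beta_ml(x: np.ndarray, tol: float = 1e-8, max_iter: int = 100) -> tuple[float, float]:
    """Maximum-likelihood Beta(a, b) fit via Newton with moment start."""
    x = np.clip(np.asarray(x, dtype=float), 1e-300, 1 - 1e-16)
    m, v = x.mean(), x.var()
    v = max(v, 1e-12)
    common = m * (1 - m) / v - 1
    a = max(m * common, 1e-3)
    b = max((1 - m) * common, 1e-3)
    mlx = np.log(x).mean()
    ml1x = np.log1p(-x).mean()
    theta = np.log([a, b])
    for _ in range(max_iter):
        a, b = np.exp(theta)
        dig_ab = special.digamma(a + b)
        grad = np.array(
            [
                a * (dig_ab - special.digamma(a) + mlx),
                b * (dig_ab - special.digamma(b) + ml1x),
            ]
        )
        tri_ab = special.polygamma(1, a + b)
        h_aa = a**2 * (tri_ab - special.polygamma(1, a)) + grad[0]
        h_bb = b**2 * (tri_ab - special.polygamma(1, b)) + grad[1]
        h_ab = a * b * tri_ab
        hess = np.array([[h_aa, h_ab], [h_ab, h_bb]])
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        step = np.clip(step, -2, 2)
        theta = theta - step
        if np.abs(step).max() < tol:
            break
    a, b = np.exp(theta)
    if not (np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0):
        a = max(m * common, 1e-3)
        b = max((1 - m) * common, 1e-3)
    return float(a), float(b)


def _min_p_over_variants(yperm: np.ndarray, xres: np.ndarray, df: int) -> np.ndarray:
    """Min two-sided p across variants for each permuted phenotype row."""
    xnorm = np.sqrt((xres**2).sum(axis=0))
    ynorm = np.sqrt((yperm**2).sum(axis=1))
    r = (yperm @ xres) / (ynorm[:, None] * xnorm[None, :])
    r2 = np.clip(r**2, 0.0, 1.0 - 1e-14)
    tmax = np.sqrt(df * (r2.max(axis=1) / (1 - r2.max(axis=1))))
    return 2 * stats.t.sf(tmax, df)


def permutation_pass(
    y: np.ndarray,
    cis_dosages: np.ndarray,
    covariates: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "residual",
) -> dict:
    """Gene-level permutation p-value with beta approximation.

    ``mode='residual'`` (default) residualizes the phenotype against the
    covariates once and permutes the residuals; ``mode='refit'``
    re-residualizes the permuted phenotype each time.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations for a stable beta fit")
    n = len(y)
    cov = _check_covariates(n, covariates)
    k = cov.shape[1]
    df = n - (k + 2)
    xres = residualize(np.asarray(cis_dosages, dtype=float), cov)
    keep = (xres**2).sum(axis=0) > 1e-12
    xres = xres[:, keep]
    if xres.shape[1] == 0:
        raise ValueError("no polymorphic cis variants")
    yres = residualize(np.asarray(y, dtype=float)[:, None], cov)[:, 0]

    p_obs = _min_p_over_variants(yres[None, :], xres, df)[0]
    top_j = int(
        np.argmin(
            2 * stats.t.sf(
                np.abs(xres.T @ yres)
                / np.sqrt(
                    (xres**2).sum(axis=0) * (yres @ yres) - (xres.T @ yres) ** 2
                )
                * np.sqrt(df),
                df,
            )
        )
    )

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    if mode == "residual":
        # permuted residuals are re-projected onto the covariate-orthogonal
        # subspace so the permuted statistics share the observed statistic's
        # degrees of freedom (otherwise the mid-tail of the gene-level p is
        # inflated by ~(k+1)/n)
        yperm = residualize(yres[perms].T, cov).T
    elif mode == "refit":
        yperm = residualize(np.asarray(y, dtype=float)[perms].T, cov).T
    else:
        raise ValueError("mode must be 'residual' or 'refit'")
    minima = _min_p_over_variants(yperm, xres, df)

    shape1, shape2 = fit_beta_ml(minima)
    p_beta = float(stats.beta.cdf(p_obs, shape1, shape2))
    p_emp = float((1 + (minima <= p_obs).sum()) / (1 + n_perm))
    return dict(
        p_nominal_top=float(p_obs),
        top_index=top_j,
        beta_shape1=shape1,
        beta_shape2=shape2,
        p_perm_empirical=p_emp,
        p_beta_adjusted=p_beta,
        perm_minima=minima,
    )


def storey_qvalues(p: np.ndarray, lambda_: float = 0.5) -> tuple[np.ndarray, float]:
    """Storey q-values with pi0 estimated at a single lambda."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    if m < 20:
        warnings.warn("fewer than 20 genes: falling back to pi0 = 1 (BH)", stacklevel=2)
        pi0 = 1.0
    else:
        pi0 = min(1.0, float((p > lambda_).mean() / (1 - lambda_)))
        pi0 = max(pi0, 1e-8)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    ranked = pi0 * p[order] * m / (np.arange(m) + 1)
    q[order] = np.minimum.accumulate(ranked[::-1])[::-1]
    return np.clip(q, 0, 1), pi0


def call_egenes(egenes: pd.DataFrame, alpha: float = 0.05, lambda_: float = 0.5) -> pd.DataFrame:
    """Attach Storey q-values over p_beta_adjusted and flag eGenes."""
    out = egenes.copy()
    q, pi0 = storey_qvalues(out["p_beta_adjusted"].to_numpy(), lambda_)
    out["q_value"] = q
    out["is_egene"] = out["q_value"] < alpha
    out.attrs["pi0"] = pi0
    return out


def map_cell_type(
    pheno: pd.DataFrame,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | np.ndarray,
    tss: pd.DataFrame,
    vfilter: VariantFilter | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    mode: str = "residual",
) -> pd.DataFrame:
    """Nominal + permutation pass for every gene; returns the eGene table.

    The top variant per gene is the lowest nominal p, ties broken by larger
    |t| then lexicographically smaller variant_id.
    """
    vfilter = vfilter or VariantFilter()
    nominal = nominal_pass(pheno, genotypes, covariates, tss, vfilter)
    if nominal.empty:
        return pd.DataFrame()
    donors = list(pheno.columns)
    didx = [genotypes.donors.index(d) for d in donors]
    cov = np.asarray(covariates, dtype=float)
    tss_map = tss.set_index("gene_id")
    keep = vfilter.apply(genotypes.variants)

    ss = np.random.SeedSequence(seed)
    rows = []
    genes = nominal["gene_id"].unique()
    child_seeds = ss.generate_state(len(genes)) % (2**31)
    for gene, gseed in zip(genes, child_seeds):
        sub = nominal[nominal["gene_id"] == gene].copy()
        sub["_negabs_t"] = -sub["t_stat"].abs()
        best = sub.sort_values(["p_nominal", "_negabs_t", "variant_id"]).iloc[0]
        grow = tss_map.loc[gene]
        mask = keep & cis_mask(
            genotypes.variants, grow["chrom"], int(grow["tss"]), vfilter.cis_window
        )
        cis_dos = genotypes.dosages[np.ix_(didx, np.flatnonzero(mask))]
        perm = permutation_pass(
            pheno.loc[gene].to_numpy(), cis_dos, cov,
            n_perm=n_perm, seed=int(gseed), mode=mode,
        )
        rows.append(
            dict(
                gene_id=gene,
                top_variant=best["variant_id"],
                beta=best["beta"],
                se=best["se"],
                maf=best["maf"],
                p_nominal_top=perm["p_nominal_top"],
                beta_shape1=perm["beta_shape1"],
                beta_shape2=perm["beta_shape2"],
                p_perm_empirical=perm["p_perm_empirical"],
                p_beta_adjusted=perm["p_beta_adjusted"],
            )
        )
    return call_egenes(pd.DataFrame(rows), alpha=alpha)


def nb_pass(
    raw: pd.DataFrame,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | np.ndarray,
    tss: pd.DataFrame,
    vfilter: VariantFilter | None = None,
) -> pd.DataFrame:
    """NB-GLM cis associations on raw pseudobulk counts.

    Per (gene, variant): negative binomial regression (log link) of donor
    counts on dosage plus covariates with a log-library-size offset;
    dispersion estimated by ML; Wald test on the dosage coefficient.
    Non-converged fits fall back to Poisson and are flagged.
    """
    import statsmodels.api as sm
    from statsmodels.discrete.discrete_model import NegativeBinomial

    vfilter = vfilter or VariantFilter()
    donors = list(raw.columns)
    didx = [genotypes.donors.index(d) for d in donors]
    dos_all = genotypes.dosages[didx, :]
    n = len(donors)
    cov = _check_covariates(n, np.asarray(covariates, dtype=float))
    offset = np.log(raw.sum(axis=0).to_numpy().astype(float))
    keep = vfilter.apply(genotypes.variants)
    tss_map = tss.set_index("gene_id")

    rows = []
    for gene in raw.index:
        if gene not in tss_map.index:
            continue
        y = raw.loc[gene].to_numpy().astype(float)
        if y.sum() == 0:
            logger.info("gene %s: all-zero counts, skipped", gene)
            continue
        grow = tss_map.loc[gene]
        mask = keep & cis_mask(
            genotypes.variants, grow["chrom"], int(grow["tss"]), vfilter.cis_window
        )
        for j in np.flatnonzero(mask):
            x = dos_all[:, j]
            if x.var() < 1e-12:
                logger.info("variant %d monomorphic in sample, skipped", j)
                continue
            design = np.column_stack([np.ones(n), x, cov])
            fallback = False
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = NegativeBinomial(y, design, offset=offset).fit(
                        disp=0, maxiter=200
                    )
                if not res.mle_retvals.get("converged", False) or not np.isfinite(
                    res.bse[1]
                ):
                    raise RuntimeError("NB fit did not converge")
                beta, se = res.params[1], res.bse[1]
            except Exception:
                fallback = True
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.GLM(
                        y, design, family=sm.families.Poisson(), offset=offset
                    ).fit()
                beta, se = res.params[1], res.bse[1]
                logger.info("gene %s variant %d: Poisson fallback", gene, j)
            z = beta / se
            rows.append(
                dict(
                    gene_id=gene,
                    variant_id=genotypes.variants["variant_id"].iloc[j],
                    tss_distance=int(genotypes.variants["pos"].iloc[j]) - int(grow["tss"]),
                    beta=beta,
                    se=se,
                    t_stat=z,
                    p_nominal=2 * stats.norm.sf(abs(z)),
                    maf=genotypes.variants["maf"].iloc[j],
                    poisson_fallback=fallback,
                )
            )
    return pd.DataFrame(rows)
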