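"""Empirical-Bayes harmonization of eQTL effects across cell types.

The model is a self-contained multivariate adaptive-shrinkage
("mash"-style) mixture: the true effect vector b of each (gene, variant)
row across R cell types is given a prior that mixes a point mass at zero
with zero-mean multivariate normals whose covariances are canonical
patterns (identity, per-cell-type singletons, equal-effects) and
data-driven patterns (empirical covariance and top principal components of
the strong-set z-scores), each expanded over a geometric scale grid.
Observed effects are bhat ~ N(b, V) with V = S R_err S built from the
reported standard errors and a residual error correlation estimated from
near-null rows.  Only the mixture weights are estimated (by EM on a random
subset of tested pairs), so the marginal likelihood is monotone in the
iterations.  Posterior summaries per row x cell type are the posterior
mean, sd and the local false sign rate

    lfsr = min{ P(b <= 0 | data), P(b >= 0 | data) },

with the point mass at zero counted on both sides.  Significant cell-type
sets (lfsr < alpha) drive the sharing classification: cell-type-specific
(one cell type), category-shared (>= 2 cell types, one category) or
cross-category-shared (>= 2 categories).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

_EPS = 1e-12


@dataclass
class EffectPanel:
    """(gene, variant) x cell type matrices of effect estimates and SEs."""

    bhat: pd.DataFrame  # rows x cell types
    shat: pd.DataFrame
    conditions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.conditions:
            self.conditions = list(self.bhat.columns)
        if (np.asarray(self.shat, dtype=float) <= 0).any():
            if np.nanmin(np.asarray(self.shat, dtype=float)) <= 0:
                raise ValueError("standard errors must be positive")

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def zscores(self) -> np.ndarray:
        return self.bhat.to_numpy() / self.shat.to_numpy()


@dataclass
class EbModel:
    component_names: list[str]
    covariances: list[np.ndarray]  # prior covariance per component (null = zeros)
    weights: np.ndarray
    resid_corr: np.ndarray
    conditions: list[str]
    loglik_path: list[float] = field(default_factory=list)


@dataclass
class ShrunkenEffectSet:
    posterior_mean: pd.DataFrame
    posterior_sd: pd.DataFrame
    lfsr: pd.DataFrame

    @property
    def conditions(self) -> list[str]:
        return list(self.posterior_mean.columns)


def build_panel(
    egenes: dict[str, pd.DataFrame],
    nominal: dict[str, pd.DataFrame],
    random_size: int = 10_000,
    seed: int = 0,
) -> tuple[EffectPanel, EffectPanel]:
    """Assemble strong (union of per-cell-type top eQTLs) and random panels.

    Rows are "gene_id:variant_id"; entries missing in a cell type are NaN
    in bhat and carry a large finite se so they are effectively
    uninformative there.
    """
    conditions = sorted(egenes)
    strong_rows = set()
    for ct in conditions:
        eg = egenes[ct]
        strong_rows.update(eg["gene_id"] + ":" + eg["top_variant"])
    strong_rows = sorted(strong_rows)

    def lookup(rows):
        bhat = pd.DataFrame(np.nan, index=rows, columns=conditions)
        shat = pd.DataFrame(np.nan, index=rows, columns=conditions)
        for ct in conditions:
            nom = nominal[ct]
            key = nom["gene_id"] + ":" + nom["variant_id"]
            sub = nom.set_index(key).reindex(rows)
            bhat[ct] = sub["beta"].to_numpy()
            shat[ct] = sub["se"].to_numpy()
        return bhat, shat

    b_s, s_s = lookup(strong_rows)
    all_pairs = sorted(
        set().union(
            *(nominal[ct]["gene_id"] + ":" + nominal[ct]["variant_id"] for ct in conditions)
        )
    )
    rng = np.random.default_rng(seed)
    take = min(random_size, len(all_pairs))
    rand_rows = sorted(rng.choice(all_pairs, size=take, replace=False))
    b_r, s_r = lookup(rand_rows)
    return (
        EffectPanel(b_s, s_s, conditions),
        EffectPanel(b_r, s_r, conditions),
    )


def _fill_missing(panel: EffectPanel, se_inflation: float = 1e3):
    """Replace missing entries by bhat=0 with a huge se (uninformative)."""
    bhat = panel.bhat.to_numpy(dtype=float).copy()
    shat = panel.shat.to_numpy(dtype=float).copy()
    miss = ~np.isfinite(bhat) | ~np.isfinite(shat)
    if miss.any():
        big = np.nanmax(shat[np.isfinite(shat)]) * se_inflation
        bhat[miss] = 0.0
        shat[miss] = big
    return bhat, shat


def estimate_resid_corr(panel: EffectPanel, z_thresh: float = 2.0) -> np.ndarray:
    """Error correlation from rows whose |z| < z_thresh in every condition."""
    bhat, shat = _fill_missing(panel)
    z = bhat / shat
    nearnull = (np.abs(z) < z_thresh).all(axis=1)
    if nearnull.sum() < 20 or panel.n_conditions == 1:
        return np.eye(panel.n_conditions)
    corr = np.corrcoef(z[nearnull].T)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    return _nearest_psd(corr)


def _nearest_psd(mat: np.ndarray, min_eig: float = 1e-8) -> np.ndarray:
    vals, vecs = np.linalg.eigh((mat + mat.T) / 2)
    if vals.min() < min_eig:
        warnings.warn("non-PSD covariance component: clipping eigenvalues", stacklevel=2)
        vals = np.clip(vals, min_eig, None)
    return vecs @ np.diag(vals) @ vecs.T


def _normalize_cov(sigma: np.ndarray) -> np.ndarray:
    d = np.max(np.diag(sigma))
    return sigma / d if d > 0 else sigma


def canonical_covariances(r: int) -> list[tuple[str, np.ndarray]]:
    comps = [("identity", np.eye(r))]
    for j in range(r):
        s = np.zeros((r, r))
        s[j, j] = 1.0
        comps.append((f"singleton_{j}", s))
    comps.append(("equal_effects", np.ones((r, r))))
    return comps


def data_driven_covariances(
    strong: EffectPanel, n_pcs: int = 2
) -> list[tuple[str, np.ndarray]]:
    """Empirical covariance and top-PC rank-1 patterns of strong-set z-scores."""
    bhat, shat = _fill_missing(strong)
    z = bhat / shat
    comps = []
    if z.shape[0] >= 2:
        emp = _nearest_psd(np.cov(z.T, bias=True).reshape(strong.n_conditions, -1))
        comps.append(("empirical", _normalize_cov(emp)))
        vals, vecs = np.linalg.eigh(emp)
        order = np.argsort(vals)[::-1]
        for i in range(min(n_pcs, strong.n_conditions)):
            v = vecs[:, order[i]]
            comps.append((f"pc_{i+1}", _normalize_cov(np.outer(v, v))))
    return comps


def scale_grid(panel: EffectPanel, length: int = 20) -> np.ndarray:
    """Geometric grid from 0.1 * min(se) to 2 * max(|bhat|)."""
    bhat, shat = _fill_missing(panel)
    finite = np.isfinite(panel.shat.to_numpy(dtype=float))
    lo = 0.1 * float(np.nanmin(panel.shat.to_numpy(dtype=float)[finite]))
    hi = 2.0 * float(np.max(np.abs(bhat))) if np.max(np.abs(bhat)) > 0 else 1.0
    hi = max(hi, lo * 2)
    return np.geomspace(lo, hi, length)


def _component_logliks(
    bhat: np.ndarray, shat: np.ndarray, covs: list[np.ndarray], resid_corr: np.ndarray
) -> np.ndarray:
    """log N(bhat_i; 0, Sigma_c + V_i) for every row i and component c."""
    n, r = bhat.shape
    out = np.empty((n, len(covs)))
    v = shat[:, :, None] * resid_corr[None, :, :] * shat[:, None, :]
    const = -0.5 * r * np.log(2 * np.pi)
    for c, sigma in enumerate(covs):
        a = v + sigma[None, :, :]
        chol = np.linalg.cholesky(a)
        logdet = 2 * np.log(np.diagonal(chol, axis1=1, axis2=2)).sum(axis=1)
        sol = np.linalg.solve(chol, bhat[:, :, None])[:, :, 0]
        quad = (sol**2).sum(axis=1)
        out[:, c] = const - 0.5 * (logdet + quad)
    return out


def fit_eb_model(
    random_panel: EffectPanel,
    strong_panel: EffectPanel | None = None,
    grid_length: int = 20,
    n_pcs: int = 2,
    null_prior_weight: float = 10.0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> EbModel:
    """Fit mixture weights by EM on the random panel.

    Covariance patterns are canonical plus data-driven from the strong
    panel (if given); each is expanded over the scale grid, with a
    point-mass-at-zero null first.  The marginal log-likelihood is
    monotone non-decreasing over iterations (asserted).
    """
    r = random_panel.n_conditions
    grid = scale_grid(strong_panel or random_panel, grid_length)
    patterns = canonical_covariances(r)
    if strong_panel is not None and r >= 2:
        patterns += data_driven_covariances(strong_panel, n_pcs)

    names = ["null"]
    covs = [np.zeros((r, r))]
    for pname, sigma in patterns:
        sigma = _normalize_cov(sigma)
        for w in grid:
            names.append(f"{pname}@{w:.4g}")
            covs.append(w**2 * sigma)

    resid_corr = estimate_resid_corr(random_panel)
    bhat, shat = _fill_missing(random_panel)
    loglik = _component_logliks(bhat, shat, covs, resid_corr)

    n, n_comp = loglik.shape
    prior = np.ones(n_comp)
    prior[0] = null_prior_weight  # mild bias toward the null, as in mashr
    weights = np.full(n_comp, 1.0 / n_comp)
    weights, path = _em_weights(loglik, prior, weights, max_iter, tol)
    return EbModel(names, covs, weights, resid_corr, list(random_panel.conditions), path)


def _em_objective(loglik, prior, w):
    row_ll = logsumexp(loglik + np.log(w + _EPS)[None, :], axis=1)
    return float(row_ll.sum() + ((prior - 1) * np.log(w + _EPS)).sum())


def _em_step(loglik, prior, w):
    logpost = loglik + np.log(w + _EPS)[None, :]
    gamma = np.exp(logpost - logsumexp(logpost, axis=1)[:, None])
    new = gamma.sum(axis=0) + (prior - 1)
    new = np.maximum(new, 0)
    return new / new.sum()


def _em_weights(loglik, prior, w, max_iter, tol):
    """Penalized-ML mixture weights via SQUAREM-accelerated EM.

    The extrapolated step is only accepted when it does not decrease the
    penalized objective, so the recorded path is monotone non-decreasing.
    """
    path = [_em_objective(loglik, prior, w)]
    for _ in range(max_iter):
        w1 = _em_step(loglik, prior, w)
        w2 = _em_step(loglik, prior, w1)
        r, v = w1 - w, (w2 - w1) - (w1 - w)
        vn = float(v @ v)
        cand = w2
        if vn > 0:
            alpha = -np.sqrt(float(r @ r) / vn)
            accel = w - 2 * alpha * r + alpha**2 * v
            accel = np.maximum(accel, 0)
            s = accel.sum()
            if s > 0:
                accel = _em_step(loglik, prior, accel / s)  # stabilizing EM step
                if _em_objective(loglik, prior, accel) >= _em_objective(
                    loglik, prior, w2
                ):
                    cand = accel
        obj = _em_objective(loglik, prior, cand)
        if obj < path[-1] - 1e-6 * abs(path[-1]):
            raise RuntimeError("EM objective decreased beyond tolerance")
        converged = abs(obj - path[-1]) < tol * (abs(path[-1]) + 1)
        w = cand
        path.append(obj)
        if converged:
            break
    return w, path


def posterior_summaries(model: EbModel, panel: EffectPanel) -> ShrunkenEffectSet:
    """Posterior mean, sd and lfsr per row x cell type under the mixture."""
    bhat, shat = _fill_missing(panel)
    n, r = bhat.shape
    covs = model.covariances
    loglik = _component_logliks(bhat, shat, covs, model.resid_corr)
    logw = loglik + np.log(model.weights + _EPS)[None, :]
    post_w = np.exp(logw - logsumexp(logw, axis=1)[:, None])  # (n, C)

    v = shat[:, :, None] * model.resid_corr[None, :, :] * shat[:, None, :]
    mean_acc = np.zeros((n, r))
    m2_acc = np.zeros((n, r))
    p_neg = np.zeros((n, r))
    p_pos = np.zeros((n, r))
    p_zero = np.zeros((n, r))
    for c, sigma in enumerate(covs):
        wc = post_w[:, c][:, None]
        if not np.any(sigma):
            p_zero += wc
            continue
        a = v + sigma[None, :, :]
        gain = np.linalg.solve(a, np.broadcast_to(sigma, a.shape))  # A^-1 Sigma
        mu = np.einsum("nij,nj->ni", np.transpose(gain, (0, 2, 1)), bhat)
        lam = sigma[None, :, :] - np.einsum("ij,njk->nik", sigma, gain)
        var = np.clip(np.diagonal(lam, axis1=1, axis2=2), 0.0, None)
        sd = np.sqrt(var)
        mean_acc += wc * mu
        m2_acc += wc * (var + mu**2)
        degen = sd < _EPS
        with np.errstate(divide="ignore", invalid="ignore"):
            cdf0 = norm.cdf(-mu / np.where(degen, 1.0, sd))
        p_neg += wc * np.where(degen & (mu < _EPS), 0.0, np.where(degen, (mu < 0).astype(float), cdf0))
        p_pos += wc * np.where(degen & (np.abs(mu) < _EPS), 0.0, np.where(degen, (mu > 0).astype(float), 1 - cdf0))
        p_zero += wc * (degen & (np.abs(mu) < _EPS)).astype(float)

    sd_out = np.sqrt(np.clip(m2_acc - mean_acc**2, 0.0, None))
    lfsr = np.minimum(p_neg + p_zero, p_pos + p_zero)
    idx, cols = panel.bhat.index, panel.bhat.columns
    return ShrunkenEffectSet(
        posterior_mean=pd.DataFrame(mean_acc, index=idx, columns=cols),
        posterior_sd=pd.DataFrame(sd_out, index=idx, columns=cols),
        lfsr=pd.DataFrame(np.clip(lfsr, 0, 1), index=idx, columns=cols),
    )


SHARING_CATEGORIES = ("endothelial", "epithelial", "immune", "stromal")


def classify_sharing(
    effects: ShrunkenEffectSet,
    categories: dict[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify each row by its significant (lfsr < alpha) cell-type set.

    cell-type-specific: one significant cell type; category-shared: >= 2,
    all in one category; cross-category-shared: >= 2 categories;
    non-significant otherwise.
    """
    for ct in effects.conditions:
        if ct not in categories:
            raise ValueError(f"cell type {ct!r} has no category mapping")
    sig = effects.lfsr < alpha
    rows = []
    for row in sig.index:
        hits = [ct for ct in effects.conditions if sig.loc[row, ct]]
        cats = {categories[ct] for ct in hits}
        if not hits:
            cls = "non-significant"
        elif len(hits) == 1:
            cls = "cell-type-specific"
        elif len(cats) == 1:
            cls = "category-shared"
        else:
            cls = "cross-category-shared"
        rows.append(dict(row=row, category=cls, significant_cell_types=",".join(hits)))
    return pd.DataFrame(rows).set_index("row")


def pairwise_sharing(
    effects: ShrunkenEffectSet,
    alpha: float = 0.05,
    fold: tuple[float, float] = (0.5, 2.0),
) -> pd.DataFrame:
    """Fraction of jointly significant rows shared in sign and magnitude.

    A row counts as shared between cell types A and B when both are
    significant (lfsr < alpha), the posterior means agree in sign, and the
    ratio mean_B / mean_A lies within ``fold`` (boundaries inclusive).  A
    zero posterior mean in either cell type fails the rule.  Pairs with no
    jointly significant rows are NaN; the diagonal is 1.
    """
    cts = effects.conditions
    sig = (effects.lfsr < alpha).to_numpy()
    means = effects.posterior_mean.to_numpy()
    out = pd.DataFrame(np.eye(len(cts)), index=cts, columns=cts)
    for i in range(len(cts)):
        for j in range(len(cts)):
            if i == j:
                continue
            both = sig[:, i] & sig[:, j]
            if not both.any():
                out.iloc[i, j] = np.nan
                continue
            a, b = means[both, i], means[both, j]
            nonzero = (a != 0) & (b != 0)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(nonzero, b / a, np.nan)
            shared = nonzero & (np.sign(a) == np.sign(b)) & (ratio >= fold[0]) & (ratio <= fold[1])
            out.iloc[i, j] = shared.sum() / both.sum()
    return out
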