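"""Functional annotation of eQTL SNPs.

LD pruning mirrors plink's ``--indep-pairwise 250 50 0.9`` sliding-window
scheme (within a 250-variant window advanced by 50, one member of each pair
with r2 above threshold is dropped — here the lower-MAF member, ties broken
toward the later position).  Pruned eQTL SNPs are tested for enrichment or
depletion against per-label annotation intervals (two-sided Fisher exact,
BH FDR across labels) with the pruned non-eQTL SNPs as background.
TSS-distance and ATAC-peak-group comparisons contrast cell-type-specific
with shared eQTL SNPs.

Interval queries use 0-based half-open BED semantics: a SNP at 1-based
position p overlaps [start, end) iff start <= p - 1 < end.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simdata import GenotypeMatrix


def ld_prune(
    genotypes: GenotypeMatrix,
    window: int = 250,
    step: int = 50,
    r2_threshold: float = 0.9,
) -> list[str]:
    """Greedy pairwise LD pruning; returns kept variant IDs in position order.

    Output depends only on variant order, dosages and MAFs (donor order is
    immaterial since r2 is a correlation across donors).
    """
    dos = genotypes.dosages
    m = dos.shape[1]
    maf = genotypes.variants["maf"].to_numpy()
    removed = np.zeros(m, dtype=bool)
    removed[dos.std(axis=0) < 1e-12] = True  # monomorphic: uninformative

    centered = dos - dos.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    norms[norms == 0] = 1.0
    unit = centered / norms

    start = 0
    while True:
        stop = min(start + window, m)
        idx = [j for j in range(start, stop) if not removed[j]]
        if len(idx) > 1:
            sub = unit[:, idx]
            r2 = (sub.T @ sub) ** 2
            for a in range(len(idx)):
                i = idx[a]
                if removed[i]:
                    continue
                for b in range(a + 1, len(idx)):
                    j = idx[b]
                    if removed[j]:
                        continue
                    if r2[a, b] > r2_threshold:
                        if maf[i] < maf[j]:
                            removed[i] = True
                            break
                        removed[j] = True  # lower MAF or tie -> later position
        if stop >= m:
            break
        start += step
    return list(genotypes.variants["variant_id"].to_numpy()[~removed])


def _label_trees(track: pd.DataFrame) -> dict[str, dict[str, IntervalTree]]:
    trees: dict[str, dict[str, IntervalTree]] = {}
    for (label, chrom), sub in track.groupby(["label", "chrom"]):
        trees.setdefault(str(label), {})[str(chrom)] = IntervalTree.from_tuples(
            zip(sub["start"], sub["end"])
        )
    return trees


def snp_in_label(
    snps: pd.DataFrame, trees: dict[str, dict[str, IntervalTree]], label: str
) -> np.ndarray:
    """Boolean: 1-based SNP position falls in a [start, end) interval of label."""
    per_chrom = trees.get(label, {})
    out = np.zeros(len(snps), dtype=bool)
    for i, (chrom, pos) in enumerate(zip(snps["chrom"].astype(str), snps["pos"])):
        tree = per_chrom.get(chrom)
        if tree is not None and tree.overlaps_point(int(pos) - 1):
            out[i] = True
    return out


def enrichment_test(
    eqtl_snps: pd.DataFrame,
    background_snps: pd.DataFrame,
    track: pd.DataFrame,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-label two-sided Fisher exact test of eQTL vs background SNPs.

    SNP frames need ``chrom`` and ``pos`` (1-based) columns.  Odds ratio is
    the unconditional (ad)/(bc) with 0 or inf allowed for zero cells.
    """
    if background_snps.empty:
        raise ValueError("background SNP set is empty")
    trees = _label_trees(track)
    rows = []
    for label in sorted(trees):
        in_e = snp_in_label(eqtl_snps, trees, label)
        in_b = snp_in_label(background_snps, trees, label)
        a, b = int(in_e.sum()), int((~in_e).sum())
        c, d = int(in_b.sum()), int((~in_b).sum())
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        with np.errstate(divide="ignore", invalid="ignore"):
            oratio = (a * d) / (b * c) if b * c > 0 else (np.inf if a * d > 0 else np.nan)
        rows.append(dict(label=label, a=a, b=b, c=c, d=d, odds_ratio=oratio, p=p))
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["fdr"] < fdr_alpha
    return out


def signed_tss_distance(
    snps: pd.DataFrame, tss: pd.DataFrame
) -> pd.Series:
    """Strand-aware signed SNP-TSS distance (positive = downstream of TSS).

    ``snps`` needs ``pos`` and ``gene_id``; SNPs whose gene lacks a TSS are
    dropped.
    """
    tmap = tss.set_index("gene_id")
    keep = snps["gene_id"].isin(tmap.index)
    if (~keep).any():
        warnings.warn(
            f"dropping {int((~keep).sum())} SNPs with no TSS for their gene",
            stacklevel=2,
        )
    sub = snps[keep]
    t = tmap.loc[sub["gene_id"], "tss"].to_numpy()
    strand = (
        tmap.loc[sub["gene_id"], "strand"].to_numpy()
        if "strand" in tmap.columns
        else np.full(len(sub), "+")
    )
    raw = sub["pos"].to_numpy() - t
    return pd.Series(np.where(strand == "-", -raw, raw), index=sub.index)


def tss_distance_compare(
    specific_snps: pd.DataFrame,
    shared_snps: pd.DataFrame,
    tss: pd.DataFrame,
) -> dict:
    """Compare |TSS distance| of shared vs specific eQTL SNPs.

    One-sided Mann-Whitney U with alternative: shared SNPs sit closer to
    the TSS than cell-type-specific ones.
    """
    d_spec = signed_tss_distance(specific_snps, tss).abs()
    d_shared = signed_tss_distance(shared_snps, tss).abs()
    u, p = stats.mannwhitneyu(d_shared, d_spec, alternative="less")
    return dict(
        median_specific=float(d_spec.median()),
        median_shared=float(d_shared.median()),
        u_stat=float(u),
        p=float(p),
        distances_specific=d_spec.to_numpy(),
        distances_shared=d_shared.to_numpy(),
    )


PEAK_GROUP_PRECEDENCE = ("cell-type-specific", "multi-category", "other")


def assign_peak_group(
    snps: pd.DataFrame,
    peaks: pd.DataFrame,
    precedence: tuple[str, ...] = PEAK_GROUP_PRECEDENCE,
) -> pd.Series:
    """Assign each SNP to at most one peak group by precedence (else NaN)."""
    trees = _label_trees(peaks)
    out = pd.Series(np.nan, index=snps.index, dtype=object)
    for label in reversed(precedence):
        hit = snp_in_label(snps, trees, label)
        out[hit] = label
    return out


def atac_overlap_test(
    specific_snps: pd.DataFrame,
    shared_snps: pd.DataFrame,
    peaks: pd.DataFrame,
    precedence: tuple[str, ...] = PEAK_GROUP_PRECEDENCE,
) -> dict:
    """eQTL class x peak group contingency with a Pearson chi-square test.

    SNPs overlapping no peak are excluded; SNPs overlapping several groups
    go to the highest-precedence group.
    """
    table = pd.DataFrame(
        0, index=["specific", "shared"], columns=list(precedence)
    )
    for cls, snps in (("specific", specific_snps), ("shared", shared_snps)):
        groups = assign_peak_group(snps, peaks, precedence)
        for label in precedence:
            table.loc[cls, label] = int((groups == label).sum())
    nonzero = table.columns[table.sum(axis=0) > 0]
    if len(nonzero) < len(table.columns):
        warnings.warn("dropping peak groups with no overlapping SNPs", stacklevel=2)
    chi2, p, dof, expected = stats.chi2_contingency(
        table[nonzero].to_numpy(), correction=False
    )
    if (expected < 1).any():
        warnings.warn("expected cell count < 1: chi-square unreliable", stacklevel=2)
    props = table.div(table.sum(axis=1), axis=0)
    return dict(table=table, chi2=float(chi2), p=float(p), dof=int(dof), proportions=props)
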