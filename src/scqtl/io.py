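"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats: VCF v4.2 with GT and DS fields (genotypes), MatrixMarket MTX with
features/cells TSVs (counts), a TSS table TSV, BED4 annotation tracks
(0-based half-open) and a ground-truth TSV.  All writers emit uncompressed
text so fixtures stay inspectable and diffable.
"""

from __future__ import annotations

import os
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

if TYPE_CHECKING:  # pragma: no cover
    from .simdata import CellTable, GenotypeMatrix

VCF_HEADER = """\
##fileformat=VCFv4.2
##source=scqtl
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of the ALT allele">
##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality">
"""


def _format_dosage(d: float) -> str:
    if d == round(d):
        return str(int(round(d)))
    return repr(float(d))


def _gt_from_dosage(d: float) -> str:
    g = int(round(d))
    return {0: "0/0", 1: "0/1", 2: "1/1"}[min(max(g, 0), 2)]


def write_vcf(path: str, geno: "GenotypeMatrix") -> None:
    """Write a donor x variant dosage matrix as a VCF with GT and DS fields."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        contigs = geno.variants["chrom"].unique()
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.donors)
            + "\n"
        )
        for j, row in enumerate(geno.variants.itertuples()):
            info = f"R2={row.impq:g}"
            fields = [
                str(row.chrom),
                str(int(row.pos)),
                row.variant_id,
                row.ref,
                row.alt,
                ".",
                "PASS",
                info,
                "GT:DS",
            ]
            ds = geno.dosages[:, j]
            fields.extend(
                f"{_gt_from_dosage(d)}:{_format_dosage(d)}" for d in ds
            )
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str):
    """Read a VCF with DS (preferred) or GT fields into a GenotypeMatrix."""
    from cyvcf2 import VCF

    from .simdata import GenotypeMatrix

    vcf = VCF(path)
    donors = list(vcf.samples)
    rows = []
    dosage_cols = []
    for var in vcf:
        try:
            ds = np.asarray(var.format("DS"), dtype=float).ravel()
        except (KeyError, TypeError, ValueError):
            gt = np.asarray(var.gt_types, dtype=float)
            gt[gt == 2] = np.nan  # cyvcf2 codes UNKNOWN as 2
            gt[gt == 3] = 2.0
            ds = gt
        impq = var.INFO.get("R2", 1.0)
        rows.append(
            dict(
                variant_id=var.ID or f"{var.CHROM}:{var.POS}",
                chrom=var.CHROM,
                pos=var.POS,
                ref=var.REF,
                alt=var.ALT[0] if var.ALT else ".",
                impq=float(impq),
            )
        )
        dosage_cols.append(ds)
    variants = pd.DataFrame(rows)
    dosages = np.column_stack(dosage_cols) if dosage_cols else np.empty((len(donors), 0))
    variants["maf"] = np.minimum(dosages.mean(axis=0) / 2.0, 1 - dosages.mean(axis=0) / 2.0)
    return GenotypeMatrix(dosages=dosages, variants=variants, donors=donors)


def write_counts_mtx(prefix_dir: str, cells: "CellTable") -> None:
    """Write counts as MTX plus features.tsv / cells.tsv metadata."""
    mat = scipy.sparse.coo_matrix(cells.counts)
    scipy.io.mmwrite(os.path.join(prefix_dir, "counts.mtx"), mat, field="integer")
    cells.genes.to_csv(os.path.join(prefix_dir, "features.tsv"), sep="\t", index=False)
    cells.cells.to_csv(os.path.join(prefix_dir, "cells.tsv"), sep="\t", index=False)


def read_counts_mtx(prefix_dir: str):
    from .simdata import CellTable

    counts = scipy.sparse.csr_matrix(
        scipy.io.mmread(os.path.join(prefix_dir, "counts.mtx"))
    )
    genes = pd.read_csv(os.path.join(prefix_dir, "features.tsv"), sep="\t")
    cellmeta = pd.read_csv(os.path.join(prefix_dir, "cells.tsv"), sep="\t")
    return CellTable(counts=counts, genes=genes, cells=cellmeta)


def write_tss_table(path: str, genes: pd.DataFrame) -> None:
    genes[["gene_id", "chrom", "tss", "strand"]].to_csv(path, sep="\t", index=False)


def read_tss_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(path: str, intervals: pd.DataFrame) -> None:
    """BED4: chrom, start, end, label; 0-based half-open, no header."""
    intervals[["chrom", "start", "end", "label"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_bed(path: str) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "label"]
    )
    if (bed["start"] >= bed["end"]).any():
        raise ValueError("BED intervals must satisfy start < end")
    return bed
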