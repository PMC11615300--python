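"""Readers and writers for the standard formats touched by the pipeline.

Cytosine reports follow the Bismark per-cytosine layout
(chrom, pos, strand, meth_count, unmeth_count, context[, trinucleotide]);
genotypes come from VCF; genes from GFF3; TEs from BED (0-based half-open,
converted to 1-based closed on read). All tabular outputs are plain TSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    CONTEXTS,
    EpiGenotypeMatrix,
    ExpressionMatrix,
    FeatureSet,
    GenotypeMatrix,
    MethylationCountMatrix,
)

CYTOSINE_REPORT_COLUMNS = ["chrom", "pos", "strand", "meth_count", "unmeth_count", "context"]


class ParseError(ValueError):
    """Malformed input with file/line context."""


def read_cytosine_report(path: str | Path) -> pd.DataFrame:
    """Read one per-cytosine report into a validated DataFrame."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except Exception as exc:  # pandas raises several flavours
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] not in (6, 7):  # optional trailing trinucleotide column
        raise ParseError(f"{path}: expected 6 or 7 columns, found {df.shape[1]}")
    df = df.iloc[:, :6].copy()
    df.columns = CYTOSINE_REPORT_COLUMNS
    for col in ("pos", "meth_count", "unmeth_count"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != vals.round())
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ParseError(f"{path}, line {line}: bad {col} value {df[col].iloc[line - 1]!r}")
        df[col] = vals.astype(np.int64)
    bad_ctx = ~df["context"].isin(CONTEXTS)
    if bad_ctx.any():
        line = int(bad_ctx.idxmax()) + 1
        raise ParseError(f"{path}, line {line}: unknown context {df['context'].iloc[line - 1]!r}")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        line = int(bad_strand.idxmax()) + 1
        raise ParseError(f"{path}, line {line}: bad strand")
    dup = df.duplicated(subset=["chrom", "pos", "strand"])
    if dup.any():
        line = int(dup.idxmax()) + 1
        raise ParseError(f"{path}, line {line}: duplicate (chrom, pos, strand)")
    return df


def read_cytosine_reports(
    paths: Sequence[str | Path], accession_ids: Sequence[str]
) -> MethylationCountMatrix:
    """Assemble per-accession cytosine reports into one count matrix.

    The site index is the union across accessions; a site absent from an
    accession's file is recorded as missing (total_count = 0).
    """
    if len(paths) != len(accession_ids):
        raise ValueError("paths and accession_ids must have equal length")
    if len(set(accession_ids)) != len(accession_ids):
        raise ValueError("accession ids must be unique")
    tables = {acc: read_cytosine_report(p) for acc, p in zip(accession_ids, paths)}

    key_cols = ["chrom", "pos", "strand", "context"]
    sites = (
        pd.concat([t[key_cols] for t in tables.values()], ignore_index=True)
        .drop_duplicates()
        .sort_values(["chrom", "pos", "strand"], kind="mergesort")
        .reset_index(drop=True)
    )
    site_key = pd.MultiIndex.from_frame(sites[["chrom", "pos", "strand"]])
    n_sites, n_acc = len(sites), len(accession_ids)
    meth = np.zeros((n_sites, n_acc), dtype=np.int64)
    total = np.zeros((n_sites, n_acc), dtype=np.int64)
    for j, acc in enumerate(accession_ids):
        t = tables[acc]
        idx = site_key.get_indexer(pd.MultiIndex.from_frame(t[["chrom", "pos", "strand"]]))
        meth[idx, j] = t["meth_count"].to_numpy()
        total[idx, j] = (t["meth_count"] + t["unmeth_count"]).to_numpy()
    return MethylationCountMatrix(sites, meth, total, list(accession_ids))


def write_cytosine_report(counts: MethylationCountMatrix, accession: str, path: str | Path) -> None:
    """Write one accession's covered sites back out in report layout."""
    j = counts.accessions.index(accession)
    covered = counts.total[:, j] > 0
    df = counts.sites.loc[covered, ["chrom", "pos", "strand"]].copy()
    df["meth_count"] = counts.meth[covered, j]
    df["unmeth_count"] = counts.total[covered, j] - counts.meth[covered, j]
    df["context"] = counts.sites.loc[covered, "context"].to_numpy()
    df.to_csv(path, sep="\t", header=False, index=False)


def read_vcf_genotypes(
    path: str | Path, min_maf: float = 0.05, max_missing: float = 0.20
) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF as additive alt-allele dosages.

    Multi-allelic records are skipped (counted); SNPs failing
    MAF >= min_maf or missing fraction > max_missing are dropped.
    Half-missing genotypes (./1) are treated as missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no samples")
    rows, dosages = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1 or var.REF is None:
            n_multi += 1
            continue
        gts = var.genotypes  # [allele1, allele2, phased]
        d = np.empty(len(samples))
        for i, g in enumerate(gts):
            a, b = g[0], g[1]
            d[i] = np.nan if (a < 0 or b < 0) else float(a + b)
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        dosages.append(d)
    vcf.close()
    snps = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    dosage = np.asarray(dosages, dtype=float).reshape(len(rows), len(samples))
    gm = GenotypeMatrix(snps, dosage, samples)
    keep = (gm.maf() >= min_maf) & (gm.missing_fraction() <= max_missing)
    gm = gm.subset_snps(np.asarray(keep))
    gm.n_multiallelic_skipped = n_multi
    return gm


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as an unphased diploid VCF (plumbing for round-trips)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.accessions) + "\n")
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for i, row in genotypes.snps.iterrows():
            calls = [
                "./." if not np.isfinite(d) else gt_map[float(d)]
                for d in genotypes.dosage[i]
            ]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\tsnp{i}\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_gff_genes(path: str | Path) -> pd.DataFrame:
    """Extract gene records (chrom, start, end, strand, gene_id) from GFF3."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "source", "type", "start", "end", "score", "strand", "frame", "attributes"],
        dtype={"chrom": str, "strand": str},
    )
    genes = df[df["type"] == "gene"].copy()
    if (~genes["strand"].isin(["+", "-"])).any():
        bad = genes.loc[~genes["strand"].isin(["+", "-"])].iloc[0]
        raise ValueError(f"gene without strand at {bad['chrom']}:{bad['start']}")
    ids = genes["attributes"].str.extract(r"ID=([^;]+)")[0]
    genes["gene_id"] = ids.fillna(
        genes["chrom"].astype(str) + ":" + genes["start"].astype(str)
    )
    return genes[["chrom", "start", "end", "strand", "gene_id"]].reset_index(drop=True)


def read_te_bed(path: str | Path) -> pd.DataFrame:
    """Read a TE BED (0-based half-open) into 1-based closed intervals."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    te = df.iloc[:, :3].copy()
    te.columns = ["chrom", "start", "end"]
    te["chrom"] = te["chrom"].astype(str)
    te["start"] = te["start"].astype(np.int64) + 1  # 0-based -> 1-based
    te["end"] = te["end"].astype(np.int64)
    te["te_id"] = (
        df.iloc[:, 3].astype(str)
        if df.shape[1] > 3
        else "TE_" + te.index.astype(str)
    )
    return te


def build_feature_set(
    gff_path: str | Path,
    te_bed_path: str | Path | None = None,
    promoter_bp: int = 2000,
    downstream_bp: int = 2000,
) -> FeatureSet:
    """Gene bodies, promoters (upstream of TSS), downstream (poly-A) regions,
    and TEs, as a point-queryable feature set.

    For a + strand gene [s, e] the promoter is [s - promoter_bp, s - 1] and
    the downstream region [e + 1, e + downstream_bp]; mirrored on - strand.
    """
    if promoter_bp < 0 or downstream_bp < 0:
        raise ValueError("promoter_bp and downstream_bp must be non-negative")
    genes = read_gff_genes(gff_path)
    recs = []
    for _, g in genes.iterrows():
        s, e = int(g["start"]), int(g["end"])
        recs.append((g["chrom"], s, e, g["strand"], "gene_body", g["gene_id"]))
        if g["strand"] == "+":
            prom = (max(1, s - promoter_bp), s - 1)
            down = (e + 1, e + downstream_bp)
        else:
            prom = (e + 1, e + promoter_bp)
            down = (max(1, s - downstream_bp), s - 1)
        if promoter_bp > 0 and prom[0] <= prom[1]:
            recs.append((g["chrom"], prom[0], prom[1], g["strand"], "promoter", g["gene_id"]))
        if downstream_bp > 0 and down[0] <= down[1]:
            recs.append((g["chrom"], down[0], down[1], g["strand"], "downstream", g["gene_id"]))
    if te_bed_path is not None:
        for _, t in read_te_bed(te_bed_path).iterrows():
            recs.append((t["chrom"], int(t["start"]), int(t["end"]), ".", "TE", t["te_id"]))
    records = pd.DataFrame(
        recs, columns=["chrom", "start", "end", "strand", "feature_class", "feature_id"]
    )
    return FeatureSet(records)


# ---------------------------------------------------------------------------
# TSV round-trip plumbing for the matrix containers


def write_epi_genotypes(epi: EpiGenotypeMatrix, path: str | Path) -> None:
    """TSV: chrom, pos, strand, context, p_M, maf, then one code column per accession."""
    extra = pd.DataFrame(
        {"p_M": epi.p_m(), "maf": epi.maf(),
         **{acc: epi.codes[:, j] for j, acc in enumerate(epi.accessions)}})
    pd.concat([epi.sites.reset_index(drop=True), extra], axis=1).to_csv(
        path, sep="\t", index=False)


def read_epi_genotypes(path: str | Path) -> EpiGenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str, "context": str})
    accs = [c for c in df.columns if c not in ("chrom", "pos", "strand", "context", "p_M", "maf")]
    codes = df[accs].to_numpy(dtype=np.int8)
    return EpiGenotypeMatrix(df[["chrom", "pos", "strand", "context"]], codes, accs)


def write_matrix_tsv(index_df: pd.DataFrame, values: np.ndarray,
                     columns: Sequence[str], path: str | Path) -> None:
    vals = pd.DataFrame({c: values[:, j] for j, c in enumerate(columns)})
    out = pd.concat([index_df.reset_index(drop=True), vals], axis=1)
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    meta = ["gene_id", "chrom", "start", "end", "strand"]
    accs = [c for c in df.columns if c not in meta]
    return ExpressionMatrix(df[meta], df[accs].to_numpy(dtype=float), accs)


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    write_matrix_tsv(expr.genes, expr.fpkm, expr.accessions, path)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Accession x trait table, accession ids as index; blanks are missing."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, sep="\t", float_format="%.12g")
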