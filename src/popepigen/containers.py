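"""In-memory containers shared across the pipeline.

All genomic coordinates are 1-based, closed intervals (the per-cytosine
report convention). Methylation counts are stored as dense sites x
accessions integer arrays; a cell with ``total == 0`` means the site was
not covered in that accession, which is distinct from covered-but-
unmethylated (``meth == 0, total > 0``). Epi-genotype codes are additive,
mirroring SNP dosage: UU=0, MU=1, MM=2, missing=-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

CONTEXTS = ("CG", "CHG", "CHH")

#: epi-genotype codes
UU, MU, MM, MISSING = 0, 1, 2, -1

SITE_COLUMNS = ["chrom", "pos", "strand", "context"]


def _check_site_index(sites: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in SITE_COLUMNS if c not in sites.columns]
    if missing_cols:
        raise ValueError(f"site table lacks columns {missing_cols}")
    bad_ctx = set(sites["context"].unique()) - set(CONTEXTS)
    if bad_ctx:
        raise ValueError(f"unknown cytosine contexts: {sorted(bad_ctx)}")
    if not sites["pos"].gt(0).all():
        raise ValueError("positions must be 1-based positive integers")
    order = sites.sort_values(["chrom", "pos", "strand"], kind="mergesort").index
    if not np.array_equal(order.to_numpy(), sites.index.to_numpy()):
        raise ValueError("site index must be sorted by (chrom, pos)")
    return sites


@dataclass
class MethylationCountMatrix:
    """Per-cytosine methylated/total read counts for a cohort.

    sites : DataFrame with columns chrom, pos (1-based), strand, context,
        sorted by (chrom, pos); one row per cytosine.
    meth, total : (n_sites, n_accessions) int arrays, ``meth <= total``.
    accessions : ordered unique accession ids (columns of the arrays).
    """

    sites: pd.DataFrame
    meth: np.ndarray
    total: np.ndarray
    accessions: list[str]

    def __post_init__(self) -> None:
        self.sites = _check_site_index(self.sites.reset_index(drop=True))
        self.meth = np.asarray(self.meth, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        if self.meth.shape != self.total.shape:
            raise ValueError("meth and total shapes differ")
        if self.meth.shape != (len(self.sites), len(self.accessions)):
            raise ValueError("count arrays do not match sites x accessions")
        if len(set(self.accessions)) != len(self.accessions):
            raise ValueError("accession ids must be unique")
        if (self.meth < 0).any() or (self.total < 0).any():
            raise ValueError("negative read counts")
        if (self.meth > self.total).any():
            raise ValueError("meth_count exceeds total_count")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    def subset_sites(self, mask: np.ndarray) -> "MethylationCountMatrix":
        return MethylationCountMatrix(
            self.sites.loc[mask].reset_index(drop=True),
            self.meth[mask], self.total[mask], list(self.accessions),
        )


@dataclass
class MethylationLevelMatrix:
    """Per-site methylation fractions mC in [0, 1]; NaN = missing."""

    sites: pd.DataFrame
    levels: np.ndarray  # float, NaN missing
    accessions: list[str]

    def __post_init__(self) -> None:
        self.sites = _check_site_index(self.sites.reset_index(drop=True))
        self.levels = np.asarray(self.levels, dtype=float)
        if self.levels.shape != (len(self.sites), len(self.accessions)):
            raise ValueError("level array does not match sites x accessions")
        finite = self.levels[np.isfinite(self.levels)]
        if finite.size and ((finite < 0).any() or (finite > 1).any()):
            raise ValueError("methylation levels must lie in [0, 1]")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.levels).mean(axis=1)

    def subset_sites(self, mask: np.ndarray) -> "MethylationLevelMatrix":
        return MethylationLevelMatrix(
            self.sites.loc[mask].reset_index(drop=True),
            self.levels[mask], list(self.accessions),
        )


@dataclass
class EpiGenotypeMatrix:
    """Called epi-alleles per site per accession (UU=0, MU=1, MM=2, -1 missing)."""

    sites: pd.DataFrame
    codes: np.ndarray  # int8, -1 missing
    accessions: list[str]

    def __post_init__(self) -> None:
        self.sites = _check_site_index(self.sites.reset_index(drop=True))
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.sites), len(self.accessions)):
            raise ValueError("code array does not match sites x accessions")
        bad = ~np.isin(self.codes, (UU, MU, MM, MISSING))
        if bad.any():
            raise ValueError("epi-genotype codes must be in {0, 1, 2, -1}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    def codes_float(self) -> np.ndarray:
        """Codes as float with NaN for missing (for numeric work)."""
        out = self.codes.astype(float)
        out[self.codes == MISSING] = np.nan
        return out

    def p_m(self) -> np.ndarray:
        """Per-site frequency of the M epi-allele, counting 2 alleles per call."""
        called = self.codes != MISSING
        n_called = called.sum(axis=1)
        m_alleles = np.where(called, self.codes, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, m_alleles / (2.0 * n_called), np.nan)

    def maf(self) -> np.ndarray:
        p = self.p_m()
        return np.minimum(p, 1.0 - p)

    def subset_sites(self, mask: np.ndarray) -> "EpiGenotypeMatrix":
        return EpiGenotypeMatrix(
            self.sites.loc[mask].reset_index(drop=True),
            self.codes[mask], list(self.accessions),
        )


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages (0/1/2 alt-allele count, NaN missing)."""

    snps: pd.DataFrame  # chrom, pos, ref, alt
    dosage: np.ndarray  # float (n_snps, n_accessions), NaN missing
    accessions: list[str]

    def __post_init__(self) -> None:
        self.snps = self.snps.reset_index(drop=True)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.snps), len(self.accessions)):
            raise ValueError("dosage array does not match snps x accessions")
        finite = self.dosage[np.isfinite(self.dosage)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0/1/2 or missing")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def alt_freq(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=1) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=1)

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.snps.loc[mask].reset_index(drop=True),
            self.dosage[mask], list(self.accessions),
        )


FEATURE_CLASSES = ("gene_body", "promoter", "downstream", "TE", "intergenic")


@dataclass
class FeatureSet:
    """Annotated genomic intervals with point/interval overlap queries.

    records : DataFrame with chrom, start, end (1-based closed), strand,
        feature_class, feature_id.
    """

    records: pd.DataFrame
    _trees: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        req = {"chrom", "start", "end", "strand", "feature_class", "feature_id"}
        if not req.issubset(self.records.columns):
            raise ValueError(f"feature records need columns {sorted(req)}")
        if (self.records["start"] > self.records["end"]).any():
            raise ValueError("feature with start > end")
        self.records = self.records.reset_index(drop=True)
        self._trees = {}
        for chrom, grp in self.records.groupby("chrom"):
            tree = IntervalTree()
            for idx, row in grp.iterrows():
                # half-open internally: [start, end+1)
                tree.addi(int(row["start"]), int(row["end"]) + 1, idx)
            self._trees[chrom] = tree

    def query_point(self, chrom: str, pos: int) -> pd.DataFrame:
        """All features overlapping a 1-based position."""
        tree = self._trees.get(chrom)
        if tree is None:
            return self.records.iloc[0:0]
        hits = sorted(iv.data for iv in tree.at(int(pos)))
        return self.records.iloc[hits]

    def classes_at(self, chrom: str, pos: int) -> set[str]:
        hits = self.query_point(chrom, pos)
        if hits.empty:
            return {"intergenic"}
        return set(hits["feature_class"])


@dataclass
class ExpressionMatrix:
    """Gene x accession FPKM with gene coordinates (midpoint anchors)."""

    genes: pd.DataFrame  # gene_id, chrom, start, end, strand
    fpkm: np.ndarray
    accessions: list[str]

    def __post_init__(self) -> None:
        self.genes = self.genes.reset_index(drop=True)
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("gene ids must be unique")
        self.fpkm = np.asarray(self.fpkm, dtype=float)
        if self.fpkm.shape != (len(self.genes), len(self.accessions)):
            raise ValueError("fpkm array does not match genes x accessions")
        if np.nanmin(self.fpkm, initial=0.0) < 0:
            raise ValueError("FPKM must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def midpoints(self) -> np.ndarray:
        return ((self.genes["start"] + self.genes["end"]) // 2).to_numpy()

    def expressed_mask(self, min_fpkm: float = 1.0, min_fraction: float = 0.05) -> np.ndarray:
        """Genes expressed (FPKM > min_fpkm) in more than min_fraction of accessions."""
        frac = (self.fpkm > min_fpkm).mean(axis=1)
        return frac > min_fraction

    def subset_genes(self, mask: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.genes.loc[mask].reset_index(drop=True),
            self.fpkm[mask], list(self.accessions),
        )


@dataclass
class Locus:
    """A merged association locus (lead marker plus LD/MD-linked members)."""

    lead_marker: str
    members: list[str]
    chrom: str
    start: int
    end: int
    target: str
    lead_p: float
    lead_pos: int = 0

    def span(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def align_accessions(*objs, ids: Sequence[str] | None = None) -> list:
    """Subset/reorder container columns to a shared accession ordering.

    Accepts any containers with ``accessions`` plus one column-indexed
    array attribute, or DataFrames indexed by accession.
    """
    sets = []
    for o in objs:
        if isinstance(o, pd.DataFrame):
            sets.append(list(o.index))
        else:
            sets.append(list(o.accessions))
    if ids is None:
        ids = [a for a in sets[0] if all(a in s for s in sets[1:])]
    out = []
    for o in objs:
        if isinstance(o, pd.DataFrame):
            out.append(o.loc[list(ids)])
            continue
        idx = [o.accessions.index(a) for a in ids]
        for attr in ("meth", "total", "levels", "codes", "dosage", "fpkm"):
            if hasattr(o, attr):
                arr = getattr(o, attr)
                new = type(o)(
                    *_rebuild_args(o, attr, arr[:, idx], list(ids))
                )
                out.append(new)
                break
        else:  # pragma: no cover
            raise TypeError(f"cannot align {type(o)}")
    return out


def _rebuild_args(o, attr, arr, ids):
    if isinstance(o, MethylationCountMatrix):
        # meth and total both need slicing
        idx = [o.accessions.index(a) for a in ids]
        return (o.sites, o.meth[:, idx], o.total[:, idx], ids)
    if isinstance(o, MethylationLevelMatrix):
        return (o.sites, arr, ids)
    if isinstance(o, EpiGenotypeMatrix):
        return (o.sites, arr, ids)
    if isinstance(o, GenotypeMatrix):
        return (o.snps, arr, ids)
    if isinstance(o, ExpressionMatrix):
        return (o.genes, arr, ids)
    raise TypeError(type(o))  # pragma: no cover
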