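"""Single methylation polymorphism (SMP) calling and site-level summaries.

A cytosine's methylation level across reads, mC = meth/(meth+unmeth), is
discretized into epi-alleles per accession:

    UU  if 0   <= mC <= 0.3
    MU  if 0.3 <  mC <= 0.7
    MM  if 0.7 <  mC <= 1

The boundary values 0.30 and 0.70 belong to the lower class. Epi-allele
frequencies count two alleles per called accession (p_M = (2 n_MM + n_MU)
/ (2 n_called)); a genotype-frequency mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence
import warnings

import numpy as np
import pandas as pd

from .containers import (
    MISSING,
    MM,
    MU,
    UU,
    EpiGenotypeMatrix,
    FeatureSet,
    MethylationCountMatrix,
    MethylationLevelMatrix,
)

UU_MAX = 0.3   # 0 <= mC <= 0.3 -> UU
MU_MAX = 0.7   # 0.3 < mC <= 0.7 -> MU; above -> MM


def compute_levels(counts: MethylationCountMatrix, min_coverage: int = 5) -> MethylationLevelMatrix:
    """Per-site methylation fraction where coverage >= min_coverage, else NaN."""
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    total = counts.total.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        levels = counts.meth / total
    levels[counts.total < min_coverage] = np.nan
    return MethylationLevelMatrix(counts.sites.copy(), levels, list(counts.accessions))


@dataclass
class FilterReport:
    n_input: int
    n_removed_missing: int
    n_removed_snp: int
    n_retained: int


def filter_sites(
    levels: MethylationLevelMatrix,
    max_missing_rate: float = 0.30,
    snp_positions: Iterable[tuple[str, int]] = (),
) -> tuple[MethylationLevelMatrix, FilterReport]:
    """Apply the two QC rules: drop sites missing in more than
    ``max_missing_rate`` of accessions, and drop sites whose position
    coincides with a SNP. Returns the filtered matrix plus a removal report.
    """
    miss = levels.missing_fraction()
    fail_missing = miss > max_missing_rate
    snp_set = set(snp_positions)
    keys = list(zip(levels.sites["chrom"], levels.sites["pos"]))
    fail_snp = np.array([k in snp_set for k in keys], dtype=bool)
    keep = ~(fail_missing | fail_snp)
    report = FilterReport(
        n_input=levels.n_sites,
        n_removed_missing=int(fail_missing.sum()),
        n_removed_snp=int((fail_snp & ~fail_missing).sum()),
        n_retained=int(keep.sum()),
    )
    if report.n_retained == 0:
        warnings.warn("all sites removed by QC filters")
    return levels.subset_sites(keep), report


def call_epi_alleles(levels: MethylationLevelMatrix) -> EpiGenotypeMatrix:
    """Discretize methylation levels into UU/MU/MM epi-alleles."""
    x = levels.levels
    finite = np.isfinite(x)
    if finite.any() and ((x[finite] < 0).any() or (x[finite] > 1).any()):
        raise ValueError("methylation levels outside [0, 1]")
    codes = np.full(x.shape, MISSING, dtype=np.int8)
    codes[finite & (x <= UU_MAX)] = UU
    codes[finite & (x > UU_MAX) & (x <= MU_MAX)] = MU
    codes[finite & (x > MU_MAX)] = MM
    return EpiGenotypeMatrix(levels.sites.copy(), codes, list(levels.accessions))


class EpiAlleleCaller:
    """sklearn-style transformer view of epi-allele calling.

    ``transform`` maps a (sites x accessions) level array to codes;
    stateless, provided for pipeline composition.
    """

    def __init__(self, uu_max: float = UU_MAX, mu_max: float = MU_MAX):
        self.uu_max = uu_max
        self.mu_max = mu_max

    def get_params(self, deep: bool = True) -> dict:
        return {"uu_max": self.uu_max, "mu_max": self.mu_max}

    def set_params(self, **params) -> "EpiAlleleCaller":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "EpiAlleleCaller":
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        codes = np.full(X.shape, MISSING, dtype=np.int8)
        finite = np.isfinite(X)
        codes[finite & (X <= self.uu_max)] = UU
        codes[finite & (X > self.uu_max) & (X <= self.mu_max)] = MU
        codes[finite & (X > self.mu_max)] = MM
        return codes


def site_maf_spectrum(
    epi: EpiGenotypeMatrix, min_maf: float = 0.05, mode: str = "allele"
) -> tuple[pd.DataFrame, EpiGenotypeMatrix]:
    """Per-site MAF table and the common-SMP subset (maf >= min_maf).

    mode="allele" counts 2 alleles per called accession; mode="genotype"
    uses genotype-class frequencies (frequency of the rarer homozygous
    class plus half the heterozygotes, equivalent up to weighting).
    """
    called = epi.codes != MISSING
    n_called = called.sum(axis=1)
    if mode == "allele":
        p_m = epi.p_m()
    elif mode == "genotype":
        with np.errstate(invalid="ignore", divide="ignore"):
            p_m = (
                np.where(called, epi.codes == MM, 0).sum(axis=1)
                + 0.5 * np.where(called, epi.codes == MU, 0).sum(axis=1)
            ) / n_called
        p_m = np.where(n_called > 0, p_m, np.nan)
    else:
        raise ValueError("mode must be 'allele' or 'genotype'")
    maf = np.minimum(p_m, 1 - p_m)
    table = epi.sites.copy()
    table["n_called"] = n_called
    table["p_M"] = p_m
    table["maf"] = maf
    defined = np.isfinite(maf)
    table["common"] = defined & (maf >= min_maf)
    common = epi.subset_sites(table["common"].to_numpy())
    return table, common


def annotate_sites(
    epi: EpiGenotypeMatrix, features: FeatureSet, precedence: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label every site with all overlapping feature classes.

    Returns (labels, summary): ``labels`` has one boolean column per class
    plus an ``intergenic`` flag (and, with ``precedence=True``, a single
    ``label`` column using promoter > gene_body > downstream > TE >
    intergenic); ``summary`` gives per-class MAF quartiles including the
    gene_body&TE vs gene_body-not-TE split.
    """
    classes = ["gene_body", "promoter", "downstream", "TE"]
    n = epi.n_sites
    flags = {c: np.zeros(n, dtype=bool) for c in classes}
    chroms = epi.sites["chrom"].to_numpy()
    poss = epi.sites["pos"].to_numpy()
    for i in range(n):
        for c in features.classes_at(chroms[i], int(poss[i])):
            if c in flags:
                flags[c][i] = True
    labels = epi.sites.copy()
    for c in classes:
        labels[c] = flags[c]
    labels["intergenic"] = ~np.any(np.column_stack([flags[c] for c in classes]), axis=1)
    if precedence:
        order = ["promoter", "gene_body", "downstream", "TE"]
        lab = np.full(n, "intergenic", dtype=object)
        for c in reversed(order):
            lab[flags[c]] = c
        labels["label"] = lab

    maf = epi.maf()
    rows = []
    groups = {c: flags[c] for c in classes}
    groups["intergenic"] = labels["intergenic"].to_numpy()
    groups["gene_body&TE"] = flags["gene_body"] & flags["TE"]
    groups["gene_body-notTE"] = flags["gene_body"] & ~flags["TE"]
    for name, mask in groups.items():
        vals = maf[mask & np.isfinite(maf)]
        rows.append({
            "feature_class": name,
            "n_sites": int(mask.sum()),
            "maf_mean": float(np.mean(vals)) if vals.size else np.nan,
            "maf_median": float(np.median(vals)) if vals.size else np.nan,
            "maf_q25": float(np.percentile(vals, 25)) if vals.size else np.nan,
            "maf_q75": float(np.percentile(vals, 75)) if vals.size else np.nan,
        })
    return labels, pd.DataFrame(rows)


def region_methylation(
    counts: MethylationCountMatrix,
    chrom: str,
    start: int,
    end: int,
    accession: str | None = None,
) -> float | np.ndarray:
    """Weighted methylation of a region: sum(C_i) / sum(C_i + T_i) over
    covered cytosines in [start, end]; NaN if nothing is covered.

    With ``accession=None`` returns the per-accession vector.
    """
    if end < start:
        raise ValueError("empty region (end < start)")
    in_region = (
        (counts.sites["chrom"] == chrom)
        & (counts.sites["pos"] >= start)
        & (counts.sites["pos"] <= end)
    ).to_numpy()
    meth = counts.meth[in_region]
    total = counts.total[in_region]
    num = meth.sum(axis=0).astype(float)
    den = total.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    if accession is None:
        return out
    return float(out[counts.accessions.index(accession)])
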