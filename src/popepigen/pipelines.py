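"""The four association scans with the study's windows and thresholds.

cis-meQTL : SNPs within 1 Mb of each SMP; methylation codes
    quantile-normalized as the phenotype; permutation empirical p for the
    lead SNP per SMP; Benjamini–Hochberg across SMPs.
trans-meQTL : genome-wide EMMAX scan over a seeded subsample of SMPs at
    the effective-test threshold, results labeled cis/trans at 1 Mb.
eQTM : common SMPs within 1 Mb of each gene midpoint against
    quantile-normalized expression; permutation lead p; BH across genes.
eQTL : genome-wide EMMAX scan per expressed gene; lead SNPs merged into
    loci within LD blocks (r^2 > 0.1); cis/trans at 1 Mb from the gene.
EWAS : EMMAX scan of SMP codes per trait per context at a per-context
    effective-test threshold; significant SMPs merged along MD blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import EpiGenotypeMatrix, ExpressionMatrix, GenotypeMatrix, Locus
from .association import (
    EmmaNull,
    classify_cis_trans,
    compute_kinship,
    effective_tests,
    merge_lead_loci,
    permutation_empirical_p,
    quantile_normalize,
    structure_pcs,
)
from .md import md_blocks
from .smp import site_maf_spectrum


@dataclass
class ScanConfig:
    """Shared scan parameters; defaults are the study's thresholds."""

    cis_window: int = 1_000_000
    snp_maf: float = 0.05
    smp_maf: float = 0.05
    expr_min_fpkm: float = 1.0
    expr_min_fraction: float = 0.05
    n_perm: int = 1000
    beta_approx: bool = True
    seed: int = 0
    k_struct: int = 3
    k_conf: int = 2
    fdr: float = 0.05
    alpha: float = 0.05
    meff_window: int = 1000
    min_shared_accessions: int = 30
    trans_sample_size: int | None = None
    md_block_r2: float = 0.1
    md_block_max_gap: int = 10_000

    def __post_init__(self) -> None:
        for name in ("cis_window", "n_perm", "expr_min_fpkm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CisScanResult:
    """Per-target lead associations of a windowed (cis) scan."""

    leads: pd.DataFrame
    untestable: list
    loci: list
    meta: dict = field(default_factory=dict)


@dataclass
class GenomeScanResult:
    """Significant marker-target pairs of a genome-wide scan."""

    results: pd.DataFrame
    loci: list
    threshold: float
    m_eff: float
    meta: dict = field(default_factory=dict)


def _check_shared(n: int, config: ScanConfig) -> None:
    if n < config.min_shared_accessions:
        raise ValueError(
            f"only {n} shared accessions (< {config.min_shared_accessions})"
        )


def _qnorm_complete(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize and mean-impute residual missingness (scores
    are centered, so imputation at 0)."""
    y = quantile_normalize(values)
    y[~np.isfinite(y)] = 0.0
    return y


def _common_codes(epi: EpiGenotypeMatrix, min_maf: float) -> EpiGenotypeMatrix:
    _, common = site_maf_spectrum(epi, min_maf=min_maf)
    return common


def _cis_scan(
    null: EmmaNull,
    targets: list[dict],
    marker_dosage: np.ndarray,
    marker_index: pd.DataFrame,
    config: ScanConfig,
    anchor_kind: str,
) -> CisScanResult:
    """Shared driver for cis-meQTL and eQTM scans.

    Each target dict carries id, y, chrom, anchor (position), plus extras
    copied to the output.
    """
    m_chrom = marker_index["chrom"].to_numpy()
    m_pos = marker_index["pos"].to_numpy()
    rows, untestable = [], []
    for t_i, tgt in enumerate(targets):
        window = np.flatnonzero(
            (m_chrom == tgt["chrom"])
            & (np.abs(m_pos - tgt["anchor"]) <= config.cis_window)
        )
        if window.size == 0:
            untestable.append(tgt["id"])
            continue
        fitted = null.fit(tgt["y"])
        G = marker_dosage[window].T  # n x m
        try:
            perm = permutation_empirical_p(
                fitted, G, n_perm=config.n_perm,
                seed=config.seed * 100_003 + t_i,
                beta_approx=config.beta_approx,
            )
        except ValueError:  # all window markers monomorphic
            untestable.append(tgt["id"])
            continue
        lead_global = int(window[perm["lead_idx"]])
        scan = fitted.scan(G)
        lead_row = scan.iloc[perm["lead_idx"]]
        label, dist = classify_cis_trans(
            str(m_chrom[lead_global]), int(m_pos[lead_global]),
            tgt["chrom"], int(tgt["anchor"]), window_bp=config.cis_window,
        )
        row = {
            "target_id": tgt["id"],
            "marker_idx": lead_global,
            "marker_chrom": m_chrom[lead_global],
            "marker_pos": int(m_pos[lead_global]),
            "beta": float(lead_row["beta"]),
            "se": float(lead_row["se"]),
            "p_nominal": perm["p_nominal"],
            "p_empirical": perm["p_empirical"],
            "p_beta": perm.get("p_beta", np.nan),
            "n_window": int(window.size),
            "distance_bp": dist,
            "label": label,
            "h2": fitted.h2,
        }
        row.update({k: v for k, v in tgt.items() if k not in ("id", "y", "chrom", "anchor")})
        rows.append(row)
    leads = pd.DataFrame(rows)
    if not leads.empty:
        p_for_fdr = leads["p_beta"].where(
            config.beta_approx & leads["p_beta"].notna(), leads["p_empirical"]
        )
        leads["q_value"] = multipletests(p_for_fdr, method="fdr_bh")[1]
        leads["significant"] = leads["q_value"] <= config.fdr
    return CisScanResult(leads, untestable, [], {"anchor": anchor_kind})


def map_cis_meqtl(
    geno: GenotypeMatrix, epi: EpiGenotypeMatrix, config: ScanConfig
) -> CisScanResult:
    """cis-meQTL scan: SNPs within the cis window of each common SMP."""
    if geno.accessions != epi.accessions:
        raise ValueError("genotypes and epi-genotypes must share accession order")
    _check_shared(len(geno.accessions), config)
    snps = geno.subset_snps(np.asarray(geno.maf() >= config.snp_maf))
    common = _common_codes(epi, config.smp_maf)
    X_snp = snps.dosage.T
    K = compute_kinship(X_snp)
    pcs = structure_pcs(X_snp, config.k_struct)
    conf = structure_pcs(common.codes_float().T, config.k_conf)
    null = EmmaNull(K, np.hstack([pcs, conf]))
    codes = common.codes_float()
    targets = [
        {
            "id": f"{common.sites['chrom'].iloc[i]}:{common.sites['pos'].iloc[i]}",
            "y": _qnorm_complete(codes[i]),
            "chrom": common.sites["chrom"].iloc[i],
            "anchor": int(common.sites["pos"].iloc[i]),
            "context": common.sites["context"].iloc[i],
            "site_idx": i,
        }
        for i in range(common.n_sites)
    ]
    res = _cis_scan(null, targets, snps.dosage, snps.snps, config, "smp_position")
    if not res.leads.empty:
        sig = res.leads[res.leads["significant"]]
        if not sig.empty:
            res.loci = merge_lead_loci(
                sig.rename(columns={"target_id": "target_id"})[
                    ["marker_idx", "target_id", "p_empirical"]
                ].rename(columns={"p_empirical": "p"}),
                snps.dosage, snps.snps, r2_threshold=0.1, by_target=False,
            )
    res.meta["common_sites"] = common
    res.meta["snps"] = snps
    return res


def map_eqtm(
    epi: EpiGenotypeMatrix, expression: ExpressionMatrix, config: ScanConfig
) -> CisScanResult:
    """eQTM scan: common SMPs within the cis window of each gene midpoint.

    Expression is floored (FPKM > expr_min_fpkm in > expr_min_fraction of
    accessions) and quantile-normalized; kinship and structure PCs come
    from the common SMP codes, confounder PCs from expression.
    """
    if epi.accessions != expression.accessions:
        raise ValueError("epi-genotypes and expression must share accession order")
    _check_shared(len(epi.accessions), config)
    common = _common_codes(epi, config.smp_maf)
    expr = expression.subset_genes(
        expression.expressed_mask(config.expr_min_fpkm, config.expr_min_fraction)
    )
    X_smp = common.codes_float().T
    K = compute_kinship(X_smp)
    pcs = structure_pcs(X_smp, config.k_struct)
    conf = structure_pcs(expr.fpkm.T, config.k_conf)
    null = EmmaNull(K, np.hstack([pcs, conf]))
    mids = expr.midpoints()
    strands = expr.genes["strand"].to_numpy()
    tss = np.where(strands == "+", expr.genes["start"], expr.genes["end"]).astype(int)
    targets = [
        {
            "id": expr.genes["gene_id"].iloc[g],
            "y": _qnorm_complete(expr.fpkm[g]),
            "chrom": expr.genes["chrom"].iloc[g],
            "anchor": int(mids[g]),
            "tss": int(tss[g]),
            "strand": strands[g],
        }
        for g in range(expr.n_genes)
    ]
    res = _cis_scan(
        null, targets,
        common.codes_float(), common.sites, config, "gene_midpoint",
    )
    if not res.leads.empty:
        # context of the lead SMP and its strand-aware distance to the TSS
        ctx = common.sites["context"].to_numpy()
        res.leads["context"] = ctx[res.leads["marker_idx"].to_numpy()]
        sign = np.where(res.leads["strand"].to_numpy() == "+", 1, -1)
        res.leads["tss_distance"] = sign * (
            res.leads["marker_pos"].to_numpy() - res.leads["tss"].to_numpy()
        )
    res.meta["common_sites"] = common
    res.meta["expressed"] = expr
    return res


def map_trans_meqtl(
    geno: GenotypeMatrix, epi: EpiGenotypeMatrix, config: ScanConfig
) -> GenomeScanResult:
    """Genome-wide meQTL scan over a seeded subsample of common SMPs."""
    if geno.accessions != epi.accessions:
        raise ValueError("genotypes and epi-genotypes must share accession order")
    _check_shared(len(geno.accessions), config)
    snps = geno.subset_snps(np.asarray(geno.maf() >= config.snp_maf))
    common = _common_codes(epi, config.smp_maf)
    rng = np.random.default_rng(config.seed)
    n_sample = config.trans_sample_size or common.n_sites
    n_sample = min(n_sample, common.n_sites)
    sampled = np.sort(rng.choice(common.n_sites, size=n_sample, replace=False))
    X_snp = snps.dosage.T
    K = compute_kinship(X_snp)
    pcs = structure_pcs(X_snp, config.k_struct)
    null = EmmaNull(K, pcs)
    m_eff, threshold = effective_tests(X_snp, config.meff_window, config.alpha)
    codes = common.codes_float()
    G_all = snps.dosage.T
    rows = []
    for i in sampled:
        y = _qnorm_complete(codes[i])
        fitted = null.fit(y)
        scan = fitted.scan(G_all)
        hits = np.flatnonzero(scan["p"].to_numpy() <= threshold)
        for h in hits:
            label, dist = classify_cis_trans(
                str(snps.snps["chrom"].iloc[h]), int(snps.snps["pos"].iloc[h]),
                common.sites["chrom"].iloc[i], int(common.sites["pos"].iloc[i]),
                window_bp=config.cis_window,
            )
            rows.append({
                "target_id": f"{common.sites['chrom'].iloc[i]}:{common.sites['pos'].iloc[i]}",
                "site_idx": int(i),
                "marker_idx": int(h),
                "marker_chrom": snps.snps["chrom"].iloc[h],
                "marker_pos": int(snps.snps["pos"].iloc[h]),
                "beta": float(scan["beta"].iloc[h]),
                "p": float(scan["p"].iloc[h]),
                "distance_bp": dist,
                "label": label,
            })
    results = pd.DataFrame(rows, columns=[
        "target_id", "site_idx", "marker_idx", "marker_chrom", "marker_pos",
        "beta", "p", "distance_bp", "label",
    ])
    loci = merge_lead_loci(results, snps.dosage, snps.snps) if len(rows) else []
    return GenomeScanResult(results, loci, threshold, m_eff,
                            {"sampled_sites": sampled, "snps": snps,
                             "common_sites": common})


def map_eqtl(
    geno: GenotypeMatrix, expression: ExpressionMatrix, config: ScanConfig
) -> GenomeScanResult:
    """Genome-wide eQTL scan per expressed gene at the effective-test
    threshold; significant SNPs merged into loci within LD blocks
    (r^2 > 0.1); cis/trans labeled by distance to the gene body."""
    if geno.accessions != expression.accessions:
        raise ValueError("genotypes and expression must share accession order")
    _check_shared(len(geno.accessions), config)
    snps = geno.subset_snps(np.asarray(geno.maf() >= config.snp_maf))
    expr = expression.subset_genes(
        expression.expressed_mask(config.expr_min_fpkm, config.expr_min_fraction)
    )
    X_snp = snps.dosage.T
    K = compute_kinship(X_snp)
    pcs = structure_pcs(X_snp, config.k_struct)
    conf = structure_pcs(expr.fpkm.T, config.k_conf)
    null = EmmaNull(K, np.hstack([pcs, conf]))
    m_eff, threshold = effective_tests(X_snp, config.meff_window, config.alpha)
    rows = []
    for g in range(expr.n_genes):
        y = _qnorm_complete(expr.fpkm[g])
        fitted = null.fit(y)
        scan = fitted.scan(X_snp)
        pvals = scan["p"].to_numpy()
        hits = np.flatnonzero(pvals <= threshold)
        for h in hits:
            label, dist = classify_cis_trans(
                str(snps.snps["chrom"].iloc[h]), int(snps.snps["pos"].iloc[h]),
                expr.genes["chrom"].iloc[g],
                int(expr.genes["start"].iloc[g]), int(expr.genes["end"].iloc[g]),
                window_bp=config.cis_window,
            )
            rows.append({
                "target_id": expr.genes["gene_id"].iloc[g],
                "marker_idx": int(h),
                "marker_chrom": snps.snps["chrom"].iloc[h],
                "marker_pos": int(snps.snps["pos"].iloc[h]),
                "beta": float(scan["beta"].iloc[h]),
                "p": float(pvals[h]),
                "distance_bp": dist,
                "label": label,
            })
    results = pd.DataFrame(rows, columns=[
        "target_id", "marker_idx", "marker_chrom", "marker_pos",
        "beta", "p", "distance_bp", "label",
    ])
    loci = merge_lead_loci(results, snps.dosage, snps.snps) if len(rows) else []
    return GenomeScanResult(results, loci, threshold, m_eff,
                            {"snps": snps, "expressed": expr})


@dataclass
class EwasResult:
    loci: pd.DataFrame
    results: pd.DataFrame
    thresholds: dict
    m_eff: dict
    meta: dict = field(default_factory=dict)


def run_ewas(
    epi_common: EpiGenotypeMatrix,
    phenotypes: pd.DataFrame,
    config: ScanConfig,
    contexts: tuple = ("CG", "CHG", "CHH"),
    kinship_source: GenotypeMatrix | None = None,
) -> EwasResult:
    """EWAS of SMP codes per trait per context with MD-block locus merging.

    Kinship and structure PCs default to the common SMP codes; when SNP
    genotypes are supplied as ``kinship_source`` they are used instead,
    which is preferable when the confounding to absorb (polygenic trait
    background, population structure) is genetic. The per-context
    threshold is alpha over the Li–Ji effective test count. Each locus
    reports the lead SMP's per-epi-allele trait means.
    """
    acc = list(epi_common.accessions)
    missing_acc = [a for a in acc if a not in phenotypes.index]
    if missing_acc:
        raise ValueError(f"phenotypes lack accessions, e.g. {missing_acc[:3]}")
    pheno = phenotypes.loc[acc]
    loci_rows, res_rows = [], []
    thresholds, meffs = {}, {}
    for trait in pheno.columns:
        y_raw = pheno[trait].to_numpy(dtype=float)
        have = np.isfinite(y_raw)
        if have.sum() < 30:
            raise ValueError(f"trait {trait}: fewer than 30 phenotyped accessions")
        sub_ids = [a for a, h in zip(acc, have) if h]
        sub = EpiGenotypeMatrix(epi_common.sites.copy(),
                                epi_common.codes[:, have], sub_ids)
        if kinship_source is not None:
            if kinship_source.accessions != acc:
                raise ValueError("kinship_source must share accession order")
            X_kin = kinship_source.dosage[:, have].T
        else:
            X_kin = sub.codes_float().T
        K = compute_kinship(X_kin)
        pcs = structure_pcs(X_kin, config.k_struct)
        null = EmmaNull(K, pcs)
        fitted = null.fit(quantile_normalize(y_raw[have]))
        for context in contexts:
            ctx_mask = (sub.sites["context"] == context).to_numpy()
            if ctx_mask.sum() < 2:
                continue
            ctx_idx = np.flatnonzero(ctx_mask)
            Xc = sub.codes_float()[ctx_idx].T
            key = (trait, context)
            if context not in meffs:
                meffs[context], thresholds[context] = effective_tests(
                    Xc, config.meff_window, config.alpha)
            scan = fitted.scan(Xc)
            pvals = scan["p"].to_numpy()
            hits = np.flatnonzero(pvals <= thresholds[context])
            for h in hits:
                res_rows.append({
                    "trait": trait, "context": context,
                    "site_idx": int(ctx_idx[h]),
                    "chrom": sub.sites["chrom"].iloc[ctx_idx[h]],
                    "pos": int(sub.sites["pos"].iloc[ctx_idx[h]]),
                    "beta": float(scan["beta"].iloc[h]),
                    "p": float(pvals[h]),
                })
            if hits.size == 0:
                continue
            sig_sites = np.sort(ctx_idx[hits])
            sig_epi = sub.subset_sites(np.isin(np.arange(sub.n_sites), sig_sites))
            blocks = md_blocks(sig_epi, r2_threshold=config.md_block_r2,
                               max_gap=config.md_block_max_gap,
                               n_min=min(20, len(sub_ids)))
            p_by_site = {int(ctx_idx[h]): pvals[h] for h in hits}
            for b, block in enumerate(blocks):
                member_global = sig_sites[block["sites"]]
                lead = min(member_global, key=lambda s: (p_by_site[int(s)], s))
                codes_lead = sub.codes[lead]
                yv = y_raw[have]
                means = {
                    lbl: (float(np.mean(yv[codes_lead == code]))
                          if np.any(codes_lead == code) else np.nan)
                    for lbl, code in (("UU", 0), ("MU", 1), ("MM", 2))
                }
                loci_rows.append({
                    "trait": trait, "context": context, "locus_id":
                        f"{trait}_{context}_{b}",
                    "chrom": block["chrom"], "start": block["start"],
                    "end": block["end"], "n_members": block["n_sites"],
                    "lead_site_idx": int(lead),
                    "lead_pos": int(sub.sites["pos"].iloc[lead]),
                    "lead_p": float(p_by_site[int(lead)]),
                    "mean_UU": means["UU"], "mean_MU": means["MU"],
                    "mean_MM": means["MM"],
                })
    return EwasResult(
        pd.DataFrame(loci_rows, columns=[
            "trait", "context", "locus_id", "chrom", "start", "end",
            "n_members", "lead_site_idx", "lead_pos", "lead_p",
            "mean_UU", "mean_MU", "mean_MM"]),
        pd.DataFrame(res_rows, columns=[
            "trait", "context", "site_idx", "chrom", "pos", "beta", "p"]),
        thresholds, meffs,
    )
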