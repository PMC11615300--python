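"""Synthetic cohort generator with recorded ground truth.

Emulates the statistical structure the pipeline assumes: a structured
population of diploid accessions (founder-copying haplotypes, two
subpopulations under a Balding–Nichols model), per-cytosine latent
epi-states {UU, MU, MM} whose frequencies follow context-specific Beta
priors, spatial correlation of epi-states that decays with distance so
the measured Mr^2 half-decay equals the configured ``md_half_decay_bp``,
bisulfite read counts (Poisson depth, binomial methylated reads with a
non-conversion error floor), log-normal expression, and phenotypes built
from planted marker effects plus a polygenic term.

Planted effects (cis-meQTL, trans-meQTL hotspot, eQTL, eQTM, EWAS/GWAS
loci) are parameterized by variance explained and recorded in a truth
registry for recovery scoring.

Spatial correlation uses a per-accession uniform-copula chain: adjacent
sites retain a shared latent uniform with probability
exp(-d * ln2 / (2 * lambda)) and the epi-state is the site-specific
Hardy-Weinberg quantile of that uniform. Marginals are exact per site
while the squared code correlation decays as exp(-d * ln2 / lambda),
i.e. half-decay at d = lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    MISSING,
    EpiGenotypeMatrix,
    ExpressionMatrix,
    GenotypeMatrix,
    MethylationCountMatrix,
)
from . import io as pio

@dataclass
class TraitSpec:
    """Genetic architecture of one simulated trait."""

    n_ewas_loci: int = 1
    ewas_variance: float = 0.05   # trait-variance fraction per planted SMP locus
    n_gwas_loci: int = 0
    gwas_variance: float = 0.05
    h2_poly: float = 0.40         # polygenic fraction (genotype kinship)
    subpop_shift: float = 0.0     # confounding mean shift (SD units) for subpop 0
    direction: str = "higher"     # direction of merit for pyramiding


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort."""

    seed: int
    n_accessions: int = 300
    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 400_000, "chr2": 400_000})
    # genotypes
    n_snps_per_chrom: int = 400
    n_founders: int = 24
    n_subpops: int = 2
    fst: float = 0.15
    switch_rate: float = 2e-4     # per-bp founder re-copy probability
    # methylome geometry
    sites_per_chrom: dict = field(default_factory=lambda: {"CG": 900, "CHG": 500, "CHH": 900})
    intra_gap_mean: float = 30.0
    cluster_jump_mean: float = 2500.0
    cluster_size_mean: float = 8.0
    md_half_decay_bp: float = 50.0
    epi_freq_beta: dict = field(default_factory=lambda: {
        "CG": (0.25, 0.10), "CHG": (0.30, 0.16), "CHH": (0.70, 1.10),
    })
    mean_depth: float = 15.0
    depth_dispersion: float = 0.0  # 0 -> Poisson; >0 -> gamma-Poisson
    epsilon: float = 0.003         # non-conversion error (99.70% conversion)
    # planted registries
    n_cis_meqtl: int = 0
    cis_meqtl_r2: float = 0.30
    n_trans_targets: int = 0
    trans_r2: float = 0.30
    n_eqtl: int = 0
    eqtl_r2: float = 0.20
    n_eqtm: int = 0
    eqtm_r2: float = 0.20
    eqtm_genetic_fraction: float = 0.5  # share of eQTMs whose SMP is itself a cis-meQTL target
    # expression
    n_genes_per_chrom: int = 40
    gene_length: int = 2000
    expr_noise_sd: float = 1.0
    zero_gene_fraction: float = 0.05
    # phenotypes
    traits: dict = field(default_factory=dict)  # name -> TraitSpec

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.md_half_decay_bp <= 0:
            raise ValueError("md_half_decay_bp must be positive")
        for r in (self.epsilon, self.fst, self.zero_gene_fraction,
                  self.eqtm_genetic_fraction):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        for name, spec in self.traits.items():
            tot = (spec.n_ewas_loci * spec.ewas_variance
                   + spec.n_gwas_loci * spec.gwas_variance + spec.h2_poly)
            if tot > 1:
                raise ValueError(f"trait {name}: variance fractions sum to {tot} > 1")


@dataclass
class SyntheticTruth:
    """Registry of planted effects and latent states."""

    meqtl: pd.DataFrame          # snp_idx, site_idx, positions, effect, r2, label
    eqtl: pd.DataFrame
    eqtm: pd.DataFrame
    trait_loci: dict             # trait -> DataFrame of planted loci
    subpops: np.ndarray
    latent: EpiGenotypeMatrix | None = None


@dataclass
class Cohort:
    config: SimulationConfig
    genotypes: GenotypeMatrix
    counts: MethylationCountMatrix
    latent: EpiGenotypeMatrix
    expression: ExpressionMatrix
    phenotypes: pd.DataFrame
    truth: SyntheticTruth


def _accession_ids(n: int) -> list[str]:
    return [f"acc{i:04d}" for i in range(n)]


def simulate_genotypes(config: SimulationConfig, rng: np.random.Generator | None = None
                       ) -> tuple[GenotypeMatrix, np.ndarray]:
    """Founder-copying diploid genotypes with block LD and subpopulation
    structure. Returns (GenotypeMatrix, subpop labels)."""
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_accessions
    subpops = np.arange(n) % config.n_subpops
    rows, haps_all = [], []
    for chrom, length in config.chrom_lengths.items():
        m = config.n_snps_per_chrom
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=m, replace=False))
        anc = rng.uniform(0.05, 0.95, size=m)
        F = config.fst
        if F > 0 and config.n_subpops > 1:
            a = anc * (1 - F) / F
            b = (1 - anc) * (1 - F) / F
            sub_freq = np.stack([rng.beta(a, b) for _ in range(config.n_subpops)])
        else:
            sub_freq = np.tile(anc, (config.n_subpops, 1))
        founders = {
            s: (rng.random((config.n_founders, m)) < sub_freq[s]).astype(np.int8)
            for s in range(config.n_subpops)
        }
        gaps = np.diff(pos, prepend=pos[0])
        p_switch = 1.0 - np.exp(-config.switch_rate * gaps)
        p_switch[0] = 1.0
        haps = np.empty((2 * n, m), dtype=np.int8)
        for h in range(2 * n):
            s = subpops[h // 2]
            switch = rng.random(m) < p_switch
            seg = np.cumsum(switch) - 1
            founder_per_seg = rng.integers(0, config.n_founders, size=seg[-1] + 1)
            haps[h] = founders[s][founder_per_seg[seg], np.arange(m)]
        haps_all.append(haps)
        for p_ in pos:
            rows.append((chrom, int(p_), "A", "G"))
    H = np.concatenate(haps_all, axis=1)
    dosage = (H[0::2] + H[1::2]).T.astype(float)  # snps x accessions
    snps = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(snps, dosage, _accession_ids(n)), subpops


def _site_positions(config: SimulationConfig, rng: np.random.Generator, length: int,
                    n_sites: int) -> np.ndarray:
    """Clustered cytosine positions: short intra-cluster gaps with
    occasional long jumps, so close pairs exist at all MD-relevant
    distances."""
    p_jump = 1.0 / max(config.cluster_size_mean, 1.0)
    gaps = np.where(
        rng.random(n_sites) < p_jump,
        rng.exponential(config.cluster_jump_mean, n_sites),
        rng.exponential(config.intra_gap_mean, n_sites),
    )
    gaps = np.maximum(1, np.round(gaps)).astype(np.int64)
    pos = np.cumsum(gaps) + rng.integers(1, 1000)
    scale = length / max(pos[-1], length)
    if scale < 1.0:  # compress to fit, keeping >=1 bp gaps
        pos = np.maximum.accumulate(np.round(pos * scale).astype(np.int64)
                                    + np.arange(n_sites))
    return pos


def _effect_for_r2(r2: float, var_g: float, var_noise: float) -> float:
    """Slope giving a target variance-explained fraction against noise."""
    if not 0 < r2 < 1:
        raise ValueError("target R2 must be in (0, 1)")
    return float(np.sqrt(r2 / (1 - r2) * var_noise / max(var_g, 1e-12)))


def simulate_methylome(
    config: SimulationConfig,
    genotypes: GenotypeMatrix,
    rng: np.random.Generator | None = None,
) -> tuple[MethylationCountMatrix, EpiGenotypeMatrix, pd.DataFrame]:
    """Latent epi-states with spatial correlation and planted meQTLs, plus
    observed bisulfite counts. Returns (counts, latent truth, meQTL registry)."""
    rng = rng or np.random.default_rng(config.seed + 1)
    n = config.n_accessions
    lam = config.md_half_decay_bp
    eps = config.epsilon
    chrom_names = list(config.chrom_lengths)

    # -- site geometry ---------------------------------------------------
    site_rows = []
    for chrom, length in config.chrom_lengths.items():
        n_tot = sum(config.sites_per_chrom.values())
        pos = _site_positions(config, rng, length, n_tot)
        ctx = np.concatenate([
            np.repeat(c, k) for c, k in config.sites_per_chrom.items()
        ])
        rng.shuffle(ctx)
        strand = rng.choice(["+", "-"], size=n_tot)
        for p_, c_, s_ in zip(pos, ctx, strand):
            site_rows.append((chrom, int(p_), s_, c_))
    sites = (
        pd.DataFrame(site_rows, columns=["chrom", "pos", "strand", "context"])
        .sort_values(["chrom", "pos", "strand"], kind="mergesort")
        .reset_index(drop=True)
    )
    n_sites = len(sites)

    # -- per-site population M frequency --------------------------------
    p_m = np.empty(n_sites)
    for c, (a, b) in config.epi_freq_beta.items():
        mask = (sites["context"] == c).to_numpy()
        p_m[mask] = rng.beta(a, b, size=int(mask.sum()))
    p_m = np.clip(p_m, 1e-4, 1 - 1e-4)

    # -- planted meQTLs --------------------------------------------------
    meqtl_rows = []
    planted_effect = np.zeros(n_sites)       # slope on per-accession p_M
    planted_snp = np.full(n_sites, -1, dtype=np.int64)
    snp_chrom = genotypes.snps["chrom"].to_numpy()
    snp_pos = genotypes.snps["pos"].to_numpy()
    cg_idx = np.flatnonzero((sites["context"] == "CG").to_numpy())

    def _plant(site_idx: np.ndarray, snp_idx: np.ndarray, r2: float, label: str):
        for si, gi in zip(site_idx, snp_idx):
            g = genotypes.dosage[gi]
            var_g = np.nanvar(g)
            if var_g <= 0:
                continue
            # within-accession code variance at p=0.5 under HW is 2pq = 0.5;
            # between-accession signal variance is 4 a^2 Var(g)
            a = min(_effect_for_r2(r2, 4 * var_g, 0.5), 0.45)
            p_m[si] = 0.5
            planted_effect[si] = a
            planted_snp[si] = gi
            meqtl_rows.append({
                "snp_idx": gi, "site_idx": si,
                "snp_chrom": snp_chrom[gi], "snp_pos": int(snp_pos[gi]),
                "site_chrom": sites["chrom"].iloc[si],
                "site_pos": int(sites["pos"].iloc[si]),
                "effect": a, "r2_target": r2, "label": label,
            })

    if config.n_cis_meqtl > 0:
        chosen_sites = rng.choice(cg_idx, size=config.n_cis_meqtl, replace=False)
        chosen_snps = []
        mafs = genotypes.maf()
        for si in chosen_sites:
            chrom = sites["chrom"].iloc[si]
            p_site = sites["pos"].iloc[si]
            cand = np.flatnonzero(
                (snp_chrom == chrom)
                & (np.abs(snp_pos - p_site) <= 1_000_000)
                & (mafs >= 0.1)
            )
            chosen_snps.append(rng.choice(cand))
        _plant(chosen_sites, np.array(chosen_snps), config.cis_meqtl_r2, "cis")

    if config.n_trans_targets > 0 and len(chrom_names) >= 2:
        mafs = genotypes.maf()
        hot = rng.choice(np.flatnonzero((snp_chrom == chrom_names[1]) & (mafs >= 0.2)))
        remaining = np.setdiff1d(
            cg_idx[sites["chrom"].iloc[cg_idx] == chrom_names[0]],
            np.flatnonzero(planted_effect != 0),
        )
        tgt = rng.choice(remaining, size=config.n_trans_targets, replace=False)
        _plant(tgt, np.full(len(tgt), hot), config.trans_r2, "trans")

    # -- latent states via the uniform-copula chain ----------------------
    codes = np.empty((n_sites, n), dtype=np.int8)
    chroms_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    # chain retention scale: exp(-d/lam_eff) per-accession retention gives
    # squared code correlation ~ 2^(-d/lam) between same-frequency sites;
    # the 0.8 factor calibrates the *measured* half-decay (common SMPs,
    # finite cohort, binned crossing estimator) to md_half_decay_bp
    lam_eff = 2.0 * (0.8 * lam) / np.log(2.0)
    u = rng.random(n)
    for i in range(n_sites):
        first = i == 0 or chroms_arr[i] != chroms_arr[i - 1]
        planted = planted_effect[i] != 0
        if first or planted:
            refresh = np.ones(n, dtype=bool)
        else:
            gap = pos_arr[i] - pos_arr[i - 1]
            keep_p = np.exp(-gap / lam_eff)
            refresh = rng.random(n) >= keep_p
        if refresh.any():
            u = u.copy()
            u[refresh] = rng.random(int(refresh.sum()))
        if planted:
            g = genotypes.dosage[planted_snp[i]]
            g = np.where(np.isfinite(g), g, np.nanmean(g))
            p_i = np.clip(p_m[i] + planted_effect[i] * (g - np.nanmean(g)), 0.02, 0.98)
        else:
            p_i = np.full(n, p_m[i])
        q_i = 1.0 - p_i
        t_uu = q_i * q_i
        t_mu = t_uu + 2.0 * p_i * q_i
        codes[i] = (u >= t_uu).astype(np.int8) + (u >= t_mu).astype(np.int8)

    # -- observed counts -------------------------------------------------
    if config.depth_dispersion > 0:
        shape = 1.0 / config.depth_dispersion
        lam_d = rng.gamma(shape, config.mean_depth / shape, size=(n_sites, n))
        depth = rng.poisson(lam_d)
    else:
        depth = rng.poisson(config.mean_depth, size=(n_sites, n))
    mu = np.choose(codes, [eps, 0.5, 1.0 - eps])
    meth = rng.binomial(depth, mu)
    counts = MethylationCountMatrix(sites.copy(), meth, depth, _accession_ids(n))
    latent = EpiGenotypeMatrix(sites.copy(), codes, _accession_ids(n))
    meqtl = pd.DataFrame(meqtl_rows, columns=[
        "snp_idx", "site_idx", "snp_chrom", "snp_pos",
        "site_chrom", "site_pos", "effect", "r2_target", "label",
    ])
    return counts, latent, meqtl


def simulate_expression(
    config: SimulationConfig,
    genotypes: GenotypeMatrix,
    latent: EpiGenotypeMatrix,
    meqtl_truth: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Log-normal expression with planted eQTL and eQTM effects.

    Returns (expression, eQTL registry, eQTM registry). A configurable
    share of planted eQTMs reuses cis-meQTL target sites, so the
    downstream regulatory typing has genuine type-I and type-III genes.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    n = config.n_accessions
    rows = []
    gid = 0
    for chrom, length in config.chrom_lengths.items():
        starts = np.sort(rng.choice(
            np.arange(1, max(2, length - config.gene_length)),
            size=config.n_genes_per_chrom, replace=False))
        for s in starts:
            rows.append((f"gene{gid:04d}", chrom, int(s),
                         int(s + config.gene_length - 1),
                         rng.choice(["+", "-"])))
            gid += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    g_mid = ((genes["start"] + genes["end"]) // 2).to_numpy()
    g_chrom = genes["chrom"].to_numpy()
    n_genes = len(genes)

    log_expr = rng.normal(3.0, 1.0, size=n_genes)[:, None] + \
        rng.normal(0.0, config.expr_noise_sd, size=(n_genes, n))

    snp_chrom = genotypes.snps["chrom"].to_numpy()
    snp_pos = genotypes.snps["pos"].to_numpy()
    mafs = genotypes.maf()
    site_chrom = latent.sites["chrom"].to_numpy()
    site_pos = latent.sites["pos"].to_numpy()
    site_maf = latent.maf()

    free_genes = list(rng.permutation(n_genes))
    eqtl_rows = []
    for _ in range(config.n_eqtl):
        gi = free_genes.pop()
        cand = np.flatnonzero(
            (snp_chrom == g_chrom[gi])
            & (np.abs(snp_pos - g_mid[gi]) <= 1_000_000)
            & (mafs >= 0.1)
        )
        if cand.size == 0:
            continue
        mi = rng.choice(cand)
        g = genotypes.dosage[mi]
        g = np.where(np.isfinite(g), g, np.nanmean(g))
        b = _effect_for_r2(config.eqtl_r2, g.var(), config.expr_noise_sd**2)
        log_expr[gi] += b * (g - g.mean())
        eqtl_rows.append({"gene_id": genes["gene_id"].iloc[gi], "gene_idx": gi,
                          "snp_idx": mi, "chrom": snp_chrom[mi],
                          "pos": int(snp_pos[mi]), "effect": b,
                          "r2_target": config.eqtl_r2})

    eqtm_rows = []
    n_genetic = int(round(config.n_eqtm * config.eqtm_genetic_fraction))
    if len(meqtl_truth):
        meqtl_sites = meqtl_truth.loc[meqtl_truth["label"] == "cis", "site_idx"].to_numpy()
        trans_sites = meqtl_truth.loc[meqtl_truth["label"] == "trans", "site_idx"].to_numpy()
    else:
        meqtl_sites = np.array([], dtype=int)
        trans_sites = np.array([], dtype=int)
    for k in range(config.n_eqtm):
        gi = free_genes.pop()
        use_genetic = k < n_genetic and meqtl_sites.size > 0
        if use_genetic:
            cand = meqtl_sites[
                (site_chrom[meqtl_sites] == g_chrom[gi])
                & (np.abs(site_pos[meqtl_sites] - g_mid[gi]) <= 1_000_000)
            ]
            if cand.size == 0:
                cand = meqtl_sites  # fall back to any planted site
        else:
            cand = np.flatnonzero(
                (site_chrom == g_chrom[gi])
                & (np.abs(site_pos - g_mid[gi]) <= 1_000_000)
                & (site_maf >= 0.15)
            )
            cand = np.setdiff1d(cand, np.concatenate([meqtl_sites, trans_sites]))
        if cand.size == 0:
            continue
        si = rng.choice(cand)
        m = latent.codes[si].astype(float)
        b = _effect_for_r2(config.eqtm_r2, m.var(), config.expr_noise_sd**2)
        log_expr[gi] += b * (m - m.mean())
        if si in meqtl_sites:
            expected_type = "I"
        elif si in trans_sites:
            expected_type = "II"
        else:
            expected_type = "III"
        eqtm_rows.append({"gene_id": genes["gene_id"].iloc[gi], "gene_idx": gi,
                          "site_idx": int(si), "chrom": site_chrom[si],
                          "pos": int(site_pos[si]), "effect": b,
                          "r2_target": config.eqtm_r2,
                          "expected_type": expected_type})

    fpkm = np.exp(log_expr - 3.0)  # centered scale, FPKM-like magnitudes
    n_zero = int(config.zero_gene_fraction * n_genes)
    if n_zero:
        zero_idx = rng.choice(n_genes, size=n_zero, replace=False)
        fpkm[zero_idx] = 0.0
    expr = ExpressionMatrix(genes, fpkm, _accession_ids(n))
    return (expr,
            pd.DataFrame(eqtl_rows, columns=["gene_id", "gene_idx", "snp_idx",
                                             "chrom", "pos", "effect", "r2_target"]),
            pd.DataFrame(eqtm_rows, columns=["gene_id", "gene_idx", "site_idx",
                                             "chrom", "pos", "effect", "r2_target",
                                             "expected_type"]))


def simulate_phenotypes(
    config: SimulationConfig,
    genotypes: GenotypeMatrix,
    latent: EpiGenotypeMatrix,
    subpops: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Traits from planted SMP/SNP effects + polygenic + noise at the
    configured variance fractions. Returns (phenotypes, per-trait truth)."""
    rng = rng or np.random.default_rng(config.seed + 3)
    n = config.n_accessions
    from .association import compute_kinship

    K = compute_kinship(genotypes.dosage.T)
    lamK, UK = np.linalg.eigh(K)
    A = UK * np.sqrt(np.maximum(lamK, 0))
    site_maf = latent.maf()
    mafs = genotypes.maf()
    cols, truth = {}, {}
    for name, spec in config.traits.items():
        y = np.zeros(n)
        loci_rows = []
        cand_sites = np.flatnonzero(
            (latent.sites["context"] == "CG").to_numpy() & (site_maf >= 0.2))
        chosen = rng.choice(cand_sites, size=spec.n_ewas_loci, replace=False) \
            if spec.n_ewas_loci else np.array([], dtype=int)
        for si in chosen:
            x = latent.codes[si].astype(float)
            xs = (x - x.mean()) / x.std()
            y += np.sqrt(spec.ewas_variance) * xs
            loci_rows.append({"kind": "ewas", "idx": int(si),
                              "chrom": latent.sites["chrom"].iloc[si],
                              "pos": int(latent.sites["pos"].iloc[si]),
                              "variance": spec.ewas_variance})
        chosen_snps = rng.choice(np.flatnonzero(mafs >= 0.2),
                                 size=spec.n_gwas_loci, replace=False) \
            if spec.n_gwas_loci else np.array([], dtype=int)
        for gi in chosen_snps:
            g = genotypes.dosage[gi]
            g = np.where(np.isfinite(g), g, np.nanmean(g))
            gs = (g - g.mean()) / g.std()
            y += np.sqrt(spec.gwas_variance) * gs
            loci_rows.append({"kind": "gwas", "idx": int(gi),
                              "chrom": genotypes.snps["chrom"].iloc[gi],
                              "pos": int(genotypes.snps["pos"].iloc[gi]),
                              "variance": spec.gwas_variance})
        if spec.h2_poly > 0:
            u = A @ rng.normal(size=n)
            y += np.sqrt(spec.h2_poly) * (u - u.mean()) / u.std()
        v_resid = 1.0 - spec.n_ewas_loci * spec.ewas_variance \
            - spec.n_gwas_loci * spec.gwas_variance - spec.h2_poly
        y += np.sqrt(max(v_resid, 0.0)) * rng.normal(size=n)
        if spec.subpop_shift != 0 and config.n_subpops > 1:
            z = (subpops == 0).astype(float)
            y += spec.subpop_shift * (z - z.mean()) / z.std()
        cols[name] = y
        truth[name] = pd.DataFrame(loci_rows,
                                   columns=["kind", "idx", "chrom", "pos", "variance"])
    pheno = pd.DataFrame(cols, index=_accession_ids(n))
    return pheno, truth


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate the full cohort deterministically from ``config.seed``."""
    rng_g = np.random.default_rng(config.seed)
    genotypes, subpops = simulate_genotypes(config, rng_g)
    counts, latent, meqtl = simulate_methylome(
        config, genotypes, np.random.default_rng(config.seed + 1))
    expr, eqtl, eqtm = simulate_expression(
        config, genotypes, latent, meqtl, np.random.default_rng(config.seed + 2))
    pheno, trait_loci = simulate_phenotypes(
        config, genotypes, latent, subpops, np.random.default_rng(config.seed + 3))
    truth = SyntheticTruth(meqtl=meqtl, eqtl=eqtl, eqtm=eqtm,
                           trait_loci=trait_loci, subpops=subpops, latent=latent)
    return Cohort(config, genotypes, counts, latent, expr, pheno, truth)


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Emit the cohort in the formats the readers ingest: per-accession
    cytosine reports, VCF, expression/phenotype TSV, gene GFF3, truth TSVs."""
    out = Path(outdir)
    (out / "reports").mkdir(parents=True, exist_ok=True)
    for acc in cohort.counts.accessions:
        pio.write_cytosine_report(cohort.counts, acc, out / "reports" / f"{acc}.CX_report.txt")
    pio.write_vcf(cohort.genotypes, out / "genotypes.vcf")
    pio.write_expression_tsv(cohort.expression, out / "expression.tsv")
    pio.write_phenotypes(cohort.phenotypes, out / "phenotypes.tsv")
    with open(out / "genes.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in cohort.expression.genes.iterrows():
            fh.write(f"{g['chrom']}\tsim\tgene\t{g['start']}\t{g['end']}\t.\t"
                     f"{g['strand']}\t.\tID={g['gene_id']}\n")
    cohort.truth.meqtl.to_csv(out / "truth_meqtl.tsv", sep="\t", index=False)
    cohort.truth.eqtl.to_csv(out / "truth_eqtl.tsv", sep="\t", index=False)
    cohort.truth.eqtm.to_csv(out / "truth_eqtm.tsv", sep="\t", index=False)
    for name, df in cohort.truth.trait_loci.items():
        df.to_csv(out / f"truth_trait_{name}.tsv", sep="\t", index=False)


def evaluate_recovery(
    discovered: pd.DataFrame,
    truth: pd.DataFrame,
    distance_tolerance_bp: int = 0,
    match_target: bool = False,
) -> dict:
    """Score a discovery list against planted truth.

    A discovery matches a planted effect if on the same chromosome within
    the tolerance (and, optionally, for the same target). Returns power,
    empirical FDR, counts, and the mean relative bias of effect sizes
    where both ``beta`` (discovered) and ``effect`` (truth) are present.
    """
    n_truth = len(truth)
    n_disc = len(discovered)
    if n_truth == 0:
        return {"power": np.nan, "fdr": 0.0 if n_disc == 0 else 1.0,
                "n_truth": 0, "n_discovered": n_disc, "effect_bias": np.nan}
    if n_disc == 0:
        return {"power": 0.0, "fdr": 0.0, "n_truth": n_truth,
                "n_discovered": 0, "effect_bias": np.nan}
    t_chrom = truth["chrom"].to_numpy()
    t_pos = truth["pos"].to_numpy()
    d_chrom = discovered["chrom"].to_numpy()
    d_pos = discovered["pos"].to_numpy()
    same_target = np.ones((n_disc, n_truth), dtype=bool)
    if match_target:
        same_target = (discovered["target_id"].to_numpy()[:, None]
                       == truth["target_id"].to_numpy()[None, :])
    match = (
        (d_chrom[:, None] == t_chrom[None, :])
        & (np.abs(d_pos[:, None] - t_pos[None, :]) <= distance_tolerance_bp)
        & same_target
    )
    power = float(match.any(axis=0).mean())
    fdr = float((~match.any(axis=1)).mean())
    bias = np.nan
    if "beta" in discovered.columns and "effect" in truth.columns:
        pairs = np.argwhere(match)
        if len(pairs):
            b_hat = np.abs(discovered["beta"].to_numpy()[pairs[:, 0]])
            b_true = np.abs(truth["effect"].to_numpy()[pairs[:, 1]])
            bias = float(np.mean((b_hat - b_true) / np.where(b_true > 0, b_true, np.nan)))
    return {"power": power, "fdr": fdr, "n_truth": n_truth,
            "n_discovered": n_disc, "effect_bias": bias}
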