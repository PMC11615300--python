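"""Self-contained calibration experiments for the whole pipeline.

Each function regenerates its inputs from a seed, runs the relevant part
of the package, and returns measured quantities (errors, rates, power,
FDR, decay distances, prediction accuracy). They back both the
acceptance test suite and ``scripts/acceptance.py``.

Problem sizes are desk-scale by design: cohorts of 300-500 accessions
over a few hundred kilobases with a few thousand cytosines — large
enough for stable rates, small enough to run in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .association import (
    EmmaNull,
    compute_kinship,
    lambda_gc,
    permutation_empirical_p,
    quantile_normalize,
    structure_pcs,
)
from .containers import EpiGenotypeMatrix, MethylationCountMatrix
from .integrate import classify_eqtm_genes, gblup_predict
from .md import composite_md, em_md, md_decay, mr2_from_haplotype_counts
from .pipelines import ScanConfig, map_cis_meqtl, map_eqtm, run_ewas
from .simulate import (
    SimulationConfig,
    TraitSpec,
    evaluate_recovery,
    simulate_cohort,
    simulate_genotypes,
)
from .smp import (
    call_epi_alleles,
    compute_levels,
    filter_sites,
    region_methylation,
    site_maf_spectrum,
)


# ---------------------------------------------------------------------------
# 1. formula oracles

def formula_checks(n_haplotypes: int = 10) -> dict:
    """Exactness of the MD/Mr2 and region-methylation formulas.

    Enumerates every epi-haplotype count table over ``n_haplotypes``
    haplotypes and compares (a) the haplotype-table statistic against an
    inline evaluation of MD^2/(p_M1 p_U1 p_M2 p_U2) and (b) the composite
    and EM estimators on the equivalent duplicated-haplotype codes, which
    must reduce to the same value. Also checks the weighted region
    methylation example and the epi-allele boundary calls.
    """
    max_err_formula = 0.0
    max_err_composite = 0.0
    max_err_em = 0.0
    n_tables = 0
    for n_mm in range(n_haplotypes + 1):
        for n_mu in range(n_haplotypes + 1 - n_mm):
            for n_um in range(n_haplotypes + 1 - n_mm - n_mu):
                n_uu = n_haplotypes - n_mm - n_mu - n_um
                res = mr2_from_haplotype_counts(n_mm, n_mu, n_um, n_uu)
                # independent hand evaluation
                p1 = (n_mm + n_mu) / n_haplotypes
                p2 = (n_mm + n_um) / n_haplotypes
                md = n_mm / n_haplotypes - p1 * p2
                denom = p1 * (1 - p1) * p2 * (1 - p2)
                if denom <= 0:
                    continue
                n_tables += 1
                expect = md * md / denom
                max_err_formula = max(max_err_formula, abs(res.mr2 - expect))
                # duplicated-haplotype codes (no heterozygotes)
                x = np.repeat([2, 2, 0, 0], [n_mm, n_mu, n_um, n_uu]).astype(np.int8)
                y = np.repeat([2, 0, 2, 0], [n_mm, n_mu, n_um, n_uu]).astype(np.int8)
                _, _, _, mr2_c, _ = composite_md(x, y)
                _, _, _, mr2_e, _ = em_md(x, y)
                max_err_composite = max(max_err_composite, abs(mr2_c - expect))
                max_err_em = max(max_err_em, abs(mr2_e - expect))
    # weighted region methylation: C=[3,0,5], T=[1,4,0] -> 8/13
    sites = pd.DataFrame({
        "chrom": ["chr1"] * 3, "pos": [10, 20, 30],
        "strand": ["+"] * 3, "context": ["CG"] * 3,
    })
    counts = MethylationCountMatrix(
        sites, np.array([[3], [0], [5]]), np.array([[4], [4], [5]]), ["a"])
    region_err = abs(region_methylation(counts, "chr1", 1, 100, "a") - 8.0 / 13.0)
    # boundary calls
    from .containers import MethylationLevelMatrix
    lv = MethylationLevelMatrix(
        sites.iloc[:1], np.array([[0.0, 0.3, 0.5, 0.7, 0.85, 1.0]]),
        [f"a{i}" for i in range(6)],
    )
    codes = call_epi_alleles(lv).codes[0]
    boundary_ok = list(codes) == [0, 0, 1, 1, 2, 2]
    return {
        "n_tables": n_tables,
        "mr2_formula_max_error": max_err_formula,
        "mr2_composite_max_error": max_err_composite,
        "mr2_em_max_error": max_err_em,
        "region_methylation_error": float(region_err),
        "boundary_calls_correct": bool(boundary_ok),
    }


# ---------------------------------------------------------------------------
# 2. statistical-engine calibration

def _structured_genotypes(seed: int, n: int = 300, n_chrom: int = 5,
                          snps_per_chrom: int = 800):
    cfg = SimulationConfig(
        seed=seed, n_accessions=n,
        chrom_lengths={f"chr{i}": 500_000 for i in range(1, n_chrom + 1)},
        n_snps_per_chrom=snps_per_chrom,
    )
    return simulate_genotypes(cfg)


def engine_calibration(seed: int = 7, n: int = 300, n_null_phenos: int = 3) -> dict:
    """Mixed-model engine against its analytic and Monte-Carlo oracles.

    (a) with K = I the scan must match OLS t-test p-values;
    (b) on null polygenic phenotypes over a structured cohort, type-I
    error at alpha = 0.05 and genomic-control lambda with the kinship+PC
    correction (and without it, as the positive control).
    """
    rng = np.random.default_rng(seed)
    # (a) OLS equivalence
    n_small, m_small = 120, 40
    G = rng.integers(0, 3, (n_small, m_small)).astype(float)
    y = rng.normal(size=n_small)
    scan = EmmaNull(np.eye(n_small)).fit(y).scan(G)
    max_dp = 0.0
    for j in range(m_small):
        X = np.column_stack([np.ones(n_small), G[:, j]])
        bh = np.linalg.solve(X.T @ X, X.T @ y)
        r = y - X @ bh
        s2 = r @ r / (n_small - 2)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        p_ols = 2 * stats.t.sf(abs(bh[1] / se), n_small - 2)
        max_dp = max(max_dp, abs(p_ols - scan["p"].iloc[j]))
    # (b) null calibration on a structured cohort
    geno, _ = _structured_genotypes(seed + 1, n=n)
    X = geno.dosage.T
    K = compute_kinship(X)
    pcs = structure_pcs(X, 3)
    lamK, UK = np.linalg.eigh(K)
    lam_c, lam_u, hits, m_tests = [], [], 0, 0
    for rep in range(n_null_phenos):
        u = UK @ (np.sqrt(np.maximum(lamK, 0)) * rng.normal(size=n))
        yp = np.sqrt(0.5) * u / u.std() + np.sqrt(0.5) * rng.normal(size=n)
        yp = quantile_normalize(yp)
        p_c = EmmaNull(K, pcs).fit(yp).scan(X)["p"].to_numpy()
        p_u = EmmaNull(np.eye(n)).fit(yp).scan(X)["p"].to_numpy()
        lam_c.append(lambda_gc(p_c))
        lam_u.append(lambda_gc(p_u))
        hits += int(np.sum(p_c <= 0.05))
        m_tests += p_c.size
    return {
        "lmm_vs_ols_max_p_diff": float(max_dp),
        "type_i_error": hits / m_tests,
        "n_null_tests": m_tests,
        "lambda_corrected": float(np.mean(lam_c)),
        "lambda_uncorrected": float(np.mean(lam_u)),
    }


# ---------------------------------------------------------------------------
# 3. permutation null

def permutation_calibration(seed: int = 7, n_reps: int = 200,
                            n_perm: int = 200) -> dict:
    """Empirical p-values under permuted phenotypes must be uniform, and
    a fixed seed must reproduce bit-identical output."""
    geno, _ = _structured_genotypes(seed, n=300, n_chrom=2, snps_per_chrom=400)
    X = geno.dosage.T
    K = compute_kinship(X)
    null = EmmaNull(K, structure_pcs(X, 3))
    rng = np.random.default_rng(seed + 1)
    emp = []
    for rep in range(n_reps):
        y = rng.permutation(quantile_normalize(rng.normal(size=300)))
        fitted = null.fit(y)
        res = permutation_empirical_p(fitted, X[:, :20], n_perm=n_perm,
                                      seed=rep, beta_approx=False)
        emp.append(res["p_empirical"])
    ks = stats.kstest(emp, "uniform")
    fitted = null.fit(quantile_normalize(rng.normal(size=300)))
    a = permutation_empirical_p(fitted, X[:, :50], n_perm=500, seed=1234)
    b = permutation_empirical_p(fitted, X[:, :50], n_perm=500, seed=1234)
    return {
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "n_reps": n_reps,
        "bit_identical": a == b,
    }


# ---------------------------------------------------------------------------
# 4. end-to-end recovery on a planted cohort

def _recovery_config(seed: int, n_cis: int = 200) -> SimulationConfig:
    return SimulationConfig(
        seed=seed, n_accessions=300,
        chrom_lengths={"chr1": 800_000, "chr2": 800_000},
        n_snps_per_chrom=500,
        sites_per_chrom={"CG": 900, "CHG": 400, "CHH": 700},
        n_cis_meqtl=n_cis, cis_meqtl_r2=0.30,
        n_eqtm=40, eqtm_r2=0.20, n_genes_per_chrom=60,
        traits={"LP": TraitSpec(n_ewas_loci=1, ewas_variance=0.05, h2_poly=0.40)},
    )


def endtoend_recovery(seed: int = 7, n_perm: int = 300,
                      n_ewas_reps: int = 16) -> dict:
    """Planted-effect recovery through the real pipelines.

    One cohort (n = 300) with 200 planted cis-meQTLs (R^2 = 0.3) and 40
    planted eQTMs (R^2 = 0.2, half on cis-meQTL target sites) is scanned
    by map_cis_meqtl and map_eqtm; regulatory typing is scored against
    the planted architecture. EWAS power for a 5%-variance locus is
    measured over ``n_ewas_reps`` fresh cohorts at the per-context
    effective-test threshold, using the genotype-derived kinship.
    """
    cohort = simulate_cohort(_recovery_config(seed))
    epi = call_epi_alleles(compute_levels(cohort.counts, 5))
    sc = ScanConfig(seed=seed, n_perm=n_perm)

    # --- cis-meQTL
    cis = map_cis_meqtl(cohort.genotypes, epi, sc)
    sig = cis.leads[cis.leads["significant"]].copy()
    sig["chrom"] = [t.split(":")[0] for t in sig["target_id"]]
    sig["pos"] = [int(t.split(":")[1]) for t in sig["target_id"]]
    truth_cis = cohort.truth.meqtl.rename(
        columns={"site_chrom": "chrom", "site_pos": "pos"})
    # an SMP within 200 bp shares the planted site's MD block
    m_cis = evaluate_recovery(sig, truth_cis, distance_tolerance_bp=200)

    # --- eQTM
    eq = map_eqtm(epi, cohort.expression, sc)
    sig_eq = eq.leads[eq.leads["significant"]].copy()
    sig_eq["chrom"] = sig_eq["marker_chrom"]
    sig_eq["pos"] = sig_eq["marker_pos"]
    truth_eq = cohort.truth.eqtm.rename(columns={"gene_id": "target_id"})
    m_eq = evaluate_recovery(sig_eq, truth_eq,
                             distance_tolerance_bp=1_000_000, match_target=True)

    # --- regulatory typing against the planted architecture
    site_key = {(r.chrom, r.pos, r.strand): i
                for i, r in enumerate(epi.sites.itertuples())}

    def _global_idx(sub: EpiGenotypeMatrix, local: int) -> int:
        row = sub.sites.iloc[local]
        return site_key[(row["chrom"], row["pos"], row["strand"])]

    meqtl_evidence = pd.DataFrame([
        {"site_idx": _global_idx(cis.meta["common_sites"], int(r["site_idx"])),
         "label": "cis"}
        for _, r in sig.iterrows()
    ], columns=["site_idx", "label"])
    common_eq = eq.meta["common_sites"]
    eqtm_leads = pd.DataFrame({
        "gene_id": sig_eq["target_id"].to_numpy(),
        "site_idx": [_global_idx(common_eq, int(i)) for i in sig_eq["marker_idx"]],
    })
    typed = classify_eqtm_genes(eqtm_leads, meqtl_evidence)
    expected = cohort.truth.eqtm.set_index("gene_id")["expected_type"]
    overlap = typed[typed["gene_id"].isin(expected.index)]
    typing_acc = float(np.mean([
        expected[g] == t for g, t in zip(overlap["gene_id"], overlap["type"])
    ])) if len(overlap) else np.nan

    # --- EWAS power over replicate cohorts
    ewas_hits, ewas_false, ewas_loci = 0, 0, 0
    for rep in range(n_ewas_reps):
        cfg = _recovery_config(seed * 1000 + rep, n_cis=0)
        c = simulate_cohort(cfg)
        e = call_epi_alleles(compute_levels(c.counts, 5))
        _, common = site_maf_spectrum(e, 0.05)
        ew = run_ewas(common, c.phenotypes, ScanConfig(seed=rep),
                      contexts=("CG",), kinship_source=c.genotypes)
        planted = c.truth.trait_loci["LP"]
        pp, pc = int(planted["pos"].iloc[0]), planted["chrom"].iloc[0]
        near = (ew.loci["chrom"] == pc) & (abs(ew.loci["lead_pos"] - pp) <= 10_000)
        ewas_hits += int(near.any())
        ewas_false += int((~near).sum())
        ewas_loci += len(ew.loci)
    return {
        "cis_meqtl_power": m_cis["power"],
        "cis_meqtl_fdr": m_cis["fdr"],
        "cis_meqtl_n_planted": m_cis["n_truth"],
        "eqtm_power": m_eq["power"],
        "eqtm_fdr": m_eq["fdr"],
        "eqtm_n_planted": m_eq["n_truth"],
        "typing_accuracy": typing_acc,
        "typing_n": int(len(overlap)),
        "ewas_power": ewas_hits / n_ewas_reps,
        "ewas_n_reps": n_ewas_reps,
        "ewas_false_loci": ewas_false,
    }


# ---------------------------------------------------------------------------
# 5. MD decay round-trip

def md_roundtrip(seed: int = 7) -> dict:
    """Simulator lambda = 50 bp -> measured Mr^2 half-decay distance,
    through the full calling pipeline (counts -> levels -> epi-alleles ->
    common SMPs), as the decay analysis is defined on variant sites."""
    cfg = SimulationConfig(
        seed=seed, n_accessions=300,
        chrom_lengths={"chr1": 1_800_000},
        n_snps_per_chrom=100,
        sites_per_chrom={"CG": 6000, "CHG": 500, "CHH": 500},
        md_half_decay_bp=50.0,
    )
    cohort = simulate_cohort(cfg)
    epi = call_epi_alleles(compute_levels(cohort.counts, 5))
    _, common = site_maf_spectrum(epi, 0.05)
    prof = md_decay(common, max_distance=1500, bin_width=10, context="CG",
                    seed=seed)
    return {
        "half_decay_bp": float(prof.half_decay_bp),
        "n_pairs": prof.n_pairs_total,
        "lambda_configured": cfg.md_half_decay_bp,
    }


# ---------------------------------------------------------------------------
# 6. GBLUP sanity

def gblup_calibration(seed: int = 7, n: int = 500, n_null: int = 8,
                      n_h2: int = 3, cv_folds: int = 5) -> dict:
    """Cross-validated GBLUP accuracy on marker-tagged traits.

    The benchmark population is a highly related germplasm panel (8
    founders per subpopulation, ~100 kb copying segments — long-LD, as in
    dense cultivar collections) so the expected BLUP accuracy
    sqrt(h^2 n/(n + Me)) sits well above chance. h^2 = 0.5 traits (200
    causal SNPs among the genotyped markers) must predict with PCC well
    above chance; h^2 = 0 traits must average near zero; and a (1, 0)
    kinship weight vector must reproduce the single-kinship result
    bit-exactly. PCC is fold-averaged.
    """
    cfg = SimulationConfig(
        seed=seed, n_accessions=n, n_founders=8, switch_rate=1e-5,
        chrom_lengths={f"chr{i}": 500_000 for i in range(1, 5)},
        n_snps_per_chrom=400,
    )
    geno, _ = simulate_genotypes(cfg)
    X = geno.dosage.T
    K = compute_kinship(X)
    K2 = compute_kinship(X[:, ::2])
    rng = np.random.default_rng(seed + 1)
    pcc_h2 = []
    for rep in range(n_h2):
        causal = rng.choice(X.shape[1], 200, replace=False)
        b = rng.normal(size=200)
        g = (X[:, causal] - X[:, causal].mean(0)) @ b
        y = np.sqrt(0.5) * (g - g.mean()) / g.std() + np.sqrt(0.5) * rng.normal(size=n)
        pcc_h2.append(gblup_predict({"snp": K}, {"snp": 1.0}, y,
                                    cv_folds=cv_folds, seed=rep)["pcc_fold_mean"])
    pcc_null = [
        gblup_predict({"snp": K}, {"snp": 1.0}, rng.normal(size=n),
                      cv_folds=cv_folds, seed=rep)["pcc_fold_mean"]
        for rep in range(n_null)
    ]
    y = np.sqrt(0.5) * rng.normal(size=n) + np.sqrt(0.5) * rng.normal(size=n)
    single = gblup_predict({"snp": K}, {"snp": 1.0}, y, cv_folds=cv_folds, seed=0)
    combo = gblup_predict({"snp": K, "smp": K2}, {"snp": 1.0, "smp": 0.0}, y,
                          cv_folds=cv_folds, seed=0)
    return {
        "pcc_h2_50_mean": float(np.mean(pcc_h2)),
        "pcc_h2_50_all": [float(v) for v in pcc_h2],
        "pcc_null_mean": float(np.mean(pcc_null)),
        "pcc_null_mean_abs": float(abs(np.mean(pcc_null))),
        "n_null_traits": n_null,
        "weights_bit_exact": bool(np.array_equal(
            single["predictions"], combo["predictions"], equal_nan=True)),
    }


# ---------------------------------------------------------------------------
# 7. filter bookkeeping

def filter_bookkeeping(seed: int = 7) -> dict:
    """A 100-site fixture with designed rule hits: 17 sites failing the
    missingness rule, 3 (disjoint) on SNP positions -> 80 retained."""
    rng = np.random.default_rng(seed)
    n_sites, n_acc = 100, 40
    sites = pd.DataFrame({
        "chrom": ["chr1"] * n_sites,
        "pos": np.arange(1, n_sites + 1) * 100,
        "strand": ["+"] * n_sites,
        "context": ["CG"] * n_sites,
    })
    levels = rng.uniform(0, 1, size=(n_sites, n_acc))
    order = rng.permutation(n_sites)
    fail_missing = order[:17]
    on_snp = order[17:20]
    for i in fail_missing:  # missing in >30% of accessions
        k = int(np.ceil(0.30 * n_acc)) + 1
        levels[i, rng.choice(n_acc, size=k, replace=False)] = np.nan
    from .containers import MethylationLevelMatrix

    lm = MethylationLevelMatrix(sites, levels, [f"a{i}" for i in range(n_acc)])
    snp_positions = [("chr1", int(sites["pos"].iloc[i])) for i in on_snp]
    filtered, report = filter_sites(lm, 0.30, snp_positions)
    return {
        "n_input": report.n_input,
        "n_removed_missing": report.n_removed_missing,
        "n_removed_snp": report.n_removed_snp,
        "n_retained": report.n_retained,
        "expected_retained": 80,
        "attribution_correct": (report.n_removed_missing == 17
                                and report.n_removed_snp == 3
                                and report.n_retained == 80),
    }
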