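"""Regulatory typing, co-localization, GRN, pyramiding, GBLUP."""

import numpy as np
import pandas as pd
import pytest

from popepigen.containers import EpiGenotypeMatrix
from popepigen.integrate import (
    GBLUP,
    build_grn,
    classify_eqtm_genes,
    colocalize_ewas_gwas,
    combine_kinships,
    edges_to_graphml,
    exclude_markers_near_loci,
    gblup_predict,
    jonckheere_terpstra,
    network_overlap,
    pyramiding_analysis,
)


class TestTyping:
    def _meqtl(self):
        return pd.DataFrame({"site_idx": [1, 2], "label": ["cis", "trans"]})

    def test_three_types(self):
        eqtm = pd.DataFrame({"gene_id": ["g1", "g2", "g3"],
                             "site_idx": [1, 2, 3]})
        typed = classify_eqtm_genes(eqtm, self._meqtl())
        assert list(typed["type"]) == ["I", "II", "III"]

    def test_untested_site_unclassified(self):
        eqtm = pd.DataFrame({"gene_id": ["g1"], "site_idx": [9]})
        typed = classify_eqtm_genes(eqtm, self._meqtl(), tested_sites={1, 2})
        assert typed["type"].iloc[0] == "unclassified"

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        eqtm = pd.DataFrame({"gene_id": [f"g{i}" for i in range(50)],
                             "site_idx": rng.integers(0, 20, 50)})
        typed = classify_eqtm_genes(eqtm, self._meqtl(), tested_sites=set(range(10)))
        counts = typed["type"].value_counts()
        assert counts.sum() == 50
        assert set(counts.index) <= {"I", "II", "III", "unclassified"}


class TestColocalize:
    def _loci(self):
        ewas = pd.DataFrame({"trait": ["LP", "LP"], "chrom": ["chr1", "chr1"],
                             "pos": [100_000, 500_000],
                             "lead_site_idx": [1, 2]})
        gwas = pd.DataFrame({"trait": ["LP"], "chrom": ["chr1"], "pos": [110_000]})
        return ewas, gwas

    def test_distance_rule(self):
        ewas, gwas = self._loci()
        out = colocalize_ewas_gwas(ewas, gwas, distance_bp=20_000)
        e = out[out["source"] == "EWAS"]
        assert list(e["shared"]) == [True, False]  # 10 kb vs 390 kb
        assert e["class"].iloc[1] == "epigenetic_only"

    def test_identical_position_shared(self):
        ewas, gwas = self._loci()
        gwas.loc[0, "pos"] = 100_000
        out = colocalize_ewas_gwas(ewas, gwas)
        assert out[out["source"] == "EWAS"]["shared"].iloc[0]

    def test_meqtl_evidence_typing(self):
        ewas, gwas = self._loci()
        meqtl = pd.DataFrame({"site_idx": [1], "label": ["cis"]})
        out = colocalize_ewas_gwas(ewas, gwas, meqtl_results=meqtl)
        assert out["class"].iloc[0] == "genetic_cis_epigenetic"

    def test_gwas_only_class(self):
        ewas, gwas = self._loci()
        gwas2 = pd.concat([gwas, pd.DataFrame(
            {"trait": ["LP"], "chrom": ["chr2"], "pos": [1]})], ignore_index=True)
        out = colocalize_ewas_gwas(ewas, gwas2)
        g = out[(out["source"] == "GWAS") & (out["chrom"] == "chr2")]
        assert g["class"].iloc[0] == "genetic_only"

    def test_trait_mismatch_rejected(self):
        ewas, gwas = self._loci()
        gwas["trait"] = "FL"
        with pytest.raises(ValueError, match="FL"):
            colocalize_ewas_gwas(ewas, gwas)

    def test_order_invariance(self):
        ewas, gwas = self._loci()
        a = colocalize_ewas_gwas(ewas, gwas)
        b = colocalize_ewas_gwas(ewas.iloc[::-1].reset_index(drop=True), gwas)
        assert sorted(a[a["source"] == "EWAS"]["pos"]) == \
               sorted(b[b["source"] == "EWAS"]["pos"])
        assert a[a["source"] == "EWAS"].set_index("pos")["shared"].to_dict() == \
               b[b["source"] == "EWAS"].set_index("pos")["shared"].to_dict()


class TestGrn:
    def _setup(self, rng, linked=True):
        x = rng.binomial(2, 0.5, 300).astype(float)
        if linked:
            y = x.copy()
            flip = rng.random(300) < 0.15
            y[flip] = rng.binomial(2, 0.5, flip.sum())
        else:
            y = rng.binomial(2, 0.5, 300).astype(float)
        M = np.vstack([x, y])
        trait_loci = pd.DataFrame({"trait": ["LP"], "chrom": ["chr1"],
                                   "marker_idx": [0], "p": [1e-9]})
        reg = pd.DataFrame({"target_id": ["geneA", "geneB"],
                            "chrom": ["chr1", "chr1"],
                            "marker_idx": [1, 1], "p": [1e-7, 1e-5]})
        return trait_loci, reg, M

    def test_linked_lead_yields_edges_per_egene(self, rng):
        trait_loci, reg, M = self._setup(rng, linked=True)
        edges = build_grn(trait_loci, reg, M, r2_threshold=0.1)
        assert set(edges["target_gene"]) == {"geneA", "geneB"}
        assert len(edges) == 2

    def test_unlinked_lead_no_edges(self, rng):
        trait_loci, reg, M = self._setup(rng, linked=False)
        edges = build_grn(trait_loci, reg, M, r2_threshold=0.1)
        assert edges.empty

    def test_network_overlap_and_graphml(self, rng, tmp_path):
        trait_loci, reg, M = self._setup(rng, linked=True)
        edges = build_grn(trait_loci, reg, M)
        other = edges[edges["target_gene"] == "geneA"]
        ov = network_overlap(edges, other)
        assert ov["n_shared"] == 1 and ov["shared_genes"] == ["geneA"]
        edges_to_graphml(edges, tmp_path / "grn.graphml")
        assert (tmp_path / "grn.graphml").exists()

    def test_trait_gene_cascade_recovered(self, small_cohort):
        """Planted SNP->expression->trait path links the trait locus to
        the causal gene through the eQTL results."""
        from popepigen.pipelines import ScanConfig, map_eqtl

        c = small_cohort
        res = map_eqtl(c.genotypes, c.expression, ScanConfig(seed=3))
        truth = c.truth.eqtl
        if truth.empty or res.results.empty:
            pytest.skip("no planted eQTL recovered in this fixture")
        # build a synthetic trait locus at the planted eQTL SNP itself
        snp_idx_scan = res.meta["snps"].snps.reset_index().merge(
            truth[["chrom", "pos"]], on=["chrom", "pos"])["index"]
        if snp_idx_scan.empty:
            pytest.skip("planted SNP filtered")
        trait_loci = pd.DataFrame({"trait": ["LP"],
                                   "chrom": [truth["chrom"].iloc[0]],
                                   "marker_idx": [int(snp_idx_scan.iloc[0])],
                                   "p": [1e-9]})
        edges = build_grn(trait_loci, res.results.rename(
            columns={"marker_chrom": "chrom"}), res.meta["snps"].dosage)
        assert truth["gene_id"].iloc[0] in set(edges["target_gene"])


class TestJonckheere:
    def test_strong_trend_detected(self, rng):
        groups = [rng.normal(loc=m, size=30) for m in (0.0, 0.5, 1.0, 1.5)]
        z, p = jonckheere_terpstra(groups, "increasing")
        assert p < 1e-6

    def test_null_uniformish(self, rng):
        ps = []
        for rep in range(200):
            groups = [rng.normal(size=15) for _ in range(4)]
            ps.append(jonckheere_terpstra(groups, "increasing")[1])
        assert 0.3 < np.mean(ps) < 0.7

    def test_direction_flip(self, rng):
        groups = [rng.normal(loc=m, size=30) for m in (0.0, 1.0)]
        z_inc, _ = jonckheere_terpstra(groups, "increasing")
        z_dec, _ = jonckheere_terpstra(groups, "decreasing")
        assert z_inc == pytest.approx(-z_dec)


class TestPyramiding:
    def _epi(self, codes):
        codes = np.asarray(codes, dtype=np.int8)
        n = codes.shape[1]
        sites = pd.DataFrame({"chrom": ["chr1"] * len(codes),
                              "pos": np.arange(1, len(codes) + 1) * 1000,
                              "strand": ["+"] * len(codes),
                              "context": ["CG"] * len(codes)})
        return EpiGenotypeMatrix(sites, codes, [f"a{i}" for i in range(n)])

    def test_elite_allele_definition(self):
        codes = [[2] * 5 + [0] * 5]
        epi = self._epi(codes)
        y = np.array([40.0] * 5 + [35.0] * 5)
        pheno = pd.DataFrame({"LP": y}, index=epi.accessions)
        loci = pd.DataFrame({"trait": ["LP"], "lead_site_idx": [0],
                             "locus_id": ["l0"]})
        out = pyramiding_analysis(loci, epi, pheno, {"LP": "higher"})
        assert out["LP"]["elite_classes"]["l0"] == "MM"
        np.testing.assert_array_equal(
            out["LP"]["elite_count"].to_numpy(), [1] * 5 + [0] * 5)

    def test_direction_flip_inverts_elite(self):
        codes = [[2] * 5 + [0] * 5]
        epi = self._epi(codes)
        pheno = pd.DataFrame({"LP": [40.0] * 5 + [35.0] * 5}, index=epi.accessions)
        loci = pd.DataFrame({"trait": ["LP"], "lead_site_idx": [0],
                             "locus_id": ["l0"]})
        hi = pyramiding_analysis(loci, epi, pheno, {"LP": "higher"})
        lo = pyramiding_analysis(loci, epi, pheno, {"LP": "lower"})
        assert hi["LP"]["elite_classes"]["l0"] == "MM"
        assert lo["LP"]["elite_classes"]["l0"] == "UU"

    def test_single_class_locus_dropped(self):
        epi = self._epi([[2] * 10])
        pheno = pd.DataFrame({"LP": np.arange(10.0)}, index=epi.accessions)
        loci = pd.DataFrame({"trait": ["LP"], "lead_site_idx": [0],
                             "locus_id": ["l0"]})
        out = pyramiding_analysis(loci, epi, pheno, {"LP": "higher"})
        assert out["LP"]["n_loci_used"] == 0

    def test_additive_loci_monotone_trend(self):
        rng = np.random.default_rng(9)
        n, L = 300, 10
        codes = rng.integers(0, 3, (L, n)).astype(np.int8)
        epi = self._epi(codes)
        y = codes.sum(axis=0) * 0.3 + rng.normal(size=n)
        pheno = pd.DataFrame({"LP": y}, index=epi.accessions)
        loci = pd.DataFrame({"trait": ["LP"] * L, "lead_site_idx": range(L),
                             "locus_id": [f"l{i}" for i in range(L)]})
        out = pyramiding_analysis(loci, epi, pheno, {"LP": "higher"})
        assert out["LP"]["trend_p"] < 0.01
        gs = out["LP"]["group_summary"]
        big = gs[gs["n"] >= 5]
        assert np.corrcoef(big["elite_count"], big["trait_mean"])[0, 1] > 0.5


class TestGblup:
    def test_k_identity_predicts_train_mean(self, rng):
        y = rng.normal(size=80)
        m = GBLUP().fit(np.eye(80), y)
        pred = m.predict(np.zeros((20, 80)))
        np.testing.assert_allclose(pred, m.mu_, atol=1e-10)

    def test_weight_vector_one_zero_bit_exact(self, rng):
        K1 = np.eye(60) + 0.1
        K2 = np.eye(60) * 2
        y = rng.normal(size=60)
        a = gblup_predict({"a": K1}, {"a": 1.0}, y, cv_folds=4, seed=0)
        b = gblup_predict({"a": K1, "b": K2}, {"a": 1.0, "b": 0.0}, y,
                          cv_folds=4, seed=0)
        assert np.array_equal(a["predictions"], b["predictions"], equal_nan=True)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            combine_kinships({"a": np.eye(3), "b": np.eye(3)},
                             {"a": 0.7, "b": 0.5})
        with pytest.raises(ValueError):
            combine_kinships({"a": np.eye(3)}, {"a": -1.0})

    def test_exclusion_mask(self):
        idx = pd.DataFrame({"chrom": ["chr1", "chr1", "chr2"],
                            "pos": [100, 5000, 100]})
        loci = pd.DataFrame({"chrom": ["chr1"], "pos": [120]})
        keep = exclude_markers_near_loci(idx, loci, window_bp=50)
        np.testing.assert_array_equal(keep, [False, True, True])

    def test_heritable_trait_predicts_null_does_not(self, small_cohort, rng):
        from popepigen.association import compute_kinship

        K = compute_kinship(small_cohort.genotypes.dosage.T)
        n = K.shape[0]
        lam, U = np.linalg.eigh(K)
        u = U @ (np.sqrt(np.maximum(lam, 0)) * rng.normal(size=n))
        y = np.sqrt(0.6) * u / u.std() + np.sqrt(0.4) * rng.normal(size=n)
        hit = gblup_predict({"snp": K}, {"snp": 1.0}, y, cv_folds=5, seed=1)
        nul = gblup_predict({"snp": K}, {"snp": 1.0}, rng.normal(size=n),
                            cv_folds=5, seed=1)
        assert hit["pcc_fold_mean"] > nul["pcc_fold_mean"] + 0.1

    def test_missing_phenotypes_excluded(self, rng):
        K = np.eye(50) + 0.05
        y = rng.normal(size=50)
        y[:5] = np.nan
        res = gblup_predict({"a": K}, {"a": 1.0}, y, cv_folds=4, seed=0)
        assert np.isnan(res["predictions"][:5]).all()
        assert np.isfinite(res["pcc"])
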