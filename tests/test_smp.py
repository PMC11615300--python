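"""Methylation levels, QC filters, epi-allele calling, MAF, annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from popepigen.containers import (
    MethylationCountMatrix, MethylationLevelMatrix, EpiGenotypeMatrix,
)
from popepigen.smp import (
    EpiAlleleCaller,
    annotate_sites,
    call_epi_alleles,
    compute_levels,
    filter_sites,
    region_methylation,
    site_maf_spectrum,
)


def _sites(n, chrom="chr1", context="CG"):
    return pd.DataFrame({
        "chrom": [chrom] * n, "pos": np.arange(1, n + 1) * 50,
        "strand": ["+"] * n, "context": [context] * n,
    })


class TestLevels:
    @pytest.mark.parametrize("meth,unmeth,min_cov,expect", [
        (8, 2, 1, 0.8),
        (0, 5, 1, 0.0),
        (2, 2, 5, np.nan),   # below coverage threshold -> missing
        (5, 0, 5, 1.0),
    ])
    def test_level_formula_and_coverage(self, meth, unmeth, min_cov, expect):
        m = MethylationCountMatrix(_sites(1), [[meth]], [[meth + unmeth]], ["a"])
        lv = compute_levels(m, min_cov).levels[0, 0]
        if np.isnan(expect):
            assert np.isnan(lv)
        else:
            assert lv == pytest.approx(expect)

    def test_min_coverage_validated(self):
        m = MethylationCountMatrix(_sites(1), [[1]], [[2]], ["a"])
        with pytest.raises(ValueError):
            compute_levels(m, 0)


class TestCalling:
    @pytest.mark.parametrize("level,code", [
        (0.0, 0), (0.3, 0),          # closed upper bound of UU
        (0.30001, 1), (0.5, 1), (0.7, 1),  # closed upper bound of MU
        (0.70001, 2), (0.85, 2), (1.0, 2),
    ])
    def test_boundary_inclusivity(self, level, code):
        lv = MethylationLevelMatrix(_sites(1), [[level]], ["a"])
        assert call_epi_alleles(lv).codes[0, 0] == code

    def test_missing_propagates(self):
        lv = MethylationLevelMatrix(_sites(1), [[np.nan]], ["a"])
        assert call_epi_alleles(lv).codes[0, 0] == -1

    def test_out_of_range_rejected(self):
        lv = MethylationLevelMatrix(_sites(1), [[0.5]], ["a"])
        lv.levels[0, 0] = 1.5  # bypass container validation
        with pytest.raises(ValueError):
            call_epi_alleles(lv)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20))
    def test_calling_monotone_in_level(self, levels):
        """Raising mC never moves a call toward UU."""
        caller = EpiAlleleCaller()
        codes = caller.transform(np.array([sorted(levels)]))
        assert (np.diff(codes[0]) >= 0).all()

    def test_transformer_equals_function(self, small_cohort):
        lv = compute_levels(small_cohort.counts, 5)
        a = call_epi_alleles(lv).codes
        b = EpiAlleleCaller().fit(None).transform(lv.levels)
        np.testing.assert_array_equal(a, b)


class TestFilter:
    def test_missingness_rule_boundary(self):
        # 31% missing at threshold 0.30 -> removed; exactly 30% -> kept
        n_acc = 100
        lv = MethylationLevelMatrix(
            _sites(2), np.ones((2, n_acc)) * 0.5, [f"a{i}" for i in range(n_acc)])
        lv.levels[0, :31] = np.nan
        lv.levels[1, :30] = np.nan
        out, rep = filter_sites(lv, 0.30, [])
        assert rep.n_removed_missing == 1 and rep.n_retained == 1

    def test_snp_overlap_rule(self):
        lv = MethylationLevelMatrix(_sites(3), np.ones((3, 4)) * 0.5,
                                    list("abcd"))
        out, rep = filter_sites(lv, 0.3, [("chr1", 100)])
        assert rep.n_removed_snp == 1
        assert 100 not in out.sites["pos"].to_numpy()

    def test_designed_fixture_bookkeeping(self):
        from popepigen.calibration import filter_bookkeeping

        res = filter_bookkeeping(3)
        assert res["attribution_correct"]
        assert res["n_retained"] == 80


class TestMaf:
    def _epi(self, codes):
        codes = np.asarray(codes, dtype=np.int8).reshape(1, -1)
        return EpiGenotypeMatrix(_sites(1), codes,
                                 [f"a{i}" for i in range(codes.shape[1])])

    def test_symmetric_site(self):
        tab, _ = site_maf_spectrum(self._epi([2] * 5 + [0] * 5))
        assert tab["p_M"].iloc[0] == pytest.approx(0.5)
        assert tab["maf"].iloc[0] == pytest.approx(0.5)

    def test_allele_counting_by_hand(self):
        # 9 MM + 1 MU over 10 accessions: p_U = 1/20
        tab, common = site_maf_spectrum(self._epi([2] * 9 + [1]), min_maf=0.05)
        assert tab["maf"].iloc[0] == pytest.approx(0.05)
        assert common.n_sites == 1  # maf >= 0.05 inclusive

    def test_monomorphic_excluded(self):
        tab, common = site_maf_spectrum(self._epi([0] * 10), min_maf=0.05)
        assert tab["maf"].iloc[0] == 0.0
        assert common.n_sites == 0

    def test_all_missing_site_excluded(self):
        tab, common = site_maf_spectrum(self._epi([-1] * 10))
        assert np.isnan(tab["maf"].iloc[0])
        assert not tab["common"].iloc[0]

    def test_p_m_equals_half_mean_code(self, small_cohort):
        epi = small_cohort.truth.latent
        p = epi.p_m()
        mean_code = np.array([
            r[r >= 0].mean() if (r >= 0).any() else np.nan
            for r in epi.codes
        ])
        np.testing.assert_allclose(p, mean_code / 2.0, atol=1e-12)

    def test_genotype_mode_available(self):
        tab, _ = site_maf_spectrum(self._epi([2] * 9 + [1]), mode="genotype")
        assert tab["maf"].iloc[0] == pytest.approx(0.05)


class TestRegionMethylation:
    def test_hand_example(self):
        m = MethylationCountMatrix(
            _sites(3), np.array([[3], [0], [5]]), np.array([[4], [4], [5]]), ["a"])
        assert region_methylation(m, "chr1", 1, 200, "a") == pytest.approx(8 / 13)

    def test_all_unmethylated(self):
        m = MethylationCountMatrix(
            _sites(2), np.zeros((2, 1), int), np.array([[4], [6]]), ["a"])
        assert region_methylation(m, "chr1", 1, 200, "a") == 0.0

    def test_single_site_reduces_to_level(self):
        m = MethylationCountMatrix(_sites(1), [[3]], [[4]], ["a"])
        assert region_methylation(m, "chr1", 1, 100, "a") == pytest.approx(0.75)

    def test_uncovered_region_missing(self):
        m = MethylationCountMatrix(_sites(1), [[0]], [[0]], ["a"])
        assert np.isnan(region_methylation(m, "chr1", 1, 100, "a"))

    def test_bounded_by_site_levels(self, small_cohort):
        m = small_cohort.counts
        vals = region_methylation(m, "chr1", 1, 100_000)
        lv = compute_levels(m, 1)
        sel = ((m.sites["chrom"] == "chr1") & (m.sites["pos"] <= 100_000)).to_numpy()
        for j in range(5):
            col = lv.levels[sel, j]
            col = col[np.isfinite(col)]
            if col.size and np.isfinite(vals[j]):
                assert col.min() - 1e-12 <= vals[j] <= col.max() + 1e-12

    def test_empty_region_rejected(self):
        m = MethylationCountMatrix(_sites(1), [[1]], [[2]], ["a"])
        with pytest.raises(ValueError):
            region_methylation(m, "chr1", 200, 100, "a")


class TestAnnotation:
    def test_labels_match_bruteforce(self, tmp_path, rng):
        from popepigen import io as pio

        genes = [("chr1", int(s), int(s) + 400, "+", f"g{i}")
                 for i, s in enumerate(sorted(rng.integers(1000, 30_000, 12)))]
        gff = tmp_path / "g.gff3"
        with open(gff, "w") as fh:
            for chrom, s, e, strand, gid in genes:
                fh.write(f"{chrom}\tx\tgene\t{s}\t{e}\t.\t{strand}\t.\tID={gid}\n")
        bed = tmp_path / "te.bed"
        bed.write_text("".join(
            f"chr1\t{int(s)}\t{int(s) + 200}\tTE{i}\n"
            for i, s in enumerate(rng.integers(500, 30_000, 8))))
        fs = pio.build_feature_set(gff, bed, 300, 300)
        n = 200
        sites = pd.DataFrame({
            "chrom": ["chr1"] * n,
            "pos": np.sort(rng.choice(np.arange(1, 32_000), n, replace=False)),
            "strand": ["+"] * n, "context": ["CG"] * n,
        })
        codes = rng.integers(0, 3, (n, 10)).astype(np.int8)
        epi = EpiGenotypeMatrix(sites, codes, [f"a{i}" for i in range(10)])
        labels, summary = annotate_sites(epi, fs)
        rec = fs.records
        for i in range(n):
            pos = sites["pos"].iloc[i]
            hit = rec[(rec["start"] <= pos) & (rec["end"] >= pos)]
            expect = set(hit["feature_class"])
            for c in ("gene_body", "promoter", "downstream", "TE"):
                assert labels[c].iloc[i] == (c in expect)
            assert labels["intergenic"].iloc[i] == (len(expect) == 0)
        assert {"gene_body&TE", "gene_body-notTE"} <= set(summary["feature_class"])

    def test_precedence_mode_single_label(self, tmp_path):
        from popepigen import io as pio

        gff = tmp_path / "g.gff3"
        gff.write_text("chr1\tx\tgene\t1000\t2000\t.\t+\t.\tID=g1\n")
        bed = tmp_path / "te.bed"
        bed.write_text("chr1\t1400\t1600\tTE1\n")
        fs = pio.build_feature_set(gff, bed)
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [1500],
                              "strand": ["+"], "context": ["CG"]})
        epi = EpiGenotypeMatrix(sites, np.array([[2, 0]], dtype=np.int8), ["a", "b"])
        labels, _ = annotate_sites(epi, fs, precedence=True)
        assert labels["label"].iloc[0] == "gene_body"  # above TE in precedence


def test_call_accuracy_improves_with_depth():
    """Binomial counts around latent states: near-perfect calls at depth 100."""
    rng = np.random.default_rng(1)
    n = 2000
    states = rng.integers(0, 3, n)
    mu = np.array([0.003, 0.5, 0.997])[states]
    for depth, max_err in [(100, 0.01)]:
        d = rng.poisson(depth, n).clip(min=1)
        meth = rng.binomial(d, mu)
        sites = pd.DataFrame({"chrom": ["chr1"] * n, "pos": np.arange(1, n + 1),
                              "strand": ["+"] * n, "context": ["CG"] * n})
        m = MethylationCountMatrix(sites, meth[:, None], d[:, None], ["a"])
        codes = call_epi_alleles(compute_levels(m, 5)).codes[:, 0]
        called = codes >= 0
        err = np.mean(codes[called] != states[called])
        assert err < max_err
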