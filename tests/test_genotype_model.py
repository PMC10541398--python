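"""Genotype container, VCF round-tripping, and site filters."""

import numpy as np
import pytest

from clonalpop import (MISSING, FilterConfig, GenotypeMatrix, SampleMeta,
                       SiteMeta, apply_filters, heterozygosity_ratio,
                       heterozygosity_screen, read_vcf, write_vcf)
from clonalpop.genotype import GenotypeError

from conftest import make_matrix

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsampA\tsampB\n"
)


def write_text_vcf(path, records):
    path.write_text(VCF_HEADER + "".join(records))
    return path


def test_read_vcf_parses_biallelic_snps(tmp_path):
    vcf = write_text_vcf(
        tmp_path / "in.vcf",
        [
            "loc1\t5\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\n",
            "loc2\t9\t.\tC\tT\t.\tPASS\t.\tGT\t1|1\t./.\n",
            "loc3\t2\t.\tG\tA\t.\tPASS\t.\tGT\t0/1\t1/1\n",
        ],
    )
    m = read_vcf(vcf)
    assert (m.n_samples, m.n_sites) == (2, 3)
    assert m.sample_ids == ["sampA", "sampB"]
    # phased and unphased separators identical; ./. becomes MISSING
    np.testing.assert_array_equal(m.calls, [[0, 2, 1], [1, MISSING, 2]])


def test_read_vcf_skips_multiallelic_and_indels(tmp_path):
    vcf = write_text_vcf(
        tmp_path / "mix.vcf",
        [
            "loc1\t1\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\n",
            "loc2\t1\t.\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t0/2\n",  # triallelic
            "loc3\t1\t.\tAT\tA\t.\tPASS\t.\tGT\t0/0\t0/1\n",    # indel
            "loc4\t1\t.\tC\tT\t.\tPASS\t.\tGT\t1/1\t0/0\n",
            "loc5\t1\t.\tG\tC\t.\tPASS\t.\tGT\t0/1\t0/1\n",
        ],
    )
    m = read_vcf(vcf)
    assert m.n_sites == 3
    assert [s.locus_id for s in m.sites] == ["loc1", "loc4", "loc5"]


def test_read_vcf_errors(tmp_path):
    with pytest.raises(GenotypeError, match="no such file"):
        read_vcf(tmp_path / "absent.vcf")
    only_indels = write_text_vcf(
        tmp_path / "bad.vcf", ["loc1\t1\t.\tAT\tA\t.\tPASS\t.\tGT\t0/0\t0/1\n"]
    )
    with pytest.raises(GenotypeError, match="no biallelic"):
        read_vcf(only_indels)


def test_vcf_round_trip_identity(tmp_path):
    rng = np.random.default_rng(42)
    calls = rng.choice([0, 1, 2, MISSING], size=(10, 50), p=[0.3, 0.3, 0.3, 0.1])
    m = make_matrix(calls)
    out = tmp_path / "round.vcf"
    write_vcf(m, out)
    again = read_vcf(out)
    assert m.equals(again)
    # and a second round trip is stable
    write_vcf(again, tmp_path / "round2.vcf")
    assert again.equals(read_vcf(tmp_path / "round2.vcf"))


def test_matrix_invariants_enforced():
    with pytest.raises(ValueError, match="not unique"):
        make_matrix([[0, 1], [1, 0]], sample_ids=["a", "a"])
    with pytest.raises(ValueError, match="invalid genotype codes"):
        make_matrix([[0, 3]])
    with pytest.raises(ValueError, match="replicate_of"):
        GenotypeMatrix(
            [SampleMeta("a", replicate_of="ghost")],
            [SiteMeta("l1", 1)],
            np.array([[0]], dtype=np.int8),
        )
    with pytest.raises(ValueError):
        SiteMeta("l1", 0)          # position < 1
    with pytest.raises(ValueError):
        SiteMeta("l1", 1, "A", "A")  # ref == alt


class TestFilters:
    def test_presence_filter(self):
        # site 1 genotyped in 4/10 samples -> removed at R=0.5
        calls = np.zeros((10, 2), dtype=np.int8)
        calls[:6, 0] = MISSING
        calls[::2, 1] = 1
        m = make_matrix(calls)
        cfg = FilterConfig(min_presence_fraction=0.5, min_maf=0.0,
                           single_snp_per_locus=False)
        filtered, rep = apply_filters(m, cfg)
        assert filtered.n_sites == 1
        assert rep.removed_presence == 1

    def test_maf_boundary_retained(self):
        # 1 alt / 19 ref alleles over 10 diploids: MAF exactly 0.05 is kept
        calls = np.zeros((10, 1), dtype=np.int8)
        calls[0, 0] = 1
        m = make_matrix(calls)
        cfg = FilterConfig(min_presence_fraction=0.0, min_maf=0.05,
                           single_snp_per_locus=False)
        filtered, _ = apply_filters(m, cfg)
        assert filtered.n_sites == 1
        # but 1/40 alleles (MAF 0.025) is not
        calls20 = np.zeros((20, 1), dtype=np.int8)
        calls20[0, 0] = 1
        with pytest.raises(GenotypeError):
            apply_filters(make_matrix(calls20), cfg)

    def test_single_snp_keeps_lowest_position(self):
        m = make_matrix(
            [[0, 1], [1, 0], [1, 1]],
            loci=[("locX", 40), ("locX", 12)],
        )
        cfg = FilterConfig(min_presence_fraction=0.0, min_maf=0.0,
                           single_snp_per_locus=True)
        filtered, rep = apply_filters(m, cfg)
        assert filtered.n_sites == 1
        assert filtered.sites[0].position == 12
        assert rep.removed_single_snp == 1

    def test_idempotent_and_calls_untouched(self, small_matrix):
        cfg = FilterConfig(min_presence_fraction=0.5, min_maf=0.05,
                           single_snp_per_locus=True)
        once, _ = apply_filters(small_matrix, cfg)
        twice, rep2 = apply_filters(once, cfg)
        assert once.equals(twice)
        assert rep2.n_retained == rep2.n_input
        kept = [s.key for s in once.sites]
        orig_cols = [i for i, s in enumerate(small_matrix.sites) if s.key in kept]
        np.testing.assert_array_equal(once.calls, small_matrix.calls[:, orig_cols])

    def test_all_missing_site_removed_by_any_presence(self):
        calls = np.array([[MISSING, 0], [MISSING, 1]], dtype=np.int8)
        m = make_matrix(calls)
        cfg = FilterConfig(min_presence_fraction=0.01, min_maf=0.0,
                           single_snp_per_locus=False)
        filtered, _ = apply_filters(m, cfg)
        assert filtered.n_sites == 1

    def test_bounds_validated(self):
        with pytest.raises(ValueError):
            FilterConfig(min_presence_fraction=1.5)
        with pytest.raises(ValueError):
            FilterConfig(min_maf=0.6)


class TestHeterozygosityRatio:
    def test_worked_examples(self):
        m = make_matrix([[1, 1, 0, 2], [0, 2, 2, MISSING]])
        assert heterozygosity_ratio(m, "s1") == 0.5
        assert heterozygosity_ratio(m, "s2") == 0.0

    def test_all_missing_is_an_error_not_zero(self):
        m = make_matrix([[MISSING, MISSING], [0, 1]])
        with pytest.raises(GenotypeError):
            heterozygosity_ratio(m, "s1")

    def test_hwe_expectation_half(self):
        # p = 0.5 everywhere at HWE: expected het fraction 2pq = 0.5
        from clonalpop import simulate_individual
        rng = np.random.default_rng(7)
        freqs = np.full((1, 10000), 0.5)
        g = simulate_individual(np.array([1.0]), freqs, rng)
        m = make_matrix(g[None, :])
        assert heterozygosity_ratio(m, "s1") == pytest.approx(0.5, abs=0.01)

    def test_screen_flags_low_het(self):
        m = make_matrix([[1, 1, 0, 2], [0, 2, 2, 0]])
        df = heterozygosity_screen(m, threshold=0.2)
        assert df.set_index("sample_id")["low_het"].to_dict() == {
            "s1": False, "s2": True}
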