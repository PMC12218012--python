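import numpy as np
import pytest

from ldne import (SimConfig, assign_genetic_positions, filter_sites,
                  read_plink, read_vcf, simulate, write_tped, write_vcf)
from ldne.genotype_io import GenotypeDataError

from conftest import make_matrix

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=1>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
)


def write(tmp_path, body, name="toy.vcf"):
    p = tmp_path / name
    p.write_text(VCF_HEADER + body)
    return str(p)


def test_vcf_dosage_encoding(tmp_path):
    path = write(tmp_path, "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n")
    g = read_vcf(path, maf_min=0, call_rate_min=0)
    assert g.ploidy == 2
    assert g.dosages[:, 0].tolist() == [0, 1, 2]
    assert not g.missing.any()
    assert g.sites.loc[0, "pos_bp"] == 100


def test_vcf_triallelic_and_indel_skipped(tmp_path):
    body = ("1\t100\t.\tA\tG,T\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\t.\tAT\tA\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t300\t.\tA\tC\t.\tPASS\t.\tGT\t0/1\t0/1\t1/1\n")
    g = read_vcf(write(tmp_path, body), maf_min=0, call_rate_min=0)
    assert g.n_sites == 1
    assert g.sites.loc[0, "pos_bp"] == 300


def test_vcf_missing_masked_and_call_rate_filter(tmp_path):
    body = ("1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t./.\t0/1\t1/1\n"
            "1\t200\t.\tA\tC\t.\tPASS\t.\tGT\t0/1\t0/1\t1/1\n")
    g = read_vcf(write(tmp_path, body), maf_min=0, call_rate_min=0)
    assert g.missing[0, 0] and not g.missing[1, 0]
    assert g.dosages[0, 0] == 0  # masked entries are zeroed
    g2 = read_vcf(write(tmp_path, body), maf_min=0, call_rate_min=0.9)
    assert g2.n_sites == 1


def test_haploid_read_of_diploid_fails_loudly(tmp_path):
    path = write(tmp_path, "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n")
    with pytest.raises(GenotypeDataError, match="haploid"):
        read_vcf(path, ploidy=1, maf_min=0, call_rate_min=0)


def test_vcf_roundtrip_with_simulator_output(tmp_path):
    g, _ = simulate(SimConfig(N=60, chromosomes=2, chrom_length_cM=50,
                              chrom_length_bp=1_000_000, mu=2e-7,
                              sample_n=20, seed=9))
    write_vcf(g, tmp_path / "sim.vcf")
    g2 = read_vcf(tmp_path / "sim.vcf", maf_min=0, call_rate_min=0)
    assert np.array_equal(g.dosages, g2.dosages)
    assert np.array_equal(g.missing, g2.missing)
    assert g.sites["pos_bp"].tolist() == g2.sites["pos_bp"].tolist()
    assert g.sites["chrom"].astype(str).tolist() == g2.sites["chrom"].tolist()


def test_tped_roundtrip_preserves_genetic_positions(tmp_path):
    g, _ = simulate(SimConfig(N=60, chromosomes=2, chrom_length_cM=50,
                              chrom_length_bp=1_000_000, mu=2e-7,
                              sample_n=20, seed=10))
    write_tped(g, tmp_path / "sim")
    g2 = read_plink(str(tmp_path / "sim.tped"), maf_min=0, call_rate_min=0)
    # alt = minor allele on read; dosages may be complemented where the
    # simulated alt allele is the major one
    p = g.allele_frequencies()
    flip = p > 0.5
    same = np.array_equal(g.dosages[:, ~flip], g2.dosages[:, ~flip])
    comp = np.array_equal(2 - g.dosages[:, flip], g2.dosages[:, flip])
    assert same and comp
    np.testing.assert_allclose(g.sites["pos_cM"], g2.sites["pos_cM"])


def test_ped_map_toy(tmp_path):
    (tmp_path / "toy.map").write_text("1 s1 0.5 1000\n1 s2 1.5 2000\n")
    (tmp_path / "toy.ped").write_text(
        "f1 i1 0 0 0 -9 A A A C\n"
        "f2 i2 0 0 0 -9 A C C C\n")
    g = read_plink(str(tmp_path / "toy.ped"), str(tmp_path / "toy.map"),
                   maf_min=0, call_rate_min=0)
    assert g.dosages.shape == (2, 2)
    # site 1: C is minor; site 2: A is minor
    assert g.dosages[:, 0].tolist() == [0, 1]
    assert g.dosages[:, 1].tolist() == [1, 0]
    assert g.sites["pos_cM"].tolist() == [0.5, 1.5]


def test_ped_inconsistent_with_map(tmp_path):
    (tmp_path / "toy.map").write_text("1 s1 0 1000\n")
    (tmp_path / "toy.ped").write_text("f1 i1 0 0 0 -9 A A A C\n")
    with pytest.raises(GenotypeDataError, match="inconsistent"):
        read_plink(str(tmp_path / "toy.ped"), str(tmp_path / "toy.map"))


def test_map_all_zero_cm_marks_positions_absent(tmp_path):
    (tmp_path / "toy.map").write_text("1 s1 0 1000000\n1 s2 0 2000000\n")
    (tmp_path / "toy.ped").write_text(
        "f1 i1 0 0 0 -9 A C A C\nf2 i2 0 0 0 -9 A A C C\n")
    g = read_plink(str(tmp_path / "toy.ped"), str(tmp_path / "toy.map"),
                   maf_min=0, call_rate_min=0)
    assert not g.has_genetic_positions
    g2 = assign_genetic_positions(g, 1.0)
    assert g2.sites["pos_cM"].tolist() == [1.0, 2.0]


class TestAssignGeneticPositions:
    def test_unit_conversion(self):
        g = make_matrix([[0, 1], [1, 2]], cM=[np.nan, np.nan])
        g.sites["pos_bp"] = [1_000_000, 10_000_000]
        assert assign_genetic_positions(g, 1.0).sites["pos_cM"].tolist() == \
            [1.0, 10.0]

    def test_turbot_rate(self):
        g = make_matrix([[0, 1], [1, 2]], cM=[np.nan, np.nan])
        g.sites["pos_bp"] = [1_000_000, 10_000_000]
        out = assign_genetic_positions(g, 2.47).sites["pos_cM"]
        np.testing.assert_allclose(out, [2.47, 24.7])

    def test_existing_positions_kept(self):
        g = make_matrix([[0, 1], [1, 2]], cM=[7.0, np.nan])
        g.sites["pos_bp"] = [1_000_000, 2_000_000]
        out = assign_genetic_positions(g, 1.0).sites["pos_cM"]
        assert out.tolist() == [7.0, 2.0]

    @pytest.mark.parametrize("rate", [0.0, -1.0])
    def test_nonpositive_rate_rejected(self, rate):
        g = make_matrix([[0, 1]], cM=[np.nan, np.nan])
        with pytest.raises(ValueError):
            assign_genetic_positions(g, rate)


def test_maf_and_chrom_length_filters():
    dos = np.array([[0, 0, 1], [0, 1, 1], [0, 0, 1], [0, 0, 1]] * 25,
                   dtype=np.int8)
    g = make_matrix(dos, chrom=["1", "1", "2"])
    g.sites["pos_bp"] = [1, 5_000_000, 10]
    out = filter_sites(g, maf_min=0.01, call_rate_min=0)
    assert out.n_sites == 2  # monomorphic site dropped
    out2 = filter_sites(g, maf_min=0, call_rate_min=0,
                        min_chrom_length_bp=1_000_000)
    assert set(out2.sites["chrom"]) == {"1"}


def test_zero_usable_sites_raises(tmp_path):
    p = tmp_path / "empty.vcf"
    p.write_text(VCF_HEADER)
    with pytest.raises(GenotypeDataError):
        read_vcf(str(p))
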