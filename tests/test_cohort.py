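"""Genotype I/O, descriptive genetics and the clinical classifier."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sipiscan import (ClinicalRecord, DataError, GenotypeDistribution,
                      GenotypeFormatError, TableDialect, Variant,
                      classify_aggressiveness, compare_distributions,
                      compute_maf, determine_minor_alleles,
                      genotype_distribution, ld_r2, read_genotype_table,
                      read_vcf_biallelic, simulate_genotypes)
from sipiscan.cohort import ClassificationError

from conftest import build_cohort


# ---------------------------------------------------------------------------
# Delimited table reading
# ---------------------------------------------------------------------------

HEADER = "sample\tphenotype\tage\tsite\tancestry\t"


def _write(tmp_path, body, name="geno.tsv"):
    path = tmp_path / name
    path.write_text(body)
    return path


def test_read_dosage_table_with_missing(tmp_path):
    body = (HEADER + "rs1\trs2\n"
            "a\t1\t60\t1\t0.95\t0\t2\n"
            "b\t0\t65\t0\t0.99\t1\t1\n"
            "c\t0\t70\t1\t0.90\t2\tNA\n"
            "d\t1\t55\t0\t0.97\t1\t0\n")
    cohort = read_genotype_table(_write(tmp_path, body))
    assert cohort.n == 4
    assert int(np.sum(~np.isfinite(cohort.genotypes))) == 1
    assert cohort.dosage("rs1").tolist() == [0, 1, 2, 1]


def test_read_allele_pair_cells(tmp_path):
    body = (HEADER + "rs1\n"
            "a\t1\t60\t1\t0.95\tA/G\n"
            "b\t0\t65\t0\t0.99\tG/G\n")
    var = Variant("rs1", allele_a="A", allele_b="G", minor_allele="A")
    cohort = read_genotype_table(_write(tmp_path, body), variants=[var])
    assert cohort.dosage("rs1").tolist() == [1.0, 0.0]


def test_read_rejects_non_binary_phenotype(tmp_path):
    body = HEADER + "rs1\n" "a\t2\t60\t1\t0.95\t0\n"
    with pytest.raises(DataError):
        read_genotype_table(_write(tmp_path, body))


def test_read_requires_mandatory_columns(tmp_path):
    body = "sample\tage\tsite\tancestry\trs1\n" "a\t60\t1\t0.95\t0\n"
    with pytest.raises(GenotypeFormatError):
        read_genotype_table(_write(tmp_path, body))


def test_unparseable_cells_become_missing(tmp_path):
    body = (HEADER + "rs1\n"
            "a\t1\t60\t1\t0.95\tX/Y\n"
            "b\t0\t65\t0\t0.99\t7\n")
    var = Variant("rs1", allele_a="A", allele_b="G", minor_allele="A")
    cohort = read_genotype_table(_write(tmp_path, body), variants=[var])
    assert np.all(~np.isfinite(cohort.dosage("rs1")))


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

VCF_BODY = """##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4
1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t./.
1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t0/1\t./1\t1/1\t0/0
1\t300\trs3\tG\tA,T\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\t0/0
"""


def test_read_vcf_biallelic(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(VCF_BODY)
    matrix, variants, samples = read_vcf_biallelic(path)
    # tri-allelic rs3 skipped
    assert [v.variant_id for v in variants] == ["rs1", "rs2"]
    assert samples == ["S1", "S2", "S3", "S4"]
    col1, col2 = matrix[:, 0], matrix[:, 1]
    assert col1[:3].tolist() == [0.0, 1.0, 2.0] and np.isnan(col1[3])
    # half-missing ./1 is treated as fully missing
    assert np.isnan(col2[1]) and col2[0] == 1.0 and col2[2] == 2.0


# ---------------------------------------------------------------------------
# Minor-allele assignment and MAF
# ---------------------------------------------------------------------------

def _freq_cohort(freq_minor, n=1000, seed=7):
    """Cohort whose single variant counts allele 'C' at the given frequency."""
    g = np.random.default_rng(seed).binomial(2, freq_minor, n).astype(float)
    var = Variant("rs4652", allele_a="C", allele_b="A", minor_allele="C")
    return build_cohort({"rs4652": g}, np.zeros(n), variants=[var])


def test_minor_allele_kept_when_rare():
    cohort = _freq_cohort(0.42)
    determine_minor_alleles(cohort)
    var = cohort.variant("rs4652")
    assert var.minor_allele == "C" and var.maf <= 0.5


def test_minor_allele_flips_when_common():
    cohort = _freq_cohort(0.84)
    before = cohort.dosage("rs4652").copy()
    determine_minor_alleles(cohort)
    var = cohort.variant("rs4652")
    assert var.minor_allele == "A"
    assert np.allclose(cohort.dosage("rs4652"), 2.0 - before)
    assert var.maf == pytest.approx(1.0 - compute_maf(before))


def test_minor_allele_tie_breaks_lexicographically():
    g = np.array([0.0, 2.0, 1.0, 1.0])  # freq exactly 0.5
    var = Variant("v", allele_a="G", allele_b="A", minor_allele="G")
    cohort = build_cohort({"v": g}, np.zeros(4), variants=[var])
    determine_minor_alleles(cohort)
    assert cohort.variant("v").minor_allele == "A"


def test_determine_minor_alleles_idempotent():
    cohort = _freq_cohort(0.84)
    determine_minor_alleles(cohort)
    snapshot = cohort.genotypes.copy()
    mafs = [v.maf for v in cohort.variants]
    determine_minor_alleles(cohort)
    assert np.array_equal(cohort.genotypes, snapshot, equal_nan=True)
    assert [v.maf for v in cohort.variants] == mafs


@pytest.mark.parametrize("dosages, expected", [
    ([0, 0, 0, 0], 0.0),
    ([2, 2], 1.0),          # needs re-orientation downstream
    ([0, 1, 1, 2], 0.5),
])
def test_compute_maf(dosages, expected):
    assert compute_maf(np.array(dosages, dtype=float)) == expected


# ---------------------------------------------------------------------------
# LD r-squared
# ---------------------------------------------------------------------------

def test_ld_r2_perfect_correlation_and_anticorrelation():
    d = np.array([0.0, 0.0, 1.0, 2.0])
    assert ld_r2(d, d) == pytest.approx(1.0)
    assert ld_r2(d, 2.0 - d) == pytest.approx(1.0)


def test_ld_r2_independent_variants_near_zero():
    g1 = simulate_genotypes(0.3, 10_000, 1)
    g2 = simulate_genotypes(0.4, 10_000, 2)
    assert ld_r2(g1, g2) < 0.01


def test_ld_r2_degenerate_returns_nan():
    assert np.isnan(ld_r2(np.zeros(5), np.array([0.0, 1, 2, 1, 0])))


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.sampled_from([0.0, 1.0, 2.0]), min_size=4, max_size=30),
       st.lists(st.sampled_from([0.0, 1.0, 2.0]), min_size=4, max_size=30))
def test_ld_r2_symmetric_and_flip_invariant(a, b):
    m = min(len(a), len(b))
    g1, g2 = np.array(a[:m]), np.array(b[:m])
    r2 = ld_r2(g1, g2)
    assert np.isnan(r2) or 0.0 <= r2 <= 1.0 + 1e-12
    for x, y in [(g2, g1), (2 - g1, g2), (g1, 2 - g2)]:
        other = ld_r2(x, y)
        assert (np.isnan(r2) and np.isnan(other)) or other == pytest.approx(r2)


# ---------------------------------------------------------------------------
# Genotype distributions
# ---------------------------------------------------------------------------

def test_genotype_distribution_counts():
    d = genotype_distribution(np.array([0, 0, 1, 2, np.nan, 1, 1]))
    assert (d.hom_major, d.het, d.hom_minor, d.missing) == (2, 3, 1, 1)
    assert d.n_genotyped == 6


def test_compare_distributions_identical_is_null():
    d = GenotypeDistribution(30, 50, 20)
    stat, p = compare_distributions(d, d)
    assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)


def test_compare_distributions_complete_separation():
    _, p = compare_distributions(GenotypeDistribution(50, 0, 0),
                                 GenotypeDistribution(0, 0, 50))
    assert p < 1e-3


def test_compare_distributions_matches_hand_computed_pearson():
    d1, d2 = GenotypeDistribution(30, 50, 20), GenotypeDistribution(45, 40, 15)
    stat, _ = compare_distributions(d1, d2)
    obs = np.array([[30, 50, 20], [45, 40, 15]], dtype=float)
    expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
    assert stat == pytest.approx(np.sum((obs - expected) ** 2 / expected))


def test_compare_distributions_collapses_empty_category():
    d1, d2 = GenotypeDistribution(30, 50, 0), GenotypeDistribution(45, 40, 0)
    stat, p = compare_distributions(d1, d2)
    obs = np.array([[30, 50], [45, 40]], dtype=float)
    expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
    assert stat == pytest.approx(np.sum((obs - expected) ** 2 / expected))
    assert 0 < p < 1


# ---------------------------------------------------------------------------
# Clinical aggressiveness classifier
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("gleason, psa, stage, expected", [
    (8, 4.0, "T2", "high"),        # Gleason alone
    (5, 25.0, "T1", "high"),       # PSA alone
    (7, 5.0, "T3", "high"),        # Gleason 7 + advanced stage
    (6, 5.0, "T1", "low"),
    (6, 15.0, "T2", "intermediate"),
    (7, 5.0, "T2", "intermediate"),
    (6, 5.0, "T3", "intermediate"),
])
def test_classify_aggressiveness_rules(gleason, psa, stage, expected):
    assert classify_aggressiveness(ClinicalRecord(gleason, psa, stage)) == expected


def test_classify_partitions_the_whole_grid():
    """Every valid (Gleason, PSA, stage) combination falls in exactly one
    category, and the category agrees with an independent restatement of
    the rule at every boundary."""
    psas = [0.0, 5.0, 9.99, 10.0, 15.0, 20.0, 20.01, 100.0]
    for gleason in range(2, 11):
        for t in (1, 2, 3, 4):
            for psa in psas:
                cat = classify_aggressiveness(
                    ClinicalRecord(gleason, psa, f"T{t}"))
                high = gleason >= 8 or psa > 20 or (gleason >= 7 and t >= 3)
                low = (not high) and gleason < 7 and t <= 2 and psa < 10
                assert cat == ("high" if high else "low" if low
                               else "intermediate")


def test_classify_requires_all_fields():
    with pytest.raises(ClassificationError):
        classify_aggressiveness(ClinicalRecord(7, None, "T2"))
    with pytest.raises(ClassificationError):
        classify_aggressiveness(ClinicalRecord(7, 5.0, "N0"))
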