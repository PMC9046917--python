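"""Genotype I/O, allele frequencies, HWE exact test, QC and imputation."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from aquagp import genio, simdata


def make_gm(dosages, chrom=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    markers = pd.DataFrame(
        {
            "id": [f"m{j}" for j in range(m)],
            "chrom": chrom or ["1"] * m,
            "pos": np.arange(1, m + 1),
            "a1": "A",
            "a2": "B",
        }
    )
    return genio.GenotypeMatrix([f"s{i}" for i in range(n)], markers, dosages)


# ---------------------------------------------------------------------------
# readers / writers


def test_plink_text_round_trip(tmp_path, small_ds):
    paths = simdata.write_dataset(small_ds, tmp_path)
    g = genio.read_genotypes(paths["ped"], "plink_text")
    assert g.samples == small_ds.genotypes.samples
    np.testing.assert_array_equal(g.dosages, small_ds.genotypes.dosages)


def test_vcf_and_ped_encode_identical_genotypes(tmp_path, small_ds):
    paths = simdata.write_dataset(small_ds, tmp_path)
    g_ped = genio.read_genotypes(paths["ped"], "plink_text")
    g_vcf = genio.read_genotypes(paths["vcf"], "vcf")
    np.testing.assert_array_equal(g_ped.dosages, g_vcf.dosages)
    assert list(g_vcf.markers["id"]) == list(g_ped.markers["id"])


def test_round_trip_preserves_missing(tmp_path, small_ds):
    masked = simdata.inject_missing(small_ds.genotypes, 0.1, seed=3)
    ds = simdata.SimulatedDataset(
        genotypes=masked,
        phenotypes=small_ds.phenotypes,
        pedigree=small_ds.pedigree,
        families=small_ds.families,
        true_bv=small_ds.true_bv,
        true_effects=small_ds.true_effects,
    )
    paths = simdata.write_dataset(ds, tmp_path)
    for fmt, key in (("plink_text", "ped"), ("vcf", "vcf")):
        g = genio.read_genotypes(paths[key], fmt)
        np.testing.assert_array_equal(np.isnan(g.dosages), np.isnan(masked.dosages))


def test_hand_coded_ped(tmp_path):
    (tmp_path / "toy.map").write_text("1 m1 0 100\n1 m2 0 200\n")
    (tmp_path / "toy.ped").write_text(
        "f1 s1 0 0 0 -9 A A A B\n"
        "f2 s2 0 0 0 -9 A B B B\n"
        "f3 s3 0 0 0 -9 B B 0 0\n"
    )
    g = genio.read_genotypes(tmp_path / "toy.ped", "plink_text")
    expected = np.array([[0, 1], [1, 2], [2, np.nan]])
    np.testing.assert_array_equal(g.dosages, expected)


def test_truth_file_row_count(tmp_path, small_ds):
    paths = simdata.write_dataset(small_ds, tmp_path)
    truth = pd.read_csv(paths["truth_bv"], sep="\t")
    assert len(truth) == small_ds.genotypes.n_samples


def test_empty_marker_set_rejected(tmp_path):
    (tmp_path / "e.map").write_text("")
    (tmp_path / "e.ped").write_text("")
    with pytest.raises(ValueError, match="empty"):
        genio.read_genotypes(tmp_path / "e.ped", "plink_text")


def test_malformed_ped_line_reports_line_number(tmp_path):
    (tmp_path / "b.map").write_text("1 m1 0 100\n")
    (tmp_path / "b.ped").write_text("f1 s1 0 0 0 -9 A\n")
    with pytest.raises(ValueError, match=":1"):
        genio.read_genotypes(tmp_path / "b.ped", "plink_text")


# ---------------------------------------------------------------------------
# allele frequencies


def test_allele_frequency_arithmetic():
    g = make_gm([[0], [1], [2]])
    assert genio.allele_frequencies(g)[0] == 0.5
    g2 = make_gm([[2], [2], [np.nan]])
    assert genio.allele_frequencies(g2)[0] == 1.0


def test_allele_frequencies_match_per_marker_loop(rng):
    dos = rng.integers(0, 3, size=(60, 40)).astype(float)
    dos[rng.random(dos.shape) < 0.1] = np.nan
    g = make_gm(dos)
    p = genio.allele_frequencies(g)
    for j in range(40):
        col = dos[:, j]
        col = col[~np.isnan(col)]
        assert p[j] == pytest.approx(col.sum() / (2 * len(col)))


# ---------------------------------------------------------------------------
# HWE exact test


def hwe_oracle(n_aa2, n_het, n_aa1):
    """Exact-rational enumeration of the conditional heterozygote
    distribution given allele counts."""
    n = n_aa2 + n_het + n_aa1
    n_rare = 2 * min(n_aa2, n_aa1) + n_het

    def weight(h):
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        if rare_hom < 0 or common_hom < 0 or (n_rare - h) % 2:
            return Fraction(0)
        return Fraction(
            2**h * math.factorial(n),
            math.factorial(h) * math.factorial(rare_hom) * math.factorial(common_hom),
        )

    weights = {h: weight(h) for h in range(n_rare % 2, n_rare + 1, 2)}
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs))


@pytest.mark.parametrize(
    "counts", [(0, 0, 10), (3, 5, 2), (1, 1, 1), (10, 2, 10), (0, 7, 0)]
)
def test_hwe_matches_enumeration_oracle(counts):
    assert genio.hwe_exact_test(*counts) == pytest.approx(hwe_oracle(*counts), abs=1e-10)


def test_hwe_monomorphic_and_symmetry():
    assert genio.hwe_exact_test(0, 0, 25) == 1.0
    assert genio.hwe_exact_test(4, 6, 2) == pytest.approx(genio.hwe_exact_test(2, 6, 4))


# ---------------------------------------------------------------------------
# QC


def qc_toy():
    # 10 samples × 6 markers: m3 low MAF, m4 low call rate, m5 violates HWE
    rng = np.random.default_rng(1)
    dos = rng.binomial(2, 0.4, size=(10, 6)).astype(float)
    dos[:, 2] = 0.0
    dos[0, 2] = 1.0  # MAF 0.05 < 0.1 threshold used below
    dos[:3, 3] = np.nan  # call rate 0.7
    dos[:, 4] = [0, 2, 0, 2, 0, 2, 0, 2, 0, 2]  # no hets: extreme HWE violation
    dos[:, 0] = [1, 0, 1, 1, 0, 1, 0, 1, 1, 0]  # safe fillers
    dos[:, 1] = [1, 1, 0, 1, 2, 1, 0, 1, 2, 1]
    dos[:, 5] = [0, 1, 1, 2, 0, 1, 1, 2, 1, 0]
    return make_gm(dos)


def test_qc_removes_constructed_failures():
    g = qc_toy()
    out, report = genio.qc_filter(
        g, maf_min=0.1, marker_call_min=0.9, hwe_p_min=1e-2, sample_call_min=0.5
    )
    assert report.markers_removed_maf == 1
    assert report.markers_removed_call_rate == 1
    assert report.markers_removed_hwe == 1
    assert out.n_markers == 3
    assert report.n_markers_out == 3


def test_qc_sample_filter_precedes_marker_filters():
    g = qc_toy()
    dos = g.dosages.copy()
    dos[9, :4] = np.nan  # sample 9: 4/6 missing → call rate 1/3
    g2 = genio.GenotypeMatrix(g.samples, g.markers, dos)
    out, report = genio.qc_filter(g2, sample_call_min=0.5, maf_min=0.0,
                                  marker_call_min=0.0, hwe_p_min=0.0)
    assert report.samples_removed_call_rate == 1
    assert out.n_samples == 9


def test_qc_idempotent(std_ds):
    masked = simdata.inject_missing(std_ds.genotypes.subset_markers(np.arange(300)), 0.03, seed=8)
    once, _ = genio.qc_filter(masked)
    twice, rep2 = genio.qc_filter(once)
    assert rep2.n_markers_out == once.n_markers
    assert rep2.samples_removed_call_rate == 0
    assert twice.n_markers == once.n_markers


# ---------------------------------------------------------------------------
# imputation


def test_impute_marker_mean_fills_2p():
    g = make_gm([[0.0], [2.0], [np.nan], [0.0]])
    out = genio.impute_missing(g, "marker_mean")
    # p = 2/6 → fill 2p = 2/3
    assert out.dosages[2, 0] == pytest.approx(2.0 / 3.0)
    assert out.imputed_mask[2, 0]


def test_impute_identity_without_missing(small_ds):
    out = genio.impute_missing(small_ds.genotypes)
    np.testing.assert_array_equal(out.dosages, small_ds.genotypes.dosages)


def test_impute_preserves_allele_frequencies(std_ds):
    g = std_ds.genotypes.subset_markers(np.arange(400))
    masked = simdata.inject_missing(g, 0.05, seed=9)
    p_before = genio.allele_frequencies(masked)
    imputed = genio.impute_missing(masked, "marker_mean")
    np.testing.assert_allclose(genio.allele_frequencies(imputed), p_before, atol=1e-12)
    assert not np.isnan(imputed.dosages).any()


def test_impute_correlates_with_truth(std_ds):
    g = std_ds.genotypes.subset_markers(np.arange(500))
    masked = simdata.inject_missing(g, 0.1, seed=10)
    imputed = genio.impute_missing(masked, "marker_mean")
    miss = np.isnan(masked.dosages)
    r = np.corrcoef(imputed.dosages[miss], g.dosages[miss])[0, 1]
    assert r > 0
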