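"""Population generator: pedigree design, gene drop, trait architecture."""

import numpy as np
import pytest

from aquagp import kinship, simdata


def test_default_map_shape_and_invariants():
    gmap = simdata.default_map(n_chromosomes=5, chrom_length_cm=80, n_markers=200)
    assert gmap.n_markers == 200
    assert len(gmap.chromosomes) == 5
    for _, grp in gmap.markers.groupby("chrom"):
        assert (np.diff(grp["pos_cm"]) >= 0).all()


def test_founder_haplotype_frequencies_point_mass():
    gmap = simdata.default_map(n_chromosomes=2, n_markers=400)
    haps = simdata.simulate_founder_haplotypes(100, gmap, maf_law=(0.5, 0.5), seed=1)
    assert haps.shape == (200, 400)
    # mean frequency ≈ 0.5 within 3 SE of the Bernoulli mean over 200×400 draws
    se = 0.5 / np.sqrt(haps.size)
    assert abs(haps.mean() - 0.5) < 3 * se


def test_founder_haplotypes_deterministic_and_counts():
    gmap = simdata.default_map(n_chromosomes=2, n_markers=100)
    a = simdata.simulate_founder_haplotypes(60, gmap, seed=7)
    b = simdata.simulate_founder_haplotypes(60, gmap, seed=7)
    np.testing.assert_array_equal(a, b)
    assert a.shape[0] == 120


def test_founder_maf_law_validation():
    gmap = simdata.default_map(n_chromosomes=1, n_markers=10)
    with pytest.raises(ValueError):
        simdata.simulate_founder_haplotypes(10, gmap, maf_law=(0.0, 0.5))
    with pytest.raises(ValueError):
        simdata.simulate_founder_haplotypes(10, gmap, maf_law=(0.1, 0.7))


def test_ancestral_mosaic_founders_create_ld():
    gmap = simdata.default_map(n_chromosomes=4, n_markers=800)
    le = simdata.simulate_founder_haplotypes(80, gmap, seed=3)
    ld = simdata.simulate_founder_haplotypes(80, gmap, seed=3, n_ancestral=10)

    def adj_r2(h):
        z = (h - h.mean(0)) / np.where(h.std(0) == 0, np.inf, h.std(0))
        r = np.einsum("ij,ij->j", z[:, :-1], z[:, 1:]) / len(h)
        return np.nanmean(r**2)

    assert adj_r2(ld) > 10 * adj_r2(le)


def test_factorial_pedigree_carp_like():
    ped = simdata.make_factorial_pedigree(
        10, 5, n_blocks=4, n_families=195,
        family_size_law=("uniform", 1, 21), seed=2,
    )
    assert ped.n_families == 195
    assert len(ped.dams) == 20 and len(ped.sires) == 40
    assert ped.family_sizes.min() >= 1 and ped.family_sizes.max() <= 21
    # factorial block constraint: every mating pairs a sire and dam of one block
    for sire, dam in ped.matings:
        assert sire.split("_")[0][4:] == dam.split("_")[0][3:]


def test_single_family_pedigree():
    ped = simdata.make_factorial_pedigree(1, 1, family_size_law=("constant", 10), seed=0)
    assert ped.n_families == 1
    assert ped.n_offspring == 10


def test_family_capacity_enforced():
    with pytest.raises(ValueError, match="capacity"):
        simdata.make_factorial_pedigree(2, 2, n_blocks=1, n_families=5, seed=0)


def test_gene_drop_mendelian_consistency():
    gmap = simdata.default_map(n_chromosomes=3, n_markers=300)
    ped = simdata.make_factorial_pedigree(4, 3, family_size_law=("constant", 6), seed=4)
    haps = simdata.simulate_founder_haplotypes(len(ped.founders), gmap, seed=4)
    g = simdata.gene_drop(ped, haps, gmap, seed=5, include_founders=True)
    dosage = {s: g.dosages[i] for i, s in enumerate(g.samples)}
    off = ped.offspring_table()
    for _, row in off.iterrows():
        child, sire, dam = dosage[row["id"]], dosage[row["sire"]], dosage[row["dam"]]
        lo = (sire == 2).astype(int) + (dam == 2).astype(int)
        hi = (sire >= 1).astype(int) + (dam >= 1).astype(int)
        assert ((child >= lo) & (child <= hi)).all()


def test_gene_drop_zero_length_map_copies_parent_haplotypes():
    gmap = simdata.GeneticMap(
        chromosomes=[("1", 0.0)],
        markers=simdata.pd.DataFrame(
            {"chrom": ["1"] * 50, "pos_cm": [0.0] * 50, "id": [f"m{i}" for i in range(50)]}
        ),
    )
    ped = simdata.make_factorial_pedigree(1, 1, family_size_law=("constant", 40), seed=1)
    haps = simdata.simulate_founder_haplotypes(2, gmap, seed=2)
    g = simdata.gene_drop(ped, haps, gmap, seed=3)
    # every gamete is an exact parental haplotype → at most 4 distinct genotype rows
    assert len({tuple(r) for r in g.dosages}) <= 4


def test_full_sib_genomic_relationship_near_half(std_ds):
    G = kinship.build_G(std_ds.genotypes)
    fam = std_ds.families
    vals = []
    for f in fam.unique()[:40]:
        ids = list(fam[fam == f].index)
        if len(ids) < 2:
            continue
        sub = G.subset(ids).values
        vals.append(sub[np.triu_indices(len(ids), 1)].mean())
    assert np.mean(vals) == pytest.approx(0.5, abs=0.05)


def test_qtl_effect_class_counts_binomial():
    ds = simdata.simulate_dataset(
        n_sires=5, n_dams=4, n_blocks=1, n_families=20,
        family_size_law=("constant", 10), n_markers=3000, seed=6,
    )
    nonzero = (ds.true_effects["class"] > 0).sum()
    p = 0.05
    se = np.sqrt(3000 * p * (1 - p))
    assert abs(nonzero - 3000 * p) < 3 * se


def test_qtl_all_zero_class_rejected():
    arch = simdata.TraitArchitecture(class_proportions=(1, 0, 0, 0), target_h2=0.3)
    ds = simdata.simulate_dataset(
        n_sires=2, n_dams=2, n_blocks=1, family_size_law=("constant", 5),
        n_markers=50, arch=simdata.TraitArchitecture(class_proportions=(1, 0, 0, 0),
                                                     target_h2=0.0), seed=1,
    )
    with pytest.raises(ValueError, match="zero class"):
        simdata.assign_qtl_effects(arch, ds.genotypes, seed=2)


def test_effect_rescaling_hits_target_variance(small_ds):
    arch = simdata.TraitArchitecture(genetic_variance=2.5)
    eff = simdata.assign_qtl_effects(arch, small_ds.genotypes, seed=3)
    centered = small_ds.genotypes.dosages - small_ds.genotypes.dosages.mean(0)
    bv = centered @ eff["effect"].to_numpy()
    assert bv.var() / 2.5 == pytest.approx(1.0, abs=0.01)


def test_realized_h2_near_target_across_seeds():
    vals = []
    for seed in range(5):
        ds = simdata.simulate_dataset(
            n_sires=10, n_dams=5, n_blocks=2, n_families=84,
            family_size_law=("negative_binomial", 12, 3), n_markers=1000,
            seed=300 + seed,
        )
        vals.append(ds.true_bv.var() / ds.phenotypes["y"].var())
    assert np.mean(vals) == pytest.approx(0.25, abs=0.04)


def test_h2_one_means_phenotype_equals_bv_plus_fixed():
    arch = simdata.TraitArchitecture(target_h2=1.0, factor_levels=(), covariate_slope=0.0)
    ds = simdata.simulate_dataset(
        n_sires=3, n_dams=3, n_blocks=1, family_size_law=("constant", 8),
        n_markers=300, arch=arch, seed=8,
    )
    np.testing.assert_allclose(
        ds.phenotypes["y"].to_numpy() - arch.mean, ds.true_bv.to_numpy(), atol=1e-10
    )


def test_inject_missing_rate_and_identity(rng, small_ds):
    g = small_ds.genotypes
    assert simdata.inject_missing(g, 0.0, seed=1) is g
    masked = simdata.inject_missing(g, 0.05, seed=2)
    frac = np.isnan(masked.dosages).mean()
    se = np.sqrt(0.05 * 0.95 / masked.dosages.size)
    assert abs(frac - 0.05) < 3 * se


def test_dataset_determinism():
    kw = dict(n_sires=4, n_dams=3, n_blocks=1, family_size_law=("constant", 6),
              n_markers=200, seed=123)
    a = simdata.simulate_dataset(**kw)
    b = simdata.simulate_dataset(**kw)
    np.testing.assert_array_equal(a.genotypes.dosages, b.genotypes.dosages)
    np.testing.assert_array_equal(a.phenotypes["y"], b.phenotypes["y"])
    np.testing.assert_array_equal(a.true_effects["effect"], b.true_effects["effect"])
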