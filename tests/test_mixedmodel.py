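"""REML and BLUP: grid-search oracle, equivalences, invariances."""

import numpy as np
import pandas as pd
import pytest

from aquagp import kinship, mixedmodel as mm, simdata
from aquagp.genio import allele_frequencies


def reml_loglik_direct(y, X, V):
    """Straight-line restricted log-likelihood for the grid oracle."""
    Vinv = np.linalg.inv(V)
    XtVinvX = X.T @ Vinv @ X
    beta = np.linalg.solve(XtVinvX, X.T @ Vinv @ y)
    P_y = Vinv @ (y - X @ beta)
    return -0.5 * (
        np.linalg.slogdet(V)[1] + np.linalg.slogdet(XtVinvX)[1] + y @ P_y
    )


def test_reml_matches_grid_search_on_tiny_data():
    rng = np.random.default_rng(4)
    n = 8
    K = rng.standard_normal((n, 12))
    K = K @ K.T / 12 + np.eye(n) * 0.2
    kern = kinship.RelationshipMatrix([f"s{i}" for i in range(n)], K, "G")
    L = np.linalg.cholesky(K)
    y = 1.5 + L @ rng.standard_normal(n) * 0.7 + rng.standard_normal(n) * 1.0
    data = pd.DataFrame({"id": kern.ids, "y": y})
    spec = mm.ModelSpec("y", [], [], [kern])
    vc = mm.fit_reml(spec, data)
    X = np.ones((n, 1))
    grid = np.linspace(0.01, 5.0, 150)
    best, best_ll = None, -np.inf
    for sa in grid:
        for se in grid:
            ll = reml_loglik_direct(y, X, sa * K + se * np.eye(n))
            if ll > best_ll:
                best, best_ll = (sa, se), ll
    assert vc.loglik >= best_ll - 1e-4
    assert vc.components["G"] == pytest.approx(best[0], abs=0.07)
    assert vc.sigma_e2 == pytest.approx(best[1], abs=0.07)


def test_reml_boundary_at_h2_zero():
    from tests.conftest import standard_dataset

    for seed in range(3):
        ds = standard_dataset(
            n_markers=1000,
            arch=simdata.TraitArchitecture(class_proportions=(1, 0, 0, 0), target_h2=0.0),
            seed=900 + seed,
        )
        G = kinship.build_G(ds.genotypes)
        vc = mm.fit_reml(mm.ModelSpec("y", ds.fixed_factors, [], [G]), ds.phenotypes)
        assert vc.components["G"] < 0.02 * (vc.genetic_variance + vc.sigma_e2)


def test_rank_deficient_design_rejected():
    data = pd.DataFrame(
        {"id": list("abcdef"), "y": np.arange(6.0),
         "f1": ["x", "x", "y", "y", "z", "z"], "f2": ["x", "x", "y", "y", "z", "z"]}
    )
    with pytest.raises(ValueError, match="rank deficient"):
        mm.build_design(data, ["f1", "f2"], [])


def test_blup_zero_genetic_variance_limit(small_ds):
    G = kinship.build_G(small_ds.genotypes)
    spec = mm.ModelSpec("y", small_ds.fixed_factors, [], [G])
    vc = mm.VarianceEstimates(
        components={"G": 1e-12}, sigma_e2=1.0, h2=0.0, loglik=0.0,
        converged=True, n_iter=0,
    )
    pred = mm.solve_blup(spec, small_ds.phenotypes, vc)
    assert np.abs(pred.gebv).max() < 1e-8
    # fixed effects collapse to ordinary least squares
    X, _ = mm.build_design(small_ds.phenotypes, small_ds.fixed_factors, [])
    y = small_ds.phenotypes["y"].to_numpy()
    ols = np.linalg.lstsq(X, y, rcond=None)[0]
    np.testing.assert_allclose(pred.fixed_effects.to_numpy(), ols, atol=1e-6)


def test_gblup_equals_snp_blup(small_ds):
    """GEBVs from the kernel solver equal Z·û from the marker-ridge system."""
    g = small_ds.genotypes
    G = kinship.build_G(g)
    spec = mm.ModelSpec("y", small_ds.fixed_factors, [], [G])
    vc = mm.fit_reml(spec, small_ds.phenotypes)
    pred = mm.solve_blup(spec, small_ds.phenotypes, vc)
    p = allele_frequencies(g)
    twopq = 2 * p * (1 - p)
    poly = twopq > 0
    k = twopq[poly].sum()
    Z = g.dosages[:, poly] - 2 * p[poly]
    X, _ = mm.build_design(small_ds.phenotypes, small_ds.fixed_factors, [])
    y = small_ds.phenotypes["y"].to_numpy()
    lam = vc.sigma_e2 / (vc.genetic_variance / k)
    mme = np.block(
        [[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + lam * np.eye(Z.shape[1])]]
    )
    sol = np.linalg.solve(mme, np.concatenate([X.T @ y, Z.T @ y]))
    np.testing.assert_allclose(
        pred.gebv.to_numpy(), Z @ sol[X.shape[1]:], atol=1e-6
    )


def test_blup_satisfies_mixed_model_equations(small_ds):
    """Normal-equation residual of Henderson's MME < 1e-8 on a nonsingular
    (blended) kernel."""
    g = small_ds.genotypes
    Gb = kinship.blend(kinship.build_G(g))
    spec = mm.ModelSpec("y", small_ds.fixed_factors, [], [Gb])
    vc = mm.fit_reml(spec, small_ds.phenotypes)
    pred = mm.solve_blup(spec, small_ds.phenotypes, vc)
    X, _ = mm.build_design(small_ds.phenotypes, small_ds.fixed_factors, [])
    y = small_ds.phenotypes["y"].to_numpy()
    lam = vc.sigma_e2 / vc.genetic_variance
    Ginv = np.linalg.inv(Gb.values)
    b = pred.fixed_effects.to_numpy()
    u = pred.gebv.to_numpy()
    r1 = X.T @ X @ b + X.T @ u - X.T @ y
    r2 = X @ b + (np.eye(len(u)) + lam * Ginv) @ u - y
    scale = max(np.abs(y).max(), 1.0)
    assert np.abs(np.concatenate([r1 / len(y), r2])).max() / scale < 1e-8


def test_gfblup_equal_variances_collapse_to_gblup(small_ds):
    """With σf² = σr² and the matched Σ2pq scaling, the two-kernel GEBV sum
    equals single-kernel GBLUP on the recombined G."""
    g = small_ds.genotypes
    feat = list(g.markers["id"][:250])
    Gf, Gr = kinship.split_feature_G(g, feat)
    p = allele_frequencies(g)
    twopq = 2 * p * (1 - p)
    kf, kr = twopq[:250].sum(), twopq[250:].sum()
    k = kf + kr
    G = kinship.build_G(g)
    sigma = 0.4
    vc2 = mm.VarianceEstimates(
        components={"G_feature": sigma * kf / k, "G_residual": sigma * kr / k},
        sigma_e2=0.6, h2=0.4, loglik=0.0, converged=True, n_iter=0,
    )
    vc1 = mm.VarianceEstimates(
        components={"G": sigma}, sigma_e2=0.6, h2=0.4, loglik=0.0,
        converged=True, n_iter=0,
    )
    spec2 = mm.ModelSpec("y", small_ds.fixed_factors, [], [Gf, Gr])
    spec1 = mm.ModelSpec("y", small_ds.fixed_factors, [], [G])
    p2 = mm.solve_blup(spec2, small_ds.phenotypes, vc2)
    p1 = mm.solve_blup(spec1, small_ds.phenotypes, vc1)
    np.testing.assert_allclose(p2.gebv.to_numpy(), p1.gebv.to_numpy(), atol=1e-6)


def test_gebv_shift_equivariance(small_ds):
    G = kinship.build_G(small_ds.genotypes)
    spec = mm.ModelSpec("y", small_ds.fixed_factors, [], [G])
    vc = mm.fit_reml(spec, small_ds.phenotypes)
    pred = mm.solve_blup(spec, small_ds.phenotypes, vc)
    shifted = small_ds.phenotypes.copy()
    shifted["y"] = shifted["y"] + 7.5
    pred2 = mm.solve_blup(spec, shifted, vc)
    np.testing.assert_allclose(pred.gebv.to_numpy(), pred2.gebv.to_numpy(), atol=1e-8)
    assert pred2.fixed_effects["intercept"] == pytest.approx(
        pred.fixed_effects["intercept"] + 7.5, abs=1e-8
    )


def test_masked_records_do_not_influence_fit(std_ds, std_spec):
    G = kinship.build_G(std_ds.genotypes)
    spec = mm.ModelSpec("y", std_spec.factors, [], [G])
    ids = list(std_ds.phenotypes["id"])
    train = ids[: len(ids) * 4 // 5]
    vc, pred = mm.fit_and_predict(spec, std_ds.phenotypes, train_ids=train)
    perturbed = std_ds.phenotypes.copy()
    mask = ~perturbed["id"].isin(set(train))
    perturbed.loc[mask, "y"] += 100.0
    vc2, pred2 = mm.fit_and_predict(spec, perturbed, train_ids=train)
    assert vc.loglik == pytest.approx(vc2.loglik)
    np.testing.assert_allclose(pred.gebv.to_numpy(), pred2.gebv.to_numpy(), atol=1e-10)


def test_no_pedigree_blup_unavailable(std_ds, std_spec):
    from aquagp.evalpipe import _fit_method

    out = _fit_method(
        "BLUP", std_ds.genotypes, std_ds.phenotypes.set_index("id", drop=False),
        std_spec, list(std_ds.phenotypes["id"][:100]), None, None, None, None, 0.05,
    )
    assert out is None


def test_two_kernel_reml_recovers_variance_ordering(std_ds):
    """Feature kernel built on the truly enriched marker set should get the
    larger variance share in most splits."""
    g = std_ds.genotypes
    big = set(std_ds.true_effects.loc[std_ds.true_effects["class"] >= 2, "id"])
    Gf, Gr = kinship.split_feature_G(g, big)
    spec = mm.ModelSpec("y", std_ds.fixed_factors, [], [Gf, Gr])
    vc = mm.fit_reml(spec, std_ds.phenotypes)
    assert vc.components["G_feature"] > vc.components["G_residual"]
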