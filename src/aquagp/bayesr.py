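"""BayesR: Gibbs sampler for the four-class mixture model of SNP effects.

Each SNP effect u_j belongs to one of four normal classes with variances
(0, 0.0001, 0.001, 0.01)·σg², where σg² is the total genetic variance; class
memberships, effects, mixture proportions π ~ Dirichlet, fixed effects and
the residual variance are sampled by single-site Gibbs.  σg² anchoring the
class variances is fixed at a preliminary GBLUP REML estimate on the same
training records (the original BayesR formulation; a config switch resamples
it each cycle instead).  An optional polygenic term v ~ N(0, A σa²) is
sampled through the pedigree-relationship Cholesky factor; v enters the model
residual structure but is excluded from the GEBV, which is the sum of SNP
effects given the SNP genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .genio import GenotypeMatrix
from .kinship import RelationshipMatrix, build_G
from .mixedmodel import ModelSpec, PredictionResult, build_design, fit_reml

__all__ = ["BayesRConfig", "BayesRChain", "run_bayesr", "gebv_from_chain"]

CLASS_MULTIPLIERS = (0.0, 1e-4, 1e-3, 1e-2)


@dataclass
class BayesRConfig:
    """Chain settings; defaults are the standard 50,000-cycle protocol."""

    n_iter: int = 50_000
    burn_in: int = 10_000
    thin: int = 10
    class_multipliers: tuple = CLASS_MULTIPLIERS
    dirichlet_alpha: tuple = (1.0, 1.0, 1.0, 1.0)
    seed: int = 0
    polygenic: bool = True
    resample_sigma_g: bool = False
    sigma_g2: float | None = None  # fixed anchor; None = take from GBLUP REML

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be ≥ 1")
        m = np.asarray(self.class_multipliers)
        if np.any(m < 0) or np.any(np.diff(m) < 0):
            raise ValueError("class multipliers must be non-negative, non-decreasing")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class BayesRChain:
    """Posterior summaries and scalar traces from one BayesR run."""

    marker_ids: pd.Index
    u_mean: np.ndarray  # posterior-mean SNP effects
    class_probs: np.ndarray  # m × 4 membership probabilities
    pi_samples: np.ndarray  # R × 4 mixture proportions
    sigma_e2_samples: np.ndarray
    sigma_g2_samples: np.ndarray
    v_mean: np.ndarray | None  # posterior-mean polygenic effects (train order)
    centers: np.ndarray  # column centering used for W
    n_retained: int
    config: BayesRConfig = field(repr=False, default=None)

    def summary(self) -> pd.DataFrame:
        cols = {f"p_class{k}": self.class_probs[:, k] for k in range(4)}
        return pd.DataFrame({"id": self.marker_ids, "effect": self.u_mean, **cols})


@njit(cache=True)
def _gibbs(
    y, X, W, wtw, xtx, L, ltl, use_poly,
    mults, alpha, sigma_g2_init, resample_sigma_g,
    n_iter, burn_in, thin, seed,
):
    np.random.seed(seed)
    n = y.shape[0]
    p = X.shape[1]
    m = W.shape[1]
    nc = mults.shape[0]
    b = np.zeros(p)
    u = np.zeros(m)
    classes = np.zeros(m, dtype=np.int64)
    pi = alpha / alpha.sum()
    a = np.zeros(n)  # whitened polygenic coefficients, v = L a
    sigma_g2 = sigma_g2_init
    sigma_e2 = np.var(y)
    sigma_a2 = 0.1 * np.var(y) + 1e-8
    e = y.copy()

    n_ret = (n_iter - burn_in) // thin
    u_sum = np.zeros(m)
    v_sum = np.zeros(n)
    class_counts = np.zeros((m, nc))
    pi_out = np.zeros((n_ret, nc))
    se_out = np.zeros(n_ret)
    sg_out = np.zeros(n_ret)
    logp = np.empty(nc)

    for it in range(1, n_iter + 1):
        # fixed effects, flat prior
        for k in range(p):
            xk = X[:, k]
            rhs = xk @ e + xtx[k] * b[k]
            mean = rhs / xtx[k]
            bnew = mean + np.random.standard_normal() * np.sqrt(sigma_e2 / xtx[k])
            diff = b[k] - bnew
            for i in range(n):
                e[i] += xk[i] * diff
            b[k] = bnew
        # SNP effects: marginalized class draw, then conditional normal
        counts = np.zeros(nc)
        for j in range(m):
            wj = W[:, j]
            rhs = wj @ e + wtw[j] * u[j]
            maxlp = -1e300
            for k in range(nc):
                v = mults[k] * sigma_g2
                if v <= 0.0:
                    logp[k] = np.log(pi[k] + 1e-300)
                else:
                    lhs = wtw[j] + sigma_e2 / v
                    logp[k] = (
                        np.log(pi[k] + 1e-300)
                        - 0.5 * np.log(v * lhs / sigma_e2)
                        + 0.5 * rhs * rhs / (sigma_e2 * lhs)
                    )
                if logp[k] > maxlp:
                    maxlp = logp[k]
            tot = 0.0
            for k in range(nc):
                logp[k] = np.exp(logp[k] - maxlp)
                tot += logp[k]
            r = np.random.random() * tot
            cls = nc - 1
            acc = 0.0
            for k in range(nc):
                acc += logp[k]
                if r <= acc:
                    cls = k
                    break
            classes[j] = cls
            counts[cls] += 1.0
            if mults[cls] * sigma_g2 <= 0.0:
                unew = 0.0
            else:
                lhs = wtw[j] + sigma_e2 / (mults[cls] * sigma_g2)
                unew = rhs / lhs + np.random.standard_normal() * np.sqrt(sigma_e2 / lhs)
            diff = u[j] - unew
            if diff != 0.0:
                for i in range(n):
                    e[i] += wj[i] * diff
            u[j] = unew
        # mixture proportions
        tot = 0.0
        for k in range(nc):
            pi[k] = np.random.gamma(alpha[k] + counts[k], 1.0)
            tot += pi[k]
        for k in range(nc):
            pi[k] /= tot
        # polygenic term via A = L L'
        if use_poly:
            for i2 in range(n):
                li = L[:, i2]
                rhs = li @ e + ltl[i2] * a[i2]
                lhs = ltl[i2] + sigma_e2 / sigma_a2
                anew = rhs / lhs + np.random.standard_normal() * np.sqrt(sigma_e2 / lhs)
                diff = a[i2] - anew
                if diff != 0.0:
                    for i in range(n):
                        e[i] += li[i] * diff
                a[i2] = anew
            sigma_a2 = (a @ a) / (2.0 * np.random.gamma(max(n - 2, 1) / 2.0, 1.0))
        # residual variance, flat scaled-inv-chi-square (nu = -2)
        sigma_e2 = (e @ e) / (2.0 * np.random.gamma(max(n - 2, 1) / 2.0, 1.0))
        # optional resampling of the genetic-variance anchor
        if resample_sigma_g:
            ssq = 0.0
            kk = 0
            for j in range(m):
                if classes[j] > 0:
                    ssq += u[j] * u[j] / mults[classes[j]]
                    kk += 1
            if kk > 2:
                sigma_g2 = ssq / (2.0 * np.random.gamma((kk - 2) / 2.0, 1.0))
        if it > burn_in and (it - burn_in) % thin == 0:
            r_idx = (it - burn_in) // thin - 1
            for j in range(m):
                u_sum[j] += u[j]
                class_counts[j, classes[j]] += 1.0
            if use_poly:
                v = L @ a
                for i in range(n):
                    v_sum[i] += v[i]
            for k in range(nc):
                pi_out[r_idx, k] = pi[k]
            se_out[r_idx] = sigma_e2
            sg_out[r_idx] = sigma_g2
    return u_sum, class_counts, pi_out, se_out, sg_out, v_sum


def run_bayesr(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    spec: ModelSpec,
    A: RelationshipMatrix | None = None,
    cfg: BayesRConfig | None = None,
) -> BayesRChain:
    """Run the BayesR Gibbs chain on the training records in ``phenotypes``.

    ``spec`` supplies response/fixed-effect names (its kernels are ignored —
    marker effects replace the genomic kernel here).  Fractional (imputed)
    dosages are rounded to the nearest integer before building the design.
    When no pedigree matrix ``A`` is supplied the polygenic term is dropped
    with a warning, mirroring how populations without pedigrees are handled.
    """
    import warnings

    cfg = cfg or BayesRConfig()
    ids = list(phenotypes["id"])
    pos = {s: i for i, s in enumerate(genotypes.samples)}
    ridx = np.array([pos[s] for s in ids])
    W_raw = np.rint(genotypes.dosages[ridx]).astype(float)
    centers = W_raw.mean(axis=0)
    W = W_raw - centers
    y = phenotypes[spec.response].to_numpy(dtype=float)
    X, _ = build_design(phenotypes, spec.factors, spec.covariates)

    sigma_g2 = cfg.sigma_g2
    if sigma_g2 is None:
        gspec = ModelSpec(
            spec.response, spec.factors, spec.covariates,
            kernels=[build_G(genotypes.subset_samples(ridx))],
        )
        sigma_g2 = fit_reml(gspec, phenotypes).genetic_variance

    use_poly = cfg.polygenic and A is not None
    if cfg.polygenic and A is None:
        warnings.warn("no pedigree supplied: polygenic term dropped", stacklevel=2)
    if use_poly:
        Asub = A.subset(ids).values + 1e-8 * np.eye(len(ids))
        L = np.linalg.cholesky(Asub)
    else:
        L = np.zeros((len(ids), 1))
    ltl = (L**2).sum(axis=0)
    wtw = (W**2).sum(axis=0)
    wtw = np.maximum(wtw, 1e-12)  # zero-variance markers stay in the zero class
    xtx = (X**2).sum(axis=0)

    u_sum, class_counts, pi_out, se_out, sg_out, v_sum = _gibbs(
        y, np.asfortranarray(X), np.asfortranarray(W), wtw, xtx,
        np.asfortranarray(L), ltl, use_poly,
        np.asarray(cfg.class_multipliers, dtype=float),
        np.asarray(cfg.dirichlet_alpha, dtype=float),
        float(sigma_g2), cfg.resample_sigma_g,
        cfg.n_iter, cfg.burn_in, cfg.thin, cfg.seed,
    )
    R = cfg.n_retained
    return BayesRChain(
        marker_ids=pd.Index(genotypes.markers["id"]),
        u_mean=u_sum / R,
        class_probs=class_counts / R,
        pi_samples=pi_out,
        sigma_e2_samples=se_out,
        sigma_g2_samples=sg_out,
        v_mean=(v_sum / R)[: len(ids)] if use_poly else None,
        centers=centers,
        n_retained=R,
        config=cfg,
    )


def gebv_from_chain(chain: BayesRChain, genotypes: GenotypeMatrix) -> PredictionResult:
    """GEBV = centered genotype design times the posterior-mean SNP effects.

    The polygenic term is excluded: the GEBV is the sum of SNP effects given
    the SNP genotypes.  Marker sets must match the chain exactly.
    """
    if not chain.marker_ids.equals(pd.Index(genotypes.markers["id"])):
        raise ValueError("marker set does not match the chain")
    W = np.rint(genotypes.dosages).astype(float) - chain.centers
    gebv = W @ chain.u_mean
    idx = pd.Index(genotypes.samples, name="id")
    return PredictionResult(
        gebv=pd.Series(gebv, index=idx, name="gebv"),
        by_kernel=pd.DataFrame({"snp": gebv}, index=idx),
        fixed_effects=pd.Series(dtype=float),
        method="BayesR",
    )
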