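"""Variance components (average-information REML with EM safeguarding) and
BLUP for one- or two-kernel animal models.

The model is y = Xb + Σ_k L g_k + e with g_k ~ N(0, K_k σ_k²) for kernels
K_k (pedigree A, genomic G, or a feature split G_f/G_r) and e ~ N(0, I σe²).
Each phenotyped record maps to exactly one genetic-effect level, so on a
training subset the kernel simply restricts to the training rows/columns.

Predictions use the covariance form ĝ_k = σ_k² K_k[·, train] V⁻¹ (y − Xb̂),
which is algebraically identical to solving Henderson's mixed-model equations
but remains defined when a kernel is singular (e.g. a raw VanRaden G with
duplicated full-sibs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship import RelationshipMatrix

__all__ = [
    "ModelSpec",
    "VarianceEstimates",
    "PredictionResult",
    "build_design",
    "fit_reml",
    "solve_blup",
    "fit_and_predict",
]

logger = logging.getLogger(__name__)


@dataclass
class ModelSpec:
    """Response, fixed effects, and the genetic kernels of a mixed model."""

    response: str
    factors: list[str] = field(default_factory=list)
    covariates: list[str] = field(default_factory=list)
    kernels: list[RelationshipMatrix] = field(default_factory=list)

    def kernel_names(self) -> list[str]:
        return [k.kind for k in self.kernels]


@dataclass
class VarianceEstimates:
    """REML estimates: one variance per kernel plus the residual."""

    components: dict  # kernel kind -> variance
    sigma_e2: float
    h2: float
    loglik: float
    converged: bool
    n_iter: int
    se: dict = field(default_factory=dict)

    @property
    def genetic_variance(self) -> float:
        return float(sum(self.components.values()))


@dataclass
class PredictionResult:
    """Per-individual GEBVs (total and per kernel) plus fixed-effect estimates."""

    gebv: pd.Series  # indexed by individual id, total genetic value
    by_kernel: pd.DataFrame
    fixed_effects: pd.Series
    method: str = "GBLUP"


def build_design(
    data: pd.DataFrame, factors: list[str], covariates: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design: intercept + reference-coded factor dummies +
    covariates.  The first observed level of each factor is the reference.
    Raises on rank deficiency, naming the aliased columns.
    """
    n = len(data)
    cols = [np.ones(n)]
    names = ["intercept"]
    for f in factors:
        levels = pd.unique(data[f])
        for lev in levels[1:]:
            cols.append((data[f] == lev).to_numpy(dtype=float))
            names.append(f"{f}[{lev}]")
    for c in covariates:
        cols.append(data[c].to_numpy(dtype=float))
        names.append(c)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by pivoted QR
        _, r = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-8]
        raise ValueError(f"fixed-effect design is rank deficient; aliased: {bad}")
    return X, names


def _prepare(spec: ModelSpec, data: pd.DataFrame):
    used = [spec.response] + spec.factors + spec.covariates
    ok = data[used].notna().all(axis=1)
    if (~ok).any():
        logger.info("dropping %d records with missing response/fixed effects", int((~ok).sum()))
        data = data.loc[ok]
    ids = list(data["id"])
    y = data[spec.response].to_numpy(dtype=float)
    X, names = build_design(data, spec.factors, spec.covariates)
    Ks = [k.subset(ids).values for k in spec.kernels]
    return ids, y, X, names, Ks


def _reml_loglik(y, X, V):
    c, low = _chol(V)
    from scipy.linalg import cho_solve

    Vinv_y = cho_solve((c, low), y)
    Vinv_X = cho_solve((c, low), X)
    XtVinvX = X.T @ Vinv_X
    sign, logdet_xvx = np.linalg.slogdet(XtVinvX)
    logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
    beta = np.linalg.solve(XtVinvX, X.T @ Vinv_y)
    Py = Vinv_y - Vinv_X @ beta
    ll = -0.5 * (logdet_v + logdet_xvx + float(y @ Py))
    return ll, Py, Vinv_X, XtVinvX, (c, low)


def _chol(V):
    from scipy.linalg import cho_factor

    return cho_factor(V, lower=True)


def fit_reml(
    spec: ModelSpec,
    data: pd.DataFrame,
    max_iter: int = 200,
    tol: float = 1e-8,
    verbose: bool = False,
) -> VarianceEstimates:
    """Average-information REML with EM fallback.

    AI steps are taken whenever they keep all variances inside bounds and do
    not decrease the restricted likelihood; otherwise the guaranteed-ascent EM
    update is used.  Convergence: relative parameter change < ``tol`` or
    ``max_iter`` iterations (boundary estimates returned flagged either way).
    """
    from scipy.linalg import cho_solve

    ids, y, X, names, Ks = _prepare(spec, data)
    n, p = X.shape
    if n <= p:
        raise ValueError("fewer records than fixed-effect columns")
    vary = float(np.var(y))
    if vary == 0:
        raise ValueError("response has zero variance")
    K = len(Ks)
    theta = np.full(K + 1, vary / 2.0)
    theta[:K] /= K
    lb = 1e-8 * vary
    ub = 100.0 * vary

    def V_of(th):
        V = th[K] * np.eye(n)
        for k in range(K):
            V += th[k] * Ks[k]
        return V

    ll, Py, Vinv_X, XtVinvX, chol = _reml_loglik(y, X, V_of(theta))
    converged = False
    it = 0
    AI = None
    for it in range(1, max_iter + 1):
        # score and AI matrix; G_e = I handled as the last "kernel"
        KPy = [Ks[k] @ Py for k in range(K)] + [Py.copy()]
        # P v = V⁻¹v − V⁻¹X (X'V⁻¹X)⁻¹ X'V⁻¹ v for arbitrary v
        c, low = chol

        def P_dot(v):
            Vinv_v = cho_solve((c, low), v)
            return Vinv_v - Vinv_X @ np.linalg.solve(XtVinvX, Vinv_X.T @ v)

        PKPy = [P_dot(v) for v in KPy]
        # tr(P K) = tr(V⁻¹K) − tr((X'V⁻¹X)⁻¹ X'V⁻¹ K V⁻¹ X)
        Vinv = cho_solve((c, low), np.eye(n))
        W = np.linalg.solve(XtVinvX, Vinv_X.T)
        trPK = np.empty(K + 1)
        score = np.empty(K + 1)
        for k in range(K + 1):
            Kk = Ks[k] if k < K else None
            if Kk is None:
                trPK[k] = np.trace(Vinv) - np.sum(W * Vinv_X.T)
            else:
                trPK[k] = np.sum(Vinv * Kk) - np.sum(W * (Kk @ Vinv_X).T)
            # y'P K P y = (Py)' K (Py)
            score[k] = -0.5 * (trPK[k] - float(Py @ KPy[k]))
        AI = 0.5 * np.array(
            [[float(KPy[i] @ PKPy[j]) for j in range(K + 1)] for i in range(K + 1)]
        )
        # proposed AI step
        new = state = None
        try:
            delta = np.linalg.solve(AI, score)
            cand = np.clip(theta + delta, lb, ub)
            state = _reml_loglik(y, X, V_of(cand))
            if state[0] >= ll - 1e-10:
                new = cand
        except np.linalg.LinAlgError:
            pass
        if new is None:
            # EM update: θ ← θ + θ² (y'P K P y − tr(P K)) / n  (ascent step)
            yPKPy = np.array([float(Py @ KPy[k]) for k in range(K + 1)])
            new = np.clip(theta + theta**2 * (yPKPy - trPK) / n, lb, ub)
            state = _reml_loglik(y, X, V_of(new))
        rel = np.max(np.abs(new - theta) / np.maximum(np.abs(theta), 1e-4 * vary))
        theta = new
        ll, Py, Vinv_X, XtVinvX, chol = state
        if verbose:
            logger.info("REML iter %d: ll=%.6f theta=%s", it, ll, theta)
        if rel < tol:
            converged = True
            break

    comps = {spec.kernels[k].kind: float(theta[k]) for k in range(K)}
    genetic = float(theta[:K].sum())
    se = {}
    if AI is not None:
        try:
            cov = np.linalg.inv(AI)
            labels = list(comps) + ["sigma_e2"]
            se = {lab: float(np.sqrt(max(cov[i, i], 0.0))) for i, lab in enumerate(labels)}
        except np.linalg.LinAlgError:
            pass
    return VarianceEstimates(
        components=comps,
        sigma_e2=float(theta[K]),
        h2=genetic / (genetic + float(theta[K])),
        loglik=float(ll),
        converged=converged,
        n_iter=it,
        se=se,
    )


def solve_blup(
    spec: ModelSpec, data: pd.DataFrame, vc: VarianceEstimates
) -> PredictionResult:
    """BLUP at the given variance components.

    ``data`` holds the phenotyped (training) records; predictions are
    returned for every individual present in the kernels, including those
    with masked phenotypes.
    """
    from scipy.linalg import cho_factor, cho_solve

    ids, y, X, names, Ks = _prepare(spec, data)
    n = len(ids)
    K = len(Ks)
    theta = [vc.components[k.kind] for k in spec.kernels]
    V = vc.sigma_e2 * np.eye(n)
    for k in range(K):
        V += theta[k] * Ks[k]
    c = cho_factor(V, lower=True)
    Vinv_y = cho_solve(c, y)
    Vinv_X = cho_solve(c, X)
    XtVinvX = X.T @ Vinv_X
    beta = np.linalg.solve(XtVinvX, X.T @ Vinv_y)
    alpha = cho_solve(c, y - X @ beta)

    all_ids = list(spec.kernels[0].ids)
    pos = {s: i for i, s in enumerate(all_ids)}
    tr_idx = np.array([pos[s] for s in ids])
    parts = {}
    total = np.zeros(len(all_ids))
    for k, kern in enumerate(spec.kernels):
        gk = theta[k] * (kern.values[:, tr_idx] @ alpha)
        parts[kern.kind] = gk
        total += gk
    idx = pd.Index(all_ids, name="id")
    return PredictionResult(
        gebv=pd.Series(total, index=idx, name="gebv"),
        by_kernel=pd.DataFrame(parts, index=idx),
        fixed_effects=pd.Series(beta, index=names),
    )


def fit_and_predict(
    spec: ModelSpec,
    data: pd.DataFrame,
    train_ids=None,
    method: str = "GBLUP",
) -> tuple[VarianceEstimates, PredictionResult]:
    """REML on the training records only, then BLUP prediction for everyone
    in the kernels.  ``train_ids=None`` trains on all phenotyped records."""
    if train_ids is not None:
        train = data[data["id"].isin(set(train_ids))]
    else:
        train = data
    vc = fit_reml(spec, train)
    pred = solve_blup(spec, train, vc)
    pred.method = method
    return vc, pred
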