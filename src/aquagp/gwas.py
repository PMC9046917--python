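"""Mixed-linear-model single-SNP association scan and p-value feature
selection for the genomic-feature BLUP.

The scan is two-stage: variance components (σa², σe²) are estimated once by
REML under the null polygenic model y = Xb + g + e with the all-marker G,
then each marker is tested by generalized least squares with the fitted
covariance held fixed (the standard fast MLM-GWAS approximation).  Wald
p-values come from the normal approximation.  The tested marker is not
removed from G (proximal contamination accepted; ``loco``-style exclusion is
out of scope here).  No multiple-testing correction is applied — feature
selection deliberately uses the raw per-marker threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix
from .kinship import RelationshipMatrix
from .mixedmodel import ModelSpec, VarianceEstimates, build_design, fit_reml

__all__ = ["GwasResult", "mlm_gwas", "select_features"]


@dataclass
class GwasResult:
    """Per-marker effect, SE, Wald statistic and p-value."""

    table: pd.DataFrame  # id, chrom, pos, effect, se, z, p, tested
    vc: VarianceEstimates

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def mlm_gwas(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    spec: ModelSpec,
    G: RelationshipMatrix,
    vc: VarianceEstimates | None = None,
) -> GwasResult:
    """Association scan on the (training) records in ``phenotypes``.

    Markers with zero variance among the tested records are flagged
    ``tested=False`` with p = 1, as are markers collinear with the fixed
    effects.
    """
    from scipy.linalg import cho_factor, cho_solve

    ids = list(phenotypes["id"])
    null_spec = ModelSpec(spec.response, spec.factors, spec.covariates, [G])
    if vc is None:
        vc = fit_reml(null_spec, phenotypes)
    y = phenotypes[spec.response].to_numpy(dtype=float)
    X, _ = build_design(phenotypes, spec.factors, spec.covariates)
    Gtr = G.subset(ids).values
    V = vc.genetic_variance * Gtr + vc.sigma_e2 * np.eye(len(ids))
    c = cho_factor(V, lower=True)
    Vinv_X = cho_solve(c, X)
    XtVinvX = X.T @ Vinv_X
    # P = V⁻¹ − V⁻¹X(X'V⁻¹X)⁻¹X'V⁻¹ applied to y and all marker columns
    Py = cho_solve(c, y) - Vinv_X @ np.linalg.solve(XtVinvX, Vinv_X.T @ y)
    pos = {s: i for i, s in enumerate(genotypes.samples)}
    ridx = np.array([pos[s] for s in ids])
    Wm = genotypes.dosages[ridx]
    PW = cho_solve(c, Wm) - Vinv_X @ np.linalg.solve(XtVinvX, Vinv_X.T @ Wm)
    num = Wm.T @ Py
    den = np.einsum("ij,ij->j", Wm, PW)
    tested = den > 1e-10 * max(float(den.max()), 1.0)
    effect = np.zeros(genotypes.n_markers)
    se = np.full(genotypes.n_markers, np.nan)
    z = np.zeros(genotypes.n_markers)
    pvals = np.ones(genotypes.n_markers)
    effect[tested] = num[tested] / den[tested]
    se[tested] = 1.0 / np.sqrt(den[tested])
    z[tested] = effect[tested] / se[tested]
    pvals[tested] = 2.0 * stats.norm.sf(np.abs(z[tested]))
    table = pd.DataFrame(
        {
            "id": genotypes.markers["id"],
            "chrom": genotypes.markers["chrom"],
            "pos": genotypes.markers["pos"],
            "effect": effect,
            "se": se,
            "z": z,
            "p": pvals,
            "tested": tested,
        }
    )
    return GwasResult(table=table, vc=vc)


def select_features(res: GwasResult, p_threshold: float = 0.05) -> set:
    """Marker ids with p below the (uncorrected) threshold.

    An empty result signals the caller to fall back to plain GBLUP.
    """
    if len(res.table) == 0:
        raise ValueError("empty GWAS result")
    hit = res.table["tested"] & (res.table["p"] < p_threshold)
    return set(res.table.loc[hit, "id"])
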