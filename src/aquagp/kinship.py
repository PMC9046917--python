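"""Relationship matrices: pedigree A, VanRaden genomic G, blended G*, SNP-
weighted G_w and genomic-feature partitions G_f/G_r.

All genomic builders share the same centering and scaling: columns of the
dosage matrix are centered by twice the current allele frequency, Z = M − 2p,
and the kernel is Z D Z' / Σ 2p_j(1−p_j) with D = I unless SNP weights are
supplied.  Monomorphic markers contribute nothing to the numerator and are
excluded from the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, allele_frequencies

__all__ = [
    "RelationshipMatrix",
    "SnpWeights",
    "build_A",
    "build_G",
    "blend",
    "build_weighted_G",
    "split_feature_G",
    "write_matrix",
    "read_matrix",
]


@dataclass
class RelationshipMatrix:
    """Symmetric n×n kernel over a named sample set."""

    ids: list[str]
    values: np.ndarray
    kind: str  # A | G | G_blend | G_weighted | G_feature | G_residual
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape inconsistent with id count")
        asym = np.abs(self.values - self.values.T).max() if n else 0.0
        if asym > 1e-8:
            raise ValueError(f"matrix not symmetric (max asymmetry {asym:.2e})")
        self.values = 0.5 * (self.values + self.values.T)

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, ids: list[str]) -> "RelationshipMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = np.array([pos[s] for s in ids])
        return RelationshipMatrix(
            ids=list(ids),
            values=self.values[np.ix_(idx, idx)],
            kind=self.kind,
            provenance=dict(self.provenance),
        )


@dataclass
class SnpWeights:
    """Diagonal SNP weights d_jj ≥ 0, normalized so Σ d_jj = marker count."""

    weights: np.ndarray
    iteration: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("negative SNP weight")


def build_A(pedigree: pd.DataFrame) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    ``pedigree`` has columns id, sire, dam with "0" for unknown parents;
    parents must appear before their offspring.  Founders are taken as
    unrelated and non-inbred.
    """
    ids = list(pedigree["id"])
    pos = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    sire_idx = np.full(n, -1)
    dam_idx = np.full(n, -1)
    for i, (ind, s, d) in enumerate(
        zip(pedigree["id"], pedigree["sire"], pedigree["dam"])
    ):
        for parent, arr in ((s, sire_idx), (d, dam_idx)):
            if parent not in ("0", 0, None) and not (
                isinstance(parent, float) and np.isnan(parent)
            ):
                if parent not in pos:
                    raise ValueError(f"parent {parent!r} of {ind!r} not in pedigree")
                if pos[parent] >= i:
                    raise ValueError(
                        f"parent {parent!r} listed at or after offspring {ind!r}"
                    )
                arr[i] = pos[parent]
    A = np.zeros((n, n))
    for i in range(n):
        si, di = sire_idx[i], dam_idx[i]
        f = 0.5 * A[si, di] if si >= 0 and di >= 0 else 0.0
        A[i, i] = 1.0 + f
        parts = []
        if si >= 0:
            parts.append(A[si, :i])
        if di >= 0:
            parts.append(A[di, :i])
        if parts:
            row = 0.5 * np.sum(parts, axis=0)
            A[i, :i] = row
            A[:i, i] = row
    return RelationshipMatrix(ids=ids, values=A, kind="A")


def _centered(g: GenotypeMatrix):
    if np.isnan(g.dosages).any():
        raise ValueError("missing dosages: impute before building G")
    p = allele_frequencies(g)
    twopq = 2.0 * p * (1.0 - p)
    poly = twopq > 0
    if not poly.any():
        raise ValueError("all markers monomorphic")
    Z = g.dosages[:, poly] - 2.0 * p[poly]
    return Z, twopq, poly


def build_G(g: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix G = ZZ' / Σ 2p_j(1−p_j)."""
    Z, twopq, poly = _centered(g)
    G = (Z @ Z.T) / twopq[poly].sum()
    return RelationshipMatrix(
        ids=list(g.samples),
        values=G,
        kind="G",
        provenance={"n_markers": int(poly.sum())},
    )


def blend(G: RelationshipMatrix, identity_weight: float = 0.05) -> RelationshipMatrix:
    """G* = (1 − w)·G + w·I; invertible whenever G is PSD and w > 0."""
    out = (1.0 - identity_weight) * G.values + identity_weight * np.eye(G.n)
    return RelationshipMatrix(
        ids=list(G.ids),
        values=out,
        kind="G_blend",
        provenance={**G.provenance, "identity_weight": identity_weight},
    )


def build_weighted_G(g: GenotypeMatrix, w: SnpWeights) -> RelationshipMatrix:
    """Weighted kernel Z D Z' / Σ 2p_j(1−p_j), same centering/denominator as
    :func:`build_G`."""
    if len(w.weights) != g.n_markers:
        raise ValueError("weight vector length must equal marker count")
    Z, twopq, poly = _centered(g)
    d = w.weights[poly]
    G = ((Z * d) @ Z.T) / twopq[poly].sum()
    return RelationshipMatrix(
        ids=list(g.samples),
        values=G,
        kind="G_weighted",
        provenance={"iteration": w.iteration},
    )


def split_feature_G(
    g: GenotypeMatrix, feature_markers
) -> tuple[RelationshipMatrix, RelationshipMatrix]:
    """Two kernels from disjoint marker sets: feature markers vs the rest.

    Each kernel uses its own Σ2pq denominator.  Degenerate splits (empty
    feature set, or feature = all markers) are rejected; callers fall back to
    plain GBLUP in that case.
    """
    feat = set(feature_markers)
    is_feat = g.markers["id"].isin(feat).to_numpy()
    if not is_feat.any() or is_feat.all():
        raise ValueError("feature set must be a non-empty proper subset of markers")
    Gf = build_G(g.subset_markers(is_feat))
    Gr = build_G(g.subset_markers(~is_feat))
    Gf.kind, Gr.kind = "G_feature", "G_residual"
    Gf.provenance["feature_size"] = int(is_feat.sum())
    Gr.provenance["feature_size"] = int(is_feat.sum())
    return Gf, Gr


def write_matrix(G: RelationshipMatrix, path) -> None:
    """Whitespace-delimited square text with an id header line."""
    with open(path, "w") as fh:
        fh.write(" ".join(G.ids) + "\n")
        np.savetxt(fh, G.values, fmt="%.10g")


def read_matrix(path, kind: str = "G") -> RelationshipMatrix:
    with open(path) as fh:
        ids = fh.readline().split()
        values = np.loadtxt(fh)
    return RelationshipMatrix(ids=ids, values=np.atleast_2d(values), kind=kind)
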