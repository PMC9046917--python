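"""Genotype, phenotype and pedigree I/O, allele frequencies, QC and naive imputation.

Genotypes are held as a samples × markers dosage matrix counting copies of the
A2 (alternate) allele, with ``numpy.nan`` marking missing calls.  Supported
on-disk formats are PLINK text (.ped/.map, alleles as single characters,
``0 0`` = missing) and VCF v4.2 (GT field only, read through cyvcf2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "QCReport",
    "read_genotypes",
    "read_phenotypes",
    "read_pedigree",
    "allele_frequencies",
    "hwe_exact_test",
    "qc_filter",
    "impute_missing",
]

MARKER_COLUMNS = ["id", "chrom", "pos", "a1", "a2"]


@dataclass
class GenotypeMatrix:
    """Samples × markers dosage matrix (0/1/2 copies of A2, nan = missing).

    ``markers`` is a DataFrame with columns id, chrom, pos, a1, a2; ``pos`` is
    1-based (PLINK/VCF convention) and may be nonpositive for markers of
    unknown position (those are excluded from LD pruning).
    """

    samples: list[str]
    markers: pd.DataFrame
    dosages: np.ndarray  # float array, shape (n_samples, n_markers)
    imputed_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.samples)} samples × {len(self.markers)} markers"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        ids = self.markers["id"]
        if ids.duplicated().any():
            raise ValueError("duplicate marker ids")
        # fractional dosages in [0, 2] are allowed (mean imputation)
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < 0 or np.nanmax(
                self.dosages, initial=0.0
            ) > 2:
                raise ValueError("dosages outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def p(self) -> np.ndarray:
        """Per-marker A2 allele frequency from non-missing calls."""
        return allele_frequencies(self)

    def subset_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            markers=self.markers.iloc[index].reset_index(drop=True),
            dosages=self.dosages[:, index],
            imputed_mask=None if self.imputed_mask is None else self.imputed_mask[:, index],
        )

    def subset_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in index],
            markers=self.markers.copy(),
            dosages=self.dosages[index],
            imputed_mask=None if self.imputed_mask is None else self.imputed_mask[index],
        )


@dataclass
class QCReport:
    """Tally of samples/markers removed per quality-control criterion."""

    n_samples_in: int
    n_markers_in: int
    samples_removed_call_rate: int = 0
    markers_removed_maf: int = 0
    markers_removed_call_rate: int = 0
    markers_removed_hwe: int = 0
    thresholds: dict = field(default_factory=dict)

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - self.samples_removed_call_rate

    @property
    def n_markers_out(self) -> int:
        return self.n_markers_in - (
            self.markers_removed_maf
            + self.markers_removed_call_rate
            + self.markers_removed_hwe
        )


# ---------------------------------------------------------------------------
# readers


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read genotypes from PLINK text (.ped with sibling .map) or VCF.

    ``format`` is ``"plink_text"`` or ``"vcf"``; inferred from the file suffix
    when omitted.  A2 is the second allele observed in the PED (minor-ish by
    convention of our own writer) or the VCF ALT allele.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in (".vcf", ".gz") else "plink_text"
    if format == "plink_text":
        return _read_plink_text(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_plink_text(ped_path: Path) -> GenotypeMatrix:
    map_path = ped_path.with_suffix(".map")
    mp = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos"], dtype={"chrom": str, "id": str},
    )
    m = len(mp)
    if m == 0:
        raise ValueError(f"{map_path}: empty marker set")
    samples: list[str] = []
    # first pass records the allele labels seen per marker; A2 (the counted
    # allele) is the lexicographically larger of the two
    seen: list[set] = [set() for _ in range(m)]
    raw: list[list[str]] = []
    for lineno, line in enumerate(ped_path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 6 + 2 * m:
            raise ValueError(
                f"{ped_path}:{lineno}: expected {6 + 2 * m} fields, got {len(fields)}"
            )
        samples.append(fields[1])
        alleles = fields[6:]
        raw.append(alleles)
        for j in range(m):
            for a in (alleles[2 * j], alleles[2 * j + 1]):
                if a != "0":
                    seen[j].add(a)
            if len(seen[j]) > 2:
                raise ValueError(
                    f"{ped_path}:{lineno}: marker {mp['id'][j]} has >2 alleles"
                )
    if len(set(samples)) != len(samples):
        raise ValueError(f"{ped_path}: duplicate sample ids")
    allele1 = np.array(
        [min(s) if s else "0" for s in seen], dtype=object
    )
    allele2 = np.array(
        [max(s) if len(s) > 1 else "0" for s in seen], dtype=object
    )
    dos = np.full((len(samples), m), np.nan)
    for i, alleles in enumerate(raw):
        a = np.array(alleles, dtype=object).reshape(m, 2)
        missing = (a[:, 0] == "0") | (a[:, 1] == "0")
        cnt = (a[:, 0] == allele2).astype(float) + (a[:, 1] == allele2).astype(float)
        cnt[missing] = np.nan
        dos[i] = cnt
    markers = pd.DataFrame(
        {
            "id": mp["id"],
            "chrom": mp["chrom"],
            "pos": mp["pos"],
            "a1": allele1,
            "a2": allele2,
        }
    )
    return GenotypeMatrix(samples=samples, markers=markers, dosages=dos)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts = [], [], [], [], []
    cols = []
    for var in vcf:
        ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else "0")
        g = var.gt_types.astype(float)  # 0/1/2 copies of ALT, 3 = unknown
        g[g == 3] = np.nan
        cols.append(g)
    vcf.close()
    if not cols:
        raise ValueError(f"{path}: empty marker set")
    markers = pd.DataFrame(
        {"id": ids, "chrom": chroms, "pos": poss, "a1": refs, "a2": alts}
    )
    return GenotypeMatrix(samples=samples, markers=markers, dosages=np.array(cols).T)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a header-bearing phenotype TSV; first column must be ``id``."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if df.columns[0] != "id":
        raise ValueError(f"{path}: first column must be 'id', got {df.columns[0]!r}")
    return df


def read_pedigree(path: str | Path) -> pd.DataFrame:
    """Read a 3-column pedigree TSV (id, sire, dam; 0 = unknown parent)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["id", "sire", "dam"]
    if list(df.columns[:3]) != expected:
        raise ValueError(f"{path}: columns must start with {expected}")
    return df


# ---------------------------------------------------------------------------
# allele frequencies / HWE / QC


def allele_frequencies(g: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """p_j = (sum of A2 dosages) / (2 × non-missing count) per marker.

    All-missing markers yield nan and must be excluded downstream.
    """
    dos = g.dosages if isinstance(g, GenotypeMatrix) else np.asarray(g, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.nanmean(dos, axis=0) / 2.0


@lru_cache(maxsize=100_000)
def _hwe_cached(n_aa2: int, n_het: int, n_aa1: int) -> float:
    # conditional exact test: enumerate heterozygote counts given allele counts
    n = n_aa2 + n_het + n_aa1
    n_rare = 2 * min(n_aa2, n_aa1) + n_het
    # possible het counts share parity with n_rare
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    logs = np.array(
        [
            _log_hwe_prob(n, n_rare, int(h))
            for h in hets
        ]
    )
    logs -= logs.max()
    probs = np.exp(logs)
    probs /= probs.sum()
    obs = probs[np.searchsorted(hets, n_het)]
    return float(probs[probs <= obs + 1e-12].sum())


def _log_hwe_prob(n: int, n_rare: int, n_het: int) -> float:
    # P(het = h | allele counts) ∝ 2^h · n! / (h! · n_AA! · n_aa!) with
    # fixed rare-allele count; written with log-gammas for stability
    n_rare_hom = (n_rare - n_het) // 2
    n_common_hom = n - n_het - n_rare_hom
    if n_rare_hom < 0 or n_common_hom < 0:
        return -np.inf
    return (
        n_het * math.log(2.0)
        + math.lgamma(n + 1)
        - math.lgamma(n_het + 1)
        - math.lgamma(n_rare_hom + 1)
        - math.lgamma(n_common_hom + 1)
    )


def hwe_exact_test(n_aa2: int, n_het: int, n_aa1: int) -> float:
    """Two-sided exact Hardy–Weinberg test p-value.

    Arguments are genotype counts (A2A2 homozygote, heterozygote, A1A1
    homozygote).  Sums the conditional probabilities, given the allele counts,
    of all heterozygote counts no more probable than the observed one.
    """
    if min(n_aa2, n_het, n_aa1) < 0:
        raise ValueError("negative genotype count")
    if n_aa2 + n_het + n_aa1 < 1:
        raise ValueError("empty genotype sample")
    return _hwe_cached(int(n_aa2), int(n_het), int(n_aa1))


def _marker_stats(dos: np.ndarray):
    nonmiss = ~np.isnan(dos)
    call = nonmiss.mean(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(dos, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    return call, p, maf, nonmiss


def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    marker_call_min: float = 0.90,
    hwe_p_min: float = 1e-7,
    sample_call_min: float = 0.90,
) -> tuple[GenotypeMatrix, QCReport]:
    """Quality control: sample call rate first, then MAF / marker call rate /
    HWE on the reduced sample set.

    Markers failing several criteria are attributed to the first failed one in
    the order MAF → call rate → HWE.
    """
    report = QCReport(
        n_samples_in=g.n_samples,
        n_markers_in=g.n_markers,
        thresholds=dict(
            maf_min=maf_min,
            marker_call_min=marker_call_min,
            hwe_p_min=hwe_p_min,
            sample_call_min=sample_call_min,
        ),
    )
    sample_call = (~np.isnan(g.dosages)).mean(axis=1)
    keep_samples = sample_call >= sample_call_min
    report.samples_removed_call_rate = int((~keep_samples).sum())
    g = g.subset_samples(keep_samples)

    call, p, maf, nonmiss = _marker_stats(g.dosages)
    fail_maf = np.isnan(maf) | (maf < maf_min)
    fail_call = ~fail_maf & (call < marker_call_min)
    fail_hwe = np.zeros(g.n_markers, dtype=bool)
    for j in np.flatnonzero(~(fail_maf | fail_call)):
        col = g.dosages[nonmiss[:, j], j]
        counts = (int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum()))
        if hwe_exact_test(*counts) < hwe_p_min:
            fail_hwe[j] = True
    report.markers_removed_maf = int(fail_maf.sum())
    report.markers_removed_call_rate = int(fail_call.sum())
    report.markers_removed_hwe = int(fail_hwe.sum())
    keep = ~(fail_maf | fail_call | fail_hwe)
    if not keep.any():
        import warnings

        warnings.warn("all markers removed by QC", stacklevel=2)
    return g.subset_markers(keep), report


def impute_missing(g: GenotypeMatrix, method: str = "marker_mean") -> GenotypeMatrix:
    """Fill missing dosages per marker.

    ``marker_mean`` fills 2·p_j (fractional dosages, fine for G-matrix
    builders); ``major_allele`` fills the modal integer genotype.
    """
    miss = np.isnan(g.dosages)
    if np.isnan(allele_frequencies(g)).any():
        raise ValueError("all-missing marker: cannot impute")
    dos = g.dosages.copy()
    if method == "marker_mean":
        fill = 2.0 * allele_frequencies(g)
    elif method == "major_allele":
        fill = np.empty(g.n_markers)
        for j in range(g.n_markers):
            col = dos[~miss[:, j], j]
            vals, counts = np.unique(col, return_counts=True)
            fill[j] = vals[np.argmax(counts)]
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    dos[miss] = np.broadcast_to(fill, dos.shape)[miss]
    return GenotypeMatrix(
        samples=list(g.samples),
        markers=g.markers.copy(),
        dosages=dos,
        imputed_mask=miss,
    )
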