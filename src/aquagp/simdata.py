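"""Synthetic aquaculture populations: factorial full-sib families, gene-drop
genotypes, mixture-architecture traits.

The generator emulates the structure of array/RAD-genotyped fish breeding
populations: a factorial mating design (blocks of dams × sires) producing tens
to hundreds of full-sib families with highly unequal sizes, 11K–40K SNPs on a
sex-averaged linkage map, and phenotypes composed of fixed effects (batch-like
factors, an optional continuous covariate), an additive polygenic/oligogenic
value, and Gaussian noise calibrated to a target narrow-sense heritability.

Founders are simulated in linkage equilibrium: within- and between-family LD
arises from the two-generation gene-drop, which is the dominant source of
marker–relationship information in these designs.  Crossovers per chromosome
are Poisson(length/100) with uniform positions and no interference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, MARKER_COLUMNS

__all__ = [
    "GeneticMap",
    "PedigreeDesign",
    "TraitArchitecture",
    "SimulatedDataset",
    "default_map",
    "simulate_founder_haplotypes",
    "make_factorial_pedigree",
    "gene_drop",
    "assign_qtl_effects",
    "simulate_phenotypes",
    "inject_missing",
    "simulate_dataset",
    "write_dataset",
]


@dataclass
class GeneticMap:
    """Marker positions on chromosomes measured in centimorgans."""

    chromosomes: list[tuple[str, float]]  # (chrom id, length in cM)
    markers: pd.DataFrame  # columns: chrom, pos_cm, id

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        if self.markers["id"].duplicated().any():
            raise ValueError("duplicate marker ids")
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            pos = grp["pos_cm"].to_numpy()
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"positions not sorted on chromosome {chrom}")
            if len(pos) and (pos.min() < 0 or pos.max() > lengths[chrom]):
                raise ValueError(f"marker outside chromosome {chrom}")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_table(self) -> pd.DataFrame:
        """Marker table in GenotypeMatrix layout (positions as integer bp-like
        coordinates at 10 kb per cM, 1-based)."""
        return pd.DataFrame(
            {
                "id": self.markers["id"],
                "chrom": self.markers["chrom"].astype(str),
                "pos": (self.markers["pos_cm"] * 10_000).round().astype(int) + 1,
                "a1": "A",
                "a2": "B",
            }
        )[MARKER_COLUMNS]


def default_map(
    n_chromosomes: int = 20, chrom_length_cm: float = 100.0, n_markers: int = 12_000
) -> GeneticMap:
    """Evenly filled map: markers spread uniformly (deterministic grid) over
    ``n_chromosomes`` chromosomes of equal length."""
    if n_markers <= 0:
        raise ValueError("need at least one marker")
    chroms = [(f"chr{i + 1}", chrom_length_cm) for i in range(n_chromosomes)]
    per = np.diff(np.linspace(0, n_markers, n_chromosomes + 1).astype(int))
    rows = []
    for (cid, length), k in zip(chroms, per):
        pos = (np.arange(k) + 0.5) / k * length
        for p in pos:
            rows.append((cid, p))
    markers = pd.DataFrame(rows, columns=["chrom", "pos_cm"])
    markers["id"] = [f"snp{i + 1}" for i in range(len(markers))]
    return GeneticMap(chromosomes=chroms, markers=markers)


@dataclass
class PedigreeDesign:
    """Founders plus factorial matings with per-family offspring counts."""

    sires: list[str]
    dams: list[str]
    matings: list[tuple[str, str]]  # (sire, dam), one per full-sib family
    family_sizes: np.ndarray

    def __post_init__(self) -> None:
        if len(self.matings) != len(self.family_sizes):
            raise ValueError("one family size per mating required")
        if np.any(np.asarray(self.family_sizes) < 1):
            raise ValueError("family sizes must be ≥ 1")

    @property
    def n_families(self) -> int:
        return len(self.matings)

    @property
    def n_offspring(self) -> int:
        return int(np.sum(self.family_sizes))

    @property
    def founders(self) -> list[str]:
        return list(self.sires) + list(self.dams)

    def offspring_table(self) -> pd.DataFrame:
        """One row per offspring: id, sire, dam, family index."""
        rows = []
        k = 0
        for fam, ((sire, dam), size) in enumerate(zip(self.matings, self.family_sizes)):
            for _ in range(int(size)):
                rows.append((f"ind{k + 1}", sire, dam, fam))
                k += 1
        return pd.DataFrame(rows, columns=["id", "sire", "dam", "family"])

    def pedigree_table(self) -> pd.DataFrame:
        """3-column pedigree (id, sire, dam; founders have parents '0')."""
        founders = pd.DataFrame({"id": self.founders, "sire": "0", "dam": "0"})
        off = self.offspring_table()[["id", "sire", "dam"]]
        return pd.concat([founders, off], ignore_index=True)


@dataclass
class TraitArchitecture:
    """Mixture genetic architecture plus noise/fixed-effect model.

    Marker effects fall in four classes with variances (0, 1e-4, 1e-3, 1e-2)
    times the genetic variance — mirroring the mixture prior the BayesR model
    assumes — with membership probabilities ``class_proportions``.
    """

    class_proportions: tuple[float, float, float, float] = (0.95, 0.03, 0.015, 0.005)
    class_multipliers: tuple[float, float, float, float] = (0.0, 1e-4, 1e-3, 1e-2)
    target_h2: float = 0.25
    genetic_variance: float = 1.0
    factor_levels: tuple[int, ...] = (3, 2)  # batch-like factors
    factor_effect_sd: float = 0.5
    covariate_slope: float = 0.0
    mean: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if not 0.0 <= self.target_h2 <= 1.0:
            raise ValueError("target_h2 must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame  # id, y, fixed-effect columns
    pedigree: pd.DataFrame  # id, sire, dam
    families: pd.Series  # family index per offspring id
    true_bv: pd.Series  # additive genetic value per individual (genotyped set)
    true_effects: pd.DataFrame  # marker id, effect, class

    @property
    def fixed_factors(self) -> list[str]:
        return [c for c in self.phenotypes.columns if c.startswith("factor")]

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.phenotypes.columns if c.startswith("cov")]


# ---------------------------------------------------------------------------
# simulation operations


def simulate_founder_haplotypes(
    n_founders: int,
    gmap: GeneticMap,
    maf_law: tuple[float, float] = (0.05, 0.5),
    seed: int | np.random.Generator = 0,
    n_ancestral: int | None = None,
    switch_rate: float = 0.05,
) -> np.ndarray:
    """Draw 2·n_founders founder haplotypes.

    Allele frequencies are i.i.d. uniform on ``maf_law = (lo, hi)`` per marker
    (a point mass when lo == hi).  With ``n_ancestral=None`` founders are in
    linkage equilibrium and all LD downstream arises from the family design.
    With a small ``n_ancestral``, each founder haplotype is instead a mosaic
    of that many ancestral haplotypes (segment switches form a Markov chain
    with ``switch_rate`` per cM), emulating the long-range LD of a population
    with small effective size — the regime typical of aquaculture broodstock.
    Returns a (2·n_founders, m) 0/1 array; haplotypes 2i, 2i+1 belong to
    founder i.
    """
    if n_founders < 2:
        raise ValueError("need at least two founders")
    if gmap.n_markers == 0:
        raise ValueError("zero-length map")
    lo, hi = maf_law
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_law must satisfy 0 < lo <= hi <= 0.5")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    freqs = rng.uniform(lo, hi, size=gmap.n_markers) if lo < hi else np.full(gmap.n_markers, lo)
    if n_ancestral is None:
        return (rng.random((2 * n_founders, gmap.n_markers)) < freqs).astype(np.int8)
    if n_ancestral < 2:
        raise ValueError("need at least two ancestral haplotypes")
    pool = (rng.random((n_ancestral, gmap.n_markers)) < freqs).astype(np.int8)
    chrom_col = gmap.markers["chrom"].to_numpy()
    pos_col = gmap.markers["pos_cm"].to_numpy()
    blocks = []
    for cid, _length in gmap.chromosomes:
        idx = np.flatnonzero(chrom_col == cid)
        if len(idx) == 0:
            continue
        pos = pos_col[idx]
        gaps = np.diff(pos, prepend=pos[0])
        blocks.append((idx, 1.0 - np.exp(-switch_rate * gaps)))
    haps = np.empty((2 * n_founders, gmap.n_markers), dtype=np.int8)
    for h in range(2 * n_founders):
        for idx, p_switch in blocks:
            switch = rng.random(len(idx)) < p_switch
            switch[0] = True  # fresh ancestor per chromosome
            anc = rng.integers(n_ancestral, size=int(switch.sum()))
            state = anc[np.cumsum(switch) - 1]
            haps[h, idx] = pool[state, idx]
    return haps


def make_factorial_pedigree(
    n_sires: int,
    n_dams: int,
    n_blocks: int = 1,
    n_families: int | None = None,
    family_size_law=("negative_binomial", 10.0, 2.0),
    seed: int | np.random.Generator = 0,
) -> PedigreeDesign:
    """Factorial mating design: within each block every dam × sire pair is a
    candidate family; realized families are subsampled to ``n_families``.

    ``family_size_law`` is ``("negative_binomial", mean, dispersion)``,
    ``("uniform", lo, hi)`` or ``("constant", k)``; draws are truncated at 1.
    Highly unequal family sizes (single fish up to >100 per family) come out
    of small dispersion values.
    """
    if min(n_sires, n_dams, n_blocks) < 1:
        raise ValueError("counts must be ≥ 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    capacity = n_sires * n_dams * n_blocks
    if n_families is None:
        n_families = capacity
    if n_families > capacity:
        raise ValueError(f"requested {n_families} families > capacity {capacity}")
    sires = [f"sire{b + 1}_{s + 1}" for b in range(n_blocks) for s in range(n_sires)]
    dams = [f"dam{b + 1}_{d + 1}" for b in range(n_blocks) for d in range(n_dams)]
    candidates = [
        (f"sire{b + 1}_{s + 1}", f"dam{b + 1}_{d + 1}")
        for b in range(n_blocks)
        for d in range(n_dams)
        for s in range(n_sires)
    ]
    chosen = rng.choice(len(candidates), size=n_families, replace=False)
    matings = [candidates[i] for i in sorted(chosen)]
    sizes = _draw_family_sizes(family_size_law, n_families, rng)
    return PedigreeDesign(sires=sires, dams=dams, matings=matings, family_sizes=sizes)


def _draw_family_sizes(law, k: int, rng: np.random.Generator) -> np.ndarray:
    kind = law[0]
    if kind == "constant":
        return np.full(k, int(law[1]))
    if kind == "uniform":
        lo, hi = int(law[1]), int(law[2])
        return rng.integers(lo, hi + 1, size=k)
    if kind == "negative_binomial":
        mean, disp = float(law[1]), float(law[2])
        # NB with mean μ and size r: p = r/(r+μ)
        p = disp / (disp + mean)
        return np.maximum(rng.negative_binomial(disp, p, size=k), 1)
    raise ValueError(f"unknown family size law {kind!r}")


def _meiosis(
    parent_haps: np.ndarray,
    chrom_slices: list[slice],
    chrom_lengths: np.ndarray,
    marker_pos: list[np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete from a (2, m) parental haplotype pair."""
    gamete = np.empty(parent_haps.shape[1], dtype=np.int8)
    for sl, length, pos in zip(chrom_slices, chrom_lengths, marker_pos):
        n_x = rng.poisson(length / 100.0) if length > 0 else 0
        start = rng.integers(2)
        if n_x == 0:
            gamete[sl] = parent_haps[start, sl]
            continue
        xpos = np.sort(rng.uniform(0.0, length, size=n_x))
        phase = (start + np.searchsorted(xpos, pos, side="right")) % 2
        seg = parent_haps[:, sl]
        gamete[sl] = np.where(phase == 0, seg[0], seg[1])
    return gamete


def gene_drop(
    ped: PedigreeDesign,
    founder_haps: np.ndarray,
    gmap: GeneticMap,
    seed: int | np.random.Generator = 0,
    include_founders: bool = False,
) -> GenotypeMatrix:
    """Drop founder haplotypes through the pedigree.

    Each offspring receives one recombinant gamete per parent; crossover
    counts per chromosome are Poisson(length/100), positions uniform.
    """
    founders = ped.founders
    if founder_haps.shape[0] != 2 * len(founders):
        raise ValueError("founder haplotype count mismatch")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    fidx = {f: i for i, f in enumerate(founders)}
    chrom_slices, marker_pos = [], []
    lengths = []
    start = 0
    for cid, length in gmap.chromosomes:
        pos = gmap.markers.loc[gmap.markers["chrom"] == cid, "pos_cm"].to_numpy()
        chrom_slices.append(slice(start, start + len(pos)))
        marker_pos.append(pos)
        lengths.append(length)
        start += len(pos)
    lengths = np.asarray(lengths, dtype=float)

    off = ped.offspring_table()
    n_off = len(off)
    haps = np.empty((2 * n_off, gmap.n_markers), dtype=np.int8)
    for k, (sire, dam) in enumerate(zip(off["sire"], off["dam"])):
        for parent_col, parent in enumerate((sire, dam)):
            if parent not in fidx:
                raise ValueError(f"offspring references unknown parent {parent!r}")
            ph = founder_haps[2 * fidx[parent] : 2 * fidx[parent] + 2]
            haps[2 * k + parent_col] = _meiosis(
                ph, chrom_slices, lengths, marker_pos, rng
            )
    dosages = (haps[0::2] + haps[1::2]).astype(float)
    samples = list(off["id"])
    if include_founders:
        fdos = (founder_haps[0::2] + founder_haps[1::2]).astype(float)
        dosages = np.vstack([fdos, dosages])
        samples = founders + samples
    return GenotypeMatrix(
        samples=samples, markers=gmap.marker_table(), dosages=dosages
    )


def assign_qtl_effects(
    arch: TraitArchitecture,
    genotypes: GenotypeMatrix,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Assign each marker to an effect class and draw/rescale effects so that
    the realized variance of the breeding values equals ``genetic_variance``.

    Returns a DataFrame (id, effect, class) aligned with the marker table.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    m = genotypes.n_markers
    classes = rng.choice(4, size=m, p=arch.class_proportions)
    sds = np.sqrt(np.array(arch.class_multipliers) * arch.genetic_variance)
    effects = rng.standard_normal(m) * sds[classes]
    if arch.target_h2 > 0:
        if not np.any(effects != 0):
            raise ValueError(
                "all markers landed in the zero class but target_h2 > 0; "
                "increase nonzero class proportions or marker count"
            )
        bv = _breeding_values(genotypes, effects)
        sd = bv.std()
        if sd == 0:
            raise ValueError("degenerate genotypes: breeding values constant")
        effects *= np.sqrt(arch.genetic_variance) / sd
    return pd.DataFrame(
        {"id": genotypes.markers["id"], "effect": effects, "class": classes}
    )


def _breeding_values(genotypes: GenotypeMatrix, effects: np.ndarray) -> np.ndarray:
    centered = genotypes.dosages - np.nanmean(genotypes.dosages, axis=0)
    return centered @ effects


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    true_effects: pd.DataFrame,
    arch: TraitArchitecture,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """y = μ + factor effects + covariate·slope + breeding value + e.

    σe² is set from the realized breeding-value variance so that
    var(bv) / (var(bv) + σe²) equals ``target_h2``.  Returns (phenotypes,
    true breeding values).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    bv = _breeding_values(genotypes, true_effects["effect"].to_numpy())
    n = genotypes.n_samples
    var_bv = bv.var()
    h2 = arch.target_h2
    if h2 <= 0.0:
        if var_bv > 0:
            raise ValueError("target_h2 = 0 but nonzero breeding values supplied")
        sigma_e2 = 1.0
    elif h2 >= 1.0:
        sigma_e2 = 0.0
    else:
        sigma_e2 = var_bv * (1.0 - h2) / h2
    df = pd.DataFrame({"id": genotypes.samples})
    fixed_part = np.full(n, arch.mean)
    for i, n_levels in enumerate(arch.factor_levels):
        levels = rng.integers(n_levels, size=n)
        fx = rng.standard_normal(n_levels) * arch.factor_effect_sd
        df[f"factor{i + 1}"] = [f"L{l + 1}" for l in levels]
        fixed_part += fx[levels]
    cov = rng.standard_normal(n)
    df["cov1"] = cov
    fixed_part += arch.covariate_slope * cov
    e = rng.standard_normal(n) * np.sqrt(sigma_e2)
    df.insert(1, "y", fixed_part + bv + e)
    return df, pd.Series(bv, index=pd.Index(genotypes.samples, name="id"), name="true_bv")


def inject_missing(
    g: GenotypeMatrix, rate: float, seed: int | np.random.Generator = 0
) -> GenotypeMatrix:
    """Mask each genotype call independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0.0:
        return g
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mask = rng.random(g.dosages.shape) < rate
    dos = g.dosages.copy()
    dos[mask] = np.nan
    return GenotypeMatrix(
        samples=list(g.samples), markers=g.markers.copy(), dosages=dos
    )


def simulate_dataset(
    n_sires: int = 10,
    n_dams: int = 5,
    n_blocks: int = 4,
    n_families: int | None = None,
    family_size_law=("negative_binomial", 10.0, 2.0),
    gmap: GeneticMap | None = None,
    n_markers: int = 12_000,
    maf_law: tuple[float, float] = (0.05, 0.5),
    n_ancestral: int | None = 30,
    switch_rate: float = 0.05,
    arch: TraitArchitecture | None = None,
    seed: int = 0,
) -> SimulatedDataset:
    """One-call generator for a complete study population.

    Defaults sketch a mid-sized aquaculture dataset: 4 factorial blocks of
    5 dams × 10 sires (200 candidate families), negative-binomial family
    sizes, 12K SNPs on 20 × 100 cM chromosomes with small-Ne founder LD
    (mosaics of 30 ancestral haplotypes), h² = 0.25 with two batch-like
    fixed factors.
    """
    rng = np.random.default_rng(seed)
    arch = arch or TraitArchitecture()
    gmap = gmap or default_map(n_markers=n_markers)
    ped = make_factorial_pedigree(
        n_sires, n_dams, n_blocks, n_families, family_size_law, rng
    )
    fh = simulate_founder_haplotypes(
        len(ped.founders), gmap, maf_law, rng,
        n_ancestral=n_ancestral, switch_rate=switch_rate,
    )
    geno = gene_drop(ped, fh, gmap, rng)
    effects = assign_qtl_effects(arch, geno, rng)
    pheno, bv = simulate_phenotypes(geno, effects, arch, rng)
    if arch.missing_rate > 0:
        geno = inject_missing(geno, arch.missing_rate, rng)
    off = ped.offspring_table()
    return SimulatedDataset(
        genotypes=geno,
        phenotypes=pheno,
        pedigree=ped.pedigree_table(),
        families=pd.Series(off["family"].to_numpy(), index=off["id"], name="family"),
        true_bv=bv,
        true_effects=effects,
    )


# ---------------------------------------------------------------------------
# writers


def write_dataset(ds: SimulatedDataset, out_dir) -> dict:
    """Write PLINK .ped/.map, VCF, phenotype/pedigree/truth TSVs.

    Returns a dict of the file paths written.  Dosages must be integral
    (write before imputation).
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g = ds.genotypes
    paths = {
        "ped": out / "genotypes.ped",
        "map": out / "genotypes.map",
        "vcf": out / "genotypes.vcf",
        "phenotypes": out / "phenotypes.tsv",
        "pedigree": out / "pedigree.tsv",
        "truth_bv": out / "true_bv.tsv",
        "truth_effects": out / "true_effects.tsv",
    }
    _write_plink_text(g, paths["ped"], paths["map"])
    _write_vcf(g, paths["vcf"])
    ds.phenotypes.to_csv(paths["phenotypes"], sep="\t", index=False)
    ds.pedigree.to_csv(paths["pedigree"], sep="\t", index=False)
    ds.true_bv.reset_index().to_csv(paths["truth_bv"], sep="\t", index=False)
    ds.true_effects.to_csv(paths["truth_effects"], sep="\t", index=False)
    return paths


def _write_plink_text(g: GenotypeMatrix, ped_path, map_path) -> None:
    mk = g.markers
    with open(map_path, "w") as fh:
        for _, r in mk.iterrows():
            fh.write(f"{r['chrom']}\t{r['id']}\t0\t{int(r['pos'])}\n")
    a1 = mk["a1"].to_numpy()
    a2 = mk["a2"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(g.samples):
            row = g.dosages[i]
            fields = [sid, sid, "0", "0", "0", "-9"]
            for j, d in enumerate(row):
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [a1[j], a1[j]]
                elif d == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a2[j], a2[j]]
            fh.write(" ".join(fields) + "\n")


def _write_vcf(g: GenotypeMatrix, path) -> None:
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in g.markers["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        for j, r in g.markers.iterrows():
            calls = [
                "./." if np.isnan(d) else gt_codes[int(d)] for d in g.dosages[:, j]
            ]
            ref = r["a1"] if r["a1"] not in ("", "0") else "A"
            alt = r["a2"] if r["a2"] not in ("", "0") else "B"
            fh.write(
                f"{r['chrom']}\t{int(r['pos'])}\t{r['id']}\t{ref}\t{alt}\t.\t.\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )
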