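"""Simulation of bi-parental F3:4 testcross populations and field trials.

The generator emulates the structure of an elite hybrid rye breeding
experiment: three inbred parents produce two half-sib bi-parental
populations (A = P1 x P2, B = P1 x P3, sharing parent P1), each selfed for
two generations by single seed descent to F3, testcrossed to an unrelated
CMS tester, and evaluated for quantitative traits in multi-environment
trials (location x year combinations) with replications and incomplete
blocks.

Meiosis follows Haldane's model: crossovers are a Poisson process on the
centimorgan map with no interference.  The tester contributes a constant to
every testcross hybrid and is absorbed into the trait mean, so phenotypes
are additive in the line's marker dosage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

# F3 genotype distribution at a locus segregating in the cross: two selfing
# generations from Aa give P(AA)=3/8, P(Aa)=1/4, P(aa)=3/8, hence
# E[het] = 1/4, dosage mean 1 and dosage variance 3/4.
F3_HET_FRACTION = 0.25
F3_DOSAGE_VARIANCE = 0.75

#: Location x year trial network: nine environments for grain yield and
#: plant height (HOH tested in 2010 only) ...
DEFAULT_ENVIRONMENTS_9 = (
    ("BEK", 2010), ("BEK", 2011),
    ("PET", 2010), ("PET", 2011),
    ("HOH", 2010),
    ("WAL", 2010), ("WAL", 2011),
    ("WOH", 2010), ("WOH", 2011),
)
#: ... and six environments for the NIRS quality traits.
DEFAULT_ENVIRONMENTS_6 = (
    ("PET", 2010), ("PET", 2011),
    ("WAL", 2010), ("WAL", 2011),
    ("WOH", 2010), ("WOH", 2011),
)


def env_key(location: str, year: int) -> str:
    """Compact environment label, e.g. ``("BEK", 2010) -> "BEK10"``."""
    return f"{location}{str(year)[-2:]}"


class InvalidParameterError(ValueError):
    pass


@dataclass(frozen=True)
class GeneticMap:
    """Genetic map on the seven rye linkage groups.

    ``table`` has columns ``marker_id``, ``chromosome`` (1..7) and
    ``position_cM`` (non-negative, non-decreasing within chromosome).
    """

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        required = {"marker_id", "chromosome", "position_cM"}
        if not required.issubset(t.columns):
            raise InvalidParameterError(f"map table needs columns {sorted(required)}")
        if t["marker_id"].duplicated().any():
            raise InvalidParameterError("duplicate marker_ids in map")
        if (t["position_cM"] < 0).any():
            raise InvalidParameterError("negative map positions")
        for _, grp in t.groupby("chromosome"):
            if not grp["position_cM"].is_monotonic_increasing:
                raise InvalidParameterError("positions not sorted within chromosome")

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.unique(self.table["chromosome"].to_numpy())

    def positions(self, chromosome: int) -> pd.DataFrame:
        return self.table[self.table["chromosome"] == chromosome]


@dataclass(frozen=True)
class ParentSet:
    """Fully homozygous founder genotypes: shared parent P1, the two
    non-shared parents P2/P3 and the unrelated CMS tester.

    ``alleles`` maps parent name to a 0/1 allele vector over the map's
    markers (homozygous, so one allele per locus suffices).
    """

    alleles: dict[str, np.ndarray]
    gmap: GeneticMap

    def __post_init__(self):
        for name, a in self.alleles.items():
            if len(a) != self.gmap.n_markers:
                raise InvalidParameterError(f"parent {name}: allele vector off-map")
            if not np.isin(a, (0, 1)).all():
                raise InvalidParameterError(f"parent {name}: alleles must be 0/1")

    def heterozygosity(self, name: str) -> float:
        # inbred founders carry one allele per locus by construction
        return 0.0

    def segregating(self, p_a: str, p_b: str) -> np.ndarray:
        """Boolean mask of loci at which two parents carry different alleles."""
        return self.alleles[p_a] != self.alleles[p_b]


@dataclass(frozen=True)
class Population:
    """F3:4 lines from one bi-parental cross.

    ``genotypes``: lines x markers DataFrame of allele-1 dosages in {0,1,2}
    (1 = residual heterozygosity).  The dosage reference is the same "1"
    allele for every population, so matrices from different crosses are
    directly comparable; per-marker reflection ``2 - x`` converts to the
    non-shared-parent-allele coding and leaves every downstream analysis
    invariant.
    """

    label: str
    genotypes: pd.DataFrame
    parent_pair: tuple[str, str]
    gmap: GeneticMap

    @property
    def n_lines(self) -> int:
        return len(self.genotypes)

    @property
    def line_ids(self) -> np.ndarray:
        return self.genotypes.index.to_numpy()

    def segregating_markers(self) -> np.ndarray:
        g = self.genotypes.to_numpy()
        return self.genotypes.columns.to_numpy()[g.std(axis=0) > 0]


@dataclass
class TraitArchitecture:
    """Genetic and experimental architecture of one simulated trait.

    Variances are on the plot-data scale of the trait's unit (e.g. dt/ha
    for grain yield).  ``sigma2_g`` is the target additive testcross
    variance among lines; QTL effects are scaled so the expected variance
    of the genetic values matches it (see :func:`simulate_trial`).
    """

    trait: str
    mean: float = 0.0
    n_qtl: int = 50
    sigma2_g: float = 1.0
    sigma2_ge: float = 0.0
    sigma2_e: float = 0.0
    sigma2_env: float = 0.0
    sigma2_rep: float = 0.0
    sigma2_block: float = 0.0
    n_env: int = 9
    n_rep: int = 2
    qtl_markers: Sequence[str] | None = None
    qtl_effects: Sequence[float] | None = None
    calibration: str = "empirical"  # or "theoretical"
    ge_mode: str = "genetic"        # or "iid"

    def __post_init__(self):
        for name in ("sigma2_g", "sigma2_ge", "sigma2_e", "sigma2_env",
                     "sigma2_rep", "sigma2_block"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.n_qtl < 1:
            raise InvalidParameterError("need at least one QTL")
        if self.n_env < 1 or self.n_rep < 1:
            raise InvalidParameterError("n_env and n_rep must be >= 1")


# Trait architectures calibrated to the variance-component magnitudes of the
# hybrid rye testcross experiment that this simulator emulates (population A
# magnitudes; grain yield in dt/ha, plant height in cm, starch and total
# pentosan content in %).
REFERENCE_ARCHITECTURES: dict[str, TraitArchitecture] = {
    "grain_yield": TraitArchitecture(
        trait="grain_yield", mean=79.3, sigma2_g=3.33, sigma2_ge=8.40,
        sigma2_e=3.48, sigma2_env=12.0, sigma2_rep=0.5, sigma2_block=0.5,
        n_env=9, n_rep=2),
    "plant_height": TraitArchitecture(
        trait="plant_height", mean=118.2, sigma2_g=7.30, sigma2_ge=4.03,
        sigma2_e=2.94, sigma2_env=20.0, sigma2_rep=0.5, sigma2_block=0.5,
        n_env=9, n_rep=2),
    "starch_content": TraitArchitecture(
        trait="starch_content", mean=61.6, sigma2_g=0.24, sigma2_ge=0.26,
        sigma2_e=0.14, sigma2_env=0.5, sigma2_rep=0.02, sigma2_block=0.02,
        n_env=6, n_rep=2),
    "pentosan_content": TraitArchitecture(
        trait="pentosan_content", mean=10.0, sigma2_g=0.03, sigma2_ge=0.08,
        sigma2_e=0.04, sigma2_env=0.1, sigma2_rep=0.005, sigma2_block=0.005,
        n_env=6, n_rep=2),
}


def simulate_parents(
    n_markers_per_chrom: int = 150,
    map_length_cM: float = 120.0,
    seed: int = 0,
    seg_frac_a: float = 0.376,
    seg_frac_b: float = 0.557,
    n_chromosomes: int = 7,
) -> tuple[ParentSet, GeneticMap]:
    """Draw a random genetic map and four homozygous founder genotypes.

    Markers are placed uniformly at random on each linkage group and sorted.
    P2 (resp. P3) differs from the shared parent P1 at a ``seg_frac_a``
    (resp. ``seg_frac_b``) fraction of loci, so the two crosses segregate at
    different numbers of markers; the defaults reproduce the 394-vs-584
    out-of-1048 asymmetry of the emulated experiment.  The tester's alleles
    are drawn independently of all parents (unrelated).
    """
    if n_markers_per_chrom < 2:
        raise InvalidParameterError("need at least 2 markers per chromosome")
    if map_length_cM <= 0:
        raise InvalidParameterError("map length must be positive")
    if not (0 <= seg_frac_a <= 1 and 0 <= seg_frac_b <= 1):
        raise InvalidParameterError("segregating fractions must lie in [0,1]")
    rng = np.random.default_rng(seed)

    rows = []
    for chrom in range(1, n_chromosomes + 1):
        pos = np.sort(rng.uniform(0.0, map_length_cM, size=n_markers_per_chrom))
        for i, p in enumerate(pos):
            rows.append((f"c{chrom}m{i + 1:03d}", chrom, float(p)))
    gmap = GeneticMap(pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_cM"]))

    m = gmap.n_markers
    p1 = rng.integers(0, 2, size=m)
    flip_a = rng.random(m) < seg_frac_a
    flip_b = rng.random(m) < seg_frac_b
    parents = {
        "P1": p1,
        "P2": np.where(flip_a, 1 - p1, p1),
        "P3": np.where(flip_b, 1 - p1, p1),
        "tester": rng.integers(0, 2, size=m),
    }
    return ParentSet(parents, gmap), gmap


def _gametes(h0: np.ndarray, h1: np.ndarray, gmap: GeneticMap,
             rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw ``n`` gametes from an individual with haplotypes ``h0``/``h1``.

    Haldane model: crossover count per chromosome ~ Poisson(L/100 Morgan),
    crossover positions uniform, no interference.
    """
    out = np.empty((n, gmap.n_markers), dtype=h0.dtype)
    tab = gmap.table
    chrom_arr = tab["chromosome"].to_numpy()
    pos_arr = tab["position_cM"].to_numpy()
    for chrom in gmap.chromosomes:
        idx = np.flatnonzero(chrom_arr == chrom)
        pos = pos_arr[idx]
        length = pos[-1] if len(pos) else 0.0
        for g in range(n):
            n_x = rng.poisson(length / 100.0)
            start = rng.integers(0, 2)
            if n_x == 0:
                hap = np.full(len(idx), start)
            else:
                xpos = np.sort(rng.uniform(0.0, length, size=n_x))
                hap = (start + np.searchsorted(xpos, pos, side="right")) % 2
            out[g, idx] = np.where(hap == 0, h0[idx], h1[idx])
    return out


def simulate_f3_population(
    parents: ParentSet,
    cross: tuple[str, str],
    n_lines: int = 220,
    seed: int = 0,
    label: str = "A",
) -> Population:
    """Simulate F3 lines from one bi-parental cross by single seed descent.

    The F1 (one haplotype from each parent) is selfed twice; each line is
    one F3 plant, genotyped as allele-1 dosage in {0,1,2}.  At loci where
    the parents carry the same allele the population is monomorphic.
    """
    if n_lines < 1:
        raise InvalidParameterError("n_lines must be >= 1")
    p_a, p_b = cross
    for p in cross:
        if p not in parents.alleles:
            raise InvalidParameterError(f"unknown parent {p!r}")
    gmap = parents.gmap
    rng = np.random.default_rng(seed)
    f1_h0 = parents.alleles[p_a]
    f1_h1 = parents.alleles[p_b]

    geno = np.empty((n_lines, gmap.n_markers), dtype=np.int8)
    for i in range(n_lines):
        f2 = _gametes(f1_h0, f1_h1, gmap, rng, 2)
        f3 = _gametes(f2[0], f2[1], gmap, rng, 2)
        geno[i] = f3[0] + f3[1]

    ids = [f"{label}{i + 1:03d}" for i in range(n_lines)]
    gdf = pd.DataFrame(geno, index=ids, columns=gmap.marker_ids)
    return Population(label=label, genotypes=gdf, parent_pair=cross, gmap=gmap)


def with_missing(genotypes: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Return a copy with a ``rate`` fraction of entries set missing (NaN),
    emulating genotyping dropout."""
    if not 0 <= rate < 1:
        raise InvalidParameterError("missing rate must lie in [0,1)")
    rng = np.random.default_rng(seed)
    out = genotypes.astype(float).copy()
    mask = rng.random(out.shape) < rate
    arr = out.to_numpy()
    arr[mask] = np.nan
    return pd.DataFrame(arr, index=out.index, columns=out.columns)


@dataclass
class TrialSimulation:
    """A simulated multi-environment trial plus its generating truth."""

    trial: pd.DataFrame            # long format plot observations
    genetic_values: pd.Series      # true genotypic value per line
    qtl: pd.DataFrame              # marker_id, chromosome, position_cM, effect
    architecture: TraitArchitecture
    environments: list[tuple[str, int]]

    @property
    def env_keys(self) -> list[str]:
        return [env_key(*e) for e in self.environments]

    def marker_panel(self, genotypes: pd.DataFrame) -> pd.DataFrame:
        """Genotype matrix restricted to assayed markers: causal QTL loci
        are excluded, as in a real assay where the causal polymorphisms are
        tagged by linked markers rather than genotyped themselves."""
        drop = [m for m in self.qtl["marker_id"] if m in genotypes.columns]
        return genotypes.drop(columns=drop)


def _draw_qtl(arch: TraitArchitecture, populations: Sequence[Population],
              gmap: GeneticMap, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Choose QTL marker loci and calibrated additive effects."""
    if arch.qtl_markers is not None:
        qtl_ids = np.asarray(arch.qtl_markers)
        missing = set(qtl_ids) - set(gmap.marker_ids)
        if missing:
            raise InvalidParameterError(f"QTL off-map: {sorted(missing)}")
    else:
        seg = set()
        for pop in populations:
            seg |= set(pop.segregating_markers())
        seg = np.array(sorted(seg))
        if len(seg) < arch.n_qtl:
            raise InvalidParameterError("fewer segregating markers than requested QTL")
        qtl_ids = rng.choice(seg, size=arch.n_qtl, replace=False)

    if arch.qtl_effects is not None:
        effects = np.asarray(arch.qtl_effects, dtype=float)
        if len(effects) != len(qtl_ids):
            raise InvalidParameterError("qtl_effects length mismatch")
        return qtl_ids, effects

    effects = rng.standard_normal(len(qtl_ids))
    if arch.calibration == "empirical":
        # scale so the mean within-population variance of the genetic
        # values across the supplied lines matches the target exactly;
        # unlike the theoretical scaling this accounts for linkage
        # disequilibrium between QTL
        v = np.mean([
            (pop.genotypes[qtl_ids].to_numpy(dtype=float) @ effects).var(ddof=1)
            for pop in populations
        ])
    else:
        # expected variance under independent F3 loci: Var(dosage) = 3/4 at
        # a segregating locus; averaged over the supplied populations
        v = np.mean([
            sum(0.75 * e * e
                for mid, e in zip(qtl_ids, effects)
                if mid in set(pop.segregating_markers()))
            for pop in populations
        ])
    if v <= 0:
        raise InvalidParameterError("no QTL segregates in the supplied populations")
    effects *= np.sqrt(arch.sigma2_g / v)
    return qtl_ids, effects


def simulate_trial(
    populations: Sequence[Population],
    arch: TraitArchitecture,
    environments: Sequence[tuple[str, int]] | None = None,
    seed: int = 0,
    n_blocks: int = 10,
) -> TrialSimulation:
    """Simulate plot-level phenotypes for the testcross hybrids.

    Plot value = mean + genetic value + environment effect + GxE deviation
    (one draw per genotype x environment) + replication effect + block
    effect + plot error.  The tester is constant across lines and absorbed
    into the mean.  Lines from all supplied populations are evaluated
    together, as in the emulated experiment.
    """
    if environments is None:
        environments = list(DEFAULT_ENVIRONMENTS_9[: arch.n_env])
    environments = [tuple(e) for e in environments]
    if not environments:
        raise InvalidParameterError("environments must be non-empty")
    gmap = populations[0].gmap
    rng = np.random.default_rng(seed)

    qtl_ids, effects = _draw_qtl(arch, populations, gmap, rng)
    geno_all = pd.concat([pop.genotypes for pop in populations])
    gvals = pd.Series(
        geno_all[qtl_ids].to_numpy(dtype=float) @ effects,
        index=geno_all.index, name="genetic_value",
    )

    n_g = len(gvals)
    n_env = len(environments)
    n_rep = arch.n_rep
    env_eff = rng.normal(0.0, np.sqrt(arch.sigma2_env), size=n_env)
    if arch.sigma2_ge == 0:
        ge = np.zeros((n_g, n_env))
    elif arch.ge_mode == "genetic":
        # marker-associated interaction: each environment perturbs the QTL
        # effects, so related lines share their G x E deviations — the
        # mechanism behind the within- vs across-environment transfer
        # penalty of genomic prediction
        Q = geno_all[qtl_ids].to_numpy(dtype=float)
        raw = Q @ rng.standard_normal((len(qtl_ids), n_env))
        pop_slices = np.cumsum([0] + [p.n_lines for p in populations])
        v = np.mean([raw[pop_slices[i]:pop_slices[i + 1]].var(axis=0, ddof=1).mean()
                     for i in range(len(populations))])
        ge = raw * np.sqrt(arch.sigma2_ge / v)
        ge -= ge.mean(axis=0, keepdims=True)
    elif arch.ge_mode == "iid":
        ge = rng.normal(0.0, np.sqrt(arch.sigma2_ge), size=(n_g, n_env))
    else:
        raise InvalidParameterError("ge_mode must be 'genetic' or 'iid'")
    rep_eff = rng.normal(0.0, np.sqrt(arch.sigma2_rep), size=(n_env, n_rep))

    frames = []
    ids = gvals.index.to_numpy()
    g = gvals.to_numpy()
    for j, (loc, year) in enumerate(environments):
        for r in range(n_rep):
            blocks = rng.permutation(np.arange(n_g) % n_blocks) + 1
            block_eff = rng.normal(0.0, np.sqrt(arch.sigma2_block), size=n_blocks)
            err = rng.normal(0.0, np.sqrt(arch.sigma2_e), size=n_g)
            value = (arch.mean + g + env_eff[j] + ge[:, j]
                     + rep_eff[j, r] + block_eff[blocks - 1] + err)
            frames.append(pd.DataFrame({
                "genotype": ids,
                "location": loc,
                "year": year,
                "rep": r + 1,
                "block": blocks,
                "trait": arch.trait,
                "value": value,
            }))
    trial = pd.concat(frames, ignore_index=True)
    trial["environment"] = [env_key(l, y) for l, y in zip(trial["location"], trial["year"])]

    qtl_tab = gmap.table.set_index("marker_id").loc[qtl_ids].reset_index()
    qtl_tab["effect"] = effects
    return TrialSimulation(
        trial=trial, genetic_values=gvals, qtl=qtl_tab,
        architecture=arch, environments=list(environments),
    )


def haldane_recombination_fraction(d_cM: float) -> float:
    """Haldane map function: r = (1 - exp(-2d/100)) / 2."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cM / 100.0))
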