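"""Marker quality control, binomial imputation and LD estimation.

QC mirrors standard practice for dominant/biallelic marker panels in
bi-parental populations: markers with more than 5 % missing genotype calls
or with allele frequencies below 0.05 or above 0.95 are excluded; remaining
missing genotypes are drawn from Binomial(2, p-hat) with the allele
frequency observed in the line's own population.  Linkage disequilibrium is
the squared Pearson correlation of dosage columns (allele-frequency
correlation r^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import GeneticMap


@dataclass(frozen=True)
class MarkerSet:
    """Genotype matrix (lines x markers, dosage 0/1/2, NaN = missing) with
    its genetic map and per-line population labels."""

    genotypes: pd.DataFrame
    gmap: GeneticMap
    populations: pd.Series

    def __post_init__(self):
        if not self.genotypes.index.equals(self.populations.index):
            raise ValueError("population labels do not match genotype lines")
        unknown = set(self.genotypes.columns) - set(self.gmap.marker_ids)
        if unknown:
            raise ValueError(f"markers absent from map: {sorted(unknown)[:5]}")
        vals = self.genotypes.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype entries must be 0/1/2 or missing")

    @property
    def marker_ids(self) -> np.ndarray:
        return self.genotypes.columns.to_numpy()

    @property
    def n_lines(self) -> int:
        return len(self.genotypes)

    def lines_of(self, population: str) -> pd.Index:
        return self.populations.index[self.populations == population]

    def subset_population(self, population: str) -> "MarkerSet":
        idx = self.lines_of(population)
        return MarkerSet(self.genotypes.loc[idx], self.gmap, self.populations.loc[idx])

    def allele_frequencies(self) -> pd.Series:
        """Allele-1 frequency per marker: mean(dosage)/2 over non-missing lines."""
        return self.genotypes.mean(axis=0, skipna=True) / 2.0

    def missing_rates(self) -> pd.Series:
        return self.genotypes.isna().mean(axis=0)

    def dominant_view(self) -> "MarkerSet":
        """Lossy presence/absence recoding (dosage > 0 -> 1), emulating a
        dominant DArT-style assay.  Missing entries stay missing."""
        g = self.genotypes.copy()
        arr = g.to_numpy(dtype=float)
        arr[arr > 0] = 1.0
        return MarkerSet(pd.DataFrame(arr, index=g.index, columns=g.columns),
                         self.gmap, self.populations)


def filter_markers(
    ms: MarkerSet,
    max_missing: float = 0.05,
    maf_bounds: tuple[float, float] = (0.05, 0.95),
) -> tuple[MarkerSet, pd.DataFrame]:
    """Exclude markers by missing rate and allele frequency.

    A marker is dropped when its missing rate exceeds ``max_missing`` or
    its allele frequency is *strictly* below ``maf_bounds[0]`` or strictly
    above ``maf_bounds[1]`` (frequencies exactly at a bound are kept).
    Frequencies are computed on the full matrix, so for a multi-population
    set this is combined-set QC; apply to ``subset_population(...)`` for
    per-population QC.  Marker order is preserved.
    """
    lo, hi = maf_bounds
    miss = ms.missing_rates()
    freq = ms.allele_frequencies()
    reasons = pd.Series("", index=ms.genotypes.columns, dtype=object)
    reasons[miss > max_missing] = "missing_rate"
    bad_freq = (freq < lo) | (freq > hi) | freq.isna()
    reasons[bad_freq & (reasons == "")] = "allele_frequency"
    keep = reasons == ""
    report = pd.DataFrame({
        "marker_id": ms.genotypes.columns,
        "missing_rate": miss.to_numpy(),
        "allele_frequency": freq.to_numpy(),
        "kept": keep.to_numpy(),
        "reason": reasons.to_numpy(),
    })
    kept_ids = report.loc[report["kept"], "marker_id"]
    if kept_ids.empty:
        warnings.warn("all markers excluded by QC", stacklevel=2)
    out = MarkerSet(ms.genotypes[list(kept_ids)], ms.gmap, ms.populations)
    return out, report


def impute_missing(ms: MarkerSet, seed: int, per_population: bool = True) -> MarkerSet:
    """Impute missing dosages as Binomial(2, p-hat) draws.

    p-hat is the observed allele frequency of the marker within the line's
    population (or over all lines when ``per_population`` is False).
    Observed entries are untouched.  A marker with no observed genotype in
    a population cannot be imputed and raises a ValueError naming it.
    """
    rng = np.random.default_rng(seed)
    g = ms.genotypes.copy().astype(float)
    groups = ([(p, ms.lines_of(p)) for p in ms.populations.unique()]
              if per_population else [("all", g.index)])
    for pop, idx in groups:
        sub = g.loc[idx]
        miss = sub.isna()
        if not miss.to_numpy().any():
            continue
        freq = sub.mean(axis=0, skipna=True) / 2.0
        dead = freq.index[freq.isna() & (miss.sum(axis=0) > 0)]
        if len(dead):
            raise ValueError(
                f"marker(s) fully missing in population {pop!r}: {list(dead[:5])}")
        for col in sub.columns[miss.any(axis=0)]:
            rows = miss.index[miss[col]]
            g.loc[rows, col] = rng.binomial(2, freq[col], size=len(rows)).astype(float)
    return MarkerSet(g, ms.gmap, ms.populations)


def ld_r2(
    ms: MarkerSet,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Squared allele-frequency correlation r^2 between marker pairs.

    With ``pairs=None`` all unordered pairs are returned.  Requires a
    complete matrix (impute first).  Pairs involving a zero-variance
    (monomorphic) column get ``r2 = NaN`` and ``defined = False`` rather
    than a silent 0.
    """
    g = ms.genotypes
    if g.isna().to_numpy().any():
        raise ValueError("missing genotypes present; impute before LD estimation")
    arr = g.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    if pairs is None:
        cols = list(g.columns)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(arr, rowvar=False)
        iu, ju = np.triu_indices(len(cols), k=1)
        r2 = c[iu, ju] ** 2
        bad = (sd[iu] == 0) | (sd[ju] == 0)
        r2[bad] = np.nan
        out = pd.DataFrame({
            "marker_a": np.asarray(cols)[iu],
            "marker_b": np.asarray(cols)[ju],
            "r2": r2,
            "defined": ~bad,
        })
        return out
    rows = []
    for a, b in pairs:
        xa, xb = g[a].to_numpy(dtype=float), g[b].to_numpy(dtype=float)
        if xa.std() == 0 or xb.std() == 0:
            rows.append((a, b, np.nan, False))
        else:
            rows.append((a, b, float(np.corrcoef(xa, xb)[0, 1] ** 2), True))
    return pd.DataFrame(rows, columns=["marker_a", "marker_b", "r2", "defined"])


def ld_distance_table(ms: MarkerSet) -> pd.DataFrame:
    """r^2 against map distance for all within-chromosome marker pairs."""
    ld = ld_r2(ms)
    tab = ms.gmap.table.set_index("marker_id")
    chrom_a = tab.loc[ld["marker_a"], "chromosome"].to_numpy()
    chrom_b = tab.loc[ld["marker_b"], "chromosome"].to_numpy()
    pos_a = tab.loc[ld["marker_a"], "position_cM"].to_numpy()
    pos_b = tab.loc[ld["marker_b"], "position_cM"].to_numpy()
    ld = ld.assign(same_chromosome=chrom_a == chrom_b,
                   distance_cM=np.abs(pos_a - pos_b))
    return ld[ld["same_chromosome"]].drop(columns="same_chromosome")
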