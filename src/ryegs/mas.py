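"""Marker-assisted selection: QTL detection by composite interval mapping
(CIM) and prediction from detected or randomly sampled markers.

CIM follows the regression approach: background marker cofactors are chosen
by forward stepwise regression, and at each grid position on the genetic
map the phenotype is regressed on an expected-QTL covariate interpolated
from the flanking markers, with cofactors inside a window around the tested
position dropped from both the null and the full model.  The test statistic
is the RSS-ratio LOD,

    LOD = (n/2) * log10(RSS_reduced / RSS_full).

MAS prediction regresses the training phenotype on the dosage covariates of
the detected QTL and scores the test set; its cross-validated accuracy is
standardized as r_g = sqrt(R2_cv / h2) where R2_cv is the share of test-set
phenotypic variance explained and h2 the heritability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

from .simulate import GeneticMap


@dataclass
class QTLScanResult:
    """Genome scan output: per-position LOD profile, detected QTL above the
    threshold (peaks separated by a minimum distance), the joint-model
    adjusted R2 and the cofactors used."""

    scan: pd.DataFrame          # chromosome, position_cM, lod, effect
    qtl: pd.DataFrame           # chromosome, position_cM, lod, effect
    r2_adj: float
    cofactors: list[str] = field(default_factory=list)
    lod_threshold: float = 3.73

    @property
    def n_qtl(self) -> int:
        return len(self.qtl)


def _forward_stepwise(y: np.ndarray, C: np.ndarray, alpha: float,
                      max_terms: int) -> list[int]:
    """Forward selection of cofactor columns by partial F-test (p < alpha)."""
    n = len(y)
    Q = np.ones((n, 1)) / np.sqrt(n)
    yr = y - Q @ (Q.T @ y)
    Cr = C - Q @ (Q.T @ C)
    chosen: list[int] = []
    for _ in range(max_terms):
        rss = float(yr @ yr)
        norms = (Cr ** 2).sum(axis=0)
        ok = norms > 1e-10 * max(1.0, norms.max(initial=0.0))
        if not ok.any() or rss <= 0:
            break
        proj = Cr.T @ yr
        ssr = np.where(ok, proj ** 2 / np.where(ok, norms, 1.0), -np.inf)
        j = int(np.argmax(ssr))
        df2 = n - Q.shape[1] - 1
        if df2 <= 0:
            break
        denom = (rss - ssr[j]) / df2
        if denom <= 0:
            f = np.inf
        else:
            f = ssr[j] / denom
        p = st.f.sf(f, 1, df2)
        if p >= alpha:
            break
        chosen.append(j)
        qnew = Cr[:, j] / np.sqrt(norms[j])
        Q = np.column_stack([Q, qnew])
        yr = yr - qnew * (qnew @ yr)
        Cr = Cr - np.outer(qnew, qnew @ Cr)
    return chosen


def _position_covariates(geno: pd.DataFrame, gmap: GeneticMap,
                         positions: pd.DataFrame) -> np.ndarray:
    """Expected dosage covariates at arbitrary map positions.

    Linear interpolation between the flanking markers (a first-order
    Haley-Knott style approximation); beyond the terminal markers the
    nearest marker dosage is used.
    """
    out = np.empty((len(geno), len(positions)))
    # restrict to markers actually present (QC may have dropped some)
    tab = gmap.table[gmap.table["marker_id"].isin(geno.columns)]
    for k, (chrom, pos) in enumerate(zip(positions["chromosome"],
                                         positions["position_cM"])):
        sub = tab[tab["chromosome"] == chrom]
        p = sub["position_cM"].to_numpy()
        ids = sub["marker_id"].to_numpy()
        j = np.searchsorted(p, pos)
        if j == 0:
            out[:, k] = geno[ids[0]].to_numpy(dtype=float)
        elif j >= len(p):
            out[:, k] = geno[ids[-1]].to_numpy(dtype=float)
        else:
            lo, hi = p[j - 1], p[j]
            w = 0.5 if hi == lo else (hi - pos) / (hi - lo)
            out[:, k] = (w * geno[ids[j - 1]].to_numpy(dtype=float)
                         + (1 - w) * geno[ids[j]].to_numpy(dtype=float))
    return out


def _rss(design: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    coef, res, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid), coef


def cim_scan(
    genotypes: pd.DataFrame,
    phenotypes: pd.Series,
    gmap: GeneticMap,
    lod_threshold: float = 3.73,
    step_cM: float = 1.0,
    cofactor_alpha: float = 0.01,
    max_cofactors: int | None = None,
    window_cM: float = 10.0,
    min_peak_distance_cM: float = 20.0,
) -> QTLScanResult:
    """Composite interval mapping scan on a 1-cM grid.

    ``genotypes``: complete (imputed) lines x markers dosage matrix;
    ``phenotypes``: one value per line (e.g. across-environment BLUEs).
    """
    lines = genotypes.index.intersection(phenotypes.index)
    if len(lines) < len(genotypes):
        raise ValueError("phenotypes missing for some lines")
    geno = genotypes.loc[lines]
    y = phenotypes.loc[lines].to_numpy(dtype=float)
    n = len(y)
    if max_cofactors is None:
        max_cofactors = max(1, n // 5)
    if n < max_cofactors + 2:
        raise ValueError("fewer lines than cofactors + 2")

    marker_ids = list(geno.columns)
    C = geno.to_numpy(dtype=float)
    cof_idx = _forward_stepwise(y, C, cofactor_alpha, max_cofactors)
    cof_ids = [marker_ids[j] for j in cof_idx]
    tab = gmap.table.set_index("marker_id")
    cof_chrom = tab.loc[cof_ids, "chromosome"].to_numpy() if cof_ids else np.array([])
    cof_pos = tab.loc[cof_ids, "position_cM"].to_numpy() if cof_ids else np.array([])
    cof_mat = C[:, cof_idx] if cof_idx else np.empty((n, 0))

    rows = []
    ones = np.ones((n, 1))
    for chrom in gmap.chromosomes:
        sub = gmap.table[gmap.table["chromosome"] == chrom]
        if sub.empty:
            continue
        pmax = float(sub["position_cM"].max())
        grid = np.arange(0.0, pmax + step_cM / 2, step_cM)
        grid_df = pd.DataFrame({"chromosome": chrom, "position_cM": grid})
        cov = _position_covariates(geno, gmap, grid_df)
        for k, d in enumerate(grid):
            keep = (cof_chrom != chrom) | (np.abs(cof_pos - d) > window_cM) \
                if len(cof_ids) else np.array([], dtype=bool)
            base = np.column_stack([ones, cof_mat[:, keep]]) if keep.size else ones
            rss0, _ = _rss(base, y)
            full = np.column_stack([base, cov[:, k]])
            rss1, coef = _rss(full, y)
            if rss1 <= 0 or rss0 <= 0:
                lod = np.inf if rss0 > rss1 else 0.0
            else:
                lod = max(0.0, (n / 2.0) * np.log10(rss0 / rss1))
            rows.append((int(chrom), float(d), float(lod), float(coef[-1])))
    scan = pd.DataFrame(rows, columns=["chromosome", "position_cM", "lod", "effect"])

    # peak calling: greedy maxima per chromosome, >= min distance apart
    peaks = []
    for chrom, grp in scan.groupby("chromosome"):
        g = grp.sort_values("position_cM").reset_index(drop=True)
        avail = g["lod"].to_numpy() >= lod_threshold
        lods = g["lod"].to_numpy()
        pos = g["position_cM"].to_numpy()
        while avail.any():
            j = int(np.argmax(np.where(avail, lods, -np.inf)))
            peaks.append(g.iloc[j])
            avail &= np.abs(pos - pos[j]) > min_peak_distance_cM
    qtl = (pd.DataFrame(peaks).reset_index(drop=True)
           if peaks else scan.iloc[:0].copy())

    if len(qtl):
        qcov = _position_covariates(geno, gmap, qtl)
        design = np.column_stack([ones, qcov])
        rss1, _ = _rss(design, y)
        tss = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - rss1 / tss if tss > 0 else 0.0
        k = design.shape[1] - 1
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1) if n - k - 1 > 0 else r2
    else:
        r2_adj = 0.0
    return QTLScanResult(scan=scan, qtl=qtl, r2_adj=float(r2_adj),
                         cofactors=cof_ids, lod_threshold=lod_threshold)


@dataclass
class MASPrediction:
    predicted: pd.Series
    r2_cv: float
    n_qtl: int
    degenerate: bool = False


def mas_qtl_predict(
    train_geno: pd.DataFrame,
    train_pheno: pd.Series,
    test_geno: pd.DataFrame,
    test_pheno: pd.Series,
    scan: QTLScanResult,
    gmap: GeneticMap,
) -> MASPrediction:
    """Predict test lines from the QTL detected on the training set.

    Multiple regression of the training phenotype on the detected-QTL
    covariates; R2_cv is the squared Pearson correlation of predicted and
    observed values in the test set.  With zero detected QTL the prediction
    is the training mean and R2_cv = 0 (flagged degenerate).
    """
    lines = train_geno.index.intersection(train_pheno.index)
    y = train_pheno.loc[lines].to_numpy(dtype=float)
    if scan.n_qtl == 0:
        pred = pd.Series(np.full(len(test_geno), y.mean()), index=test_geno.index)
        return MASPrediction(predicted=pred, r2_cv=0.0, n_qtl=0, degenerate=True)
    cov_tr = _position_covariates(train_geno.loc[lines], gmap, scan.qtl)
    cov_te = _position_covariates(test_geno, gmap, scan.qtl)
    design = np.column_stack([np.ones(len(y)), cov_tr])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    pred = pd.Series(np.column_stack([np.ones(len(test_geno)), cov_te]) @ coef,
                     index=test_geno.index)
    obs = test_pheno.loc[pred.index].to_numpy(dtype=float)
    if pred.std() == 0 or obs.std() == 0:
        return MASPrediction(predicted=pred, r2_cv=0.0, n_qtl=scan.n_qtl,
                             degenerate=True)
    r = float(np.corrcoef(pred.to_numpy(), obs)[0, 1])
    return MASPrediction(predicted=pred, r2_cv=r * r, n_qtl=scan.n_qtl)


def sample_neutral_markers(n_qtl: int, gmap: GeneticMap, seed: int) -> list[str]:
    """Random marker sample spread over linkage groups (MAS-NEUT).

    For up to seven markers: one random marker from each of ``n_qtl``
    distinct randomly chosen linkage groups.  Beyond seven: one per group
    plus additional distinct markers drawn from the remainder.
    """
    if n_qtl < 1:
        raise ValueError("n_qtl must be >= 1")
    if n_qtl > gmap.n_markers:
        raise ValueError("more markers requested than exist on the map")
    rng = np.random.default_rng(seed)
    chroms = list(gmap.chromosomes)
    chosen: list[str] = []
    groups = (list(rng.choice(chroms, size=n_qtl, replace=False))
              if n_qtl <= len(chroms) else chroms)
    for c in groups:
        ids = gmap.positions(c)["marker_id"].to_numpy()
        chosen.append(str(rng.choice(ids)))
    extra = n_qtl - len(chosen)
    if extra > 0:
        pool = np.setdiff1d(gmap.marker_ids, chosen)
        chosen.extend(str(m) for m in rng.choice(pool, size=extra, replace=False))
    return chosen


def mas_accuracy(r2_cv: float, h2: float) -> float:
    """Standardized MAS accuracy r_g = sqrt(R2_cv / h2), capped at 1."""
    if not 0.0 <= r2_cv <= 1.0:
        raise ValueError("R2_cv must lie in [0, 1]")
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must lie in (0, 1]")
    r_g = float(np.sqrt(r2_cv / h2))
    if r_g > 1.0:
        warnings.warn("standardized accuracy exceeds 1; capped", stacklevel=2)
        return 1.0
    return r_g
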