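"""Cross-validation schemes for genomic and marker-assisted prediction.

Every scheme partitions genotypes into five near-equal subsets (S1..S5);
S1-S4 form the estimation set (ES) on which marker effects are fitted and
S5 the test set (TS).  The schemes differ in which population(s) and which
environments feed the ES and TS:

* within/across populations: Within-Within-Same, Within-Within-Different,
  Across-Across, Across-Within;
* environment count: ES and TS phenotypes built from k randomly chosen
  location-year combinations (k = 1..n_env);
* location/year transfer: ES from two locations x two years (G(L), GxL) or
  one year x four locations (G(Y), GxY), with the TS drawn from the same or
  the complementary environments (a configurable environment list, by
  default the single-year HOH10 analog, is excluded from TS construction).

Accuracy per replicate is the predictive ability r_p = Pearson(observed TS
BLUEs, predictions); the standardized accuracy r_g = r_p / sqrt(h2) uses
the heritability re-estimated from each replicate's estimation set, which
also supplies the RR-BLUP penalty lambda = m (1 - h2) / h2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .pheno import step1_blues, twoway_anova_components
from .rrblup import RRBLUP, lambda_from_h2
from .mas import cim_scan, mas_qtl_predict, sample_neutral_markers
from .simulate import GeneticMap

H2_CLAMP = (0.01, 0.99)   # keeps the ridge penalty finite in edge replicates


def make_folds(genotype_ids, k: int = 5, seed: int | np.random.Generator = 0
               ) -> list[np.ndarray]:
    """Random partition of genotypes into k subsets with sizes differing by
    at most one (S1..Sk)."""
    ids = np.asarray(genotype_ids)
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > len(ids):
        raise ValueError("more folds than genotypes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(ids)
    return [np.sort(f) for f in np.array_split(perm, k)]


def accuracy(observed, predicted) -> float:
    """Predictive ability r_p = Pearson correlation; NaN when degenerate
    (fewer than 3 pairs or zero variance on either side)."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if len(obs) != len(pred):
        raise ValueError("length mismatch")
    if len(obs) < 3 or obs.std() == 0 or pred.std() == 0:
        return np.nan
    return float(np.corrcoef(obs, pred)[0, 1])


def standardize(r_p: float, h2: float) -> float:
    """Standardized accuracy r_g = r_p / sqrt(h2)."""
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must lie in (0, 1]")
    return r_p / np.sqrt(h2)


@dataclass
class PopulationData:
    """Everything the CV engine needs about one population: per-environment
    BLUEs, per-environment effective error, the (imputed) marker matrix and
    the environment metadata; optionally the simulation-truth genotypic
    values for oracle checks."""

    label: str
    blues_by_env: pd.DataFrame        # lines x environment keys
    error_variances: pd.Series        # effective error per environment
    n_rep: int
    markers: pd.DataFrame             # lines x markers (complete)
    gmap: GeneticMap
    env_meta: pd.DataFrame            # index env key; columns location, year
    true_values: pd.Series | None = None

    def __post_init__(self):
        common = self.blues_by_env.index.intersection(self.markers.index)
        self.blues_by_env = self.blues_by_env.loc[common]
        self.markers = self.markers.loc[common]

    @property
    def line_ids(self) -> np.ndarray:
        return self.blues_by_env.index.to_numpy()

    @property
    def env_keys(self) -> list[str]:
        return list(self.blues_by_env.columns)


def prepare_population_data(trial: pd.DataFrame, markers: pd.DataFrame,
                            gmap: GeneticMap, label: str,
                            trait: str | None = None,
                            true_values: pd.Series | None = None
                            ) -> PopulationData:
    """Run step 1 per environment for the lines of one population and
    assemble the CV input container."""
    d = trial[trial["genotype"].isin(markers.index)]
    if trait is not None:
        d = d[d["trait"] == trait]
    envs = sorted(d["environment"].unique())
    blues, err = {}, {}
    for e in envs:
        s1 = step1_blues(d, e)
        blues[e] = s1.blues
        err[e] = s1.sigma2_e
    env_meta = (d[["environment", "location", "year"]]
                .drop_duplicates().set_index("environment").loc[envs])
    return PopulationData(
        label=label, blues_by_env=pd.DataFrame(blues),
        error_variances=pd.Series(err), n_rep=int(d["rep"].nunique()),
        markers=markers, gmap=gmap, env_meta=env_meta,
        true_values=true_values)


def estimate_h2_entry_means(Y: pd.DataFrame, error_variances: pd.Series,
                            n_rep: int) -> float:
    """Heritability of entry means from a lines x environments BLUE matrix.

    With >= 2 environments the genotype and residual components come from
    the two-way ANOVA of the cell means and h2 = s2_G / (s2_G + resid/k).
    With a single environment the genotypic signal cannot be separated from
    G x E; the plot error from step 1 is then the only removable noise:
    h2 = (var - s2_e/n_rep) / var.  Clamped away from 0 and 1 so the
    derived ridge penalty stays finite.
    """
    k = Y.shape[1]
    if k >= 2:
        comps = twoway_anova_components(Y.to_numpy())
        s_g, resid = comps["genotype"], comps["residual"]
        h2 = s_g / (s_g + resid / k) if (s_g + resid) > 0 else 0.0
    else:
        v = float(Y.iloc[:, 0].var(ddof=1))
        err = float(error_variances[Y.columns[0]]) / n_rep
        h2 = (v - err) / v if v > 0 else 0.0
    return float(np.clip(h2, *H2_CLAMP))


@dataclass
class CVResult:
    """Distribution of accuracies over CV replicates."""

    scheme: str
    r_p: np.ndarray
    r_g: np.ndarray
    h2_es: np.ndarray
    h2_full: float | None = None
    n_degenerate: int = 0
    metadata: dict = field(default_factory=dict)

    def summary(self) -> dict:
        rp = self.r_p[~np.isnan(self.r_p)]
        if len(rp) == 0:
            return {"scheme": self.scheme, "n": 0}
        return {
            "scheme": self.scheme,
            "n": int(len(rp)),
            "n_degenerate": int(self.n_degenerate),
            "median_r_p": float(np.median(rp)),
            "q1_r_p": float(np.quantile(rp, 0.25)),
            "q3_r_p": float(np.quantile(rp, 0.75)),
            "mean_r_p": float(rp.mean()),
            "sd_r_p": float(rp.std(ddof=1)) if len(rp) > 1 else 0.0,
            "median_r_g": float(np.median(self.r_g[~np.isnan(self.r_g)])),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "replicate": np.arange(len(self.r_p)),
            "scheme": self.scheme,
            "r_p": self.r_p,
            "r_g": self.r_g,
            "h2_es": self.h2_es,
        })


# ----------------------------------------------------------------------
# predictors

def _predict_rrblup(es_X, es_y, ts_X, h2, rng, ctx):
    lam = lambda_from_h2(es_X.shape[1], h2)
    return RRBLUP(es_y, es_X, lam).fit().predict(ts_X)


def _predict_mas_qtl(es_X, es_y, ts_X, h2, rng, ctx):
    scan = cim_scan(
        es_X, es_y, ctx["gmap"],
        lod_threshold=ctx.get("lod_threshold", 3.73),
        step_cM=ctx.get("step_cM", 1.0),
        cofactor_alpha=ctx.get("cofactor_alpha", 0.01),
        window_cM=ctx.get("window_cM", 10.0),
        min_peak_distance_cM=ctx.get("min_peak_distance_cM", 20.0),
    )
    dummy_obs = pd.Series(np.zeros(len(ts_X)), index=ts_X.index)
    out = mas_qtl_predict(es_X, es_y, ts_X, dummy_obs, scan, ctx["gmap"])
    return out.predicted


def _predict_mas_neut(es_X, es_y, ts_X, h2, rng, ctx):
    n_mark = ctx.get("n_neutral", 7)
    ids = sample_neutral_markers(n_mark, ctx["gmap"],
                                 int(rng.integers(0, 2 ** 31 - 1)))
    ids = [m for m in ids if m in es_X.columns]
    if not ids:
        return pd.Series(np.full(len(ts_X), float(np.mean(es_y))), index=ts_X.index)
    design = np.column_stack([np.ones(len(es_y)),
                              es_X[ids].to_numpy(dtype=float)])
    coef, *_ = np.linalg.lstsq(design, np.asarray(es_y, dtype=float), rcond=None)
    te = np.column_stack([np.ones(len(ts_X)), ts_X[ids].to_numpy(dtype=float)])
    return pd.Series(te @ coef, index=ts_X.index)


def _predict_oracle(es_X, es_y, ts_X, h2, rng, ctx):
    truth = ctx["true_values"]
    return truth.loc[ts_X.index]


PREDICTORS: dict[str, Callable] = {
    "rrblup": _predict_rrblup,
    "mas-qtl": _predict_mas_qtl,
    "mas-neut": _predict_mas_neut,
    "oracle": _predict_oracle,
}


def _evaluate(es_ids, ts_ids, es_envs, ts_envs, es_data: PopulationData,
              ts_data: PopulationData, predictor: str, rng, ctx,
              es_extra: tuple[PopulationData, np.ndarray] | None = None):
    """One CV replicate: fit on the ES, predict and score the TS.

    ``es_extra`` optionally appends lines of a second population (for the
    Across schemes).  Returns (r_p, h2_es, degenerate flag).
    """
    all_es = set(es_ids) | (set(es_extra[1]) if es_extra is not None else set())
    if all_es & set(ts_ids):
        raise RuntimeError("estimation and test sets overlap")

    Y_es = es_data.blues_by_env.loc[es_ids, es_envs]
    err = es_data.error_variances
    X_es = es_data.markers.loc[es_ids]
    if es_extra is not None:
        extra_data, extra_ids = es_extra
        Y_es = pd.concat([Y_es, extra_data.blues_by_env.loc[extra_ids, es_envs]])
        X_es = pd.concat([X_es, extra_data.markers.loc[extra_ids]])
        err = (err + extra_data.error_variances) / 2.0
    y_es = Y_es.mean(axis=1)
    h2 = estimate_h2_entry_means(Y_es, err, es_data.n_rep)

    X_ts = ts_data.markers.loc[ts_ids]
    obs = ts_data.blues_by_env.loc[ts_ids, ts_envs].mean(axis=1)
    ctx = dict(ctx)
    ctx.setdefault("gmap", es_data.gmap)
    if ts_data.true_values is not None:
        ctx.setdefault("true_values", ts_data.true_values)
    pred = PREDICTORS[predictor](X_es, y_es, X_ts, h2, rng, ctx)
    pred = np.asarray(pd.Series(pred).reindex(obs.index)
                      if isinstance(pred, pd.Series) else pred, dtype=float)
    r_p = accuracy(obs.to_numpy(), pred)
    return r_p, h2, np.isnan(r_p)


def _collect(scheme, vals, h2_full=None, metadata=None) -> CVResult:
    r_p = np.array([v[0] for v in vals])
    h2s = np.array([v[1] for v in vals])
    r_g = r_p / np.sqrt(h2s)
    return CVResult(scheme=scheme, r_p=r_p, r_g=r_g, h2_es=h2s,
                    h2_full=h2_full, n_degenerate=int(sum(v[2] for v in vals)),
                    metadata=metadata or {})


def run_cv_population(
    scheme: str,
    data_a: PopulationData,
    data_b: PopulationData | None = None,
    predictor: str = "rrblup",
    n_resamples: int = 200,
    seed: int = 0,
    test_population: str | None = None,
    env_subset: list[str] | None = None,
    **ctx,
) -> CVResult:
    """Within/across-population genotype cross-validation (CV_G).

    Schemes: ``within-within-same`` (5-fold CV inside one population),
    ``within-within-different`` (ES = all of one population, TS = all of
    the other; deterministic, evaluated once), ``across-across`` (5-fold
    CV over the pooled populations, folds stratified by population) and
    ``across-within`` (ES = S1-S4 of both populations, TS = held-out fold
    of the target population).
    """
    if scheme != "within-within-same" and data_b is None:
        raise ValueError(f"scheme {scheme!r} needs both populations")
    envs = env_subset or data_a.env_keys
    target = data_a if (test_population in (None, data_a.label)) else data_b
    other = data_b if target is data_a else data_a
    children = np.random.SeedSequence(seed).spawn(max(n_resamples, 1))

    vals = []
    if scheme == "within-within-same":
        for ss in children[:n_resamples]:
            rng = np.random.default_rng(ss)
            folds = make_folds(target.line_ids, 5, rng)
            es_ids = np.concatenate(folds[:4])
            vals.append(_evaluate(es_ids, folds[4], envs, envs, target,
                                  target, predictor, rng, ctx))
    elif scheme == "within-within-different":
        rng = np.random.default_rng(children[0])
        vals.append(_evaluate(other.line_ids, target.line_ids, envs, envs,
                              other, target, predictor, rng, ctx))
    elif scheme == "across-across":
        for ss in children[:n_resamples]:
            rng = np.random.default_rng(ss)
            fa = make_folds(data_a.line_ids, 5, rng)
            fb = make_folds(data_b.line_ids, 5, rng)
            es_a, ts_a = np.concatenate(fa[:4]), fa[4]
            es_b, ts_b = np.concatenate(fb[:4]), fb[4]
            # pooled ES and pooled TS, stratified by population
            merged_ts = _MergedView(data_a, data_b, ts_a, ts_b)
            vals.append(_evaluate(es_a, merged_ts.line_ids, envs, envs,
                                  data_a, merged_ts, predictor, rng, ctx,
                                  es_extra=(data_b, es_b)))
    elif scheme == "across-within":
        for ss in children[:n_resamples]:
            rng = np.random.default_rng(ss)
            ft = make_folds(target.line_ids, 5, rng)
            fo = make_folds(other.line_ids, 5, rng)
            vals.append(_evaluate(np.concatenate(ft[:4]), ft[4], envs, envs,
                                  target, target, predictor, rng, ctx,
                                  es_extra=(other, np.concatenate(fo[:4]))))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    h2_full = estimate_h2_entry_means(
        target.blues_by_env[envs], target.error_variances, target.n_rep)
    return _collect(f"cv-g:{scheme}", vals, h2_full,
                    {"predictor": predictor, "environments": envs})


class _MergedView:
    """Read-only pooled view of two populations' TS lines (Across-Across)."""

    def __init__(self, a: PopulationData, b: PopulationData, ids_a, ids_b):
        self.blues_by_env = pd.concat([a.blues_by_env.loc[ids_a],
                                       b.blues_by_env.loc[ids_b]])
        self.markers = pd.concat([a.markers.loc[ids_a], b.markers.loc[ids_b]])
        self.n_rep = a.n_rep
        self.gmap = a.gmap
        self.true_values = (
            pd.concat([a.true_values, b.true_values])
            if a.true_values is not None and b.true_values is not None else None)
        self.error_variances = (a.error_variances + b.error_variances) / 2.0
        self.line_ids = self.blues_by_env.index.to_numpy()


def run_cv_env(
    data: PopulationData,
    k_env: int,
    predictor: str = "rrblup",
    n_resamples: int = 200,
    seed: int = 0,
    **ctx,
) -> CVResult:
    """CV_G Env: genotype 5-fold CV with ES and TS phenotypes built from
    ``k_env`` randomly drawn location-year combinations per replicate."""
    envs = data.env_keys
    if k_env < 1 or k_env > len(envs):
        raise ValueError(f"k_env must lie in 1..{len(envs)}")
    children = np.random.SeedSequence(seed).spawn(n_resamples)
    vals = []
    for ss in children:
        rng = np.random.default_rng(ss)
        chosen = sorted(rng.choice(envs, size=k_env, replace=False))
        folds = make_folds(data.line_ids, 5, rng)
        vals.append(_evaluate(np.concatenate(folds[:4]), folds[4],
                              chosen, chosen, data, data, predictor, rng, ctx))
    h2_full = estimate_h2_entry_means(data.blues_by_env, data.error_variances,
                                      data.n_rep)
    return _collect(f"cv-g-env:k={k_env}", vals, h2_full,
                    {"predictor": predictor, "k_env": k_env})


def run_cv_location_year(
    data: PopulationData,
    mode: str,
    predictor: str = "rrblup",
    n_resamples: int = 200,
    seed: int = 0,
    exclude_envs: tuple[str, ...] = ("HOH10",),
    **ctx,
) -> CVResult:
    """Location/year transfer CV: modes ``g-l``, ``gxl``, ``g-y``, ``gxy``.

    g-l / gxl: ES environments are two randomly chosen locations tested in
    both years; the TS uses the same environments (g-l) or the remaining
    complete locations' environments (gxl).  g-y / gxy: ES environments are
    one randomly chosen year at all complete locations; TS from the same
    year (g-y) or the other year (gxy).  Environments listed in
    ``exclude_envs`` never enter a test set.  Genotype folds are disjoint
    in every mode.
    """
    meta = data.env_meta
    by_loc = meta.groupby("location")["year"].nunique()
    complete = sorted(by_loc.index[by_loc == 2])
    years = sorted(meta["year"].unique())
    if len(complete) < 3 or len(years) != 2:
        raise ValueError("need >= 3 locations tested in both years")
    if mode not in {"g-l", "gxl", "g-y", "gxy"}:
        raise ValueError(f"unknown mode {mode!r}")

    children = np.random.SeedSequence(seed).spawn(n_resamples)
    vals = []
    for ss in children:
        rng = np.random.default_rng(ss)
        if mode in {"g-l", "gxl"}:
            locs = sorted(rng.choice(complete, size=2, replace=False))
            es_envs = [e for e in data.env_keys if meta.loc[e, "location"] in locs]
            if mode == "g-l":
                ts_envs = es_envs
            else:
                ts_envs = [e for e in data.env_keys
                           if meta.loc[e, "location"] not in locs
                           and meta.loc[e, "location"] in complete]
        else:
            year = int(rng.choice(years))
            es_envs = [e for e in data.env_keys
                       if meta.loc[e, "year"] == year
                       and meta.loc[e, "location"] in complete]
            if mode == "g-y":
                ts_envs = es_envs
            else:
                other = [y for y in years if y != year][0]
                ts_envs = [e for e in data.env_keys
                           if meta.loc[e, "year"] == other
                           and meta.loc[e, "location"] in complete]
        ts_envs = [e for e in ts_envs if e not in exclude_envs]
        if not ts_envs:
            raise ValueError("no test environments left after exclusions")
        folds = make_folds(data.line_ids, 5, rng)
        vals.append(_evaluate(np.concatenate(folds[:4]), folds[4],
                              es_envs, ts_envs, data, data, predictor,
                              rng, ctx))
    h2_full = estimate_h2_entry_means(data.blues_by_env, data.error_variances,
                                      data.n_rep)
    return _collect(f"cv-{mode}", vals, h2_full,
                    {"predictor": predictor, "mode": mode,
                     "excluded": list(exclude_envs)})
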