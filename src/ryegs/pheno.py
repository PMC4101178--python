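"""Two-step analysis of multi-environment trial data.

Step 1 fits, within each environment, plot values with genotype fixed and
replication and block random; the genotype solutions are the
per-environment BLUEs and the residual variance is that environment's
effective error.  Step 2 operates on the per-environment BLUEs: with
genotype fixed it yields the across-environment BLUEs (the response for
genomic prediction); with genotype random it yields the genotypic and
genotype-by-environment variance components.

Because step 2 has one record per genotype-by-environment cell, its
residual mixes the interaction variance with the carried-forward error of
the step-1 means: resid = sigma2_GE + sigma2_e / n_rep.  The split uses the
mean per-environment effective error from step 1.

Entry-mean heritability (n_env environments, n_rep replications):

    h2 = sigma2_G / (sigma2_G + sigma2_GE/n_env + sigma2_e/(n_env*n_rep))

Single-environment repeatability: r = sigma2_g / (sigma2_g + sigma2_e/n_rep).
The G-by-E ratio sigma2_GE / (sigma2_G + sigma2_GE) measures how much of the
genotype-plus-interaction variance is environment specific, and predicts how
much prediction accuracy degrades when transferring to unseen environments.

On balanced complete layouts the REML estimates coincide with the
closed-form ANOVA method-of-moments estimators; the balanced fast paths
below exploit this (the equality is asserted against the iterative engine
in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixed import VarianceComponentsModel


@dataclass
class VarianceComponents:
    """Across-environment variance components on the plot-data scale."""

    sigma2_g: float
    sigma2_ge: float
    sigma2_e: float
    n_env: int
    n_rep: int
    sigma2_env: float | None = None
    per_env: pd.DataFrame | None = None

    def __post_init__(self):
        if min(self.sigma2_g, self.sigma2_ge, self.sigma2_e) < 0:
            raise ValueError("variance components must be >= 0")
        if self.n_env < 1 or self.n_rep < 1:
            raise ValueError("n_env and n_rep must be >= 1")

    def heritability(self) -> float:
        return heritability(self)

    def ge_ratio(self) -> float:
        return ge_ratio(self)


def heritability(vc: VarianceComponents) -> float:
    """Entry-mean heritability h2 in [0, 1]."""
    denom = vc.sigma2_g + vc.sigma2_ge / vc.n_env + vc.sigma2_e / (vc.n_env * vc.n_rep)
    if denom <= 0:
        raise ValueError("heritability undefined: all variance components are zero")
    return vc.sigma2_g / denom


def repeatability(sigma2_g_env: float, sigma2_e_env: float, n_rep: int) -> float:
    """Within-environment broad-sense heritability of plot means."""
    if sigma2_g_env < 0 or sigma2_e_env < 0:
        raise ValueError("variances must be >= 0")
    denom = sigma2_g_env + sigma2_e_env / n_rep
    if denom <= 0:
        raise ValueError("repeatability undefined: zero denominator")
    return sigma2_g_env / denom


def ge_ratio(vc: VarianceComponents) -> float:
    """Share of genotype-plus-interaction variance due to the interaction."""
    denom = vc.sigma2_g + vc.sigma2_ge
    if denom <= 0:
        raise ValueError("G x E ratio undefined: zero denominator")
    return vc.sigma2_ge / denom


# ----------------------------------------------------------------------
# balanced closed forms (equal to REML on balanced complete data)

def oneway_anova_components(y_groups: np.ndarray) -> tuple[float, float]:
    """Closed-form variance components for a balanced one-way random layout.

    ``y_groups``: g x n matrix (g groups, n observations each).  Returns
    (between-group variance, within-group variance): ((MSB-MSW)/n, MSW),
    the between component clamped at zero.
    """
    y = np.asarray(y_groups, dtype=float)
    g, n = y.shape
    means = y.mean(axis=1)
    msw = float(((y - means[:, None]) ** 2).sum() / (g * (n - 1)))
    msb = float(n * ((means - means.mean()) ** 2).sum() / (g - 1))
    return max((msb - msw) / n, 0.0), msw


def twoway_anova_components(Y: np.ndarray) -> dict[str, float]:
    """Two-way crossed random model with one observation per cell.

    ``Y``: g x e cell-mean matrix.  Returns dicts of variance estimates for
    rows (genotypes), columns (environments) and the residual (interaction
    plus carried error), clamped at zero.
    """
    Y = np.asarray(Y, dtype=float)
    g, e = Y.shape
    if g < 2 or e < 2:
        raise ValueError("need at least 2 genotypes and 2 environments")
    grand = Y.mean()
    rm = Y.mean(axis=1)
    cm = Y.mean(axis=0)
    ms_g = e * ((rm - grand) ** 2).sum() / (g - 1)
    ms_e = g * ((cm - grand) ** 2).sum() / (e - 1)
    resid = Y - rm[:, None] - cm[None, :] + grand
    ms_ge = (resid ** 2).sum() / ((g - 1) * (e - 1))
    return {
        "genotype": max((ms_g - ms_ge) / e, 0.0),
        "environment": max((ms_e - ms_ge) / g, 0.0),
        "residual": float(ms_ge),
    }


# ----------------------------------------------------------------------
# step 1: within-environment analysis

@dataclass
class Step1Result:
    environment: str
    blues: pd.Series            # genotype -> BLUE
    sigma2_e: float             # effective error within the environment
    vcomp: dict[str, float]
    # average sampling variance of a genotype-centered BLUE, from the GLS
    # covariance; exceeds sigma2_e/n_rep by the part of the block and
    # replication shrinkage that leaks into genotype contrasts
    blue_error_variance: float = float("nan")


def step1_blues(trial: pd.DataFrame, environment: str,
                trait: str | None = None) -> Step1Result:
    """Per-environment BLUEs: genotype fixed, replication and block random.

    ``trial`` is long-format plot data with columns genotype, environment,
    rep, block, value (and optionally trait).  Requires >= 2 replications.
    """
    d = trial[trial["environment"] == environment]
    if trait is not None:
        d = d[d["trait"] == trait]
    if d.empty:
        raise ValueError(f"no data for environment {environment!r}")
    if d["rep"].nunique() < 2:
        raise ValueError(f"environment {environment!r} has < 2 replications")

    genos = np.sort(d["genotype"].unique())
    gidx = pd.Index(genos).get_indexer(d["genotype"])
    X = np.zeros((len(d), len(genos)))
    X[np.arange(len(d)), gidx] = 1.0
    vc = {"rep": d["rep"].astype(str).to_numpy()}
    block_labels = d["rep"].astype(str) + ":" + d["block"].astype(str)
    if block_labels.nunique() > d["rep"].nunique():
        vc["block"] = block_labels.to_numpy()

    res = VarianceComponentsModel(d["value"].to_numpy(), X, vc).fit()
    blues = pd.Series(res.fe_params, index=genos, name=environment)
    C = res.cov_fe_params
    g = len(genos)
    Cc = C - C.mean(axis=0, keepdims=True) - C.mean(axis=1, keepdims=True) \
        + C.mean()
    return Step1Result(environment=environment, blues=blues,
                       sigma2_e=res.vcomp["residual"], vcomp=dict(res.vcomp),
                       blue_error_variance=float(np.trace(Cc) / (g - 1)))


def step1_genotype_random(trial: pd.DataFrame, environment: str,
                          trait: str | None = None) -> tuple[float, float]:
    """Within-environment fit with genotype random, for repeatability:
    returns (sigma2_g, sigma2_e) of that environment."""
    d = trial[trial["environment"] == environment]
    if trait is not None:
        d = d[d["trait"] == trait]
    vc = {"genotype": d["genotype"].to_numpy(),
          "rep": d["rep"].astype(str).to_numpy()}
    block_labels = d["rep"].astype(str) + ":" + d["block"].astype(str)
    if block_labels.nunique() > d["rep"].nunique():
        vc["block"] = block_labels.to_numpy()
    res = VarianceComponentsModel(d["value"].to_numpy(), None, vc).fit()
    return res.vcomp["genotype"], res.vcomp["residual"]


# ----------------------------------------------------------------------
# step 2: across-environment analysis of the BLUE table

def step2_fit(
    blues: pd.DataFrame,
    genotype_role: str = "fixed",
    error_variances: pd.Series | None = None,
    n_rep: int | None = None,
    blue_error_variances: pd.Series | None = None,
):
    """Across-environment analysis of the per-environment BLUE table.

    ``blues``: genotypes x environments.  With ``genotype_role="fixed"``
    returns the across-environment BLUEs (Series).  With ``"random"``
    returns :class:`VarianceComponents`; the cell-level residual is split
    into sigma2_GE and effective error using ``error_variances`` (the
    step-1 per-environment residuals) and ``n_rep``.  When the exact
    per-environment BLUE sampling variances from step 1 are supplied
    (``blue_error_variances``) they are subtracted instead of
    sigma2_e/n_rep, removing the small upward bias in sigma2_GE caused by
    block/replication shrinkage leaking into the BLUEs.  Without any error
    information the BLUEs are treated as error-free and the whole residual
    is attributed to G x E.
    """
    if blues.shape[1] < 2:
        raise ValueError("need >= 2 environments; "
                         "G x E is inestimable from a single environment")
    complete = not blues.isna().to_numpy().any()

    if genotype_role == "fixed":
        if complete:
            return blues.mean(axis=1)
        long = blues.stack().rename("value").reset_index()
        long.columns = ["genotype", "environment", "value"]
        genos = np.sort(long["genotype"].unique())
        gidx = pd.Index(genos).get_indexer(long["genotype"])
        X = np.zeros((len(long), len(genos)))
        X[np.arange(len(long)), gidx] = 1.0
        res = VarianceComponentsModel(
            long["value"].to_numpy(), X,
            {"environment": long["environment"].to_numpy()}).fit()
        return pd.Series(res.fe_params, index=genos)

    if genotype_role != "random":
        raise ValueError("genotype_role must be 'fixed' or 'random'")

    n_env = blues.shape[1]
    if complete:
        comps = twoway_anova_components(blues.to_numpy())
        sigma2_env = comps["environment"]
        sigma2_g = comps["genotype"]
        resid = comps["residual"]
    else:
        long = blues.stack().rename("value").reset_index()
        long.columns = ["genotype", "environment", "value"]
        res = VarianceComponentsModel(
            long["value"].to_numpy(), None,
            {"genotype": long["genotype"].to_numpy(),
             "environment": long["environment"].to_numpy()}).fit()
        sigma2_g = res.vcomp["genotype"]
        sigma2_env = res.vcomp["environment"]
        resid = res.vcomp["residual"]

    if error_variances is not None:
        if n_rep is None:
            raise ValueError("n_rep required to split the step-2 residual")
        sigma2_e = float(np.mean([error_variances[e] for e in blues.columns]))
        if blue_error_variances is not None:
            carried = float(np.mean([blue_error_variances[e]
                                     for e in blues.columns]))
        else:
            carried = sigma2_e / n_rep
        sigma2_ge = max(resid - carried, 0.0)
    else:
        sigma2_e = 0.0
        sigma2_ge = resid
        n_rep = n_rep or 1
    return VarianceComponents(
        sigma2_g=sigma2_g, sigma2_ge=sigma2_ge, sigma2_e=sigma2_e,
        n_env=n_env, n_rep=n_rep, sigma2_env=sigma2_env)


# ----------------------------------------------------------------------
# full two-step pipeline for one trait

@dataclass
class PhenoAnalysis:
    trait: str
    blues_by_env: pd.DataFrame          # genotypes x environments
    blues_across: pd.Series             # across-environment BLUEs
    error_variances: pd.Series          # per-environment effective error
    vc: VarianceComponents
    h2: float
    repeatabilities: pd.Series | None = None


def analyze_trial(trial: pd.DataFrame, trait: str | None = None,
                  environments: list[str] | None = None,
                  compute_repeatability: bool = False) -> PhenoAnalysis:
    """Run the full two-step analysis for one trait of a trial table."""
    d = trial if trait is None else trial[trial["trait"] == trait]
    if trait is None:
        trait = str(d["trait"].iloc[0])
    envs = environments or sorted(d["environment"].unique())
    n_rep = int(d["rep"].nunique())

    step1 = {e: step1_blues(d, e) for e in envs}
    blues_by_env = pd.DataFrame({e: step1[e].blues for e in envs})
    err = pd.Series({e: step1[e].sigma2_e for e in envs}, name="sigma2_e")
    blue_err = pd.Series({e: step1[e].blue_error_variance for e in envs},
                         name="blue_error_variance")

    blues_across = step2_fit(blues_by_env, "fixed")
    vc = step2_fit(blues_by_env, "random", error_variances=err, n_rep=n_rep,
                   blue_error_variances=blue_err)
    vc.per_env = pd.DataFrame({"sigma2_e": err,
                               "blue_error_variance": blue_err})

    reps = None
    if compute_repeatability:
        vals = {}
        for e in envs:
            s2g, s2e = step1_genotype_random(d, e)
            vals[e] = repeatability(s2g, s2e, n_rep)
        reps = pd.Series(vals, name="repeatability")

    return PhenoAnalysis(
        trait=trait, blues_by_env=blues_by_env, blues_across=blues_across,
        error_variances=err, vc=vc, h2=heritability(vc),
        repeatabilities=reps)
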