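"""End-to-end orchestration: simulate -> qc -> blue -> varcomp -> cv.

A single YAML configuration drives the whole study; every stage derives its
seed from the root seed by a fixed offset, so a rerun with the same config
produces bit-identical result tables.  Each run writes a manifest recording
the config hash, seeds, stage outputs and timestamps.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd
import yaml

from . import io as rio
from .simulate import (TraitArchitecture, simulate_parents,
                       simulate_f3_population, simulate_trial, with_missing,
                       DEFAULT_ENVIRONMENTS_9)
from .qc import MarkerSet, filter_markers, impute_missing
from .pheno import analyze_trial, ge_ratio
from .cv import (run_cv_population, run_cv_env, run_cv_location_year,
                 PopulationData)

# fixed per-stage seed offsets from the root seed (all results < 2**31)
STAGE_SEEDS = {"parents": 11, "pop_a": 23, "pop_b": 37, "missing": 41,
               "trial": 53, "impute": 67, "cv": 101}

_ALLOWED_TOP = {"seed", "out_dir", "populations", "markers", "traits", "qc", "cv"}


def _stage_seed(root: int, stage: str, extra: int = 0) -> int:
    return (int(root) * 1009 + STAGE_SEEDS[stage] + 97 * extra) % (2 ** 31 - 1)


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        cfg = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    unknown = set(cfg) - _ALLOWED_TOP
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("seed", "traits"):
        if key not in cfg:
            raise ValueError(f"missing required config key: {key!r}")
    return cfg


def _architecture(name: str, params: dict) -> tuple[TraitArchitecture, list]:
    params = dict(params)
    envs = params.pop("environments", 9)
    if isinstance(envs, int):
        envs = list(DEFAULT_ENVIRONMENTS_9[:envs])
    else:
        envs = [(str(l), int(y)) for l, y in envs]
    arch = TraitArchitecture(trait=name, n_env=len(envs), **params)
    return arch, envs


def run_pipeline(config, out_dir=None) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    cfg = load_config(config)
    root = int(cfg["seed"])
    out = Path(out_dir or cfg.get("out_dir", "ryegs_run"))
    out.mkdir(parents=True, exist_ok=True)
    cfg_text = yaml.safe_dump(cfg, sort_keys=True)
    manifest = {
        "config_hash": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": root,
        "stages": [],
        "outputs": {},
    }

    def record(stage, outputs, t0, error=None):
        manifest["stages"].append({
            "stage": stage,
            "outputs": [str(p) for p in outputs],
            "seconds": round(time.time() - t0, 3),
            "status": "failed" if error else "ok",
            **({"error": error} if error else {}),
        })
        for p in outputs:
            manifest["outputs"][Path(p).name] = str(p)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    pop_cfg = cfg.get("populations", {})
    mk_cfg = cfg.get("markers", {})
    qc_cfg = cfg.get("qc", {})
    cv_cfg = cfg.get("cv", {})

    # ---- simulate ------------------------------------------------------
    t0 = time.time()
    try:
        parents, gmap = simulate_parents(
            n_markers_per_chrom=mk_cfg.get("n_per_chrom", 150),
            map_length_cM=mk_cfg.get("map_length_cM", 120.0),
            seed=_stage_seed(root, "parents"),
            seg_frac_a=mk_cfg.get("seg_frac_a", 0.376),
            seg_frac_b=mk_cfg.get("seg_frac_b", 0.557))
        n_lines = pop_cfg.get("n_lines", 220)
        pop_a = simulate_f3_population(parents, ("P1", "P2"), n_lines,
                                       _stage_seed(root, "pop_a"), "A")
        pop_b = simulate_f3_population(parents, ("P1", "P3"), n_lines,
                                       _stage_seed(root, "pop_b"), "B")
        geno = pd.concat([pop_a.genotypes, pop_b.genotypes]).astype(float)
        rate = mk_cfg.get("missing_rate", 0.0)
        if rate:
            geno = with_missing(geno, rate, _stage_seed(root, "missing"))
        pops = pd.Series(["A"] * pop_a.n_lines + ["B"] * pop_b.n_lines,
                         index=geno.index)
        rio.write_genotypes(geno, out / "genotypes.tsv")
        rio.write_map(gmap, out / "map.tsv")
        rio.write_populations(pops, out / "populations.tsv")

        sims = {}
        for i, (name, params) in enumerate(cfg["traits"].items()):
            arch, envs = _architecture(name, params)
            sim = simulate_trial([pop_a, pop_b], arch, envs,
                                 seed=_stage_seed(root, "trial", i))
            sims[name] = sim
            rio.write_trial(sim.trial, out / f"trial_{name}.csv")
            sim.genetic_values.rename("genetic_value").to_csv(
                out / f"true_values_{name}.csv", index_label="line")
        record("simulate", [out / "genotypes.tsv", out / "map.tsv",
                            out / "populations.tsv"]
               + [out / f"trial_{n}.csv" for n in sims], t0)
    except Exception as exc:  # partial manifest with failure record
        record("simulate", [], t0, error=str(exc))
        raise

    # ---- qc ------------------------------------------------------------
    t0 = time.time()
    try:
        ms = MarkerSet(geno, gmap, pops)
        filtered, report = filter_markers(
            ms, max_missing=qc_cfg.get("max_missing", 0.05),
            maf_bounds=tuple(qc_cfg.get("maf", (0.05, 0.95))))
        imputed = impute_missing(filtered, _stage_seed(root, "impute"))
        report.to_csv(out / "qc_report.csv", index=False)
        rio.write_genotypes(imputed.genotypes, out / "genotypes_qc.tsv")
        record("qc", [out / "qc_report.csv", out / "genotypes_qc.tsv"], t0)
    except Exception as exc:
        record("qc", [], t0, error=str(exc))
        raise

    # ---- blue + varcomp ------------------------------------------------
    t0 = time.time()
    analyses = {}
    try:
        from .pheno import step2_fit, heritability

        vc_rows = []
        for name, sim in sims.items():
            ana = analyze_trial(sim.trial, trait=name)
            analyses[name] = ana
            ana.blues_by_env.to_csv(out / f"blues_by_env_{name}.csv",
                                    index_label="line")
            ana.blues_across.rename("blue").to_csv(
                out / f"blues_across_{name}.csv", index_label="line")
            # variance components per population (as reported for the
            # emulated experiment) and for the combined set, whose sigma2_G
            # additionally contains the between-population divergence
            subsets = {"combined": ana.blues_by_env.index}
            for lab in sorted(pops.unique()):
                subsets[lab] = ana.blues_by_env.index.intersection(
                    pops.index[pops == lab])
            for label, lines in subsets.items():
                vc = (ana.vc if label == "combined" else step2_fit(
                    ana.blues_by_env.loc[lines], "random",
                    error_variances=ana.error_variances,
                    n_rep=ana.vc.n_rep,
                    blue_error_variances=ana.vc.per_env["blue_error_variance"]))
                vc_rows.append({
                    "trait": name,
                    "population": label,
                    "sigma2_G": vc.sigma2_g,
                    "sigma2_GxE": vc.sigma2_ge,
                    "sigma2_e": vc.sigma2_e,
                    "n_env": vc.n_env,
                    "n_rep": vc.n_rep,
                    "h2": heritability(vc),
                    "ge_ratio": ge_ratio(vc),
                })
        pd.DataFrame(vc_rows).to_csv(out / "variance_components.csv", index=False)
        record("blue+varcomp", [out / "variance_components.csv"]
               + [out / f"blues_across_{n}.csv" for n in sims], t0)
    except Exception as exc:
        record("blue+varcomp", [], t0, error=str(exc))
        raise

    # ---- cv ------------------------------------------------------------
    t0 = time.time()
    try:
        resamples = cv_cfg.get("resamples", 200)
        predictor = cv_cfg.get("predictor", "rrblup")
        schemes = cv_cfg.get("schemes", ["within-within-same"])
        env_counts = cv_cfg.get("env_counts", [])
        ly_modes = cv_cfg.get("location_year_modes", [])
        exclude = tuple(cv_cfg.get("exclude_envs", ("HOH10",)))

        rows, summaries = [], []
        for i, (name, sim) in enumerate(sims.items()):
            ana = analyses[name]
            panel = sim.marker_panel(imputed.genotypes)
            data = {}
            for lab in ("A", "B"):
                lines = pops.index[pops == lab]
                lines = lines.intersection(ana.blues_by_env.index)
                data[lab] = PopulationData(
                    label=lab,
                    blues_by_env=ana.blues_by_env.loc[lines],
                    error_variances=ana.error_variances,
                    n_rep=ana.vc.n_rep,
                    markers=panel.loc[lines],
                    gmap=gmap,
                    env_meta=(sim.trial[["environment", "location", "year"]]
                              .drop_duplicates().set_index("environment")),
                    true_values=sim.genetic_values.loc[lines])
            seed_cv = _stage_seed(root, "cv", i)
            results = []
            for scheme in schemes:
                results.append(run_cv_population(
                    scheme, data["A"], data["B"], predictor=predictor,
                    n_resamples=resamples, seed=seed_cv))
            for k in env_counts:
                results.append(run_cv_env(data["A"], k, predictor=predictor,
                                          n_resamples=resamples, seed=seed_cv))
            for mode in ly_modes:
                results.append(run_cv_location_year(
                    data["A"], mode, predictor=predictor,
                    n_resamples=resamples, seed=seed_cv,
                    exclude_envs=exclude))
            for res in results:
                df = res.to_frame()
                df.insert(0, "trait", name)
                rows.append(df)
                summaries.append({"trait": name, **res.summary()})
        pd.concat(rows, ignore_index=True).to_csv(
            out / "cv_replicates.csv", index=False)
        with open(out / "cv_summary.json", "w") as fh:
            json.dump(summaries, fh, indent=2)
        record("cv", [out / "cv_replicates.csv", out / "cv_summary.json"], t0)
    except Exception as exc:
        record("cv", [], t0, error=str(exc))
        raise

    return manifest
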