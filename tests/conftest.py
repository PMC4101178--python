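"""Shared fixtures: one simulated half-sib study reused across the suite.

Everything is generated at test time from fixed seeds; no data files.
"""

from __future__ import annotations

import pandas as pd
import pytest

import ryegs as rg
from ryegs.qc import MarkerSet, filter_markers


@pytest.fixture(scope="session")
def world():
    """Founders, map and the two 220-line half-sib populations."""
    parents, gmap = rg.simulate_parents(seed=11)
    pop_a = rg.simulate_f3_population(parents, ("P1", "P2"), 220, seed=12,
                                      label="A")
    pop_b = rg.simulate_f3_population(parents, ("P1", "P3"), 220, seed=13,
                                      label="B")
    return {"parents": parents, "gmap": gmap, "pop_a": pop_a, "pop_b": pop_b}


def _study(world, trait: str, seed: int) -> dict:
    """Simulate a trial for both populations, run the two-step analysis and
    assemble CV containers on the QC'd non-causal marker panel."""
    arch = rg.REFERENCE_ARCHITECTURES[trait]
    sim = rg.simulate_trial([world["pop_a"], world["pop_b"]], arch, seed=seed)
    ana = rg.analyze_trial(sim.trial)
    geno = pd.concat([world["pop_a"].genotypes,
                      world["pop_b"].genotypes]).astype(float)
    pops = pd.Series(["A"] * 220 + ["B"] * 220, index=geno.index)
    panel = sim.marker_panel(geno)
    filt, _ = filter_markers(MarkerSet(panel, world["gmap"], pops))
    env_meta = (sim.trial[["environment", "location", "year"]]
                .drop_duplicates().set_index("environment"))
    data = {}
    for lab in ("A", "B"):
        lines = pops.index[pops == lab]
        data[lab] = rg.PopulationData(
            label=lab, blues_by_env=ana.blues_by_env.loc[lines],
            error_variances=ana.error_variances, n_rep=2,
            markers=filt.genotypes.loc[lines], gmap=world["gmap"],
            env_meta=env_meta, true_values=sim.genetic_values.loc[lines])
    return {"sim": sim, "ana": ana, "data": data}


@pytest.fixture(scope="session")
def yield_study(world):
    """Grain-yield-calibrated study (high G x E ratio ~ 0.72)."""
    return _study(world, "grain_yield", seed=14)


@pytest.fixture(scope="session")
def height_study(world):
    """Plant-height-calibrated study (low G x E ratio ~ 0.36)."""
    return _study(world, "plant_height", seed=15)
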