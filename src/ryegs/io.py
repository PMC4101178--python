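"""Plain-text file formats used by the pipeline stages.

Genotypes: TSV, rows = lines, columns = marker ids, values 0/1/2 or NA.
Genetic map: TSV with marker_id, chromosome, position_cM.
Trial data: CSV long format (genotype, location, year, rep, block, trait,
value).  BLUE and variance-component tables: CSV.
"""

from __future__ import annotations


import pandas as pd

from .simulate import GeneticMap, env_key
from .qc import MarkerSet


def write_genotypes(genotypes: pd.DataFrame, path) -> None:
    genotypes.to_csv(path, sep="\t", na_rep="NA", index_label="line")


def read_genotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="line", na_values="NA")


def write_map(gmap: GeneticMap, path) -> None:
    gmap.table[["marker_id", "chromosome", "position_cM"]].to_csv(
        path, sep="\t", index=False)


def read_map(path) -> GeneticMap:
    return GeneticMap(pd.read_csv(path, sep="\t"))


def write_trial(trial: pd.DataFrame, path) -> None:
    cols = ["genotype", "location", "year", "rep", "block", "trait", "value"]
    trial[cols].to_csv(path, index=False)


def read_trial(path) -> pd.DataFrame:
    trial = pd.read_csv(path)
    trial["environment"] = [env_key(l, y)
                            for l, y in zip(trial["location"], trial["year"])]
    return trial


def write_populations(populations: pd.Series, path) -> None:
    populations.rename("population").to_csv(path, sep="\t", index_label="line")


def read_populations(path) -> pd.Series:
    return pd.read_csv(path, sep="\t", index_col="line")["population"]


def read_marker_set(geno_path, map_path, pop_path) -> MarkerSet:
    return MarkerSet(read_genotypes(geno_path), read_map(map_path),
                     read_populations(pop_path))
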