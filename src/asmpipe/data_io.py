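"""Domain types, delimited-text I/O, validation and configuration.

The pipeline operates on three plain CSV tables:

``abundance.csv``
    Wide matrix: one row per transect, one column per species, integer
    counts of individuals observed along the transect.
``traits.csv``
    One row per species (``species_id`` column), one column per
    continuous trait (e.g. standard length, delta15N, delta13C, gut
    length, pharyngeal-jaw shape PC1, body shape PC1).
``environment.csv``
    One row per transect with ``transect_id``, ``cluster_id`` (sampling
    clusters of 3 transects; the random-effect grouping), ``depth`` in
    metres, ``sand`` (fraction of sand cover in [0, 1]; percentages are
    auto-detected and rescaled), and ``complexity`` (substrate contour
    length / linear length, >= 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("asmpipe")

__all__ = [
    "TraitTable",
    "Transect",
    "SpeciesPool",
    "Dataset",
    "read_dataset",
    "write_dataset",
    "prune_correlated_traits",
    "occupancy_frequencies",
    "load_config",
    "DEFAULT_CONFIG",
]


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "standardize": True,
    "prune": {"r_threshold": 0.7},
    "fd": {"m": 3},
    "abc": {
        "n_particles": 1000,
        "stop_acceptance_rate": 1.0 / 20000.0,
        "shrink_quantile": 0.5,
        "n_replicates": 3,
        "n_calibration": 1000,
    },
    "nulls": {"n_rep": 100},
    "stats": {"alpha": 0.05},
    "dissimilarity": {"n_permutations": 100000},
}


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config file, merged over :data:`DEFAULT_CONFIG`."""
    cfg = _deep_copy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(cfg, user)
    return cfg


def _deep_copy(d: dict) -> dict:
    return {k: _deep_copy(v) if isinstance(v, dict) else v for k, v in d.items()}


def _deep_update(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class TraitTable:
    """Species x trait matrix of continuous trait values.

    ``values`` is indexed by species id with one float column per trait.
    ``standardized`` records whether columns have been z-scored (mean 0,
    sample sd 1) across the species pool; all multivariate analyses
    require standardized traits so that traits are weighted equally.
    """

    values: pd.DataFrame
    standardized: bool = False
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            bad = self.values.index[self.values.isna().any(axis=1)].tolist()
            raise ValueError(f"missing trait values for species: {bad}")
        self.values = self.values.sort_index()

    @property
    def species(self) -> pd.Index:
        return self.values.index

    @property
    def trait_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def standardize(self) -> "TraitTable":
        """z-score each trait column (sample sd, ddof=1)."""
        sd = self.values.std(ddof=1)
        zero = sd.index[sd == 0].tolist()
        if zero:
            raise ValueError(
                f"cannot standardize constant trait column(s): {zero} (sd = 0)"
            )
        z = (self.values - self.values.mean()) / sd
        return TraitTable(z, standardized=True, dropped=list(self.dropped))

    def subset(self, species_ids) -> "TraitTable":
        return TraitTable(
            self.values.loc[sorted(species_ids)],
            standardized=self.standardized,
            dropped=list(self.dropped),
        )


@dataclass
class Transect:
    """A single surveyed local community with its environment.

    ``abundances`` maps species id to a positive integer count (species
    with zero counts are not stored).
    """

    transect_id: str
    cluster_id: str
    abundances: pd.Series
    depth: float
    sand: float
    complexity: float

    def __post_init__(self) -> None:
        self.abundances = self.abundances[self.abundances > 0].sort_index()
        if len(self.abundances) < 1:
            raise ValueError(f"transect {self.transect_id} has no species")
        if not 0.0 <= self.sand <= 1.0:
            raise ValueError(
                f"transect {self.transect_id}: sand fraction {self.sand} not in [0, 1]"
            )
        if self.complexity < 1.0:
            raise ValueError(
                f"transect {self.transect_id}: complexity {self.complexity} < 1"
            )

    @property
    def species(self) -> list[str]:
        return list(self.abundances.index)

    @property
    def richness(self) -> int:
        return int((self.abundances > 0).sum())

    @property
    def total_abundance(self) -> int:
        return int(self.abundances.sum())


@dataclass
class SpeciesPool:
    """The regional candidate set: all species observed anywhere.

    ``occupancy`` counts, per species, the number of transects where the
    species occurs (its frequency across local communities, used as the
    species-pool abundance proxy for the stochastic removal kernel).
    """

    traits: TraitTable
    occupancy: pd.Series

    def __post_init__(self) -> None:
        self.occupancy = self.occupancy.sort_index()
        if not self.occupancy.index.equals(self.traits.species):
            raise ValueError("pool occupancy and trait table index mismatch")
        if (self.occupancy < 1).any():
            bad = self.occupancy.index[self.occupancy < 1].tolist()
            raise ValueError(f"pool species never observed: {bad}")

    @property
    def species(self) -> pd.Index:
        return self.traits.species

    @property
    def size(self) -> int:
        return len(self.occupancy)

    @property
    def matrix(self) -> np.ndarray:
        return self.traits.matrix

    @property
    def occupancy_array(self) -> np.ndarray:
        return self.occupancy.to_numpy(dtype=float)


@dataclass
class Dataset:
    """A full study: trait table, transects and the derived species pool."""

    traits: TraitTable
    transects: list[Transect]
    pool: SpeciesPool

    @property
    def transect_ids(self) -> list[str]:
        return [t.transect_id for t in self.transects]

    def transect(self, transect_id: str) -> Transect:
        for t in self.transects:
            if t.transect_id == transect_id:
                return t
        raise KeyError(transect_id)

    def abundance_matrix(self) -> pd.DataFrame:
        """Wide transect x species count matrix (zeros for absences)."""
        mat = pd.DataFrame(
            0,
            index=pd.Index(self.transect_ids, name="transect_id"),
            columns=self.pool.species,
            dtype=int,
        )
        for t in self.transects:
            mat.loc[t.transect_id, t.abundances.index] = t.abundances.values
        return mat

    def environment(self) -> pd.DataFrame:
        rows = {
            t.transect_id: {
                "cluster_id": t.cluster_id,
                "depth": t.depth,
                "sand": t.sand,
                "complexity": t.complexity,
            }
            for t in self.transects
        }
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "transect_id"
        return df

    def community_indices(self, transect_id: str) -> np.ndarray:
        """Positional indices (into the sorted pool) of a transect's species."""
        idx = self.pool.species.get_indexer(self.transect(transect_id).species)
        return np.sort(idx)

    @classmethod
    def from_tables(
        cls,
        abundance: pd.DataFrame,
        traits: pd.DataFrame,
        environment: pd.DataFrame,
        standardize: bool = True,
    ) -> "Dataset":
        """Assemble and validate a Dataset from the three raw tables."""
        _check_numeric(abundance, "abundance")
        _check_numeric(traits, "traits")
        _check_numeric(environment.drop(columns=["cluster_id"]), "environment")

        observed = abundance.columns[(abundance > 0).any(axis=0)]
        missing = sorted(set(observed) - set(traits.index))
        if missing:
            raise ValueError(
                f"species observed in abundance table but absent from trait table: {missing}"
            )
        extra_env = sorted(set(abundance.index) ^ set(environment.index))
        if extra_env:
            raise ValueError(
                f"transect ids differ between abundance and environment tables: {extra_env}"
            )

        env = environment.copy()
        if (env["sand"] > 1).any():
            log.info("sand column looks like percentages; rescaling to fractions")
            env["sand"] = env["sand"] / 100.0

        trait_table = TraitTable(traits.loc[sorted(observed)].astype(float))
        if standardize:
            trait_table = trait_table.standardize()

        transects = []
        for tid in abundance.index:
            row = abundance.loc[tid]
            e = env.loc[tid]
            transects.append(
                Transect(
                    transect_id=str(tid),
                    cluster_id=str(e["cluster_id"]),
                    abundances=row[row > 0].astype(int),
                    depth=float(e["depth"]),
                    sand=float(e["sand"]),
                    complexity=float(e["complexity"]),
                )
            )

        occupancy = (abundance.loc[:, sorted(observed)] > 0).sum(axis=0)
        pool = SpeciesPool(traits=trait_table, occupancy=occupancy)
        return cls(traits=trait_table, transects=transects, pool=pool)


def _check_numeric(df: pd.DataFrame, name: str) -> None:
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"non-numeric value in {name} table, column {col!r}, row(s) {list(bad)}"
            )
        if df[col].isna().any():
            raise ValueError(
                f"missing value in {name} table, column {col!r}, "
                f"row(s) {list(df.index[df[col].isna()])}"
            )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_dataset(
    abundance_path: str | Path,
    trait_path: str | Path,
    environment_path: str | Path,
    config: dict | None = None,
) -> Dataset:
    """Read the three CSV tables and return a validated :class:`Dataset`."""
    config = config or DEFAULT_CONFIG
    abundance = pd.read_csv(abundance_path, index_col=0)
    traits = pd.read_csv(trait_path, index_col=0)
    environment = pd.read_csv(environment_path, index_col=0)
    use = (config.get("traits") or {}).get("use")
    if use:
        traits = traits[list(use)]
    return Dataset.from_tables(
        abundance, traits, environment, standardize=config.get("standardize", True)
    )


def write_dataset(dataset: Dataset, outdir: str | Path) -> dict[str, Path]:
    """Write ``abundance.csv``, ``traits.csv`` and ``environment.csv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": outdir / "abundance.csv",
        "traits": outdir / "traits.csv",
        "environment": outdir / "environment.csv",
    }
    dataset.abundance_matrix().to_csv(paths["abundance"])
    tr = dataset.traits.values.copy()
    tr.index.name = "species_id"
    tr.to_csv(paths["traits"])
    dataset.environment().to_csv(paths["environment"])
    return paths


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def prune_correlated_traits(traits: TraitTable, r_threshold: float = 0.7) -> TraitTable:
    """Greedily drop traits until all pairwise |Pearson r| <= threshold.

    At each step the trait with the largest mean absolute correlation to
    the remaining traits is removed. Dropped names are recorded on the
    returned table. Guards against collinear trait sets that would give
    some niche axes double weight in the multivariate analyses.
    """
    if not 0 < r_threshold < 1:
        raise ValueError("r_threshold must be in (0, 1)")
    df = traits.values.copy()
    if df.shape[1] < 2:
        log.warning("fewer than 2 traits; nothing to prune")
        return traits
    dropped: list[str] = []
    while df.shape[1] >= 2:
        corr = df.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        if corr.values.max() <= r_threshold:
            break
        mean_abs = corr.mean(axis=0)
        worst = mean_abs.sort_values(ascending=False, kind="stable").index[0]
        dropped.append(str(worst))
        log.info("pruning trait %r (mean |r| = %.3f)", worst, mean_abs[worst])
        df = df.drop(columns=[worst])
    if df.shape[1] < 2:
        log.warning("pruning left fewer than 2 traits")
    return TraitTable(
        df, standardized=traits.standardized, dropped=traits.dropped + dropped
    )


def occupancy_frequencies(dataset: Dataset) -> pd.Series:
    """Number of transects in which each pool species occurs (f_i >= 1)."""
    return dataset.pool.occupancy.copy()
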