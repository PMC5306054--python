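"""Synthetic datasets with the structure the analyses assume.

The generator emulates a littoral survey of a rocky/sandy shoreline:
a regional pool of ~49 species with six continuous traits, 36 transects
grouped in sampling clusters of 3, environmental gradients (depth with a
cluster-level component, sand cover, substrate complexity), and local
communities assembled from the pool through the stepwise forward model
under a *known* mix of stochastic / filtering / limiting-similarity
steps. Habitat filtering is linked to the environment through a linear
map from (standardized) environment to the trait optimum, so that
niche-driven trait-environment relationships of configurable strength
arise by construction.

Abundance counts are then assigned to retained species from a geometric
rank-abundance profile, scaled so that sandier (harsher) transects hold
fewer individuals; abundances only matter for occupancy and the
dissimilarity analyses — assembly itself is presence-based.

Because real occupancies only exist once communities have been
generated, the stochastic-removal kernel uses latent per-species
"commonness" weights (lognormal) in place of occupancy during
generation; realized occupancy is recomputed from the generated data,
and the latent weights are recorded in the ground-truth file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_io import Dataset, TraitTable, Transect, SpeciesPool, write_dataset
from .stepcam_forward import Assembler, StepComposition

log = logging.getLogger("asmpipe")

__all__ = [
    "SynthConfig",
    "generate_pool",
    "generate_environment",
    "generate_transect_community",
    "generate_dataset",
    "write_truth",
    "read_truth",
]


@dataclass
class SynthConfig:
    """Generator settings; defaults mirror the survey the pipeline targets."""

    n_species_pool: int = 49
    n_traits: int = 6
    n_transects: int = 36
    n_clusters: int = 12
    richness_range: tuple[int, int] = (15, 30)  # mean ~22 species per transect
    trait_correlation: float = 0.0
    # percent (stochastic, filtering, limiting); a single tuple applied to
    # every transect, or a list of one tuple per transect
    true_mix: tuple[float, float, float] | list = (70.0, 10.0, 20.0)
    # linear map from z-scored environment to the optimum of trait 0
    depth_slope: float = 1.0
    sand_slope: float = 0.0
    complexity_slope: float = 0.0
    # environment generation
    depth_mean: float = 7.0
    depth_cluster_sd: float = 3.0
    depth_within_sd: float = 0.5
    sand_range: tuple[float, float] = (0.05, 0.95)
    complexity_shape: float = 2.0
    complexity_scale: float = 0.25
    # abundance model: expected individuals = abundance_base * (1 - sand),
    # i.e. ~137 per transect at the default mid-range sand cover
    abundance_base: float = 274.0
    geometric_param: float = 0.75
    commonness_sd: float = 1.0
    n_passes: int = 2
    order_policy: str = "shuffled"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transects % self.n_clusters:
            raise ValueError("n_transects must be divisible by n_clusters")
        if self.richness_range[1] >= self.n_species_pool:
            raise ValueError(
                "richness_range upper bound must be below the pool size "
                f"({self.richness_range[1]} >= {self.n_species_pool})"
            )
        mixes = self.true_mix if isinstance(self.true_mix, list) else [self.true_mix]
        for mx in mixes:
            arr = np.asarray(mx, dtype=float)
            if arr.min() < 0 or not np.isclose(arr.sum(), 100.0):
                raise ValueError(f"process mix must be nonnegative and sum to 100: {mx}")

    def mix_for(self, transect_index: int) -> tuple[float, float, float]:
        if isinstance(self.true_mix, list):
            return tuple(self.true_mix[transect_index])
        return tuple(self.true_mix)


def _species_ids(n: int) -> list[str]:
    return [f"sp{i:03d}" for i in range(1, n + 1)]


def generate_pool(config: SynthConfig, rng: np.random.Generator) -> TraitTable:
    """Species pool with multivariate-normal traits, standardized."""
    if config.n_species_pool < 2 or config.n_traits < 1:
        raise ValueError("need at least 2 species and 1 trait")
    k = config.n_traits
    corr = np.full((k, k), config.trait_correlation)
    np.fill_diagonal(corr, 1.0)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("trait correlation matrix is not positive definite") from exc
    raw = rng.standard_normal((config.n_species_pool, k)) @ chol.T
    df = pd.DataFrame(
        raw,
        index=pd.Index(_species_ids(config.n_species_pool), name="species_id"),
        columns=[f"trait{j + 1}" for j in range(k)],
    )
    return TraitTable(df).standardize()


def generate_environment(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Clustered environment table: depth, sand cover, complexity.

    Depth has a cluster-level random intercept plus within-cluster
    noise; sand and complexity are drawn independently per transect, so
    the three variables are mutually uncorrelated by construction.
    """
    per = config.n_transects // config.n_clusters
    cluster_ids = [f"c{i + 1:02d}" for i in range(config.n_clusters)]
    cluster_depth = config.depth_mean + config.depth_cluster_sd * rng.standard_normal(
        config.n_clusters
    )
    rows = []
    for t in range(config.n_transects):
        c = t // per
        depth = cluster_depth[c] + config.depth_within_sd * rng.standard_normal()
        rows.append(
            {
                "transect_id": f"t{t + 1:02d}",
                "cluster_id": cluster_ids[c],
                "depth": max(0.5, float(depth)),
                "sand": float(rng.uniform(*config.sand_range)),
                "complexity": 1.0
                + float(rng.gamma(config.complexity_shape, config.complexity_scale)),
            }
        )
    return pd.DataFrame(rows).set_index("transect_id")


def optimum_for(config: SynthConfig, env_z: np.ndarray, n_traits: int) -> np.ndarray:
    """Trait optimum implied by a (z-scored) environment row.

    The environment shifts the optimum of trait 0 linearly; remaining
    trait optima sit at the pool centre (0 after standardization).
    """
    opt = np.zeros(n_traits)
    slopes = np.array([config.depth_slope, config.sand_slope, config.complexity_slope])
    opt[0] = float(slopes @ env_z)
    return opt


def generate_transect_community(
    pool: TraitTable,
    commonness: np.ndarray,
    sand: float,
    true_mix,
    richness: int,
    optimum: np.ndarray,
    rng: np.random.Generator,
    config: SynthConfig | None = None,
) -> tuple[pd.Series, StepComposition]:
    """Assemble one community and draw its abundance counts.

    Returns (abundance series over retained species, the step
    composition actually used). ``commonness`` stands in for occupancy
    in the stochastic-removal kernel.
    """
    config = config or SynthConfig()
    n_pool = len(pool.species)
    if richness >= n_pool:
        raise ValueError("richness must be below pool size")
    comp = StepComposition.from_fractions(true_mix, n_pool - richness)
    asm = Assembler(pool.matrix, commonness, optimum=optimum)
    idx = asm.run(comp, rng, order_policy=config.order_policy)
    species = [pool.species[i] for i in idx]

    total = max(richness, int(round(config.abundance_base * (1.0 - sand))))
    ranks = rng.permutation(richness)
    w = config.geometric_param ** ranks
    w /= w.sum()
    counts = np.ones(richness, dtype=int)
    if total > richness:
        counts += rng.multinomial(total - richness, w)
    return pd.Series(counts, index=species).sort_index(), comp


def generate_dataset(
    config: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[Dataset, dict]:
    """Generate a full synthetic dataset plus its ground-truth record."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    pool = generate_pool(config, rng)
    env = generate_environment(config, rng)
    env_z = (env[["depth", "sand", "complexity"]] - env[["depth", "sand", "complexity"]].mean()) / env[
        ["depth", "sand", "complexity"]
    ].std(ddof=1)
    commonness = np.exp(config.commonness_sd * rng.standard_normal(config.n_species_pool))

    lo, hi = config.richness_range
    plan = []  # (transect_id, richness, composition, optimum)
    for t_idx, tid in enumerate(env.index):
        richness = int(rng.integers(lo, hi + 1))
        optimum = optimum_for(config, env_z.loc[tid].to_numpy(), config.n_traits)
        comp = StepComposition.from_fractions(
            config.mix_for(t_idx), config.n_species_pool - richness
        )
        plan.append((tid, richness, comp, optimum))

    # The downstream stochastic kernel uses occupancy across transects,
    # which only exists once communities exist; iterate assembly so the
    # generating kernel converges onto the realized occupancies (latent
    # commonness seeds the first pass).
    weights = commonness
    for _ in range(max(1, config.n_passes)):
        communities = {}
        removals = {}
        occ = np.zeros(config.n_species_pool)
        for tid, richness, comp, optimum in plan:
            asm = Assembler(pool.matrix, weights, optimum=optimum)
            idx = asm.run(comp, rng, order_policy=config.order_policy)
            communities[tid] = idx
            removals[tid] = asm.last_removals
            occ[idx] += 1
        weights = np.maximum(occ, 0.5)

    transects: list[Transect] = []
    truth_rows = []
    for tid, richness, comp, optimum in plan:
        erow = env.loc[tid]
        species = [pool.species[i] for i in communities[tid]]
        total = max(richness, int(round(config.abundance_base * (1.0 - erow["sand"]))))
        ranks = rng.permutation(richness)
        w = config.geometric_param ** ranks
        w /= w.sum()
        counts = np.ones(richness, dtype=int)
        if total > richness:
            counts += rng.multinomial(total - richness, w)
        transects.append(
            Transect(
                transect_id=tid,
                cluster_id=str(erow["cluster_id"]),
                abundances=pd.Series(counts, index=species).sort_index(),
                depth=float(erow["depth"]),
                sand=float(erow["sand"]),
                complexity=float(erow["complexity"]),
            )
        )
        truth_rows.append(
            {
                "transect_id": tid,
                "richness": richness,
                "n_random": comp.n_random,
                "n_filter": comp.n_filter,
                "n_limiting": comp.n_limiting,
                "optimum_trait1": float(optimum[0]),
                "removals": removals[tid],
            }
        )

    # realized dataset: drop pool species never observed in any transect
    observed = sorted(set().union(*[t.species for t in transects]))
    never = sorted(set(pool.species) - set(observed))
    if never:
        log.info("trimming %d species never observed in any transect", len(never))
    # effective (realized-pool) step composition per transect: the steps
    # whose victims survive trimming are the removals the fitted model,
    # whose pool is the union of observed species, has to explain
    observed_mask = np.isin(np.arange(config.n_species_pool),
                            [list(pool.species).index(s) for s in observed])
    for row in truth_rows:
        victims, types = row.pop("removals")
        eff = np.zeros(3, dtype=int)
        for v, st in zip(victims, types):
            if observed_mask[v]:
                eff[st] += 1
        row["n_random_effective"] = int(eff[0])
        row["n_filter_effective"] = int(eff[1])
        row["n_limiting_effective"] = int(eff[2])
    trait_table = pool.subset(observed)
    occupancy = pd.Series(
        {s: sum(s in t.abundances.index for t in transects) for s in observed}
    )
    dataset = Dataset(
        traits=trait_table,
        transects=transects,
        pool=SpeciesPool(traits=trait_table, occupancy=occupancy),
    )
    truth = {
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "commonness": {s: float(w) for s, w in zip(pool.species, commonness)},
        "trimmed_species": never,
        "transects": truth_rows,
    }
    return dataset, truth


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=False)


def read_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def simulate_to_dir(config: SynthConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate a dataset and write abundance/traits/environment/truth files."""
    outdir = Path(outdir)
    dataset, truth = generate_dataset(config)
    paths = write_dataset(dataset, outdir)
    truth_path = outdir / "truth.yaml"
    write_truth(truth, truth_path)
    paths["truth"] = truth_path
    return paths
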