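"""End-to-end orchestration with provenance capture.

``run_full_pipeline`` wires the stages together — (optionally) simulate
a dataset, compute per-transect summary statistics, fit the assembly
model to every transect, build the null ensembles, run the
trait-environment and dissimilarity analyses — and writes every product
as a plain text table plus a ``manifest.json`` with config hash, seeds
and per-file digests so a run can be audited and reproduced.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abc_smc import AbcConfig, fit_all
from .community_dissimilarity import (
    abundance_richness_regressions,
    bray_curtis_matrix,
    env_distance_matrix,
    mantel,
    slope_contrast,
)
from .data_io import Dataset, read_dataset
from .fd_metrics import SummaryEngine
from .null_ensembles import (
    ensemble_relative_abundance,
    simulate_bestfit_ensemble,
    simulate_stochastic_ensemble,
)
from .synthetic_data import SynthConfig, generate_dataset, write_truth
from .data_io import write_dataset
from .trait_env_stats import table1_pipeline

log = logging.getLogger("asmpipe")

__all__ = ["run_full_pipeline", "summary_stats_table"]


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def summary_stats_table(dataset: Dataset, m: int = 3) -> pd.DataFrame:
    """One row of (FRic, FEve, FDiv, CTM...) per transect."""
    engine = SummaryEngine(dataset.pool.matrix, m=m)
    rows = {}
    for tid in dataset.transect_ids:
        s = engine.stats(dataset.community_indices(tid))
        row = {"fric": s.fric, "feve": s.feve, "fdiv": s.fdiv}
        for name, val in zip(dataset.pool.traits.trait_names, s.ctm):
            row[f"ctm_{name}"] = val
        rows[tid] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "transect_id"
    return df


def _load_or_simulate(config: dict, outdir: Path) -> Dataset:
    if "simulate" in config:
        sim = dict(config["simulate"])
        sim.setdefault("seed", config.get("seed", 0))
        for key in ("richness_range", "sand_range", "true_mix"):
            if key in sim and isinstance(sim[key], list) and key != "true_mix":
                sim[key] = tuple(sim[key])
        if isinstance(sim.get("true_mix"), list) and sim["true_mix"] and not isinstance(
            sim["true_mix"][0], list
        ):
            sim["true_mix"] = tuple(sim["true_mix"])
        scfg = SynthConfig(**sim)
        dataset, truth = generate_dataset(scfg)
        write_dataset(dataset, outdir / "data")
        write_truth(truth, outdir / "data" / "truth.yaml")
        return dataset
    inputs = config["inputs"]
    return read_dataset(
        inputs["abundance"], inputs["traits"], inputs["environment"], config
    )


def run_full_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run every stage; returns the manifest (also written to disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    seed = int(config.get("seed", 0))
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": {},
        "stages": [],
    }

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _digest(path)}

    dataset = _load_or_simulate(config, outdir)
    manifest["stages"].append("data")

    m = config.get("fd", {}).get("m", 3)
    stats = summary_stats_table(dataset, m=m)
    stats.to_csv(outdir / "summary_stats.csv")
    record("summary_stats", outdir / "summary_stats.csv")
    manifest["stages"].append("stats")

    abc_cfg = AbcConfig(seed=seed, m=m, **config.get("abc", {}))
    fits_table, fits = fit_all(dataset, abc_cfg)
    fits_table.to_csv(outdir / "fits.csv")
    record("fits", outdir / "fits.csv")
    post_dir = outdir / "posteriors"
    post_dir.mkdir(exist_ok=True)
    for tid, reps in fits.items():
        frames = []
        for r, f in enumerate(reps):
            df = pd.DataFrame(f.posterior, columns=["n_random", "n_filter", "n_limiting"])
            df.insert(0, "replicate", r)
            df["distance"] = f.distances
            frames.append(df)
        pd.concat(frames).to_csv(post_dir / f"posterior_{tid}.csv", index=False)
    manifest["stages"].append("fit")

    n_rep = config.get("nulls", {}).get("n_rep", 100)
    rng_nulls = np.random.default_rng([seed, 101])
    stoch = simulate_stochastic_ensemble(dataset, n_rep=n_rep, rng=rng_nulls)
    best = simulate_bestfit_ensemble(dataset, fits, n_rep=n_rep, rng=rng_nulls)
    ensemble_relative_abundance(stoch).to_csv(outdir / "ensemble_stochastic.csv")
    ensemble_relative_abundance(best).to_csv(outdir / "ensemble_bestfit.csv")
    record("ensemble_stochastic", outdir / "ensemble_stochastic.csv")
    record("ensemble_bestfit", outdir / "ensemble_bestfit.csv")
    manifest["stages"].append("nulls")

    alpha = config.get("stats", {}).get("alpha", 0.05)
    table1 = table1_pipeline(dataset, {"bestfit": best, "stochastic": stoch}, alpha=alpha)
    table1.to_csv(outdir / "table1.csv", index=False)
    record("table1", outdir / "table1.csv")
    manifest["stages"].append("analyze_ctm")

    n_perm = config.get("dissimilarity", {}).get("n_permutations", 100_000)
    bc_obs = bray_curtis_matrix(dataset.abundance_matrix())
    bc_null = bray_curtis_matrix(ensemble_relative_abundance(stoch))
    env_d = env_distance_matrix(dataset.environment())
    rng_mantel = np.random.default_rng([seed, 202])
    man_obs = mantel(bc_obs, env_d, n_perm=n_perm, rng=rng_mantel)
    man_null = mantel(bc_null, env_d, n_perm=n_perm, rng=rng_mantel)
    contrast = slope_contrast(bc_obs, bc_null, env_d)
    fig2 = abundance_richness_regressions(dataset, alpha=alpha)
    fig2.to_csv(outdir / "abundance_richness.csv", index=False)
    record("abundance_richness", outdir / "abundance_richness.csv")
    dissim = {
        "observed": {"mantel_r": man_obs.r, "p": man_obs.p, "slope": man_obs.slope,
                     "r_squared": man_obs.r_squared},
        "stochastic_null": {"mantel_r": man_null.r, "p": man_null.p,
                            "slope": man_null.slope, "r_squared": man_null.r_squared},
        "slope_contrast": {k: v for k, v in contrast.items() if k != "caveat"},
        "n_permutations": n_perm,
    }
    (outdir / "dissimilarity.json").write_text(json.dumps(dissim, indent=2))
    record("dissimilarity", outdir / "dissimilarity.json")
    manifest["stages"].append("analyze_dissim")

    mean_pct = fits_table[["pct_stochastic", "pct_filtering", "pct_limiting"]].mean()
    report = {
        "n_transects": len(dataset.transects),
        "pool_size": dataset.pool.size,
        "mean_pct_stochastic": float(mean_pct["pct_stochastic"]),
        "mean_pct_filtering": float(mean_pct["pct_filtering"]),
        "mean_pct_limiting": float(mean_pct["pct_limiting"]),
        "mantel_r_observed": man_obs.r,
        "mantel_r_stochastic_null": man_null.r,
        "slope_observed": contrast["slope_observed"],
        "slope_null": contrast["slope_null"],
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    record("report", outdir / "report.json")
    manifest["stages"].append("report")

    manifest["runtime_seconds"] = round(time.time() - t0, 1)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
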