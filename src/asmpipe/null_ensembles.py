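"""Ensembles of artificial communities for null contrasts.

Two ensemble modes are built per transect:

* **fully stochastic** — every removal step is the stochastic operator
  (composition = (total, 0, 0)); the niche-free reference against which
  observed trait-environment structure is judged.
* **best-fit** — compositions are drawn from the transect's ABC
  posterior particle set, communities are simulated forward, and only
  communities whose summary-statistic distance to the observed data is
  at most the final tolerance of the fit are kept; these are the
  "as good as the accepted particles" communities.

Per-replicate community lists are retained (for replicate-wise trait
mean regressions), and the per-transect occurrence frequency of each
species across replicates — a value in [0, 1] — doubles as its relative
abundance in the artificial communities for dissimilarity analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abc_smc import FitResult
from .data_io import Dataset
from .fd_metrics import SummaryEngine
from .stepcam_forward import Assembler, StepComposition

log = logging.getLogger("asmpipe")

__all__ = [
    "NullEnsemble",
    "simulate_stochastic_ensemble",
    "simulate_bestfit_ensemble",
    "ensemble_relative_abundance",
]


@dataclass
class NullEnsemble:
    """Replicate artificial communities for every transect."""

    mode: str  # "stochastic" | "bestfit"
    n_rep: int
    occurrence: pd.DataFrame  # transect x species frequencies in [0, 1]
    communities: dict[str, list[np.ndarray]]  # transect -> list of pool-index arrays
    provenance: dict = field(default_factory=dict)

    def replicate_indices(self, transect_id: str, rep: int) -> np.ndarray:
        return self.communities[transect_id][rep]


def _occurrence_frame(dataset: Dataset, communities: dict[str, list[np.ndarray]],
                      n_rep: int) -> pd.DataFrame:
    species = dataset.pool.species
    occ = pd.DataFrame(
        0.0, index=pd.Index(dataset.transect_ids, name="transect_id"), columns=species
    )
    for tid, reps in communities.items():
        counts = np.zeros(len(species))
        for idx in reps:
            counts[idx] += 1
        occ.loc[tid] = counts / n_rep
    return occ


def simulate_stochastic_ensemble(
    dataset: Dataset, n_rep: int = 100, rng: np.random.Generator | None = None
) -> NullEnsemble:
    """n_rep fully stochastic communities per transect."""
    rng = rng if rng is not None else np.random.default_rng()
    asm = Assembler(dataset.pool.matrix, dataset.pool.occupancy_array)
    communities: dict[str, list[np.ndarray]] = {}
    for t in dataset.transects:
        total = dataset.pool.size - t.richness
        comp = StepComposition(total, 0, 0)
        communities[t.transect_id] = [asm.run(comp, rng) for _ in range(n_rep)]
    return NullEnsemble(
        mode="stochastic",
        n_rep=n_rep,
        occurrence=_occurrence_frame(dataset, communities, n_rep),
        communities=communities,
        provenance={"composition": "fully stochastic (total, 0, 0)"},
    )


def simulate_bestfit_ensemble(
    dataset: Dataset,
    fits: dict[str, list[FitResult]] | dict[str, FitResult],
    n_rep: int = 100,
    rng: np.random.Generator | None = None,
    max_attempts: int = 1_000_000,
) -> NullEnsemble:
    """n_rep well-fitting communities per transect.

    ``fits`` maps transect id to a FitResult (or replicate list; the
    first replicate's posterior and tolerance are then used). Candidate
    compositions are resampled from the posterior particles; a community
    is accepted when its distance to the observed summary statistics is
    at most the final tolerance of the fit.
    """
    rng = rng if rng is not None else np.random.default_rng()
    engine: SummaryEngine | None = None
    communities: dict[str, list[np.ndarray]] = {}
    thresholds: dict[str, float] = {}
    for t in dataset.transects:
        fit = fits[t.transect_id]
        if isinstance(fit, list):
            fit = fit[0]
        if engine is None:
            engine = SummaryEngine(dataset.pool.matrix, m=fit.config.m)
        optimum = dataset.pool.matrix[dataset.community_indices(t.transect_id)].mean(axis=0)
        asm = Assembler(
            dataset.pool.matrix,
            dataset.pool.occupancy_array,
            optimum=optimum,
            kernel=fit.config.kernel,
        )
        scales = fit.scales
        obs = fit.obs_stats
        eps = fit.final_eps
        thresholds[t.transect_id] = eps
        accepted: list[np.ndarray] = []
        attempts = 0
        post = fit.posterior
        cum_w = np.cumsum(fit.weights)
        while len(accepted) < n_rep:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    f"best-fit ensemble stalled for transect {t.transect_id}: "
                    f"{len(accepted)}/{n_rep} accepted after {attempts} attempts"
                )
            j = int(np.searchsorted(cum_w, rng.random() * cum_w[-1], side="right"))
            comp = StepComposition(*post[j].tolist())
            idx = asm.run(comp, rng, order_policy=fit.config.order_policy)
            vec = engine.stats_vector(idx)
            mask = ~np.isnan(vec) & ~np.isnan(obs) & (scales > 0)
            diff = (vec[mask] - obs[mask]) / scales[mask]
            if float(np.sqrt(np.sum(diff * diff))) <= eps:
                accepted.append(idx)
        communities[t.transect_id] = accepted
    return NullEnsemble(
        mode="bestfit",
        n_rep=n_rep,
        occurrence=_occurrence_frame(dataset, communities, n_rep),
        communities=communities,
        provenance={"fit_threshold": thresholds},
    )


def ensemble_relative_abundance(ensemble: NullEnsemble) -> pd.DataFrame:
    """Occurrence frequencies as relative abundances (transect x species)."""
    return ensemble.occurrence.copy()
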