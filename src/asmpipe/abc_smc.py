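"""ABC-SMC inference of removal-step compositions.

For each transect the unknown parameter is the composition
(n_stochastic, n_filtering, n_limiting) of removal steps, which sums to
pool size minus observed richness. The likelihood is intractable, so
inference is approximate-Bayesian: candidate compositions are simulated
through the forward model, summarized by (FRic, FEve, FDiv, CTM), and
accepted when their scaled Euclidean distance to the observed summary
statistics falls below a tolerance that shrinks over sequential Monte
Carlo generations.

* prior: uniform over the discrete composition simplex;
* move kernel: shift one step between categories (symmetric in the
  simplex interior);
* tolerance schedule: each generation's epsilon is the
  ``shrink_quantile`` (default: median) of the previous generation's
  accepted distances;
* stopping: a generation is abandoned — and the previous generation
  returned as the posterior — once its attempts-per-acceptance ratio
  exceeds ``1 / stop_acceptance_rate`` (default 20,000 attempts per
  acceptance, i.e. a final acceptance rate of 1 in 20,000);
* per-statistic scales are the standard deviations of each summary
  statistic over a prior-predictive calibration batch, so no statistic
  dominates the distance by virtue of its units.

Reported estimates are posterior mean step-type percentages, averaged
over replicate runs seeded with different seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from numba import njit

from .data_io import Dataset
from .fd_metrics import SummaryEngine, SummaryStats, _hull_volume
from .stepcam_forward import Assembler, StepComposition, _run_steps
from scipy.spatial import ConvexHull, QhullError

log = logging.getLogger("asmpipe")

__all__ = [
    "AbcConfig",
    "FitResult",
    "sample_prior",
    "perturb",
    "abc_distance",
    "fit_transect",
    "fit_all",
    "TransectFitter",
]


@dataclass
class AbcConfig:
    n_particles: int = 1000
    stop_acceptance_rate: float = 1.0 / 20000.0
    # aggressive tolerance decay: fewer intermediate generations in
    # which near-deterministic (filter-heavy) compositions can take
    # over the population before their acceptance collapses
    shrink_quantile: float = 0.2
    n_replicates: int = 3
    n_calibration: int = 1000
    # convergence guard: stop once the tolerance improves by less than
    # this relative amount per generation (the distance noise floor)
    min_eps_improvement: float = 0.02
    max_generations: int | None = None
    # weight the CTM vector as ONE statistic among four: each CTM
    # component's scale gains a sqrt(n_traits) factor, so FRic, FEve,
    # FDiv and the CTM block contribute comparably to the distance
    # (without this, the trait-mean block dominates and the fit is
    # biased toward filtering, which matches trait means by
    # construction since the filtering optimum is the observed CTM)
    ctm_block_weight: bool = True
    m: int = 3
    order_policy: str = "shuffled"
    kernel: str = "inverse"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if not 0 < self.stop_acceptance_rate < 1:
            raise ValueError("stop_acceptance_rate must be in (0, 1)")
        if not 0 < self.shrink_quantile < 1:
            raise ValueError("shrink_quantile must be in (0, 1)")


@dataclass
class FitResult:
    """Posterior and diagnostics for one ABC-SMC run on one transect."""

    transect_id: str
    total_steps: int
    posterior: np.ndarray  # (n_accepted, 3) integer compositions
    weights: np.ndarray  # importance weights, sum to 1
    distances: np.ndarray
    eps_schedule: list[float]
    acceptance_rates: list[float]
    generations: list[np.ndarray]
    final_eps: float
    n_simulations: int
    scales: np.ndarray
    obs_stats: np.ndarray
    seed: int
    config: AbcConfig
    degenerate: bool = False
    notes: list[str] = field(default_factory=list)

    @property
    def posterior_mean_percentages(self) -> np.ndarray:
        """(stochastic, filtering, limiting) posterior-mean step percentages."""
        if self.total_steps == 0:
            return np.zeros(3)
        mean = self.weights @ self.posterior
        return 100.0 * mean / self.total_steps


# ---------------------------------------------------------------------------
# prior and move kernel on the discrete composition simplex
# ---------------------------------------------------------------------------


@lru_cache(maxsize=256)
def enumerate_compositions(total: int) -> np.ndarray:
    """All (n_r, n_f, n_l) with n_r + n_f + n_l = total; (total+1)(total+2)/2 rows."""
    out = [
        (r, f, total - r - f)
        for r in range(total + 1)
        for f in range(total - r + 1)
    ]
    return np.array(out, dtype=int)


def sample_prior(total_steps: int, rng: np.random.Generator) -> StepComposition:
    """Uniform draw from the discrete composition simplex."""
    if total_steps < 0:
        raise ValueError("total_steps must be >= 0")
    comps = enumerate_compositions(total_steps)
    return StepComposition(*comps[int(rng.integers(len(comps)))].tolist())


def perturb(composition: StepComposition, rng: np.random.Generator) -> StepComposition:
    """Move one step from a random nonempty category to a different one."""
    counts = list(composition.as_tuple())
    if sum(counts) < 1:
        raise ValueError("cannot perturb an empty composition")
    nonempty = [i for i, c in enumerate(counts) if c > 0]
    src = nonempty[int(rng.integers(len(nonempty)))]
    others = [i for i in range(3) if i != src]
    dst = others[int(rng.integers(2))]
    counts[src] -= 1
    counts[dst] += 1
    return StepComposition(*counts)


def move_kernel_prob(parent: tuple, child: tuple) -> float:
    """P(perturb(parent) == child) for the one-step move kernel."""
    diff = [c - p for p, c in zip(parent, child)]
    if sorted(diff) != [-1, 0, 1]:
        return 0.0
    src = diff.index(-1)
    if parent[src] == 0:
        return 0.0
    n_nonempty = sum(1 for c in parent if c > 0)
    return 1.0 / (n_nonempty * 2.0)


def smc_weights(
    prev: np.ndarray, prev_w: np.ndarray, accepted: np.ndarray
) -> np.ndarray:
    """Importance weights for a new generation of accepted particles.

    With a uniform prior the weight of particle theta is proportional to
    1 / sum_j w_j K(theta_j -> theta): particles that the previous
    population proposes often are downweighted, which preserves
    diversity on the simplex and keeps the sampler a valid
    approximation of the sequential target (the move kernel alone is
    only symmetric in the simplex interior).
    """
    # aggregate previous weight per unique composition
    agg: dict[tuple, float] = {}
    for comp, w in zip(map(tuple, prev), prev_w):
        agg[comp] = agg.get(comp, 0.0) + w
    out = np.empty(len(accepted))
    for i, child in enumerate(map(tuple, accepted)):
        denom = 0.0
        for parent, w in agg.items():
            denom += w * move_kernel_prob(parent, child)
        out[i] = 1.0 / denom if denom > 0 else 0.0
    s = out.sum()
    return out / s if s > 0 else np.full(len(accepted), 1.0 / len(accepted))


def abc_distance(
    sim: SummaryStats | np.ndarray,
    obs: SummaryStats | np.ndarray,
    scales: np.ndarray,
) -> float:
    """Scaled Euclidean distance between two summary-statistic vectors.

    Components undefined (NaN) in either vector, or with zero scale, are
    excluded from the sum.
    """
    a = sim.as_vector() if isinstance(sim, SummaryStats) else np.asarray(sim, float)
    b = obs.as_vector() if isinstance(obs, SummaryStats) else np.asarray(obs, float)
    scales = np.asarray(scales, dtype=float)
    mask = ~np.isnan(a) & ~np.isnan(b) & (scales > 0)
    if not mask.all():
        log.debug("abc_distance: %d component(s) excluded", (~mask).sum())
    diff = (a[mask] - b[mask]) / scales[mask]
    return float(np.sqrt(np.sum(diff * diff)))


@njit(cache=True)
def _sim_core(dist, d_opt, w, steps, uniforms, traits, obs, inv_sc):
    """Fused removal sequence + cheap summary statistics (compiled).

    Runs the removal steps, then computes FEve (full-space MST) and the
    CTM components on the survivors, and returns (alive mask, partial
    squared scaled distance over those components). The hull-based
    FRic/FDiv terms are added by the caller only when the partial
    distance has not already exceeded the tolerance — a pure
    lower-bound rejection that never changes which candidates are
    accepted.
    """
    n = dist.shape[0]
    alive, _victims, _types = _run_steps(dist, d_opt, w, steps, uniforms)
    s = 0
    for i in range(n):
        if alive[i]:
            s += 1
    partial = 0.0
    # FEve on the survivors (component 1)
    if s >= 3 and inv_sc[1] > 0.0:
        idx = np.empty(s, dtype=np.int64)
        j = 0
        for i in range(n):
            if alive[i]:
                idx[j] = i
                j += 1
        in_tree = np.zeros(s, dtype=np.bool_)
        in_tree[0] = True
        best = np.empty(s)
        for i in range(s):
            best[i] = dist[idx[0], idx[i]]
        best[0] = np.inf
        total_len = 0.0
        edges = np.empty(s - 1)
        for k in range(s - 1):
            jmin = 0
            bv = np.inf
            for i in range(s):
                if not in_tree[i] and best[i] < bv:
                    bv = best[i]
                    jmin = i
            edges[k] = best[jmin]
            total_len += best[jmin]
            in_tree[jmin] = True
            for i in range(s):
                if not in_tree[i]:
                    dji = dist[idx[jmin], idx[i]]
                    if dji < best[i]:
                        best[i] = dji
        if total_len > 0.0:
            thr = 1.0 / (s - 1)
            acc = 0.0
            for k in range(s - 1):
                pew = edges[k] / total_len
                acc += pew if pew < thr else thr
            fe = (acc - thr) / (1.0 - thr)
        else:
            fe = 1.0
        diff = (fe - obs[1]) * inv_sc[1]
        partial += diff * diff
    # CTM components (3..)
    k_tr = traits.shape[1]
    for t in range(k_tr):
        if inv_sc[3 + t] > 0.0:
            m = 0.0
            for i in range(n):
                if alive[i]:
                    m += traits[i, t]
            m /= s
            diff = (m - obs[3 + t]) * inv_sc[3 + t]
            partial += diff * diff
    return alive, partial


@njit(cache=True)
def _propose_and_sim(prev, cum_w, dist, d_opt, w, traits, obs, inv_sc, u):
    """One batch of SMC proposals, simulated through the forward model.

    For each row of the uniform buffer ``u``: resample a parent from the
    weighted previous population, apply the one-step move kernel, build
    and shuffle the step sequence, run the removal model, and compute
    the cheap partial distance (FEve + CTM terms). Returns candidate
    compositions, partial squared distances, and survivor masks; the
    caller adds hull-based terms for candidates whose partial distance
    is still below the tolerance.
    """
    B = u.shape[0]
    n = dist.shape[0]
    cand = np.empty((B, 3), dtype=np.int64)
    partial = np.empty(B)
    alive_mat = np.zeros((B, n), dtype=np.bool_)
    for b in range(B):
        # weighted parent resampling
        r = u[b, 0] * cum_w[-1]
        j = np.searchsorted(cum_w, r, side="right")
        if j >= prev.shape[0]:
            j = prev.shape[0] - 1
        c0 = prev[j, 0]
        c1 = prev[j, 1]
        c2 = prev[j, 2]
        # one-step move kernel
        n_nonempty = (1 if c0 > 0 else 0) + (1 if c1 > 0 else 0) + (1 if c2 > 0 else 0)
        pick = int(u[b, 1] * n_nonempty)
        src = -1
        seen = 0
        for cat in range(3):
            cc = c0 if cat == 0 else (c1 if cat == 1 else c2)
            if cc > 0:
                if seen == pick:
                    src = cat
                    break
                seen += 1
        dpick = int(u[b, 2] * 2)
        dst = -1
        seen = 0
        for cat in range(3):
            if cat != src:
                if seen == dpick:
                    dst = cat
                    break
                seen += 1
        counts = np.empty(3, dtype=np.int64)
        counts[0] = c0
        counts[1] = c1
        counts[2] = c2
        counts[src] -= 1
        counts[dst] += 1
        cand[b, 0] = counts[0]
        cand[b, 1] = counts[1]
        cand[b, 2] = counts[2]
        total = counts[0] + counts[1] + counts[2]
        # step sequence, Fisher-Yates shuffled from the uniform buffer
        steps = np.empty(total, dtype=np.int8)
        pos = 0
        for cat in range(3):
            for _ in range(counts[cat]):
                steps[pos] = cat
                pos += 1
        for i in range(total - 1, 0, -1):
            jj = int(u[b, 3 + (total - 1 - i)] * (i + 1))
            tmp = steps[i]
            steps[i] = steps[jj]
            steps[jj] = tmp
        alive, p = _sim_core(
            dist, d_opt, w, steps, u[b, 3 + total : 3 + 2 * total], traits, obs, inv_sc
        )
        alive_mat[b] = alive
        partial[b] = p
    return cand, partial, alive_mat


# ---------------------------------------------------------------------------
# per-transect fitter
# ---------------------------------------------------------------------------


class TransectFitter:
    """ABC-SMC machinery for a single transect.

    Holds the precomputed assembler (pairwise distances, removal
    weights, optimum = observed community trait mean) and summary-
    statistic engine, both shared across replicate runs.
    """

    def __init__(self, dataset: Dataset, transect_id: str, config: AbcConfig,
                 engine: SummaryEngine | None = None):
        self.transect_id = transect_id
        self.config = config
        self.pool_size = dataset.pool.size
        self.obs_idx = dataset.community_indices(transect_id)
        self.total_steps = self.pool_size - len(self.obs_idx)
        self.engine = engine or SummaryEngine(dataset.pool.matrix, m=config.m)
        optimum = dataset.pool.matrix[self.obs_idx].mean(axis=0)
        self.assembler = Assembler(
            dataset.pool.matrix,
            dataset.pool.occupancy_array,
            optimum=optimum,
            kernel=config.kernel,
        )
        self.obs_stats = self.engine.stats_vector(self.obs_idx)
        self.scales: np.ndarray | None = None
        self._mask: np.ndarray | None = None
        self._inv_sc: np.ndarray | None = None
        self._traits = np.ascontiguousarray(dataset.pool.matrix)

    # -- simulation ---------------------------------------------------------

    def simulate_stats(self, comp: StepComposition, rng: np.random.Generator) -> np.ndarray:
        idx = self.assembler.run(comp, rng, order_policy=self.config.order_policy)
        return self.engine.stats_vector(idx)

    def calibrate(self, rng: np.random.Generator) -> np.ndarray:
        """Per-statistic scales from a prior-predictive batch."""
        sims = np.empty((self.config.n_calibration, len(self.obs_stats)))
        for i in range(self.config.n_calibration):
            sims[i] = self.simulate_stats(sample_prior(self.total_steps, rng), rng)
        scales = np.nanstd(sims, axis=0, ddof=1)
        if self.config.ctm_block_weight:
            n_ctm = len(scales) - 3
            scales[3:] *= np.sqrt(n_ctm)
        zero = scales == 0
        if zero.any():
            log.warning(
                "transect %s: %d summary statistic(s) constant under the prior; dropped",
                self.transect_id,
                int(zero.sum()),
            )
        self.scales = scales
        self._mask = ~np.isnan(self.obs_stats) & (scales > 0)
        self._inv_sc = np.where(self._mask, 1.0 / np.where(scales > 0, scales, 1.0), 0.0)
        return scales

    def _distance(self, sim_vec: np.ndarray) -> float:
        m = self._mask & ~np.isnan(sim_vec)
        diff = (sim_vec[m] - self.obs_stats[m]) / self.scales[m]
        return float(np.sqrt(np.sum(diff * diff)))

    def _attempt(self, comp: StepComposition, rng: np.random.Generator,
                 eps: float) -> float | None:
        """One simulation, with early rejection against ``eps``.

        The compiled core returns the scaled squared distance over the
        cheap components (FEve + CTMs); the hull-based FRic/FDiv terms
        are only evaluated when that lower bound has not already
        exceeded the tolerance. Returns the full distance, or None if
        the candidate is rejected.
        """
        steps = np.repeat(np.array([0, 1, 2], dtype=np.int8), comp.as_tuple())
        if self.config.order_policy == "shuffled":
            rng.shuffle(steps)
        uniforms = rng.random(len(steps))
        asm = self.assembler
        alive, partial = _sim_core(
            asm.dist, asm.d_opt, asm.weights, steps, uniforms,
            self._traits, self.obs_stats, self._inv_sc,
        )
        eps2 = eps * eps
        if partial > eps2:
            return None
        return self._finish_distance(np.flatnonzero(alive), partial, eps2)

    def _finish_distance(self, idx: np.ndarray, partial: float, eps2: float) -> float | None:
        """Add the hull-based FRic/FDiv terms; None if the tolerance is exceeded."""
        pts = self.engine.coords[idx]
        vertices = None
        if len(idx) < 2:
            fr = 0.0
        else:
            try:
                hull = ConvexHull(pts)
                fr = hull.volume
                vertices = hull.vertices
            except QhullError:
                fr, vertices = _hull_volume(pts)
        total = partial
        if self._inv_sc[0] > 0.0:
            diff = (fr - self.obs_stats[0]) * self._inv_sc[0]
            total += diff * diff
        if self._inv_sc[2] > 0.0 and len(idx) >= 3:
            if vertices is not None and len(vertices) >= 2 and fr > 0:
                g = pts[vertices].mean(axis=0)
            else:
                g = pts.mean(axis=0)
            d = np.sqrt(((pts - g) ** 2).sum(axis=1))
            dbar = d.mean()
            if dbar > 0:
                fd = dbar / (np.abs(d - dbar).mean() + dbar)
                diff = (fd - self.obs_stats[2]) * self._inv_sc[2]
                total += diff * diff
        if total > eps2:
            return None
        return float(np.sqrt(total))

    # -- the SMC loop -------------------------------------------------------

    def fit(self, seed: int) -> FitResult:
        cfg = self.config
        rng = np.random.default_rng(seed)
        if self.total_steps == 0:
            log.warning(
                "transect %s: richness equals pool size; degenerate fit", self.transect_id
            )
            return FitResult(
                transect_id=self.transect_id,
                total_steps=0,
                posterior=np.zeros((1, 3), dtype=int),
                weights=np.ones(1),
                distances=np.zeros(1),
                eps_schedule=[],
                acceptance_rates=[],
                generations=[np.zeros((1, 3), dtype=int)],
                final_eps=0.0,
                n_simulations=0,
                scales=np.ones_like(self.obs_stats),
                obs_stats=self.obs_stats,
                seed=seed,
                config=cfg,
                degenerate=True,
            )
        if self.scales is None:
            self.calibrate(rng)

        n_sims = 0
        comps = np.empty((cfg.n_particles, 3), dtype=int)
        dists = np.empty(cfg.n_particles)
        weights = np.full(cfg.n_particles, 1.0 / cfg.n_particles)
        for i in range(cfg.n_particles):
            c = sample_prior(self.total_steps, rng)
            comps[i] = c.as_tuple()
            dists[i] = self._attempt(c, rng, np.inf)
            n_sims += 1

        eps_schedule: list[float] = []
        acc_rates: list[float] = [1.0]
        generations: list[np.ndarray] = [comps.copy()]
        final_eps = float(np.inf)
        limit = 1.0 / cfg.stop_acceptance_rate
        gen = 0
        while True:
            gen += 1
            if cfg.max_generations is not None and gen > cfg.max_generations:
                break
            eps = float(np.quantile(dists, cfg.shrink_quantile))
            if eps_schedule and eps >= (1.0 - cfg.min_eps_improvement) * eps_schedule[-1]:
                log.debug("transect %s: epsilon stopped shrinking", self.transect_id)
                break
            new_c = np.empty_like(comps)
            new_d = np.empty_like(dists)
            accepted = 0
            attempts = 0
            abandoned = False
            cum_w = np.cumsum(weights)
            eps2 = eps * eps
            batch = 256
            asm = self.assembler
            while accepted < cfg.n_particles and not abandoned:
                if cfg.order_policy == "shuffled":
                    u = rng.random((batch, 3 + 2 * self.total_steps))
                    cand, partial, alive = _propose_and_sim(
                        comps, cum_w, asm.dist, asm.d_opt, asm.weights,
                        self._traits, self.obs_stats, self._inv_sc, u,
                    )
                    n_sims += batch
                    for b in range(batch):
                        attempts += 1
                        if attempts > (accepted + 1) * limit:
                            abandoned = True
                            break
                        if partial[b] > eps2:
                            continue
                        d = self._finish_distance(
                            np.flatnonzero(alive[b]), partial[b], eps2
                        )
                        if d is not None and d < eps:
                            new_c[accepted] = cand[b]
                            new_d[accepted] = d
                            accepted += 1
                            if accepted == cfg.n_particles:
                                break
                else:  # fixed step order: sequential reference path
                    attempts += 1
                    if attempts > (accepted + 1) * limit:
                        abandoned = True
                        break
                    j = int(np.searchsorted(cum_w, rng.random() * cum_w[-1], side="right"))
                    parent = StepComposition(*comps[j].tolist())
                    candidate = perturb(parent, rng)
                    d = self._attempt(candidate, rng, eps)
                    n_sims += 1
                    if d is not None and d < eps:
                        new_c[accepted] = candidate.as_tuple()
                        new_d[accepted] = d
                        accepted += 1
            if abandoned:
                log.debug(
                    "transect %s: generation %d abandoned after %d attempts "
                    "(%d accepted); acceptance rate below threshold",
                    self.transect_id, gen, attempts, accepted,
                )
                break
            weights = smc_weights(comps, weights, new_c)
            comps, dists = new_c, new_d
            eps_schedule.append(eps)
            acc_rates.append(accepted / attempts)
            generations.append(comps.copy())
            final_eps = eps

        return FitResult(
            transect_id=self.transect_id,
            total_steps=self.total_steps,
            posterior=comps,
            weights=weights,
            distances=dists,
            eps_schedule=eps_schedule,
            acceptance_rates=acc_rates,
            generations=generations,
            final_eps=final_eps,
            n_simulations=n_sims,
            scales=self.scales.copy(),
            obs_stats=self.obs_stats,
            seed=seed,
            config=cfg,
        )


def fit_transect(
    dataset: Dataset,
    transect_id: str,
    config: AbcConfig | None = None,
    seed: int | None = None,
    engine: SummaryEngine | None = None,
) -> FitResult:
    """Run a single ABC-SMC fit for one transect."""
    config = config or AbcConfig()
    fitter = TransectFitter(dataset, transect_id, config, engine=engine)
    return fitter.fit(config.seed if seed is None else seed)


def fit_all(
    dataset: Dataset,
    config: AbcConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, list[FitResult]]]:
    """Fit every transect with replicate runs; average the estimates.

    Replicate r of every transect uses seed ``config.seed + r`` (mixed
    with the transect index so transects get independent streams).
    Returns a per-transect table of replicate-averaged step percentages
    plus the raw :class:`FitResult` objects.
    """
    config = config or AbcConfig()
    engine = SummaryEngine(dataset.pool.matrix, m=config.m)
    rows = []
    all_fits: dict[str, list[FitResult]] = {}
    for t_idx, tid in enumerate(dataset.transect_ids):
        fitter = TransectFitter(dataset, tid, config, engine=engine)
        # scales are deterministic per transect, shared across replicates
        fitter.calibrate(np.random.default_rng([config.seed, t_idx, 97]))
        fits = []
        for r in range(config.n_replicates):
            rng_seed = np.random.SeedSequence([config.seed + r, t_idx]).generate_state(1)[0] % (2**31)
            fits.append(fitter.fit(int(rng_seed)))
        all_fits[tid] = fits
        pct = np.mean([f.posterior_mean_percentages for f in fits], axis=0)
        rows.append(
            {
                "transect_id": tid,
                "pct_stochastic": pct[0],
                "pct_filtering": pct[1],
                "pct_limiting": pct[2],
                "total_steps": fits[0].total_steps,
                "n_generations": float(np.mean([len(f.eps_schedule) for f in fits])),
                "final_eps": float(np.mean([f.final_eps for f in fits])),
                "n_simulations": int(np.sum([f.n_simulations for f in fits])),
                "degenerate": any(f.degenerate for f in fits),
            }
        )
    return pd.DataFrame(rows).set_index("transect_id"), all_fits
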