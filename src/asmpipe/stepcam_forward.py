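"""Stepwise community assembly forward model.

Starting from the full regional species pool, species are removed one at
a time until the observed local richness is reached. Each removal step
is one of three operators:

* **stochastic** — remove species i with probability proportional to
  1/f_i, where f_i is the species' occupancy (number of transects where
  it occurs). Widespread species rarely drop out; locally rare,
  narrowly distributed species are lost first, mimicking neutral
  sampling from the pool.
* **filtering** — remove the species whose traits are farthest
  (Euclidean distance in standardized trait space) from the habitat
  optimum. When fitting observed data the optimum is the observed
  community's trait mean, held fixed over the whole removal sequence.
* **limiting similarity** — find the most trait-similar pair of
  remaining species and remove the member of that pair whose
  second-nearest neighbour is closer, modelling competitive exclusion of
  ecologically redundant species.

The parameter of interest is the composition of the removal-step
multiset: how many steps of each type were taken. Step order is
shuffled uniformly per simulation by default (the ``order_policy``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.spatial.distance import pdist, squareform

log = logging.getLogger("asmpipe")

__all__ = [
    "StepComposition",
    "remove_random",
    "remove_filter",
    "remove_limiting",
    "assemble",
    "Assembler",
]

_RANDOM, _FILTER, _LIMITING = 0, 1, 2


@dataclass(frozen=True)
class StepComposition:
    """Counts of (stochastic, filtering, limiting-similarity) removal steps."""

    n_random: int
    n_filter: int
    n_limiting: int

    def __post_init__(self) -> None:
        if min(self.n_random, self.n_filter, self.n_limiting) < 0:
            raise ValueError("step counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.n_random + self.n_filter + self.n_limiting

    @property
    def percentages(self) -> tuple[float, float, float]:
        """(stochastic, filtering, limiting) as percentages of all steps."""
        if self.total == 0:
            return (0.0, 0.0, 0.0)
        return tuple(100.0 * c / self.total for c in self.as_tuple())

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_random, self.n_filter, self.n_limiting)

    @classmethod
    def from_fractions(cls, fractions, total: int) -> "StepComposition":
        """Integer composition closest to ``fractions`` of ``total`` steps.

        Uses largest-remainder rounding so counts always sum to
        ``total``; fractions may be percentages or proportions.
        """
        frac = np.asarray(fractions, dtype=float)
        if frac.min() < 0 or frac.sum() <= 0:
            raise ValueError("fractions must be nonnegative and not all zero")
        frac = frac / frac.sum()
        raw = frac * total
        counts = np.floor(raw).astype(int)
        short = total - counts.sum()
        if short:
            order = np.argsort(-(raw - counts), kind="stable")
            counts[order[:short]] += 1
            log.debug("largest-remainder correction applied: %s -> %s", raw, counts)
        return cls(*counts.tolist())


# ---------------------------------------------------------------------------
# single-step operators (id-based; used directly in tests and small analyses)
# ---------------------------------------------------------------------------


def remove_random(current_ids, occupancy, rng: np.random.Generator) -> str:
    """Pick the species to remove stochastically, p_i proportional to 1/f_i."""
    ids = sorted(current_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 species for a removal step")
    f = np.array([occupancy[i] for i in ids], dtype=float)
    if np.all(f <= 0):
        raise ValueError("all occupancies are zero")
    w = 1.0 / f
    w /= w.sum()
    return ids[int(rng.choice(len(ids), p=w))]


def remove_filter(current_ids, traits, optimum) -> str:
    """Remove the species farthest from the habitat optimum (ties: smaller id)."""
    ids = sorted(current_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 species for a removal step")
    x = np.asarray([traits.loc[i] for i in ids], dtype=float)
    d = np.linalg.norm(x - np.asarray(optimum, dtype=float), axis=1)
    return ids[int(np.argmax(d))]


def remove_limiting(current_ids, traits) -> str:
    """Remove one member of the most similar pair.

    The victim is the pair member whose second-nearest neighbour is
    closer (it is the more redundant of the two); ties break to the
    lexicographically smaller id.
    """
    ids = sorted(current_ids)
    if len(ids) == 2:
        log.warning("limiting-similarity step with only 2 species; removing %s", ids[0])
        return ids[0]
    if len(ids) < 2:
        raise ValueError("need at least 2 species for a removal step")
    x = np.asarray([traits.loc[i] for i in ids], dtype=float)
    dist = squareform(pdist(x))
    np.fill_diagonal(dist, np.inf)
    i, j = np.unravel_index(np.argmin(dist), dist.shape)
    i, j = min(i, j), max(i, j)
    # second-nearest: nearest neighbour excluding the partner
    di = np.delete(dist[i], j).min()
    dj = np.delete(dist[j], i).min()
    victim = i if di <= dj else j
    return ids[int(victim)]


# ---------------------------------------------------------------------------
# fast index-based assembler
# ---------------------------------------------------------------------------


@njit(cache=True)
def _run_steps(dist, d_opt, w, steps, uniforms):  # pragma: no cover - compiled
    """Apply a removal-step sequence; returns (alive mask, victims, types).

    ``dist`` must have +inf on the diagonal; ``uniforms`` holds one
    U(0,1) draw per step (consumed by stochastic steps). ``victims``
    records the removed species index per step and ``types`` the
    operator actually applied (after the <3-species fallback from
    limiting to stochastic). All argmax / argmin tie-breaks take the
    lowest index, i.e. species-id order.
    """
    n = dist.shape[0]
    alive = np.ones(n, dtype=np.bool_)
    victims = np.empty(steps.shape[0], dtype=np.int64)
    types = np.empty(steps.shape[0], dtype=np.int8)
    n_alive = n
    for s in range(steps.shape[0]):
        st = steps[s]
        if st == 2 and n_alive < 3:
            st = 0  # limiting undefined below 3 species: stochastic fallback
        k = -1
        if st == 0:
            total = 0.0
            for i in range(n):
                if alive[i]:
                    total += w[i]
            r = uniforms[s] * total
            acc = 0.0
            for i in range(n):
                if alive[i]:
                    acc += w[i]
                    if r < acc:
                        k = i
                        break
            if k == -1:  # guard against r == total from rounding
                for i in range(n - 1, -1, -1):
                    if alive[i]:
                        k = i
                        break
        elif st == 1:
            best = -1.0
            for i in range(n):
                if alive[i] and d_opt[i] > best:
                    best = d_opt[i]
                    k = i
        else:
            bmin = np.inf
            bi = -1
            bj = -1
            for i in range(n):
                if not alive[i]:
                    continue
                for j in range(i + 1, n):
                    if alive[j] and dist[i, j] < bmin:
                        bmin = dist[i, j]
                        bi = i
                        bj = j
            di = np.inf
            dj = np.inf
            for t in range(n):
                if not alive[t] or t == bi or t == bj:
                    continue
                if dist[bi, t] < di:
                    di = dist[bi, t]
                if dist[bj, t] < dj:
                    dj = dist[bj, t]
            k = bi if di <= dj else bj
        alive[k] = False
        victims[s] = k
        types[s] = st
        n_alive -= 1
    return alive, victims, types


class Assembler:
    """Runs full removal sequences on one pool, index-based for speed.

    Pairwise trait distances and distances to the optimum are computed
    once; each :meth:`run` then works on copies of small arrays. Species
    are addressed by their row index in the (id-sorted) pool trait
    matrix, so tie-breaks by lowest index coincide with lexicographic
    species-id order.
    """

    def __init__(
        self,
        traits: np.ndarray,
        occupancy: np.ndarray,
        optimum: np.ndarray | None = None,
        kernel: str = "inverse",
    ):
        self.traits = np.asarray(traits, dtype=float)
        self.n = self.traits.shape[0]
        occ = np.asarray(occupancy, dtype=float)
        if np.any(occ <= 0):
            raise ValueError("occupancies must be positive")
        if kernel == "inverse":
            self.weights = 1.0 / occ
        elif kernel == "complement":
            self.weights = 1.0 - occ / (occ.max() + 1.0)
        else:
            raise ValueError(f"unknown stochastic kernel {kernel!r}")
        self.dist = squareform(pdist(self.traits))
        np.fill_diagonal(self.dist, np.inf)
        self.d_opt = None
        if optimum is not None:
            self.set_optimum(optimum)

    def set_optimum(self, optimum: np.ndarray) -> None:
        opt = np.asarray(optimum, dtype=float)
        self.d_opt = np.linalg.norm(self.traits - opt, axis=1)

    def run(
        self,
        composition: StepComposition,
        rng: np.random.Generator,
        order_policy: str = "shuffled",
    ) -> np.ndarray:
        """Apply all removal steps; returns surviving pool indices (sorted)."""
        total = composition.total
        if total >= self.n:
            raise ValueError("cannot remove as many species as the pool holds")
        steps = np.repeat(
            [_RANDOM, _FILTER, _LIMITING], composition.as_tuple()
        ).astype(np.int8)
        if order_policy == "shuffled":
            rng.shuffle(steps)
        elif order_policy != "fixed":
            raise ValueError(f"unknown order_policy {order_policy!r}")
        if composition.n_filter and self.d_opt is None:
            raise ValueError("filtering steps require an optimum")

        d_opt = self.d_opt if self.d_opt is not None else np.zeros(self.n)
        uniforms = rng.random(len(steps))
        alive, victims, types = _run_steps(self.dist, d_opt, self.weights, steps, uniforms)
        self.last_removals = (victims, types)
        return np.flatnonzero(alive)


def assemble(
    pool,
    composition: StepComposition,
    optimum: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    order_policy: str = "shuffled",
    kernel: str = "inverse",
) -> list[str]:
    """Assemble one community from a :class:`~asmpipe.data_io.SpeciesPool`.

    Returns the ids of the surviving species (pool size minus
    ``composition.total`` of them).
    """
    rng = rng if rng is not None else np.random.default_rng()
    asm = Assembler(pool.matrix, pool.occupancy_array, optimum=optimum, kernel=kernel)
    idx = asm.run(composition, rng, order_policy=order_policy)
    return [pool.species[i] for i in idx]
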