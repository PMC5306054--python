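"""Functional-diversity summary statistics.

Four statistics summarize a community's position and spread in trait
space and serve as the targets for likelihood-free inference:

* **CTM** — community trait means: the per-trait arithmetic mean over the
  species present (unweighted; the assembly model is presence-based).
* **FRic** — functional richness: the convex-hull volume of the
  community's species in a reduced trait space (the first ``m``
  principal coordinates of the pooled standardized trait matrix).
* **FEve** — functional evenness: regularity of species spacing along
  the minimum spanning tree of the community's trait points.
* **FDiv** — functional divergence: spread of species distances from the
  centroid of the convex-hull vertices.

Hull-based indices are computed in a reduced space because hulls in full
6-D trait space need at least seven affinely independent species and are
numerically fragile at typical community sizes (~22 species); reducing
dimensionality first is the standard remedy in the functional-diversity
literature. ``m`` defaults to 3 and is configurable. CTMs are always
computed on the original standardized traits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform

log = logging.getLogger("asmpipe")

__all__ = ["SummaryStats", "ctm", "fric", "feve", "fdiv", "summary_stats", "SummaryEngine"]


@dataclass
class SummaryStats:
    """The four summary statistics for one community."""

    fric: float
    feve: float | None
    fdiv: float | None
    ctm: np.ndarray
    notes: list[str] = field(default_factory=list)

    def as_vector(self) -> np.ndarray:
        """Flat (3 + n_traits) vector [FRic, FEve, FDiv, CTM...]; NaN if undefined."""
        head = [
            self.fric,
            np.nan if self.feve is None else self.feve,
            np.nan if self.fdiv is None else self.fdiv,
        ]
        return np.concatenate([head, self.ctm])


def ctm(community_traits: np.ndarray) -> np.ndarray:
    """Per-trait arithmetic mean over the species present."""
    x = np.asarray(community_traits, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[0] < 1:
        raise ValueError("empty community")
    return x.mean(axis=0)


def _hull_volume(points: np.ndarray) -> tuple[float, np.ndarray]:
    """Convex-hull volume with dimensionality fallback.

    Returns (volume, vertex indices). Degenerate point sets are projected
    onto their own principal axes and the hull recomputed in the largest
    dimension that is nondegenerate; in 1-D the 'volume' is the range; a
    coincident point set has volume 0.
    """
    pts = np.asarray(points, dtype=float)
    n, d = pts.shape
    centered = pts - pts.mean(axis=0)
    if np.allclose(centered, 0.0, atol=1e-12):
        return 0.0, np.arange(n)
    # effective dimensionality: at most n-1, at most ambient, at most rank
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    rank = int((s > 1e-10 * s[0]).sum())
    q = min(n - 1, d, rank)
    proj = centered @ vt[:q].T
    while q >= 2:
        try:
            hull = ConvexHull(proj[:, :q])
            return float(hull.volume), hull.vertices
        except QhullError:
            q -= 1
    lo, hi = int(np.argmin(proj[:, 0])), int(np.argmax(proj[:, 0]))
    return float(proj[hi, 0] - proj[lo, 0]), np.unique([lo, hi])


def fric(community_points: np.ndarray, m: int | None = None) -> float:
    """Functional richness: convex-hull volume of the community's points.

    ``community_points`` are coordinates in the (already reduced) trait
    space; pass ``m`` to truncate to the first ``m`` columns.
    """
    if m is not None and m < 1:
        raise ValueError("m must be >= 1")
    pts = np.asarray(community_points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.shape[0] < 2:
        raise ValueError("FRic requires at least 2 species")
    if m is not None:
        pts = pts[:, :m]
    vol, _ = _hull_volume(pts)
    return vol


@njit(cache=True)
def _mst_edges(dist):  # pragma: no cover - compiled
    """Edge lengths of the Euclidean minimum spanning tree (Prim).

    Ties are resolved by lowest index, i.e. species-id order, so the
    tree (and FEve) is deterministic.
    """
    n = dist.shape[0]
    in_tree = np.zeros(n, dtype=np.bool_)
    in_tree[0] = True
    best = dist[0].copy()
    best[0] = np.inf
    edges = np.empty(n - 1)
    for k in range(n - 1):
        j = 0
        bv = np.inf
        for i in range(n):
            if not in_tree[i] and best[i] < bv:
                bv = best[i]
                j = i
        edges[k] = best[j]
        in_tree[j] = True
        for i in range(n):
            if not in_tree[i] and dist[j, i] < best[i]:
                best[i] = dist[j, i]
    return edges


def feve(community_points: np.ndarray, dist: np.ndarray | None = None) -> float:
    """Functional evenness (equal species weights).

    With MST branch lengths EW_l and PEW_l = EW_l / sum(EW), S species:
    FEve = (sum_l min(PEW_l, 1/(S-1)) - 1/(S-1)) / (1 - 1/(S-1)).
    Equals 1 when species are perfectly regularly spaced along the tree.
    """
    if dist is None:
        pts = np.asarray(community_points, dtype=float)
        if pts.ndim == 1:
            pts = pts[:, None]
        s = pts.shape[0]
        if s < 3:
            raise ValueError("FEve undefined for fewer than 3 species")
        dist = squareform(pdist(pts))
    else:
        s = dist.shape[0]
        if s < 3:
            raise ValueError("FEve undefined for fewer than 3 species")
    edges = _mst_edges(dist)
    total = edges.sum()
    if total == 0:
        return 1.0  # all species coincident: vacuously even
    pew = edges / total
    thr = 1.0 / (s - 1)
    return float((np.minimum(pew, thr).sum() - thr) / (1.0 - thr))


def fdiv(community_points: np.ndarray) -> float:
    """Functional divergence (equal species weights).

    G is the centroid of the convex-hull vertex species; with dG_i the
    distance of species i to G and dbar their mean:
    FDiv = dbar / (mean(|dG_i - dbar|) + dbar).
    Equals 1 when all species are equidistant from G.
    """
    pts = np.asarray(community_points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.shape[0] < 3:
        raise ValueError("FDiv undefined for fewer than 3 species")
    vol, vertices = _hull_volume(pts)
    if vol == 0 or len(vertices) < 2:
        log.debug("degenerate hull in FDiv; using all-species centroid")
        g = pts.mean(axis=0)
    else:
        g = pts[vertices].mean(axis=0)
    d = np.linalg.norm(pts - g, axis=1)
    dbar = d.mean()
    if dbar == 0:
        raise ValueError("all species coincide with the centroid; FDiv undefined")
    return float(dbar / (np.abs(d - dbar).mean() + dbar))


class SummaryEngine:
    """Precomputed summary-statistic machinery for one species pool.

    Builds, once per pool, the reduced principal-coordinate space (PCA
    of the pooled standardized trait matrix, for the hull-based FRic and
    FDiv) and the full-trait-space pairwise distance matrix (for the
    MST-based FEve, which has no dimensionality constraint); community
    statistics then require only array subsetting, which keeps the inner
    simulation loop of the ABC fast.
    """

    def __init__(self, pool_traits: np.ndarray, m: int = 3):
        traits = np.asarray(pool_traits, dtype=float)
        if m < 1:
            raise ValueError("m must be >= 1")
        self.traits = traits
        self.m = min(m, traits.shape[1], traits.shape[0] - 1)
        centered = traits - traits.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        self.coords = np.ascontiguousarray(centered @ vt[: self.m].T)
        self.dist_full = squareform(pdist(traits))

    def stats_vector(self, idx: np.ndarray) -> np.ndarray:
        """Flat [FRic, FEve, FDiv, CTM...] for the community ``idx`` (fast path)."""
        idx = np.asarray(idx)
        s = len(idx)
        k = self.traits.shape[1]
        out = np.empty(3 + k)
        pts = self.coords[idx]
        vertices = None
        if s < 2:
            out[0] = 0.0
        else:
            try:
                hull = ConvexHull(pts)
                out[0] = hull.volume
                vertices = hull.vertices
            except QhullError:
                out[0], vertices = _hull_volume(pts)
        if s < 3:
            out[1] = np.nan
            out[2] = np.nan
        else:
            out[1] = feve(None, dist=self.dist_full[np.ix_(idx, idx)])
            if vertices is not None and len(vertices) >= 2 and out[0] > 0:
                g = pts[vertices].mean(axis=0)
            else:
                g = pts.mean(axis=0)
            d = np.sqrt(((pts - g) ** 2).sum(axis=1))
            dbar = d.mean()
            out[2] = np.nan if dbar == 0 else dbar / (np.abs(d - dbar).mean() + dbar)
        out[3:] = self.traits[idx].mean(axis=0)
        return out

    def stats(self, idx: np.ndarray) -> SummaryStats:
        """Summary statistics for the community given by pool indices."""
        idx = np.asarray(idx)
        vec = self.stats_vector(idx)
        notes: list[str] = []
        if len(idx) < 2:
            notes.append("FRic set to 0 for a single-species community")
        if len(idx) < 3:
            notes.append("FEve/FDiv undefined for S < 3; dropped")
        return SummaryStats(
            fric=float(vec[0]),
            feve=None if np.isnan(vec[1]) else float(vec[1]),
            fdiv=None if np.isnan(vec[2]) else float(vec[2]),
            ctm=vec[3:].copy(),
            notes=notes,
        )


def summary_stats(community_idx: np.ndarray, pool_traits: np.ndarray, m: int = 3) -> SummaryStats:
    """Convenience wrapper: build an engine and evaluate one community.

    ``community_idx`` holds row indices into ``pool_traits`` (the full
    standardized pool trait matrix).
    """
    return SummaryEngine(pool_traits, m=m).stats(np.asarray(community_idx))
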