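"""Weighted graph topology of density-thresholded connectomes.

The FC matrix is reduced to a sparse weighted graph by keeping the top
d-fraction of positive connections (proportional density threshold), then
nodal (strength/degree, Onnela clustering, harmonic closeness) and global
(efficiency, clustering, characteristic path length, small-worldness)
measures are computed at each density of a grid — by default 15%..35% in 1%
steps — and summarized by a range-normalized trapezoidal integral across
densities, so results do not hinge on any single threshold.

Small-worldness sigma = (C / <C_rand>) / (L / <L_rand>) normalizes
clustering and path length against degree-preserving Maslov-Sneppen
rewired null graphs carrying the same weight multiset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import dijkstra

from .connectivity import ConnectivityMatrix

#: default proportional-density grid: 15-35% in 1% steps (21 points)
DEFAULT_DENSITIES: tuple[float, ...] = tuple(
    np.round(np.arange(15, 36) / 100.0, 2))
DEFAULT_N_NULLS = 100
DEFAULT_SWAPS_PER_EDGE = 10


def _round_half_away(x: float) -> int:
    """Round half away from zero (0.5 -> 1), unlike banker's rounding."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass
class ThresholdedGraph:
    """Nonnegative symmetric weight matrix at one density."""

    weights: np.ndarray
    density: float
    n_edges: int = 0
    truncated: bool = False  # fewer positive entries than the target count

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if np.any(np.diag(w) != 0):
            raise ValueError("weight matrix diagonal must be zero")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if np.max(np.abs(w - w.T)) > 1e-12:
            raise ValueError("weight matrix must be symmetric")
        self.weights = w
        if self.n_edges == 0:
            iu = np.triu_indices(w.shape[0], k=1)
            self.n_edges = int(np.count_nonzero(w[iu]))

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def apply_density_threshold(fc: ConnectivityMatrix | np.ndarray,
                            density: float) -> ThresholdedGraph:
    """Keep the strongest positive connections at proportional density d.

    Negative z values are set to zero, then the round(d * R(R-1)/2) largest
    positive upper-triangle weights are retained (round half away from
    zero; ties at the cutoff broken by row-major upper-triangle order so
    runs are reproducible).  Weights are kept, not binarized.  If fewer
    positive entries exist than the target edge count, all positives are
    kept and the graph is flagged ``truncated`` with a warning.
    """
    if not (0 < density <= 1):
        raise ValueError("density must lie in (0, 1]")
    v = fc.values if isinstance(fc, ConnectivityMatrix) else np.asarray(fc, float)
    r = v.shape[0]
    n_possible = r * (r - 1) // 2
    k = _round_half_away(density * n_possible)
    if k == 0:
        raise ValueError(f"density {density} yields 0 edges for {r} nodes")
    iu = np.triu_indices(r, k=1)
    w = v[iu]
    pos = w > 0
    n_pos = int(pos.sum())
    truncated = n_pos < k
    if n_pos == 0:
        raise ValueError("no positive connections to threshold")
    if truncated:
        warnings.warn(
            f"only {n_pos} positive entries for target {k} edges at "
            f"density {density}; keeping all positives", stacklevel=2)
        keep = pos
    else:
        # stable sort on -w preserves first-occurrence (row-major) order at ties
        order = np.argsort(-w, kind="stable")
        keep = np.zeros(w.size, bool)
        keep[order[:k]] = True
        keep &= pos
    out = np.zeros_like(v)
    rows, cols = iu[0][keep], iu[1][keep]
    out[rows, cols] = v[rows, cols]
    out[cols, rows] = v[rows, cols]
    return ThresholdedGraph(out, density=density, n_edges=int(keep.sum()),
                            truncated=truncated)


def nodal_strength(g: ThresholdedGraph) -> np.ndarray:
    """Weighted degree: sum of each node's edge weights."""
    return g.weights.sum(axis=1)


def nodal_degree(g: ThresholdedGraph) -> np.ndarray:
    """Binary degree: number of edges at each node."""
    return (g.weights > 0).sum(axis=1).astype(float)


def nodal_clustering(g: ThresholdedGraph) -> np.ndarray:
    """Onnela weighted clustering coefficient per node.

    C_i = (1/(k_i (k_i - 1))) * sum_{j,h} (w'_ij w'_jh w'_hi)^(1/3), with
    weights normalized by the graph maximum (w' = w / max w); C_i = 0 when
    the binary degree k_i < 2.
    """
    w = g.weights
    wmax = w.max()
    if wmax == 0:
        return np.zeros(g.n_nodes)
    cube = np.cbrt(w / wmax)
    # diagonal of cube^3 counts each triangle at i twice (j,h and h,j)
    tri = np.einsum("ij,jh,hi->i", cube, cube, cube)
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return c


def shortest_path_lengths(g: ThresholdedGraph) -> np.ndarray:
    """All-pairs shortest-path distances with edge length 1/weight.

    Stronger connections are shorter; unreachable pairs are +inf; the
    diagonal is 0.
    """
    w = g.weights
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, 0.0)
    return dijkstra(csr_array(lengths), directed=False)


def nodal_closeness(g: ThresholdedGraph,
                    dist: np.ndarray | None = None) -> np.ndarray:
    """Harmonic closeness: mean inverse distance to every other node.

    closeness_i = (1/(R-1)) * sum_{j != i} 1/d_ij, with 1/inf = 0, so the
    measure stays finite on disconnected graphs and an isolated node scores
    0.
    """
    d = shortest_path_lengths(g) if dist is None else dist
    r = d.shape[0]
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (r - 1)


def global_efficiency(g: ThresholdedGraph,
                      dist: np.ndarray | None = None) -> float:
    """Mean inverse shortest-path distance over ordered node pairs.

    Equals the mean of nodal harmonic closeness.
    """
    return float(nodal_closeness(g, dist).mean())


def characteristic_path_length(
        g: ThresholdedGraph,
        dist: np.ndarray | None = None) -> tuple[float, float]:
    """Mean shortest-path distance over reachable ordered pairs.

    Returns ``(L, unreachable_fraction)``; unreachable pairs are excluded
    from the mean and reported as a fraction of all ordered pairs.  Raises
    if no pair is reachable.
    """
    d = shortest_path_lengths(g) if dist is None else dist
    r = d.shape[0]
    off = ~np.eye(r, dtype=bool)
    finite = np.isfinite(d) & off
    n_pairs = r * (r - 1)
    if not finite.any():
        raise ValueError("no reachable node pairs")
    frac_unreachable = 1.0 - finite.sum() / n_pairs
    return float(d[finite].mean()), float(frac_unreachable)


def _double_edge_swaps(edges: list[tuple[int, int]], nswap: int,
                       max_tries: int, rng: np.random.Generator) -> int:
    """In-place Maslov-Sneppen double-edge swaps on an undirected edge list.

    Picks two edges uniformly, (u, v) and (x, y), and replaces them with
    (u, x) and (v, y) (after a random orientation flip of the second edge)
    unless that would create a self-loop or duplicate an existing edge.
    Node degrees are invariant.  Returns the number of achieved swaps.
    """
    eset = {frozenset(e) for e in edges}
    m = len(edges)
    swaps = tries = 0
    batch = 1024
    while swaps < nswap and tries < max_tries:
        idx = rng.integers(0, m, size=(batch, 2))
        flips = rng.random(batch) < 0.5
        for (i, j), flip in zip(idx, flips):
            tries += 1
            if swaps >= nswap or tries > max_tries:
                break
            if i == j:
                continue
            u, v = edges[i]
            x, y = edges[j]
            if flip:
                x, y = y, x
            if u == x or u == y or v == x or v == y:
                continue
            e1, e2 = frozenset((u, x)), frozenset((v, y))
            if e1 in eset or e2 in eset:
                continue
            eset.discard(frozenset((u, v)))
            eset.discard(frozenset((x, y)))
            eset.add(e1)
            eset.add(e2)
            edges[i] = (u, x)
            edges[j] = (v, y)
            swaps += 1
    return swaps


def rewire_null(g: ThresholdedGraph, n_swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
                seed: int | np.random.Generator = 0) -> ThresholdedGraph:
    """Degree-preserving Maslov-Sneppen null graph with shuffled weights.

    Double-edge swaps randomize the topology while preserving every node's
    binary degree exactly; the original weight multiset is then reassigned
    to the rewired edges in random order.  If no swap is achievable within
    the retry budget (e.g. a complete graph admits no legal swap) the input
    is returned unchanged.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    w = g.weights
    iu = np.triu_indices(g.n_nodes, k=1)
    mask = w[iu] > 0
    edges = list(zip(iu[0][mask].tolist(), iu[1][mask].tolist()))
    weights = w[iu][mask]
    if len(edges) < 2:
        raise ValueError("need at least 2 edges to rewire")
    if g.n_nodes < 4:
        # a double swap needs 4 distinct endpoints: no legal swap exists
        return ThresholdedGraph(w.copy(), density=g.density,
                                n_edges=g.n_edges, truncated=g.truncated)
    nswap = n_swaps_per_edge * len(edges)
    achieved = _double_edge_swaps(edges, nswap, max_tries=100 * nswap, rng=rng)
    if achieved == 0:
        return ThresholdedGraph(w.copy(), density=g.density,
                                n_edges=g.n_edges, truncated=g.truncated)
    new_edges = sorted(tuple(sorted(e)) for e in edges)
    shuffled = weights[rng.permutation(len(weights))]
    out = np.zeros_like(w)
    rows = np.fromiter((e[0] for e in new_edges), int, len(new_edges))
    cols = np.fromiter((e[1] for e in new_edges), int, len(new_edges))
    out[rows, cols] = shuffled
    out[cols, rows] = shuffled
    return ThresholdedGraph(out, density=g.density, n_edges=len(new_edges),
                            truncated=g.truncated)


@dataclass
class SmallWorldResult:
    """Small-worldness sigma with its null-model statistics."""

    sigma: float
    clustering: float
    path_length: float
    null_clustering_mean: float
    null_clustering_sd: float
    null_path_length_mean: float
    null_path_length_sd: float
    n_nulls: int


def small_worldness(g: ThresholdedGraph, n_nulls: int = DEFAULT_N_NULLS,
                    seed: int | np.random.Generator = 0,
                    n_swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE) -> SmallWorldResult:
    """sigma = (C/<C_rand>) / (L/<L_rand>) against rewired null graphs.

    C is the mean Onnela nodal clustering, L the characteristic path
    length; the angle brackets average over ``n_nulls`` Maslov-Sneppen
    rewired graphs.  sigma > 1 indicates small-world organization (more
    clustered than random at comparable path length).
    """
    if n_nulls < 2:
        raise ValueError("n_nulls must be >= 2")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    c = float(nodal_clustering(g).mean())
    l, _ = characteristic_path_length(g)
    c_rand = np.empty(n_nulls)
    l_rand = np.empty(n_nulls)
    for i in range(n_nulls):
        null = rewire_null(g, n_swaps_per_edge=n_swaps_per_edge, seed=rng)
        c_rand[i] = nodal_clustering(null).mean()
        l_rand[i] = characteristic_path_length(null)[0]
    sigma = (c / c_rand.mean()) / (l / l_rand.mean())
    return SmallWorldResult(
        sigma=float(sigma), clustering=c, path_length=l,
        null_clustering_mean=float(c_rand.mean()),
        null_clustering_sd=float(c_rand.std(ddof=1)),
        null_path_length_mean=float(l_rand.mean()),
        null_path_length_sd=float(l_rand.std(ddof=1)),
        n_nulls=n_nulls)


def integrate_over_densities(curve: np.ndarray,
                             densities: np.ndarray | tuple = DEFAULT_DENSITIES) -> float | np.ndarray:
    """Range-normalized trapezoidal integral of a metric across densities.

    Dividing the trapezoid integral by the density range keeps the result
    on the per-density scale: a constant curve integrates to itself, and a
    linear ramp from a to b integrates to (a+b)/2.  ``curve`` may be 1-D
    (global metric) or 2-D with one row per density (nodal metric).
    """
    d = np.asarray(densities, float)
    if d.size < 2:
        raise ValueError("need at least 2 densities to integrate")
    if np.any(np.diff(d) <= 0):
        raise ValueError("densities must be strictly increasing")
    y = np.asarray(curve, float)
    if y.shape[0] != d.size:
        raise ValueError("curve length must match densities")
    integral = np.trapezoid(y, d, axis=0) / (d[-1] - d[0])
    return float(integral) if np.ndim(integral) == 0 else integral


#: metric names produced per subject-session by :func:`metric_profile`
GLOBAL_METRICS = ("global_efficiency", "global_clustering",
                  "characteristic_path_length", "small_worldness")
NODAL_METRICS = ("strength", "degree", "clustering", "closeness")


@dataclass
class GraphMetricProfile:
    """Nodal + global topology per density, with across-density integrals."""

    densities: np.ndarray
    nodal: dict[str, np.ndarray]        # metric -> densities x nodes
    global_: dict[str, np.ndarray]      # metric -> per-density values
    nodal_integrated: dict[str, np.ndarray]   # metric -> per-node value
    global_integrated: dict[str, float]
    sigma_details: list[SmallWorldResult] = field(default_factory=list)
    subject: str = "sub"
    session: str = "1"

    def to_long(self, roi_names: tuple[str, ...] | None = None) -> pd.DataFrame:
        rows = []
        for m, vals in self.global_.items():
            for d, v in zip(self.densities, vals):
                rows.append({"subject": self.subject, "session": self.session,
                             "density": d, "metric": m,
                             "node_or_global": "global", "value": v})
        for m, mat in self.nodal.items():
            for di, d in enumerate(self.densities):
                for ni in range(mat.shape[1]):
                    name = roi_names[ni] if roi_names else f"ROI_{ni + 1:03d}"
                    rows.append({"subject": self.subject, "session": self.session,
                                 "density": d, "metric": m,
                                 "node_or_global": name, "value": mat[di, ni]})
        return pd.DataFrame(rows)

    def integrated_frame(self, roi_names: tuple[str, ...] | None = None) -> pd.DataFrame:
        rows = [{"subject": self.subject, "session": self.session,
                 "metric": m, "node_or_global": "global", "value": v}
                for m, v in self.global_integrated.items()]
        for m, vals in self.nodal_integrated.items():
            for ni, v in enumerate(vals):
                name = roi_names[ni] if roi_names else f"ROI_{ni + 1:03d}"
                rows.append({"subject": self.subject, "session": self.session,
                             "metric": m, "node_or_global": name, "value": v})
        return pd.DataFrame(rows)


def metric_profile(fc: ConnectivityMatrix,
                   densities: tuple | np.ndarray = DEFAULT_DENSITIES,
                   n_nulls: int = DEFAULT_N_NULLS,
                   seed: int | np.random.Generator = 0,
                   n_swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
                   compute_sigma: bool = True) -> GraphMetricProfile:
    """Full topology profile of one connectome across the density grid."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    d_arr = np.asarray(densities, float)
    r = fc.n_rois
    nodal = {m: np.zeros((d_arr.size, r)) for m in NODAL_METRICS}
    global_ = {m: np.zeros(d_arr.size) for m in GLOBAL_METRICS
               if compute_sigma or m != "small_worldness"}
    sigma_details: list[SmallWorldResult] = []
    for di, dens in enumerate(d_arr):
        g = apply_density_threshold(fc, float(dens))
        dist = shortest_path_lengths(g)
        nodal["strength"][di] = nodal_strength(g)
        nodal["degree"][di] = nodal_degree(g)
        clus = nodal_clustering(g)
        nodal["clustering"][di] = clus
        nodal["closeness"][di] = nodal_closeness(g, dist)
        global_["global_efficiency"][di] = global_efficiency(g, dist)
        global_["global_clustering"][di] = clus.mean()
        global_["characteristic_path_length"][di] = characteristic_path_length(g, dist)[0]
        if compute_sigma:
            sw = small_worldness(g, n_nulls=n_nulls, seed=rng,
                                 n_swaps_per_edge=n_swaps_per_edge)
            global_["small_worldness"][di] = sw.sigma
            sigma_details.append(sw)
    nodal_integrated = {m: integrate_over_densities(v, d_arr)
                        for m, v in nodal.items()}
    global_integrated = {m: float(integrate_over_densities(v, d_arr))
                         for m, v in global_.items()}
    return GraphMetricProfile(
        densities=d_arr, nodal=nodal, global_=global_,
        nodal_integrated=nodal_integrated, global_integrated=global_integrated,
        sigma_details=sigma_details, subject=fc.subject, session=fc.session)
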