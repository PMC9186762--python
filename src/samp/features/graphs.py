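"""Neighbourhood graphs on nuclear centroids.

Four graphs underlie the spatial features, each defined on the Euclidean
plane of centroid coordinates:

* **SOI** (sphere of influence): edge (a, b) iff d(a, b) <= r_a + r_b,
  where r_x is the nearest-neighbour distance of x.
* **MIN**: Euclidean minimum spanning tree.
* **Gabriel**: edge iff no third point lies in the closed disk whose
  diameter is the segment ab.
* **Lune** (relative neighbourhood graph): edge iff there is no c with
  max(d(a, c), d(b, c)) < d(a, b).

With distinct points these satisfy MST subset-of RNG subset-of Gabriel and
every node has degree >= 1 for n >= 2.  Coincident centroids are broken by
a deterministic 1e-6 px jitter before construction.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import Delaunay, QhullError, distance_matrix

Edge = tuple[int, int]

GRAPH_METHODS = ("SOI", "MIN", "Gabriel", "Lune")

_JITTER_SEED = 1902


def resolve_ties(points: np.ndarray) -> np.ndarray:
    """Deterministically jitter coincident points by 1e-6 px."""
    pts = np.asarray(points, float).copy()
    _, inverse, counts = np.unique(pts, axis=0, return_inverse=True, return_counts=True)
    if counts.max() > 1:
        rng = np.random.default_rng(_JITTER_SEED)
        jitter = rng.normal(scale=1e-6, size=pts.shape)
        dup = counts[inverse] > 1
        pts[dup] += jitter[dup]
    return pts


def _candidate_edges(points: np.ndarray) -> set[Edge]:
    """Delaunay edges (superset of Gabriel); complete graph for tiny/degenerate inputs."""
    n = len(points)
    if n >= 4:
        try:
            tri = Delaunay(points)
            edges: set[Edge] = set()
            for simplex in tri.simplices:
                for i in range(3):
                    a, b = int(simplex[i]), int(simplex[(i + 1) % 3])
                    edges.add((min(a, b), max(a, b)))
            return edges
        except QhullError:
            pass
    return {(i, j) for i in range(n) for j in range(i + 1, n)}


def gabriel_edges(points: np.ndarray) -> set[Edge]:
    points = np.asarray(points, float)
    edges = set()
    for a, b in _candidate_edges(points):
        mid = (points[a] + points[b]) / 2.0
        r2 = ((points[a] - points[b]) ** 2).sum() / 4.0
        d2 = ((points - mid) ** 2).sum(axis=1)
        # closed disk: boundary points block; small relative slack keeps the
        # decision stable under floating-point rounding of exact geometry
        blocked = d2 <= r2 * (1.0 + 1e-9)
        blocked[[a, b]] = False
        if not blocked.any():
            edges.add((a, b))
    return edges


def lune_edges(points: np.ndarray) -> set[Edge]:
    """Relative neighbourhood graph; subset of the Gabriel graph."""
    points = np.asarray(points, float)
    edges = set()
    for a, b in gabriel_edges(points):
        dab2 = ((points[a] - points[b]) ** 2).sum()
        da2 = ((points - points[a]) ** 2).sum(axis=1)
        db2 = ((points - points[b]) ** 2).sum(axis=1)
        # open lune (strict inequality): near-equal distances do not block
        blocked = np.maximum(da2, db2) < dab2 * (1.0 - 1e-9)
        blocked[[a, b]] = False
        if not blocked.any():
            edges.add((a, b))
    return edges


def mst_edges(points: np.ndarray) -> set[Edge]:
    points = np.asarray(points, float)
    dm = distance_matrix(points, points)
    tree = minimum_spanning_tree(dm).tocoo()
    return {(min(int(i), int(j)), max(int(i), int(j))) for i, j in zip(tree.row, tree.col)}


def soi_edges(points: np.ndarray) -> set[Edge]:
    points = np.asarray(points, float)
    dm = distance_matrix(points, points)
    np.fill_diagonal(dm, np.inf)
    r = dm.min(axis=1)
    n = len(points)
    return {
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if dm[i, j] <= r[i] + r[j]
    }


_BUILDERS = {
    "SOI": soi_edges,
    "MIN": mst_edges,
    "Gabriel": gabriel_edges,
    "Lune": lune_edges,
}


def build_neighbor_graph(centroids: np.ndarray, method: str) -> set[Edge]:
    """Edge set of one of the four neighbourhood graphs on *centroids*."""
    if method not in _BUILDERS:
        raise ValueError(f"unknown graph method {method!r}; choose from {GRAPH_METHODS}")
    centroids = np.asarray(centroids, float)
    if len(centroids) < 2:
        raise ValueError("need at least two points")
    return _BUILDERS[method](resolve_ties(centroids))


def spatial_stats(centroids: np.ndarray) -> dict[str, np.ndarray]:
    """Per-node spacing (mean incident edge length) and degree for all 4 graphs.

    Returns a mapping like ``{"Spacing (SOI)": array, "Neighbor Count (SOI)":
    array, ...}``; all values NaN-free because every graph covers every node.
    """
    centroids = np.asarray(centroids, float)
    n = len(centroids)
    if n < 2:
        raise ValueError("need at least two points")
    pts = resolve_ties(centroids)
    dm = distance_matrix(pts, pts)
    out: dict[str, np.ndarray] = {}
    for method in GRAPH_METHODS:
        edges = _BUILDERS[method](pts)
        degree = np.zeros(n)
        total = np.zeros(n)
        for a, b in edges:
            d = dm[a, b]
            degree[[a, b]] += 1
            total[[a, b]] += d
        with np.errstate(invalid="ignore"):
            spacing = np.where(degree > 0, total / np.maximum(degree, 1), np.nan)
        out[f"Spacing ({method})"] = spacing
        out[f"Neighbor Count ({method})"] = degree
    return out
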