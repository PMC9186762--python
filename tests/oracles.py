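"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a quantity from its definition with the simplest
possible algorithm (per-pixel walks, all-pairs predicates, explicit
Lance-Williams recursion), deliberately sharing no code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------- moments

def moment_axes(mask: np.ndarray) -> tuple[float, float]:
    """Major/minor axis lengths from the eigenvalues of the pixel covariance."""
    pts = np.argwhere(mask).astype(float)
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    ev = np.sort(np.linalg.eigvalsh(cov))
    return 4.0 * np.sqrt(ev[1]), 4.0 * np.sqrt(ev[0])


def hull_perimeter(mask: np.ndarray) -> float:
    """Perimeter of the convex hull of pixel corners (tight for convex shapes)."""
    from scipy.spatial import ConvexHull

    pts = np.argwhere(mask).astype(float)
    corners = np.concatenate(
        [pts + off for off in ([0.5, 0.5], [0.5, -0.5], [-0.5, 0.5], [-0.5, -0.5])]
    )
    hull = ConvexHull(corners)
    verts = corners[hull.vertices]
    d = np.diff(np.vstack([verts, verts[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


# ----------------------------------------------------------------- GLRLM

def glrlm_counts(levels: np.ndarray, mask: np.ndarray):
    """(level, length) run multiset by naive per-pixel walking, 4 directions."""
    runs = []
    h, w = mask.shape

    def inside(r, c):
        return 0 <= r < h and 0 <= c < w and mask[r, c]

    for dr, dc in ((0, 1), (1, 1), (1, 0), (1, -1)):
        for r in range(h):
            for c in range(w):
                if not mask[r, c]:
                    continue
                pr, pc = r - dr, c - dc
                if inside(pr, pc) and levels[pr, pc] == levels[r, c]:
                    continue  # not a run start
                length = 1
                nr, nc = r + dr, c + dc
                while inside(nr, nc) and levels[nr, nc] == levels[r, c]:
                    length += 1
                    nr, nc = nr + dr, nc + dc
                runs.append((int(levels[r, c]), length))
    return runs


def glrlm_statistics(runs, levels: int = 16):
    nr = len(runs)
    r = np.zeros(levels)
    c_counts: dict[int, int] = {}
    for lev, length in runs:
        r[lev - 1] += 1
        c_counts[length] = c_counts.get(length, 0) + 1
    c = np.array(list(c_counts.values()), float)
    i = np.arange(1, levels + 1, dtype=float)
    return {
        "n_runs": nr,
        "gln": float((r**2).sum() / nr),
        "rln": float((c**2).sum() / nr),
        "hglre": float((r * i**2).sum() / nr),
        "lglre": float((r / i**2).sum() / nr),
    }


# ----------------------------------------------------------------- graphs

def _d(p, q):
    return float(np.hypot(p[0] - q[0], p[1] - q[1]))


def gabriel_bf(points):
    points = np.asarray(points, float)
    n = len(points)
    edges = set()
    for a, b in itertools.combinations(range(n), 2):
        mid = (points[a] + points[b]) / 2
        r = _d(points[a], points[b]) / 2
        ok = True
        for c in range(n):
            if c in (a, b):
                continue
            if _d(points[c], mid) <= r:
                ok = False
                break
        if ok:
            edges.add((a, b))
    return edges


def rng_bf(points):
    points = np.asarray(points, float)
    n = len(points)
    edges = set()
    for a, b in itertools.combinations(range(n), 2):
        dab = _d(points[a], points[b])
        ok = True
        for c in range(n):
            if c in (a, b):
                continue
            if max(_d(points[a], points[c]), _d(points[b], points[c])) < dab:
                ok = False
                break
        if ok:
            edges.add((a, b))
    return edges


def mst_bf(points):
    """Prim's algorithm, hand-rolled."""
    points = np.asarray(points, float)
    n = len(points)
    in_tree = {0}
    edges = set()
    while len(in_tree) < n:
        best = None
        for a in in_tree:
            for b in range(n):
                if b in in_tree:
                    continue
                d = _d(points[a], points[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        _, a, b = best
        edges.add((min(a, b), max(a, b)))
        in_tree.add(b)
    return edges


def soi_bf(points):
    points = np.asarray(points, float)
    n = len(points)
    r = [min(_d(points[i], points[j]) for j in range(n) if j != i) for i in range(n)]
    return {
        (a, b)
        for a, b in itertools.combinations(range(n), 2)
        if _d(points[a], points[b]) <= r[a] + r[b]
    }


# ---------------------------------------------------------------- ward.D2

def ward_d2_heights(x: np.ndarray) -> list[float]:
    """Merge heights of ward.D2 clustering by explicit Lance-Williams updates."""
    n = len(x)
    d = {
        (i, j): float(np.linalg.norm(x[i] - x[j]))
        for i in range(n)
        for j in range(i + 1, n)
    }
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    heights = []
    nxt = n

    def dist(a, b):
        return d[(min(a, b), max(a, b))]

    while len(active) > 1:
        (a, b) = min(
            ((i, j) for i in active for j in active if i < j), key=lambda ij: dist(*ij)
        )
        h = dist(a, b)
        heights.append(h)
        for c in active - {a, b}:
            na, nb, nc = size[a], size[b], size[c]
            new = np.sqrt(
                ((na + nc) * dist(a, c) ** 2 + (nb + nc) * dist(b, c) ** 2 - nc * h**2)
                / (na + nb + nc)
            )
            d[(min(c, nxt), max(c, nxt))] = float(new)
        size[nxt] = size[a] + size[b]
        active -= {a, b}
        active.add(nxt)
        nxt += 1
    return heights


def ward_d2_first_merge(x: np.ndarray) -> tuple[int, int]:
    n = len(x)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    return min(pairs, key=lambda ij: np.linalg.norm(x[ij[0]] - x[ij[1]]))
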