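"""Exact nearest point-to-triangle queries with a KD-tree spatial index.

Used for part-comparison distance maps and for ICP closest-point
correspondences.  Distances are exact (closest point on the triangle,
whether in its interior, on an edge or at a corner); the spatial index
only prunes candidates and certifies optimality.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .volume_io import InputError, SurfaceMesh


def point_triangle_closest(points: np.ndarray, tri: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closest points on paired triangles and the distances to them.

    ``points``: (n, 3); ``tri``: (n, 3, 3).  Vectorized region-based
    closest-point computation (interior, three edges, three corners).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac = b - a, c - a
    ap = points - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    closest = np.empty_like(points)
    done = np.zeros(len(points), dtype=bool)

    def settle(mask: np.ndarray, value: np.ndarray) -> None:
        m = mask & ~done
        closest[m] = value[m]
        done[m] = True

    settle((d1 <= 0) & (d2 <= 0), a)  # corner a
    settle((d3 >= 0) & (d4 <= d3), b)  # corner b
    settle((d6 >= 0) & (d5 <= d6), c)  # corner c

    vc = d1 * d4 - d3 * d2
    m = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    settle(m, a + v[:, None] * ab)  # edge ab

    vb = d5 * d2 - d1 * d6
    m = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    settle(m, a + w[:, None] * ac)  # edge ac

    va = d3 * d6 - d5 * d4
    m = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4 - d3) + (d5 - d6)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(denom != 0, (d4 - d3) / denom, 0.0)
    settle(m, b + w[:, None] * (c - b))  # edge bc

    denom = va + vb + vc
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
    settle(np.ones(len(points), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)

    return np.linalg.norm(points - closest, axis=1), closest


def point_triangle_distance(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact unsigned distances between paired points and triangles."""
    return point_triangle_closest(points, tri)[0]


class MeshDistanceIndex:
    """Spatial index answering exact nearest point-to-surface queries.

    Candidate triangles are pruned with a KD-tree over triangle
    centroids: the ``k`` nearest centroids are tested exactly, and the
    result is certified optimal when the best exact distance does not
    exceed the k-th centroid distance minus the largest triangle
    circumradius; uncertified points fall back to a ball query that
    cannot miss the optimum.
    """

    def __init__(self, mesh: SurfaceMesh):
        if mesh.n_faces == 0:
            raise InputError("reference mesh has no triangles")
        self.tri = mesh.triangles()
        self.centroids = self.tri.mean(axis=1)
        self.r_max = float(
            np.linalg.norm(self.tri - self.centroids[:, None, :], axis=2).max()
        )
        normals = np.cross(self.tri[:, 1] - self.tri[:, 0], self.tri[:, 2] - self.tri[:, 0])
        lens = np.linalg.norm(normals, axis=1)
        lens[lens == 0] = 1.0
        self.normals = normals / lens[:, None]
        self.tree = cKDTree(self.centroids)

    def _exact_k(
        self, points: np.ndarray, k: int
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Exact distances/closest points over the k nearest-centroid candidates."""
        cdist, cidx = self.tree.query(points, k=k, workers=-1)
        cdist = cdist.reshape(len(points), k)
        cidx = cidx.reshape(len(points), k)
        d, cp = point_triangle_closest(
            np.repeat(points, k, axis=0), self.tri[cidx.ravel()]
        )
        d = d.reshape(len(points), k)
        cp = cp.reshape(len(points), k, 3)
        rows = np.arange(len(points))
        sel = d.argmin(axis=1)
        return d[rows, sel], cp[rows, sel], cidx[rows, sel], cdist[:, -1]

    def query(
        self,
        points: np.ndarray,
        k: int = 16,
        return_points: bool = False,
        return_triangles: bool = False,
        certify: bool = True,
    ):
        """Nearest surface distances; optionally the foot points and triangles.

        With ``certify`` (default) the candidate count escalates until
        the result is provably the global nearest: a missed triangle
        would need a centroid beyond the k-th candidate, hence a surface
        point no closer than that distance minus the largest triangle
        circumradius.  ``certify=False`` returns the best of the first
        ``k`` candidates — sufficient for ICP correspondences.
        """
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        n_tri = len(self.centroids)
        best = np.empty(len(points))
        best_pt = np.empty((len(points), 3))
        best_tri = np.empty(len(points), dtype=np.int64)
        pending = np.arange(len(points))
        while pending.size:
            kk = min(k, n_tri)
            d, cp, ti, kth = self._exact_k(points[pending], kk)
            best[pending] = d
            best_pt[pending] = cp
            best_tri[pending] = ti
            if kk == n_tri or not certify:
                break
            certified = d <= kth - self.r_max
            pending = pending[~certified]
            k *= 8
        out = [best]
        if return_points:
            out.append(best_pt)
        if return_triangles:
            out.append(best_tri)
        return tuple(out) if len(out) > 1 else best
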