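"""Standardized condylar volume-of-interest selection.

The condyle is isolated by a sphere whose boundary passes through the
lowest point of the sigmoid (mandibular) notch and whose radius is the
smallest that still encloses the whole condylar head.  With the boundary
pinned at the notch point ``n``, a sphere is parameterized by its center
direction ``u`` and radius ``r = ||c - n||``; enclosing a vertex ``v``
requires ``r >= ||v - n||^2 / (2 u.(v - n))``, so for a fixed direction
the minimal radius is the maximum of that ratio over the condyle
vertices, and the fit reduces to a smooth-ish 2-D minimization over the
unit direction, solved with multi-start Nelder-Mead.

In a paired analysis exactly one sphere per side is fitted — on the
fixed (postoperative) frame — and transferred rigidly to the other time
point, so the volume difference cannot originate from VOI placement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

from .registration import LandmarkSet, RigidTransform
from .segmentation import BinaryMask
from .volume_io import GeometryError, SurfaceMesh

_BOUNDARY_TOL = 1e-6


@dataclass(frozen=True)
class SphereVOI:
    """A spherical region of interest with its boundary pinned at the notch."""

    center: np.ndarray
    radius: float
    notch_point: np.ndarray
    side: str = "left"

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=float).reshape(3)
        n = np.asarray(self.notch_point, dtype=float).reshape(3)
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "notch_point", n)
        if self.radius <= 0:
            raise GeometryError("sphere radius must be positive")
        if abs(np.linalg.norm(c - n) - self.radius) > _BOUNDARY_TOL:
            raise GeometryError(
                "sphere boundary must pass through the notch point: "
                f"|‖center−notch‖ − r| = {abs(np.linalg.norm(c - n) - self.radius):.3g} mm"
            )

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Inclusive membership test for (n, 3) points."""
        pts = np.asarray(points, dtype=float)
        return np.sum((pts - self.center) ** 2, axis=-1) <= self.radius**2

    def to_dict(self) -> dict:
        return {
            "center": [float(x) for x in self.center],
            "radius": float(self.radius),
            "notch_point": [float(x) for x in self.notch_point],
            "side": self.side,
        }


def _vertex_normals(mesh: SurfaceMesh, smooth_passes: int = 2) -> np.ndarray:
    """Area-weighted vertex normals, smoothed over the 1-ring.

    Smoothing suppresses single-vertex staircase artifacts of
    marching-cubes surfaces, whose raw normals can point diagonally on
    an otherwise flat wall.
    """

    def _normalize(v: np.ndarray) -> np.ndarray:
        n = np.linalg.norm(v, axis=1)
        n[n == 0] = 1.0
        return v / n[:, None]

    tri = mesh.triangles()
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    vn = np.zeros_like(mesh.vertices)
    for i in range(3):
        np.add.at(vn, mesh.faces[:, i], fn)
    vn = _normalize(vn)
    for _ in range(smooth_passes):
        acc = vn.copy()
        for i, j in ((0, 1), (1, 2), (2, 0)):
            np.add.at(acc, mesh.faces[:, i], vn[mesh.faces[:, j]])
            np.add.at(acc, mesh.faces[:, j], vn[mesh.faces[:, i]])
        vn = _normalize(acc)
    return vn


def lowest_notch_point(
    mesh: SurfaceMesh,
    landmarks: LandmarkSet,
    superior_axis: np.ndarray = (0.0, 0.0, 1.0),
    band: tuple[float, float] = (0.2, 0.8),
    min_up_normal: float = 0.5,
) -> np.ndarray:
    """Lowest surface point of the sigmoid notch.

    Candidate vertices are those whose projection onto the coronoid →
    condyle axis falls in the interior ``band`` (default 20%–80%) of the
    segment and whose surface normal points upward (cosine with
    ``superior_axis`` at least ``min_up_normal`` — this keeps the notch
    groove and discards the inferior mandible border and the vertical
    ramus walls, which also fall inside the band on a closed mesh).
    Among the candidates the vertex minimal along ``superior_axis`` is
    returned, ties broken by smallest vertex index.
    """
    axis = np.asarray(superior_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = landmarks.get("coronoid")
    b = landmarks.get("condyle")
    ab = b - a
    denom = float(ab @ ab)
    if denom <= 0:
        raise GeometryError("coronoid and condyle landmarks coincide")
    frac = (mesh.vertices - a) @ ab / denom
    in_band = (frac >= band[0]) & (frac <= band[1])
    if not in_band.any():
        raise GeometryError("no mesh vertices between the coronoid and condyle landmarks")
    up = _vertex_normals(mesh) @ axis >= min_up_normal
    cand = np.flatnonzero(in_band & up)
    if cand.size == 0:  # open sheets or odd winding: fall back to the bare band
        cand = np.flatnonzero(in_band)
    heights = mesh.vertices[cand] @ axis
    # argmin returns the first minimizer -> smallest index among ties
    return mesh.vertices[cand[int(np.argmin(heights))]].copy()


def _condyle_vertices(
    mesh: SurfaceMesh, notch_point: np.ndarray, head_landmark: np.ndarray, axis: np.ndarray
) -> np.ndarray:
    """Vertices of the mesh component containing the head landmark after
    cutting with the plane through the notch point normal to ``axis``."""
    above = (mesh.vertices - notch_point) @ axis > 0
    keep_face = above[mesh.faces].all(axis=1)
    faces = mesh.faces[keep_face]
    if len(faces) == 0:
        raise GeometryError("no mesh faces above the notch plane")
    # connected components on the vertex graph of the cut mesh
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    nv = mesh.n_vertices
    adj = sp.coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(nv, nv))
    _, labels = connected_components(adj, directed=False)
    used = np.unique(faces)
    d2 = np.sum((mesh.vertices[used] - head_landmark) ** 2, axis=1)
    seed = used[int(np.argmin(d2))]
    comp = used[labels[used] == labels[seed]]
    return mesh.vertices[comp]


_INFEASIBLE = 1e12


def _min_radius_for_direction(u: np.ndarray, rel: np.ndarray, norm2: np.ndarray) -> float:
    """Minimal pinned-sphere radius enclosing all points for direction u."""
    dots = rel @ u
    if np.any(dots <= 0):
        # some point lies behind the notch-tangent plane of this direction:
        # no pinned sphere in direction u encloses it (finite penalty keeps
        # the simplex search numerically happy)
        return _INFEASIBLE
    return float(np.max(norm2 / (2.0 * dots)))


def fit_condylar_sphere(
    mesh: SurfaceMesh,
    notch_point: np.ndarray,
    head_landmark: np.ndarray,
    superior_axis: np.ndarray = (0.0, 0.0, 1.0),
    side: str = "left",
    center_override: np.ndarray | None = None,
    plane_offset: float = 0.0,
) -> SphereVOI:
    """Fit the minimal condyle-enclosing sphere pinned at the notch point.

    ``center_override`` reproduces a manually centred sphere: the center
    direction is taken as given and only the radius is optimized.
    ``plane_offset`` (mm) raises the cutting plane above the notch point
    when isolating the condyle component; on voxelized surfaces an
    offset of about one voxel prevents slivers of the notch groove from
    bridging the condyle to the coronoid side.  The sphere itself stays
    pinned at the notch point regardless.
    """
    axis = np.asarray(superior_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    notch_point = np.asarray(notch_point, dtype=float).reshape(3)
    head_landmark = np.asarray(head_landmark, dtype=float).reshape(3)
    if (head_landmark - notch_point) @ axis <= 0:
        raise GeometryError("head landmark must lie superior to the notch point")
    C = _condyle_vertices(mesh, notch_point + plane_offset * axis, head_landmark, axis)
    rel = C - notch_point
    norm2 = np.sum(rel * rel, axis=1)

    if center_override is not None:
        c = np.asarray(center_override, dtype=float).reshape(3)
        u = c - notch_point
        u = u / np.linalg.norm(u)
        r = _min_radius_for_direction(u, rel, norm2)
        return SphereVOI(notch_point + r * u, r, notch_point, side)

    def unpack(angles: np.ndarray) -> np.ndarray:
        theta, phi = angles
        return np.array(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
        )

    def objective(angles: np.ndarray) -> float:
        return _min_radius_for_direction(unpack(angles), rel, norm2)

    def to_angles(v: np.ndarray) -> np.ndarray:
        v = v / np.linalg.norm(v)
        return np.array([np.arccos(np.clip(v[2], -1, 1)), np.arctan2(v[1], v[0])])

    starts = [
        to_angles(head_landmark - notch_point),
        to_angles(C.mean(axis=0) - notch_point),
        to_angles(axis),
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 2000},
        )
        if res.fun < _INFEASIBLE / 2 and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise GeometryError("sphere fit failed: no feasible center direction found")
    u = unpack(best.x)
    r = float(best.fun)
    center = notch_point + r * u
    max_excess = float(np.max(np.linalg.norm(C - center, axis=1)) - r)
    if max_excess > 1e-4:
        raise GeometryError(f"sphere fit violates enclosure by {max_excess:.3g} mm")
    return SphereVOI(center, r, notch_point, side)


def crop_to_sphere(mask: BinaryMask, voi: SphereVOI) -> BinaryMask:
    """Restrict a mask to voxels whose world center lies inside the sphere."""
    shape = mask.shape
    sp = np.asarray(mask.spacing)
    org = np.asarray(mask.origin)
    # squared distance field evaluated separably
    ax = [(org[i] + np.arange(shape[i]) * sp[i] - voi.center[i]) ** 2 for i in range(3)]
    d2 = ax[0][:, None, None] + ax[1][None, :, None] + ax[2][None, None, :]
    inside = d2 <= voi.radius**2
    out = replace(mask, voxels=mask.voxels & inside)
    if out.count() == 0:
        warnings.warn("sphere crop produced an empty mask", stacklevel=2)
    return out


def transfer_voi(voi: SphereVOI, T: RigidTransform) -> SphereVOI:
    """Map a VOI rigidly into the other time point's frame.

    The radius is untouched: the *same* sphere is applied to both
    registered volumes, so a volume difference cannot arise from VOI
    placement.
    """
    return SphereVOI(T.apply(voi.center), voi.radius, T.apply(voi.notch_point), voi.side)
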