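"""Reproducibility and accuracy measurements between 3D models.

Implements the validation toolkit: part-comparison (exact shortest
point-to-triangle distances from every vertex of one model — interior
sheets included — to the surface of another), distance-to-curve between
the lower borders of sphere-cropped models, VOI-mismatch subtraction,
and the comparison of a segmentation against a gold-standard mask.

Distances are unsigned; over/under-estimation is carried by the sign of
the volume difference.  The colour-map threshold of 0.375 mm flags
discrepancies close to one working voxel (0.4 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .meshquery import MeshDistanceIndex, point_triangle_distance  # noqa: F401  (re-export)
from .quantify import mask_volume
from .registration import RigidTransform, apply_transform
from .segmentation import BinaryMask, mask_to_mesh
from .volume_io import GeometryError, InputError, SurfaceMesh
from .voi import SphereVOI

ONE_VOXEL_CUTOFF_MM = 0.375


@dataclass
class DistanceSummary:
    """Summary of an unsigned distance sample (mm)."""

    mean: float
    sd: float
    max: float
    n: int
    distances: np.ndarray
    cutoff: float = ONE_VOXEL_CUTOFF_MM
    direction: str = "query->reference"

    @property
    def threshold_exceed_fraction(self) -> float:
        """Fraction of samples above ``cutoff`` (default 0.375 mm)."""
        return float(np.mean(self.distances > self.cutoff))

    @classmethod
    def from_distances(cls, d: np.ndarray, cutoff: float = ONE_VOXEL_CUTOFF_MM,
                       direction: str = "query->reference") -> "DistanceSummary":
        d = np.asarray(d, dtype=float)
        if d.size == 0:
            raise InputError("empty distance sample")
        sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
        return cls(float(d.mean()), sd, float(d.max()), int(d.size), d, cutoff, direction)

    def to_dict(self) -> dict:
        return {
            "mean_mm": self.mean,
            "sd_mm": self.sd,
            "max_mm": self.max,
            "n": self.n,
            "cutoff_mm": self.cutoff,
            "threshold_exceed_fraction": self.threshold_exceed_fraction,
            "direction": self.direction,
        }


def part_comparison(query: SurfaceMesh, reference: SurfaceMesh,
                    cutoff: float = ONE_VOXEL_CUTOFF_MM) -> DistanceSummary:
    """Shortest unsigned distance from every query vertex to the reference surface.

    All surface sheets of the query participate, interior trabecular
    sheets included.  The per-vertex distances are attached to the query
    mesh (``vertex_attr``) for colour-mapped export.
    """
    if query.n_faces == 0 or reference.n_faces == 0:
        raise InputError("part comparison needs two non-empty meshes")
    d = MeshDistanceIndex(reference).query(query.vertices)
    query.vertex_attr = d
    return DistanceSummary.from_distances(d, cutoff=cutoff)


# --------------------------------------------------------------------------
# lower borders and distance-to-curve


def boundary_polylines(mesh: SurfaceMesh) -> list[np.ndarray]:
    """Chain the open-boundary edges of a mesh into ordered polylines.

    Closed loops are returned with the first point repeated at the end.
    """
    edges = mesh.boundary_edges()
    if len(edges) == 0:
        raise GeometryError("mesh is watertight: no boundary to extract")
    neighbors: dict[int, list[int]] = {}
    for u, v in edges:
        neighbors.setdefault(int(u), []).append(int(v))
        neighbors.setdefault(int(v), []).append(int(u))
    unused = {tuple(sorted((int(u), int(v)))) for u, v in edges}
    polylines = []
    while unused:
        # prefer an endpoint of an open chain (degree-1 vertex with an unused edge)
        start = None
        for u, v in unused:
            if len(neighbors[u]) == 1:
                start = u
                break
            if len(neighbors[v]) == 1:
                start = v
                break
        if start is None:
            start = min(min(e) for e in unused)
        chain = [start]
        cur = start
        while True:
            nxt = None
            for cand in neighbors[cur]:
                if tuple(sorted((cur, cand))) in unused:
                    nxt = cand
                    break
            if nxt is None:
                break
            unused.discard(tuple(sorted((cur, nxt))))
            chain.append(nxt)
            cur = nxt
        polylines.append(mesh.vertices[np.asarray(chain)])
    return polylines


def extract_lower_border(mesh: SurfaceMesh,
                         superior_axis: np.ndarray = (0.0, 0.0, 1.0)) -> np.ndarray:
    """The boundary polyline with the lowest mean superior coordinate.

    The input must be an open (sphere-cropped) mesh; its lower border is
    the rim used to quantify VOI-selection discrepancy.
    """
    axis = np.asarray(superior_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    polys = boundary_polylines(mesh)
    heights = [float(np.mean(p @ axis)) for p in polys]
    return polys[int(np.argmin(heights))]


def _point_segment_distances(points: np.ndarray, seg_a: np.ndarray, seg_b: np.ndarray) -> np.ndarray:
    """(n_points, n_segments) exact point-to-segment distances."""
    ab = seg_b - seg_a  # (m, 3)
    ap = points[:, None, :] - seg_a[None, :, :]  # (n, m, 3)
    denom = np.einsum("ij,ij->i", ab, ab)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.clip(np.einsum("nmj,mj->nm", ap, ab) / np.where(denom > 0, denom, 1.0), 0.0, 1.0)
    closest = seg_a[None, :, :] + t[:, :, None] * ab[None, :, :]
    return np.linalg.norm(points[:, None, :] - closest, axis=2)


def distance_to_curve(curve_a: np.ndarray, curve_b: np.ndarray) -> DistanceSummary:
    """Shortest distance from each vertex of curve A to the segments of curve B.

    Asymmetric by definition; the direction is recorded in the summary.
    """
    A = np.asarray(curve_a, dtype=float).reshape(-1, 3)
    B = np.asarray(curve_b, dtype=float).reshape(-1, 3)
    if len(A) < 2 or len(B) < 2:
        raise InputError("polylines need at least two points")
    d = _point_segment_distances(A, B[:-1], B[1:]).min(axis=1)
    return DistanceSummary.from_distances(d, direction="A->B")


# --------------------------------------------------------------------------
# VOI-mismatch subtraction and gold-standard accuracy


def subtract_voi_mismatch(
    mask_a: BinaryMask, voi_a: SphereVOI, mask_b: BinaryMask, voi_b: SphereVOI
) -> tuple[BinaryMask, BinaryMask]:
    """Restrict both masks to the intersection of the two sphere VOIs.

    After subtraction a part-comparison between the masks measures
    segmentation (threshold) discrepancy only, with the VOI-placement
    disagreement removed.  Masks must live on the same grid.
    """
    if mask_a.shape != mask_b.shape or mask_a.spacing != mask_b.spacing or mask_a.origin != mask_b.origin:
        raise GeometryError("masks must share one grid; register/resample first")
    gap = float(np.linalg.norm(voi_a.center - voi_b.center))
    if gap > voi_a.radius + voi_b.radius:
        raise GeometryError(f"sphere VOIs are disjoint (center gap {gap:.2f} mm)")
    from .voi import crop_to_sphere

    a = crop_to_sphere(crop_to_sphere(mask_a, voi_a), voi_b)
    b = crop_to_sphere(crop_to_sphere(mask_b, voi_a), voi_b)
    return a, b


@dataclass
class AccuracyResult:
    """Part-comparison of a test segmentation against a gold standard."""

    distances: DistanceSummary
    test_volume: float
    gold_volume: float

    @property
    def volume_excess(self) -> float:
        """Test minus gold, mm^3; positive means overestimation."""
        return self.test_volume - self.gold_volume

    def to_dict(self) -> dict:
        return {
            "part_comparison": self.distances.to_dict(),
            "test_volume_mm3": self.test_volume,
            "gold_volume_mm3": self.gold_volume,
            "volume_excess_mm3": self.volume_excess,
        }


def accuracy_vs_gold(
    test_mask: BinaryMask, gold_mask: BinaryMask, transform: RigidTransform | None = None
) -> AccuracyResult:
    """Compare a test segmentation with a gold-standard segmentation.

    ``transform`` maps the test frame onto the gold frame (supplied
    externally, e.g. from an intensity-based alignment).  The distance
    direction is fixed test→gold; the volume excess sign reports over-
    or underestimation.
    """
    if transform is None:
        transform = RigidTransform.identity()
    test_mesh = apply_transform(mask_to_mesh(test_mask), transform)
    gold_mesh = mask_to_mesh(gold_mask)
    summary = part_comparison(test_mesh, gold_mesh)
    summary = replace(summary, direction="test->gold")
    return AccuracyResult(summary, mask_volume(test_mask), mask_volume(gold_mask))
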