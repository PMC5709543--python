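"""Global-threshold bone segmentation and surface extraction.

The mineralized bone is delineated by a single global threshold, realized
as an automatic suggestion (maximal between-class-variance split of a
256-bin histogram restricted to the upper half of the intensity
distribution) plus an optional manual override.  No morphological cleanup
is applied to the mask: interior trabecular gaps are deliberately kept so
that both the inner and the outer mineralized structure enter the
quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import measure

from .volume_io import GeometryError, ImageVolume, InputError, SurfaceMesh


class DegenerateInputError(ValueError):
    """The input has no structure the operation could work with."""


@dataclass
class BinaryMask:
    """A boolean grid sharing the geometry of its source :class:`ImageVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise GeometryError("mask must be a non-empty 3D grid")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def count(self) -> int:
        return int(self.voxels.sum())

    def is_isotropic(self, tol: float = 1e-9) -> bool:
        s = self.spacing
        return abs(s[0] - s[1]) <= tol and abs(s[1] - s[2]) <= tol

    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def world_coords(self) -> np.ndarray:
        """(n, 3) world coordinates of the foreground voxel centers."""
        idx = np.argwhere(self.voxels)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)


@dataclass(frozen=True)
class ThresholdDecision:
    """A suggested bone threshold and the value actually applied."""

    suggested: float
    applied: float
    method: str = "automatic"  # or "manual-override"


def _between_class_variance_split(values: np.ndarray, nbins: int = 256) -> float:
    """Exhaustive maximal between-class-variance threshold on an nbins histogram.

    Returns the intensity (bin center of the first upper-class bin) that
    maximizes omega0 * omega1 * (mu0 - mu1)^2 over all bin splits.
    """
    counts, edges = np.histogram(values, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = counts.astype(float)
    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    m = np.cumsum(counts * centers)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = m / w0
        mu1 = (m[-1] - m) / w1
        bcv = w0 * w1 * (mu0 - mu1) ** 2
    bcv[~np.isfinite(bcv)] = -np.inf
    # split after bin i: classes [0..i] and [i+1..]; empty bins between
    # well-separated classes produce an exact-tie plateau — take the first
    # maximizer (lowest threshold), matching the common Otsu convention
    i = int(np.argmax(bcv[:-1]))
    return float(centers[i])


def suggest_threshold(vol: ImageVolume, nbins: int = 256) -> ThresholdDecision:
    """Suggest a global bone threshold for a CT volume.

    The histogram is restricted to intensities strictly above the volume
    median, which discards the air/soft-tissue bulk that would otherwise
    dominate a two-class split, then the exhaustive between-class-variance
    (Otsu) threshold is computed on 256 bins.  Deterministic for a fixed
    input.
    """
    data = vol.voxels.ravel()
    lo, hi = float(data.min()), float(data.max())
    if hi - lo <= 0:
        raise DegenerateInputError("constant volume: no threshold separates two classes")
    median = float(np.median(data))
    upper = data[data > median]
    if upper.size < 2 or float(upper.max()) - float(upper.min()) <= 0:
        upper = data  # median == max: fall back to the full histogram
    t = _between_class_variance_split(np.asarray(upper, dtype=float), nbins)
    return ThresholdDecision(suggested=t, applied=t, method="automatic")


def override_threshold(decision: ThresholdDecision, value: float) -> ThresholdDecision:
    """Record a visually-confirmed manual threshold override."""
    return ThresholdDecision(suggested=decision.suggested, applied=float(value), method="manual-override")


def segment_bone(vol: ImageVolume, decision: ThresholdDecision) -> BinaryMask:
    """Mask of voxels with intensity >= the applied threshold (inclusive)."""
    return BinaryMask(vol.voxels >= decision.applied, vol.spacing, vol.origin)


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def extract_mandible_component(mask: BinaryMask) -> BinaryMask:
    """Keep only the largest 26-connected foreground component.

    Isolates the mandible from other thresholded bone (maxilla, skull
    base) present in a large field of view.
    """
    if mask.count() == 0:
        raise InputError("empty mask: nothing to extract")
    labels, n = ndimage.label(mask.voxels, structure=_STRUCT_26)
    if n == 1:
        return replace(mask, voxels=mask.voxels.copy())
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    return replace(mask, voxels=labels == keep)


def mask_to_mesh(mask: BinaryMask) -> SurfaceMesh:
    """Triangulate the 0.5-isosurface of a binary mask (marching cubes).

    Interior surface sheets (trabecular cavities) are retained; vertices
    are in world mm with consistent outward orientation.
    """
    if mask.count() == 0:
        raise InputError("empty mask: no surface to extract")
    # pad so surfaces at the grid border are closed
    grid = np.pad(mask.voxels.astype(np.float32), 1)
    verts, faces, _, _ = measure.marching_cubes(grid, level=0.5, spacing=mask.spacing)
    verts = verts + np.asarray(mask.origin) - np.asarray(mask.spacing)  # undo pad offset
    return SurfaceMesh(verts, faces[:, ::-1])  # flip winding -> outward normals


def threshold_isosurface(
    vol: ImageVolume, decision: ThresholdDecision, component: BinaryMask | None = None
) -> SurfaceMesh:
    """Triangulate the grayscale isosurface at the applied bone threshold.

    Unlike :func:`mask_to_mesh`, vertices interpolate the intensity
    field and therefore localize the thresholded boundary with sub-voxel
    accuracy — the representation used for surface registration, VOI
    geometry and part-comparison.  ``component`` (e.g. the extracted
    mandible) restricts meshing to its neighbourhood so detached bone is
    left out; the restriction cannot cut the isosurface because the
    component is bounded by sub-threshold voxels.
    """
    grid = np.pad(vol.voxels.astype(np.float32), 1, constant_values=float(vol.voxels.min()))
    mc_mask = None
    if component is not None:
        if component.shape != vol.shape:
            raise GeometryError("component mask must share the volume grid")
        grown = ndimage.binary_dilation(component.voxels, iterations=2)
        mc_mask = np.pad(grown, 1)
        # marching_cubes requires mask borders to be False; padding gives that
    level = float(decision.applied)
    lo, hi = float(grid.min()), float(grid.max())
    if not lo < level < hi:
        raise DegenerateInputError(f"threshold {level} outside intensity range ({lo}, {hi})")
    verts, faces, _, _ = measure.marching_cubes(
        grid, level=level, spacing=vol.spacing, mask=mc_mask
    )
    verts = verts + np.asarray(vol.origin) - np.asarray(vol.spacing)
    return SurfaceMesh(verts, faces[:, ::-1])
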