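"""Volumetric image and surface-mesh I/O plus isotropic resampling.

All geometry in this package lives in one world convention: arrays are
indexed ``(i, j, k)`` along ``(x, y, z)``, voxel *centers* sit at
``world = origin + index * spacing`` (0-based indices, mm), and axis
directions are the identity after reading — oblique acquisitions are
resampled onto an axis-aligned grid at load time.  Meshes are triangle
soups welded into indexed vertex/face arrays, coordinates in mm.

Supported container formats: DICOM series directories, NIfTI
(``.nii``/``.nii.gz``), NRRD, MetaImage for volumes; binary STL for meshes.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import SimpleITK as sitk
import trimesh


class InputError(ValueError):
    """A file is missing, unreadable, or structurally invalid."""


class GeometryError(ValueError):
    """Metadata describes an inconsistent or degenerate geometry."""


# --------------------------------------------------------------------------
# domain types


@dataclass
class ImageVolume:
    """A 3D scalar image on a regular axis-aligned grid.

    Parameters
    ----------
    voxels
        Scalar intensities indexed ``(x, y, z)``.
    spacing
        Per-axis voxel size in mm, strictly positive.
    origin
        World position (mm) of the center of voxel ``(0, 0, 0)``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise GeometryError("voxel array must be a non-empty 3D grid")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def is_isotropic(self, tol: float = 1e-9) -> bool:
        s = self.spacing
        return abs(s[0] - s[1]) <= tol and abs(s[1] - s[2]) <= tol

    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to world mm coordinates."""
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * np.asarray(self.spacing)


@dataclass
class SurfaceMesh:
    """An indexed triangle mesh in world mm.

    ``vertex_attr`` optionally carries one scalar per vertex (e.g. a
    distance map in mm) for colour-coded export.
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_attr: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise GeometryError("face indices out of range")
        if self.vertex_attr is not None:
            self.vertex_attr = np.asarray(self.vertex_attr, dtype=float)
            if self.vertex_attr.shape != (len(self.vertices),):
                raise GeometryError("vertex_attr must have one value per vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of face corner coordinates."""
        return self.vertices[self.faces]

    def edges_unique(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique undirected edges and the number of faces sharing each."""
        e = np.sort(
            np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]),
            axis=1,
        )
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq, counts

    def boundary_edges(self) -> np.ndarray:
        """Edges incident to exactly one face (open boundary)."""
        uniq, counts = self.edges_unique()
        return uniq[counts == 1]


# --------------------------------------------------------------------------
# SimpleITK bridging


def _from_sitk(img: sitk.Image) -> ImageVolume:
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        img = _resample_axis_aligned(img)
    arr = sitk.GetArrayFromImage(img)  # [z, y, x]
    return ImageVolume(
        voxels=np.ascontiguousarray(arr.transpose(2, 1, 0)),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
    )


def _to_sitk(vol: ImageVolume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.voxels.transpose(2, 1, 0)))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    return img


def _resample_axis_aligned(img: sitk.Image) -> sitk.Image:
    """Resample an oblique image onto the axis-aligned bounding grid."""
    size = np.array(img.GetSize())
    corners_idx = np.array([[i, j, k] for i in (0, size[0] - 1) for j in (0, size[1] - 1) for k in (0, size[2] - 1)])
    corners = np.array([img.TransformIndexToPhysicalPoint([int(a), int(b), int(c)]) for a, b, c in corners_idx])
    lo, hi = corners.min(0), corners.max(0)
    spacing = np.array(img.GetSpacing())
    out_size = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 1)
    res = sitk.ResampleImageFilter()
    res.SetOutputSpacing(tuple(spacing))
    res.SetOutputOrigin(tuple(lo))
    res.SetOutputDirection((1.0, 0, 0, 0, 1.0, 0, 0, 0, 1.0))
    res.SetSize([int(s) for s in out_size])
    res.SetInterpolator(sitk.sitkLinear)
    res.SetDefaultPixelValue(float(sitk.GetArrayViewFromImage(img).min()))
    return res.Execute(img)


def _check_dicom_slice_spacing(directory: str, tol: float = 0.01) -> None:
    """Reject DICOM series whose slice gaps vary by more than ``tol`` (1%)."""
    import pydicom

    positions = []
    for name in sorted(os.listdir(directory)):
        path = os.path.join(directory, name)
        try:
            ds = pydicom.dcmread(path, stop_before_pixels=True)
        except Exception:
            continue
        if hasattr(ds, "ImagePositionPatient"):
            positions.append(np.asarray(ds.ImagePositionPatient, dtype=float))
    if len(positions) < 3:
        return
    pos = np.array(sorted(positions, key=lambda p: p[2]))
    gaps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    ref = np.median(gaps)
    bad = np.where(np.abs(gaps - ref) > tol * ref)[0]
    if bad.size:
        i = int(bad[0])
        raise GeometryError(
            f"inconsistent DICOM slice spacing: gap {gaps[i]:.4f} mm between slices "
            f"{i} and {i + 1} deviates from the median gap {ref:.4f} mm by more than {tol:.0%}"
        )


# --------------------------------------------------------------------------
# operations


def read_volume(path: str, format_hint: str | None = None) -> ImageVolume:
    """Read a CT volume from a DICOM series directory or a volume file.

    Intensities are preserved as stored (the format's slope/intercept is
    applied by the reader, nothing else).  Spacing and origin are taken
    from the file metadata.
    """
    if not os.path.exists(path):
        raise InputError(f"no such file or directory: {path}")
    if os.path.isdir(path):
        _check_dicom_slice_spacing(path)
        reader = sitk.ImageSeriesReader()
        files = reader.GetGDCMSeriesFileNames(path)
        if not files:
            raise InputError(f"no DICOM series found in {path}")
        reader.SetFileNames(files)
        img = reader.Execute()
    else:
        try:
            img = sitk.ReadImage(path)
        except RuntimeError as exc:  # pragma: no cover - message passthrough
            raise InputError(f"could not read volume {path}: {exc}") from exc
    return _from_sitk(img)


def write_volume(vol: ImageVolume, path: str) -> None:
    """Write a volume as NIfTI/NRRD/MetaImage, chosen by file extension."""
    sitk.WriteImage(_to_sitk(vol), path)


def resample_isotropic(vol: ImageVolume, target: float) -> ImageVolume:
    """Reslice a volume to isotropic voxels of size ``target`` mm.

    Trilinear interpolation; the world extent is preserved to within one
    voxel and the new grid size is ``ceil(extent / target)`` per axis.
    """
    if target <= 0:
        raise GeometryError("target spacing must be positive")
    if min(np.array(vol.shape) * np.array(vol.spacing)) < target:
        warnings.warn(
            f"target spacing {target} mm exceeds the smallest object dimension", stacklevel=2
        )
    if vol.is_isotropic() and abs(vol.spacing[0] - target) <= 1e-9:
        return replace(vol, voxels=vol.voxels.copy())
    extent = np.array(vol.shape) * np.array(vol.spacing)
    new_size = np.maximum(np.ceil(extent / target - 1e-9).astype(int), 1)
    res = sitk.ResampleImageFilter()
    res.SetOutputSpacing((target, target, target))
    res.SetOutputOrigin(vol.origin)
    res.SetSize([int(s) for s in new_size])
    res.SetInterpolator(sitk.sitkLinear)
    res.SetDefaultPixelValue(float(vol.voxels.min()))
    return _from_sitk(res.Execute(_to_sitk(vol)))


def write_mesh(mesh: SurfaceMesh, path: str) -> None:
    """Write a mesh as binary STL (coordinates in mm)."""
    if mesh.n_faces == 0:
        raise InputError("refusing to write an empty mesh")
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(path, file_type="stl")


def read_mesh(path: str) -> SurfaceMesh:
    """Read a binary STL and weld its triangle soup on exact coordinates."""
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    tm = trimesh.load_mesh(path, process=False)
    if tm.faces.shape[0] == 0:
        raise InputError(f"mesh in {path} has no triangles")
    return weld_vertices(SurfaceMesh(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces)))


def weld_vertices(mesh: SurfaceMesh) -> SurfaceMesh:
    """Merge vertices with bit-identical coordinates and drop degenerate faces."""
    uniq, inverse = np.unique(mesh.vertices, axis=0, return_inverse=True)
    faces = inverse[mesh.faces]
    # drop zero-area (repeated-index) triangles introduced by welding
    ok = (faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2]) & (faces[:, 0] != faces[:, 2])
    return SurfaceMesh(uniq, faces[ok])
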