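"""Shared geometry builders for the test suite."""

from __future__ import annotations

import numpy as np
import trimesh

from condylometry.segmentation import BinaryMask
from condylometry.volume_io import SurfaceMesh


def cube_mesh(size: float = 1.0, center=(0.0, 0.0, 0.0)) -> SurfaceMesh:
    tm = trimesh.creation.box((size, size, size))
    return SurfaceMesh(np.asarray(tm.vertices) + np.asarray(center), np.asarray(tm.faces))


def icosphere_mesh(radius: float = 1.0, center=(0.0, 0.0, 0.0), subdivisions: int = 3) -> SurfaceMesh:
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(np.asarray(tm.vertices) + np.asarray(center), np.asarray(tm.faces))


def grid_surface_mesh(
    nx: int, ny: int, extent: float, height=None, z0: float = 0.0
) -> SurfaceMesh:
    """Open triangulated height-field surface over [0, extent]^2.

    ``height(x, y)`` gives z; defaults to the constant ``z0``.  Normals
    point along +z.
    """
    xs = np.linspace(0.0, extent, nx)
    ys = np.linspace(0.0, extent, ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    Z = np.full_like(X, z0) if height is None else height(X, Y)
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            faces.append([a, b, a + 1])
            faces.append([b, b + 1, a + 1])
    return SurfaceMesh(verts, np.asarray(faces))


def open_cylinder_mesh(radius: float, z0: float, z1: float, n_theta: int = 90, n_z: int = 8) -> SurfaceMesh:
    """Open tube (no caps) around the z axis."""
    thetas = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    zs = np.linspace(z0, z1, n_z)
    verts = np.array(
        [[radius * np.cos(t), radius * np.sin(t), z] for z in zs for t in thetas]
    )
    faces = []
    for i in range(n_z - 1):
        for j in range(n_theta):
            a = i * n_theta + j
            b = i * n_theta + (j + 1) % n_theta
            c = (i + 1) * n_theta + j
            d = (i + 1) * n_theta + (j + 1) % n_theta
            faces.append([a, b, c])
            faces.append([b, d, c])
    return SurfaceMesh(verts, np.asarray(faces))


def ellipsoid_mask(semi, spacing: float, margin: float = 2.0) -> BinaryMask:
    """Digitized solid ellipsoid centered in its grid (voxel-center test)."""
    semi = np.asarray(semi, dtype=float)
    lo = -(semi + margin)
    n = np.ceil(2 * (semi + margin) / spacing).astype(int)
    axes = [lo[i] + np.arange(n[i]) * spacing for i in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    inside = (X / semi[0]) ** 2 + (Y / semi[1]) ** 2 + (Z / semi[2]) ** 2 <= 1.0
    return BinaryMask(inside, (spacing,) * 3, tuple(lo))


def random_triangle_mesh(rng: np.random.Generator, n_faces: int = 12, scale: float = 2.0) -> SurfaceMesh:
    """A random triangle soup (not closed) for brute-force distance oracles."""
    verts = rng.uniform(-scale, scale, (3 * n_faces, 3))
    faces = np.arange(3 * n_faces).reshape(n_faces, 3)
    # reject degenerate triangles by re-drawing tiny-area ones
    tri = verts[faces]
    area = 0.5 * np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    for i in np.flatnonzero(area < 1e-3):
        verts[faces[i, 2]] += rng.uniform(0.5, 1.0, 3)
    return SurfaceMesh(verts, faces)


def brute_force_mesh_distance(points: np.ndarray, mesh: SurfaceMesh) -> np.ndarray:
    """Exhaustive exact point-to-mesh distance (oracle)."""
    from condylometry.meshquery import point_triangle_distance

    tri = mesh.triangles()
    out = np.empty(len(points))
    for i, p in enumerate(points):
        d = point_triangle_distance(np.broadcast_to(p, (len(tri), 3)).copy(), tri)
        out[i] = d.min()
    return out
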