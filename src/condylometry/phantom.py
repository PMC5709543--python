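"""Synthetic mandible phantom with known ground truth.

Generates pre/post CT volume pairs of a stylized hemi-mandible — ramus
plate, coronoid process, sigmoid notch, condylar neck and ellipsoidal
condylar head, wrapped in a soft-tissue envelope — with a high-intensity
cortical shell and a mid-intensity trabecular interior, PSF blur and
additive noise.  Between "pre" and "post" the condylar head is eroded by
a known resorption depth and the whole object is moved by a known rigid
pose delta, so every pipeline stage (segmentation, registration, VOI
selection, quantification) can be checked against exact truth.

All stochastic draws are controlled by the single seed; the anatomy and
labels are deterministic, only the noise differs between seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .registration import LandmarkSet, RigidTransform
from .volume_io import GeometryError, ImageVolume


def _rotation(axis: np.ndarray, deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(deg)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and acquisition parameters of the phantom.

    Defaults emulate a patient-scale ramus imaged with a cone-beam CT
    protocol: 0.4 mm isotropic voxels, a PSF of roughly 0.7 mm FWHM
    (``blur_sigma`` 0.3 mm) and additive noise of SD 80 intensity units
    against a soft-tissue/bone contrast of 150/600/1200.  The condyle is
    sized so that the fitted VOI sphere lands in the anatomically
    observed 14–19 mm radius band.
    """

    spacing: float = 0.4  # mm; 0.1 emulates an ex-vivo high-resolution scan
    seed: int = 0

    # intensities (arbitrary CT units)
    intensity_air: float = 0.0
    intensity_soft: float = 150.0
    intensity_trabecular: float = 600.0
    intensity_cortical: float = 1200.0

    # acquisition
    blur_sigma: float = 0.3  # mm, PSF sigma
    noise_sd: float = 80.0

    # anatomy (mm, world frame of the "pre" scan)
    shell_thickness: float = 1.5
    slab_half_thickness: float = 5.0
    slab_y: tuple[float, float] = (0.0, 40.0)
    slab_top: float = 46.0
    notch_center_y: float = 21.0
    notch_carve_radius: float = 8.0
    notch_carve_z: float = 50.0  # carve bottom = notch_carve_z - notch_carve_radius
    coronoid_apex: tuple[float, float, float] = (0.0, 8.0, 58.0)
    coronoid_base_z: float = 40.0
    coronoid_base_radius: float = 7.0
    neck_center_xy: tuple[float, float] = (0.0, 32.0)
    neck_radius: float = 4.5
    neck_z: tuple[float, float] = (40.0, 54.0)
    head_center: tuple[float, float, float] = (0.0, 33.0, 58.0)
    head_semiaxes: tuple[float, float, float] = (10.0, 9.0, 8.0)
    soft_center: tuple[float, float, float] = (0.0, 22.0, 32.0)
    soft_semiaxes: tuple[float, float, float] = (12.0, 28.0, 38.0)
    include_speck: bool = True
    speck_center: tuple[float, float, float] = (0.0, 43.5, 10.0)
    speck_radius: float = 1.5

    # remodelling and pose difference between pre and post
    resorption_depth: float = 1.0  # mm shaved off each head semi-axis
    pose_rotation_deg: float = 5.0
    pose_rotation_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    pose_translation: tuple[float, float, float] = (2.0, 0.0, 0.0)

    # field of view
    fov_lo: tuple[float, float, float] = (-14.0, -8.0, -8.0)
    fov_hi: tuple[float, float, float] = (14.0, 48.0, 70.0)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise GeometryError("spacing must be positive")
        if self.resorption_depth < 0:
            raise GeometryError("resorption depth must be non-negative")
        if self.resorption_depth >= min(self.head_semiaxes):
            raise GeometryError("resorption depth would consume the whole head")
        if self.shell_thickness >= min(self.head_semiaxes):
            raise GeometryError("cortical shell thicker than the condylar head")

    @property
    def notch_point(self) -> np.ndarray:
        """Lowest point of the sigmoid notch (carve bottom, midline), pre frame."""
        return np.array([0.0, self.notch_center_y, self.notch_carve_z - self.notch_carve_radius])

    @property
    def pose(self) -> RigidTransform:
        return RigidTransform(
            _rotation(np.asarray(self.pose_rotation_axis), self.pose_rotation_deg),
            np.asarray(self.pose_translation, dtype=float),
        )

    def landmarks(self, frame: str = "pre") -> LandmarkSet:
        """True anatomical landmark set (coronoid, ramus, angle, condyle)."""
        pts = {
            "coronoid": (0.0, 8.0, 54.0),
            "ramus": (self.slab_half_thickness, 20.0, 20.0),
            "angle": (0.0, 38.0, 3.0),
            "condyle": self.head_center,
        }
        names = list(pts)
        arr = np.array([pts[n] for n in names], dtype=float)
        if frame == "post":
            arr = self.pose.apply(arr)
        elif frame != "pre":
            raise ValueError(f"unknown frame {frame!r}")
        return LandmarkSet(names, arr, side="left")


# label codes
AIR, SOFT, TRABECULAR, CORTICAL = 0, 1, 2, 3


@dataclass
class PhantomTruth:
    """Exact ground truth accompanying one generated pre/post pair."""

    spec: PhantomSpec
    pre_label: np.ndarray
    post_label: np.ndarray
    spacing: float
    origin: tuple[float, float, float]
    transform: RigidTransform  # maps pre-frame coordinates onto post-frame
    landmarks_pre: LandmarkSet
    landmarks_post: LandmarkSet
    notch_point_pre: np.ndarray
    sphere_center_pre: np.ndarray
    sphere_radius: float
    pre_condylar_voxels: int
    post_condylar_voxels: int

    @property
    def pre_condylar_volume(self) -> float:
        return self.pre_condylar_voxels * self.spacing**3

    @property
    def post_condylar_volume(self) -> float:
        return self.post_condylar_voxels * self.spacing**3

    @property
    def percent_change(self) -> float:
        return 100.0 * (self.post_condylar_volume - self.pre_condylar_volume) / self.pre_condylar_volume


# --------------------------------------------------------------------------
# constructive solid geometry


def _sdf_box(X, Y, Z, lo, hi):
    """Signed distance to an axis-aligned box (negative inside)."""
    qx = np.maximum(lo[0] - X, X - hi[0])
    qy = np.maximum(lo[1] - Y, Y - hi[1])
    qz = np.maximum(lo[2] - Z, Z - hi[2])
    inside = np.minimum(np.maximum(qx, np.maximum(qy, qz)), 0.0)
    ox = np.maximum(qx, 0.0)
    oy = np.maximum(qy, 0.0)
    oz = np.maximum(qz, 0.0)
    return np.sqrt(ox * ox + oy * oy + oz * oz) + inside


def _sdf_ellipsoid(X, Y, Z, center, semi):
    """Approximate ellipsoid signed distance (exact for spheres).

    ``r (1 - 1/k)`` with ``k`` the normalized radius — accurate for the
    mildly eccentric shapes used here.
    """
    dx, dy, dz = X - center[0], Y - center[1], Z - center[2]
    r = np.sqrt(dx * dx + dy * dy + dz * dz)
    k = np.sqrt((dx / semi[0]) ** 2 + (dy / semi[1]) ** 2 + (dz / semi[2]) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(k > 0, r * (1.0 - 1.0 / np.maximum(k, 1e-12)), -float(min(semi)))
    return out


def _bone_sdf(
    spec: PhantomSpec, X: np.ndarray, Y: np.ndarray, Z: np.ndarray, erosion: float
) -> tuple[np.ndarray, np.ndarray]:
    """(signed distance of mineralized solid, head-region bool) at pre-frame coords.

    Signed distances make the rendering sub-voxel accurate: boundary
    voxels get partial-volume occupancy instead of an inclusion test, so
    flat faces that happen to align with the sampling lattice are not
    quantized by half a voxel.
    """
    slab_box = _sdf_box(
        X, Y, Z,
        (-spec.slab_half_thickness, spec.slab_y[0], 0.0),
        (spec.slab_half_thickness, spec.slab_y[1], spec.slab_top),
    )
    carve = (
        np.sqrt((Y - spec.notch_center_y) ** 2 + (Z - spec.notch_carve_z) ** 2)
        - spec.notch_carve_radius
    )
    slab = np.maximum(slab_box, -carve)

    ax, ay, az = spec.coronoid_apex
    h = az - spec.coronoid_base_z
    cos_half = h / np.hypot(h, spec.coronoid_base_radius)
    radial = np.sqrt((X - ax) ** 2 + (Y - ay) ** 2)
    side = (radial - spec.coronoid_base_radius * (az - Z) / h) * cos_half
    coronoid = np.maximum(side, spec.coronoid_base_z - Z)

    nx, ny = spec.neck_center_xy
    neck_side = np.sqrt((X - nx) ** 2 + (Y - ny) ** 2) - spec.neck_radius
    neck = np.maximum(neck_side, np.maximum(spec.neck_z[0] - Z, Z - spec.neck_z[1]))

    semi = np.asarray(spec.head_semiaxes) - erosion
    head = _sdf_ellipsoid(X, Y, Z, spec.head_center, semi)

    bone = np.minimum(np.minimum(slab, coronoid), np.minimum(neck, head))
    if spec.include_speck:
        sc = np.asarray(spec.speck_center)
        speck = (
            np.sqrt((X - sc[0]) ** 2 + (Y - sc[1]) ** 2 + (Z - sc[2]) ** 2)
            - spec.speck_radius
        )
        bone = np.minimum(bone, speck)

    # the condylar-head region label is defined on the un-eroded anatomy
    head0 = _sdf_ellipsoid(X, Y, Z, spec.head_center, np.asarray(spec.head_semiaxes))
    head_region = (head0 <= 0) | (neck <= 0)
    return bone, head_region


def _label_grid(
    spec: PhantomSpec,
    origin: np.ndarray,
    shape: tuple[int, int, int],
    spacing: float,
    transform: RigidTransform | None = None,
    erosion: float = 0.0,
    chunk: int = 64,
    with_intensity: bool = False,
):
    """Render (label, head_region[, intensity]) grids; ``transform`` poses the anatomy.

    Voxel centers in the grid frame are pulled back through the inverse
    pose before evaluating the pre-frame solid geometry (a rigid motion
    preserves signed distances).  Labels are center-in-solid binary; the
    intensity rendering uses signed-distance partial-volume occupancy of
    boundary voxels, mimicking the partial-volume averaging of real CT.
    Evaluation is chunked along z to bound memory on fine grids.
    """
    nxs, nys, nzs = shape
    xs = origin[0] + np.arange(nxs) * spacing
    ys = origin[1] + np.arange(nys) * spacing
    zs = origin[2] + np.arange(nzs) * spacing
    inv = transform.inverse() if transform is not None else None
    mineral = np.empty(shape, dtype=bool)
    head_region = np.empty(shape, dtype=bool)
    soft = np.empty(shape, dtype=bool)
    if with_intensity:
        f_min = np.empty(shape, dtype=np.float64)
        f_soft = np.empty(shape, dtype=np.float64)
    for k0 in range(0, nzs, chunk):
        k1 = min(k0 + chunk, nzs)
        X, Y, Z = np.meshgrid(xs, ys, zs[k0:k1], indexing="ij")
        if inv is not None:
            pts = np.stack([X, Y, Z], axis=-1) @ inv.rotation.T + inv.translation
            X, Y, Z = pts[..., 0], pts[..., 1], pts[..., 2]
        sdf_bone, hreg = _bone_sdf(spec, X, Y, Z, erosion)
        sdf_soft = _sdf_ellipsoid(X, Y, Z, spec.soft_center, spec.soft_semiaxes)
        mineral[:, :, k0:k1] = sdf_bone <= 0
        head_region[:, :, k0:k1] = hreg
        soft[:, :, k0:k1] = sdf_soft <= 0
        if with_intensity:
            fm = np.clip(0.5 - sdf_bone / spacing, 0.0, 1.0)
            f_min[:, :, k0:k1] = fm
            f_soft[:, :, k0:k1] = np.clip(0.5 - sdf_soft / spacing, 0.0, 1.0) * (1.0 - fm)
    # cortical shell: morphological boundary layer of the mineralized solid
    interior = ndimage.distance_transform_edt(mineral, sampling=spacing) > spec.shell_thickness
    label = np.full(shape, AIR, dtype=np.uint8)
    label[soft & ~mineral] = SOFT
    label[mineral & interior] = TRABECULAR
    label[mineral & ~interior] = CORTICAL
    if not with_intensity:
        return label, head_region
    bone_value = np.where(interior, spec.intensity_trabecular, spec.intensity_cortical)
    intensity = (
        spec.intensity_air
        + (spec.intensity_soft - spec.intensity_air) * f_soft
        + (bone_value - spec.intensity_air) * f_min
    )
    return label, head_region, intensity


def _truth_sphere(
    spec: PhantomSpec, label: np.ndarray, origin: np.ndarray, spacing: float
) -> tuple[np.ndarray, float]:
    """Minimal condyle-enclosing sphere pinned at the true notch point.

    Computed directly from the pre-frame label grid: mineralized voxels
    more than one voxel above the notch plane, component containing the
    head center, then the pinned-sphere direction optimization.
    """
    from .voi import _min_radius_for_direction  # geometric subroutine
    from scipy import optimize

    n = spec.notch_point
    mineral = label >= TRABECULAR
    k_cut = int(np.ceil((n[2] + spacing - origin[2]) / spacing))
    above = np.zeros_like(mineral)
    above[:, :, k_cut:] = mineral[:, :, k_cut:]
    lab, _ = ndimage.label(above, structure=np.ones((3, 3, 3)))
    seed_idx = np.round((np.asarray(spec.head_center) - origin) / spacing).astype(int)
    comp = lab[tuple(seed_idx)]
    if comp == 0:
        raise GeometryError("head center voxel is not mineralized; check the phantom geometry")
    coords = origin + np.argwhere(lab == comp) * spacing
    rel = coords - n
    norm2 = np.sum(rel * rel, axis=1)

    def unpack(angles):
        t, p = angles
        return np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])

    def obj(angles):
        return _min_radius_for_direction(unpack(angles), rel, norm2)

    v0 = np.asarray(spec.head_center) - n
    v0 = v0 / np.linalg.norm(v0)
    x0 = np.array([np.arccos(np.clip(v0[2], -1, 1)), np.arctan2(v0[1], v0[0])])
    res = optimize.minimize(obj, x0, method="Nelder-Mead",
                            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 2000})
    r = float(res.fun)
    center = n + r * unpack(res.x)
    return center, r


def _count_in_sphere(
    label: np.ndarray, origin: np.ndarray, spacing: float, center: np.ndarray, radius: float
) -> int:
    shape = label.shape
    ax = [(origin[i] + np.arange(shape[i]) * spacing - center[i]) ** 2 for i in range(3)]
    d2 = ax[0][:, None, None] + ax[1][None, :, None] + ax[2][None, None, :]
    return int(np.sum((label >= TRABECULAR) & (d2 <= radius**2)))


def generate_phantom(
    spec: PhantomSpec, render: bool = True
) -> tuple[ImageVolume | None, ImageVolume | None, PhantomTruth]:
    """Generate the pre/post volume pair and its ground truth.

    ``render=False`` skips blur/noise rendering and returns only the
    truth (label grids, sphere, counts) — useful for calibrating the
    resorption depth.
    """
    origin = np.asarray(spec.fov_lo, dtype=float)
    extent = np.asarray(spec.fov_hi) - origin
    shape = tuple(int(np.ceil(e / spec.spacing)) for e in extent)

    pre_label, _, pre_int = _label_grid(spec, origin, shape, spec.spacing, with_intensity=True)
    post_label, _, post_int = _label_grid(
        spec, origin, shape, spec.spacing, transform=spec.pose,
        erosion=spec.resorption_depth, with_intensity=True,
    )
    center, radius = _truth_sphere(spec, pre_label, origin, spec.spacing)
    pose = spec.pose
    pre_count = _count_in_sphere(pre_label, origin, spec.spacing, center, radius)
    post_count = _count_in_sphere(post_label, origin, spec.spacing, pose.apply(center), radius)

    truth = PhantomTruth(
        spec=spec,
        pre_label=pre_label,
        post_label=post_label,
        spacing=spec.spacing,
        origin=tuple(origin),
        transform=pose,
        landmarks_pre=spec.landmarks("pre"),
        landmarks_post=spec.landmarks("post"),
        notch_point_pre=spec.notch_point,
        sphere_center_pre=center,
        sphere_radius=radius,
        pre_condylar_voxels=pre_count,
        post_condylar_voxels=post_count,
    )
    if not render:
        return None, None, truth

    rng = np.random.default_rng(spec.seed)
    volumes = []
    for img in (pre_int, post_int):
        if spec.noise_sd > 0:
            # noise enters before the PSF: reconstructed CT noise is
            # correlated at the resolution scale, not voxel-independent
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        if spec.blur_sigma > 0:
            img = ndimage.gaussian_filter(img, sigma=spec.blur_sigma / spec.spacing)
        volumes.append(ImageVolume(img, (spec.spacing,) * 3, tuple(origin)))
    return volumes[0], volumes[1], truth


def truth_volume_at_spacing(
    spec: PhantomSpec,
    spacing: float,
    region_lo: tuple[float, float, float] | None = None,
    region_hi: tuple[float, float, float] | None = None,
    erosion: float = 0.0,
) -> float:
    """Mineralized truth volume (mm^3) rendered at an arbitrary spacing.

    Evaluates the analytic anatomy on a fresh grid — used to check that
    coarse and fine renderings of the same truth agree up to
    voxelization, emulating a high-resolution gold-standard scan of the
    condylar region (``region_lo/hi`` crop the field of view).
    """
    lo = np.asarray(region_lo if region_lo is not None else spec.fov_lo, dtype=float)
    hi = np.asarray(region_hi if region_hi is not None else spec.fov_hi, dtype=float)
    sub = replace(spec, spacing=spacing, fov_lo=tuple(lo), fov_hi=tuple(hi))
    shape = tuple(int(np.ceil(e / spacing)) for e in (hi - lo))
    label, _ = _label_grid(sub, lo, shape, spacing, erosion=erosion)
    return float(np.sum(label >= TRABECULAR)) * spacing**3


@dataclass
class RecoveryReport:
    """End-to-end pipeline recovery versus phantom ground truth."""

    rotation_error_deg: float
    translation_error_mm: float  # mean displacement of the registered ramus region
    notch_error_mm: float  # sagittal-plane distance to the analytic notch
    # groove surface: along a shallow groove the exact lowest point is
    # weakly identified, but the detected point must lie ON the groove
    sphere_radius_mm: float
    truth_sphere_radius_mm: float
    measured_pre_mm3: float
    measured_post_mm3: float
    measured_percent_change: float
    truth_percent_change: float

    @property
    def percent_change_error(self) -> float:
        return self.measured_percent_change - self.truth_percent_change

    def to_dict(self) -> dict:
        d = {k: float(getattr(self, k)) for k in (
            "rotation_error_deg", "translation_error_mm", "notch_error_mm",
            "sphere_radius_mm", "truth_sphere_radius_mm",
            "measured_pre_mm3", "measured_post_mm3",
            "measured_percent_change", "truth_percent_change",
        )}
        d["percent_change_error"] = float(self.percent_change_error)
        return d


def end_to_end_truth_check(
    spec: PhantomSpec,
    workdir: str | None = None,
    landmark_jitter_sd: float = 0.5,
) -> RecoveryReport:
    """Run the full paired pipeline on a generated phantom and score it.

    The phantom pair is written to disk (NIfTI volumes, JSON landmarks)
    and analysed through the standard file-based pipeline, so the check
    exercises I/O as well.  Landmarks are jittered with isotropic
    Gaussian noise of SD ``landmark_jitter_sd`` mm (independently per
    time point), emulating observer placement error; the jitter draw is
    seeded from the phantom seed.
    """
    import tempfile

    from . import pipeline as pl
    from . import volume_io
    from .registration import LandmarkSet

    pre, post, truth = generate_phantom(spec)
    rng = np.random.default_rng([spec.seed, 917])

    def jitter(lm: LandmarkSet) -> LandmarkSet:
        return LandmarkSet(
            list(lm.names), lm.points + rng.normal(0.0, landmark_jitter_sd, lm.points.shape), lm.side
        )

    with tempfile.TemporaryDirectory() as tmp:
        base = workdir or tmp
        paths = {
            "pre_volume": f"{base}/pre.nii",
            "post_volume": f"{base}/post.nii",
            "pre_landmarks": f"{base}/pre_landmarks.json",
            "post_landmarks": f"{base}/post_landmarks.json",
        }
        volume_io.write_volume(pre, paths["pre_volume"])
        volume_io.write_volume(post, paths["post_volume"])
        pl.save_landmarks(jitter(truth.landmarks_pre), paths["pre_landmarks"])
        pl.save_landmarks(jitter(truth.landmarks_post), paths["post_landmarks"])
        config = pl.RunConfig(
            **paths, case_id=f"phantom-{spec.seed}", side="left",
            working_spacing=spec.spacing, seed=spec.seed,
        )
        result = pl.run_paired(config)

    err = result.transform.compose(truth.transform.inverse())
    # displacement measured at the object: sample points on the truth anatomy
    probe = truth.landmarks_post.points
    disp = np.linalg.norm(err.apply(probe) - probe, axis=1)
    notch_meas = np.asarray(result.run_report["voi"]["notch_point"])
    # distance to the carve (groove) surface in the sagittal projection
    carve_yz = np.array([spec.notch_center_y, spec.notch_carve_z])
    notch_err = float(
        abs(np.linalg.norm(notch_meas[1:] - carve_yz) - spec.notch_carve_radius)
    )
    rep = result.report
    return RecoveryReport(
        rotation_error_deg=err.rotation_angle_deg(),
        translation_error_mm=float(disp.mean()),
        notch_error_mm=notch_err,
        sphere_radius_mm=float(rep.voi.radius),
        truth_sphere_radius_mm=float(truth.sphere_radius),
        measured_pre_mm3=rep.pre_volume,
        measured_post_mm3=rep.post_volume,
        measured_percent_change=rep.percent_change,
        truth_percent_change=truth.percent_change,
    )


def calibrate_resorption_depth(
    spec: PhantomSpec, target_percent_loss: float, tol: float = 0.05, max_iter: int = 30
) -> float:
    """Resorption depth producing a given truth percent loss, by bisection.

    The loss is measured exactly as the truth reports it: mineralized
    voxels inside the truth sphere, pre versus post (pose excluded —
    the count is pose-invariant up to voxelization).
    """
    if not 0 < target_percent_loss < 100:
        raise ValueError("target loss must be in (0, 100) percent")

    # pose excluded: render pre once, re-render only the eroded anatomy
    origin = np.asarray(spec.fov_lo, dtype=float)
    shape = tuple(int(np.ceil(e / spec.spacing)) for e in (np.asarray(spec.fov_hi) - origin))
    pre_label, _ = _label_grid(spec, origin, shape, spec.spacing)
    center, radius = _truth_sphere(spec, pre_label, origin, spec.spacing)
    pre_count = _count_in_sphere(pre_label, origin, spec.spacing, center, radius)

    def loss(depth: float) -> float:
        post_label, _ = _label_grid(spec, origin, shape, spec.spacing, erosion=depth)
        post_count = _count_in_sphere(post_label, origin, spec.spacing, center, radius)
        return 100.0 * (pre_count - post_count) / pre_count

    lo, hi = 0.0, min(spec.head_semiaxes) * 0.8
    f_hi = loss(hi)
    if f_hi < target_percent_loss:
        raise GeometryError(f"target loss {target_percent_loss}% unreachable (max {f_hi:.1f}%)")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f = loss(mid)
        if abs(f - target_percent_loss) <= tol:
            return mid
        if f < target_percent_loss:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
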