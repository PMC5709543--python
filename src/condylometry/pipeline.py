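"""End-to-end orchestration of the paired condylar-remodelling analysis.

The paired workflow: read both volumes → reslice to the isotropic working
resolution → global-threshold segmentation (automatic suggestion,
optional override) → largest-component extraction → surface rendering →
landmark-initialized ICP registration restricted to the ramus/coronoid →
sigmoid-notch detection → condylar sphere VOI (fitted once, on the
preoperative surface, and rigidly transferred) → sphere cropping →
mineralized volume quantification per time point.

Every stage's parameters and key outputs are logged into a versioned
JSON report; a rerun with identical config and seed is bit-identical.
"""

from __future__ import annotations

import json
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from . import metrics, quantify, reliability_stats, segmentation, voi, volume_io
from .registration import (
    LandmarkSet,
    RigidTransform,
    define_ramus_region,
    icp_refine,
    landmark_align,
)

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration of one paired run (one side of one case)."""

    pre_volume: str
    post_volume: str
    pre_landmarks: str
    post_landmarks: str
    case_id: str = "case"
    side: str = "left"
    working_spacing: float = 0.4  # mm
    threshold_pre: float | None = None  # manual overrides; None = automatic
    threshold_post: float | None = None
    icp_radius: float = 15.0  # landmark-ball radius of the fitting region, mm
    icp_max_iter: int = 100
    icp_tol: float = 1e-4
    sphere_plane_offset_voxels: float = 1.0
    # manual sphere centring (observer choice); None = automatic minimal fit
    sphere_center_override: tuple[float, float, float] | None = None
    output_dir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        missing = [
            p
            for p in (self.pre_volume, self.post_volume, self.pre_landmarks, self.post_landmarks)
            if not os.path.exists(p)
        ]
        if missing:
            raise volume_io.InputError(f"missing input file(s): {missing}")
        if self.working_spacing <= 0:
            raise volume_io.GeometryError("working spacing must be positive")


def load_landmarks(path: str) -> LandmarkSet:
    with open(path) as f:
        return LandmarkSet.from_dict(json.load(f))


def save_landmarks(lm: LandmarkSet, path: str) -> None:
    with open(path, "w") as f:
        json.dump(lm.to_dict(), f, indent=1)


@dataclass
class _Stage:
    name: str
    seconds: float
    info: dict = field(default_factory=dict)


class _Log:
    def __init__(self) -> None:
        self.stages: list[_Stage] = []
        self._t0 = time.perf_counter()

    def stage(self, name: str, **info) -> None:
        t = time.perf_counter()
        self.stages.append(_Stage(name, round(t - self._t0, 3), info))
        self._t0 = t

    def to_list(self) -> list[dict]:
        return [asdict(s) for s in self.stages]


@dataclass
class PairedResult:
    report: quantify.CondyleReport
    voi_fixed_frame: voi.SphereVOI
    transform: RigidTransform
    run_report: dict


def _prepare_side(vol: volume_io.ImageVolume, spacing: float, threshold: float | None):
    """Reslice, threshold, extract mandible, mesh. Returns working objects."""
    iso = volume_io.resample_isotropic(vol, spacing)
    decision = segmentation.suggest_threshold(iso)
    if threshold is not None:
        decision = segmentation.override_threshold(decision, threshold)
    mask = segmentation.segment_bone(iso, decision)
    comp = segmentation.extract_mandible_component(mask)
    mesh = segmentation.threshold_isosurface(iso, decision, comp)
    return iso, decision, comp, mesh


def run_paired(config: RunConfig) -> PairedResult:
    """Execute the full paired analysis for one condyle side.

    Deterministic for a fixed config; the preoperative frame is moving,
    the postoperative frame fixed, and the sphere VOI is fitted once on
    the preoperative surface (which contains the postoperative condyle
    in the presence of resorption) and transferred rigidly.
    """
    config.validate()
    log = _Log()

    pre_vol = volume_io.read_volume(config.pre_volume)
    post_vol = volume_io.read_volume(config.post_volume)
    lm_pre = load_landmarks(config.pre_landmarks)
    lm_post = load_landmarks(config.post_landmarks)
    log.stage("read", pre_shape=pre_vol.shape, post_shape=post_vol.shape)

    pre_iso, dec_pre, comp_pre, mesh_pre = _prepare_side(
        pre_vol, config.working_spacing, config.threshold_pre
    )
    post_iso, dec_post, comp_post, mesh_post = _prepare_side(
        post_vol, config.working_spacing, config.threshold_post
    )
    log.stage(
        "segment",
        threshold_pre=dec_pre.applied,
        threshold_post=dec_post.applied,
        method_pre=dec_pre.method,
        method_post=dec_post.method,
        pre_voxels=comp_pre.count(),
        post_voxels=comp_post.count(),
    )

    init = landmark_align(lm_pre, lm_post)
    region = define_ramus_region(mesh_pre, lm_pre, radius=config.icp_radius)
    icp = icp_refine(
        mesh_pre,
        mesh_post,
        init=init,
        region=region,
        tol=config.icp_tol,
        max_iter=config.icp_max_iter,
    )
    T = icp.transform  # pre -> post
    log.stage(
        "register",
        region_vertices=int(region.sum()),
        icp_iterations=len(icp.rms_history),
        icp_rms_mm=icp.rms,
        converged=icp.converged,
    )

    plane_offset = config.sphere_plane_offset_voxels * config.working_spacing
    notch_pre = voi.lowest_notch_point(mesh_pre, lm_pre)
    voi_pre = voi.fit_condylar_sphere(
        mesh_pre,
        notch_pre,
        lm_pre.get("condyle"),
        side=config.side,
        plane_offset=plane_offset,
        center_override=(
            np.asarray(config.sphere_center_override, dtype=float)
            if config.sphere_center_override is not None
            else None
        ),
    )
    voi_post = voi.transfer_voi(voi_pre, T)
    log.stage("voi", radius_mm=voi_pre.radius, notch=[float(x) for x in notch_pre])

    pre_crop = voi.crop_to_sphere(comp_pre, voi_pre)
    post_crop = voi.crop_to_sphere(comp_post, voi_post)
    v_pre = quantify.mask_volume(pre_crop)
    v_post = quantify.mask_volume(post_crop)
    log.stage("quantify", pre_mm3=v_pre, post_mm3=v_post)

    report = quantify.CondyleReport(
        case_id=config.case_id,
        side=config.side,
        pre_volume=v_pre,
        post_volume=v_post,
        voi=voi_pre,
        threshold_pre=dec_pre.applied,
        threshold_post=dec_post.applied,
        transform=T,
    )
    run_report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": asdict(config),
        "stages": log.to_list(),
        "threshold": {
            "pre": {"suggested": dec_pre.suggested, "applied": dec_pre.applied, "method": dec_pre.method},
            "post": {"suggested": dec_post.suggested, "applied": dec_post.applied, "method": dec_post.method},
        },
        "transform_pre_to_post": T.matrix().tolist(),
        "voi": voi_pre.to_dict(),
        "result": report.to_row(),
    }
    if config.output_dir:
        os.makedirs(config.output_dir, exist_ok=True)
        with open(os.path.join(config.output_dir, "report.json"), "w") as f:
            json.dump(run_report, f, indent=1, sort_keys=True)
    return PairedResult(report, voi_post, T, run_report)


# --------------------------------------------------------------------------
# reproducibility mode (two observers / two occasions over the same scans)


def run_reproducibility(config_a: RunConfig, config_b: RunConfig) -> dict:
    """Observer-discrepancy analysis between two configurations.

    Both configs must reference the same volumes and may differ in
    threshold overrides and/or landmark files (observer choices).
    Reports the three discrepancy measurements on the preoperative
    frame: condylar volume (mm^3), VOI selection (mean distance between
    the cropped models' lower borders, mm) and segmentation (mean
    part-comparison distance after restriction to the common VOI, mm).
    """
    if config_a.pre_volume != config_b.pre_volume:
        raise volume_io.InputError("reproducibility configs must share the same volumes")
    res_a = run_paired(config_a)
    res_b = run_paired(config_b)

    pre_vol = volume_io.read_volume(config_a.pre_volume)

    def pre_side(cfg: RunConfig):
        iso, dec, comp, mesh = _prepare_side(pre_vol, cfg.working_spacing, cfg.threshold_pre)
        return iso, dec, comp, mesh

    _, dec_a, comp_a, mesh_a = pre_side(config_a)
    _, dec_b, comp_b, mesh_b = pre_side(config_b)
    voi_a = res_a.report.voi
    voi_b = res_b.report.voi

    volume_discrepancy = abs(res_a.report.pre_volume - res_b.report.pre_volume)

    # VOI selection: distance between the lower borders of the cropped surfaces
    crop_mesh_a = _crop_mesh_to_sphere(mesh_a, voi_a)
    crop_mesh_b = _crop_mesh_to_sphere(mesh_b, voi_b)
    border_a = metrics.extract_lower_border(crop_mesh_a)
    border_b = metrics.extract_lower_border(crop_mesh_b)
    voi_discrepancy = metrics.distance_to_curve(border_a, border_b).mean

    # segmentation: part comparison after removing the VOI mismatch
    sub_a, sub_b = metrics.subtract_voi_mismatch(comp_a, voi_a, comp_b, voi_b)
    seg_mesh_a = segmentation.mask_to_mesh(sub_a)
    seg_mesh_b = segmentation.mask_to_mesh(sub_b)
    seg_discrepancy = metrics.part_comparison(seg_mesh_a, seg_mesh_b).mean

    return {
        "volume_mm3": {"a": res_a.report.pre_volume, "b": res_b.report.pre_volume,
                       "abs_discrepancy": volume_discrepancy},
        "voi_mm": voi_discrepancy,
        "segmentation_mm": seg_discrepancy,
        "thresholds": {"a": dec_a.applied, "b": dec_b.applied},
        "voi_radii_mm": {"a": voi_a.radius, "b": voi_b.radius},
    }


def _crop_mesh_to_sphere(mesh: volume_io.SurfaceMesh, sphere: voi.SphereVOI):
    """Keep faces whose vertices all lie inside the sphere (open crop)."""
    inside = sphere.contains(mesh.vertices)
    keep = inside[mesh.faces].all(axis=1)
    faces = mesh.faces[keep]
    used = np.unique(faces)
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return volume_io.SurfaceMesh(mesh.vertices[used], remap[faces])


def icc_over_cases(volumes_a: list[float], volumes_b: list[float]) -> float:
    """Two-way mixed single-measures consistency ICC over a case batch."""
    table = reliability_stats.RatingTable(np.column_stack([volumes_a, volumes_b]))
    return reliability_stats.icc_consistency(table)
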