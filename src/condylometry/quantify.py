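"""Mineralized condylar bone volume and pre/post remodelling summaries."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .registration import RigidTransform
from .segmentation import BinaryMask
from .volume_io import GeometryError, SurfaceMesh
from .voi import SphereVOI


def mask_volume(mask: BinaryMask) -> float:
    """Foreground voxel count times voxel volume, in mm^3.

    Requires an isotropic mask (reslice first): the working resolution is
    part of the measurement definition.
    """
    if not mask.is_isotropic(tol=1e-9):
        raise GeometryError(f"mask is anisotropic {mask.spacing}: reslice to isotropic first")
    return mask.count() * mask.voxel_volume()


def mesh_volume(mesh: SurfaceMesh) -> float:
    """Enclosed volume of a closed oriented mesh by the divergence theorem.

    Sums signed tetrahedron volumes against the origin; inner cavity
    sheets wound opposite to the outer surface subtract, so a hollow
    shell reports its mineralized (material) volume.  The absolute value
    is returned, making the result independent of global winding.
    """
    edges, counts = mesh.edges_unique()
    n_boundary = int((counts == 1).sum())
    if n_boundary or (counts > 2).any():
        raise GeometryError(
            f"mesh is not closed-manifold: {n_boundary} boundary edges, "
            f"{int((counts > 2).sum())} over-shared edges"
        )
    tri = mesh.triangles()
    signed = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0
    return float(abs(signed.sum()))


@dataclass
class CondyleReport:
    """Per-condyle paired measurement record."""

    case_id: str
    side: str
    pre_volume: float
    post_volume: float
    voi: SphereVOI | None = None
    threshold_pre: float | None = None
    threshold_post: float | None = None
    transform: RigidTransform | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pre_volume <= 0:
            raise GeometryError("preoperative volume must be positive")

    @property
    def absolute_change(self) -> float:
        """Post minus pre, mm^3 (negative = loss)."""
        return self.post_volume - self.pre_volume

    @property
    def percent_change(self) -> float:
        """100 * (post - pre) / pre (negative = loss)."""
        return 100.0 * (self.post_volume - self.pre_volume) / self.pre_volume

    def to_row(self) -> dict:
        row = {
            "case_id": self.case_id,
            "side": self.side,
            "pre_volume_mm3": self.pre_volume,
            "post_volume_mm3": self.post_volume,
            "absolute_change_mm3": self.absolute_change,
            "percent_change": self.percent_change,
            "threshold_pre": self.threshold_pre,
            "threshold_post": self.threshold_post,
        }
        if self.voi is not None:
            row["voi_radius_mm"] = float(self.voi.radius)
        return row


def _mean_sd(x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    if len(x) == 1:
        return float(x[0]), 0.0
    return float(x.mean()), float(x.std(ddof=1))


def remodelling_summary(reports: list[CondyleReport]) -> dict:
    """Cohort summary: per-side and pooled mean ± sample SD of the percent
    and absolute change, per-patient left–right asymmetry, and loss/gain
    counts.  SD is reported as 0 with an ``n=1`` flag for singletons."""
    if not reports:
        raise ValueError("need at least one report")
    df = pd.DataFrame([r.to_row() for r in reports])

    def block(sub: pd.DataFrame) -> dict:
        pm, ps = _mean_sd(sub["percent_change"].to_numpy())
        am, asd = _mean_sd(sub["absolute_change_mm3"].to_numpy())
        return {
            "n": int(len(sub)),
            "percent_change_mean": pm,
            "percent_change_sd": ps,
            "absolute_change_mean_mm3": am,
            "absolute_change_sd_mm3": asd,
            "sd_undefined": len(sub) == 1,
        }

    out = {"pooled": block(df), "per_side": {s: block(g) for s, g in df.groupby("side")}}
    out["n_loss"] = int((df["absolute_change_mm3"] < 0).sum())
    out["n_gain"] = int((df["absolute_change_mm3"] > 0).sum())

    asym = []
    for case, g in df.groupby("case_id"):
        sides = {s: g[g["side"] == s]["percent_change"].mean() for s in g["side"].unique()}
        if "left" in sides and "right" in sides:
            asym.append({"case_id": case, "asymmetry_pct": abs(sides["left"] - sides["right"])})
    if asym:
        vals = np.array([a["asymmetry_pct"] for a in asym])
        m, s = _mean_sd(vals)
        out["left_right_asymmetry"] = {"per_case": asym, "mean": m, "sd": s}
    return out


def reports_to_csv(reports: list[CondyleReport], path: str) -> None:
    pd.DataFrame([r.to_row() for r in reports]).to_csv(path, index=False)
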