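"""Optic-disc ellipse fitting and peripapillary ROI placement.

The optic-disc margin is delineated manually (clicked points on a choroidal
slab, loaded from CSV) and approximated by a least-squares ellipse.  Five
~2x2 degree regions of interest (superior, superotemporal, temporal,
inferotemporal, inferior) are placed radially around the disc, each with
one degree of clearance between the disc boundary and the ROI's near edge.
Within each ROI, intercapillary distance is sampled with a narrow
0.1 x 1 degree box whose long axis runs perpendicular to the expected
(radial) vessel direction.

Angles follow the ophthalmic convention for a right eye (OD): 0 deg points
temporally (+col), 90 deg superiorly (-row); for a left eye (OS) the layout
is mirrored horizontally.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.measure import EllipseModel

from .scale import ScaleModel

__all__ = [
    "DiscEllipse",
    "ROISpec",
    "SamplingBox",
    "ROI_ANGLES_OD",
    "fit_ellipse",
    "place_rois",
    "icd_sampling_box",
    "read_margin_points",
]

ROI_LABELS = ("S", "ST", "T", "IT", "I")
ROI_ANGLES_OD = {"S": 90.0, "ST": 45.0, "T": 0.0, "IT": -45.0, "I": -90.0}


def _direction(angle_deg: float) -> np.ndarray:
    """(row, col) unit vector for an ophthalmic angle (0=temporal, 90=up)."""
    t = np.radians(angle_deg)
    return np.array([-np.sin(t), np.cos(t)])


@dataclass(frozen=True)
class DiscEllipse:
    """Elliptical approximation of the optic-disc margin."""

    center_px: tuple[float, float]  # (row, col)
    semi_axes_px: tuple[float, float]  # (a, b) with a >= b
    tilt_deg: float  # major-axis angle, ophthalmic convention
    rms_residual_px: float = 0.0

    def __post_init__(self) -> None:
        a, b = self.semi_axes_px
        if not (a >= b > 0):
            raise ValueError("semi axes must satisfy a >= b > 0")

    def radius_at(self, angle_deg: float) -> float:
        """Centre-to-boundary distance along an ophthalmic direction."""
        a, b = self.semi_axes_px
        psi = np.radians(angle_deg - self.tilt_deg)
        return float(a * b / np.hypot(b * np.cos(psi), a * np.sin(psi)))

    def boundary_points(self, n: int = 90) -> np.ndarray:
        """(n, 2) array of (row, col) boundary samples."""
        angles = np.linspace(0, 360, n, endpoint=False)
        return np.array(
            [np.asarray(self.center_px) + self.radius_at(t) * _direction(t) for t in angles]
        )


@dataclass
class ROISpec:
    """One peripapillary region of interest.

    ``box`` is a half-open (r0, r1, c0, c1) pixel rectangle;
    ``vessel_orientation_deg`` is the expected local capillary direction
    (0 = horizontal), radial from the disc centre by construction.
    """

    label: str
    box: tuple[int, int, int, int]
    vessel_orientation_deg: float
    excluded: bool = False
    exclusion_reason: str = ""

    @property
    def side_px(self) -> tuple[int, int]:
        r0, r1, c0, c1 = self.box
        return (r1 - r0, c1 - c0)

    @property
    def center_px(self) -> tuple[float, float]:
        r0, r1, c0, c1 = self.box
        return ((r0 + r1 - 1) / 2.0, (c0 + c1 - 1) / 2.0)

    @property
    def area_mm2(self) -> float:
        raise AttributeError("area depends on scale; use roi_area_mm2(roi, scale)")


def roi_area_mm2(roi: ROISpec, scale: ScaleModel) -> float:
    h, w = roi.side_px
    return (h * scale.um_per_px / 1000.0) * (w * scale.um_per_px / 1000.0)


def read_margin_points(path: str | Path) -> np.ndarray:
    """Read clicked disc-margin points from CSV with columns x,y (0-based
    pixels, x = column).  Returns an (n, 2) array of (row, col)."""
    pts = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for row in reader:
            if not row or row[0].strip().lower() in ("x", "col", "column"):
                continue
            x, y = float(row[0]), float(row[1])
            pts.append((y, x))
    return np.asarray(pts, dtype=float)


def fit_ellipse(points: np.ndarray | list) -> DiscEllipse:
    """Least-squares ellipse fit to clicked disc-margin points.

    ``points`` is an (n, 2) array of (row, col) with n >= 5, not all
    collinear.  Raises ValueError on too few or degenerate points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise ValueError("need at least 5 (row, col) points to fit an ellipse")
    # collinearity check via the smaller singular value of centred points
    centred = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    if sv[-1] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("margin points are collinear; ellipse is degenerate")
    # EllipseModel works in (x, y) = (col, row)
    xy = pts[:, ::-1]
    model = EllipseModel.from_estimate(xy)
    if not model:
        raise ValueError("ellipse fit failed on the given points")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if not (np.isfinite([xc, yc, a, b, theta]).all() and a > 0 and b > 0):
        raise ValueError("ellipse fit produced a degenerate conic")
    tilt = -np.degrees(theta)  # image y runs down; flip into ophthalmic sense
    if b > a:
        a, b = b, a
        tilt += 90.0
    tilt = ((tilt + 90.0) % 180.0) - 90.0
    rms = float(np.sqrt(np.mean(model.residuals(xy) ** 2)))
    return DiscEllipse(
        center_px=(float(yc), float(xc)),
        semi_axes_px=(float(a), float(b)),
        tilt_deg=float(tilt),
        rms_residual_px=rms,
    )


def roi_side_px(scale: ScaleModel) -> int:
    """ROI box side in pixels: 2 degrees at the native sampling (60 px)."""
    return 2 * int(round(scale.px_per_degree))


def place_rois(
    ellipse: DiscEllipse,
    scale: ScaleModel | None = None,
    laterality: str = "OD",
    manual_offsets: dict[str, tuple[float, float]] | None = None,
    image_shape: tuple[int, int] = (304, 304),
    clearance_deg: float = 1.0,
    angles: dict[str, float] | None = None,
    orientation_override: dict[str, float] | float | None = None,
) -> list[ROISpec]:
    """Place the five peripapillary ROIs around the disc ellipse.

    Each ROI centre lies along its sector direction at the disc boundary
    plus ``clearance_deg`` of clearance plus half the ROI side, so the near
    edge sits ~1 degree outside the margin.  ``manual_offsets`` maps labels
    to (row, col) pixel shifts, emulating the manual nudge used to dodge
    major vessels and arterial capillary-free zones.  Boxes extending off
    the image are flagged excluded, not erased.  ``orientation_override``
    replaces the radial vessel-orientation assumption (a single value or a
    per-label mapping), for scenes whose vessels are not radial.
    """
    scale = scale or ScaleModel()
    if laterality not in ("OD", "OS"):
        raise ValueError("laterality must be 'OD' or 'OS'")
    angles = dict(angles or ROI_ANGLES_OD)
    if laterality == "OS":
        angles = {lab: (180.0 - ang if abs(ang) != 90.0 else ang) for lab, ang in angles.items()}
    manual_offsets = manual_offsets or {}
    side = roi_side_px(scale)
    half = side / 2.0
    h, w = image_shape
    rois: list[ROISpec] = []
    for label in ROI_LABELS:
        ang = angles[label]
        direction = _direction(ang)
        dist = ellipse.radius_at(ang) + scale.degrees_to_px(clearance_deg) + half
        center = np.asarray(ellipse.center_px) + dist * direction
        off = manual_offsets.get(label, (0.0, 0.0))
        center = center + np.asarray(off, dtype=float)
        # box centre lands on the nearest representable (half-integer)
        # point, keeping it within 0.5 px of the prescribed centre
        r0 = int(round(center[0] - (side - 1) / 2.0))
        c0 = int(round(center[1] - (side - 1) / 2.0))
        box = (r0, r0 + side, c0, c0 + side)
        excluded = r0 < 0 or c0 < 0 or r0 + side > h or c0 + side > w
        if orientation_override is None:
            orient = ang % 180.0
        elif isinstance(orientation_override, dict):
            orient = orientation_override.get(label, ang % 180.0)
        else:
            orient = float(orientation_override)
        rois.append(
            ROISpec(
                label=label,
                box=box,
                vessel_orientation_deg=orient,
                excluded=excluded,
                exclusion_reason="off_image" if excluded else "",
            )
        )
    return rois


@dataclass
class SamplingBox:
    """The narrow intensity-sampling box used for intercapillary distance.

    0.1 x 1 degree, centred in the ROI, long axis perpendicular to the
    local vessel direction; the averaged profile runs along the long axis
    in 1-px steps, averaging across the short axis.  ``center_px`` is in
    whole-image coordinates.
    """

    center_px: tuple[float, float]
    long_axis_deg: float  # ophthalmic angle of the long (profile) axis
    length_px: int
    width_px: int

    @property
    def corners(self) -> np.ndarray:
        """(4, 2) rectangle corners in (row, col), for QC overlays."""
        u = _direction(self.long_axis_deg)
        v = _direction(self.long_axis_deg - 90.0)
        c = np.asarray(self.center_px)
        hl, hw = (self.length_px - 1) / 2.0, (self.width_px - 1) / 2.0
        return np.array([c + hl * u + hw * v, c + hl * u - hw * v,
                         c - hl * u - hw * v, c - hl * u + hw * v])

    def profile(self, image_data: np.ndarray) -> np.ndarray:
        """Averaged intensity profile along the long axis (length_px,)."""
        u = _direction(self.long_axis_deg)
        v = _direction(self.long_axis_deg - 90.0)
        c = np.asarray(self.center_px)
        steps = np.arange(self.length_px) - (self.length_px - 1) / 2.0
        lanes = np.arange(self.width_px) - (self.width_px - 1) / 2.0
        pts = (
            c[None, None, :]
            + steps[:, None, None] * u[None, None, :]
            + lanes[None, :, None] * v[None, None, :]
        )
        vals = ndimage.map_coordinates(
            np.asarray(image_data, float),
            [pts[..., 0].ravel(), pts[..., 1].ravel()],
            order=1,
            mode="nearest",
        ).reshape(self.length_px, self.width_px)
        return vals.mean(axis=1)


def icd_sampling_box(roi: ROISpec, scale: ScaleModel | None = None) -> SamplingBox:
    """Build the ICD sampling box for an ROI: 0.1 x 1 degree, long axis
    perpendicular to the expected vessel direction, centred in the ROI."""
    if roi.excluded:
        raise ValueError(f"ROI {roi.label} is excluded ({roi.exclusion_reason})")
    scale = scale or ScaleModel()
    length = max(int(round(scale.degrees_to_px(1.0))), 1)
    width = max(int(round(scale.degrees_to_px(0.1))), 1)
    return SamplingBox(
        center_px=roi.center_px,
        long_axis_deg=roi.vessel_orientation_deg + 90.0,
        length_px=length,
        width_px=width,
    )
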