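"""Synthetic radial peripapillary capillary (RPC) scenes.

The RPC network is distinctive: long, nearly straight capillaries of about
9 um diameter running parallel to the nerve fibre bundles, spaced 30-40 um
apart, with few anastomoses.  This module builds ground-truth centreline
maps with that morphology, renders them as en-face angiogram frames with a
configurable noise model (multiplicative speckle + additive background
noise + occasional whole-row motion-artifact lines), and simulates
multi-frame acquisition with small rigid inter-frame misalignment, so the
registration, quantification and statistics stages can all be exercised
against known truth.

Determinism: identical (scene, scale, seed, n_frames) reproduce identical
arrays bit-for-bit; per-frame noise uses a sub-generator derived from
(seed, frame_index).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .image import EnFaceImage, FrameStack
from .register import RigidTransform, apply_transform
from .scale import ScaleModel

__all__ = ["SyntheticScene", "GroundTruth", "generate_capillary_map", "render_frame", "simulate_stack"]

# distinct stream keys so the geometry, transform and per-frame noise RNGs
# never collide
_GEOMETRY_STREAM = 11
_TRANSFORM_STREAM = 23
_FRAME_STREAM = 37

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class SyntheticScene:
    """Parameters of a synthetic capillary scene.

    Spacing/diameter are in retinal microns; noise parameters are in
    normalised intensity units.  ``tortuosity_wavelength_um`` sets the
    period of the sinusoidal centreline wobble whose amplitude is
    ``tortuosity_amp_um``.
    """

    image_size_px: tuple[int, int] = (304, 304)
    orientation_deg: float = 0.0
    true_icd_um: float = 38.0
    icd_jitter_frac: float = 0.1
    true_diameter_um: float = 9.0
    tortuosity_amp_um: float = 5.0
    tortuosity_wavelength_um: float = 300.0
    anastomosis_rate: float = 0.1
    speckle_sigma: float = 0.3
    additive_sigma: float = 0.05
    motion_line_prob: float = 0.01
    motion_line_axis: str = "rows"  # rows | cols | both
    shift_range_px: float = 3.0
    rot_range_deg: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.true_icd_um > self.true_diameter_um > 0):
            raise ValueError("need true_icd_um > true_diameter_um > 0")
        for name in ("icd_jitter_frac", "motion_line_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("speckle_sigma", "additive_sigma", "tortuosity_amp_um",
                     "shift_range_px", "rot_range_deg", "anastomosis_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.motion_line_axis not in ("rows", "cols", "both"):
            raise ValueError("motion_line_axis must be rows, cols or both")
        if len(self.image_size_px) != 2 or min(self.image_size_px) < 4:
            raise ValueError("image_size_px must be (rows, cols), each >= 4")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_size_px"] = list(self.image_size_px)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticScene":
        d = dict(d)
        d["image_size_px"] = tuple(d["image_size_px"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Exact geometry and provenance of a simulated stack."""

    centerline_map: np.ndarray
    clean_image: EnFaceImage
    true_density_mm_inv: float
    true_icd_um: float
    scene: SyntheticScene
    scale: ScaleModel
    true_transforms: list[RigidTransform] = field(default_factory=list)


def _direction_vectors(orientation_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors (row, col) along and perpendicular to the capillaries.

    Orientation 0 means vessels run horizontally (along columns); 90 means
    vertically.
    """
    t = np.radians(orientation_deg)
    along = np.array([-np.sin(t), np.cos(t)])
    perp = np.array([np.cos(t), np.sin(t)])
    return along, perp


def centerline_length_px(centerlines: np.ndarray) -> float:
    """Geometric length of one-pixel-wide curves, in pixel units.

    Counts 8-adjacency steps (1 for orthogonal, sqrt(2) for diagonal),
    dropping a diagonal step whenever the two pixels are already joined
    through a shared 4-neighbour, so staircase corners are not counted
    twice.  Works on any thin binary map, including branched skeletons.
    """
    s = np.asarray(centerlines, dtype=bool)
    horiz = s[:, 1:] & s[:, :-1]
    vert = s[1:, :] & s[:-1, :]
    d_main = s[1:, 1:] & s[:-1, :-1]
    d_anti = s[1:, :-1] & s[:-1, 1:]
    # shared 4-neighbours of each diagonal pair
    d_main &= ~(s[1:, :-1] | s[:-1, 1:])
    d_anti &= ~(s[1:, 1:] | s[:-1, :-1])
    return float(horiz.sum() + vert.sum() + np.sqrt(2.0) * (d_main.sum() + d_anti.sum()))


def generate_capillary_map(
    scene: SyntheticScene, scale: ScaleModel | None = None
) -> GroundTruth:
    """Build the ground-truth centreline map and its noise-free rendering.

    Capillaries are near-parallel curves at mean centre-to-centre spacing
    ``true_icd_um`` with optional per-vessel spacing jitter, sinusoidal
    tortuosity and sparse perpendicular anastomoses.  The noise-free image
    is the centreline map convolved with a Gaussian cross-section of FWHM
    equal to the true diameter, normalised to [0, 1].
    """
    scale = scale or ScaleModel()
    rng = np.random.default_rng(np.random.SeedSequence([scene.seed, _GEOMETRY_STREAM]))
    h, w = scene.image_size_px
    spacing_px = scene.true_icd_um / scale.um_per_px
    diag = float(np.hypot(h, w))
    n_side = int(np.ceil(diag / 2 / spacing_px)) + 1
    if 2 * n_side + 1 < 2 or spacing_px > diag:
        raise ValueError(
            f"image {h}x{w} px too small for capillary spacing {scene.true_icd_um} um"
        )
    along, perp = _direction_vectors(scene.orientation_deg)
    # anchor the central capillary on a pixel centre so that, with zero
    # jitter and tortuosity, axis-aligned lines rasterise at exact spacing
    center = np.floor([(h - 1) / 2.0, (w - 1) / 2.0])

    amp_px = scene.tortuosity_amp_um / scale.um_per_px
    wavelength_px = scene.tortuosity_wavelength_um / scale.um_per_px
    ts = np.arange(-diag / 2, diag / 2, 0.25)

    canvas = np.zeros((h, w), dtype=bool)
    offsets = []
    phases = []
    for k in range(-n_side, n_side + 1):
        off = k * spacing_px
        if scene.icd_jitter_frac > 0:
            off += rng.normal(0.0, scene.icd_jitter_frac * spacing_px)
        offsets.append(off)
        phases.append(rng.uniform(0, 2 * np.pi) if amp_px > 0 else 0.0)

    def rasterize(points: np.ndarray) -> None:
        ij = np.round(points).astype(int)
        keep = (ij[:, 0] >= 0) & (ij[:, 0] < h) & (ij[:, 1] >= 0) & (ij[:, 1] < w)
        ij = ij[keep]
        canvas[ij[:, 0], ij[:, 1]] = True

    drawn = 0
    line_points = []
    for off, phase in zip(offsets, phases):
        wobble = amp_px * np.sin(2 * np.pi * ts / wavelength_px + phase) if amp_px > 0 else 0.0
        pts = center[None, :] + ts[:, None] * along[None, :] + (off + wobble)[..., None] * perp[None, :] \
            if amp_px > 0 else center[None, :] + ts[:, None] * along[None, :] + off * perp[None, :]
        inside = (
            (pts[:, 0] > -0.5) & (pts[:, 0] < h - 0.5)
            & (pts[:, 1] > -0.5) & (pts[:, 1] < w - 0.5)
        )
        if inside.any():
            drawn += 1
        line_points.append(pts)
        rasterize(pts)
    if drawn < 2:
        raise ValueError(
            f"image {h}x{w} px holds {drawn} capillary at spacing "
            f"{scene.true_icd_um} um; need at least 2"
        )

    if scene.anastomosis_rate > 0:
        for k in range(len(offsets) - 1):
            n_links = rng.poisson(scene.anastomosis_rate)
            for _ in range(n_links):
                t_link = rng.uniform(-diag / 2, diag / 2)
                i0 = int(np.clip(np.searchsorted(ts, t_link), 0, len(ts) - 1))
                p0 = line_points[k][i0]
                p1 = line_points[k + 1][i0]
                steps = np.linspace(0.0, 1.0, max(int(np.hypot(*(p1 - p0)) * 4), 2))
                rasterize(p0[None, :] + steps[:, None] * (p1 - p0)[None, :])

    sigma_px = (scene.true_diameter_um / scale.um_per_px) / FWHM_PER_SIGMA
    clean = ndimage.gaussian_filter(canvas.astype(float), sigma_px, mode="constant")
    peak = clean.max()
    if peak > 0:
        clean = clean / peak
    clean_img = EnFaceImage(np.clip(clean, 0.0, 1.0), scale)

    length_px = centerline_length_px(canvas)
    area_mm2 = (h * scale.um_per_px / 1000.0) * (w * scale.um_per_px / 1000.0)
    density = (length_px * scale.um_per_px / 1000.0) / area_mm2
    return GroundTruth(
        centerline_map=canvas,
        clean_image=clean_img,
        true_density_mm_inv=density,
        true_icd_um=scene.true_icd_um,
        scene=scene,
        scale=scale,
    )


def _frame_rng(seed: int, frame_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _FRAME_STREAM, frame_index]))


def render_frame(
    truth: GroundTruth, scene: SyntheticScene, frame_index: int
) -> EnFaceImage:
    """Render one noisy acquired frame from the ground truth.

    Applies, in order: the frame's rigid misalignment (identity when no
    transform is recorded), multiplicative speckle ~ Normal(1, sigma)
    clipped at zero, additive Normal(0, sigma) background noise, then
    per-row (and/or per-column) motion-artifact lines that brighten or
    attenuate a whole line; the result is clipped to [0, 1].
    """
    if frame_index < 0:
        raise ValueError("frame_index must be >= 0")
    if truth.true_transforms and frame_index < len(truth.true_transforms):
        t = truth.true_transforms[frame_index]
    else:
        t = RigidTransform.identity()
    img = apply_transform(truth.clean_image, t)
    data = img.data
    rng = _frame_rng(scene.seed, frame_index)
    if scene.speckle_sigma > 0:
        data = data * np.clip(rng.normal(1.0, scene.speckle_sigma, data.shape), 0.0, None)
    if scene.additive_sigma > 0:
        data = data + rng.normal(0.0, scene.additive_sigma, data.shape)
    if scene.motion_line_prob > 0:
        if scene.motion_line_axis in ("rows", "both"):
            hit = rng.random(data.shape[0]) < scene.motion_line_prob
            gains = np.where(rng.random(data.shape[0]) < 0.5,
                             rng.uniform(0.2, 0.6, data.shape[0]),
                             rng.uniform(1.5, 2.5, data.shape[0]))
            data[hit, :] = data[hit, :] * gains[hit, None] + 0.05 * (gains[hit, None] - 1)
        if scene.motion_line_axis in ("cols", "both"):
            hit = rng.random(data.shape[1]) < scene.motion_line_prob
            gains = np.where(rng.random(data.shape[1]) < 0.5,
                             rng.uniform(0.2, 0.6, data.shape[1]),
                             rng.uniform(1.5, 2.5, data.shape[1]))
            data[:, hit] = data[:, hit] * gains[None, hit] + 0.05 * (gains[None, hit] - 1)
    return EnFaceImage(np.clip(data, 0.0, 1.0), truth.scale, img.valid)


def simulate_stack(
    scene: SyntheticScene, scale: ScaleModel | None = None, n_frames: int = 10
) -> tuple[FrameStack, GroundTruth]:
    """Simulate a multi-frame acquisition of one synthetic scene.

    Frame 0 is the untransformed reference; every other frame gets an
    independently drawn rigid misalignment with |shift| <= shift_range_px
    per axis and |rotation| <= rot_range_deg.  All applied transforms are
    recorded in the returned ground truth.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    scale = scale or ScaleModel()
    truth = generate_capillary_map(scene, scale)
    rng = np.random.default_rng(np.random.SeedSequence([scene.seed, _TRANSFORM_STREAM]))
    transforms = [RigidTransform.identity()]
    for _ in range(1, n_frames):
        transforms.append(
            RigidTransform(
                dx_px=float(rng.uniform(-scene.shift_range_px, scene.shift_range_px)),
                dy_px=float(rng.uniform(-scene.shift_range_px, scene.shift_range_px)),
                theta_deg=float(rng.uniform(-scene.rot_range_deg, scene.rot_range_deg)),
            )
        )
    truth.true_transforms = transforms
    frames = [render_frame(truth, scene, i) for i in range(n_frames)]
    stack = FrameStack(frames, reference_index=0)
    return stack, truth
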