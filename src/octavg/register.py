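"""Rigid registration of en-face frame stacks.

Each frame is aligned to a reference frame with a rigid (translation +
rotation, no scaling) model: the frames come from the same device, same
session, so scale is fixed.  Estimation uses subpixel phase correlation
nested inside a one-dimensional angular search; the suggested elastic
refinement step is deliberately absent, but :func:`register_stack` accepts a
``post_hook`` so one can be bolted on.

Conventions: coordinates are 0-based (row, col), row 0 at top.  A
:class:`RigidTransform` acts on an image by rotating it ``theta_deg``
counter-clockwise about the image centre and then translating by
``(dy_px, dx_px)`` = (rows down, cols right).  Pixels resampled from outside
the original field are marked invalid rather than zero-filled, so downstream
ROI averaging is never biased by border fill.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .image import EnFaceImage, FrameStack

__all__ = [
    "RigidTransform",
    "UnregistrableError",
    "select_reference",
    "estimate_rigid",
    "apply_transform",
    "register_stack",
    "transfer_transforms",
]


class UnregistrableError(ValueError):
    """Raised when an image pair carries no usable alignment signal."""


@dataclass(frozen=True)
class RigidTransform:
    """Rotation about the image centre followed by a translation.

    dx_px is the column shift (rightwards), dy_px the row shift
    (downwards), theta_deg the counter-clockwise rotation in degrees.
    """

    dx_px: float = 0.0
    dy_px: float = 0.0
    theta_deg: float = 0.0

    def rotation_matrix(self) -> np.ndarray:
        """2x2 rotation acting on (row, col) offsets from the centre."""
        t = math.radians(self.theta_deg)
        # CCW on screen (y down): (row, col) rotates with this sign choice.
        return np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``first`` then ``self``."""
        r2 = self.rotation_matrix()
        d1 = np.array([first.dy_px, first.dx_px])
        d2 = np.array([self.dy_px, self.dx_px])
        d = r2 @ d1 + d2
        return RigidTransform(
            dx_px=float(d[1]), dy_px=float(d[0]), theta_deg=self.theta_deg + first.theta_deg
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation_matrix().T
        d = -rt @ np.array([self.dy_px, self.dx_px])
        return RigidTransform(dx_px=float(d[1]), dy_px=float(d[0]), theta_deg=-self.theta_deg)

    @property
    def is_identity(self) -> bool:
        return self.dx_px == 0.0 and self.dy_px == 0.0 and self.theta_deg == 0.0

    def magnitude(self) -> tuple[float, float]:
        """(translation magnitude in px, |rotation| in degrees)."""
        return math.hypot(self.dx_px, self.dy_px), abs(self.theta_deg)

    def to_dict(self) -> dict:
        return {"dx_px": self.dx_px, "dy_px": self.dy_px, "theta_deg": self.theta_deg}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(dx_px=d["dx_px"], dy_px=d["dy_px"], theta_deg=d["theta_deg"])

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()


def _warp(data: np.ndarray, t: RigidTransform, order: int, cval: float) -> np.ndarray:
    """Resample ``data`` under the forward map y = R(x - c) + c + d."""
    c = (np.array(data.shape, dtype=float) - 1.0) / 2.0
    r = t.rotation_matrix()
    d = np.array([t.dy_px, t.dx_px])
    # ndimage.affine_transform uses the inverse map: input = M @ output + offset
    m = r.T
    offset = c - m @ (c + d)
    return ndimage.affine_transform(
        data, m, offset=offset, order=order, mode="constant", cval=cval
    )


def apply_transform(image: EnFaceImage, t: RigidTransform) -> EnFaceImage:
    """Resample an image under a rigid transform (bicubic).

    Out-of-field pixels are flagged invalid, not filled; an identity
    transform returns a bit-identical copy.
    """
    if t.is_identity:
        return image.copy()
    data = _warp(image.data, t, order=3, cval=0.0)
    support = _warp(image.valid_mask.astype(float), t, order=1, cval=0.0)
    valid = support >= 0.999
    # the bicubic kernel has a 2-px reach: pixels that close to the border
    # are contaminated by constant fill, so shrink validity accordingly
    valid = ndimage.binary_erosion(valid, iterations=2, border_value=0)
    return EnFaceImage(data, image.scale, valid)


def select_reference(stack: FrameStack, artifact_weight: float = 1.0) -> int:
    """Pick the frame with the highest contrast and fewest artifact lines.

    Quality score = interquartile range of pixel intensity minus
    ``artifact_weight`` times the fraction of rows/columns whose mean
    deviates more than 3 SD from the other row/column means.  Ties break to
    the lowest index.
    """
    scores = []
    for f in stack.frames:
        data = f.data
        q1, q3 = np.percentile(data, [25, 75])
        iqr = q3 - q1
        bad = 0
        for means in (data.mean(axis=1), data.mean(axis=0)):
            sd = means.std()
            if sd > 0:
                bad += int(np.sum(np.abs(means - means.mean()) > 3 * sd))
        frac = bad / (data.shape[0] + data.shape[1])
        scores.append(iqr - artifact_weight * frac)
    return int(np.argmax(scores))


def _hann2d(shape: tuple[int, int]) -> np.ndarray:
    wr = np.hanning(shape[0])
    wc = np.hanning(shape[1])
    return np.outer(wr, wc)


def estimate_rigid(
    moving: EnFaceImage | np.ndarray,
    reference: EnFaceImage | np.ndarray,
    theta_bound_deg: float = 3.0,
    coarse_step_deg: float = 0.5,
    fine_step_deg: float = 0.1,
    upsample_factor: int = 50,
) -> RigidTransform:
    """Estimate the rigid transform aligning ``moving`` onto ``reference``.

    The rotation is found by minimising the phase-correlation residual over
    a coarse-then-fine angle grid (with a final parabolic refinement); the
    translation comes from subpixel phase correlation at the best angle.
    Both images are Hann-windowed so frame borders and rotation fill do not
    dominate the spectrum.

    Raises :class:`UnregistrableError` for constant (featureless) images.
    """
    mov = moving.data if isinstance(moving, EnFaceImage) else np.asarray(moving, float)
    ref = reference.data if isinstance(reference, EnFaceImage) else np.asarray(reference, float)
    if mov.shape != ref.shape:
        raise ValueError("moving and reference must share dimensions")
    tol = 1e-9
    if mov.std() <= tol * max(1.0, np.abs(mov).max()) or ref.std() <= tol * max(
        1.0, np.abs(ref).max()
    ):
        raise UnregistrableError("constant image carries no registration signal")

    window = _hann2d(ref.shape)
    ref_w = (ref - ref.mean()) * window
    fill = float(mov.mean())

    def residual(theta: float) -> tuple[float, np.ndarray]:
        if theta == 0.0:
            rot = mov
        else:
            rot = _warp(mov, RigidTransform(theta_deg=theta), order=1, cval=fill)
        mov_w = (rot - rot.mean()) * window
        shift, error, _ = phase_cross_correlation(
            ref_w, mov_w, upsample_factor=10, normalization=None
        )
        return float(error), shift

    thetas = np.arange(-theta_bound_deg, theta_bound_deg + 1e-9, coarse_step_deg)
    errs = [residual(t)[0] for t in thetas]
    best = thetas[int(np.argmin(errs))]

    fine = np.arange(best - coarse_step_deg, best + coarse_step_deg + 1e-9, fine_step_deg)
    fine_errs = np.array([residual(t)[0] for t in fine])
    i = int(np.argmin(fine_errs))
    theta = float(fine[i])
    if 0 < i < len(fine) - 1:
        # parabolic interpolation of the error minimum
        e0, e1, e2 = fine_errs[i - 1], fine_errs[i], fine_errs[i + 1]
        denom = e0 - 2 * e1 + e2
        if denom > 0:
            theta += 0.5 * float((e0 - e2) / denom) * fine_step_deg

    if abs(theta) < fine_step_deg / 2:
        theta = 0.0
    rot = mov if theta == 0.0 else _warp(mov, RigidTransform(theta_deg=theta), order=3, cval=fill)
    mov_w = (rot - rot.mean()) * window
    shift, _, _ = phase_cross_correlation(
        ref_w, mov_w, upsample_factor=upsample_factor, normalization=None
    )
    return RigidTransform(dx_px=float(shift[1]), dy_px=float(shift[0]), theta_deg=theta)


def register_stack(stack: FrameStack, post_hook=None, **estimate_kwargs) -> FrameStack:
    """Register every frame to the stack's reference frame.

    The reference frame is never resampled.  Frames whose estimation fails
    are flagged in ``unregistrable`` (transform None) rather than dropped.
    ``post_hook(frame, transform) -> frame`` is an extension point for a
    non-rigid refinement stage.
    """
    ref = stack.reference
    frames: list[EnFaceImage] = []
    transforms: list[RigidTransform | None] = []
    failed: list[int] = []
    for i, frame in enumerate(stack.frames):
        if i == stack.reference_index:
            frames.append(frame.copy())
            transforms.append(RigidTransform.identity())
            continue
        try:
            t = estimate_rigid(frame, ref, **estimate_kwargs)
        except UnregistrableError:
            frames.append(frame.copy())
            transforms.append(None)
            failed.append(i)
            continue
        out = apply_transform(frame, t)
        if post_hook is not None:
            out = post_hook(out, t)
        frames.append(out)
        transforms.append(t)
    return FrameStack(
        frames,
        reference_index=stack.reference_index,
        registered=True,
        transforms=transforms,
        unregistrable=failed,
    )


def transfer_transforms(
    target: FrameStack, transforms: list[RigidTransform | None]
) -> FrameStack:
    """Apply transforms estimated on another stack (e.g. a deeper slab with
    larger vessels) to this stack, without re-estimation."""
    if len(transforms) != target.n_frames:
        raise ValueError(
            f"got {len(transforms)} transforms for {target.n_frames} frames"
        )
    frames = []
    failed = []
    for i, (frame, t) in enumerate(zip(target.frames, transforms)):
        if t is None:
            frames.append(frame.copy())
            failed.append(i)
        else:
            frames.append(apply_transform(frame, t))
    return FrameStack(
        frames,
        reference_index=target.reference_index,
        registered=True,
        transforms=list(transforms),
        unregistrable=failed,
    )
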