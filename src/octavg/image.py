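"""En-face image and frame-stack containers.

An :class:`EnFaceImage` is a single grayscale en-face angiogram slab with
its physical scale and an optional validity mask (pixels resampled from
outside the field of view during registration are invalid and poison any
ROI they touch).  A :class:`FrameStack` is an ordered list of same-shaped
frames acquired in one session, with a designated reference frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .scale import ScaleModel

if TYPE_CHECKING:  # pragma: no cover
    from .register import RigidTransform


@dataclass
class EnFaceImage:
    """A grayscale en-face angiogram with scale metadata.

    ``data`` is float with intensities nominally in [0, 1]; ``valid`` is a
    boolean mask of pixels that carry real signal (None means all valid).
    """

    data: np.ndarray
    scale: ScaleModel = field(default_factory=ScaleModel)
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("EnFaceImage data must be 2-D")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.data.shape:
                raise ValueError("valid mask shape must match data shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def valid_mask(self) -> np.ndarray:
        if self.valid is None:
            return np.ones(self.data.shape, dtype=bool)
        return self.valid

    def crop(self, box: tuple[int, int, int, int]) -> "EnFaceImage":
        """Crop to a half-open (r0, r1, c0, c1) box."""
        r0, r1, c0, c1 = box
        valid = None if self.valid is None else self.valid[r0:r1, c0:c1].copy()
        return EnFaceImage(self.data[r0:r1, c0:c1].copy(), self.scale, valid)

    def copy(self) -> "EnFaceImage":
        valid = None if self.valid is None else self.valid.copy()
        return EnFaceImage(self.data.copy(), self.scale, valid)


@dataclass
class FrameStack:
    """Ordered en-face frames from one acquisition session.

    ``transforms`` holds, after registration, the per-frame rigid transform
    that maps each acquired frame into the reference frame's coordinates
    (identity for the reference itself, None for frames where estimation
    failed; those indices are also listed in ``unregistrable``).
    """

    frames: list[EnFaceImage]
    reference_index: int = 0
    registered: bool = False
    transforms: list["RigidTransform | None"] | None = None
    unregistrable: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("FrameStack needs at least one frame")
        shape = self.frames[0].shape
        for f in self.frames:
            if f.shape != shape:
                raise ValueError("all frames must share dimensions")
        if not 0 <= self.reference_index < len(self.frames):
            raise ValueError("reference_index out of range")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    @property
    def scale(self) -> ScaleModel:
        return self.frames[0].scale

    @property
    def reference(self) -> EnFaceImage:
        return self.frames[self.reference_index]

    def averaging_order(self) -> list[int]:
        """Frame indices in averaging order: reference first, then the
        remaining frames in acquisition order."""
        rest = [i for i in range(self.n_frames) if i != self.reference_index]
        return [self.reference_index] + rest

    def with_reference(self, index: int) -> "FrameStack":
        if not 0 <= index < self.n_frames:
            raise ValueError("reference_index out of range")
        return replace(self, reference_index=index)


def stack_from_arrays(
    arrays: Sequence[np.ndarray], scale: ScaleModel | None = None
) -> FrameStack:
    scale = scale or ScaleModel()
    return FrameStack([EnFaceImage(a, scale) for a in arrays])
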