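"""Physical scale of en-face angiograms.

The commercial scan protocol covers 10x10 degrees of visual angle with
304x304 pixels, so the native sampling is 30.4 px/degree.  Retinal
magnification varies with eye size; a linear Bennett-style correction is
applied by scaling a nominal 291 um/degree by ``axial_length_mm / 24``.
Quantification operates on images upsampled by an integer ``resize_factor``
(default 6, i.e. a 60 px ROI becomes 360 px).
"""

from __future__ import annotations

from dataclasses import dataclass

NOMINAL_AXIAL_LENGTH_MM = 24.0


@dataclass(frozen=True)
class ScaleModel:
    """Pixel <-> physical-unit conversions for one eye.

    Parameters
    ----------
    px_per_degree:
        Native sampling of the en-face image, pixels per degree of visual
        angle.  304 px over 10 degrees gives the default 30.4.
    um_per_degree:
        Retinal microns per degree for a nominal 24 mm eye.
    axial_length_mm:
        Measured axial length of the imaged eye; scales the micron
        conversion linearly.
    resize_factor:
        Integer upsampling factor applied before binarisation,
        skeletonisation and masking.
    """

    px_per_degree: float = 30.4
    um_per_degree: float = 291.0
    axial_length_mm: float = NOMINAL_AXIAL_LENGTH_MM
    resize_factor: int = 6

    def __post_init__(self) -> None:
        if self.px_per_degree <= 0:
            raise ValueError("px_per_degree must be positive")
        if self.um_per_degree <= 0:
            raise ValueError("um_per_degree must be positive")
        if self.axial_length_mm <= 0:
            raise ValueError("axial_length_mm must be positive")
        if int(self.resize_factor) != self.resize_factor or self.resize_factor < 1:
            raise ValueError("resize_factor must be an integer >= 1")

    @property
    def um_per_degree_corrected(self) -> float:
        """Microns per degree after axial-length magnification correction."""
        return self.um_per_degree * self.axial_length_mm / NOMINAL_AXIAL_LENGTH_MM

    @property
    def um_per_px(self) -> float:
        """Microns per native pixel (9.57 um at defaults)."""
        return self.um_per_degree_corrected / self.px_per_degree

    @property
    def um_per_resized_px(self) -> float:
        """Microns per pixel of the upsampled quantification grid."""
        return self.um_per_px / self.resize_factor

    def degrees_to_px(self, degrees: float) -> float:
        return degrees * self.px_per_degree

    def um_to_px(self, um: float) -> float:
        return um / self.um_per_px
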