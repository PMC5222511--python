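"""QC and summary figures (matplotlib, Agg-safe)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .geometry import DiscEllipse, ROISpec, SamplingBox
from .image import EnFaceImage

__all__ = ["roi_overlay", "qc_panel", "normative_boxplot"]


def roi_overlay(
    image: EnFaceImage,
    rois: list[ROISpec],
    ellipse: DiscEllipse | None,
    path: str | Path,
) -> Path:
    """Whole-field overlay of the disc ellipse and the five ROI boxes."""
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(image.data, cmap="gray", interpolation="nearest")
    if ellipse is not None:
        pts = ellipse.boundary_points(180)
        ax.plot(pts[:, 1], pts[:, 0], "r-", lw=1)
    for roi in rois:
        r0, r1, c0, c1 = roi.box
        color = "orange" if roi.excluded else "yellow"
        ax.add_patch(
            plt.Rectangle((c0 - 0.5, r0 - 0.5), c1 - c0, r1 - r0, fill=False, color=color)
        )
        ax.text(c0, r0 - 2, roi.label, color=color, fontsize=9)
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return Path(path)


def qc_panel(
    roi_image: np.ndarray,
    binary: np.ndarray,
    skeleton: np.ndarray,
    endpoints: np.ndarray,
    mask: np.ndarray,
    icd_profile: np.ndarray | None,
    sampling_box: SamplingBox | None,
    path: str | Path,
    title: str = "",
) -> Path:
    """Per-ROI diagnostic panel: ROI, binarisation, skeleton + endpoints,
    vessel mask, and the ICD intensity profile."""
    fig, axes = plt.subplots(1, 5, figsize=(16, 3.4))
    axes[0].imshow(roi_image, cmap="gray")
    axes[0].set_title("averaged ROI")
    axes[1].imshow(binary, cmap="gray")
    axes[1].set_title("binarised")
    axes[2].imshow(skeleton, cmap="gray")
    if len(endpoints):
        axes[2].plot(endpoints[:, 1], endpoints[:, 0], "b.", ms=3)
    axes[2].set_title("skeleton + endpoints")
    axes[3].imshow(mask, cmap="gray")
    axes[3].set_title("vessel mask")
    if icd_profile is not None and len(icd_profile):
        axes[4].plot(icd_profile, "k-")
        axes[4].set_title("ICD profile")
        axes[4].set_xlabel("px along box")
    for ax in axes[:4]:
        ax.set_axis_off()
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return Path(path)


def normative_boxplot(
    controls: dict[str, np.ndarray],
    cases: dict[str, dict[str, float]],
    path: str | Path,
    ylabel: str = "capillary density (mm$^{-1}$)",
) -> Path:
    """Box plot of per-region control densities with individual case eyes
    overlaid (one marker per case)."""
    regions = list(controls)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.boxplot([controls[r] for r in regions], tick_labels=regions, whis=1.5)
    markers = ["o", "s", "^", "D", "v"]
    for i, (case_id, values) in enumerate(cases.items()):
        xs, ys = [], []
        for j, region in enumerate(regions, start=1):
            if region in values and np.isfinite(values[region]):
                xs.append(j)
                ys.append(values[region])
        ax.plot(xs, ys, markers[i % len(markers)], ls="none", label=case_id)
    ax.set_ylabel(ylabel)
    ax.set_xlabel("peripapillary region")
    if cases:
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
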