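"""Reading and writing the pipeline's on-disk formats.

Frame stacks travel as multi-page grayscale TIFF (8- or 16-bit) with a JSON
sidecar carrying scale, scene parameters, seed and transforms; centreline
maps and QC overlays as PNG; metric tables as tidy CSV; stats-only runs can
start from an XLSX workbook with one sheet per metric (the layout of the
published per-subject supplementary workbook: sheets A-E hold long-format
subject/region/n_frames/value rows for SNR, endpoints, segment length,
density and ICD; sheet F holds per-region 10-frame densities for the
glaucoma eyes).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .image import EnFaceImage, FrameStack
from .register import RigidTransform
from .scale import ScaleModel

__all__ = [
    "write_stack_tiff",
    "read_stack_tiff",
    "write_centerline_png",
    "write_metrics_csv",
    "read_metrics_csv",
    "write_metrics_xlsx",
    "read_metrics_xlsx",
    "METRIC_SHEETS",
]

METRIC_SHEETS = {
    "A_SNR": "snr",
    "B_Endpoints": "n_endpoints",
    "C_SegmentLength": "mean_segment_length_um",
    "D_Density": "density_mm_inv",
    "E_ICD": "icd_um",
}
POAG_SHEET = "F_POAG_Density"


def _scale_dict(scale: ScaleModel) -> dict:
    return {
        "px_per_degree": scale.px_per_degree,
        "um_per_degree": scale.um_per_degree,
        "axial_length_mm": scale.axial_length_mm,
        "resize_factor": scale.resize_factor,
    }


def write_stack_tiff(
    stack: FrameStack,
    path: str | Path,
    bit_depth: int = 16,
    sidecar: dict | None = None,
) -> Path:
    """Write a frame stack as multi-page grayscale TIFF plus JSON sidecar.

    Intensities in [0, 1] are scaled to the full integer range.  Extra
    sidecar entries (scene parameters, ground-truth transforms, seed) are
    merged into the JSON.
    """
    path = Path(path)
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    peak = np.iinfo(dtype).max
    pages = np.stack([
        np.clip(np.rint(f.data * peak), 0, peak).astype(dtype) for f in stack.frames
    ])
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "bit_depth": bit_depth,
        "n_frames": stack.n_frames,
        "reference_index": stack.reference_index,
        "registered": stack.registered,
        "scale": _scale_dict(stack.scale),
        "transforms": None
        if stack.transforms is None
        else [None if t is None else t.to_dict() for t in stack.transforms],
    }
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def read_stack_tiff(path: str | Path) -> FrameStack:
    """Read a multi-page TIFF stack written by :func:`write_stack_tiff`
    (or any grayscale multi-page TIFF; the sidecar is optional)."""
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None, ...]
    peak = np.iinfo(pages.dtype).max if np.issubdtype(pages.dtype, np.integer) else 1.0
    sidecar_path = path.with_suffix(".json")
    scale = ScaleModel()
    reference_index = 0
    registered = False
    transforms = None
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        if "scale" in meta:
            scale = ScaleModel(**meta["scale"])
        reference_index = meta.get("reference_index", 0)
        registered = meta.get("registered", False)
        if meta.get("transforms"):
            transforms = [
                None if t is None else RigidTransform.from_dict(t) for t in meta["transforms"]
            ]
    frames = [EnFaceImage(p.astype(float) / peak, scale) for p in pages]
    return FrameStack(
        frames, reference_index=reference_index, registered=registered, transforms=transforms
    )


def write_centerline_png(centerlines: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    iio.imwrite(path, (np.asarray(centerlines, bool) * np.uint8(255)))
    return path


def write_metrics_csv(df: pd.DataFrame, path: str | Path, provenance: str = "") -> Path:
    """Write the tidy metrics table; a provenance comment (config hash)
    goes in a commented header line."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        if provenance:
            fh.write(f"# provenance: {provenance}\n")
        df.to_csv(fh, index=False)
    return path


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if "exclusion_reason" in df.columns:
        df["exclusion_reason"] = df["exclusion_reason"].fillna("").astype(str)
    return df


def write_metrics_xlsx(df: pd.DataFrame, path: str | Path, poag: pd.DataFrame | None = None) -> Path:
    """Write a metrics workbook with one long-format sheet per metric."""
    path = Path(path)
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        for sheet, metric in METRIC_SHEETS.items():
            sub = df[["subject", "region", "n_frames", metric]].rename(columns={metric: "value"})
            sub.to_excel(writer, sheet_name=sheet, index=False)
        if poag is not None:
            poag.to_excel(writer, sheet_name=POAG_SHEET, index=False)
    return path


def read_metrics_xlsx(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Read a per-metric workbook back into one tidy metrics table (plus
    the glaucoma density sheet if present)."""
    book = pd.read_excel(path, sheet_name=None, engine="openpyxl")
    merged: pd.DataFrame | None = None
    for sheet, metric in METRIC_SHEETS.items():
        if sheet not in book:
            continue
        sub = book[sheet].rename(columns={"value": metric})
        if merged is None:
            merged = sub
        else:
            merged = merged.merge(sub, on=["subject", "region", "n_frames"], how="outer")
    if merged is None:
        raise ValueError(f"no recognised metric sheets in {path}")
    merged["excluded"] = merged[list(METRIC_SHEETS.values())].isna().all(axis=1)
    poag = book.get(POAG_SHEET)
    return merged, poag
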