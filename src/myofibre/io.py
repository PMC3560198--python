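"""Image loading and tabular export.

Readers accept the common single-image formats (TIFF, PNG, JPEG; GIF is
read if the imageio plugin handles it).  Fluorescence channels exported
as colour images are collapsed to grayscale by the per-pixel maximum
channel, which is robust to single-channel colour exports (a pure green
WGA export keeps full contrast).  All intensities are rescaled to
[0, 1] by the dtype range.

Tables are written as UTF-8 comma-separated CSV with '.' decimals and
four decimal places — open, diff-able and byte-reproducible.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .types import Calibration, ChannelSet, DimensionError, FibreRecord, FormatError, NucleusRecord

__all__ = ["load_image", "load_channel_set", "write_fibre_table", "write_nucleus_table"]

FIBRE_COLUMNS = [
    "fibre_id",
    "area_um2",
    "min_feret_um",
    "max_feret_um",
    "fibre_type",
    "n_nuclei",
    "n_internal_nuclei",
    "nucleation_class",
    "qc_pass",
]


def _normalise(img: np.ndarray) -> np.ndarray:
    """Rescale an integer or float image to [0, 1] by its dtype range."""
    if np.issubdtype(img.dtype, np.integer):
        info = np.iinfo(img.dtype)
        return img.astype(float) / info.max
    img = img.astype(float)
    if img.size and img.max() > 1.0:  # float image on a 0..255 scale
        return img / 255.0
    return img


def load_image(path: str | os.PathLike, as_gray: bool) -> np.ndarray:
    """Read one image, normalised to [0, 1].

    ``as_gray`` collapses colour inputs to 2-D by the maximum-intensity
    channel; otherwise a 3-channel RGB array is returned (an alpha
    channel is dropped, grayscale is broadcast to RGB).
    """
    try:
        img = iio.imread(path)
    except Exception as exc:  # plugins raise assorted types for bad files
        raise FormatError(f"cannot read image file {path!r}: {exc}") from exc
    img = _normalise(np.asarray(img))
    if as_gray:
        if img.ndim == 3:
            img = img[..., :3].max(axis=2)
        if img.ndim != 2:
            raise FormatError(f"{path!r}: expected a 2-D grayscale image")
        return img
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.ndim != 3 or img.shape[2] < 3:
        raise FormatError(f"{path!r}: expected an RGB image")
    return img[..., :3]


def load_channel_set(
    membrane_path: str | os.PathLike,
    nuclei_path: str | os.PathLike,
    mhc_path: str | os.PathLike,
    calibration: Calibration,
) -> ChannelSet:
    """Load the three registered images of one section.

    Raises :class:`FormatError` for unreadable files and
    :class:`DimensionError` if the three shapes disagree.
    """
    membrane = load_image(membrane_path, as_gray=True)
    nuclei = load_image(nuclei_path, as_gray=True)
    mhc = load_image(mhc_path, as_gray=False)
    shapes = (membrane.shape, nuclei.shape, mhc.shape[:2])
    if len(set(shapes)) != 1:
        raise DimensionError(
            "channel images differ in shape: membrane %s, nuclei %s, mhc %s"
            % shapes
        )
    return ChannelSet(membrane=membrane, nuclei=nuclei, mhc=mhc, calibration=calibration)


def _fibre_frame(records: list[FibreRecord]) -> pd.DataFrame:
    rows = [
        {
            "fibre_id": r.fibre_id,
            "area_um2": r.area_um2,
            "min_feret_um": r.min_feret_um,
            "max_feret_um": r.max_feret_um,
            "fibre_type": r.fibre_type,
            "n_nuclei": r.n_nuclei,
            "n_internal_nuclei": r.n_internal_nuclei,
            "nucleation_class": r.nucleation_class,
            "qc_pass": r.qc_pass,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=FIBRE_COLUMNS)
    return df.sort_values("fibre_id").reset_index(drop=True)


def write_fibre_table(
    records: list[FibreRecord],
    nuclei: list[NucleusRecord],
    path: str | os.PathLike,
) -> tuple[str, str]:
    """Write the per-fibre CSV and a companion CSV of mean values.

    The means file sits next to ``path`` with a ``_means`` suffix and
    holds the means of the numeric per-fibre columns plus fibre and
    nucleus counts over QC-passing fibres.  Returns both paths.
    """
    path = os.fspath(path)
    df = _fibre_frame(records)
    df.to_csv(path, index=False, float_format="%.4f")
    kept = df[df["qc_pass"]] if len(df) else df
    means = {
        "n_fibres": len(kept),
        "n_nuclei_assigned": int(kept["n_nuclei"].sum()) if len(kept) else 0,
        "mean_area_um2": float(kept["area_um2"].mean()) if len(kept) else float("nan"),
        "mean_min_feret_um": float(kept["min_feret_um"].mean()) if len(kept) else float("nan"),
        "mean_max_feret_um": float(kept["max_feret_um"].mean()) if len(kept) else float("nan"),
        "mean_n_nuclei": float(kept["n_nuclei"].mean()) if len(kept) else float("nan"),
        "pct_internally_nucleated": (
            100.0 * (kept["nucleation_class"] == "internal").mean() if len(kept) else float("nan")
        ),
    }
    root, ext = os.path.splitext(path)
    means_path = f"{root}_means{ext or '.csv'}"
    pd.DataFrame([means]).to_csv(means_path, index=False, float_format="%.4f")
    return path, means_path


def write_nucleus_table(nuclei: list[NucleusRecord], path: str | os.PathLike) -> str:
    """Write the per-nucleus CSV (id, fibre, position class, distances)."""
    rows = [
        {
            "nucleus_id": n.nucleus_id,
            "fibre_id": n.fibre_id,
            "centroid_row_px": n.centroid_px[0],
            "centroid_col_px": n.centroid_px[1],
            "area_um2": n.area_um2,
            "boundary_distance_um": n.boundary_distance_um,
            "position_class": n.position_class,
        }
        for n in nuclei
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "nucleus_id",
            "fibre_id",
            "centroid_row_px",
            "centroid_col_px",
            "area_um2",
            "boundary_distance_um",
            "position_class",
        ],
    ).sort_values("nucleus_id")
    df.to_csv(os.fspath(path), index=False, float_format="%.4f")
    return os.fspath(path)
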