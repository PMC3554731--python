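"""Reading and writing images, detection CSVs and metric reports.

Images are single-plane grayscale TIFF (8/16-bit) or PNG, scaled to
[0, 1] by the dtype maximum on read.  Detections are CSV with columns
``x_px, y_px, radius_px, score`` (x = column, y = row, 0-based, header
required, dot decimal, UTF-8).  Ground-truth centroid CSVs need at least
``x_px, y_px``.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .detection import Detection
from .errors import FormatError
from .metrics import MetricsReport

__all__ = [
    "read_image",
    "write_image",
    "write_detections_csv",
    "read_detections_csv",
    "read_centroids_csv",
    "write_centroids_csv",
    "write_metrics_report",
]


def read_image(path) -> np.ndarray:
    """Load a single-plane grayscale image as float64 in [0, 1]."""
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise FormatError(f"could not read image {path}: {exc}") from exc
    if arr.ndim != 2:
        n_extra = arr.shape[-1] if arr.ndim == 3 else arr.ndim
        raise FormatError(
            f"{path} is not single-plane grayscale: shape {arr.shape} ({n_extra} channels/planes)"
        )
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / float(np.iinfo(arr.dtype).max)
    arr = arr.astype(float)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise FormatError(f"{path}: float image values must already lie in [0, 1]")
    return arr


def write_image(path, image, dtype=np.uint16) -> None:
    """Write a [0, 1] image quantized to the given integer dtype (TIFF/PNG)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    q = np.round(img * np.iinfo(dtype).max).astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, q)
    else:
        iio.imwrite(path, q)


def write_detections_csv(path, detections: list[Detection]) -> None:
    df = pd.DataFrame(
        {
            "x_px": [d.centroid[1] for d in detections],
            "y_px": [d.centroid[0] for d in detections],
            "radius_px": [d.dominant_radius for d in detections],
            "score": [d.score for d in detections],
        }
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_detections_csv(path) -> list[Detection]:
    df = pd.read_csv(path)
    required = {"x_px", "y_px", "radius_px", "score"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: detection CSV must have columns {sorted(required)}")
    return [
        Detection(
            centroid=(float(r.y_px), float(r.x_px)),
            dominant_radius=float(r.radius_px),
            score=float(r.score),
        )
        for r in df.itertuples()
    ]


def read_centroids_csv(path) -> np.ndarray:
    """Read ground-truth centroids as an (n, 2) array of (row, col)."""
    df = pd.read_csv(path)
    if not {"x_px", "y_px"}.issubset(df.columns):
        raise FormatError(f"{path}: centroid CSV must have columns x_px, y_px")
    return df[["y_px", "x_px"]].to_numpy(dtype=float)


def write_centroids_csv(path, centroids, radii=None) -> None:
    centroids = np.asarray(centroids, dtype=float).reshape(-1, 2)
    data = {"x_px": centroids[:, 1], "y_px": centroids[:, 0]}
    if radii is not None:
        data["radius_px"] = np.asarray(radii, dtype=float)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(data).to_csv(path, index=False)


def write_metrics_report(path_prefix, report: MetricsReport) -> None:
    """Write a metrics report as CSV and as human-readable text."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([report.to_dict()]).to_csv(prefix.with_suffix(".csv"), index=False)
    prefix.with_suffix(".txt").write_text(report.as_text() + "\n")
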