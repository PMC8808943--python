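"""Readers and writers for the plain-text interchange formats.

One contour per image: a CSV with columns border (superior|inferior), x_px,
y_px, plus a JSON sidecar carrying the central point, calibration, medial
direction and free-form metadata.  Measurement tables are long-format CSV
(subject, limb, region, session, image_index, thickness_mm).  Grayscale PNG
masks (cartilage = nonzero) are an alternative contour source.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .geometry import (
    CartilageSegmentation,
    ImageCalibration,
    Polyline,
    mask_to_borders,
    split_closed_outline,
)
from .imagej import read_imagej_roi_file

MEASUREMENT_COLUMNS = (
    "subject",
    "limb",
    "region",
    "session",
    "image_index",
    "thickness_mm",
)


def write_contour_csv(seg: CartilageSegmentation, path) -> None:
    rows = [("superior", x, y) for x, y in seg.superior.vertices]
    rows += [("inferior", x, y) for x, y in seg.inferior.vertices]
    pd.DataFrame(rows, columns=["border", "x_px", "y_px"]).to_csv(path, index=False)


def write_sidecar_json(seg: CartilageSegmentation, path) -> None:
    payload = {
        "central_point": list(seg.central_point),
        "calibration": {
            "mm_per_px_x": seg.calibration.mm_per_px_x,
            "mm_per_px_y": seg.calibration.mm_per_px_y,
        },
        "medial_direction": seg.medial_direction,
        "meta": seg.meta,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_sidecar_json(path) -> dict:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"sidecar {path}: invalid JSON ({exc})") from exc
    for key in ("central_point", "calibration", "medial_direction"):
        if key not in payload:
            raise FormatError(f"sidecar {path}: missing key {key!r}")
    cal = payload["calibration"]
    for key in ("mm_per_px_x", "mm_per_px_y"):
        if key not in cal:
            raise FormatError(f"sidecar {path}: calibration missing {key!r}")
    return payload


def _segmentation_from_borders(
    superior: Polyline, inferior: Polyline, sidecar: dict
) -> CartilageSegmentation:
    return CartilageSegmentation(
        superior=superior,
        inferior=inferior,
        central_point=tuple(sidecar["central_point"]),
        calibration=ImageCalibration(
            mm_per_px_x=float(sidecar["calibration"]["mm_per_px_x"]),
            mm_per_px_y=float(sidecar["calibration"]["mm_per_px_y"]),
        ),
        medial_direction=sidecar["medial_direction"],
        meta=sidecar.get("meta", {}),
    )


def read_contour_csv(csv_path, sidecar_path) -> CartilageSegmentation:
    df = pd.read_csv(csv_path)
    required = {"border", "x_px", "y_px"}
    if not required <= set(df.columns):
        raise FormatError(
            f"{csv_path}: contour CSV needs columns {sorted(required)}"
        )
    borders = {}
    for name, grp in df.groupby("border"):
        if name not in ("superior", "inferior"):
            raise FormatError(f"{csv_path}: unknown border label {name!r}")
        borders[name] = Polyline(grp[["x_px", "y_px"]].to_numpy())
    if set(borders) != {"superior", "inferior"}:
        raise FormatError(f"{csv_path}: need both superior and inferior borders")
    return _segmentation_from_borders(
        borders["superior"], borders["inferior"], read_sidecar_json(sidecar_path)
    )


def read_roi_contour(roi_path, sidecar_path) -> CartilageSegmentation:
    outline = read_imagej_roi_file(roi_path)
    superior, inferior = split_closed_outline(outline)
    return _segmentation_from_borders(
        superior, inferior, read_sidecar_json(sidecar_path)
    )


def write_mask_png(mask: np.ndarray, path) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, np.asarray(mask, dtype=np.uint8))


def read_mask_png(png_path, sidecar_path) -> CartilageSegmentation:
    import imageio.v3 as iio

    mask = np.asarray(iio.imread(png_path))
    if mask.ndim == 3:  # tolerate grayscale saved with channels
        mask = mask[..., 0]
    superior, inferior = mask_to_borders(mask)
    return _segmentation_from_borders(superior, inferior, read_sidecar_json(sidecar_path))


def read_measurements_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(
            f"{path}: measurement CSV missing columns {sorted(missing)}"
        )
    if df["thickness_mm"].isna().any():
        raise FormatError(f"{path}: thickness_mm contains missing values")
    if not np.issubdtype(df["thickness_mm"].dtype, np.number):
        raise FormatError(f"{path}: thickness_mm must be numeric")
    return df


def write_measurements_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
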