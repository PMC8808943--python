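"""Minimal read-only parser for ImageJ .roi polygon outlines.

Layout (big-endian): magic "Iout", int16 version, byte roi-type, int16
top/left/bottom/right bounds, uint16 vertex count, then from byte 64 the
x offsets (int16, relative to left) followed by the y offsets (relative to
top).  Only the polygon (0) and freehand (7) subtypes are accepted.
"""

from __future__ import annotations

import struct

import numpy as np

from .errors import FormatError

MAGIC = b"Iout"
HEADER_SIZE = 64
TYPE_POLYGON = 0
TYPE_FREEHAND = 7
MIN_VERSION = 217

_TYPE_NAMES = {
    0: "polygon", 1: "rect", 2: "oval", 3: "line", 4: "freeline",
    5: "polyline", 6: "noRoi", 7: "freehand", 8: "traced", 9: "angle",
    10: "point",
}


def read_imagej_roi(data: bytes) -> np.ndarray:
    """Decode .roi bytes into an (n, 2) float array of (x, y) pixel vertices.

    Raises :class:`FormatError` on bad magic, unsupported subtype, or a
    truncated file.
    """
    if len(data) < HEADER_SIZE:
        raise FormatError("truncated .roi file (header shorter than 64 bytes)")
    if data[:4] != MAGIC:
        raise FormatError("not an ImageJ ROI: bad magic (expected 'Iout')")
    version, roi_type = struct.unpack(">hB", data[4:7])
    if version < MIN_VERSION:
        raise FormatError(f"unsupported ROI version {version} (need >= {MIN_VERSION})")
    if roi_type not in (TYPE_POLYGON, TYPE_FREEHAND):
        name = _TYPE_NAMES.get(roi_type, f"type {roi_type}")
        raise FormatError(f"unsupported ROI subtype: {name}")
    top, left, bottom, right, n = struct.unpack(">hhhhH", data[8:18])
    if n < 3:
        raise FormatError(f"ROI has too few vertices ({n})")
    need = HEADER_SIZE + 4 * n
    if len(data) < need:
        raise FormatError(
            f"truncated .roi file: need {need} bytes for {n} vertices, got {len(data)}"
        )
    xs = np.frombuffer(data, dtype=">i2", count=n, offset=HEADER_SIZE)
    ys = np.frombuffer(data, dtype=">i2", count=n, offset=HEADER_SIZE + 2 * n)
    return np.column_stack([xs + left, ys + top]).astype(float)


def read_imagej_roi_file(path) -> np.ndarray:
    with open(path, "rb") as fh:
        return read_imagej_roi(fh.read())
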