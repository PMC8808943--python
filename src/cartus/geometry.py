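"""Regional cartilage geometry from a two-border segmentation.

A segmented cartilage band is modelled as two x-monotone polylines in pixel
coordinates (origin top-left, y increases downward): the superior
synovial-cartilage border and the inferior cartilage-bone border.  The band
is split into medial / intercondylar / lateral regions by two vertical cuts;
the intercondylar region is the middle fraction (default 25%) of the
medio-lateral extent, centred on a manually identified central point.  Per
region we compute the cross-sectional area (CSA, mm^2), the arc length of
the cartilage-bone interface (mm), and their ratio, the mean thickness (mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import (
    DegeneratePartitionError,
    GeometryError,
    ZeroAreaError,
    ZeroLengthError,
)

REGIONS = ("medial", "intercondylar", "lateral")

MedialDirection = Literal["+x", "-x"]


@dataclass(frozen=True)
class ImageCalibration:
    """Pixel-to-millimetre scale factors; anisotropy allowed."""

    mm_per_px_x: float
    mm_per_px_y: float

    def __post_init__(self) -> None:
        if not (self.mm_per_px_x > 0 and self.mm_per_px_y > 0):
            raise GeometryError("calibration factors must be positive")
        if not (np.isfinite(self.mm_per_px_x) and np.isfinite(self.mm_per_px_y)):
            raise GeometryError("calibration factors must be finite")


class Polyline:
    """An x-monotone open polyline in pixel coordinates.

    Vertices are normalized so x is strictly increasing; an input given
    right-to-left is reversed.  Non-monotone or duplicate-x input is a hard
    error, never silently repaired.
    """

    __slots__ = ("vertices",)

    def __init__(self, vertices: Sequence[Sequence[float]] | np.ndarray):
        v = np.asarray(vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise GeometryError("polyline needs an (n>=2, 2) vertex array")
        if not np.all(np.isfinite(v)):
            raise GeometryError("polyline vertices must be finite")
        dx = np.diff(v[:, 0])
        if np.all(dx < 0):
            v = v[::-1]
            dx = -dx[::-1]
        if not np.all(dx > 0):
            raise GeometryError("polyline x-coordinates must be strictly monotone")
        self.vertices = v

    @property
    def x(self) -> np.ndarray:
        return self.vertices[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.vertices[:, 1]

    @property
    def x_min(self) -> float:
        return float(self.vertices[0, 0])

    @property
    def x_max(self) -> float:
        return float(self.vertices[-1, 0])

    def __len__(self) -> int:
        return len(self.vertices)

    def y_at(self, x: np.ndarray | float) -> np.ndarray:
        """Linear interpolation of the border height at x (within extent)."""
        return np.interp(x, self.vertices[:, 0], self.vertices[:, 1])

    def clipped(self, x_lo: float, x_hi: float) -> np.ndarray:
        """Vertices restricted to [x_lo, x_hi] with interpolated endpoints."""
        if not (x_lo < x_hi):
            raise GeometryError(f"empty strip: [{x_lo}, {x_hi}]")
        if x_lo < self.x_min - 1e-12 or x_hi > self.x_max + 1e-12:
            raise GeometryError(
                f"strip [{x_lo}, {x_hi}] exceeds polyline extent "
                f"[{self.x_min}, {self.x_max}]"
            )
        x = self.vertices[:, 0]
        inside = (x > x_lo) & (x < x_hi)
        parts = [np.array([[x_lo, float(self.y_at(x_lo))]])]
        if inside.any():
            parts.append(self.vertices[inside])
        parts.append(np.array([[x_hi, float(self.y_at(x_hi))]]))
        return np.vstack(parts)


@dataclass(frozen=True)
class CartilageSegmentation:
    """Calibrated two-border cartilage contour plus the central point.

    ``central_point`` is the manually marked middle of the synovial-cartilage
    border between the condylar upslopes; only its x-coordinate is used
    geometrically, the y is provenance.  ``medial_direction`` states which
    x-direction points toward the medial side of the knee.
    """

    superior: Polyline
    inferior: Polyline
    central_point: tuple[float, float]
    calibration: ImageCalibration
    medial_direction: MedialDirection = "+x"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sup, inf = self.superior, self.inferior
        if abs(sup.x_min - inf.x_min) > 1e-9 or abs(sup.x_max - inf.x_max) > 1e-9:
            raise GeometryError("borders must share identical first and last x")
        if self.medial_direction not in ("+x", "-x"):
            raise GeometryError("medial_direction must be '+x' or '-x'")
        # the gap is piecewise linear with breakpoints at the union of the
        # two vertex sets, so checking it there is exhaustive
        grid = np.union1d(sup.x, inf.x)
        gap = inf.y_at(grid) - sup.y_at(grid)
        interior = (grid > sup.x_min) & (grid < sup.x_max)
        if np.any(gap[interior] <= 0) or np.any(gap[~interior] < 0):
            raise GeometryError(
                "superior border must lie strictly above the bone border"
            )
        cx = float(self.central_point[0])
        if not (sup.x_min < cx < sup.x_max):
            raise GeometryError("central point x must be strictly inside the extent")

    @property
    def x_min(self) -> float:
        return self.superior.x_min

    @property
    def x_max(self) -> float:
        return self.superior.x_max


@dataclass(frozen=True)
class RegionPartition:
    """Vertical cut positions bounding the intercondylar strip."""

    cut_lo: float
    cut_hi: float
    extent: tuple[float, float]

    def strips(self) -> dict[str, tuple[float, float]]:
        """Left/middle/right strip intervals keyed by position."""
        x_min, x_max = self.extent
        return {
            "left": (x_min, self.cut_lo),
            "middle": (self.cut_lo, self.cut_hi),
            "right": (self.cut_hi, x_max),
        }


@dataclass(frozen=True)
class RegionMetrics:
    """Per-region area, bone-interface length and mean thickness."""

    region: str
    csa_mm2: float
    bone_length_mm: float
    thickness_mm: float


def partition_regions(
    seg: CartilageSegmentation, fraction: float = 0.25
) -> RegionPartition:
    """Place the two vertical cuts bounding the middle ``fraction`` of the
    medio-lateral extent, centred on the central point's x.

    Raises :class:`DegeneratePartitionError` when a cut would fall outside
    the segmented extent; cuts are never clamped.
    """
    if not (0 < fraction < 1):
        raise GeometryError("region fraction must be in (0, 1)")
    x_min, x_max = seg.x_min, seg.x_max
    half = 0.5 * fraction * (x_max - x_min)
    cx = float(seg.central_point[0])
    cut_lo, cut_hi = cx - half, cx + half
    if cut_lo <= x_min or cut_hi >= x_max:
        raise DegeneratePartitionError(
            f"cuts ({cut_lo:.3f}, {cut_hi:.3f}) fall outside extent "
            f"[{x_min:.3f}, {x_max:.3f}]; move the central point"
        )
    return RegionPartition(cut_lo=cut_lo, cut_hi=cut_hi, extent=(x_min, x_max))


def _shoelace(poly_mm: np.ndarray) -> float:
    x, y = poly_mm[:, 0], poly_mm[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def region_csa(seg: CartilageSegmentation, x_lo: float, x_hi: float) -> float:
    """Cross-sectional area (mm^2) of the band between the borders over the
    vertical strip [x_lo, x_hi].

    Both polylines are clipped to the strip with interpolated cut vertices;
    the closed clipped polygon is converted to millimetres and its area taken
    by the shoelace formula.
    """
    if not (x_lo < x_hi):
        raise ZeroAreaError(f"empty strip: [{x_lo}, {x_hi}]")
    sup = seg.superior.clipped(x_lo, x_hi)
    inf = seg.inferior.clipped(x_lo, x_hi)
    scale = np.array([seg.calibration.mm_per_px_x, seg.calibration.mm_per_px_y])
    ring = np.vstack([sup, inf[::-1]]) * scale
    return _shoelace(ring)


def bone_interface_length(
    seg: CartilageSegmentation, x_lo: float, x_hi: float
) -> float:
    """Arc length (mm) of the cartilage-bone interface within the strip.

    Each clipped segment of the inferior polyline is converted to mm
    component-wise before the Euclidean norm, so anisotropic calibration is
    honoured.
    """
    if not (x_lo < x_hi):
        raise ZeroLengthError(f"empty strip: [{x_lo}, {x_hi}]")
    inf = seg.inferior.clipped(x_lo, x_hi)
    scale = np.array([seg.calibration.mm_per_px_x, seg.calibration.mm_per_px_y])
    d = np.diff(inf * scale, axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def compute_thickness(
    seg: CartilageSegmentation, fraction: float = 0.25
) -> list[RegionMetrics]:
    """Mean thickness per region: regional CSA divided by the regional
    bone-interface length.  Returns metrics ordered medial, intercondylar,
    lateral, with the medial label on the ``medial_direction`` side."""
    part = partition_regions(seg, fraction)
    strips = part.strips()
    if seg.medial_direction == "+x":
        mapping = {"medial": "right", "intercondylar": "middle", "lateral": "left"}
    else:
        mapping = {"medial": "left", "intercondylar": "middle", "lateral": "right"}
    out = []
    for region in REGIONS:
        x_lo, x_hi = strips[mapping[region]]
        csa = region_csa(seg, x_lo, x_hi)
        length = bone_interface_length(seg, x_lo, x_hi)
        out.append(
            RegionMetrics(
                region=region,
                csa_mm2=csa,
                bone_length_mm=length,
                thickness_mm=csa / length,
            )
        )
    return out


def split_closed_outline(vertices: np.ndarray) -> tuple[Polyline, Polyline]:
    """Split a closed cartilage outline into (superior, inferior) border
    polylines.

    The ring is cut at its minimum-x and maximum-x vertices (ties broken by
    vertex order); the chain with the lower mean y on screen becomes the
    superior border.  Each chain must be x-monotone.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or len(v) < 4:
        raise GeometryError("closed outline needs at least 4 (x, y) vertices")
    # drop an explicit closing vertex
    if np.allclose(v[0], v[-1]):
        v = v[:-1]
    x_min, x_max = v[:, 0].min(), v[:, 0].max()
    if x_min == x_max:
        raise GeometryError("outline has zero x-extent")
    n = len(v)
    # start the ring at the first minimum-x vertex (vertex-order tie-break)
    v = np.roll(v, -int(np.argmin(v[:, 0])), axis=0)
    i = int(np.flatnonzero(v[:, 0] == x_max)[0])
    # a vertical edge joining duplicated extreme-x vertices belongs to
    # neither border chain
    j = i
    while j + 1 < n and v[j + 1, 0] == x_max:
        j += 1
    chain1 = v[: i + 1]
    chain2 = v[j:]
    if chain2[-1, 0] != x_min:
        chain2 = np.vstack([chain2, v[:1]])
    try:
        p1, p2 = Polyline(chain1), Polyline(chain2)
    except GeometryError as exc:
        raise GeometryError(f"outline chains are not x-monotone: {exc}") from exc
    if float(p1.y.mean()) <= float(p2.y.mean()):
        superior, inferior = p1, p2
    else:
        superior, inferior = p2, p1
    return superior, inferior


def mask_to_borders(mask: np.ndarray) -> tuple[Polyline, Polyline]:
    """Extract (superior, inferior) borders from a grayscale mask.

    Cartilage pixels are nonzero; per occupied column, the superior border is
    the top nonzero row and the inferior border the bottom nonzero row.  The
    occupied columns must form one contiguous run.
    """
    m = np.asarray(mask)
    if m.ndim != 2:
        raise GeometryError("mask must be a 2-D grayscale array")
    occupied = np.flatnonzero((m != 0).any(axis=0))
    if occupied.size < 2:
        raise GeometryError("mask contains fewer than 2 occupied columns")
    if not np.array_equal(occupied, np.arange(occupied[0], occupied[-1] + 1)):
        raise GeometryError("occupied mask columns are not contiguous")
    tops, bottoms = [], []
    for c in occupied:
        rows = np.flatnonzero(m[:, c])
        tops.append((float(c), float(rows[0])))
        bottoms.append((float(c), float(rows[-1])))
    return Polyline(tops), Polyline(bottoms)
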