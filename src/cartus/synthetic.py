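"""Phantom contours and simulated cohorts with known ground truth.

Phantoms are segmentation-level: an analytic bone profile plus a vertical
thickness offset (a phantom convention that makes flat-bone regional truth
exact and sloped-bone truth derivable by quadrature, not an anatomical
claim).  Cohorts are normal variance-component draws emulating the
magnitudes of the study tables (means around 2.0-2.6 mm, between-subject SD
0.3-0.8 mm, session error 0.05-0.07 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidSpecError
from .geometry import (
    REGIONS,
    CartilageSegmentation,
    ImageCalibration,
    Polyline,
)

DEFAULT_CALIBRATION = ImageCalibration(mm_per_px_x=0.1, mm_per_px_y=0.1)

#: region means (mm) mimicking the healthy-control magnitudes
DEFAULT_REGION_MEANS: Mapping[str, float] = {
    "medial": 2.16,
    "intercondylar": 2.57,
    "lateral": 2.04,
}

_CUT_EPS = 1e-6  # half-width (px) of the ramp standing in for a thickness step


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic cartilage band."""

    x_extent_px: float = 400.0
    bone_profile: str = "flat"  # flat | sloped | bicondylar
    bone_y_px: float = 300.0
    slope: float = 0.1  # sloped: dy/dx in px/px
    condyle_amplitude_px: float = 25.0
    notch_depth_px: float = 10.0
    condyle_sigma_px: float | None = None
    thickness_profile: Mapping[str, float] | Callable[[np.ndarray], np.ndarray] = (
        field(default_factory=lambda: dict(DEFAULT_REGION_MEANS))
    )
    calibration: ImageCalibration = DEFAULT_CALIBRATION
    vertex_spacing_px: float = 1.0
    border_noise_sd_px: float = 0.0
    central_frac: float = 0.5
    region_fraction: float = 0.25
    medial_direction: str = "+x"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.x_extent_px <= 0 or self.vertex_spacing_px <= 0:
            raise InvalidSpecError("extent and vertex spacing must be positive")
        if self.border_noise_sd_px < 0:
            raise InvalidSpecError("border noise SD must be non-negative")
        if self.bone_profile not in ("flat", "sloped", "bicondylar"):
            raise InvalidSpecError(f"unknown bone profile {self.bone_profile!r}")
        if not (0 < self.central_frac < 1):
            raise InvalidSpecError("central_frac must be in (0, 1)")
        if isinstance(self.thickness_profile, Mapping):
            missing = set(REGIONS) - set(self.thickness_profile)
            if missing:
                raise InvalidSpecError(
                    f"thickness profile missing regions: {sorted(missing)}"
                )
            if any(t <= 0 for t in self.thickness_profile.values()):
                raise InvalidSpecError("thickness must be positive everywhere")

    @property
    def central_x(self) -> float:
        return self.central_frac * self.x_extent_px

    def cuts(self) -> tuple[float, float]:
        half = 0.5 * self.region_fraction * self.x_extent_px
        return self.central_x - half, self.central_x + half


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth carried alongside generated data."""

    regional_thickness_mm: dict[str, float] | None = None
    variance_components: dict[str, float] | None = None
    true_deltas: pd.DataFrame | None = None
    responder_labels: pd.DataFrame | None = None


def _bone_function(spec: PhantomSpec) -> Callable[[np.ndarray], np.ndarray]:
    if spec.bone_profile == "flat":
        return lambda x: np.full_like(np.asarray(x, dtype=float), spec.bone_y_px)
    if spec.bone_profile == "sloped":
        return lambda x: spec.bone_y_px + spec.slope * np.asarray(x, dtype=float)
    sigma = spec.condyle_sigma_px or spec.x_extent_px / 10.0
    x1, x2, xc = (
        0.25 * spec.x_extent_px,
        0.75 * spec.x_extent_px,
        spec.central_x,
    )

    def bicondylar(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        bumps = np.exp(-0.5 * ((x - x1) / sigma) ** 2) + np.exp(
            -0.5 * ((x - x2) / sigma) ** 2
        )
        notch = np.exp(-0.5 * ((x - xc) / (0.4 * sigma)) ** 2)
        return spec.bone_y_px - spec.condyle_amplitude_px * bumps + (
            spec.notch_depth_px * notch
        )

    return bicondylar


def _thickness_function(spec: PhantomSpec) -> Callable[[np.ndarray], np.ndarray]:
    prof = spec.thickness_profile
    if callable(prof):
        return lambda x: np.asarray(prof(np.asarray(x, dtype=float)), dtype=float)
    cut_lo, cut_hi = spec.cuts()
    if spec.medial_direction == "+x":
        left, mid, right = prof["lateral"], prof["intercondylar"], prof["medial"]
    else:
        left, mid, right = prof["medial"], prof["intercondylar"], prof["lateral"]
    xp = [
        0.0,
        cut_lo - _CUT_EPS,
        cut_lo + _CUT_EPS,
        cut_hi - _CUT_EPS,
        cut_hi + _CUT_EPS,
        spec.x_extent_px,
    ]
    fp = [left, left, mid, mid, right, right]
    return lambda x: np.interp(np.asarray(x, dtype=float), xp, fp)


def _vertex_grid(spec: PhantomSpec) -> np.ndarray:
    x = np.arange(0.0, spec.x_extent_px, spec.vertex_spacing_px)
    if x[-1] < spec.x_extent_px:
        x = np.append(x, spec.x_extent_px)
    if isinstance(spec.thickness_profile, Mapping):
        cut_lo, cut_hi = spec.cuts()
        extra = np.array(
            [cut_lo - _CUT_EPS, cut_lo + _CUT_EPS, cut_hi - _CUT_EPS, cut_hi + _CUT_EPS]
        )
        x = np.union1d(x, extra[(extra > 0) & (extra < spec.x_extent_px)])
    return x


def true_regional_thickness(spec: PhantomSpec, n_samples: int = 200_001) -> dict:
    """Noise-free regional thickness of the phantom by dense quadrature.

    Because the superior border is the bone profile minus the vertical
    thickness, the regional CSA is the integral of thickness over the strip
    and the denominator is the bone arc length; for a flat bone and
    piecewise-constant profile this reduces to the profile values exactly.
    """
    bone = _bone_function(spec)
    thick = _thickness_function(spec)
    cut_lo, cut_hi = spec.cuts()
    strips = {"left": (0.0, cut_lo), "middle": (cut_lo, cut_hi),
              "right": (cut_hi, spec.x_extent_px)}
    if spec.medial_direction == "+x":
        by_region = {"medial": "right", "intercondylar": "middle", "lateral": "left"}
    else:
        by_region = {"medial": "left", "intercondylar": "middle", "lateral": "right"}
    cal = spec.calibration
    out: dict[str, float] = {}
    for region, strip in by_region.items():
        lo, hi = strips[strip]
        x = np.linspace(lo, hi, n_samples)
        area = np.trapezoid(thick(x), x) * cal.mm_per_px_x  # thickness already mm
        y_mm = bone(x) * cal.mm_per_px_y
        x_mm = x * cal.mm_per_px_x
        arc = float(np.hypot(np.diff(x_mm), np.diff(y_mm)).sum())
        out[region] = float(area / arc)
    return out


def make_phantom(spec: PhantomSpec) -> tuple[CartilageSegmentation, SyntheticTruth]:
    """Build a calibrated two-border segmentation from the phantom spec.

    Deterministic given the seed.  Raises :class:`InvalidSpecError` if noise
    makes the borders touch or cross.
    """
    rng = np.random.default_rng(spec.seed)
    x = _vertex_grid(spec)
    bone = _bone_function(spec)(x)
    thick_mm = _thickness_function(spec)(x)
    if np.any(thick_mm <= 0):
        raise InvalidSpecError("thickness must be positive everywhere")
    sup_y = bone - thick_mm / spec.calibration.mm_per_px_y
    inf_y = bone.copy()
    if spec.border_noise_sd_px > 0:
        sup_y = sup_y + rng.normal(0.0, spec.border_noise_sd_px, size=x.shape)
        inf_y = inf_y + rng.normal(0.0, spec.border_noise_sd_px, size=x.shape)
    if np.any(sup_y >= inf_y):
        raise InvalidSpecError("borders touch or cross (noise too large?)")
    seg = CartilageSegmentation(
        superior=Polyline(np.column_stack([x, sup_y])),
        inferior=Polyline(np.column_stack([x, inf_y])),
        central_point=(spec.central_x, float(np.interp(spec.central_x, x, sup_y))),
        calibration=spec.calibration,
        medial_direction=spec.medial_direction,  # type: ignore[arg-type]
        meta={"seed": spec.seed, "bone_profile": spec.bone_profile},
    )
    truth = SyntheticTruth(regional_thickness_mm=true_regional_thickness(spec))
    return seg, truth


@dataclass(frozen=True)
class CohortSpec:
    """Variance-component model for a simulated measurement cohort.

    Each measurement is mu_region + subject effect + session effect + image
    error; in longitudinal mode a per-knee true change (mixture of
    thickening, thinning, and stable fractions) is added from session 2 on.
    """

    n_subjects: int = 30
    k_sessions: int = 2
    images_per_session: int = 3
    region_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_MEANS)
    )
    between_subject_sd: float = 0.4
    between_session_sd: float = 0.07
    within_session_sd: float = 0.0
    limbs: Sequence[str] = ("involved",)
    change_fraction_up: float = 0.0
    change_fraction_down: float = 0.0
    change_magnitude_mm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.k_sessions < 1 or self.images_per_session < 1:
            raise InvalidSpecError("counts must be >= 1")
        for sd in (
            self.between_subject_sd,
            self.between_session_sd,
            self.within_session_sd,
        ):
            if sd < 0:
                raise InvalidSpecError("SDs must be non-negative")
        if self.change_fraction_up < 0 or self.change_fraction_down < 0:
            raise InvalidSpecError("mixture fractions must be non-negative")
        if self.change_fraction_up + self.change_fraction_down > 1:
            raise InvalidSpecError("mixture fractions must sum to <= 1")
        if not self.limbs:
            raise InvalidSpecError("need at least one limb")


def closed_form_icc2k(
    sigma_b: float, sigma_s: float, sigma_e: float = 0.0,
    k: int = 2, images_per_session: int = 1,
) -> float:
    """Expected ICC(2,k) for the cohort model with no session main effect:
    reliability of the k-session average, sigma_b^2 / (sigma_b^2 + sigma_w^2/k)
    with sigma_w^2 = sigma_s^2 + sigma_e^2 / images_per_session."""
    sw2 = sigma_s**2 + sigma_e**2 / images_per_session
    denom = sigma_b**2 + sw2 / k
    if denom == 0:
        raise InvalidSpecError("all variance components are zero")
    return sigma_b**2 / denom


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw a long-format cohort table plus its ground truth.

    Output columns: subject, limb, region, session, image_index,
    thickness_mm.  Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    regions = list(spec.region_means)
    subjects = [f"S{i + 1:03d}" for i in range(spec.n_subjects)]

    # per-knee true change drawn from the mixture
    p = [
        spec.change_fraction_up,
        spec.change_fraction_down,
        1.0 - spec.change_fraction_up - spec.change_fraction_down,
    ]
    delta_rows = []
    for subject in subjects:
        for limb in spec.limbs:
            kind = rng.choice(("up", "down", "none"), p=p)
            delta = {
                "up": spec.change_magnitude_mm,
                "down": -spec.change_magnitude_mm,
                "none": 0.0,
            }[kind]
            delta_rows.append(
                {"subject": subject, "limb": limb, "delta_mm": delta, "label": kind}
            )
    deltas = pd.DataFrame(delta_rows)
    delta_lookup = {
        (r["subject"], r["limb"]): r["delta_mm"] for r in delta_rows
    }

    rows = []
    for subject in subjects:
        for limb in spec.limbs:
            for region in regions:
                b = rng.normal(0.0, spec.between_subject_sd)
                mu = spec.region_means[region] + b
                for session in range(1, spec.k_sessions + 1):
                    s = rng.normal(0.0, spec.between_session_sd)
                    shift = delta_lookup[(subject, limb)] if session >= 2 else 0.0
                    for image in range(1, spec.images_per_session + 1):
                        e = rng.normal(0.0, spec.within_session_sd)
                        rows.append(
                            {
                                "subject": subject,
                                "limb": limb,
                                "region": region,
                                "session": session,
                                "image_index": image,
                                "thickness_mm": mu + s + shift + e,
                            }
                        )
    df = pd.DataFrame(rows)
    truth = SyntheticTruth(
        variance_components={
            "between_subject_sd": spec.between_subject_sd,
            "between_session_sd": spec.between_session_sd,
            "within_session_sd": spec.within_session_sd,
        },
        true_deltas=deltas[["subject", "limb", "delta_mm"]],
        responder_labels=deltas[["subject", "limb", "label"]],
    )
    return df, truth


def rasterize_phantom(
    seg: CartilageSegmentation, shape: tuple[int, int] | None = None
) -> np.ndarray:
    """Binary uint8 mask (255 = cartilage) of the band, pixel-centre
    convention: pixel (r, c) is set when superior(c) <= r <= inferior(c)."""
    if shape is None:
        h = int(np.ceil(seg.inferior.y.max())) + 2
        w = int(np.ceil(seg.x_max)) + 2
        shape = (h, w)
    h, w = shape
    if seg.x_min < -0.5 or seg.x_max > w - 0.5:
        raise InvalidSpecError("segmentation does not fit the frame horizontally")
    if seg.superior.y.min() < -0.5 or seg.inferior.y.max() > h - 0.5:
        raise InvalidSpecError("segmentation does not fit the frame vertically")
    mask = np.zeros(shape, dtype=np.uint8)
    cols = np.arange(int(np.ceil(seg.x_min)), int(np.floor(seg.x_max)) + 1)
    sup = seg.superior.y_at(cols.astype(float))
    inf = seg.inferior.y_at(cols.astype(float))
    for c, ys, yi in zip(cols, sup, inf):
        r0 = int(np.ceil(ys))
        r1 = int(np.floor(yi))
        if r1 >= r0:
            mask[r0 : r1 + 1, c] = 255
    return mask
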