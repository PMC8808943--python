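"""Shared fixtures and independent oracles.

The oracle functions here deliberately avoid the package's computational
paths: areas come from dense column sampling of interpolated borders, arc
lengths from dense resampling, ANOVA quantities from longhand loops.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from cartus.geometry import (
    CartilageSegmentation,
    ImageCalibration,
    Polyline,
)


def make_band(
    sup_pts,
    inf_pts,
    central=None,
    cal=(0.1, 0.1),
    medial="+x",
) -> CartilageSegmentation:
    sup = Polyline(sup_pts)
    if central is None:
        cx = 0.5 * (sup.x_min + sup.x_max)
        central = (cx, float(sup.y_at(cx)))
    return CartilageSegmentation(
        superior=sup,
        inferior=Polyline(inf_pts),
        central_point=central,
        calibration=ImageCalibration(*cal),
        medial_direction=medial,
    )


@pytest.fixture
def flat_band() -> CartilageSegmentation:
    """Rectangle band: superior y=80, inferior y=100, x in [0, 400], 0.1 mm/px."""
    return make_band([(0, 80), (400, 80)], [(0, 100), (400, 100)])


@pytest.fixture
def sloped_band() -> CartilageSegmentation:
    """Uniform 20-px vertical gap over a bone sloping from y=100 to y=140."""
    return make_band([(0, 80), (400, 120)], [(0, 100), (400, 140)])


# ---------------------------------------------------------------------------
# independent oracles


def area_oracle_mm2(seg: CartilageSegmentation, x_lo, x_hi, dx=0.01) -> float:
    """Sub-pixel column-sampling area: midpoint-sample the vertical gap
    between np.interp'd borders at resolution dx px."""
    xs = np.arange(x_lo + dx / 2, x_hi, dx)
    sup = np.interp(xs, seg.superior.x, seg.superior.y)
    inf = np.interp(xs, seg.inferior.x, seg.inferior.y)
    gap_px = np.clip(inf - sup, 0.0, None)
    cal = seg.calibration
    return float(gap_px.sum() * dx * cal.mm_per_px_x * cal.mm_per_px_y)


def arc_oracle_mm(seg: CartilageSegmentation, x_lo, x_hi, n=200_000) -> float:
    """Dense-resampling arc length of the inferior border over the strip;
    the sample grid includes the original vertices so each linear piece is
    reproduced exactly."""
    v = seg.inferior.vertices
    xs = np.union1d(
        np.linspace(x_lo, x_hi, n), v[(v[:, 0] >= x_lo) & (v[:, 0] <= x_hi), 0]
    )
    ys = np.interp(xs, v[:, 0], v[:, 1])
    cal = seg.calibration
    dx = np.diff(xs) * cal.mm_per_px_x
    dy = np.diff(ys) * cal.mm_per_px_y
    return float(np.hypot(dx, dy).sum())


def icc2k_oracle(values: np.ndarray) -> float:
    """Longhand two-way ANOVA decomposition and ICC(2,k), loops only."""
    v = np.asarray(values, dtype=float)
    n, k = v.shape
    grand = sum(v[i][j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(v[i]) / k for i in range(n)]
    col = [sum(v[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((r - grand) ** 2 for r in row)
    ssc = n * sum((c - grand) ** 2 for c in col)
    sst = sum((v[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (msc - mse) / n)


def rm_anova_oracle(values: np.ndarray) -> dict[str, float]:
    """Longhand 2x2 within-subject F statistics, loops only."""
    v = np.asarray(values, dtype=float)
    n = v.shape[0]
    grand = v.mean()
    fs = {}
    # factor A (axis 1)
    for name, axis in (("A", 1), ("B", 2)):
        eff_means = [v.take(level, axis=axis).mean() for level in range(2)]
        ss_eff = 2 * n * sum((m - grand) ** 2 for m in eff_means)
        ss_err = 0.0
        for i in range(n):
            subj_mean = v[i].mean()
            for level in range(2):
                cell = v[i].take(level, axis=axis - 1).mean()
                ss_err += 2 * (cell - subj_mean - eff_means[level] + grand) ** 2
        fs[name] = (ss_eff / 1.0) / (ss_err / (n - 1)) if ss_err > 0 else (
            0.0 if ss_eff == 0 else math.inf
        )
    # interaction
    a_means = [v[:, level, :].mean() for level in range(2)]
    b_means = [v[:, :, level].mean() for level in range(2)]
    cell = [[v[:, a, b].mean() for b in range(2)] for a in range(2)]
    ss_ab = n * sum(
        (cell[a][b] - a_means[a] - b_means[b] + grand) ** 2
        for a in range(2)
        for b in range(2)
    )
    ss_abs = 0.0
    for i in range(n):
        subj = v[i].mean()
        sa = [v[i, a, :].mean() for a in range(2)]
        sb = [v[i, :, b].mean() for b in range(2)]
        for a in range(2):
            for b in range(2):
                ss_abs += (
                    v[i, a, b]
                    - sa[a]
                    - sb[b]
                    - cell[a][b]
                    + subj
                    + a_means[a]
                    + b_means[b]
                    - grand
                ) ** 2
    fs["AB"] = (ss_ab / 1.0) / (ss_abs / (n - 1)) if ss_abs > 0 else (
        0.0 if ss_ab == 0 else math.inf
    )
    return fs


def fisher_oracle(table) -> float:
    """Two-sided Fisher p by exhaustive enumeration over all 2x2 tables
    with the observed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x)
            * math.comb(r2, c1 - x)
            / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-12):
            total += px
    return total
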