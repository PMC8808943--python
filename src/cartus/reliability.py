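"""Test-retest reliability and precision: ICC(2,k), SEM, MDC90.

The ICC is the two-way random-effects, absolute-agreement, average-of-k
intraclass correlation (Shrout-Fleiss ICC(2,k) / McGraw-Wong ICC(A,k)) with
an F-based 95% confidence interval.  SEM = SD * sqrt(1 - ICC) and
MDC90 = 1.654 * SEM * sqrt(2); the constant 1.654 is configurable (the
conventional z for 90% two-sided confidence is 1.645).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import StatisticsError, UndefinedICCError

#: multiplier applied to SEM * sqrt(2) for the 90%-confidence detectable change
DEFAULT_MDC_CONSTANT = 1.654

ICC_CLASSES = ("poor", "moderate", "good", "excellent")


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (table-reporting convention)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MeasurementMatrix:
    """Complete subjects x sessions grid of thickness values for one region."""

    values: np.ndarray
    region: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise StatisticsError("measurement matrix must be 2-D")
        n, k = v.shape
        if k < 2:
            raise StatisticsError("need at least 2 sessions")
        if n < 3:
            raise StatisticsError("need at least 3 subjects")
        if not np.all(np.isfinite(v)):
            raise StatisticsError("measurement matrix has missing/non-finite cells")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_lo: float
    ci_hi: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n: int
    k: int


@dataclass(frozen=True)
class ReliabilityResult:
    """Table-2-style row for one region."""

    region: str | None
    icc: float
    ci_lo: float
    ci_hi: float
    sem: float
    mdc90: float
    icc_class: str


def _mean_squares(v: np.ndarray) -> tuple[float, float, float]:
    n, k = v.shape
    grand = v.mean()
    row_means = v.mean(axis=1)
    col_means = v.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((v - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    return ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))


def icc_2k(m: MeasurementMatrix | np.ndarray, confidence: float = 0.95) -> ICCResult:
    """ICC(2,k) with its F-based confidence interval.

    The point estimate is (MSR - MSE) / (MSR + (MSC - MSE)/n) from the
    two-way ANOVA mean squares.  The CI is the single-measure ICC(A,1)
    interval (Satterthwaite denominator df) stepped up to k measures by the
    Spearman-Brown relation.
    """
    if not isinstance(m, MeasurementMatrix):
        m = MeasurementMatrix(np.asarray(m, dtype=float))
    v = m.values
    n, k = m.n, m.k
    msr, msc, mse = _mean_squares(v)
    denom = msr + (msc - mse) / n
    if math.isclose(denom, 0.0, abs_tol=1e-30) or float(np.var(v)) == 0.0:
        raise UndefinedICCError("zero total variance: ICC undefined")
    icc_k = (msr - mse) / denom

    if mse == 0.0 and msc == 0.0:
        # degenerate perfect agreement; F-based interval collapses
        return ICCResult(icc_k, icc_k, icc_k, msr, msc, mse, n, k)

    # single-measure estimate drives the CI construction
    rho1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    alpha = 1.0 - confidence
    a = k * rho1 / (n * (1.0 - rho1)) if rho1 < 1.0 else math.inf
    b = 1.0 + k * rho1 * (n - 1) / (n * (1.0 - rho1)) if rho1 < 1.0 else math.inf
    if not math.isfinite(a):
        return ICCResult(icc_k, icc_k, icc_k, msr, msc, mse, n, k)
    nu_num = (a * msc + b * mse) ** 2
    nu_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    nu = nu_num / nu_den if nu_den > 0 else n - 1
    f_u = stats.f.ppf(1 - alpha / 2, n - 1, nu)
    f_l = stats.f.ppf(1 - alpha / 2, nu, n - 1)
    lo1 = n * (msr - f_u * mse) / (
        f_u * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    hi1 = n * (f_l * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_l * msr
    )
    lo = k * lo1 / (1 + (k - 1) * lo1)
    hi = k * hi1 / (1 + (k - 1) * hi1)
    lo = min(lo, icc_k)
    hi = max(hi, icc_k)
    return ICCResult(icc_k, lo, hi, msr, msc, mse, n, k)


def sem(sd: float, icc: float) -> float:
    """Standard error of measurement: SD * sqrt(1 - ICC)."""
    if not 0.0 <= icc <= 1.0:
        raise StatisticsError(f"icc must be in [0, 1], got {icc}")
    if sd < 0:
        raise StatisticsError("sd must be non-negative")
    return sd * math.sqrt(1.0 - icc)


def mdc90(sem_value: float, constant: float = DEFAULT_MDC_CONSTANT) -> float:
    """Minimal detectable change at 90% confidence: constant * SEM * sqrt(2)."""
    if sem_value < 0:
        raise StatisticsError("sem must be non-negative")
    if constant <= 0:
        raise StatisticsError("mdc constant must be positive")
    return constant * sem_value * math.sqrt(2.0)


def sem_mdc_chain(
    sd: float,
    icc: float,
    decimals: int = 2,
    mdc_constant: float = DEFAULT_MDC_CONSTANT,
) -> tuple[float, float]:
    """Published-table reporting chain: SEM rounded to ``decimals``, then
    MDC90 computed from that *rounded* SEM and rounded again.

    The two-stage rounding is what the published medial row implies
    (SD 0.38, ICC 0.97 -> SEM 0.0658 -> 0.07 -> MDC 0.1637 -> 0.16; the
    full-precision MDC would round to 0.15).
    """
    sem_r = round_half_away(sem(sd, icc), decimals)
    mdc_r = round_half_away(mdc90(sem_r, constant=mdc_constant), decimals)
    return sem_r, mdc_r


def classify_icc(icc: float) -> str:
    """Qualitative reliability label.

    The published cut-offs leave gaps (0.49/0.5 and 0.89/0.9); implemented
    as half-open bands [0, 0.5) poor, [0.5, 0.75) moderate, [0.75, 0.9)
    good, [0.9, inf) excellent.
    """
    if not math.isfinite(icc):
        raise StatisticsError("icc must be finite")
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


def sessions_from_long(df: pd.DataFrame, region: str) -> pd.DataFrame:
    """Average the repeat images within each (subject, session) for one
    region, returning a complete subjects x sessions wide table."""
    sub = df[df["region"] == region]
    if sub.empty:
        raise StatisticsError(f"no rows for region {region!r}")
    per_session = (
        sub.groupby(["subject", "session"])["thickness_mm"].mean().unstack("session")
    )
    if per_session.isna().any().any():
        missing = per_session[per_session.isna().any(axis=1)].index.tolist()
        raise StatisticsError(
            f"region {region!r}: missing sessions for subjects {missing}"
        )
    return per_session


def region_reliability(
    m: MeasurementMatrix,
    sd: float | None = None,
    confidence: float = 0.95,
    mdc_constant: float = DEFAULT_MDC_CONSTANT,
) -> ReliabilityResult:
    """ICC / SEM / MDC90 chain for one region.

    ``sd`` defaults to the between-subject SD (ddof=1) of the first-session
    values, the choice that reproduces the published SEMs from the
    healthy-control SDs.
    """
    res = icc_2k(m, confidence=confidence)
    if sd is None:
        sd = float(np.std(m.values[:, 0], ddof=1))
    icc_for_sem = min(max(res.icc, 0.0), 1.0)
    s = sem(sd, icc_for_sem)
    return ReliabilityResult(
        region=m.region,
        icc=res.icc,
        ci_lo=res.ci_lo,
        ci_hi=res.ci_hi,
        sem=s,
        mdc90=mdc90(s, constant=mdc_constant),
        icc_class=classify_icc(res.icc),
    )


def reliability_table(
    df: pd.DataFrame,
    regions: tuple[str, ...] | None = None,
    confidence: float = 0.95,
    mdc_constant: float = DEFAULT_MDC_CONSTANT,
) -> pd.DataFrame:
    """Per-region reliability summary from a long-format measurement table.

    Expects columns subject, region, session, thickness_mm (and optionally
    image_index, averaged out within session).  Returns one row per region
    with columns region, n, icc, ci_lo, ci_hi, sd, sem, mdc90, icc_class at
    full precision.
    """
    required = {"subject", "region", "session", "thickness_mm"}
    missing = required - set(df.columns)
    if missing:
        raise StatisticsError(f"measurement table missing columns: {sorted(missing)}")
    if regions is None:
        regions = tuple(pd.unique(df["region"]))
    rows = []
    for region in regions:
        wide = sessions_from_long(df, region)
        m = MeasurementMatrix(wide.to_numpy(), region=region)
        r = region_reliability(
            m, confidence=confidence, mdc_constant=mdc_constant
        )
        rows.append(
            {
                "region": region,
                "n": m.n,
                "icc": r.icc,
                "ci_lo": r.ci_lo,
                "ci_hi": r.ci_hi,
                "sd": float(np.std(m.values[:, 0], ddof=1)),
                "sem": r.sem,
                "mdc90": r.mdc90,
                "icc_class": r.icc_class,
            }
        )
    return pd.DataFrame(rows)
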