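"""Comparative statistics: 2x2 within-subject ANOVA, t-tests, Fisher exact.

The repeated-measures ANOVA is the fully-within two-factor (limb x time)
design with both factors at two levels, so every effect has (1, n-1)
degrees of freedom and sphericity holds automatically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import StatisticsError, UndefinedStatisticError


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p: float
    mean_diff: float | None = None


def rm_anova_2x2(
    values: np.ndarray, factors: tuple[str, str] = ("limb", "time")
) -> pd.DataFrame:
    """Two-way repeated-measures ANOVA on an (n_subjects, 2, 2) grid.

    Returns a tidy table with one row per effect (factor A, factor B, A x B),
    each tested against its own subject-interaction error term with
    (1, n - 1) degrees of freedom.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 3 or v.shape[1:] != (2, 2):
        raise StatisticsError("expected an (n_subjects, 2, 2) value grid")
    if not np.all(np.isfinite(v)):
        raise StatisticsError("missing cells are not allowed (no imputation)")
    n = v.shape[0]
    if n < 3:
        raise StatisticsError("need at least 3 subjects")

    grand = v.mean()
    subj = v.mean(axis=(1, 2))          # (n,)
    a_means = v.mean(axis=(0, 2))       # (2,) factor A
    b_means = v.mean(axis=(0, 1))       # (2,) factor B
    cell = v.mean(axis=0)               # (2, 2)
    sa = v.mean(axis=2)                 # (n, 2) subject x A
    sb = v.mean(axis=1)                 # (n, 2) subject x B

    ss_a = 2 * n * float(((a_means - grand) ** 2).sum())
    ss_b = 2 * n * float(((b_means - grand) ** 2).sum())
    ss_ab = n * float(
        ((cell - a_means[:, None] - b_means[None, :] + grand) ** 2).sum()
    )
    ss_as = 2 * float(
        ((sa - subj[:, None] - a_means[None, :] + grand) ** 2).sum()
    )
    ss_bs = 2 * float(
        ((sb - subj[:, None] - b_means[None, :] + grand) ** 2).sum()
    )
    resid = (
        v
        - sa[:, :, None]
        - sb[:, None, :]
        - cell[None, :, :]
        + subj[:, None, None]
        + a_means[None, :, None]
        + b_means[None, None, :]
        - grand
    )
    ss_abs = float((resid ** 2).sum())

    # guard against 0/0 from floating-point dust when a factor is inert
    ss_tot = float(((v - grand) ** 2).sum())
    tol = 1e-12 * max(ss_tot, 1e-30)

    rows = []
    for name, ss_eff, ss_err in (
        (factors[0], ss_a, ss_as),
        (factors[1], ss_b, ss_bs),
        (f"{factors[0]} x {factors[1]}", ss_ab, ss_abs),
    ):
        ms_eff = ss_eff / 1.0
        ms_err = ss_err / (n - 1)
        if ss_err <= tol:
            f = 0.0 if ss_eff <= tol else math.inf
        else:
            f = ms_eff / ms_err
        p = float(stats.f.sf(f, 1, n - 1)) if math.isfinite(f) else 0.0
        rows.append(
            {"effect": name, "F": f, "df_num": 1, "df_den": n - 1, "p": p}
        )
    return pd.DataFrame(rows)


def paired_t(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Two-sided paired t-test; x == y exactly gives t = 0, p = 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise StatisticsError("paired_t needs two equal-length 1-D samples, n >= 2")
    d = x - y
    sd = float(np.std(d, ddof=1))
    md = float(d.mean())
    n = d.size
    if sd == 0.0:
        if md == 0.0:
            return TestResult(statistic=0.0, df=n - 1, p=1.0, mean_diff=0.0)
        raise UndefinedStatisticError("zero variance of differences, nonzero mean")
    t = md / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), n - 1))
    return TestResult(statistic=t, df=n - 1, p=p, mean_diff=md)


def independent_t(
    x: np.ndarray, y: np.ndarray, equal_var: bool = True
) -> TestResult:
    """Two-sided independent-samples t-test (pooled variance by default;
    ``equal_var=False`` gives the Welch variant)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size < 2 or y.size < 2:
        raise StatisticsError("independent_t needs two 1-D samples, n >= 2 each")
    vx, vy = float(np.var(x, ddof=1)), float(np.var(y, ddof=1))
    if vx == 0.0 and vy == 0.0:
        raise UndefinedStatisticError("both samples have zero variance")
    nx, ny = x.size, y.size
    md = float(x.mean() - y.mean())
    if equal_var:
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se = math.sqrt(sp2 * (1 / nx + 1 / ny))
        df: float = nx + ny - 2
    else:
        se = math.sqrt(vx / nx + vy / ny)
        df = (vx / nx + vy / ny) ** 2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        )
    t = md / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TestResult(statistic=t, df=df, p=p, mean_diff=md)


def fisher_exact_2x2(table: np.ndarray) -> TestResult:
    """Two-sided Fisher exact test: p is the sum of hypergeometric
    probabilities no larger than that of the observed table."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise StatisticsError("fisher_exact_2x2 needs a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t < 0) or not np.allclose(t, np.round(t)):
            raise StatisticsError("table cells must be non-negative integers")
        t = t.astype(int)
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    return TestResult(statistic=float(odds), df=math.nan, p=float(p))


def compare_table(df: pd.DataFrame) -> pd.DataFrame:
    """Run the limb x time repeated-measures ANOVA per region on a
    long-format table (subject, limb, session, region, thickness_mm) and
    return a tidy results table."""
    required = {"subject", "limb", "region", "session", "thickness_mm"}
    missing = required - set(df.columns)
    if missing:
        raise StatisticsError(f"table missing columns: {sorted(missing)}")
    limbs = sorted(df["limb"].unique())
    sessions = sorted(df["session"].unique())
    if len(limbs) != 2 or len(sessions) != 2:
        raise StatisticsError("need exactly 2 limbs and 2 sessions")
    out = []
    for region, grp in df.groupby("region", sort=False):
        wide = (
            grp.groupby(["subject", "limb", "session"])["thickness_mm"]
            .mean()
            .unstack(["limb", "session"])
        )
        expected = {(limb, s) for limb in limbs for s in sessions}
        if set(wide.columns) != expected or wide.isna().any().any():
            raise StatisticsError(f"region {region!r}: incomplete limb x session grid")
        n = len(wide)
        grid = np.empty((n, 2, 2))
        for i, limb in enumerate(limbs):
            for j, s in enumerate(sessions):
                grid[:, i, j] = wide[(limb, s)].to_numpy()
        tab = rm_anova_2x2(grid, factors=("limb", "time"))
        tab.insert(0, "region", region)
        out.append(tab)
    return pd.concat(out, ignore_index=True)
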