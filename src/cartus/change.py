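"""Responder classification of longitudinal thickness change against MDC90.

A knee-region whose between-session change strictly exceeds +MDC90 is
labelled thickening, one below -MDC90 thinning, anything else no_change.
Cohort summaries report, per limb, the percentage of participants with at
least one thickening region and with at least one thinning region; the two
percentages are not mutually exclusive.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import IncompleteParticipantError, StatisticsError

THICKENING = "thickening"
THINNING = "thinning"
NO_CHANGE = "no_change"

LABELS = (THICKENING, THINNING, NO_CHANGE)


def classify_change(delta: float, mdc: float) -> str:
    """Label one knee-region change; 'exceeded' is a strict inequality, so
    |delta| == mdc is no_change."""
    if math.isnan(mdc) or mdc < 0:
        raise StatisticsError("mdc must be non-negative")
    if delta > mdc:
        return THICKENING
    if delta < -mdc:
        return THINNING
    return NO_CHANGE


def build_change_matrix(
    cohort: pd.DataFrame,
    mdc_per_region: Mapping[str, float],
    session_pre: object = 1,
    session_post: object = 2,
) -> pd.DataFrame:
    """Per-participant/limb/region deltas and labels across two sessions.

    ``cohort`` is long-format with columns subject, limb, region, session,
    thickness_mm (repeat images averaged within session).  The delta is
    session_post mean minus session_pre mean; labels use that region's MDC.
    Raises :class:`IncompleteParticipantError` listing any participant
    missing either session for a limb/region present elsewhere.
    """
    required = {"subject", "limb", "region", "session", "thickness_mm"}
    missing = required - set(cohort.columns)
    if missing:
        raise StatisticsError(f"cohort table missing columns: {sorted(missing)}")
    for region in cohort["region"].unique():
        if region not in mdc_per_region:
            raise StatisticsError(f"no MDC provided for region {region!r}")
        if mdc_per_region[region] < 0:
            raise StatisticsError(f"negative MDC for region {region!r}")

    per_session = (
        cohort.groupby(["subject", "limb", "region", "session"])["thickness_mm"]
        .mean()
        .unstack("session")
    )
    for s in (session_pre, session_post):
        if s not in per_session.columns:
            raise IncompleteParticipantError(
                sorted(per_session.index.get_level_values("subject").unique())
            )
    both = per_session[[session_pre, session_post]]
    incomplete = both[both.isna().any(axis=1)]
    if not incomplete.empty:
        raise IncompleteParticipantError(
            sorted(incomplete.index.get_level_values("subject").unique())
        )

    out = both.reset_index()
    out["delta_mm"] = out[session_post] - out[session_pre]
    out["label"] = [
        classify_change(d, mdc_per_region[r])
        for d, r in zip(out["delta_mm"], out["region"])
    ]
    return out[["subject", "limb", "region", "delta_mm", "label"]]


def frequency_summary(change_matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-limb percentages of participants with >= 1 thickening region and
    >= 1 thinning region (a participant may count in both)."""
    if change_matrix.empty:
        raise StatisticsError("change matrix is empty")
    rows = []
    for limb, grp in change_matrix.groupby("limb", sort=False):
        n = grp["subject"].nunique()
        up = grp.loc[grp["label"] == THICKENING, "subject"].nunique()
        down = grp.loc[grp["label"] == THINNING, "subject"].nunique()
        rows.append(
            {
                "limb": limb,
                "pct_thickening": 100.0 * up / n,
                "pct_thinning": 100.0 * down / n,
                "n": n,
            }
        )
    return pd.DataFrame(rows)


def exceedance_rate(deltas: np.ndarray, mdc: float) -> float:
    """Fraction of deltas whose magnitude strictly exceeds the MDC."""
    d = np.asarray(deltas, dtype=float)
    if d.size == 0:
        raise StatisticsError("no deltas supplied")
    return float(np.mean(np.abs(d) > mdc))
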