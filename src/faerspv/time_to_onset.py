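"""Time-to-onset (TTO) analysis of adverse-event reports.

TTO is the calendar-day interval from the earliest full-precision therapy
start date to the event date.  Only cases where both dates carry full
YYYYMMDD precision contribute; partial dates would fabricate day-level
intervals and are excluded with a reason, as are negative intervals
(event before therapy).  Zero days is a valid onset.

Summaries use linear-interpolation (type-7) quantiles, and the survival
curve is the empirical survival function S(t) = P(T > t): every report is
an observed event, so no censoring model applies.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .faers_ingest import CaseData, MeddraMap, MISSING_LABEL, parse_faers_date
from .reporting_util import percent

#: Onset bins in days: [0,30], [31,60], ..., [181,360], >360.
TTO_BINS: list[tuple[int, float]] = [
    (0, 30), (31, 60), (61, 90), (91, 120), (121, 150), (151, 180),
    (181, 360), (361, float("inf")),
]
TTO_BIN_LABELS = ["0-30", "31-60", "61-90", "91-120", "121-150", "151-180", "181-360", ">360"]


class TTOError(ValueError):
    pass


@dataclass(frozen=True)
class TTOResult:
    days: int | None
    reason: str = ""  # non-empty iff excluded


def compute_tto(event_dt, start_dt) -> TTOResult:
    """Calendar-day difference event − start, or the exclusion reason.

    Exclusion reasons: "partial date" (either date lacks day precision or
    is missing) and "event precedes therapy" (negative interval).
    """
    event, event_prec = parse_faers_date(event_dt)
    start, start_prec = parse_faers_date(start_dt)
    if event_prec != "full" or start_prec != "full":
        return TTOResult(None, "partial date")
    days = (event - start).days
    if days < 0:
        return TTOResult(None, "event precedes therapy")
    return TTOResult(days)


def tto_samples(dataset: CaseData, meddra_map: MeddraMap | None = None) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-case TTO samples for the target cohort, with stratum labels.

    Returns (samples, exclusion counts); samples columns: primaryid,
    tto_days, sex, age_group, occp_class, socs (tuple of reaction SOCs,
    empty without a map).
    """
    rows = []
    excluded = {"partial date": 0, "event precedes therapy": 0}
    for row in dataset.target.itertuples(index=False):
        start = "" if pd.isna(row.start_dt) else str(int(row.start_dt))
        result = compute_tto(row.event_dt, start)
        if result.days is None:
            excluded[result.reason] += 1
            continue
        socs = ()
        if meddra_map is not None:
            socs = tuple(sorted({meddra_map.soc_of(pt) for pt in row.reactions}))
        rows.append({
            "primaryid": int(row.primaryid), "tto_days": int(result.days),
            "sex": row.sex if row.sex else MISSING_LABEL,
            "age_group": row.age_group, "occp_class": row.occp_class,
            "socs": socs,
        })
    return pd.DataFrame(rows, columns=["primaryid", "tto_days", "sex", "age_group", "occp_class", "socs"]), excluded


def bin_tto(days: Sequence[int]) -> pd.DataFrame:
    """Counts and percentages per onset bin (columns bin, n, pct, pct_display).

    ``pct`` keeps full precision; ``pct_display`` is rounded half-up to one
    decimal.  Empty input yields an empty summary.
    """
    days = np.asarray(list(days), dtype=float)
    if len(days) == 0:
        return pd.DataFrame(columns=["bin", "n", "pct", "pct_display"])
    total = len(days)
    rows = []
    for label, (lo, hi) in zip(TTO_BIN_LABELS, TTO_BINS):
        n = int(((days >= lo) & (days <= hi)).sum())
        rows.append({
            "bin": label, "n": n, "pct": 100.0 * n / total,
            "pct_display": percent(n, total),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TTOSummary:
    n: int
    median: float
    q1: float
    q3: float
    min: float
    max: float


def tto_summary(days: Sequence[int]) -> TTOSummary:
    """Median and quartiles (type-7 linear interpolation), plus range."""
    arr = np.asarray(list(days), dtype=float)
    if len(arr) == 0:
        raise TTOError("tto_summary requires at least one sample")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return TTOSummary(n=len(arr), median=float(med), q1=float(q1), q3=float(q3),
                      min=float(arr.min()), max=float(arr.max()))


def km_curve(days: Sequence[int]) -> pd.DataFrame:
    """Empirical survival coordinates: S(t) = fraction with TTO > t at each
    distinct observed t (non-increasing; reaches 0 at the maximum)."""
    arr = np.sort(np.asarray(list(days), dtype=float))
    if len(arr) == 0:
        raise TTOError("km_curve requires at least one sample")
    t, counts = np.unique(arr, return_counts=True)
    exceed = len(arr) - np.cumsum(counts)
    return pd.DataFrame({"t": t, "S": exceed / len(arr)})


def tto_by_group(
    samples: pd.DataFrame,
    grouping: str,
    min_n: int = 10,
) -> pd.DataFrame:
    """Per-group TTO summaries (grouping: sex, age_group, occp_class, soc).

    Groups below ``min_n`` samples are flagged low-confidence; empty groups
    are simply absent.  SOC grouping counts a case once per reaction SOC.
    """
    if grouping not in ("sex", "age_group", "occp_class", "soc"):
        raise TTOError(f"unknown grouping {grouping!r}")
    if samples.empty:
        return pd.DataFrame(columns=["group", "n", "median", "q1", "q3", "min", "max", "low_confidence"])
    if grouping == "soc":
        work = samples.explode("socs").rename(columns={"socs": "soc"})
        work = work[work["soc"].notna()]
        key = "soc"
    else:
        work = samples
        key = grouping
    rows = []
    for group, sub in work.groupby(key, sort=True):
        s = tto_summary(sub["tto_days"])
        rows.append({
            "group": group, "n": s.n, "median": s.median, "q1": s.q1, "q3": s.q3,
            "min": s.min, "max": s.max, "low_confidence": s.n < min_n,
        })
    return pd.DataFrame(rows)


def quarter_counts(dataset: CaseData, meddra_map: MeddraMap | None = None) -> pd.DataFrame:
    """Event counts per calendar quarter of the event date (target cohort).

    Cases lacking a full-or-month-precision event date are excluded.  With
    a MedDRA map the table is SOC × quarter (one count per case-SOC);
    otherwise a single overall row per quarter.
    """
    rows = []
    for row in dataset.target.itertuples(index=False):
        s = str(row.event_dt).strip()
        if len(s) < 6 or not s.isdigit():
            continue
        month = int(s[4:6])
        if not 1 <= month <= 12:
            continue
        quarter = f"Q{(month - 1) // 3 + 1}"
        if meddra_map is None:
            rows.append({"soc": "ALL", "quarter": quarter})
        else:
            for soc in {meddra_map.soc_of(pt) for pt in row.reactions}:
                rows.append({"soc": soc, "quarter": quarter})
    if not rows:
        return pd.DataFrame(columns=["soc", "quarter", "n"])
    frame = pd.DataFrame(rows)
    out = frame.groupby(["soc", "quarter"], sort=True).size().reset_index(name="n")
    return out
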