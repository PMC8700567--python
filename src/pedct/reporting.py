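"""Cohort tables: per-subject records, age-group and volume-bin summaries.

Summaries report median (P25, P75) (min, max) per metric. Percentiles use
linear interpolation between order statistics — stated explicitly because
quartiles of ~7-subject groups depend on the convention. Volume bins are
half-open on the left, closed on the right: the first bin runs from the
data minimum to 1500 mL, then (1500, 2000], (2000, 2500], and so on.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

COHORT_COLUMNS = [
    "subject_id",
    "age_years",
    "tlc_ct_ml",
    "mean_hu",
    "sd_hu",
    "lat_hu",
    "hat_hu",
    "pct_low",
    "pct_high",
]

#: Metrics summarized in the age/volume tables, with display precision.
SUMMARY_METRICS = {
    "tlc_ct_mL": 1,
    "mean_hu": 1,
    "lat_hu": 1,
    "hat_hu": 1,
    "pct_low": 2,
    "pct_high": 2,
}

_TLC_BIN_EDGE0 = 1500.0
_TLC_BIN_WIDTH = 500.0


@dataclasses.dataclass(frozen=True)
class CohortRecord:
    """One subject's age and densitometry metrics."""

    subject_id: str
    age_years: int
    tlc_ct_mL: float
    mean_hu: float
    sd_hu: float
    lat_hu: float
    hat_hu: float
    pct_low: float
    pct_high: float

    def __post_init__(self) -> None:
        if self.age_years < 6:
            raise ValueError(f"age_years must be >= 6, got {self.age_years}")
        if self.tlc_ct_mL <= 0:
            raise ValueError("tlc_ct_mL must be > 0")
        if not (self.lat_hu <= self.mean_hu <= self.hat_hu):
            raise ValueError(
                f"threshold ordering violated: lat={self.lat_hu}, "
                f"mean={self.mean_hu}, hat={self.hat_hu}"
            )


@dataclasses.dataclass(frozen=True)
class FiveNumber:
    median: float
    p25: float
    p75: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not (self.min <= self.p25 <= self.median <= self.p75 <= self.max):
            raise ValueError("five-number summary out of order")

    def cell(self, ndigits: int) -> str:
        r = lambda v: round(v, ndigits)
        return (
            f"{r(self.median)} ({r(self.p25)}, {r(self.p75)}) "
            f"({r(self.min)}, {r(self.max)})"
        )


@dataclasses.dataclass(frozen=True)
class GroupSummary:
    group_label: str
    n: int
    stats: dict[str, FiveNumber]


def _five_number(values) -> FiveNumber:
    v = np.asarray(values, dtype=np.float64)
    p25, med, p75 = np.percentile(v, [25, 50, 75])  # linear interpolation
    return FiveNumber(
        median=float(med), p25=float(p25), p75=float(p75),
        min=float(v.min()), max=float(v.max()),
    )


def _summarize_group(label: str, group: list[CohortRecord]) -> GroupSummary:
    return GroupSummary(
        group_label=label,
        n=len(group),
        stats={
            m: _five_number([getattr(r, m) for r in group]) for m in SUMMARY_METRICS
        },
    )


def summarize_by_age(records: list[CohortRecord]) -> list[GroupSummary]:
    """One summary per integer age present, ascending."""
    if not records:
        raise ValueError("records must be nonempty")
    ages = sorted({r.age_years for r in records})
    return [
        _summarize_group(
            f"{age}-year-old", [r for r in records if r.age_years == age]
        )
        for age in ages
    ]


def tlc_bin_index(tlc_ct_mL: float) -> int:
    """0 for the first bin (up to 1500 mL inclusive), then one per 500 mL
    half-open bin above it."""
    if tlc_ct_mL <= _TLC_BIN_EDGE0:
        return 0
    return int(np.ceil((tlc_ct_mL - _TLC_BIN_EDGE0) / _TLC_BIN_WIDTH))


def summarize_by_tlc_bin(records: list[CohortRecord]) -> list[GroupSummary]:
    """Summaries over total-volume bins; empty bins omitted."""
    if not records:
        raise ValueError("records must be nonempty")
    by_bin: dict[int, list[CohortRecord]] = {}
    for r in records:
        by_bin.setdefault(tlc_bin_index(r.tlc_ct_mL), []).append(r)

    data_min = min(r.tlc_ct_mL for r in records)
    out = []
    for idx in sorted(by_bin):
        if idx == 0:
            label = f"{round(data_min, 1)}–{int(_TLC_BIN_EDGE0)}"
        else:
            lo = _TLC_BIN_EDGE0 + (idx - 1) * _TLC_BIN_WIDTH
            label = f"{int(lo) + 1}–{int(lo + _TLC_BIN_WIDTH)}"
        out.append(_summarize_group(label, by_bin[idx]))
    return out


def cohort_medians(records: list[CohortRecord]):
    """Whole-cohort (median, min, max) for total volume and mean
    attenuation, for headline reporting."""
    if not records:
        raise ValueError("records must be nonempty")
    tlc = np.array([r.tlc_ct_mL for r in records])
    mean = np.array([r.mean_hu for r in records])
    return (
        (float(np.median(tlc)), float(tlc.min()), float(tlc.max())),
        (float(np.median(mean)), float(mean.min()), float(mean.max())),
    )


# ---------------------------------------------------------------------------
# I/O and formatting
# ---------------------------------------------------------------------------


def cohort_to_frame(records: list[CohortRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "age_years": r.age_years,
                "tlc_ct_ml": r.tlc_ct_mL,
                "mean_hu": r.mean_hu,
                "sd_hu": r.sd_hu,
                "lat_hu": r.lat_hu,
                "hat_hu": r.hat_hu,
                "pct_low": r.pct_low,
                "pct_high": r.pct_high,
            }
            for r in records
        ],
        columns=COHORT_COLUMNS,
    )


def cohort_to_csv(records: list[CohortRecord], path: str | Path) -> None:
    # %.17g guarantees float64 round-trip through the text format.
    cohort_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def cohort_from_csv(path: str | Path) -> list[CohortRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return [
        CohortRecord(
            subject_id=str(row.subject_id),
            age_years=int(row.age_years),
            tlc_ct_mL=float(row.tlc_ct_ml),
            mean_hu=float(row.mean_hu),
            sd_hu=float(row.sd_hu),
            lat_hu=float(row.lat_hu),
            hat_hu=float(row.hat_hu),
            pct_low=float(row.pct_low),
            pct_high=float(row.pct_high),
        )
        for row in df.itertuples(index=False)
    ]


def summaries_to_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    """Wide table with one ``median (p25, p75) (min, max)`` cell per metric."""
    rows = []
    for s in summaries:
        row = {"group": s.group_label, "n": s.n}
        for metric, ndigits in SUMMARY_METRICS.items():
            row[metric] = s.stats[metric].cell(ndigits)
        rows.append(row)
    return pd.DataFrame(rows)


def summaries_to_markdown(summaries: list[GroupSummary]) -> str:
    return summaries_to_frame(summaries).to_markdown(index=False)
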