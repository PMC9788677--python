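"""Per-subject longitudinal severity series: interior-gap imputation,
centred moving-average trend estimation, and before/after event splits.

Missing test days strictly inside the observed span are filled by piecewise
linear interpolation (PLI) and flagged ``imputed``; no extrapolation occurs
outside the span.  The trend ẑ is a centred linear moving-average filter of
odd order (default 7 days) over the imputed series; imputed days enter the
trend but are excluded from any model evaluation or before/after testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SeriesEntry:
    study_day: int
    value: float
    imputed: bool = False


@dataclass(frozen=True)
class SeverityTimeSeries:
    """Ordered, dated daily severities for one subject."""

    subject_id: str
    entries: tuple[SeriesEntry, ...]

    def __post_init__(self) -> None:
        days = [e.study_day for e in self.entries]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("study days must be strictly increasing")

    @property
    def days(self) -> np.ndarray:
        return np.array([e.study_day for e in self.entries])

    @property
    def values(self) -> np.ndarray:
        return np.array([e.value for e in self.entries])

    @property
    def imputed_mask(self) -> np.ndarray:
        return np.array([e.imputed for e in self.entries])

    def observed(self) -> "SeverityTimeSeries":
        return SeverityTimeSeries(
            self.subject_id,
            tuple(e for e in self.entries if not e.imputed))

    @classmethod
    def from_daily(cls, subject_id: str, severities) -> "SeverityTimeSeries":
        entries = tuple(
            SeriesEntry(s.study_day, s.value, s.imputed)
            for s in sorted(severities, key=lambda s: s.study_day))
        return cls(subject_id, entries)


@dataclass(frozen=True)
class TrendSeries:
    """Moving-average severity trend ẑ on the (imputed) day grid."""

    subject_id: str
    days: np.ndarray
    trend: np.ndarray
    window_days: int


@dataclass
class EventAnalysis:
    """Observed severities partitioned around a clinical event day.

    The event day itself belongs to the *after* side (the event "onsets" on
    that date).  Imputed entries appear on neither side.
    """

    subject_id: str
    event_day: int
    before: np.ndarray
    after: np.ndarray
    tests: object | None = field(default=None)
    computable: bool = True
    reason: str = ""


def impute_pli(series: SeverityTimeSeries) -> SeverityTimeSeries:
    """Fill every integer day strictly between the first and last observed
    day by piecewise linear interpolation between the nearest observed
    neighbours.  Idempotent; no extrapolation outside the span."""
    obs = [e for e in series.entries if not e.imputed]
    if len(obs) < 2:
        logger.warning("subject %s: <2 observed entries; returning unchanged",
                       series.subject_id)
        return series
    obs_days = np.array([e.study_day for e in obs])
    obs_vals = np.array([e.value for e in obs])
    grid = np.arange(obs_days[0], obs_days[-1] + 1)
    interp = np.interp(grid, obs_days, obs_vals)
    observed_set = set(obs_days.tolist())
    entries = tuple(
        SeriesEntry(int(d), float(v), imputed=d not in observed_set)
        for d, v in zip(grid, interp))
    return SeverityTimeSeries(series.subject_id, entries)


def moving_average(series: SeverityTimeSeries,
                   window_days: int = 7) -> TrendSeries:
    """Centred linear moving-average trend of odd order ``window_days``.

    ẑ[i] is the mean of ŷ over days i−N … i+N with N = (window−1)/2; at the
    series edges the window shrinks to the available days so no days are
    dropped.  Imputed values are included (they exist for exactly this
    purpose).  Requires a contiguous day grid — run :func:`impute_pli`
    first."""
    if window_days % 2 == 0 or window_days < 1:
        raise ValueError("window_days must be odd and positive")
    if len(series.entries) == 0:
        raise ValueError("empty series")
    days = series.days
    if len(days) > 1 and np.any(np.diff(days) != 1):
        raise ValueError("day grid must be contiguous; run impute_pli first")
    s = pd.Series(series.values)
    trend = s.rolling(window=window_days, center=True, min_periods=1).mean()
    return TrendSeries(subject_id=series.subject_id, days=days,
                       trend=trend.to_numpy(), window_days=window_days)


def split_by_event(series: SeverityTimeSeries, event_day: int,
                   exclude_imputed: bool = True,
                   run_tests: bool = True, alpha: float = 0.05,
                   ) -> EventAnalysis:
    """Partition observed severities into before (< event day) and after
    (>= event day) and run the before/after statistics battery on them."""
    entries = [e for e in series.entries
               if not (exclude_imputed and e.imputed)]
    if not entries:
        raise ValueError("no observed entries in series")
    days = [e.study_day for e in entries]
    if not (min(days) < event_day <= max(days)):
        raise ValueError(
            f"event day {event_day} outside observed span [{min(days)}, "
            f"{max(days)}]")
    before = np.array([e.value for e in entries if e.study_day < event_day])
    after = np.array([e.value for e in entries if e.study_day >= event_day])
    analysis = EventAnalysis(subject_id=series.subject_id,
                             event_day=event_day, before=before, after=after)
    if len(before) < 2 or len(after) < 2:
        analysis.computable = False
        analysis.reason = (f"need >=2 observations per side; got "
                           f"{len(before)} before, {len(after)} after")
        return analysis
    if run_tests:
        from .stats import before_after_tests
        analysis.tests = before_after_tests(before, after, alpha=alpha)
        analysis.computable = analysis.tests.computable
        analysis.reason = analysis.tests.reason
    return analysis


# ---------------------------------------------------------------------------
# CSV round-trips

def series_to_frame(series: SeverityTimeSeries) -> pd.DataFrame:
    return pd.DataFrame({
        "subject_id": series.subject_id,
        "study_day": series.days,
        "value": series.values,
        "imputed": series.imputed_mask,
    })


def series_from_frame(df: pd.DataFrame) -> list[SeverityTimeSeries]:
    out = []
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("study_day")
        entries = tuple(SeriesEntry(int(r.study_day), float(r.value),
                                    bool(r.imputed))
                        for r in grp.itertuples())
        out.append(SeverityTimeSeries(str(sid), entries))
    return out


def trend_to_frame(trend: TrendSeries) -> pd.DataFrame:
    return pd.DataFrame({
        "subject_id": trend.subject_id,
        "study_day": trend.days,
        "trend": trend.trend,
        "window_days": trend.window_days,
    })
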