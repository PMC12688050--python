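"""Cumulative topic-exposure curves, windowed new-topic rates, plateau
detection, and per-PGY exposure summaries.

The central quantity is, per resident, the running union of taxonomy
topics over their attributed encounters ordered by arrival time.  Rates
of newly encountered topics are measured on windows tiling resident-
relative training time (default 30-day windows, step = window length,
so window totals conserve the final cumulative count); a plateau is the
earliest run of three consecutive windows each with fewer than 1 new
topic per 100 patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .model import DAYS_PER_PGY, N_PGY, Resident, training_day


@dataclass
class ExposureCurve:
    """Per-resident cumulative unique-topic series.

    ``events``: (training_day, encounter_id, newly_seen_topics) per
    attributed encounter, in arrival order.  ``cumulative`` pairs each
    event day with the size of the running topic union.
    """

    resident_id: str
    events: list[tuple[int, str, set[str]]]
    cumulative: list[tuple[int, int]]
    #: first-exposure day per topic (derived; drives window rates)
    first_seen: dict[str, int] = field(default_factory=dict)

    @property
    def encounter_days(self) -> np.ndarray:
        return np.array([d for d, _, _ in self.events], dtype=int)

    @property
    def total_topics(self) -> int:
        return self.cumulative[-1][1] if self.cumulative else 0

    @property
    def last_day(self) -> int:
        return self.events[-1][0] if self.events else 0

    def value_at(self, day: float) -> int:
        """Cumulative unique topics up to and including ``day`` (step
        interpolation)."""
        if not self.cumulative:
            return 0
        days = np.array([d for d, _ in self.cumulative])
        vals = np.array([v for _, v in self.cumulative])
        i = int(np.searchsorted(days, day, side="right")) - 1
        return int(vals[i]) if i >= 0 else 0


@dataclass
class WindowRate:
    window_index: int
    start_day: int
    end_day: int  # half-open [start_day, end_day)
    n_patients: int
    n_new_topics: int
    rate: float  # new topics per 100 patients; NaN when undefined
    defined: bool


@dataclass
class PlateauResult:
    resident_id: str
    plateau_day: int | None
    plateau_month: float | None  # day / 30
    encounters_before_plateau: int | None


def build_curve(
    resident: Resident,
    attributions: pd.DataFrame,
    encounters: pd.DataFrame,
    encounter_topics: dict[str, set[str]],
) -> ExposureCurve:
    """Running topic union over one resident's attributed encounters.

    Both primary and supervisory records count (exposure is credited to
    both roles).  Encounters with no topic mapping contribute an empty
    set; encounters are ordered by arrival time, ties by encounter id.
    """
    mine = attributions[attributions["resident_id"] == resident.resident_id]
    arr = encounters.set_index("encounter_id")["arrival_time"]
    rows = []
    for enc_id in mine["encounter_id"].unique():
        if enc_id not in arr.index:
            continue
        t = arr.loc[enc_id]
        rows.append((training_day(resident, t), str(enc_id)))
    rows.sort()
    seen: set[str] = set()
    events, cumulative, first_seen = [], [], {}
    for day, enc_id in rows:
        topics = encounter_topics.get(enc_id, set())
        new = set(topics) - seen
        for t in new:
            first_seen[t] = day
        seen |= new
        events.append((day, enc_id, new))
        cumulative.append((day, len(seen)))
    return ExposureCurve(resident.resident_id, events, cumulative, first_seen)


def curve_from_topic_stream(
    resident_id: str, stream: list[tuple[int, set[str]]]
) -> ExposureCurve:
    """Build a curve directly from (training_day, topic_set) pairs —
    handy for synthetic streams that bypass attribution."""
    seen: set[str] = set()
    events, cumulative, first_seen = [], [], {}
    for k, (day, topics) in enumerate(sorted(stream, key=lambda x: x[0])):
        new = set(topics) - seen
        for t in new:
            first_seen[t] = day
        seen |= new
        events.append((day, f"{resident_id}-{k}", new))
        cumulative.append((day, len(seen)))
    return ExposureCurve(resident_id, events, cumulative, first_seen)


def window_rates(
    curve: ExposureCurve, window_days: int = 30, step_days: int = 30
) -> list[WindowRate]:
    """New-topic rates per 100 patients on windows tiling training time.

    Windows are half-open [start, start + window_days), starting at
    0, step_days, 2*step_days, ... while start <= last event day.
    A window with zero patients carries an undefined rate (NaN), never
    a zero.
    """
    if window_days <= 0 or step_days <= 0:
        raise ValidationError("window_days and step_days must be positive")
    enc_days = curve.encounter_days
    new_days = np.array(sorted(curve.first_seen.values()), dtype=int)
    out = []
    start, idx = 0, 0
    last = curve.last_day
    while start <= last:
        end = start + window_days
        n_pat = int(((enc_days >= start) & (enc_days < end)).sum())
        n_new = int(((new_days >= start) & (new_days < end)).sum()) if new_days.size else 0
        defined = n_pat > 0
        rate = 100.0 * n_new / n_pat if defined else float("nan")
        out.append(WindowRate(idx, start, end, n_pat, n_new, rate, defined))
        start += step_days
        idx += 1
    return out


def detect_plateau(
    rates: list[WindowRate],
    threshold: float = 1.0,
    consecutive: int = 3,
    curve: ExposureCurve | None = None,
    resident_id: str = "",
) -> PlateauResult:
    """Earliest run of ``consecutive`` windows with defined rate
    strictly below ``threshold``.

    The plateau day is the start day of the run's first window;
    undefined-rate (empty) windows break runs.  Months are reported as
    day / 30.
    """
    rid = resident_id or (curve.resident_id if curve is not None else "")
    run = 0
    for i, w in enumerate(rates):
        if w.defined and w.rate < threshold:
            run += 1
            if run == consecutive:
                first = rates[i - consecutive + 1]
                day = first.start_day
                if curve is not None:
                    n_before = int((curve.encounter_days < day).sum())
                else:
                    n_before = sum(
                        x.n_patients for x in rates if x.start_day < day
                    )
                return PlateauResult(rid, day, day / 30.0, n_before)
        else:
            run = 0
    return PlateauResult(rid, None, None, None)


def pgy_exposure_summary(
    curves: list[ExposureCurve],
    catalog_size: int,
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-PGY cohort table: cumulative unique topics (mean, SD, CI),
    new topics per year (mean, SD), and percent of catalog covered.

    Cumulative at PGY y is each resident's topic count through the end
    of training day 365*y - 1; residents with no events are excluded.
    Mean CIs are normal-approximation t-intervals.
    """
    rows = []
    used = [c for c in curves if c.events]
    for pgy in range(1, N_PGY + 1):
        lo_day, hi_day = (pgy - 1) * DAYS_PER_PGY, pgy * DAYS_PER_PGY
        cum = np.array(
            [sum(1 for d in c.first_seen.values() if d < hi_day) for c in used],
            dtype=float,
        )
        new = np.array(
            [
                sum(1 for d in c.first_seen.values() if lo_day <= d < hi_day)
                for c in used
            ],
            dtype=float,
        )
        n = len(cum)
        mean, sd = (cum.mean(), cum.std(ddof=1)) if n > 1 else (float(cum.mean()), 0.0)
        tcrit = stats.t.ppf(0.5 + level / 2, n - 1) if n > 1 else float("nan")
        half = tcrit * sd / np.sqrt(n) if n > 1 else float("nan")
        rows.append(
            {
                "pgy": pgy,
                "n_residents": n,
                "cumulative_mean": mean,
                "cumulative_sd": sd,
                "cumulative_ci_lo": mean - half,
                "cumulative_ci_hi": mean + half,
                "new_mean": new.mean(),
                "new_sd": new.std(ddof=1) if n > 1 else 0.0,
                "pct_of_catalog": round(100.0 * mean / catalog_size, 1),
            }
        )
    return pd.DataFrame(rows).set_index("pgy")


def class_mean_curve(
    curves: list[ExposureCurve], grid_days: int = 30, max_day: int | None = None
) -> pd.DataFrame:
    """Mean cumulative curve for one graduating class on a common grid.

    Each resident's step curve is sampled at grid days (carrying the
    last value forward), then averaged pointwise.
    """
    if not curves:
        raise ValidationError("need at least one curve")
    if max_day is None:
        max_day = max(c.last_day for c in curves)
    grid = np.arange(0, max_day + grid_days, grid_days)
    vals = np.array([[c.value_at(g) for g in grid] for c in curves], dtype=float)
    return pd.DataFrame({"day": grid, "mean_cumulative_topics": vals.mean(axis=0)})
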