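"""Rule-based encounter-to-resident attribution.

Primary attribution goes to the first resident to document on the
treatment team during one of their clinical shifts; a senior resident
(strictly higher PGY at the time) documenting in close temporal
proximity is coattributed in a supervisory role.  Exposure is credited
to both roles at the resident level, while encounter-level summaries
count every encounter once, under the primary resident's PGY.
"""

from __future__ import annotations

from datetime import timedelta

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .errors import ValidationError
from .model import ATTRIBUTION_COLUMNS, DAYS_PER_PGY, N_PGY, Resident


class AttributionPolicy(BaseModel):
    """Knobs of the attribution rule.

    coattribution_window: how close a senior's documentation must be to
    the primary's to count as active supervision; the source analysis
    never quantifies "close temporal proximity", so 60 min is a
    configurable default.
    shift_grace: slack around shift boundaries absorbing documentation
    that straddles a shift end; set to 0 for strict containment.
    """

    coattribution_window: timedelta = Field(default=timedelta(minutes=60))
    shift_grace: timedelta = Field(default=timedelta(minutes=30))
    require_senior_pgy_greater: bool = True


class ShiftIndex:
    """Per-resident sorted clinical-shift intervals for O(log n) lookup.

    Relies on the invariant that one resident's shifts do not overlap;
    the grace extension can only bridge gaps shorter than twice the
    grace, which still leaves a unique covering shift per timestamp.
    """

    def __init__(self, shifts: pd.DataFrame, grace: timedelta):
        g = np.timedelta64(int(grace.total_seconds() * 1e9), "ns")
        self._by_res: dict[str, tuple] = {}
        clinical = shifts[shifts["kind"] == "clinical"]
        for rid, grp in clinical.groupby("resident_id"):
            grp = grp.sort_values("start")
            starts = grp["start"].to_numpy(dtype="datetime64[ns]") - g
            ends = grp["end"].to_numpy(dtype="datetime64[ns]") + g
            self._by_res[rid] = (starts, ends, grp["shift_id"].to_numpy())

    def lookup(self, resident_id: str, times: np.ndarray) -> np.ndarray:
        """Shift ids (object array, None = off shift) for each time."""
        out = np.full(len(times), None, dtype=object)
        entry = self._by_res.get(resident_id)
        if entry is None or len(times) == 0:
            return out
        starts, ends, ids = entry
        idx = np.searchsorted(starts, times, side="right") - 1
        valid = idx >= 0
        safe = np.where(valid, idx, 0)
        covered = valid & (times < ends[safe])
        out[covered] = ids[safe[covered]]
        return out


def _roster_frame(residents: list[Resident]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "resident_id": [r.resident_id for r in residents],
            "start_date": pd.to_datetime([r.start_date for r in residents]),
        }
    )


def _with_pgy(df: pd.DataFrame, residents: list[Resident], time_col: str,
              out_col: str) -> pd.DataFrame:
    """Attach resident-relative PGY (1..4, NaN outside training) at the
    date of ``time_col``."""
    roster = _roster_frame(residents)
    df = df.merge(roster, on="resident_id", how="left")
    days = (df[time_col].dt.normalize() - df["start_date"]).dt.days
    pgy = days // DAYS_PER_PGY + 1
    pgy = pgy.where((days >= 0) & (pgy <= N_PGY))
    return df.drop(columns="start_date").assign(**{out_col: pgy})


def _events_with_shift(
    events: pd.DataFrame, index: ShiftIndex
) -> pd.DataFrame:
    parts = []
    for rid, grp in events.groupby("resident_id", sort=False):
        sids = index.lookup(rid, grp["doc_time"].to_numpy(dtype="datetime64[ns]"))
        parts.append(grp.assign(shift_id=sids))
    if not parts:
        return events.assign(shift_id=pd.Series(dtype=object))
    out = pd.concat(parts)
    return out[out["shift_id"].notna()]


def _validate_events(events: pd.DataFrame, residents: list[Resident]) -> None:
    known = {r.resident_id for r in residents}
    offenders = sorted(set(events["resident_id"]) - known)
    if offenders:
        raise ValidationError(f"team events reference unknown residents: {offenders}")


def attribute_primary(
    events: pd.DataFrame,
    shifts: pd.DataFrame,
    residents: list[Resident],
    policy: AttributionPolicy | None = None,
) -> pd.DataFrame:
    """First on-shift documenter per encounter becomes its primary.

    Candidates are residents whose doc_time falls inside one of their
    clinical shifts (with grace); the earliest doc_time wins, ties
    broken by lexicographic resident_id.  Encounters with no on-shift
    documenter yield no record (nonclinical/administrative exclusion).
    """
    pol = policy or AttributionPolicy()
    _validate_events(events, residents)
    index = ShiftIndex(shifts, pol.shift_grace)
    ok = _events_with_shift(events, index)
    if ok.empty:
        return pd.DataFrame(columns=ATTRIBUTION_COLUMNS)
    prim = (
        ok.sort_values(["encounter_id", "doc_time", "resident_id"], kind="mergesort")
        .drop_duplicates("encounter_id")
        .assign(role="primary")
    )
    return prim[["encounter_id", "resident_id", "role", "doc_time", "shift_id"]].reset_index(
        drop=True
    )


def coattribute_senior(
    primary: pd.DataFrame,
    events: pd.DataFrame,
    shifts: pd.DataFrame,
    residents: list[Resident],
    policy: AttributionPolicy | None = None,
) -> pd.DataFrame:
    """Supervisory records for seniors documenting near the primary.

    Any other on-shift resident with strictly higher PGY at their
    documentation time, within the coattribution window of the primary's
    doc time, qualifies; the smallest |Δt| (then lexicographic id) is
    kept, so an encounter carries at most one supervisory resident.
    """
    pol = policy or AttributionPolicy()
    if primary.empty:
        return pd.DataFrame(columns=ATTRIBUTION_COLUMNS)
    index = ShiftIndex(shifts, pol.shift_grace)
    ok = _events_with_shift(events, index)
    merged = ok.merge(
        primary[["encounter_id", "resident_id", "doc_time"]].rename(
            columns={"resident_id": "primary_id", "doc_time": "primary_doc"}
        ),
        on="encounter_id",
        how="inner",
    )
    merged = merged[merged["resident_id"] != merged["primary_id"]]
    merged = merged[(merged["doc_time"] - merged["primary_doc"]).abs() <= pol.coattribution_window]
    merged = _with_pgy(merged, residents, "doc_time", "pgy")
    merged = _with_pgy(
        merged.rename(columns={"resident_id": "__rid", "primary_id": "resident_id"}),
        residents,
        "primary_doc",
        "primary_pgy",
    ).rename(columns={"resident_id": "primary_id", "__rid": "resident_id"})
    merged = merged.dropna(subset=["pgy", "primary_pgy"])
    if pol.require_senior_pgy_greater:
        merged = merged[merged["pgy"] > merged["primary_pgy"]]
    if merged.empty:
        return pd.DataFrame(columns=ATTRIBUTION_COLUMNS)
    merged = merged.assign(abs_dt=(merged["doc_time"] - merged["primary_doc"]).abs())
    sup = (
        merged.sort_values(["encounter_id", "abs_dt", "resident_id"], kind="mergesort")
        .drop_duplicates("encounter_id")
        .assign(role="supervisory")
    )
    return sup[["encounter_id", "resident_id", "role", "doc_time", "shift_id"]].reset_index(
        drop=True
    )


def attribute(
    events: pd.DataFrame,
    shifts: pd.DataFrame,
    residents: list[Resident],
    policy: AttributionPolicy | None = None,
) -> pd.DataFrame:
    """Primary + supervisory attribution in one table."""
    prim = attribute_primary(events, shifts, residents, policy)
    sup = coattribute_senior(prim, events, shifts, residents, policy)
    frames = [f for f in (prim, sup) if not f.empty]
    if not frames:
        return pd.DataFrame(columns=ATTRIBUTION_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["encounter_id", "role"]).reset_index(drop=True)


def count_encounters(records: pd.DataFrame, mode: str) -> pd.DataFrame:
    """The two counting policies behind every denominator.

    ``per_resident_exposure``: every (resident, encounter) pair counts —
    the resident-level exposure view, crediting both roles.
    ``unique_encounter``: each encounter counts once, under its primary
    resident — the encounter/patient-level view.
    """
    if mode == "per_resident_exposure":
        counts = records.groupby("resident_id").size()
    elif mode == "unique_encounter":
        counts = records[records["role"] == "primary"].groupby("resident_id").size()
    else:
        raise ValidationError(f"unknown counting mode {mode!r}")
    return counts.rename("n_encounters").reset_index()
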