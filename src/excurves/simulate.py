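"""Seeded synthetic residency cohort generator.

Produces a full closed-loop test bed — roster, shift schedule,
encounters, treatment-team events, notes with ground-truth topic
labels — with the statistical structure of a 4-year, 62-resident
academic ED cohort: per-PGY annual volumes rising ~446 to ~1528
encounters with CVs of ~25/17/18/25%, triage acuity (ESI) drifting from
a mean of 2.94 to 2.79, admission probability ~0.31 to ~0.375, and a
heavy-tailed per-topic frequency over the 895-topic taxonomy in which
roughly 5.5% of topics recur more than 100 times and ~63% fewer than
10 times.

Notes render ground-truth topic mentions as lexicon synonyms in the
MDM section and inject negated / historical / uncertain distractor
mentions at configurable rates, so the note-mapping stage can be tested
against exact per-encounter truth.

Identical seed and config give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import brentq

from .errors import CalibrationError, GenerationError
from .model import (
    Concept,
    ConceptLexicon,
    Crosswalk,
    Resident,
    TopicCatalog,
)

# ------------------------------------------------------------- config


class CohortConfig(BaseModel):
    """Generator parameters.  Defaults are the cohort conditions the
    package is designed around (a 62-resident, 4-class program)."""

    class_sizes: tuple[int, ...] = (15, 16, 15, 16)
    first_class_year: int = 2020  # earliest graduating class
    n_topics: int = 895
    zipf_exponent: float | None = None  # None -> calibrate to bucket_targets
    bucket_targets: tuple[float, float, float] = (0.055, 0.317, 0.628)
    bucket_thresholds: tuple[int, int] = (100, 10)
    # topics per encounter ~ min(1 + Poisson(mean), max)
    topics_per_encounter_mean: float = 2.0
    topics_per_encounter_max: int = 8
    pgy_volume_means: tuple[float, float, float, float] = (445.7, 772.1, 1193.4, 1528.4)
    pgy_volume_cv: tuple[float, float, float, float] = (0.246, 0.17, 0.18, 0.254)
    pgy_esi_mean: tuple[float, float, float, float] = (2.94, 2.87, 2.85, 2.79)
    esi_base: tuple[float, ...] = (1.2, 24.1, 65.7, 8.2, 0.8)  # marginal ESI 1..5
    esi_missing_rate: float = 0.018
    pgy_admit_prob: tuple[float, float, float, float] = (0.31, 0.383, 0.355, 0.375)
    negation_rate: float = 0.30
    historical_rate: float = 0.20
    uncertain_rate: float = 0.15
    senior_coattribution_prob: float = 0.5
    repeat_patient_prob: float = 0.452  # 1 - unique-patient fraction
    encounters_per_shift: float = 8.0
    nonclinical_shifts_per_year: int = 10
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        for p in (
            self.negation_rate, self.historical_rate, self.uncertain_rate,
            self.senior_coattribution_prob, self.esi_missing_rate,
            self.repeat_patient_prob, *self.pgy_admit_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0,1]")
        if any(m <= 0 for m in self.pgy_volume_means):
            raise ValueError("volume means must be positive")
        if len(self.pgy_volume_means) != 4 or len(self.pgy_volume_cv) != 4:
            raise ValueError("exactly 4 PGY entries required")
        return self

    @property
    def n_residents(self) -> int:
        return sum(self.class_sizes)


@dataclass
class GroundTruth:
    """Oracle labels for closed-loop testing."""

    #: per-encounter mentions as (topic_id, kind); kind in
    #: {affirmed, negated, historical, uncertain}
    mentions: dict[str, list[tuple[str, str]]]
    #: per-encounter true exposure set (affirmed + uncertain topics)
    exposure_topics: dict[str, set[str]]
    intended_primary: dict[str, str]
    intended_senior: dict[str, str | None]
    #: per-resident union of exposure sets over attributed encounters
    resident_exposure: dict[str, set[str]]


@dataclass
class CohortData:
    config: CohortConfig
    residents: list[Resident]
    shifts: pd.DataFrame
    encounters: pd.DataFrame
    team_events: pd.DataFrame
    notes: dict[str, dict[str, str]]
    truth: GroundTruth
    zipf_exponent: float = float("nan")


# ------------------------------------------------- power-law calibration


def zipf_probs(n_topics: int, s: float) -> np.ndarray:
    """Truncated power-law rank frequencies p_k ∝ k^-s, k = 1..n."""
    w = np.arange(1, n_topics + 1, dtype=float) ** -s
    return w / w.sum()


def expected_bucket_fractions(
    n_topics: int, s: float, total_draws: int, thresholds: tuple[int, int] = (100, 10)
) -> tuple[float, float, float]:
    """Fractions of topics whose *expected* count under the power law
    falls above/between/below the thresholds."""
    c = total_draws * zipf_probs(n_topics, s)
    hi, lo = thresholds
    n_gt = int((c > hi).sum())
    n_mid = int(((c >= lo) & (c <= hi)).sum())
    n_lt = n_topics - n_gt - n_mid
    return n_gt / n_topics, n_mid / n_topics, n_lt / n_topics


def calibrate_zipf(
    n_topics: int,
    total_draws: int,
    bucket_targets: tuple[float, float, float],
    thresholds: tuple[int, int] = (100, 10),
    error_threshold: float = 0.005,
) -> float:
    """Exponent s minimizing squared error between expected bucket
    fractions and the targets; deterministic grid search (step 0.01 on
    [0, 3]) followed by a finer local refinement (step 0.0005).

    Raises :class:`CalibrationError` (carrying the best exponent found)
    when the targets cannot be approached within ``error_threshold``
    total squared error.
    """
    if total_draws <= 0:
        raise ValueError("total_draws must be positive")
    if sum(bucket_targets) > 1 + 1e-9:
        raise ValueError("bucket targets sum above 1")
    targets = np.asarray(bucket_targets, dtype=float)

    def objective(s: float) -> float:
        f = expected_bucket_fractions(n_topics, s, total_draws, thresholds)
        return float(np.sum((np.asarray(f) - targets) ** 2))

    coarse = np.arange(0.0, 3.0001, 0.01)
    errs = [objective(s) for s in coarse]
    i = int(np.argmin(errs))  # first minimum wins (smallest s on ties)
    best_s, best_e = float(coarse[i]), errs[i]
    lo = coarse[max(0, i - 1)]
    hi = coarse[min(len(coarse) - 1, i + 1)]
    for s in np.arange(lo, hi + 1e-12, 0.0005):
        e = objective(float(s))
        if e < best_e:
            best_s, best_e = float(s), e
    if best_e > error_threshold:
        raise CalibrationError(
            f"bucket targets unattainable (best error {best_e:.4g} at s={best_s:.3f})",
            best_exponent=best_s,
            best_error=best_e,
        )
    return best_s


def expected_topics_per_encounter(mean: float, cap: int) -> float:
    """E[min(1 + Poisson(mean), cap)]."""
    from scipy import stats as _stats

    ks = np.arange(0, 200)
    pmf = _stats.poisson.pmf(ks, mean)
    return float(np.sum(np.minimum(1 + ks, cap) * pmf))


# ------------------------------------------------------ ESI tilt solve


def esi_tilted_probs(base: tuple[float, ...], target_mean: float) -> np.ndarray:
    """Exponentially tilt the base ESI distribution to a target mean.

    Weights w_e ∝ base_e * exp(theta * e); theta solved so the tilted
    mean equals the target.  Monotone in theta, so a bracketing solve
    is exact.
    """
    b = np.asarray(base, dtype=float)
    b = b / b.sum()
    e = np.arange(1, len(b) + 1, dtype=float)

    def mean_at(theta: float) -> float:
        w = b * np.exp(theta * e)
        w /= w.sum()
        return float((w * e).sum())

    if abs(mean_at(0.0) - target_mean) < 1e-12:
        return b
    theta = brentq(lambda t: mean_at(t) - target_mean, -10.0, 10.0, xtol=1e-12)
    w = b * np.exp(theta * e)
    return w / w.sum()


# ------------------------------------------------------- note rendering

_AFFIRMED_TEMPLATES = (
    "Patient presents with {term}.",
    "Evaluation notable for {term}.",
    "Assessment consistent with {term}.",
)
_NEGATED_TEMPLATES = ("No {term}.", "Denies {term}.")
_HISTORICAL_TEMPLATES = ("History of {term}.",)
_UNCERTAIN_TEMPLATES = ("Possible {term}.",)


def render_note(
    affirmed_terms: list[str],
    distractors: list[tuple[str, str]],
    enc_index: int = 0,
) -> dict[str, str]:
    """Render one note's sections.

    Affirmed mentions appear in MDM as plain phrases; distractors
    (kind, term) are prefixed by their context trigger.  Templates cycle
    deterministically with ``enc_index`` so seeded runs are stable.
    Section order is fixed: HPI, MDM, ED_COURSE.
    """
    if not affirmed_terms:
        raise GenerationError("a note needs at least one affirmed mention")
    lines = []
    for j, term in enumerate(affirmed_terms):
        tpl = _AFFIRMED_TEMPLATES[(enc_index + j) % len(_AFFIRMED_TEMPLATES)]
        lines.append(tpl.format(term=term))
    for j, (kind, term) in enumerate(distractors):
        if kind == "negated":
            tpl = _NEGATED_TEMPLATES[(enc_index + j) % len(_NEGATED_TEMPLATES)]
        elif kind == "historical":
            tpl = _HISTORICAL_TEMPLATES[0]
        elif kind == "uncertain":
            tpl = _UNCERTAIN_TEMPLATES[0]
        else:
            raise GenerationError(f"unknown distractor kind {kind!r}")
        lines.append(tpl.format(term=term))
    return {
        "HPI": "Patient presenting to the ED for evaluation. Symptoms began earlier today.",
        "MDM": " ".join(lines),
        "ED_COURSE": "Monitored during stay. Reassessed and dispositioned per plan.",
    }


# ---------------------------------------------------------- generation

_SLOT_HOURS = ((7, 15), (15, 23), (23, 31))  # third slot crosses midnight
_N_SLOTS = len(_SLOT_HOURS)


def _topic_synonyms(
    catalog: TopicCatalog, lexicon: ConceptLexicon, crosswalk: Crosswalk
) -> dict[str, list[str]]:
    """topic_id -> synonyms of its crosswalk preimage concepts."""
    by_concept: dict[str, Concept] = {c.concept_id: c for c in lexicon.concepts}
    out: dict[str, list[str]] = {t: [] for t in catalog.topic_ids}
    for cid, tid in sorted(crosswalk.mapping.items()):
        c = by_concept.get(cid)
        if c is not None and tid in out:
            out[tid].extend(c.synonyms)
    return out


def generate_cohort(
    config: CohortConfig,
    catalog: TopicCatalog,
    lexicon: ConceptLexicon,
    crosswalk: Crosswalk,
) -> CohortData:
    """Draw a full synthetic cohort under ``config``.

    Per resident training year, the encounter count is lognormal with
    the configured mean and CV; encounters are placed in 8-hour shift
    slots on a common grid so that senior residents sharing a slot can
    be coattributed.  Topic draws are i.i.d. from the calibrated power
    law; notes render the drawn topics plus distractor mentions.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_topics = cfg.n_topics
    if len(catalog) < n_topics:
        raise GenerationError("catalog smaller than configured n_topics")
    topic_ids = catalog.topic_ids[:n_topics]
    syn_by_topic = _topic_synonyms(catalog, lexicon, crosswalk)
    for tid in topic_ids:
        if not syn_by_topic.get(tid):
            raise GenerationError(f"topic {tid} has no concept synonyms to render")

    # roster: class c graduates first_class_year + c, starts 4 years prior
    residents: list[Resident] = []
    for c, size in enumerate(cfg.class_sizes):
        year = cfg.first_class_year + c
        start = date(year - 4, 7, 1)
        for i in range(size):
            residents.append(Resident(f"R{year}_{i:02d}", year, start))

    # power-law over topics, calibrated to the generator's own expected
    # number of exposure draws (affirmed + uncertain mentions)
    e_tpe = expected_topics_per_encounter(
        cfg.topics_per_encounter_mean, cfg.topics_per_encounter_max
    )
    expected_encounters = cfg.n_residents * sum(cfg.pgy_volume_means)
    total_draws = int(expected_encounters * (e_tpe + cfg.uncertain_rate))
    s = (
        cfg.zipf_exponent
        if cfg.zipf_exponent is not None
        else calibrate_zipf(n_topics, total_draws, cfg.bucket_targets, cfg.bucket_thresholds)
    )
    probs = zipf_probs(n_topics, s)

    # tilted ESI distributions per PGY
    esi_probs = [esi_tilted_probs(cfg.esi_base, m) for m in cfg.pgy_esi_mean]
    esi_cum = [np.cumsum(p) for p in esi_probs]

    # ---- pass 1: shifts and encounter skeletons -----------------------
    shift_rows: list[tuple] = []
    enc_meta: list[tuple] = []  # (res_idx, pgy0, arrival, doc, slot_key)
    slot_map: dict[tuple[int, int], list[int]] = {}
    shift_counter = 0
    for ri, res in enumerate(residents):
        start_ord = res.start_date.toordinal()
        for y in range(4):
            mean, cv = cfg.pgy_volume_means[y], cfg.pgy_volume_cv[y]
            sigma2 = math.log(1 + cv * cv)
            mu = math.log(mean) - sigma2 / 2
            n_enc = max(1, int(round(rng.lognormal(mu, math.sqrt(sigma2)))))
            n_clin = max(1, math.ceil(n_enc / cfg.encounters_per_shift))
            n_slots = 365 * _N_SLOTS
            picks = rng.choice(n_slots, size=n_clin + cfg.nonclinical_shifts_per_year,
                               replace=False)
            clin = np.sort(picks[:n_clin])
            nonclin = np.sort(picks[n_clin:])
            year_day0 = y * 365
            clin_keys = []
            for p in clin:
                day, slot = int(p) // _N_SLOTS, int(p) % _N_SLOTS
                d_ord = start_ord + year_day0 + day
                h0, h1 = _SLOT_HOURS[slot]
                t0 = datetime.fromordinal(d_ord) + timedelta(hours=h0)
                t1 = datetime.fromordinal(d_ord) + timedelta(hours=h1)
                shift_rows.append((f"S{shift_counter:07d}", res.resident_id, t0, t1, "clinical"))
                shift_counter += 1
                key = (d_ord, slot)
                slot_map.setdefault(key, []).append(ri)
                clin_keys.append((t0, key))
            for p in nonclin:
                day, slot = int(p) // _N_SLOTS, int(p) % _N_SLOTS
                d_ord = start_ord + year_day0 + day
                h0, h1 = _SLOT_HOURS[slot]
                t0 = datetime.fromordinal(d_ord) + timedelta(hours=h0)
                t1 = datetime.fromordinal(d_ord) + timedelta(hours=h1)
                shift_rows.append((f"S{shift_counter:07d}", res.resident_id, t0, t1, "nonclinical"))
                shift_counter += 1
            which = rng.integers(0, n_clin, size=n_enc)
            arrival_min = rng.uniform(0, 420, size=n_enc)  # first 7h of the 8h slot
            doc_delay = rng.uniform(10, 45, size=n_enc)
            for k in range(n_enc):
                t0, key = clin_keys[int(which[k])]
                arr = t0 + timedelta(minutes=float(arrival_min[k]))
                doc = arr + timedelta(minutes=float(doc_delay[k]))
                enc_meta.append((ri, y, arr, doc, key))

    n = len(enc_meta)

    # ---- pass 2: seniors, clinical variables, topics, notes -----------
    coat_u = rng.random(n)
    senior_pick_u = rng.random(n)
    senior_delay = rng.uniform(5, 40, size=n)
    esi_u = rng.random(n)
    esi_missing_u = rng.random(n)
    admit_u = rng.random(n)
    other_dispo_u = rng.random(n)
    repeat_u = rng.random(n)
    repeat_pick_u = rng.random(n)
    m_draw = np.minimum(
        1 + rng.poisson(cfg.topics_per_encounter_mean, size=n),
        cfg.topics_per_encounter_max,
    )
    offsets = np.concatenate([[0], np.cumsum(m_draw)])
    all_topics = rng.choice(n_topics, size=int(offsets[-1]), p=probs)
    distract_u = rng.random((n, 3))
    distract_topics = rng.choice(n_topics, size=(n, 3), p=probs)
    syn_pick_u = rng.random(n)

    res_start_ord = np.array([r.start_date.toordinal() for r in residents])

    enc_rows, ev_rows = [], []
    notes: dict[str, dict[str, str]] = {}
    mentions: dict[str, list[tuple[str, str]]] = {}
    exposure: dict[str, set[str]] = {}
    intended_primary: dict[str, str] = {}
    intended_senior: dict[str, str | None] = {}
    resident_exposure: dict[str, set[str]] = {r.resident_id: set() for r in residents}
    n_patients = 0

    def pgy_at(res_idx: int, d_ord: int) -> int | None:
        days = d_ord - res_start_ord[res_idx]
        if days < 0 or days >= 4 * 365:
            return None
        return int(days) // 365 + 1

    for k, (ri, y, arr, doc, key) in enumerate(enc_meta):
        enc_id = f"E{k:07d}"
        rid = residents[ri].resident_id
        # patient id: fresh with prob 1 - repeat_patient_prob
        if repeat_u[k] < cfg.repeat_patient_prob and n_patients > 0:
            pid = f"P{int(repeat_pick_u[k] * n_patients):07d}"
        else:
            pid = f"P{n_patients:07d}"
            n_patients += 1
        # ESI (tilted by PGY) and disposition
        if esi_missing_u[k] < cfg.esi_missing_rate:
            esi: int | None = None
        else:
            esi = int(np.searchsorted(esi_cum[y], esi_u[k])) + 1
        if admit_u[k] < cfg.pgy_admit_prob[y]:
            dispo = "admitted"
        else:
            dispo = "other" if other_dispo_u[k] < 0.05 else "discharged"
        enc_rows.append((enc_id, pid, arr, esi, dispo))

        # treatment team: junior documents first, senior maybe follows
        ev_rows.append((enc_id, rid, doc))
        intended_primary[enc_id] = rid
        senior_id: str | None = None
        # PGY evaluated at each resident's own documentation date, the
        # same convention the attribution stage applies
        my_pgy = pgy_at(ri, doc.date().toordinal())
        if coat_u[k] < cfg.senior_coattribution_prob and my_pgy is not None:
            senior_doc = doc + timedelta(minutes=float(senior_delay[k]))
            senior_ord = senior_doc.date().toordinal()
            cands = [
                rj
                for rj in slot_map.get(key, ())
                if rj != ri and (pgy_at(rj, senior_ord) or 0) > my_pgy
            ]
            if cands:
                rj = cands[int(senior_pick_u[k] * len(cands))]
                senior_id = residents[rj].resident_id
                ev_rows.append((enc_id, senior_id, senior_doc))
        intended_senior[enc_id] = senior_id

        # ground-truth topics and the note that encodes them
        draws = all_topics[offsets[k] : offsets[k + 1]]
        affirmed = sorted({topic_ids[t] for t in draws})
        taken = set(affirmed)
        ment = [(t, "affirmed") for t in affirmed]
        distractors = []
        for j, kind in enumerate(("negated", "historical", "uncertain")):
            rate = (cfg.negation_rate, cfg.historical_rate, cfg.uncertain_rate)[j]
            if distract_u[k, j] >= rate:
                continue
            t_idx = int(distract_topics[k, j])
            while topic_ids[t_idx] in taken:  # deterministic probe past collisions
                t_idx = (t_idx + 1) % n_topics
            tid = topic_ids[t_idx]
            taken.add(tid)
            ment.append((tid, kind))
            syns = syn_by_topic[tid]
            distractors.append((kind, syns[(k + j) % len(syns)]))
        aff_terms = []
        for j, tid in enumerate(affirmed):
            syns = syn_by_topic[tid]
            aff_terms.append(syns[(int(syn_pick_u[k] * 7) + j) % len(syns)])
        notes[enc_id] = render_note(aff_terms, distractors, enc_index=k)
        mentions[enc_id] = ment
        exp = set(affirmed) | {t for t, kind in ment if kind == "uncertain"}
        exposure[enc_id] = exp
        resident_exposure[rid] |= exp
        if senior_id is not None:
            resident_exposure[senior_id] |= exp

    shifts = pd.DataFrame(shift_rows, columns=["shift_id", "resident_id", "start", "end", "kind"])
    encounters = pd.DataFrame(
        enc_rows, columns=["encounter_id", "patient_id", "arrival_time", "esi", "disposition"]
    )
    encounters["esi"] = encounters["esi"].astype("Int64")
    team_events = pd.DataFrame(ev_rows, columns=["encounter_id", "resident_id", "doc_time"])
    truth = GroundTruth(
        mentions=mentions,
        exposure_topics=exposure,
        intended_primary=intended_primary,
        intended_senior=intended_senior,
        resident_exposure=resident_exposure,
    )
    return CohortData(cfg, residents, shifts, encounters, team_events, notes, truth, s)


# ----------------------------------------------- plateau test streams


def plateau_topic_stream(
    stop_day: int,
    total_days: int | None = None,
    encounters_per_day: float = 4.0,
    new_topic_prob: float = 1 / 15,
    seed: int = 0,
) -> list[tuple[int, set[str]]]:
    """Per-encounter topic stream that stops introducing new topics at
    ``stop_day`` — ground truth for plateau-detection recovery tests.

    Before ``stop_day`` each encounter introduces a brand-new topic with
    probability ``new_topic_prob`` (well above the 1-per-100-patients
    plateau threshold in expectation); afterwards encounters only revisit
    already-seen topics.
    """
    rng = np.random.default_rng(seed)
    if total_days is None:
        total_days = stop_day + 150
    stream: list[tuple[int, set[str]]] = []
    n_seen = 0
    for day in range(total_days):
        for _ in range(int(rng.poisson(encounters_per_day))):
            if day < stop_day and (n_seen == 0 or rng.random() < new_topic_prob):
                n_seen += 1
                topic = f"PT{n_seen:05d}"
            else:
                topic = f"PT{rng.integers(1, n_seen + 1):05d}"
            stream.append((day, {topic}))
    return stream


# -------------------------------------------------------------- output


def write_cohort(data: CohortData, outdir) -> dict[str, str]:
    """Write every artifact of a generated cohort; returns paths."""
    import json
    from pathlib import Path

    from . import io as _io

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "roster": out / "roster.csv",
        "shifts": out / "shifts.csv",
        "encounters": out / "encounters.csv",
        "team_events": out / "team_events.csv",
        "notes": out / "notes.jsonl",
        "ground_truth": out / "ground_truth.jsonl",
    }
    _io.save_roster(data.residents, paths["roster"])
    _io.save_shifts(data.shifts, paths["shifts"])
    _io.save_encounters(data.encounters, paths["encounters"])
    _io.save_team_events(data.team_events, paths["team_events"])
    _io.save_notes(data.notes, paths["notes"])
    with open(paths["ground_truth"], "w") as fh:
        for enc_id, ment in data.truth.mentions.items():
            fh.write(
                json.dumps(
                    {
                        "encounter_id": enc_id,
                        "mentions": [{"topic_id": t, "kind": kind} for t, kind in ment],
                        "exposure_topics": sorted(data.truth.exposure_topics[enc_id]),
                        "primary": data.truth.intended_primary[enc_id],
                        "senior": data.truth.intended_senior[enc_id],
                    }
                )
                + "\n"
            )
    return {k: str(v) for k, v in paths.items()}
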