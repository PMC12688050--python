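"""End-to-end orchestration: simulate -> attribute -> map notes ->
curves -> metrics -> report, with a checksum manifest for
reproducibility.

Every stage reads and writes the plain-text formats in :mod:`excurves.io`,
so a run can also start from externally supplied files by pointing the
config at them and disabling simulation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import io as _io
from .attribution import AttributionPolicy, attribute, count_encounters
from .curves import (
    build_curve,
    class_mean_curve,
    detect_plateau,
    pgy_exposure_summary,
    window_rates,
)
from .defaults import default_vocabulary
from .errors import ValidationError
from .metrics import (
    coefficient_of_variation,
    complexity_progression,
    frequency_buckets,
    gini,
    kruskal_wallis_eta2,
    topic_gini_summary,
)
from .model import DAYS_PER_PGY, N_PGY, Resident, assign_pgy
from .notemap import InclusionPolicy, TriggerConfig, map_notes
from .simulate import CohortConfig, generate_cohort, write_cohort

log = logging.getLogger("excurves")


class RunConfig(BaseModel):
    """One reproducible run.  Every analytically ambiguous knob is
    surfaced here with its default."""

    out_dir: str
    seed: int = 0
    simulate: bool = True
    cohort: dict = Field(default_factory=dict)  # CohortConfig overrides
    input_dir: str | None = None  # used when simulate=False
    coattribution_window_min: float = 60.0
    shift_grace_min: float = 30.0
    window_days: int = 30
    step_days: int = 30
    plateau_threshold: float = 1.0
    plateau_consecutive: int = 3
    include_contexts: tuple[str, ...] = ("affirmed", "uncertain")
    ci_level: float = 0.95
    make_figures: bool = True


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def compute_summary(
    attributions: pd.DataFrame,
    encounters: pd.DataFrame,
    residents: list[Resident],
    curves: list,
    catalog_size: int,
    encounter_topics: dict[str, set[str]],
) -> dict:
    """Cohort summary: per-PGY volume/acuity/admission with CVs, Gini
    coefficients, topic frequency buckets, and a class comparison."""
    prim = attributions[attributions["role"] == "primary"]
    arr = encounters.set_index("encounter_id")["arrival_time"]
    by_id = {r.resident_id: r for r in residents}

    # per-resident, per-PGY primary encounter counts and admissions
    recs = prim.merge(encounters, on="encounter_id")
    pgys = [
        assign_pgy(by_id[r.resident_id], r.arrival_time) if r.resident_id in by_id else None
        for r in recs.itertuples()
    ]
    recs = recs.assign(pgy=pd.array(pgys, dtype="Int64")).dropna(subset=["pgy"])

    comp = complexity_progression(attributions, encounters, residents)
    per_pgy: dict[str, dict] = {}
    for pgy in range(1, N_PGY + 1):
        grp = recs[recs["pgy"] == pgy]
        vol = grp.groupby("resident_id").size()
        adm = grp.groupby("resident_id")["disposition"].apply(
            lambda d: (d == "admitted").mean()
        )
        cum = [
            sum(1 for d in c.first_seen.values() if d < pgy * DAYS_PER_PGY)
            for c in curves
            if c.events
        ]
        row = comp.loc[pgy].to_dict() if pgy in comp.index else {}
        row.update(
            {
                "volume_mean": float(vol.mean()) if len(vol) else float("nan"),
                "cv_volume": coefficient_of_variation(vol) if len(vol) > 1 else float("nan"),
                "cv_admission_rate": (
                    coefficient_of_variation(adm) if len(adm) > 1 else float("nan")
                ),
                "cv_topic_coverage": (
                    coefficient_of_variation(cum) if len(cum) > 1 else float("nan")
                ),
            }
        )
        per_pgy[str(pgy)] = row

    # inequality over residents (whole residency)
    total_vol = recs.groupby("resident_id").size()
    high_acuity = recs[recs["esi"].notna() & (recs["esi"] <= 2)].groupby("resident_id").size()
    high_acuity = high_acuity.reindex(total_vol.index, fill_value=0)
    topic_matrix = _resident_topic_counts(attributions, encounter_topics, residents)
    gini_block = {
        "volume": gini(total_vol.to_numpy()) if len(total_vol) else float("nan"),
        "high_acuity": gini(high_acuity.to_numpy()) if len(high_acuity) else float("nan"),
        **{f"topic_{k}": v for k, v in topic_gini_summary(topic_matrix).items()},
    }

    # pooled per-topic encounter counts -> frequency buckets
    pooled = topic_matrix.sum(axis=0)
    buckets = frequency_buckets(pooled, catalog_size=catalog_size)

    # class comparison of final topic coverage
    cls_groups = {}
    for c in curves:
        if not c.events:
            continue
        res = by_id.get(c.resident_id)
        if res is None:
            continue
        cls_groups.setdefault(res.class_year, []).append(c.total_topics)
    kw = {}
    usable = [g for g in cls_groups.values() if g]
    if len(usable) >= 2 and sum(len(g) for g in usable) > len(usable):
        h, p, eta2 = kruskal_wallis_eta2(*usable)
        kw = {"H": h, "p": p, "eta_squared": eta2}

    return {
        "n_residents": len(residents),
        "n_encounters_unique": int(count_encounters(attributions, "unique_encounter")["n_encounters"].sum()),
        "n_resident_encounters": int(
            count_encounters(attributions, "per_resident_exposure")["n_encounters"].sum()
        ),
        "per_pgy": per_pgy,
        "gini": gini_block,
        "frequency_buckets": buckets,
        "class_topic_coverage_kruskal_wallis": kw,
    }


def _resident_topic_counts(
    attributions: pd.DataFrame,
    encounter_topics: dict[str, set[str]],
    residents: list[Resident],
) -> pd.DataFrame:
    """residents x topics matrix of per-topic encounter counts (both
    attribution roles credit the resident)."""
    all_topics = sorted({t for ts in encounter_topics.values() for t in ts})
    t_index = {t: i for i, t in enumerate(all_topics)}
    r_ids = [r.resident_id for r in residents]
    r_index = {r: i for i, r in enumerate(r_ids)}
    mat = np.zeros((len(r_ids), len(all_topics)), dtype=float)
    for rec in attributions.itertuples():
        ri = r_index.get(rec.resident_id)
        if ri is None:
            continue
        for t in encounter_topics.get(rec.encounter_id, ()):
            mat[ri, t_index[t]] += 1
    return pd.DataFrame(mat, index=r_ids, columns=all_topics)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk).

    Identical config and seed give identical file checksums.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog, lexicon, crosswalk = default_vocabulary()
    manifest: dict = {"seed": config.seed, "config": json.loads(config.model_dump_json())}

    # ---- stage 1: cohort --------------------------------------------
    if config.simulate:
        cohort_cfg = CohortConfig(**{"seed": config.seed, **config.cohort})
        data = generate_cohort(cohort_cfg, catalog, lexicon, crosswalk)
        write_cohort(data, out / "cohort")
        residents = data.residents
        shifts, encounters, team_events = data.shifts, data.encounters, data.team_events
        notes = data.notes
        log.info("simulated %d residents, %d encounters", len(residents), len(encounters))
    else:
        if not config.input_dir:
            raise ValidationError("input_dir required when simulate=False")
        src = Path(config.input_dir)
        for name in ("roster.csv", "shifts.csv", "encounters.csv", "team_events.csv", "notes.jsonl"):
            if not (src / name).exists():
                raise ValidationError(f"missing input file: {src / name}")
        residents = _io.load_roster(src / "roster.csv")
        shifts = _io.load_shifts(src / "shifts.csv")
        encounters = _io.load_encounters(src / "encounters.csv")
        team_events = _io.load_team_events(src / "team_events.csv")
        notes = _io.load_notes(src / "notes.jsonl")

    # ---- stage 2: attribution ---------------------------------------
    policy = AttributionPolicy(
        coattribution_window=timedelta(minutes=config.coattribution_window_min),
        shift_grace=timedelta(minutes=config.shift_grace_min),
    )
    attributions = attribute(team_events, shifts, residents, policy)
    _io.save_attributions(attributions, out / "attributions.csv")
    log.info(
        "attributed %d/%d encounters (%d supervisory)",
        attributions["encounter_id"].nunique(),
        encounters["encounter_id"].nunique(),
        (attributions["role"] == "supervisory").sum(),
    )

    # ---- stage 3: note mapping --------------------------------------
    enc_topics = map_notes(
        notes,
        lexicon,
        crosswalk,
        TriggerConfig(),
        InclusionPolicy(include=frozenset(config.include_contexts)),
    )
    _io.save_encounter_topics(enc_topics, out / "encounter_topics.jsonl")

    # ---- stage 4: curves --------------------------------------------
    curves = [build_curve(r, attributions, encounters, enc_topics) for r in residents]
    curve_rows = []
    plateau_rows = []
    for c in curves:
        for day, cumv in c.cumulative:
            curve_rows.append((c.resident_id, day, cumv))
        rates = window_rates(c, config.window_days, config.step_days)
        pl = detect_plateau(
            rates, config.plateau_threshold, config.plateau_consecutive, curve=c
        )
        plateau_rows.append(
            (c.resident_id, pl.plateau_day, pl.plateau_month, pl.encounters_before_plateau)
        )
    pd.DataFrame(curve_rows, columns=["resident_id", "training_day", "cumulative_topics"]).to_csv(
        out / "curves.csv", index=False
    )
    plateaus = pd.DataFrame(
        plateau_rows,
        columns=["resident_id", "plateau_day", "plateau_month", "encounters_before_plateau"],
    )
    plateaus.to_csv(out / "plateau.csv", index=False)
    summary_tbl = pgy_exposure_summary(curves, len(catalog), config.ci_level)
    summary_tbl.to_csv(out / "pgy_summary.csv")

    by_id = {r.resident_id: r for r in residents}
    class_curves = {}
    for year in sorted({r.class_year for r in residents}):
        cl = [c for c in curves if c.events and by_id[c.resident_id].class_year == year]
        if cl:
            cc = class_mean_curve(cl, config.window_days)
            cc.to_csv(out / f"class_{year}_mean_curve.csv", index=False)
            class_curves[year] = cc

    # ---- stage 5: metrics + report ----------------------------------
    summary = compute_summary(
        attributions, encounters, residents, curves, len(catalog), enc_topics
    )
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    report = render_report(summary, summary_tbl, plateaus, residents, len(catalog))
    (out / "report.md").write_text(report)
    if config.make_figures:
        _figures(class_curves, out)

    artifacts = sorted(
        p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest["files"] = {str(p.relative_to(out)): _sha256(p) for p in artifacts}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _figures(class_curves: dict, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for year, cc in class_curves.items():
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(cc["day"] / 30.0, cc["mean_cumulative_topics"])
        ax.set_xlabel("Months of training")
        ax.set_ylabel("Mean cumulative unique topics")
        ax.set_title(f"Class of {year}")
        fig.tight_layout()
        fig.savefig(out / f"class_{year}_mean_curve.png", dpi=100)
        plt.close(fig)


def render_report(
    summary: dict,
    pgy_table: pd.DataFrame,
    plateaus: pd.DataFrame,
    residents: list[Resident],
    catalog_size: int,
) -> str:
    """Markdown report: per-PGY progression grid, plateau statistics by
    class, inequality metrics, frequency buckets."""
    by_id = {r.resident_id: r for r in residents}
    lines = ["# Residency clinical-exposure report", ""]
    lines.append(f"Residents: {summary['n_residents']}; "
                 f"unique encounters: {summary['n_encounters_unique']}; "
                 f"resident-level encounter credits: {summary['n_resident_encounters']}")
    lines.append("")
    lines.append("## Progression by PGY")
    lines.append("")
    header = ["metric"] + [f"PGY{p}" for p in range(1, N_PGY + 1)]
    rows = []
    metrics = [
        ("Encounters (unique), n", "n_encounters", "{:.0f}"),
        ("Mean ESI", "mean_esi", "{:.2f}"),
        ("High-acuity fraction (ESI 1-2)", "high_acuity_fraction", "{:.3f}"),
        ("Admission rate", "admission_rate", "{:.3f}"),
        ("Per-resident volume, mean", "volume_mean", "{:.1f}"),
        ("CV volume, %", "cv_volume", "{:.1f}"),
        ("CV admission rate, %", "cv_admission_rate", "{:.1f}"),
        ("CV topic coverage, %", "cv_topic_coverage", "{:.1f}"),
    ]
    for label, key, fmt in metrics:
        row = [label]
        for p in range(1, N_PGY + 1):
            v = summary["per_pgy"].get(str(p), {}).get(key)
            row.append(fmt.format(v) if v is not None and v == v else "-")
        rows.append(row)
    for label, col, fmt in [
        ("Cumulative topics, mean", "cumulative_mean", "{:.1f}"),
        ("New topics per year, mean", "new_mean", "{:.1f}"),
        ("Percent of catalog, %", "pct_of_catalog", "{:.1f}"),
    ]:
        row = [label]
        for p in range(1, N_PGY + 1):
            row.append(fmt.format(pgy_table.loc[p, col]) if p in pgy_table.index else "-")
        rows.append(row)
    widths = [max(len(r[i]) for r in [header] + rows) for i in range(len(header))]
    lines.append("| " + " | ".join(h.ljust(w) for h, w in zip(header, widths)) + " |")
    lines.append("|" + "|".join("-" * (w + 2) for w in widths) + "|")
    for r in rows:
        lines.append("| " + " | ".join(c.ljust(w) for c, w in zip(r, widths)) + " |")
    lines.append("")

    lines.append("## Exposure plateaus by graduating class")
    lines.append("")
    pl = plateaus.copy()
    pl["class_year"] = [
        by_id[r].class_year if r in by_id else None for r in pl["resident_id"]
    ]
    for year, grp in pl.groupby("class_year"):
        months = grp["plateau_month"].dropna()
        if months.empty:
            lines.append(f"- Class of {year}: no plateau detected "
                         f"({len(grp)} residents)")
        else:
            lines.append(
                f"- Class of {year}: plateau at mean {months.mean():.1f} months "
                f"(SD {months.std(ddof=1):.1f} over {len(months)}/{len(grp)} residents)"
            )
    lines.append("")

    g = summary["gini"]
    lines.append("## Inequality of exposure (Gini)")
    lines.append("")
    lines.append(f"- Case volume: {g['volume']:.3f}")
    lines.append(f"- High-acuity cases: {g['high_acuity']:.3f}")
    lines.append(
        f"- Topic distribution: {g['topic_mean_per_resident']:.3f} "
        f"(mean per resident; pooled {g['topic_pooled']:.3f})"
    )
    lines.append("")

    b = summary["frequency_buckets"]
    lines.append("## Topic frequency distribution")
    lines.append("")
    lines.append(
        f"- >100 encounters: {b['n_gt_high']} topics ({b['pct_gt_high']}%)"
    )
    lines.append(f"- 10-100 encounters: {b['n_mid']} topics ({b['pct_mid']}%)")
    lines.append(f"- <10 encounters: {b['n_lt_low']} topics ({b['pct_lt_low']}%)")
    lines.append("")
    return "\n".join(lines)
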