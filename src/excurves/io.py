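"""Readers and writers for the package's on-disk formats.

Everything is plain text: JSON for the vocabularies, CSV for event
tables (ISO-8601 timestamps), JSONL for notes and per-encounter topic
sets.  Loaders validate invariants and raise the named errors from
:mod:`excurves.errors`.
"""

from __future__ import annotations

import json
from datetime import date
from pathlib import Path

import pandas as pd

from .errors import CatalogLoadError, LexiconLoadError, CrosswalkError, ValidationError
from .model import (
    ATTRIBUTION_COLUMNS,
    ENCOUNTER_COLUMNS,
    ROSTER_COLUMNS,
    SHIFT_COLUMNS,
    TEAM_EVENT_COLUMNS,
    Category,
    Concept,
    ConceptLexicon,
    Crosswalk,
    Resident,
    Topic,
    TopicCatalog,
)

# ---------------------------------------------------------------- catalog


def load_catalog(path: str | Path) -> TopicCatalog:
    path = Path(path)
    if not path.exists():
        raise CatalogLoadError(f"catalog file not found: {path}")
    try:
        raw = json.loads(path.read_text())
        categories = [Category(c["id"], c["label"]) for c in raw["categories"]]
        topics = [Topic(t["id"], t["category_id"], t["label"]) for t in raw["topics"]]
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise CatalogLoadError(f"malformed catalog {path}: {exc}") from exc
    return TopicCatalog(categories=categories, topics=topics)


def save_catalog(catalog: TopicCatalog, path: str | Path) -> None:
    payload = {
        "categories": [{"id": c.category_id, "label": c.label} for c in catalog.categories],
        "topics": [
            {"id": t.topic_id, "category_id": t.category_id, "label": t.label}
            for t in catalog.topics
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------- lexicon


def load_lexicon(path: str | Path) -> ConceptLexicon:
    path = Path(path)
    if not path.exists():
        raise LexiconLoadError(f"lexicon file not found: {path}")
    try:
        raw = json.loads(path.read_text())
        concepts = [
            Concept(c["id"], c["preferred_term"], tuple(c["synonyms"]))
            for c in raw["concepts"]
        ]
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise LexiconLoadError(f"malformed lexicon {path}: {exc}") from exc
    return ConceptLexicon(concepts=concepts)


def save_lexicon(lexicon: ConceptLexicon, path: str | Path) -> None:
    payload = {
        "concepts": [
            {"id": c.concept_id, "preferred_term": c.preferred_term,
             "synonyms": list(c.synonyms)}
            for c in lexicon.concepts
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=1))


# -------------------------------------------------------------- crosswalk


def load_crosswalk(
    path: str | Path,
    lexicon: ConceptLexicon | None = None,
    catalog: TopicCatalog | None = None,
) -> Crosswalk:
    """Read the two-column TSV (header required) and optionally validate
    totality against a lexicon/catalog pair."""
    path = Path(path)
    if not path.exists():
        raise CrosswalkError(f"crosswalk file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["concept_id", "topic_id"]:
        raise CrosswalkError(
            f"crosswalk header must be concept_id<TAB>topic_id, got {list(df.columns)}"
        )
    if df["concept_id"].duplicated().any():
        dups = df.loc[df["concept_id"].duplicated(), "concept_id"].tolist()
        raise CrosswalkError(f"concept mapped twice: {dups[:3]}")
    xw = Crosswalk(mapping=dict(zip(df["concept_id"], df["topic_id"])))
    if lexicon is not None and catalog is not None:
        xw.validate(lexicon, catalog)
    return xw


def save_crosswalk(crosswalk: Crosswalk, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("concept_id\ttopic_id\n")
        for c, t in crosswalk.mapping.items():
            fh.write(f"{c}\t{t}\n")


# ----------------------------------------------------------- event tables


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} missing columns {missing}")


def load_encounters(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"encounter_id": str, "patient_id": str})
    _require_columns(df, ENCOUNTER_COLUMNS, "encounters")
    df["arrival_time"] = pd.to_datetime(df["arrival_time"])
    df["esi"] = df["esi"].astype("Int64")
    bad = df["esi"].dropna()
    if ((bad < 1) | (bad > 5)).any():
        raise ValidationError("esi outside 1..5")
    return df


def save_encounters(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def load_team_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"encounter_id": str, "resident_id": str})
    _require_columns(df, TEAM_EVENT_COLUMNS, "team events")
    df["doc_time"] = pd.to_datetime(df["doc_time"])
    if df.duplicated(["encounter_id", "resident_id"]).any():
        raise ValidationError("duplicate (encounter_id, resident_id) team event")
    return df


def save_team_events(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def load_shifts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"shift_id": str, "resident_id": str, "kind": str})
    _require_columns(df, SHIFT_COLUMNS, "shifts")
    df["start"] = pd.to_datetime(df["start"])
    df["end"] = pd.to_datetime(df["end"])
    if (df["start"] >= df["end"]).any():
        raise ValidationError("shift with start >= end")
    return df


def save_shifts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def load_roster(path: str | Path) -> list[Resident]:
    df = pd.read_csv(path, dtype={"resident_id": str})
    _require_columns(df, ROSTER_COLUMNS, "roster")
    return [
        Resident(r.resident_id, int(r.class_year), date.fromisoformat(str(r.start_date)))
        for r in df.itertuples()
    ]


def save_roster(residents: list[Resident], path: str | Path) -> None:
    pd.DataFrame(
        {
            "resident_id": [r.resident_id for r in residents],
            "class_year": [r.class_year for r in residents],
            "start_date": [r.start_date.isoformat() for r in residents],
        }
    ).to_csv(path, index=False)


def load_attributions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"encounter_id": str, "resident_id": str,
                                  "role": str, "shift_id": str})
    _require_columns(df, ATTRIBUTION_COLUMNS, "attributions")
    df["doc_time"] = pd.to_datetime(df["doc_time"])
    return df


def save_attributions(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# ------------------------------------------------------------------ notes


def load_notes(path: str | Path) -> dict[str, dict[str, str]]:
    """notes.jsonl -> {encounter_id: {section: text}}"""
    notes: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            notes[rec["encounter_id"]] = rec["sections"]
    return notes


def save_notes(notes: dict[str, dict[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for enc_id, sections in notes.items():
            fh.write(json.dumps({"encounter_id": enc_id, "sections": sections}) + "\n")


def load_encounter_topics(path: str | Path) -> dict[str, set[str]]:
    """encounter_topics.jsonl -> {encounter_id: set of topic_ids}"""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            out[rec["encounter_id"]] = set(rec["topic_ids"])
    return out


def save_encounter_topics(topics: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for enc_id, tset in topics.items():
            fh.write(
                json.dumps({"encounter_id": enc_id, "topic_ids": sorted(tset)}) + "\n"
            )
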