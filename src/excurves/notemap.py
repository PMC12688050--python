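"""Deterministic note-to-topic mapping.

A rule-based concept pipeline with the same three-stage shape as
retrieval-augmented clinical NLP systems: (1) retrieve candidate
concept mentions by longest-match dictionary lookup over the reasoning
sections of a note, (2) classify each mention's context (affirmed /
negated / historical / uncertain) by trigger scoping within the
sentence, (3) map included concepts through the crosswalk to taxonomy
topics.  The classifier is a pluggable stand-in: anything that maps a
note to a topic set (for example an LLM-backed service) can substitute
behind :func:`map_note`.

Also provides the validation-agreement statistics (percent agreement
and Cohen's kappa) used to compare pipeline output against expert
labels.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

from .errors import UndefinedKappaError, ValidationError
from .model import NOTE_SECTIONS, ConceptLexicon, Crosswalk, normalize_term

Context = str  # "affirmed" | "negated" | "historical" | "uncertain"

_TOKEN = re.compile(r"[a-z0-9]+")
_SENTENCE_BREAK = re.compile(r"[.!?\n]")


@dataclass(frozen=True)
class Mention:
    """A candidate concept match: 0-based half-open char offsets into the
    section text it was retrieved from."""

    section: str
    start: int
    end: int
    text: str
    concept_id: str


@dataclass(frozen=True)
class MentionContext:
    mention: Mention
    context: Context


@dataclass
class TriggerConfig:
    """Context-trigger phrases.  A mention takes a context iff a trigger
    occurs earlier in the same sentence with no terminator between the
    trigger and the mention; precedence negated > historical > uncertain."""

    negated: tuple[str, ...] = ("no", "denies", "negative for", "without")
    historical: tuple[str, ...] = ("history of", "prior")
    uncertain: tuple[str, ...] = ("possible", "questionable")
    terminators: tuple[str, ...] = ("but", "however", ";")


@dataclass
class InclusionPolicy:
    """Which mention contexts count as topic exposure.

    Uncertain mentions are included by default: a condition the resident
    evaluated contributes to exposure even when it never becomes the
    final diagnosis.  Negated and historical mentions are filtered out.
    """

    include: frozenset[str] = frozenset({"affirmed", "uncertain"})


@dataclass
class EncounterTopics:
    encounter_id: str
    topic_ids: set[str]
    provenance: list[MentionContext] = field(default_factory=list)


def extract_sections(note: dict[str, str]) -> list[tuple[str, str]]:
    """Keep only the diagnostic-reasoning sections, in canonical order
    HPI, MDM, ED_COURSE; absent sections are skipped silently."""
    return [(s, note[s]) for s in NOTE_SECTIONS if s in note and note[s] is not None]


class LexiconMatcher:
    """Longest-match, non-overlapping, case-insensitive dictionary
    matcher over the lexicon's normalized synonyms.

    Matching is token-based (alphanumeric runs), scanned left to right;
    at each position the longest synonym starting there wins and the
    scan resumes after it.  Reusable across notes: build once per
    lexicon.
    """

    def __init__(self, lexicon: ConceptLexicon):
        self._phrases: dict[str, str] = {}
        self._first_tokens: dict[str, int] = {}  # first token -> max phrase len
        for syn, cid in lexicon.synonym_map.items():
            toks = tuple(_TOKEN.findall(syn))
            if not toks:
                continue
            key = " ".join(toks)
            self._phrases[key] = cid
            prev = self._first_tokens.get(toks[0], 0)
            self._first_tokens[toks[0]] = max(prev, len(toks))

    def find(self, section: str, text: str) -> list[Mention]:
        spans = [(m.group(), m.start(), m.end()) for m in _TOKEN.finditer(text.lower())]
        out: list[Mention] = []
        i, n = 0, len(spans)
        while i < n:
            tok = spans[i][0]
            max_len = self._first_tokens.get(tok, 0)
            matched = 0
            if max_len:
                for L in range(min(max_len, n - i), 0, -1):
                    key = " ".join(s[0] for s in spans[i : i + L])
                    cid = self._phrases.get(key)
                    if cid is not None:
                        start, end = spans[i][1], spans[i + L - 1][2]
                        out.append(Mention(section, start, end, text[start:end], cid))
                        matched = L
                        break
            i += matched if matched else 1
        return out


def retrieve_candidates(
    section: str, text: str, lexicon: ConceptLexicon | LexiconMatcher
) -> list[Mention]:
    """Stage 1: candidate concept mentions in one section's text."""
    matcher = lexicon if isinstance(lexicon, LexiconMatcher) else LexiconMatcher(lexicon)
    return matcher.find(section, text)


def _sentence_bounds(text: str, pos: int) -> tuple[int, int]:
    start = 0
    for m in _SENTENCE_BREAK.finditer(text, 0, pos):
        start = m.end()
    m = _SENTENCE_BREAK.search(text, pos)
    end = m.start() if m else len(text)
    return start, end


def _phrase_positions(haystack: str, phrase: str) -> list[int]:
    """Word-bounded occurrences of a (possibly multi-word) phrase."""
    if phrase == ";":
        return [m.start() for m in re.finditer(";", haystack)]
    pat = r"(?<![a-z0-9])" + re.escape(phrase) + r"(?![a-z0-9])"
    return [m.start() for m in re.finditer(pat, haystack)]


def classify_context(
    mentions: list[Mention],
    section_text: str,
    triggers: TriggerConfig | None = None,
) -> list[MentionContext]:
    """Stage 2: assign each mention a context by trigger scoping.

    A mention is negated/historical/uncertain iff a trigger phrase of
    that class occurs before it in the same sentence with no terminator
    ("but", "however", ";") between trigger and mention; otherwise
    affirmed.
    """
    trig = triggers or TriggerConfig()
    text_l = section_text.lower()
    out = []
    for m in mentions:
        sent_start, _ = _sentence_bounds(section_text, m.start)
        pre = text_l[sent_start : m.start]
        term_pos = []
        for t in trig.terminators:
            term_pos.extend(_phrase_positions(pre, t.lower()))
        context: Context = "affirmed"
        for label, phrases in (
            ("negated", trig.negated),
            ("historical", trig.historical),
            ("uncertain", trig.uncertain),
        ):
            hit = False
            for p in phrases:
                for pos in _phrase_positions(pre, p.lower()):
                    # scope holds unless a terminator intervenes
                    if not any(pos < tp for tp in term_pos):
                        hit = True
                        break
                if hit:
                    break
            if hit:
                context = label
                break
        out.append(MentionContext(m, context))
    return out


def map_to_topics(
    encounter_id: str,
    contexts: list[MentionContext],
    crosswalk: Crosswalk,
    policy: InclusionPolicy | None = None,
) -> EncounterTopics:
    """Stage 3: included concepts -> deduplicated topic set."""
    pol = policy or InclusionPolicy()
    topics = {
        crosswalk.topic_for(mc.mention.concept_id)
        for mc in contexts
        if mc.context in pol.include
    }
    return EncounterTopics(encounter_id, topics, provenance=list(contexts))


def map_note(
    encounter_id: str,
    note: dict[str, str],
    matcher: LexiconMatcher,
    crosswalk: Crosswalk,
    triggers: TriggerConfig | None = None,
    policy: InclusionPolicy | None = None,
) -> EncounterTopics:
    """Full pipeline for one note: sections -> mentions -> contexts -> topics."""
    contexts: list[MentionContext] = []
    for section, text in extract_sections(note):
        mentions = matcher.find(section, text)
        contexts.extend(classify_context(mentions, text, triggers))
    return map_to_topics(encounter_id, contexts, crosswalk, policy)


def map_notes(
    notes: dict[str, dict[str, str]],
    lexicon: ConceptLexicon,
    crosswalk: Crosswalk,
    triggers: TriggerConfig | None = None,
    policy: InclusionPolicy | None = None,
) -> dict[str, set[str]]:
    """Map every note; returns {encounter_id: topic set}."""
    matcher = LexiconMatcher(lexicon)
    return {
        enc_id: map_note(enc_id, note, matcher, crosswalk, triggers, policy).topic_ids
        for enc_id, note in notes.items()
    }


# --------------------------------------------------- validation statistics


def percent_agreement(labels_a: list, labels_b: list) -> tuple[float, float]:
    """Fraction and percentage (2 decimals) of positions that agree."""
    if len(labels_a) != len(labels_b):
        raise ValidationError("label lists differ in length")
    if not labels_a:
        raise ValidationError("empty label lists")
    matches = sum(a == b for a, b in zip(labels_a, labels_b))
    frac = matches / len(labels_a)
    return frac, round(100.0 * frac, 2)


def cohens_kappa(labels_a: list, labels_b: list) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e), chance agreement from the
    product of marginals."""
    if len(labels_a) != len(labels_b):
        raise ValidationError("label lists differ in length")
    if not labels_a:
        raise ValidationError("empty label lists")
    n = len(labels_a)
    p_o = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    ca, cb = Counter(labels_a), Counter(labels_b)
    cats = set(ca) | set(cb)
    p_e = sum((ca[c] / n) * (cb[c] / n) for c in cats)
    if p_e >= 1.0 - 1e-15:
        raise UndefinedKappaError("chance agreement is 1 (single-category marginals)")
    return (p_o - p_e) / (1 - p_e)


def mean_pairwise_kappa(ratings: list[list]) -> float:
    """Multi-rater agreement reduced to the mean of pairwise Cohen's
    kappas over all rater pairs."""
    if len(ratings) < 2:
        raise ValidationError("need at least 2 raters")
    ks = []
    for i in range(len(ratings)):
        for j in range(i + 1, len(ratings)):
            ks.append(cohens_kappa(ratings[i], ratings[j]))
    return float(sum(ks) / len(ks))
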