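"""Default packaged vocabulary: an 895-topic taxonomy, a concept
lexicon, and the concept->topic crosswalk.

The taxonomy mirrors the shape of the 2022 emergency-medicine practice
model — 895 leaf subcategories under 20 broad categories — without
reproducing its text: a curated seed of common ED presentations supplies
readable labels for the head of the distribution, and deterministic
word-built terms fill the tail.  Everything is generated in code so no
data files ship with the package.
"""

from __future__ import annotations

from .model import Category, Concept, ConceptLexicon, Crosswalk, Topic, TopicCatalog

N_DEFAULT_TOPICS = 895

_CATEGORY_LABELS = [
    "Signs, Symptoms, and Presentations",
    "Abdominal and Gastrointestinal Disorders",
    "Cardiovascular Disorders",
    "Cutaneous Disorders",
    "Endocrine and Metabolic Disorders",
    "Environmental Disorders",
    "Head, Ear, Eye, Nose, and Throat Disorders",
    "Hematologic Disorders",
    "Immune System Disorders",
    "Systemic Infectious Disorders",
    "Musculoskeletal Disorders (Nontraumatic)",
    "Nervous System Disorders",
    "Obstetrics and Gynecology",
    "Psychobehavioral Disorders",
    "Renal and Urogenital Disorders",
    "Thoracic and Respiratory Disorders",
    "Toxicologic Disorders",
    "Traumatic Disorders",
    "Procedures and Skills",
    "Other Core Competencies",
]

# Curated head-of-distribution presentations: (label, synonyms...).
# Synonyms avoid the context-trigger vocabulary ("no", "denies",
# "history", "prior", "possible", ...) so scoping is decided by the
# surrounding sentence, never by the term itself.
_SEED_TERMS: list[tuple[str, ...]] = [
    ("Chest pain", "chest pain", "chest discomfort"),
    ("Abdominal pain", "abdominal pain", "abd pain"),
    ("Shortness of breath", "shortness of breath", "dyspnea"),
    ("Headache", "headache", "cephalgia"),
    ("Back pain", "back pain"),
    ("Syncope", "syncope", "fainting episode"),
    ("Fever", "fever", "febrile illness"),
    ("Altered mental status", "altered mental status", "encephalopathy"),
    ("Nausea and vomiting", "nausea and vomiting", "emesis"),
    ("Dizziness", "dizziness", "vertigo"),
    ("Acute coronary syndrome", "acute coronary syndrome", "myocardial infarction"),
    ("Congestive heart failure", "congestive heart failure", "acute decompensated heart failure"),
    ("Atrial fibrillation", "atrial fibrillation", "afib with rapid ventricular response"),
    ("Pulmonary embolism", "pulmonary embolism", "pe protocol ct positive"),
    ("Pneumonia", "pneumonia", "community acquired pneumonia"),
    ("Asthma exacerbation", "asthma exacerbation", "acute asthma attack"),
    ("COPD exacerbation", "copd exacerbation", "obstructive lung disease flare"),
    ("Sepsis", "sepsis", "septic shock"),
    ("Urinary tract infection", "urinary tract infection", "cystitis"),
    ("Pyelonephritis", "pyelonephritis",),
    ("Nephrolithiasis", "nephrolithiasis", "renal colic"),
    ("Appendicitis", "appendicitis", "acute appendicitis"),
    ("Cholecystitis", "cholecystitis", "biliary colic"),
    ("Pancreatitis", "pancreatitis", "acute pancreatitis"),
    ("Small bowel obstruction", "small bowel obstruction", "sbo"),
    ("Gastrointestinal bleeding", "gastrointestinal bleeding", "gi bleed"),
    ("Diabetic ketoacidosis", "diabetic ketoacidosis", "dka"),
    ("Hypoglycemia", "hypoglycemia",),
    ("Stroke", "acute ischemic stroke", "cerebrovascular accident"),
    ("Transient ischemic attack", "transient ischemic attack", "tia"),
    ("Seizure", "seizure", "convulsive episode"),
    ("Migraine", "migraine", "migrainous headache"),
    ("Cellulitis", "cellulitis", "soft tissue infection"),
    ("Abscess", "cutaneous abscess", "skin abscess"),
    ("Anaphylaxis", "anaphylaxis", "anaphylactic reaction"),
    ("Deep vein thrombosis", "deep vein thrombosis", "dvt"),
    ("Hypertensive emergency", "hypertensive emergency", "malignant hypertension"),
    ("Alcohol intoxication", "alcohol intoxication", "ethanol intoxication"),
    ("Opioid overdose", "opioid overdose", "opiate toxicity"),
    ("Suicidal ideation", "suicidal ideation", "si with plan"),
    ("Ankle fracture", "ankle fracture",),
    ("Wrist fracture", "wrist fracture", "distal radius fracture"),
    ("Hip fracture", "hip fracture", "femoral neck fracture"),
    ("Laceration", "laceration", "open wound requiring repair"),
    ("Closed head injury", "closed head injury", "concussion"),
    ("Ectopic pregnancy", "ectopic pregnancy",),
    ("Ovarian torsion", "ovarian torsion",),
    ("Testicular torsion", "testicular torsion",),
]

_ROOTS = [
    "cardio", "neuro", "nephro", "hepato", "dermato", "entero", "arthro",
    "hemato", "pneumo", "myo", "osteo", "angio", "gastro", "thyro",
    "cysto", "retino", "oto", "rhino", "phlebo", "adeno",
]
_SUFFIXES = ["pathy", "itis", "osis", "dynia", "megaly", "plegia", "trophy"]


def _filler_terms(k: int) -> tuple[str, ...]:
    """Deterministic pseudo-clinical term(s) for tail topic index k."""
    root = _ROOTS[k % len(_ROOTS)]
    suffix = _SUFFIXES[(k // len(_ROOTS)) % len(_SUFFIXES)]
    base = f"{root}{suffix} type {k}"
    if k % 3 == 0:
        return (base.title(), base, f"{root}{suffix} variant {k}")
    return (base.title(), base)


def default_catalog(n_topics: int = N_DEFAULT_TOPICS) -> TopicCatalog:
    categories = [
        Category(f"CAT{i + 1:02d}", label) for i, label in enumerate(_CATEGORY_LABELS)
    ]
    topics = []
    n_cat = len(categories)
    for k in range(n_topics):
        label = _SEED_TERMS[k][0] if k < len(_SEED_TERMS) else _filler_terms(k)[0]
        topics.append(Topic(f"T{k + 1:04d}", categories[k % n_cat].category_id, label))
    return TopicCatalog(categories=categories, topics=topics)


def default_lexicon(n_topics: int = N_DEFAULT_TOPICS) -> ConceptLexicon:
    concepts = []
    for k in range(n_topics):
        terms = _SEED_TERMS[k] if k < len(_SEED_TERMS) else _filler_terms(k)
        concepts.append(
            Concept(f"C{k + 1:04d}", preferred_term=terms[0], synonyms=tuple(terms[1:]))
        )
    # A second concept for the first 20 topics (an alias concept), so the
    # crosswalk is genuinely many-to-one like a real terminology subset.
    for k in range(min(20, n_topics)):
        pref = _SEED_TERMS[k][0] if k < len(_SEED_TERMS) else _filler_terms(k)[0]
        concepts.append(
            Concept(
                f"C9{k + 1:03d}",
                preferred_term=f"{pref} (alias)",
                synonyms=(f"{pref.lower()} alias presentation",),
            )
        )
    return ConceptLexicon(concepts=concepts)


def default_crosswalk(n_topics: int = N_DEFAULT_TOPICS) -> Crosswalk:
    mapping = {f"C{k + 1:04d}": f"T{k + 1:04d}" for k in range(n_topics)}
    for k in range(min(20, n_topics)):
        mapping[f"C9{k + 1:03d}"] = f"T{k + 1:04d}"
    return Crosswalk(mapping=mapping)


def default_vocabulary(
    n_topics: int = N_DEFAULT_TOPICS,
) -> tuple[TopicCatalog, ConceptLexicon, Crosswalk]:
    catalog = default_catalog(n_topics)
    lexicon = default_lexicon(n_topics)
    crosswalk = default_crosswalk(n_topics)
    crosswalk.validate(lexicon, catalog)
    return catalog, lexicon, crosswalk
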