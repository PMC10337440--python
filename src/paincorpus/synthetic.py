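"""Seeded synthetic mental-health note corpora with gold pain labels.

Real mental-health records cannot be shared, so every other module is
exercised against simulated notes whose statistical structure matches
the corpus being emulated: long documents (~1026 words on average), a
handful of pain mentions each, and a label mixture of roughly 71%
relevant / 15% not relevant / 13% negated, with 63% of relevant
mentions carrying an anatomical location.

Documents are assembled from a template bank: neutral filler sentences
plus mention-bearing templates instantiated according to the sampled
gold labels (negation frames, experiencer frames, question-mark frames,
and anatomy/character/management slots).  The generator and the rule
annotator share no code path, so recovering gold labels through the
pipeline is a real end-to-end check.  No real patient text is used,
ever.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .annotator import NA, PainAnnotation, validate_annotation
from .lexicon import Document, MentionMatch

__all__ = [
    "SyntheticConfig",
    "GoldCorpus",
    "generate_corpus",
    "generate_double_annotations",
    "LABEL_SPACES",
]

# Emulated corpus fractions, stored as exact count ratios so each
# mixture sums to 1 while rounding to the headline percentages
# (71/15/13, 63%, 3/8/89, 7/3/89).
_N = 5644.0
_REL = 4028.0

DEFAULT_RELEVANCE_MIX = {
    "relevant": _REL / _N,        # 71%
    "not_relevant": 859.0 / _N,   # 15%
    "negated": 757.0 / _N,        # 13%
}
DEFAULT_ANATOMY_RATE = 2540.0 / _REL  # 63% of relevant mentions
DEFAULT_CHARACTER_MIX = {
    "chronic": 157.0 / _N,  # 3%
    "other": 487.0 / _N,    # 8%
    NA: 5000.0 / _N,        # 89%
}
DEFAULT_MANAGEMENT_MIX = {
    "medication": 422.0 / _N,  # 7%
    "other": 188.0 / _N,       # 3%
    NA: 5034.0 / _N,           # 89%
}
# top five anatomical regions, most common first
DEFAULT_LOCATION_WEIGHTS = {
    "chest": 0.30,
    "head": 0.25,
    "back": 0.20,
    "abdomen": 0.15,
    "neck": 0.10,
}
# chapter counts normalized by their own sum so the mixture is exact
_ND = 5643.0
DEFAULT_DIAGNOSIS_MIX = {
    "F30-39 Mood disorders": 1857 / _ND,
    "F40-49 Anxiety and other nonpsychotic mental disorders": 1122 / _ND,
    "F20-29 Schizophrenia and other nonmood psychotic disorders": 786 / _ND,
    "F01-09 Mental disorder due to known physiological condition": 460 / _ND,
    "Mental disorder, not otherwise specified": 327 / _ND,
    "F10-19 Mental and behavioral disorders due to substance use": 311 / _ND,
    "Miscellaneous": 222 / _ND,
    "Z71.1 Feared complaint, no diagnosis": 186 / _ND,
    "F80-89 Developmental disorders": 104 / _ND,
    "F50-59 Behavioral": 103 / _ND,
    "F90-98 Behavioral and emotional disorders, childhood onset": 85 / _ND,
    "F60-69 Personality disorder": 59 / _ND,
    "F70-79 Intellectual disabilities": 21 / _ND,
}
DEFAULT_DEMOGRAPHICS_MIX = {
    "age_band": {"<=20": 538 / 5636, "21-40": 1205 / 5636,
                 "41-60": 1439 / 5636, "61-80": 1888 / 5636,
                 ">80": 566 / 5636},
    "gender": {"male": 2991 / _N, "female": 2653 / _N},
    "ethnicity": {"white": 3659 / _N, "mixed": 84 / _N, "black": 941 / _N,
                  "asian": 247 / _N, "other": 713 / _N},
}

LABEL_SPACES = {
    "correct": ("yes", "no"),
    "relevance": ("relevant", "negated", "not_relevant", NA),
    "anatomy": ("mentioned", NA),
    "character": ("chronic", "other", NA),
    "management": ("medication", "other", NA),
}


def _check_mixture(name: str, mix: dict) -> None:
    total = float(sum(mix.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1, got {total!r}")
    for key, p in mix.items():
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name}[{key!r}] = {p!r} is outside [0, 1]")


@dataclass(frozen=True)
class SyntheticConfig:
    """All mixture proportions, size parameters, and the seed."""

    seed: int = 0
    n_patients: int = 50
    docs_per_patient_mean: float = 2.75
    mentions_per_doc_mean: float = 3.0
    mentions_per_doc_max: int = 84
    words_per_doc_mean: float = 1026.0
    relevance_mix: dict = field(
        default_factory=lambda: dict(DEFAULT_RELEVANCE_MIX))
    incorrect_rate: float = 0.05
    anatomy_rate_given_relevant: float = DEFAULT_ANATOMY_RATE
    location_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_LOCATION_WEIGHTS))
    character_mix: dict = field(
        default_factory=lambda: dict(DEFAULT_CHARACTER_MIX))
    management_mix: dict = field(
        default_factory=lambda: dict(DEFAULT_MANAGEMENT_MIX))
    diagnosis_mix: dict = field(
        default_factory=lambda: dict(DEFAULT_DIAGNOSIS_MIX))
    demographics_mix: dict = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in DEFAULT_DEMOGRAPHICS_MIX.items()})

    def validate(self) -> None:
        _check_mixture("relevance_mix", self.relevance_mix)
        _check_mixture("character_mix", self.character_mix)
        _check_mixture("management_mix", self.management_mix)
        _check_mixture("location_weights", self.location_weights)
        _check_mixture("diagnosis_mix", self.diagnosis_mix)
        for name, mix in self.demographics_mix.items():
            _check_mixture(f"demographics_mix[{name!r}]", mix)
        if not (0.0 <= self.incorrect_rate <= 1.0):
            raise ValueError(
                f"incorrect_rate = {self.incorrect_rate!r} is outside [0, 1]")
        if not (0.0 <= self.anatomy_rate_given_relevant <= 1.0):
            raise ValueError(
                "anatomy_rate_given_relevant = "
                f"{self.anatomy_rate_given_relevant!r} is outside [0, 1]")
        for name in ("docs_per_patient_mean", "mentions_per_doc_mean",
                     "words_per_doc_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")


@dataclass(frozen=True)
class GoldCorpus:
    documents: list[Document]
    gold: list[PainAnnotation]
    config: SyntheticConfig


# ---------------------------------------------------------------------------
# template bank

# Filler: neutral mental-health narrative, verified lexicon-silent by test.
FILLER_SENTENCES = (
    "Seen at the community clinic today for a routine review.",
    "Mood remains stable and there are no new concerns.",
    "Sleep has improved over the last two weeks.",
    "Medication was reviewed with the consultant this morning.",
    "Appetite is reasonable and weight is steady.",
    "Attended the group session and engaged well with staff.",
    "Plan to follow up in four weeks at the outpatient clinic.",
    "Family were present during the assessment and were supportive.",
    "Risk assessment completed with no changes identified.",
    "Discussed coping strategies and agreed on the care plan.",
    "Remains settled on the ward with a good daily routine.",
    "Concentration is variable but improving with structure.",
    "Home visit completed and the flat was clean and tidy.",
    "Engaged with the occupational therapy programme this week.",
    "Bloods were taken and results are awaited.",
    "No concerns were raised by the care coordinator.",
    "Continues to attend college two days a week.",
    "Speech was clear and coherent throughout the meeting.",
    "Denies any thoughts of self harm at present.",
    "Referral letter was sent to the community team.",
)

_SUBJECTS = ("He", "She", "The patient")
_REL_VERBS = ("reports", "describes", "complains of", "mentions")
# descriptors safe to embed: none of these match a lexicon pattern
_OTHER_DESCRIPTORS = ("severe", "constant", "throbbing", "sharp", "dull",
                      "stabbing", "shooting", "neuropathic")
_LOCATION_WORDS = {
    "chest": "chest",
    "head": "head",
    "back": "back",
    "abdomen": "abdominal",
    "neck": "neck",
}
# compound surfaces whose token itself encodes the location
_COMPOUND_SURFACES = {"head": ("headache", "headaches"),
                      "back": ("backache", "backaches")}
_MED_CLAUSES = (" and takes paracetamol for it",
                " and has been given ibuprofen",
                " and is using codeine at night")
_OTHER_MGMT_CLAUSES = (" and attends physiotherapy weekly",
                       " and finds massage helpful")
_MED_LEADS = ("On paracetamol", "Taking ibuprofen", "Given codeine")
_OTHER_MGMT_LEADS = ("Attends physiotherapy", "Has regular massage")

# lexical false positives and inanimate-referent frames
_INCORRECT_TEMPLATES = (
    ("She ", "painted", " a picture of the situation."),
    ("There is fresh ", "paint", " on the corridor walls."),
    ("He spent the summer holiday in ", "Spain", " with his aunt."),
    ("He ", "attaches", " great importance to his routine."),
    ("He likes ", "burning", " things in the garden."),
    ("There were ", "burn", " marks on the door."),
)


def _mgmt_clause(management: str, rng: np.random.Generator) -> str:
    if management == "medication":
        return _MED_CLAUSES[rng.integers(len(_MED_CLAUSES))]
    if management == "other":
        return _OTHER_MGMT_CLAUSES[rng.integers(len(_OTHER_MGMT_CLAUSES))]
    return ""


def _character_words(character: str, rng: np.random.Generator) -> str:
    if character == "chronic":
        return "chronic "
    if character == "other":
        return _OTHER_DESCRIPTORS[rng.integers(len(_OTHER_DESCRIPTORS))] + " "
    return ""


def _render_mention_sentence(
    labels: dict, rng: np.random.Generator
) -> tuple[str, str, int, str]:
    """Build one mention-bearing sentence.

    Returns (sentence, mention_surface, mention_offset, canonical_word).
    """
    if labels["correct"] == "no":
        prefix, surface, suffix = _INCORRECT_TEMPLATES[
            rng.integers(len(_INCORRECT_TEMPLATES))]
        canon = "Burn" if "burn" in surface.lower() else "Pain"
        if surface.lower() in ("attaches",):
            canon = "Ache"
        return prefix + surface + suffix, surface, len(prefix), canon

    chr_words = _character_words(labels["character"], rng)
    relevance = labels["relevance"]

    loc_words = ""
    surface = "pain"
    canon = "Pain"
    if labels["anatomy"] == "mentioned":
        loc = labels["anatomy_location"]
        compound = _COMPOUND_SURFACES.get(loc)
        if compound is not None and rng.random() < 0.5:
            surface = compound[rng.integers(len(compound))]
            canon = "Ache"
        else:
            loc_words = _LOCATION_WORDS[loc] + " "

    subj = _SUBJECTS[rng.integers(len(_SUBJECTS))]
    core = f"{chr_words}{loc_words}{surface}"
    # offset of the mention surface inside the core phrase
    core_off = len(chr_words) + len(loc_words)

    if relevance == "relevant":
        verb = _REL_VERBS[rng.integers(len(_REL_VERBS))]
        mgmt = _mgmt_clause(labels["management"], rng)
        prefix = f"{subj} {verb} "
        return prefix + core + mgmt + ".", surface, len(prefix) + core_off, canon

    if relevance == "negated":
        mgmt = _mgmt_clause(labels["management"], rng)
        variant = rng.integers(3)
        if variant == 0:
            prefix = f"{subj} reports no "
        elif variant == 1:
            prefix = f"{subj} denies any "
        else:
            prefix = "There is no "
            return (prefix + core + " reported" + mgmt + ".", surface,
                    len(prefix) + core_off, canon)
        return prefix + core + mgmt + ".", surface, len(prefix) + core_off, canon

    # not_relevant: experiencer / hypothetical / uncertainty frames
    variant = rng.integers(3)
    if variant == 0:
        rel = ("mother", "father", "daughter", "son", "friend")[
            rng.integers(5)]
        mgmt = _mgmt_clause(labels["management"], rng)
        prefix = f"His {rel} has "
        return prefix + core + mgmt + ".", surface, len(prefix) + core_off, canon
    if variant == 1:
        mgmt = _mgmt_clause(labels["management"], rng)
        lead = ("He is afraid of ", "She is worried about ",
                "There is a risk of ")[rng.integers(3)]
        return lead + core + mgmt + ".", surface, len(lead) + core_off, canon
    # uncertainty: "?" immediately after the mention token; any management
    # lead stays inside the same sentence so the context window sees it
    if labels["management"] == "medication":
        mgmt_lead = _MED_LEADS[rng.integers(len(_MED_LEADS))] + ", query "
    elif labels["management"] == "other":
        mgmt_lead = _OTHER_MGMT_LEADS[rng.integers(len(_OTHER_MGMT_LEADS))] \
            + ", query "
    else:
        mgmt_lead = "Query "
    return mgmt_lead + core + "?", surface, len(mgmt_lead) + core_off, canon


def _sample_categorical(mix: dict, rng: np.random.Generator) -> str:
    keys = list(mix.keys())
    probs = np.asarray([mix[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[rng.choice(len(keys), p=probs)]


def _truncated_geometric(mean: float, maximum: int,
                         rng: np.random.Generator) -> int:
    p = min(1.0, 1.0 / max(mean, 1.0))
    return int(min(rng.geometric(p), maximum))


def _sample_labels(config: SyntheticConfig, rng: np.random.Generator) -> dict:
    if rng.random() < config.incorrect_rate:
        return {"correct": "no", "relevance": NA, "anatomy": NA,
                "anatomy_location": None, "character": NA, "management": NA}
    relevance = _sample_categorical(config.relevance_mix, rng)
    anatomy, location = NA, None
    if relevance == "relevant" and rng.random() < config.anatomy_rate_given_relevant:
        anatomy, location = "mentioned", _sample_categorical(
            config.location_weights, rng)
    return {
        "correct": "yes",
        "relevance": relevance,
        "anatomy": anatomy,
        "anatomy_location": location,
        "character": _sample_categorical(config.character_mix, rng),
        "management": _sample_categorical(config.management_mix, rng),
    }


def generate_corpus(config: Optional[SyntheticConfig] = None) -> GoldCorpus:
    """Generate a seeded corpus of notes with gold annotations.

    Identical configs (including the seed) produce byte-identical
    corpora.  Every gold span slices to its surface and every gold
    annotation satisfies the structural label invariants.
    """
    if config is None:
        config = SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    documents: list[Document] = []
    gold: list[PainAnnotation] = []
    doc_counter = 0
    for p in range(config.n_patients):
        patient_id = f"P{p:05d}"
        demo = {k: _sample_categorical(v, rng)
                for k, v in config.demographics_mix.items()}
        diagnosis = _sample_categorical(config.diagnosis_mix, rng)
        n_docs = _truncated_geometric(config.docs_per_patient_mean, 50, rng)
        for _ in range(n_docs):
            doc_id = f"D{doc_counter:06d}"
            doc_counter += 1
            n_mentions = _truncated_geometric(
                config.mentions_per_doc_mean, config.mentions_per_doc_max, rng)
            mention_items = []
            mention_words = 0
            for _ in range(n_mentions):
                labels = _sample_labels(config, rng)
                sent, surface, offset, canon = _render_mention_sentence(
                    labels, rng)
                mention_items.append((sent, surface, offset, canon, labels))
                mention_words += len(sent.split())

            target_words = max(
                mention_words + 10,
                int(rng.normal(config.words_per_doc_mean,
                               config.words_per_doc_mean / 4.0)),
            )
            filler: list[str] = []
            words = mention_words
            while words < target_words:
                s = FILLER_SENTENCES[rng.integers(len(FILLER_SENTENCES))]
                filler.append(s)
                words += len(s.split())

            # interleave mention sentences at random filler positions
            positions = sorted(
                rng.integers(0, len(filler) + 1, size=len(mention_items)))
            sentences: list[tuple[str, Optional[tuple]]] = []
            fi = 0
            for pos, item in sorted(
                    zip(positions, range(len(mention_items)))):
                while fi < pos:
                    sentences.append((filler[fi], None))
                    fi += 1
                sentences.append((mention_items[item][0], mention_items[item]))
            while fi < len(filler):
                sentences.append((filler[fi], None))
                fi += 1

            parts: list[str] = []
            cursor = 0
            doc_gold: list[PainAnnotation] = []
            for sent, item in sentences:
                if parts:
                    parts.append(" ")
                    cursor += 1
                if item is not None:
                    _, surface, offset, canon, labels = item
                    start = cursor + offset
                    doc_gold.append(
                        PainAnnotation(
                            mention=MentionMatch(
                                doc_id=doc_id,
                                start=start,
                                end=start + len(surface),
                                surface=surface,
                                pattern="",
                                canonical_word=canon,
                                excluded=labels["correct"] == "no",
                            ),
                            correct=labels["correct"],
                            relevance=labels["relevance"],
                            anatomy=labels["anatomy"],
                            anatomy_location=labels["anatomy_location"],
                            character=labels["character"],
                            management=labels["management"],
                        )
                    )
                parts.append(sent)
                cursor += len(sent)
            text = "".join(parts)
            doc = Document(
                doc_id=doc_id,
                patient_id=patient_id,
                source_type="Event" if rng.random() < 0.78 else "Attachment",
                text=text,
                diagnosis_chapter=diagnosis,
                demographics=demo,
            )
            for ann in doc_gold:
                s, e = ann.mention.start, ann.mention.end
                assert text[s:e] == ann.mention.surface
                validate_annotation(ann)
            documents.append(doc)
            gold.extend(doc_gold)
    return GoldCorpus(documents=documents, gold=gold, config=config)


def generate_double_annotations(
    corpus: GoldCorpus, disagreement_rate: float, seed: int
) -> tuple[list[PainAnnotation], list[PainAnnotation]]:
    """Emulate a two-annotator setting over a gold corpus.

    Annotator A returns the gold labels.  Annotator B returns the gold
    labels with each attribute independently perturbed, with probability
    ``disagreement_rate``, to a uniformly chosen *different* category.
    """
    if not (0.0 <= disagreement_rate <= 1.0):
        raise ValueError(
            f"disagreement_rate = {disagreement_rate!r} is outside [0, 1]")
    rng = np.random.default_rng(seed)
    ann_a = list(corpus.gold)
    ann_b: list[PainAnnotation] = []
    for ann in corpus.gold:
        changes = {}
        for attr, space in LABEL_SPACES.items():
            if rng.random() < disagreement_rate:
                current = getattr(ann, attr)
                alternatives = [v for v in space if v != current]
                changes[attr] = alternatives[rng.integers(len(alternatives))]
        b = replace(ann, **changes) if changes else ann
        if b.anatomy != "mentioned" and b.anatomy_location is not None:
            b = replace(b, anatomy_location=None)
        ann_b.append(b)
    return ann_a, ann_b
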