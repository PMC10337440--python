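"""Rule-based assignment of the pain annotation scheme.

Every lexicon match receives five labels, emulating the decisions a human
annotator makes from the surrounding sentence:

* **correct** — is this genuinely a mention of pain in the medical sense,
  or a lexical false positive ("painted", "burning incense")?
* **relevance** — relevant (the patient's own physical pain), negated
  (explicit absence of pain), or not relevant (another experiencer,
  metaphor/hypothetical, or an uncertain "?"-marked mention).
* **anatomy** — whether a body part is referenced, and its normalized
  location (headache -> head, "chronic back pain" -> back).
* **character** — chronic only when the word "chronic" is explicit;
  any other descriptor ("severe", "throbbing") is "other".
* **management** — medication (painkillers, analgesics ...) vs other
  (physiotherapy, pain clinic, massage).

Rules are deterministic and gazetteer-driven; all trigger lists are
plain data and can be loaded from a config file.  Relevance rules apply
in a fixed precedence: uncertainty > experiencer > hypothetical >
negation > relevant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .lexicon import Document, Lexicon, MentionMatch, find_mentions, tokenize

__all__ = [
    "CORRECT_VALUES",
    "RELEVANCE_VALUES",
    "ANATOMY_VALUES",
    "CHARACTER_VALUES",
    "MANAGEMENT_VALUES",
    "PainAnnotation",
    "RuleGazetteers",
    "ContextWindow",
    "default_gazetteers",
    "context_window",
    "classify_correct",
    "classify_relevance",
    "detect_anatomy",
    "classify_character",
    "classify_management",
    "annotate_document",
    "validate_annotation",
]

NA = "n/a"

CORRECT_VALUES = ("yes", "no")
RELEVANCE_VALUES = ("relevant", "negated", "not_relevant", NA)
ANATOMY_VALUES = ("mentioned", NA)
CHARACTER_VALUES = ("chronic", "other", NA)
MANAGEMENT_VALUES = ("medication", "other", NA)


@dataclass(frozen=True)
class PainAnnotation:
    """A mention plus the full label scheme."""

    mention: MentionMatch
    correct: str
    relevance: str = NA
    anatomy: str = NA
    anatomy_location: Optional[str] = None
    character: str = NA
    character_surface: Optional[str] = None
    management: str = NA


def validate_annotation(ann: PainAnnotation) -> None:
    """Raise ValueError if the label combination is structurally invalid."""
    if ann.correct not in CORRECT_VALUES:
        raise ValueError(f"bad correct label {ann.correct!r}")
    if ann.relevance not in RELEVANCE_VALUES:
        raise ValueError(f"bad relevance label {ann.relevance!r}")
    if ann.anatomy not in ANATOMY_VALUES:
        raise ValueError(f"bad anatomy label {ann.anatomy!r}")
    if ann.character not in CHARACTER_VALUES:
        raise ValueError(f"bad character label {ann.character!r}")
    if ann.management not in MANAGEMENT_VALUES:
        raise ValueError(f"bad management label {ann.management!r}")
    if ann.correct == "no":
        downstream = (ann.relevance, ann.anatomy, ann.character, ann.management)
        if any(v != NA for v in downstream):
            raise ValueError(
                "incorrect mentions must have all downstream attributes n/a, "
                f"got {downstream}"
            )
    if (ann.anatomy == "mentioned") != (ann.anatomy_location is not None):
        raise ValueError("anatomy == mentioned iff anatomy_location is set")


@dataclass(frozen=True)
class RuleGazetteers:
    """Trigger phrase lists driving the contextual rules.

    All phrases lowercase.  ``anatomy_map`` maps surface terms to a
    closed location vocabulary and includes compound forms whose mention
    surface itself encodes the location (headache -> head).
    """

    negation_triggers: frozenset[str]
    experiencer_triggers: frozenset[str]
    hypothetical_triggers: frozenset[str]
    anatomy_map: dict
    character_descriptors: frozenset[str]
    management_medication_triggers: frozenset[str]
    management_other_triggers: frozenset[str]
    inanimate_referents: frozenset[str]
    negation_window: int = 6
    proximity_window: int = 3


def default_gazetteers() -> RuleGazetteers:
    return RuleGazetteers(
        negation_triggers=frozenset(
            {"no", "not", "denies", "denied", "without", "nil",
             "does not complain", "free"}
        ),
        experiencer_triggers=frozenset(
            {"mother", "father", "wife", "husband", "son", "daughter",
             "friend", "family", "carer", "staff", "brother", "sister",
             "neighbour", "neighbor"}
        ),
        hypothetical_triggers=frozenset(
            {"fear of", "afraid", "if", "would be", "in case", "risk of",
             "sore thumb", "worried about"}
        ),
        anatomy_map={
            # compound surfaces: the mention itself encodes the location
            "headache": "head", "headaches": "head",
            "backache": "back", "backaches": "back",
            "heartburn": "chest",
            "migraine": "head", "migraines": "head",
            "sciatica": "back", "sciatic": "back",
            "lumbago": "back",
            # context terms within the proximity window
            "head": "head", "temple": "head", "temples": "head",
            "chest": "chest", "heart": "chest",
            "back": "back", "spine": "back", "lumbar": "back",
            "abdomen": "abdomen", "abdominal": "abdomen",
            "stomach": "abdomen", "belly": "abdomen", "tummy": "abdomen",
            "pelvis": "abdomen", "pelvic": "abdomen",
            "neck": "neck",
            "shoulder": "shoulder", "shoulders": "shoulder",
            "knee": "knee", "knees": "knee",
            "hip": "hip", "hips": "hip",
            "leg": "leg", "legs": "leg",
            "arm": "arm", "arms": "arm",
            "hand": "hand", "hands": "hand",
            "foot": "foot", "feet": "foot",
        },
        character_descriptors=frozenset(
            {"shooting", "throbbing", "burning", "severe", "constant",
             "sharp", "dull", "aching", "stabbing", "neuropathic",
             "uropathic", "colicky"}
        ),
        management_medication_triggers=frozenset(
            {"painkiller", "painkillers", "analgesia", "analgesic",
             "analgesics", "paracetamol", "ibuprofen", "codeine",
             "morphine", "pain relief medication"}
        ),
        management_other_triggers=frozenset(
            {"physiotherapy", "pain clinic", "massage"}
        ),
        inanimate_referents=frozenset(
            {"marks", "mark", "incense", "things", "toast", "candles",
             "candle", "rubbish", "paper", "papers", "holes", "hole",
             "wood", "food", "dinner", "smell", "building", "house"}
        ),
    )


@dataclass(frozen=True)
class ContextWindow:
    """The sentence-bounded span around a mention.

    ``text`` is ``doc.text[start:end]``; ``mention_start``/``mention_end``
    are offsets of the mention *within* the window.
    """

    text: str
    start: int
    end: int
    mention_start: int
    mention_end: int

    @property
    def before(self) -> str:
        return self.text[: self.mention_start]

    @property
    def after(self) -> str:
        return self.text[self.mention_end:]


_CAP = 300  # max characters kept on each side of the mention


def _is_boundary(text: str, i: int) -> bool:
    # ". ", "! " or "? " followed by whitespace then a capital, or newline
    ch = text[i]
    if ch == "\n":
        return True
    if ch not in ".!?":
        return False
    j = i + 1
    if j >= len(text) or not text[j].isspace():
        return False
    while j < len(text) and text[j].isspace():
        j += 1
    return j < len(text) and text[j].isupper()


def context_window(doc: Document, mention: MentionMatch) -> ContextWindow:
    """Return the sentence containing the mention, capped at 300
    characters on each side of the mention span."""
    text = doc.text
    if mention.doc_id != doc.doc_id or not (
        0 <= mention.start < mention.end <= len(text)
    ):
        raise ValueError(
            f"mention {mention.doc_id}[{mention.start}:{mention.end}] does "
            f"not belong to document {doc.doc_id!r}"
        )
    lo = max(0, mention.start - _CAP)
    start = lo
    for i in range(mention.start - 1, lo - 1, -1):
        if _is_boundary(text, i):
            start = i + 1
            break
    hi = min(len(text), mention.end + _CAP)
    end = hi
    for i in range(mention.end, hi):
        if _is_boundary(text, i):
            end = i + 1
            break
    # trim the leading whitespace a boundary leaves behind
    while start < mention.start and text[start].isspace():
        start += 1
    return ContextWindow(
        text=text[start:end],
        start=start,
        end=end,
        mention_start=mention.start - start,
        mention_end=mention.end - start,
    )


def _tokens_with_spans(text: str) -> list[tuple[str, int, int]]:
    return [(m.group(0).lower(), m.start(), m.end()) for m in tokenize(text)]


def _mention_token_index(window: ContextWindow) -> tuple[list[tuple[str, int, int]], int]:
    toks = _tokens_with_spans(window.text)
    for i, (_, s, e) in enumerate(toks):
        if s == window.mention_start and e == window.mention_end:
            return toks, i
    raise ValueError("mention span does not align with a window token")


def classify_correct(
    mention: MentionMatch,
    window: ContextWindow,
    lexicon: Lexicon,
    gazetteers: RuleGazetteers,
) -> str:
    """Is the match a mention of pain in the medical sense?

    No if the surface is on the exclusion list, or if the token's
    immediate object is an inanimate referent ("burning incense",
    "burn marks on the door").
    """
    if mention.excluded or mention.surface.lower() in lexicon.exclusion_terms:
        return "no"
    toks, idx = _mention_token_index(window)
    for follow, _, _ in toks[idx + 1 : idx + 3]:
        if follow in gazetteers.inanimate_referents:
            return "no"
    return "yes"


def classify_relevance(
    mention: MentionMatch,
    window: ContextWindow,
    gazetteers: RuleGazetteers,
) -> str:
    """Three-way assertion label, rules applied in fixed precedence.

    1. uncertainty: "?" immediately adjacent to the mention token
    2. experiencer: third-person trigger before the mention, same sentence
    3. hypothetical/metaphor trigger anywhere in the window
    4. negation trigger within ``negation_window`` tokens before the
       mention, or the frames "no X reported" / "X free"
    5. otherwise relevant
    """
    before = window.before.rstrip()
    after = window.after.lstrip()
    if before.endswith("?") or after.startswith("?"):
        return "not_relevant"

    toks, idx = _mention_token_index(window)
    low = window.text.lower()
    before_tokens = [t for t, _, _ in toks[:idx]]

    if any(t in gazetteers.experiencer_triggers for t in before_tokens):
        return "not_relevant"

    for trig in gazetteers.hypothetical_triggers:
        if " " in trig:
            if trig in low:
                return "not_relevant"
        elif any(t == trig for t, _, _ in toks):
            return "not_relevant"

    recent = before_tokens[-gazetteers.negation_window:]
    single_neg = {t for t in gazetteers.negation_triggers if " " not in t}
    phrase_neg = [t for t in gazetteers.negation_triggers if " " in t]
    if any(t in single_neg for t in recent):
        return "negated"
    if any(p in low for p in phrase_neg):
        return "negated"
    # frames: "no X reported", "X free"
    after_tokens = [t for t, _, _ in toks[idx + 1 :]]
    if "no" in before_tokens and after_tokens[:2].count("reported"):
        return "negated"
    if after_tokens[:1] == ["free"]:
        return "negated"
    return "relevant"


def detect_anatomy(
    mention: MentionMatch,
    window: ContextWindow,
    gazetteers: RuleGazetteers,
) -> tuple[str, Optional[str]]:
    """Body-part detection: compound surfaces (headache -> head) or an
    anatomy term within ``proximity_window`` tokens of the mention."""
    amap = gazetteers.anatomy_map
    surf = mention.surface.lower()
    if surf in amap:
        return "mentioned", amap[surf]
    toks, idx = _mention_token_index(window)
    k = gazetteers.proximity_window
    near = toks[max(0, idx - k) : idx] + toks[idx + 1 : idx + 1 + k]
    for t, _, _ in near:
        if t in amap:
            return "mentioned", amap[t]
    return NA, None


def classify_character(
    mention: MentionMatch,
    window: ContextWindow,
    gazetteers: RuleGazetteers,
) -> tuple[str, Optional[str]]:
    """Pain character: chronic only on an explicit "chronic" shortly
    before the mention; any other descriptor nearby is "other".

    "Ongoing" is deliberately not chronic, and "period pain" is a
    special case labelled other.
    """
    toks, idx = _mention_token_index(window)
    k = gazetteers.proximity_window
    before = toks[max(0, idx - k) : idx]
    if any(t == "chronic" for t, _, _ in before):
        return "chronic", "chronic"
    near = before + toks[idx + 1 : idx + 1 + k]
    for t, _, _ in near:
        if t in gazetteers.character_descriptors:
            return "other", t
    if before and before[-1][0] == "period":
        return "other", "period"
    return NA, None


def classify_management(
    mention: MentionMatch,
    window: ContextWindow,
    gazetteers: RuleGazetteers,
) -> str:
    """Pain management: medication triggers (including the mention
    surface itself, e.g. "painkillers") beat non-drug measures."""
    low = window.text.lower()
    surf = mention.surface.lower()
    med = gazetteers.management_medication_triggers
    if surf in med:
        return "medication"
    toks = [t for t, _, _ in _tokens_with_spans(window.text)]
    for trig in med:
        if (" " in trig and trig in low) or trig in toks:
            return "medication"
    for trig in gazetteers.management_other_triggers:
        if (" " in trig and trig in low) or trig in toks:
            return "other"
    return NA


def annotate_document(
    doc: Document,
    lexicon: Lexicon,
    gazetteers: Optional[RuleGazetteers] = None,
) -> list[PainAnnotation]:
    """Run the full per-mention pipeline over one document."""
    if gazetteers is None:
        gazetteers = default_gazetteers()
    out: list[PainAnnotation] = []
    if not doc.text:
        return out
    for mention in find_mentions(doc, lexicon):
        window = context_window(doc, mention)
        if classify_correct(mention, window, lexicon, gazetteers) == "no":
            out.append(PainAnnotation(mention=mention, correct="no"))
            continue
        anatomy, location = detect_anatomy(mention, window, gazetteers)
        character, descriptor = classify_character(mention, window, gazetteers)
        out.append(
            PainAnnotation(
                mention=mention,
                correct="yes",
                relevance=classify_relevance(mention, window, gazetteers),
                anatomy=anatomy,
                anatomy_location=location,
                character=character,
                character_surface=descriptor,
                management=classify_management(mention, window, gazetteers),
            )
        )
    return out
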