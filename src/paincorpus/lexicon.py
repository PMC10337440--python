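"""Wildcard pain-term lexicon and mention matching.

Clinical pain mentions are located with a small set of wildcard patterns
(``%pain%``, ``%ache`` ...) generalizing a larger lexicon of pain terms.
A ``%`` placeholder matches zero or more alphabetic characters within a
single token; matching is case-insensitive and anchored at whichever end
carries no wildcard.  Known lexical false positives (``painted``,
``spain`` ...) are flagged at match time and resolved later by the
annotation rules, mirroring a workflow in which over-general patterns are
cleaned up during manual review.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

__all__ = [
    "WildcardPattern",
    "Lexicon",
    "Document",
    "MentionMatch",
    "compile_pattern",
    "tokenize",
    "find_mentions",
    "default_lexicon",
    "verify_coverage",
]

# Tokens are maximal runs of alphabetic characters; digits, hyphens and
# all punctuation are separators.
_TOKEN_RE = re.compile(r"[^\W\d_]+", re.UNICODE)


class PatternError(ValueError):
    """A wildcard pattern that violates the placement rules."""


@dataclass(frozen=True)
class WildcardPattern:
    """A lexicon pattern: at most one leading and one trailing ``%``.

    ``raw`` is the pattern text (e.g. ``"%pain%"``); ``canonical_word``
    is the base pain word it generalizes (e.g. ``"Pain"``).
    """

    raw: str
    canonical_word: str

    def __post_init__(self) -> None:
        if not self.raw:
            raise PatternError("pattern is empty")
        core = self.raw
        if core.startswith("%"):
            core = core[1:]
        if core.endswith("%"):
            core = core[:-1]
        if "%" in core:
            raise PatternError(
                f"pattern {self.raw!r} has an interior '%'; wildcards are "
                "allowed only at the start and end"
            )
        if "%" in self.canonical_word:
            raise PatternError(
                f"canonical word {self.canonical_word!r} must not contain '%'"
            )

    @property
    def literal(self) -> str:
        """The non-wildcard core of the pattern, lowercased."""
        return self.raw.strip("%").lower()


@dataclass(frozen=True)
class Lexicon:
    """Wildcard patterns, literal full terms, and known false positives."""

    patterns: frozenset[WildcardPattern]
    full_terms: frozenset[str]
    exclusion_terms: frozenset[str]

    def __post_init__(self) -> None:
        overlap = self.full_terms & self.exclusion_terms
        if overlap:
            raise ValueError(
                f"full_terms and exclusion_terms overlap: {sorted(overlap)}"
            )
        for term in self.full_terms | self.exclusion_terms:
            if term != term.lower():
                raise ValueError(f"term {term!r} must be lowercase")

    def __len__(self) -> int:
        return len(self.patterns) + len(self.full_terms)


@dataclass(frozen=True)
class Document:
    """One clinical note with minimal metadata."""

    doc_id: str
    patient_id: str = ""
    source_type: str = "Event"
    text: str = ""
    diagnosis_chapter: Optional[str] = None
    demographics: Optional[dict] = None


@dataclass(frozen=True)
class MentionMatch:
    """A lexicon hit: a token span plus the pattern that produced it.

    Offsets are 0-based, half-open; ``doc.text[start:end] == surface``.
    ``excluded`` flags surfaces on the lexicon's false-positive list;
    such matches are still emitted and resolved downstream.
    """

    doc_id: str
    start: int
    end: int
    surface: str
    pattern: str
    canonical_word: str
    excluded: bool = False


def compile_pattern(pattern: WildcardPattern) -> Callable[[str], bool]:
    """Compile a wildcard pattern into a single-token predicate.

    ``%`` matches zero or more alphabetic characters.  A pattern with no
    leading ``%`` is anchored at the token start, one with no trailing
    ``%`` at the token end; matching is case-insensitive.
    """
    parts = []
    raw = pattern.raw
    if raw.startswith("%"):
        parts.append(r"[^\W\d_]*")
        raw = raw[1:]
    trailing = raw.endswith("%")
    if trailing:
        raw = raw[:-1]
    parts.append(re.escape(raw))
    if trailing:
        parts.append(r"[^\W\d_]*")
    rx = re.compile("".join(parts), re.IGNORECASE | re.UNICODE)

    def matches(token: str) -> bool:
        return rx.fullmatch(token) is not None

    return matches


def tokenize(text: str) -> Iterable[re.Match]:
    """Yield regex matches for each alphabetic token in ``text``."""
    return _TOKEN_RE.finditer(text)


def _rank_key(raw: str, literal: str) -> tuple:
    # longest literal part wins; ties broken alphabetically by raw pattern
    return (-len(literal), raw)


def find_mentions(doc: Document, lexicon: Lexicon) -> list[MentionMatch]:
    """Locate every lexicon hit in a document.

    Each alphabetic token is tested against all patterns and full terms;
    when several match, the candidate with the longest literal part wins
    (full terms count their whole length), ties broken alphabetically by
    raw pattern.  Matches are non-overlapping and sorted by start offset.
    """
    if len(lexicon) == 0:
        raise ValueError("lexicon is empty")
    compiled = [
        (pat, compile_pattern(pat), _rank_key(pat.raw, pat.literal))
        for pat in sorted(lexicon.patterns, key=lambda p: p.raw)
    ]
    out: list[MentionMatch] = []
    for tok in tokenize(doc.text):
        token = tok.group(0)
        low = token.lower()
        best: Optional[tuple[tuple, str, str]] = None  # (key, raw, canonical)
        if low in lexicon.full_terms:
            best = (_rank_key(low, low), low, low)
        for pat, pred, key in compiled:
            if pred(token) and (best is None or key < best[0]):
                best = (key, pat.raw, pat.canonical_word)
        if best is not None:
            out.append(
                MentionMatch(
                    doc_id=doc.doc_id,
                    start=tok.start(),
                    end=tok.end(),
                    surface=token,
                    pattern=best[1],
                    canonical_word=best[2],
                    excluded=low in lexicon.exclusion_terms,
                )
            )
    return out


# The shipped wildcard rows: (pattern, canonical pain word).
DEFAULT_PATTERNS: Sequence[tuple[str, str]] = (
    ("%pain%", "Pain"),
    ("%ache", "Ache"),
    ("%aches", "Ache"),
    ("sore%", "Sore"),
    ("%algesi%", "Algesia"),
    ("%algia%", "Algia"),
    ("%burn%", "Burn"),
    ("colic%", "Colic"),
    ("cramp%", "Cramp"),
    ("%dynia%", "Dynia"),
    ("hurt%", "Hurt"),
    ("rheumati%", "Rheumatic"),
    ("sciati%", "Sciatic"),
    ("spasm%", "Spasm"),
    ("tender%", "Tender"),
)

DEFAULT_FULL_TERMS: Sequence[str] = ("mittelschmerz", "lumbago", "migraine")

DEFAULT_EXCLUSION_TERMS: Sequence[str] = (
    "paint",
    "painting",
    "paints",
    "painted",
    "spain",
    "attached",
    "attaches",
)


def default_lexicon() -> Lexicon:
    """The shipped lexicon: 15 wildcard patterns, 3 literal terms, and
    the known false-positive surface forms."""
    return Lexicon(
        patterns=frozenset(
            WildcardPattern(raw, canon) for raw, canon in DEFAULT_PATTERNS
        ),
        full_terms=frozenset(DEFAULT_FULL_TERMS),
        exclusion_terms=frozenset(DEFAULT_EXCLUSION_TERMS),
    )


def verify_coverage(term_list: Sequence[str], lexicon: Lexicon) -> list[str]:
    """Audit a full term list against the wildcard generalization.

    Returns every term (as a single token, lowercased) not matched by any
    pattern or full term, preserving input order, so an externally
    maintained pain lexicon can be checked for gaps.
    """
    if not term_list:
        return []
    preds = [compile_pattern(p) for p in lexicon.patterns]
    uncovered = []
    for term in term_list:
        low = term.lower()
        if low in lexicon.full_terms:
            continue
        if any(pred(low) for pred in preds):
            continue
        uncovered.append(term)
    return uncovered
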