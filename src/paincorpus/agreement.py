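"""Interannotator agreement and adjudication.

Cohen's κ is the chance-corrected agreement between two annotators over
nominal labels:

    κ = (p_o − p_e) / (1 − p_e)

with ``p_o`` the observed agreement fraction and ``p_e`` the chance
agreement expected from the two annotators' marginal label
distributions.  κ is unweighted; all label schemes here are nominal.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from .annotator import PainAnnotation, RuleGazetteers, annotate_document, default_gazetteers
from .lexicon import Document, Lexicon, default_lexicon

__all__ = [
    "KappaUndefinedError",
    "cohens_kappa",
    "AgreementReport",
    "agreement_report",
    "adjudicate",
    "ATTRIBUTES",
]

ATTRIBUTES = ("correct", "relevance", "anatomy", "character", "management")


class KappaUndefinedError(ValueError):
    """Chance agreement is 1 but observed agreement is not perfect."""


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Cohen's κ for two aligned nominal label sequences.

    When chance agreement p_e is exactly 1 (both annotators always use
    the same single category) the ratio is 0/0; perfect agreement then
    returns 1.0, anything else raises :class:`KappaUndefinedError`
    rather than producing a floating-point accident.
    """
    if len(labels_a) != len(labels_b):
        raise ValueError(
            f"label sequences differ in length: {len(labels_a)} vs "
            f"{len(labels_b)}")
    n = len(labels_a)
    if n == 0:
        raise ValueError("label sequences are empty")
    p_o = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    marg_a = Counter(labels_a)
    marg_b = Counter(labels_b)
    p_e = sum(
        (marg_a[c] / n) * (marg_b[c] / n) for c in marg_a.keys() | marg_b.keys()
    )
    if p_e >= 1.0 - 1e-12:
        if p_o >= 1.0:
            return 1.0
        raise KappaUndefinedError(
            "chance agreement is 1 (both annotators degenerate on one "
            "category) but observed agreement is below 1")
    return (p_o - p_e) / (1.0 - p_e)


def _confusion(labels_a: Sequence, labels_b: Sequence) -> dict:
    table: dict = {}
    for a, b in zip(labels_a, labels_b):
        table.setdefault(str(a), {})
        table[str(a)][str(b)] = table[str(a)].get(str(b), 0) + 1
    return table


@dataclass(frozen=True)
class AgreementReport:
    """Per-attribute and overall agreement over a doubly annotated set.

    ``percent_agreement`` and ``kappa`` are keyed by attribute plus
    ``overall_mentions`` (each mention's full label tuple treated as one
    item) and ``overall_labels`` (all attribute labels pooled); κ values
    may be None when undefined (degenerate marginals).
    """

    n_items: int
    percent_agreement: dict
    kappa: dict
    confusion: dict


def _check_alignment(
    ann_a: Sequence[PainAnnotation], ann_b: Sequence[PainAnnotation]
) -> None:
    if len(ann_a) != len(ann_b):
        raise ValueError(
            f"annotation sets differ in size: {len(ann_a)} vs {len(ann_b)}")
    for a, b in zip(ann_a, ann_b):
        ma, mb = a.mention, b.mention
        if (ma.doc_id, ma.start, ma.end) != (mb.doc_id, mb.start, mb.end):
            raise ValueError(
                "annotation sets are misaligned at "
                f"{ma.doc_id}[{ma.start}:{ma.end}] vs "
                f"{mb.doc_id}[{mb.start}:{mb.end}]")


def _safe_kappa(labels_a: Sequence, labels_b: Sequence) -> Optional[float]:
    try:
        return cohens_kappa(labels_a, labels_b)
    except KappaUndefinedError:
        return None


def agreement_report(
    ann_a: Sequence[PainAnnotation], ann_b: Sequence[PainAnnotation]
) -> AgreementReport:
    """Percent agreement, κ, and confusion tables per attribute.

    Annotation sets must be aligned on identical mention spans.  Two
    "overall" figures are emitted because the summary convention is
    ambiguous: agreement over mentions (full label tuple per item) and
    agreement over all pooled labels.
    """
    _check_alignment(ann_a, ann_b)
    n = len(ann_a)
    if n == 0:
        raise ValueError("no annotations to compare")
    pct: dict = {}
    kappa: dict = {}
    confusion: dict = {}
    pooled_a: list = []
    pooled_b: list = []
    for attr in ATTRIBUTES:
        la = [getattr(a, attr) for a in ann_a]
        lb = [getattr(b, attr) for b in ann_b]
        pct[attr] = sum(x == y for x, y in zip(la, lb)) / n
        kappa[attr] = _safe_kappa(la, lb)
        confusion[attr] = _confusion(la, lb)
        pooled_a.extend(la)
        pooled_b.extend(lb)
    tup_a = [tuple(getattr(a, attr) for attr in ATTRIBUTES) for a in ann_a]
    tup_b = [tuple(getattr(b, attr) for attr in ATTRIBUTES) for b in ann_b]
    pct["overall_mentions"] = sum(x == y for x, y in zip(tup_a, tup_b)) / n
    kappa["overall_mentions"] = _safe_kappa(tup_a, tup_b)
    pct["overall_labels"] = sum(
        x == y for x, y in zip(pooled_a, pooled_b)) / len(pooled_a)
    kappa["overall_labels"] = _safe_kappa(pooled_a, pooled_b)
    return AgreementReport(
        n_items=n, percent_agreement=pct, kappa=kappa, confusion=confusion)


def adjudicate(
    ann_a: Sequence[PainAnnotation],
    ann_b: Sequence[PainAnnotation],
    documents: Sequence[Document],
    lexicon: Optional[Lexicon] = None,
    gazetteers: Optional[RuleGazetteers] = None,
) -> tuple[list[PainAnnotation], list[dict]]:
    """Resolve double-annotation disagreements into one final set.

    Where the two annotators agree the shared annotation is kept; where
    they differ, the deterministic guideline rules are re-applied to the
    mention's own context and the rule output is taken (the codified
    guideline is the tie-breaker).  Returns the final annotations and a
    log of every decision made.
    """
    _check_alignment(ann_a, ann_b)
    if lexicon is None:
        lexicon = default_lexicon()
    if gazetteers is None:
        gazetteers = default_gazetteers()
    docs = {d.doc_id: d for d in documents}
    rule_cache: dict = {}
    final: list[PainAnnotation] = []
    log: list[dict] = []
    for a, b in zip(ann_a, ann_b):
        same = all(getattr(a, t) == getattr(b, t) for t in ATTRIBUTES)
        if same:
            final.append(a)
            continue
        doc_id = a.mention.doc_id
        if doc_id not in docs:
            raise ValueError(f"no document with id {doc_id!r} supplied")
        if doc_id not in rule_cache:
            rule_cache[doc_id] = {
                (x.mention.start, x.mention.end): x
                for x in annotate_document(docs[doc_id], lexicon, gazetteers)
            }
        ruled = rule_cache[doc_id].get((a.mention.start, a.mention.end))
        chosen = ruled if ruled is not None else a
        final.append(chosen)
        log.append({
            "doc_id": doc_id,
            "start": a.mention.start,
            "end": a.mention.end,
            "annotator_a": {t: getattr(a, t) for t in ATTRIBUTES},
            "annotator_b": {t: getattr(b, t) for t in ATTRIBUTES},
            "resolved": {t: getattr(chosen, t) for t in ATTRIBUTES},
            "source": "guideline_rules" if ruled is not None else "annotator_a",
        })
    return final, log
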