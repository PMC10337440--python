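"""Descriptive summaries of an annotated pain-mention corpus.

Produces the standard corpus tables: totals, per-document and
per-patient annotation statistics, words/characters per document, the
relevance distribution, anatomy rate among relevant mentions, ranked
anatomical locations, character and management distributions, the
diagnosis-chapter breakdown, and the most frequent matched surface
forms.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .annotator import NA, PainAnnotation
from .lexicon import Document, tokenize

__all__ = ["CorpusSummary", "summarize", "rank_locations"]


@dataclass(frozen=True)
class CorpusSummary:
    n_patients: int
    n_documents: int
    n_annotations: int
    annotations_per_document: dict  # mean/min/max, None when empty
    annotations_per_patient: dict
    words_per_document: Optional[float]
    characters_per_document: Optional[float]
    relevance_counts: dict
    relevance_fractions: dict
    n_correct: int
    anatomy_mentioned_among_relevant: int
    anatomy_rate_among_relevant: Optional[float]
    location_ranking: list  # (location, count), descending
    character_counts: dict
    management_counts: dict
    diagnosis_counts: dict
    top_concepts: list  # (lowercased surface, count), descending

    def as_dict(self) -> dict:
        percent = {
            k: round(100.0 * v) for k, v in self.relevance_fractions.items()
        }
        return {
            "totals": {
                "patients": self.n_patients,
                "documents": self.n_documents,
                "annotations": self.n_annotations,
            },
            "annotations_per_document": self.annotations_per_document,
            "annotations_per_patient": self.annotations_per_patient,
            "words_per_document_mean": self.words_per_document,
            "characters_per_document_mean": self.characters_per_document,
            "relevance": {
                "counts": self.relevance_counts,
                "fractions": self.relevance_fractions,
                "percent": percent,
            },
            "anatomy": {
                "mentioned_among_relevant":
                    self.anatomy_mentioned_among_relevant,
                "rate_among_relevant": self.anatomy_rate_among_relevant,
            },
            "locations": [list(t) for t in self.location_ranking],
            "character_counts": self.character_counts,
            "management_counts": self.management_counts,
            "diagnosis_counts": self.diagnosis_counts,
            "top_concepts": [list(t) for t in self.top_concepts],
        }


def _stats(values: Sequence[int]) -> dict:
    if not values:
        return {"mean": None, "min": None, "max": None}
    return {
        "mean": sum(values) / len(values),
        "min": min(values),
        "max": max(values),
    }


def rank_locations(annotations: Sequence[PainAnnotation]) -> list[tuple[str, int]]:
    """Anatomical locations by descending count, ties alphabetical.

    Only annotations with anatomy mentioned contribute.
    """
    counts = Counter(
        a.anatomy_location
        for a in annotations
        if a.anatomy == "mentioned" and a.anatomy_location is not None
    )
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def summarize(
    documents: Sequence[Document], annotations: Sequence[PainAnnotation]
) -> CorpusSummary:
    """Compute every corpus-level summary figure from the inputs.

    Word count is the number of alphabetic tokens; character count is
    the raw text length.  Empty inputs yield zero counts with means
    reported as absent (None), never NaN.
    """
    doc_ids = {d.doc_id for d in documents}
    dangling = sorted(
        {a.mention.doc_id for a in annotations} - doc_ids)
    if dangling:
        raise ValueError(
            f"annotations reference unknown documents: {dangling[:5]}")

    per_doc = Counter(a.mention.doc_id for a in annotations)
    doc_patient = {d.doc_id: d.patient_id for d in documents}
    per_patient: Counter = Counter()
    for doc_id, k in per_doc.items():
        per_patient[doc_patient[doc_id]] += k

    correct = [a for a in annotations if a.correct == "yes"]
    relevance_counts = Counter(a.relevance for a in correct)
    n_correct = len(correct)
    relevance_fractions = {
        k: v / n_correct for k, v in relevance_counts.items()
    } if n_correct else {}

    relevant = [a for a in correct if a.relevance == "relevant"]
    anat_mentioned = sum(1 for a in relevant if a.anatomy == "mentioned")

    words = None
    chars = None
    if documents:
        words = sum(
            sum(1 for _ in tokenize(d.text)) for d in documents
        ) / len(documents)
        chars = sum(len(d.text) for d in documents) / len(documents)

    # annotations per diagnosis chapter (chapter is document metadata)
    diag: Counter = Counter()
    for d in documents:
        if d.diagnosis_chapter is not None and per_doc[d.doc_id]:
            diag[d.diagnosis_chapter] += per_doc[d.doc_id]

    surfaces = Counter(a.mention.surface.lower() for a in annotations)

    return CorpusSummary(
        n_patients=len({d.patient_id for d in documents}),
        n_documents=len(documents),
        n_annotations=len(annotations),
        annotations_per_document=_stats(
            [per_doc[d] for d in per_doc] if per_doc else []),
        annotations_per_patient=_stats(list(per_patient.values())),
        words_per_document=words,
        characters_per_document=chars,
        relevance_counts=dict(relevance_counts),
        relevance_fractions=relevance_fractions,
        n_correct=n_correct,
        anatomy_mentioned_among_relevant=anat_mentioned,
        anatomy_rate_among_relevant=(
            anat_mentioned / len(relevant) if relevant else None),
        location_ranking=rank_locations(annotations),
        character_counts=dict(Counter(a.character for a in correct)),
        management_counts=dict(Counter(a.management for a in correct)),
        diagnosis_counts=dict(diag),
        top_concepts=sorted(
            surfaces.items(), key=lambda kv: (-kv[1], kv[0]))[:20],
    )
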