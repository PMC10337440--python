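"""Readers and writers for documents, annotations, and rule configs.

Formats:

* **Documents** — a directory of UTF-8 ``.txt`` files (file stem is the
  doc_id), a delimited table (CSV/TSV) with columns ``doc_id``,
  ``patient_id``, ``source_type``, ``text`` (+ optional metadata), or
  JSON-lines with the same keys.  Newlines are normalized to ``"\\n"``
  on read; character offsets everywhere refer to the normalized text.
* **Annotations** — standoff JSON-lines, one object per annotation with
  the span, surface, and the five labels, carrying an explicit
  ``schema_version``.  Round-trips losslessly.
* **Lexicon / gazetteer configs** — a sectioned plain-text dialect:
  ``[section]`` headers, one entry per line, ``#`` comments.  Lexicon
  sections are ``patterns`` (``raw<TAB>canonical_word``),
  ``full_terms`` and ``exclusions``; gazetteer sections are one per
  rule family, with ``anatomy_map`` lines ``surface<TAB>location``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .annotator import PainAnnotation, RuleGazetteers, default_gazetteers
from .lexicon import Document, Lexicon, MentionMatch, WildcardPattern

__all__ = [
    "SCHEMA_VERSION",
    "read_documents",
    "write_documents_jsonl",
    "read_annotations",
    "write_annotations",
    "read_lexicon_config",
    "write_lexicon_config",
    "read_gazetteer_config",
    "write_gazetteer_config",
]

SCHEMA_VERSION = "1"

_DOC_FORMATS = ("plain-dir", "delimited", "json-lines")
_REQUIRED_COLUMNS = ("doc_id", "text")
_OPTIONAL_COLUMNS = ("patient_id", "source_type", "diagnosis_chapter")


def _normalize(text: str) -> str:
    return text.replace("\r\n", "\n").replace("\r", "\n")


def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "plain-dir"
    suffix = path.suffix.lower()
    if suffix in (".jsonl", ".ndjson"):
        return "json-lines"
    if suffix in (".csv", ".tsv", ".txt"):
        return "delimited"
    raise ValueError(
        f"cannot infer document format from {path}; pass format explicitly")


def _doc_from_record(rec: dict, where: str) -> Document:
    missing = [c for c in _REQUIRED_COLUMNS if rec.get(c) in (None, "")]
    if missing:
        raise ValueError(f"{where}: missing required field(s) {missing}")
    return Document(
        doc_id=str(rec["doc_id"]),
        patient_id=str(rec.get("patient_id") or ""),
        source_type=str(rec.get("source_type") or "Event"),
        text=_normalize(str(rec["text"])),
        diagnosis_chapter=(
            str(rec["diagnosis_chapter"])
            if rec.get("diagnosis_chapter") not in (None, "") else None),
        demographics=rec.get("demographics") or None,
    )


def read_documents(
    path: Union[str, Path], format: Optional[str] = None
) -> list[Document]:
    """Read a document collection; stable lexicographic doc_id order."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _DOC_FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_DOC_FORMATS}")
    docs: list[Document] = []
    if fmt == "plain-dir":
        if not path.is_dir():
            raise ValueError(f"{path} is not a directory")
        for f in sorted(path.glob("*.txt")):
            try:
                text = f.read_text(encoding="utf-8")
            except UnicodeDecodeError as exc:
                raise ValueError(f"{f}: undecodable bytes: {exc}") from exc
            docs.append(Document(doc_id=f.stem, text=_normalize(text)))
    elif fmt == "delimited":
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing}")
        for i, rec in enumerate(frame.to_dict("records")):
            docs.append(_doc_from_record(rec, f"{path} row {i + 1}"))
    else:
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ValueError(
                        f"{path} line {lineno}: invalid JSON: {exc}") from exc
                docs.append(_doc_from_record(rec, f"{path} line {lineno}"))
    seen: dict[str, int] = {}
    for d in docs:
        seen[d.doc_id] = seen.get(d.doc_id, 0) + 1
    dupes = sorted(k for k, v in seen.items() if v > 1)
    if dupes:
        raise ValueError(f"duplicate doc_id(s): {dupes[:5]}")
    return sorted(docs, key=lambda d: d.doc_id)


def write_documents_jsonl(
    documents: Sequence[Document], path: Union[str, Path]
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in documents:
            fh.write(json.dumps({
                "doc_id": d.doc_id,
                "patient_id": d.patient_id,
                "source_type": d.source_type,
                "text": d.text,
                "diagnosis_chapter": d.diagnosis_chapter,
                "demographics": d.demographics,
            }, ensure_ascii=False) + "\n")


def write_annotations(
    annotations: Sequence[PainAnnotation], path: Union[str, Path]
) -> None:
    """Write standoff JSON-lines (schema_version included per record)."""
    with open(path, "w", encoding="utf-8") as fh:
        for a in annotations:
            m = a.mention
            fh.write(json.dumps({
                "schema_version": SCHEMA_VERSION,
                "doc_id": m.doc_id,
                "start": m.start,
                "end": m.end,
                "surface": m.surface,
                "pattern": m.pattern,
                "canonical_word": m.canonical_word,
                "excluded": m.excluded,
                "correct": a.correct,
                "relevance": a.relevance,
                "anatomy": a.anatomy,
                "anatomy_location": a.anatomy_location,
                "character": a.character,
                "character_surface": a.character_surface,
                "management": a.management,
            }, ensure_ascii=False) + "\n")


def read_annotations(path: Union[str, Path]) -> list[PainAnnotation]:
    out: list[PainAnnotation] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(
                    f"{path} line {lineno}: invalid JSON: {exc}") from exc
            version = rec.get("schema_version")
            if version != SCHEMA_VERSION:
                raise ValueError(
                    f"{path} line {lineno}: unsupported schema_version "
                    f"{version!r} (expected {SCHEMA_VERSION!r})")
            out.append(PainAnnotation(
                mention=MentionMatch(
                    doc_id=rec["doc_id"],
                    start=int(rec["start"]),
                    end=int(rec["end"]),
                    surface=rec["surface"],
                    pattern=rec.get("pattern", ""),
                    canonical_word=rec.get("canonical_word", ""),
                    excluded=bool(rec.get("excluded", False)),
                ),
                correct=rec["correct"],
                relevance=rec["relevance"],
                anatomy=rec["anatomy"],
                anatomy_location=rec.get("anatomy_location"),
                character=rec["character"],
                character_surface=rec.get("character_surface"),
                management=rec["management"],
            ))
    return out


# ---------------------------------------------------------------------------
# sectioned plain-text configs


def _parse_sections(path: Path) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current: Optional[str] = None
    for lineno, line in enumerate(
            path.read_text(encoding="utf-8").splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if stripped.startswith("[") and stripped.endswith("]"):
            current = stripped[1:-1].strip()
            sections.setdefault(current, [])
            continue
        if current is None:
            raise ValueError(
                f"{path} line {lineno}: entry before any [section] header")
        sections[current].append(stripped)
    return sections


def read_lexicon_config(path: Union[str, Path]) -> Lexicon:
    sections = _parse_sections(Path(path))
    patterns = set()
    for entry in sections.get("patterns", []):
        parts = entry.split("\t") if "\t" in entry else entry.split(None, 1)
        if len(parts) != 2:
            raise ValueError(
                f"pattern entry {entry!r} must be 'raw<TAB>canonical_word'")
        patterns.add(WildcardPattern(raw=parts[0], canonical_word=parts[1]))
    return Lexicon(
        patterns=frozenset(patterns),
        full_terms=frozenset(sections.get("full_terms", [])),
        exclusion_terms=frozenset(sections.get("exclusions", [])),
    )


def write_lexicon_config(lexicon: Lexicon, path: Union[str, Path]) -> None:
    lines = ["[patterns]"]
    for p in sorted(lexicon.patterns, key=lambda p: p.raw):
        lines.append(f"{p.raw}\t{p.canonical_word}")
    lines.append("[full_terms]")
    lines.extend(sorted(lexicon.full_terms))
    lines.append("[exclusions]")
    lines.extend(sorted(lexicon.exclusion_terms))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


_GAZ_SET_SECTIONS = {
    "negation_triggers", "experiencer_triggers", "hypothetical_triggers",
    "character_descriptors", "management_medication_triggers",
    "management_other_triggers", "inanimate_referents",
}


def read_gazetteer_config(path: Union[str, Path]) -> RuleGazetteers:
    sections = _parse_sections(Path(path))
    base = default_gazetteers()
    kwargs: dict = {}
    for name in _GAZ_SET_SECTIONS:
        if name in sections:
            kwargs[name] = frozenset(t.lower() for t in sections[name])
        else:
            kwargs[name] = getattr(base, name)
    if "anatomy_map" in sections:
        amap = {}
        for entry in sections["anatomy_map"]:
            parts = entry.split("\t") if "\t" in entry else entry.split(None, 1)
            if len(parts) != 2:
                raise ValueError(
                    f"anatomy_map entry {entry!r} must be "
                    "'surface<TAB>location'")
            amap[parts[0].lower()] = parts[1].lower()
        kwargs["anatomy_map"] = amap
    else:
        kwargs["anatomy_map"] = base.anatomy_map
    for name in ("negation_window", "proximity_window"):
        if name in sections:
            kwargs[name] = int(sections[name][0])
        else:
            kwargs[name] = getattr(base, name)
    return RuleGazetteers(**kwargs)


def write_gazetteer_config(gaz: RuleGazetteers, path: Union[str, Path]) -> None:
    lines: list[str] = []
    for name in sorted(_GAZ_SET_SECTIONS):
        lines.append(f"[{name}]")
        lines.extend(sorted(getattr(gaz, name)))
    lines.append("[anatomy_map]")
    for surface in sorted(gaz.anatomy_map):
        lines.append(f"{surface}\t{gaz.anatomy_map[surface]}")
    lines.append("[negation_window]")
    lines.append(str(gaz.negation_window))
    lines.append("[proximity_window]")
    lines.append(str(gaz.proximity_window))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
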