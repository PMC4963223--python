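"""Disease–symptom knowledge base: loading, validation, serialisation.

The store is bipartite: each rare disease is associated with the set of
phenotypic symptoms reported for it, and every symptom referenced by a
disease must exist in the symptom vocabulary. Associations are unweighted
(the ranking score is frequency-blind), and a disease's symptom collection
has set semantics — duplicate associations are collapsed.

Two on-disk dialects are supported:

* **TSV** (canonical): UTF-8, header
  ``disease_id<TAB>disease_name<TAB>symptom_id<TAB>symptom_name``,
  one association per row, no quoting, no embedded tabs.
* **JSON**: an object with ``symptoms`` (list of ``{id, name}``) and
  ``diseases`` (list of ``{id, name, symptom_ids}``).

Writing sorts rows by ``(disease_id, symptom_id)`` so output is
byte-stable across runs and platforms.
"""

from __future__ import annotations

import csv
import hashlib
import io
import json
import warnings
from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Iterable

__all__ = [
    "Symptom",
    "DiseaseEntry",
    "KnowledgeBase",
    "ValidationReport",
    "KBFormatError",
    "load_kb",
    "write_kb",
    "validate_kb",
]

TSV_HEADER = ("disease_id", "disease_name", "symptom_id", "symptom_name")


class KBFormatError(ValueError):
    """Raised when an on-disk knowledge base does not conform to its dialect."""


@dataclass(frozen=True, order=True)
class Symptom:
    """A phenotypic finding in the vocabulary (opaque id + display name)."""

    id: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("symptom id must be non-empty")


@dataclass(frozen=True)
class DiseaseEntry:
    """A rare disease and the set of symptom ids associated with it.

    ``len(entry.symptoms)`` is the disease's stored symptom count, the
    S_Disease term of the diagnostic score.
    """

    id: str
    name: str = ""
    symptoms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("disease id must be non-empty")
        object.__setattr__(self, "symptoms", frozenset(self.symptoms))

    @property
    def size(self) -> int:
        return len(self.symptoms)


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of :func:`validate_kb`; empty tuples everywhere means clean."""

    empty_symptom_sets: tuple[str, ...] = ()
    dangling_references: tuple[tuple[str, str], ...] = ()
    duplicate_set_pairs: tuple[tuple[str, str], ...] = ()

    @property
    def is_clean(self) -> bool:
        return not (
            self.empty_symptom_sets
            or self.dangling_references
            or self.duplicate_set_pairs
        )


@dataclass(frozen=True)
class KnowledgeBase:
    """In-memory disease–symptom association store.

    Diseases and the vocabulary are kept sorted by id, so two knowledge
    bases built from the same associations in any order compare equal.
    """

    diseases: tuple[DiseaseEntry, ...]
    vocabulary: tuple[Symptom, ...]

    def __post_init__(self) -> None:
        diseases = tuple(sorted(self.diseases, key=lambda d: d.id))
        vocabulary = tuple(sorted(self.vocabulary, key=lambda s: s.id))
        ids = [d.id for d in diseases]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate disease ids: {dupes}")
        sids = [s.id for s in vocabulary]
        if len(set(sids)) != len(sids):
            dupes = sorted({i for i in sids if sids.count(i) > 1})
            raise ValueError(f"duplicate symptom ids: {dupes}")
        object.__setattr__(self, "diseases", diseases)
        object.__setattr__(self, "vocabulary", vocabulary)

    # -- convenience accessors -------------------------------------------

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)

    @property
    def n_symptoms(self) -> int:
        return len(self.vocabulary)

    @cached_property
    def symptom_ids(self) -> frozenset[str]:
        return frozenset(s.id for s in self.vocabulary)

    @cached_property
    def sorted_symptom_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.vocabulary)  # vocabulary is id-sorted

    @cached_property
    def _disease_index(self) -> dict[str, DiseaseEntry]:
        return {d.id: d for d in self.diseases}

    @cached_property
    def _symptom_index(self) -> dict[str, Symptom]:
        return {s.id: s for s in self.vocabulary}

    def disease(self, disease_id: str) -> DiseaseEntry:
        return self._disease_index[disease_id]

    def symptom(self, symptom_id: str) -> Symptom:
        return self._symptom_index[symptom_id]

    def resolve_symptom_name(self, name: str) -> tuple[str, ...]:
        """Return ids of vocabulary symptoms whose name matches ``name``
        case-insensitively (exact match only, no fuzzy search)."""
        needle = name.casefold()
        return tuple(s.id for s in self.vocabulary if s.name.casefold() == needle)

    def checksum(self) -> str:
        """SHA-256 of the canonical TSV serialisation (metadata fingerprint)."""
        buf = io.StringIO()
        _write_tsv(self, buf)
        return hashlib.sha256(buf.getvalue().encode("utf-8")).hexdigest()


def validate_kb(kb: KnowledgeBase) -> ValidationReport:
    """Report structural problems without modifying the knowledge base.

    Flags diseases with empty symptom sets, symptom ids referenced by a
    disease but absent from the vocabulary, and pairs of diseases whose
    symptom sets are identical (identical sets break the guarantee that a
    noise-free query recovers its disease uniquely).
    """
    empty = tuple(d.id for d in kb.diseases if not d.symptoms)
    vocab = kb.symptom_ids
    dangling = tuple(
        (d.id, sid)
        for d in kb.diseases
        for sid in sorted(d.symptoms - vocab)
    )
    by_set: dict[frozenset[str], list[str]] = {}
    for d in kb.diseases:
        by_set.setdefault(d.symptoms, []).append(d.id)
    dupes: list[tuple[str, str]] = []
    for members in by_set.values():
        if len(members) > 1:
            members = sorted(members)
            dupes.extend(
                (a, b) for i, a in enumerate(members) for b in members[i + 1 :]
            )
    return ValidationReport(empty, dangling, tuple(sorted(dupes)))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("tsv", "json"):
            raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'json'")
        return format
    suffix = path.suffix.lower()
    if suffix in (".tsv", ".txt"):
        return "tsv"
    if suffix == ".json":
        return "json"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def load_kb(path: str | Path, format: str | None = None) -> KnowledgeBase:
    """Load a knowledge base from a TSV or JSON file.

    Duplicate (disease, symptom) associations are collapsed with a warning;
    malformed rows raise :class:`KBFormatError` naming the line number.
    Association order in the file never affects the result.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    text = path.read_text(encoding="utf-8")
    if fmt == "tsv":
        kb = _parse_tsv(text, str(path))
    else:
        kb = _parse_json(text, str(path))
    report = validate_kb(kb)
    if report.dangling_references:
        raise KBFormatError(
            f"{path}: diseases reference unknown symptom ids: "
            f"{report.dangling_references[:5]}"
        )
    if report.empty_symptom_sets:
        raise KBFormatError(
            f"{path}: diseases with no symptoms: {report.empty_symptom_sets[:5]}"
        )
    return kb


def _parse_tsv(text: str, source: str) -> KnowledgeBase:
    reader = csv.reader(io.StringIO(text), delimiter="\t")
    try:
        header = next(reader)
    except StopIteration:
        raise KBFormatError(f"{source}: empty file") from None
    if tuple(header) != TSV_HEADER:
        raise KBFormatError(
            f"{source}: line 1: bad header {header!r}; expected {list(TSV_HEADER)}"
        )
    disease_names: dict[str, str] = {}
    symptom_names: dict[str, str] = {}
    assoc: dict[str, set[str]] = {}
    n_rows = 0
    for lineno, row in enumerate(reader, start=2):
        if not row:
            continue
        if len(row) != 4:
            raise KBFormatError(
                f"{source}: line {lineno}: expected 4 tab-separated fields, got {len(row)}"
            )
        did, dname, sid, sname = row
        if not did or not sid:
            raise KBFormatError(f"{source}: line {lineno}: empty disease or symptom id")
        for store, key, value, what in (
            (disease_names, did, dname, "disease"),
            (symptom_names, sid, sname, "symptom"),
        ):
            if store.setdefault(key, value) != value:
                raise KBFormatError(
                    f"{source}: line {lineno}: conflicting names for {what} {key!r}"
                )
        if sid in assoc.setdefault(did, set()):
            warnings.warn(
                f"{source}: line {lineno}: duplicate association ({did}, {sid}); "
                "keeping one",
                stacklevel=3,
            )
        assoc[did].add(sid)
        n_rows += 1
    if n_rows == 0:
        raise KBFormatError(f"{source}: no association rows")
    return KnowledgeBase(
        diseases=tuple(
            DiseaseEntry(did, disease_names[did], frozenset(symptoms))
            for did, symptoms in assoc.items()
        ),
        vocabulary=tuple(Symptom(sid, name) for sid, name in symptom_names.items()),
    )


def _parse_json(text: str, source: str) -> KnowledgeBase:
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise KBFormatError(f"{source}: line {exc.lineno}: {exc.msg}") from exc
    if not isinstance(obj, dict) or "symptoms" not in obj or "diseases" not in obj:
        raise KBFormatError(f"{source}: expected object with 'symptoms' and 'diseases'")
    vocabulary = []
    for i, rec in enumerate(obj["symptoms"]):
        try:
            vocabulary.append(Symptom(rec["id"], rec.get("name", "")))
        except (TypeError, KeyError, ValueError) as exc:
            raise KBFormatError(f"{source}: symptoms[{i}]: {exc}") from exc
    diseases = []
    for i, rec in enumerate(obj["diseases"]):
        try:
            ids = list(rec["symptom_ids"])
        except (TypeError, KeyError) as exc:
            raise KBFormatError(f"{source}: diseases[{i}]: {exc}") from exc
        if len(set(ids)) != len(ids):
            warnings.warn(
                f"{source}: diseases[{i}] ({rec.get('id')!r}): duplicate symptom ids "
                "collapsed",
                stacklevel=3,
            )
        try:
            diseases.append(DiseaseEntry(rec["id"], rec.get("name", ""), frozenset(ids)))
        except (TypeError, KeyError, ValueError) as exc:
            raise KBFormatError(f"{source}: diseases[{i}]: {exc}") from exc
    if not diseases:
        raise KBFormatError(f"{source}: no diseases")
    return KnowledgeBase(diseases=tuple(diseases), vocabulary=tuple(vocabulary))


def write_kb(kb: KnowledgeBase, path: str | Path, format: str | None = None) -> None:
    """Serialise a knowledge base; refuses structurally invalid stores.

    The TSV rows (and all JSON lists) are id-sorted, so the output is
    byte-identical across runs and re-loads to an equal knowledge base.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    report = validate_kb(kb)
    if report.empty_symptom_sets or report.dangling_references:
        raise ValueError(
            "refusing to write invalid knowledge base: "
            f"empty sets {report.empty_symptom_sets[:5]}, "
            f"dangling {report.dangling_references[:5]}"
        )
    with path.open("w", encoding="utf-8", newline="") as fh:
        if fmt == "tsv":
            _write_tsv(kb, fh)
        else:
            _write_json(kb, fh)


def _write_tsv(kb: KnowledgeBase, fh) -> None:
    writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
    writer.writerow(TSV_HEADER)
    symptom_name = {s.id: s.name for s in kb.vocabulary}
    for d in kb.diseases:  # already sorted by id
        for sid in sorted(d.symptoms):
            writer.writerow((d.id, d.name, sid, symptom_name[sid]))


def _write_json(kb: KnowledgeBase, fh) -> None:
    obj = {
        "symptoms": [{"id": s.id, "name": s.name} for s in kb.vocabulary],
        "diseases": [
            {"id": d.id, "name": d.name, "symptom_ids": sorted(d.symptoms)}
            for d in kb.diseases
        ],
    }
    json.dump(obj, fh, indent=1, sort_keys=True)
    fh.write("\n")
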