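"""Readers and writers for every external format the toolkit touches.

Formats
-------
* PubAnnotation JSON (``text`` / ``denotations`` / ``relations`` dialect)
* tab-separated document tables (one abstract per line, authors joined
  with ``|``)
* tab-separated lexicon tables (term, entity identifier)
* tab-separated relation tables (entity_a, entity_b[, label, provenance])
* tab-separated rating tables (user_id, item_id, rating)

All I/O is UTF-8.  Tables are parsed with the stdlib ``csv`` module so
that validation errors can name the offending line; relation graphs are
returned as :class:`networkx.Graph`.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable

import networkx as nx

from .errors import FormatError, ValidationError
from .types import (
    Document,
    EntityAnnotation,
    Lexicon,
    RatingsDataset,
    RatingTriple,
    RelationRecord,
)

logger = logging.getLogger("litrec")

AUTHOR_SEP = "|"


# ---------------------------------------------------------------------------
# PubAnnotation JSON
# ---------------------------------------------------------------------------

def read_pubannotation(
    path: str | Path,
) -> tuple[Document, list[EntityAnnotation], list[RelationRecord]]:
    """Read one PubAnnotation JSON document.

    The document id is taken from ``sourceid`` when present, otherwise
    from the file stem.  Denotation spans are validated against ``text``;
    relations are resolved from denotation ids to entity identifiers.
    """
    path = Path(path)
    try:
        with path.open(encoding="utf-8") as fh:
            obj = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: malformed JSON: {exc}") from exc
    if not isinstance(obj, dict) or "text" not in obj:
        raise FormatError(f"{path}: PubAnnotation object requires a 'text' key")
    text = obj["text"]
    doc = Document(
        doc_id=str(obj.get("sourceid") or path.stem),
        title=obj.get("title", ""),
        abstract=text,
        language=obj.get("language", "en"),
        authors=tuple(obj.get("authors", ())),
        source=obj.get("sourcedb", ""),
    )

    annotations: list[EntityAnnotation] = []
    denotation_entity: dict[str, str] = {}
    for den in obj.get("denotations", []):
        den_id = str(den.get("id", "?"))
        span = den.get("span", {})
        begin, end = span.get("begin"), span.get("end")
        if (
            not isinstance(begin, int)
            or not isinstance(end, int)
            or begin < 0
            or begin >= end
            or end > len(text)
        ):
            raise ValidationError(
                f"{path}: denotation {den_id!r} has invalid span "
                f"({begin}, {end}) for text of length {len(text)}"
            )
        entity_id = den.get("obj")
        if not entity_id:
            raise ValidationError(
                f"{path}: denotation {den_id!r} has no 'obj' identifier"
            )
        annotations.append(
            EntityAnnotation(
                doc_id=doc.doc_id,
                begin=begin,
                end=end,
                surface=text[begin:end],
                entity_id=str(entity_id),
            )
        )
        denotation_entity[den_id] = str(entity_id)

    relations: list[RelationRecord] = []
    for rel in obj.get("relations", []):
        rel_id = str(rel.get("id", "?"))
        subj, robj = rel.get("subj"), rel.get("obj")
        if subj not in denotation_entity or robj not in denotation_entity:
            raise ValidationError(
                f"{path}: relation {rel_id!r} references unknown denotation "
                f"id ({subj!r} or {robj!r})"
            )
        ea, eb = denotation_entity[subj], denotation_entity[robj]
        if ea == eb:
            logger.warning(
                "%s: relation %s links an entity to itself (%s); dropped",
                path, rel_id, ea,
            )
            continue
        relations.append(
            RelationRecord(
                entity_a=ea,
                entity_b=eb,
                label=rel.get("pred"),
                provenance_doc=doc.doc_id,
            )
        )
    return doc, annotations, relations


def write_pubannotation(
    doc: Document,
    annotations: Iterable[EntityAnnotation],
    relations: Iterable[RelationRecord],
    path: str | Path,
) -> None:
    """Write one PubAnnotation JSON document.

    Denotation ids are ``T1``, ``T2``, ... in span order; relation ids
    ``R1``, ... referencing the first denotation of each endpoint entity.
    Refuses to write when an annotation violates its invariants against
    the document's abstract.
    """
    path = Path(path)
    annotations = sorted(
        annotations, key=lambda a: (a.begin, a.end, a.entity_id)
    )
    for ann in annotations:
        ann.validate_against(doc.abstract)
        if ann.doc_id and ann.doc_id != doc.doc_id:
            raise ValidationError(
                f"annotation for document {ann.doc_id!r} cannot be written "
                f"into document {doc.doc_id!r}"
            )

    denotations = []
    first_tid: dict[str, str] = {}
    for i, ann in enumerate(annotations, start=1):
        tid = f"T{i}"
        denotations.append(
            {
                "id": tid,
                "span": {"begin": ann.begin, "end": ann.end},
                "obj": ann.entity_id,
            }
        )
        first_tid.setdefault(ann.entity_id, tid)

    rel_objs = []
    for j, rel in enumerate(relations, start=1):
        try:
            subj, robj = first_tid[rel.entity_a], first_tid[rel.entity_b]
        except KeyError as exc:
            raise ValidationError(
                f"relation ({rel.entity_a!r}, {rel.entity_b!r}) references "
                f"entity {exc.args[0]!r} with no denotation in "
                f"document {doc.doc_id!r}"
            ) from None
        rel_objs.append(
            {
                "id": f"R{j}",
                "subj": subj,
                "pred": rel.label or "related_to",
                "obj": robj,
            }
        )

    obj = {
        "sourcedb": doc.source or "litrec",
        "sourceid": doc.doc_id,
        "text": doc.abstract,
        "title": doc.title,
        "language": doc.language,
        "authors": list(doc.authors),
        "denotations": denotations,
        "relations": rel_objs,
    }
    with path.open("w", encoding="utf-8") as fh:
        json.dump(obj, fh, ensure_ascii=False, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Document tables
# ---------------------------------------------------------------------------

_DOC_COLUMNS = ("doc_id", "title", "abstract", "language", "authors")


def read_documents(path: str | Path) -> list[Document]:
    """Read a tab-separated document table (one abstract per line).

    Required columns: doc_id, title, abstract, language, authors (authors
    joined with ``|``); an optional ``source`` column is honoured.
    Duplicate doc_ids are an error naming the offending lines.
    """
    path = Path(path)
    docs: list[Document] = []
    seen: dict[str, list[int]] = {}
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty document table")
        missing = [c for c in _DOC_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(
                f"{path}: document table is missing column(s) "
                f"{', '.join(missing)}"
            )
        for row in reader:
            line = reader.line_num
            for col in _DOC_COLUMNS:
                if row.get(col) is None:
                    raise FormatError(
                        f"{path}: line {line}: missing field {col!r}"
                    )
            if not row["doc_id"]:
                raise FormatError(f"{path}: line {line}: empty doc_id")
            authors_field = row["authors"].strip()
            authors = (
                tuple(a for a in authors_field.split(AUTHOR_SEP) if a)
                if authors_field
                else ()
            )
            if not authors:
                logger.warning(
                    "%s: line %d: document %r has no authors and will "
                    "contribute no ratings", path, line, row["doc_id"],
                )
            seen.setdefault(row["doc_id"], []).append(line)
            docs.append(
                Document(
                    doc_id=row["doc_id"],
                    title=row["title"],
                    abstract=row["abstract"],
                    language=row["language"],
                    authors=authors,
                    source=row.get("source", "") or "",
                )
            )
    dupes = {d: lines for d, lines in seen.items() if len(lines) > 1}
    if dupes:
        detail = "; ".join(
            f"{d!r} on lines {', '.join(map(str, lines))}"
            for d, lines in sorted(dupes.items())
        )
        raise ValidationError(f"{path}: duplicate doc_id(s): {detail}")
    return docs


def write_documents(docs: Iterable[Document], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_DOC_COLUMNS + ("source",))
        for doc in docs:
            writer.writerow(
                (
                    doc.doc_id,
                    doc.title,
                    doc.abstract,
                    doc.language,
                    AUTHOR_SEP.join(doc.authors),
                    doc.source,
                )
            )


# ---------------------------------------------------------------------------
# Lexicon tables
# ---------------------------------------------------------------------------

def load_lexicon(path: str | Path, ontology_tag: str = "") -> Lexicon:
    """Read a two-column (term, entity_id) tab-separated lexicon.

    A term may map to multiple identifiers (one row each).  Terms are
    stripped of surrounding whitespace; empty terms are dropped with a
    logged count.
    """
    path = Path(path)
    terms: dict[str, set[str]] = {}
    n_rows = 0
    n_dropped = 0
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is not None and len(header) < 2:
            raise FormatError(
                f"{path}: lexicon table requires at least 2 columns "
                f"(term, entity_id), found {len(header)}"
            )
        for row in reader:
            if not row:
                continue
            if len(row) < 2:
                raise FormatError(
                    f"{path}: line {reader.line_num}: lexicon row has fewer "
                    f"than 2 columns"
                )
            n_rows += 1
            term, entity_id = row[0].strip(), row[1].strip()
            if not term:
                n_dropped += 1
                continue
            if not entity_id:
                raise FormatError(
                    f"{path}: line {reader.line_num}: empty entity identifier"
                )
            terms.setdefault(term, set()).add(entity_id)
    if n_dropped:
        logger.warning("%s: dropped %d empty term(s)", path, n_dropped)
    if not terms:
        logger.warning("%s: lexicon is empty", path)
    return Lexicon(
        terms={t: frozenset(ids) for t, ids in terms.items()},
        ontology_tag=ontology_tag,
        n_source_rows=n_rows,
    )


def write_lexicon(lexicon: Lexicon, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(("term", "entity_id"))
        for term in sorted(lexicon.terms):
            for entity_id in sorted(lexicon.terms[term]):
                writer.writerow((term, entity_id))


# ---------------------------------------------------------------------------
# Relation tables
# ---------------------------------------------------------------------------

def build_graph(relations: Iterable[RelationRecord]) -> nx.Graph:
    """Collapse relation records into an undirected simple graph.

    Duplicate pairs (in either order) collapse onto one edge; the first
    record's label/provenance are kept as edge attributes (scoring
    ignores them).
    """
    graph = nx.Graph()
    for rel in relations:
        if not graph.has_edge(*rel.pair):
            graph.add_edge(
                rel.entity_a,
                rel.entity_b,
                label=rel.label,
                provenance_doc=rel.provenance_doc,
            )
    return graph


def load_relations(path: str | Path) -> nx.Graph:
    """Read a relation table into an undirected simple graph.

    Columns: entity_a, entity_b and optional label, provenance.  Self
    pairs are dropped with a logged count; an empty file yields an empty
    graph.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        return nx.Graph()
    records: list[RelationRecord] = []
    n_self = 0
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return nx.Graph()
        for col in ("entity_a", "entity_b"):
            if col not in reader.fieldnames:
                raise FormatError(
                    f"{path}: relation table is missing column {col!r}"
                )
        for row in reader:
            a, b = row["entity_a"].strip(), row["entity_b"].strip()
            if not a or not b:
                raise FormatError(
                    f"{path}: line {reader.line_num}: empty entity identifier"
                )
            if a == b:
                n_self += 1
                continue
            records.append(
                RelationRecord(
                    entity_a=a,
                    entity_b=b,
                    label=(row.get("label") or None),
                    provenance_doc=(row.get("provenance") or None),
                )
            )
    if n_self:
        logger.warning("%s: dropped %d self-pair(s)", path, n_self)
    return build_graph(records)


def write_relations(
    relations: Iterable[RelationRecord], path: str | Path
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(("entity_a", "entity_b", "label", "provenance"))
        for rel in sorted(relations, key=lambda r: r.pair):
            writer.writerow(
                (
                    rel.entity_a,
                    rel.entity_b,
                    rel.label or "",
                    rel.provenance_doc or "",
                )
            )


# ---------------------------------------------------------------------------
# Rating tables
# ---------------------------------------------------------------------------

def read_ratings(path: str | Path) -> RatingsDataset:
    """Read a three-column (user_id, item_id, rating) tab-separated table."""
    path = Path(path)
    triples: list[RatingTriple] = []
    seen: dict[tuple[str, str], int] = {}
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty ratings table")
        for col in ("user_id", "item_id", "rating"):
            if col not in reader.fieldnames:
                raise FormatError(
                    f"{path}: ratings table is missing column {col!r}"
                )
        for row in reader:
            line = reader.line_num
            raw = (row["rating"] or "").strip()
            if not raw.isdigit():
                raise ValidationError(
                    f"{path}: line {line}: rating must be a positive "
                    f"integer, got {raw!r}"
                )
            rating = int(raw)
            if rating < 1:
                raise ValidationError(
                    f"{path}: line {line}: rating must be >= 1, got {rating}"
                )
            key = (row["user_id"], row["item_id"])
            if key in seen:
                raise ValidationError(
                    f"{path}: line {line}: duplicate (user, item) pair "
                    f"{key!r} (first on line {seen[key]})"
                )
            seen[key] = line
            triples.append(RatingTriple(key[0], key[1], rating))
    return RatingsDataset(triples)


def write_ratings(dataset: RatingsDataset, path: str | Path) -> None:
    """Write ratings ordered by (user_id, item_id); output is byte-stable."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(("user_id", "item_id", "rating"))
        for t in dataset.triples():
            writer.writerow((t.user_id, t.item_id, t.rating))
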