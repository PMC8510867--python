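"""Synthetic corpus generator with planted author-topic structure.

Emits everything the pipeline consumes — documents, a lexicon,
gold-standard annotations, and an item-relation list — together with the
ground truth that was planted, so every stage can be tested end-to-end
without downloading a real literature corpus.

The planted structure mirrors the situation the relation-graph
recommender exploits in real literature: authors specialise in topics,
the entities they write about concentrate in their preferred topic, and
relations between entities are much denser within a topic than across
topics.  Abstracts are synthetic token streams (filler words with entity
surface terms embedded at recorded offsets), not natural language; every
consumer operates on surface-term matching, so syntax is irrelevant.
Generated surface terms include multi-word and diacritic-bearing forms
to exercise the Portuguese/Spanish matching pathway.  Each entity's
surface contains a unique digit-bearing token that appears in no filler
word and no other term, and terms are emitted whitespace-delimited, so a
dictionary matcher recovers exactly the planted spans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np

from . import io as corpus_io
from .errors import ConfigurationError
from .types import (
    Document,
    EntityAnnotation,
    Lexicon,
    RatingsDataset,
    RatingTriple,
    RelationRecord,
)

_FILLERS = (
    "study", "results", "patients", "analysis", "observed", "clinical",
    "reported", "cases", "during", "severe", "response", "evidence",
    "cohort", "methods", "increase", "associated", "findings", "após",
    "estudo", "pacientes", "análise", "también", "datos", "mediante",
)
_STEMS = ("vir", "nod", "plex", "quor", "sarn", "teg", "lum", "bria")
_QUALIFIERS = ("síndrome", "aguda", "crónica", "fiebre", "proteína")
_ONTOLOGY_TAG = "SYN"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-structure corpus.

    Defaults describe a small specialist community: 30 authors split
    over 6 topics of 15 entities each, 240 abstracts, strong topical
    affinity (0.85) and a relation graph far denser within topics (0.35)
    than across them (0.02).
    """

    n_authors: int = 30
    n_docs: int = 240
    n_topics: int = 6
    entities_per_topic: int = 15
    authors_per_doc: tuple[int, int] = (1, 3)
    entities_per_doc: tuple[int, int] = (4, 8)
    topic_affinity: float = 0.85
    intra_topic_edge_prob: float = 0.35
    inter_topic_edge_prob: float = 0.02
    languages: tuple[str, ...] = ("en", "pt", "es")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_authors", "n_docs", "n_topics", "entities_per_topic"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        for name in ("authors_per_doc", "entities_per_doc"):
            lo, hi = getattr(self, name)
            if not 1 <= lo <= hi:
                raise ConfigurationError(
                    f"{name} must be a (lo, hi) range with 1 <= lo <= hi"
                )
        for name in (
            "topic_affinity", "intra_topic_edge_prob", "inter_topic_edge_prob"
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.intra_topic_edge_prob < self.inter_topic_edge_prob:
            raise ConfigurationError(
                "intra_topic_edge_prob must be >= inter_topic_edge_prob "
                "for a planted-structure corpus"
            )
        if not self.languages:
            raise ConfigurationError("languages must be non-empty")
        n_entities = self.n_topics * self.entities_per_topic
        if self.entities_per_doc[1] > n_entities:
            raise ConfigurationError(
                f"entities_per_doc upper bound {self.entities_per_doc[1]} "
                f"exceeds the {n_entities} available entities"
            )
        if (
            self.topic_affinity >= 1.0
            and self.entities_per_doc[1] > self.entities_per_topic
        ):
            raise ConfigurationError(
                "with topic_affinity = 1 every document draws from a single "
                f"topic of {self.entities_per_topic} entities; "
                f"entities_per_doc upper bound "
                f"{self.entities_per_doc[1]} is infeasible"
            )
        if self.n_authors < self.n_topics:
            raise ConfigurationError(
                "need at least one author per topic"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Every fact planted into a generated corpus."""

    author_topic: dict[str, int]
    entity_topic: dict[str, int]
    # doc_id -> entity CURIE -> number of planted mentions
    occurrences: dict[str, dict[str, int]]
    edges: frozenset[tuple[str, str]]

    def expected_ratings(self) -> RatingsDataset:
        """Brute-force <user,item,rating> counts from the planted facts."""
        counts: dict[tuple[str, str], int] = {}
        for doc_id, per_entity in self.occurrences.items():
            for author in self._doc_authors[doc_id]:
                for entity in per_entity:
                    key = (author, entity)
                    counts[key] = counts.get(key, 0) + 1
        return RatingsDataset(
            RatingTriple(u, i, n) for (u, i), n in counts.items()
        )

    # filled in by generate_corpus; not part of the frozen public fields
    _doc_authors: dict[str, tuple[str, ...]] = field(
        default_factory=dict, repr=False, compare=False
    )


@dataclass(frozen=True)
class CorpusBundle:
    """A generated corpus plus its planted ground truth."""

    documents: list[Document]
    lexicon: Lexicon
    annotations: list[EntityAnnotation]
    relations: list[RelationRecord]
    ground_truth: GroundTruth
    spec: SyntheticSpec

    def relation_graph(self) -> nx.Graph:
        return corpus_io.build_graph(self.relations)


def _make_surfaces(n_entities: int, rng: np.random.Generator) -> list[str]:
    surfaces = []
    for idx in range(n_entities):
        stem = _STEMS[int(rng.integers(len(_STEMS)))]
        token = f"{stem}{idx}"
        if rng.random() < 0.35:
            qual = _QUALIFIERS[int(rng.integers(len(_QUALIFIERS)))]
            surfaces.append(f"{qual} {token}")
        else:
            surfaces.append(token)
    return surfaces


def _compose_abstract(
    occurrence_surfaces: list[str], rng: np.random.Generator
) -> tuple[str, list[tuple[int, int, str]]]:
    """Interleave filler words with entity surfaces, recording spans."""
    parts: list[str] = []
    spans: list[tuple[int, int, str]] = []
    pos = 0

    def emit(word: str) -> int:
        nonlocal pos
        if parts:
            parts.append(" ")
            pos += 1
        start = pos
        parts.append(word)
        pos += len(word)
        return start

    for surface in occurrence_surfaces:
        for _ in range(int(rng.integers(1, 4))):
            emit(_FILLERS[int(rng.integers(len(_FILLERS)))])
        begin = emit(surface)
        spans.append((begin, begin + len(surface), surface))
    emit(_FILLERS[int(rng.integers(len(_FILLERS)))])
    return "".join(parts) + ".", spans


def generate_corpus(spec: SyntheticSpec) -> CorpusBundle:
    """Generate a corpus; all randomness is driven by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n_entities = spec.n_topics * spec.entities_per_topic

    entity_ids = [f"SYN_{i:04d}" for i in range(n_entities)]
    entity_topic = {
        entity_ids[i]: i // spec.entities_per_topic for i in range(n_entities)
    }
    surfaces = _make_surfaces(n_entities, rng)
    lexicon = Lexicon(
        terms={
            surfaces[i]: frozenset({entity_ids[i]}) for i in range(n_entities)
        },
        ontology_tag=_ONTOLOGY_TAG,
    )

    authors = [f"author_{i:03d}" for i in range(spec.n_authors)]
    author_topic = {a: i % spec.n_topics for i, a in enumerate(authors)}
    authors_by_topic: list[list[str]] = [[] for _ in range(spec.n_topics)]
    for a in authors:
        authors_by_topic[author_topic[a]].append(a)

    topic_entities = [
        list(
            range(
                t * spec.entities_per_topic, (t + 1) * spec.entities_per_topic
            )
        )
        for t in range(spec.n_topics)
    ]
    other_entities = [
        [i for i in range(n_entities) if i // spec.entities_per_topic != t]
        for t in range(spec.n_topics)
    ]

    documents: list[Document] = []
    annotations: list[EntityAnnotation] = []
    occurrences: dict[str, dict[str, int]] = {}
    doc_authors: dict[str, tuple[str, ...]] = {}
    for j in range(spec.n_docs):
        topic = int(rng.integers(spec.n_topics))
        pool = authors_by_topic[topic]
        lo, hi = spec.authors_per_doc
        n_auth = min(int(rng.integers(lo, hi + 1)), len(pool))
        doc_author_list = tuple(
            pool[i] for i in rng.choice(len(pool), size=n_auth, replace=False)
        )

        lo, hi = spec.entities_per_doc
        n_ent = int(rng.integers(lo, hi + 1))
        n_on = int(np.sum(rng.random(n_ent) < spec.topic_affinity))
        n_on = min(n_on, len(topic_entities[topic]))
        n_off = min(n_ent - n_on, len(other_entities[topic]))
        chosen = [
            topic_entities[topic][i]
            for i in rng.choice(
                len(topic_entities[topic]), size=n_on, replace=False
            )
        ] + [
            other_entities[topic][i]
            for i in rng.choice(
                len(other_entities[topic]), size=n_off, replace=False
            )
        ]

        occurrence_surfaces: list[str] = []
        per_entity: dict[str, int] = {}
        for idx in chosen:
            n_mentions = int(rng.integers(1, 3))
            per_entity[entity_ids[idx]] = n_mentions
            occurrence_surfaces.extend([surfaces[idx]] * n_mentions)
        order = rng.permutation(len(occurrence_surfaces))
        occurrence_surfaces = [occurrence_surfaces[i] for i in order]

        abstract, spans = _compose_abstract(occurrence_surfaces, rng)
        doc_id = f"doc{j:04d}"
        surface_to_entity = {surfaces[idx]: entity_ids[idx] for idx in chosen}
        for begin, end, surface in spans:
            annotations.append(
                EntityAnnotation(
                    doc_id=doc_id,
                    begin=begin,
                    end=end,
                    surface=surface,
                    entity_id=surface_to_entity[surface],
                    ontology=_ONTOLOGY_TAG,
                )
            )
        documents.append(
            Document(
                doc_id=doc_id,
                title=f"Synthetic abstract {j}",
                abstract=abstract,
                language=spec.languages[j % len(spec.languages)],
                authors=doc_author_list,
                source="synthetic",
            )
        )
        occurrences[doc_id] = per_entity
        doc_authors[doc_id] = doc_author_list

    relations: list[RelationRecord] = []
    for a in range(n_entities):
        for b in range(a + 1, n_entities):
            same_topic = (
                a // spec.entities_per_topic == b // spec.entities_per_topic
            )
            p = (
                spec.intra_topic_edge_prob
                if same_topic
                else spec.inter_topic_edge_prob
            )
            if rng.random() < p:
                relations.append(
                    RelationRecord(
                        entity_a=entity_ids[a], entity_b=entity_ids[b]
                    )
                )

    ground_truth = GroundTruth(
        author_topic=author_topic,
        entity_topic=entity_topic,
        occurrences=occurrences,
        edges=frozenset(r.pair for r in relations),
        _doc_authors=doc_authors,
    )
    return CorpusBundle(
        documents=documents,
        lexicon=lexicon,
        annotations=annotations,
        relations=relations,
        ground_truth=ground_truth,
        spec=spec,
    )


def write_corpus(bundle: CorpusBundle, outdir: str | Path) -> dict[str, Path]:
    """Write a generated corpus to disk in the toolkit's table formats.

    Emits the document/lexicon/relation tables, one PubAnnotation JSON
    per document, and a ground-truth JSON; returns the paths written.
    Output is byte-identical across runs for the same spec.
    """
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann_dir = outdir / "annotations"
    ann_dir.mkdir(exist_ok=True)

    paths = {
        "documents": outdir / "documents.tsv",
        "lexicon": outdir / "lexicon.tsv",
        "relations": outdir / "relations.tsv",
        "annotations": ann_dir,
        "ground_truth": outdir / "ground_truth.json",
    }
    corpus_io.write_documents(bundle.documents, paths["documents"])
    corpus_io.write_lexicon(bundle.lexicon, paths["lexicon"])
    corpus_io.write_relations(bundle.relations, paths["relations"])
    by_doc: dict[str, list[EntityAnnotation]] = {}
    for ann in bundle.annotations:
        by_doc.setdefault(ann.doc_id, []).append(ann)
    for doc in bundle.documents:
        corpus_io.write_pubannotation(
            doc, by_doc.get(doc.doc_id, []), [], ann_dir / f"{doc.doc_id}.json"
        )
    gt = bundle.ground_truth
    with paths["ground_truth"].open("w", encoding="utf-8") as fh:
        json.dump(
            {
                "author_topic": gt.author_topic,
                "entity_topic": gt.entity_topic,
                "occurrences": gt.occurrences,
                "edges": sorted(list(e) for e in gt.edges),
            },
            fh,
            ensure_ascii=False,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return paths


def fig3_fixture() -> tuple[RatingsDataset, nx.Graph, list[str]]:
    """Golden worked example: one user, six liked entities, three candidates.

    The user has rated six entities; of the three candidate items, the
    severe-acute-respiratory-syndrome disease entity (DOID_2945) is
    related to exactly two liked items (score 2/6), the chemical entity
    CHEBI_34935 to exactly three (score 3/6), and the inflammatory-
    response process (GO_0006954) to none (score 0).  The six liked
    entity identifiers are synthetic stand-ins: only the three
    candidates and their relation counts define the example.
    """
    liked = (
        "CHEBI_16240",
        "CHEBI_17790",
        "DOID_0080600",
        "DOID_934",
        "GO_0008152",
        "HP_0002098",
    )
    candidates = ["DOID_2945", "CHEBI_34935", "GO_0006954"]
    graph = nx.Graph()
    graph.add_nodes_from(liked)
    graph.add_nodes_from(candidates)
    graph.add_edges_from(
        [
            ("DOID_2945", "DOID_0080600"),
            ("DOID_2945", "HP_0002098"),
            ("CHEBI_34935", "CHEBI_16240"),
            ("CHEBI_34935", "CHEBI_17790"),
            ("CHEBI_34935", "GO_0008152"),
        ]
    )
    ratings = RatingsDataset(
        RatingTriple("researcher_1", item, 1) for item in liked
    )
    return ratings, graph, candidates
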