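"""Build <user, item, rating> datasets from annotated documents.

Follows the LIBRETTI methodology: users are article authors, items are
the biomedical entities recognized in the articles, and the rating of a
(user, item) pair is the number of distinct articles the author wrote
that mention the item.  Multiple mentions within one abstract count
once; every author of an article receives equal credit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ConfigurationError, ValidationError
from .types import Document, EntityAnnotation, RatingsDataset, RatingTriple


def build_ratings(
    docs: Sequence[Document], annotations: Iterable[EntityAnnotation]
) -> RatingsDataset:
    """Count, per (author, entity), the distinct documents linking them.

    rating(u, i) = |{d : u in authors(d) and i annotated in d}|.  Pairs
    with no supporting document are absent (all ratings >= 1).  The
    result is invariant to document order and annotation order.
    """
    doc_index: dict[str, Document] = {}
    for doc in docs:
        if doc.doc_id in doc_index:
            raise ValidationError(f"duplicate doc_id {doc.doc_id!r} in corpus")
        doc_index[doc.doc_id] = doc

    entities_by_doc: dict[str, set[str]] = {}
    orphans: set[str] = set()
    for ann in annotations:
        if ann.doc_id not in doc_index:
            orphans.add(ann.doc_id)
            continue
        entities_by_doc.setdefault(ann.doc_id, set()).add(ann.entity_id)
    if orphans:
        raise ValidationError(
            "annotations reference unknown doc_id(s): "
            + ", ".join(repr(d) for d in sorted(orphans))
        )

    counts: dict[tuple[str, str], int] = {}
    for doc_id, entities in entities_by_doc.items():
        for author in set(doc_index[doc_id].authors):
            for entity in entities:
                key = (author, entity)
                counts[key] = counts.get(key, 0) + 1
    return RatingsDataset(
        RatingTriple(user, item, n) for (user, item), n in counts.items()
    )


def filter_min_ratings(
    dataset: RatingsDataset, min_items: int
) -> RatingsDataset:
    """Keep only users with at least ``min_items`` distinct rated items.

    Items left with no users simply disappear from the item universe.
    Applied once — no iterative re-filtering (dropping users never
    changes another user's item count, so a second pass is a no-op on
    the user set).
    """
    if min_items < 1:
        raise ConfigurationError(f"min_items must be >= 1, got {min_items}")
    return RatingsDataset(
        t
        for user in dataset.users()
        if len(dataset.items_of(user)) >= min_items
        for t in (
            RatingTriple(user, item, dataset.rating(user, item))
            for item in sorted(dataset.items_of(user))
        )
    )


@dataclass(frozen=True)
class DatasetStats:
    n_users: int
    n_items: int
    n_ratings: int


def dataset_stats(dataset: RatingsDataset) -> DatasetStats:
    """Summary dimensions of a ratings dataset."""
    return DatasetStats(
        n_users=dataset.n_users,
        n_items=dataset.n_items,
        n_ratings=dataset.n_ratings,
    )
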