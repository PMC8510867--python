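"""Domain types: documents, annotations, relations, ratings.

The central container is :class:`RatingsDataset`, the <user, item, rating>
triple store produced from annotated article corpora: users are author
names, items are ontology identifiers (CURIEs such as ``DOID_2945``), and
the rating counts the distinct articles an author wrote mentioning the
item.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import pandas as pd

from .errors import ValidationError

_LANG_RE = re.compile(r"^[a-z]{2}$")


@dataclass(frozen=True)
class Document:
    """One abstract with identity, language and ordered author list."""

    doc_id: str
    title: str = ""
    abstract: str = ""
    language: str = "en"
    authors: tuple[str, ...] = ()
    source: str = ""

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValidationError("Document requires a non-empty doc_id")
        if not _LANG_RE.match(self.language):
            raise ValidationError(
                f"document {self.doc_id!r}: language must be a 2-letter "
                f"lowercase ISO 639-1 code, got {self.language!r}"
            )
        object.__setattr__(self, "authors", tuple(self.authors))
        if any(not a for a in self.authors):
            raise ValidationError(
                f"document {self.doc_id!r}: empty author name in author list"
            )


@dataclass(frozen=True)
class EntityAnnotation:
    """A character span of text linked to an ontology identifier.

    Offsets are 0-based, half-open, counted in Unicode code points
    (PubAnnotation convention).
    """

    doc_id: str
    begin: int
    end: int
    surface: str
    entity_id: str
    ontology: str = ""

    def __post_init__(self) -> None:
        if self.begin < 0 or self.begin >= self.end:
            raise ValidationError(
                f"annotation {self.entity_id!r}: invalid span "
                f"[{self.begin}, {self.end})"
            )
        if not self.entity_id:
            raise ValidationError("annotation requires a non-empty entity_id")

    def validate_against(self, text: str) -> None:
        """Check the span fits ``text`` and the surface equals its slice."""
        if self.end > len(text):
            raise ValidationError(
                f"annotation {self.entity_id!r}: span [{self.begin}, "
                f"{self.end}) exceeds text of length {len(text)}"
            )
        slice_ = text[self.begin : self.end]
        if slice_ != self.surface:
            raise ValidationError(
                f"annotation {self.entity_id!r}: surface {self.surface!r} "
                f"does not match text slice {slice_!r} at "
                f"[{self.begin}, {self.end})"
            )

    def with_doc(self, doc_id: str) -> "EntityAnnotation":
        return replace(self, doc_id=doc_id)


@dataclass(frozen=True)
class RelationRecord:
    """An undirected relation between two entity identifiers.

    The pair is stored in canonical (lexicographically sorted) order so
    that (A, B) and (B, A) compare equal.
    """

    entity_a: str
    entity_b: str
    label: str | None = None
    provenance_doc: str | None = None

    def __post_init__(self) -> None:
        if not self.entity_a or not self.entity_b:
            raise ValidationError("relation endpoints must be non-empty")
        if self.entity_a == self.entity_b:
            raise ValidationError(
                f"self-relation not allowed: {self.entity_a!r}"
            )
        if self.entity_a > self.entity_b:
            a, b = self.entity_b, self.entity_a
            object.__setattr__(self, "entity_a", a)
            object.__setattr__(self, "entity_b", b)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.entity_a, self.entity_b)


@dataclass(frozen=True)
class RatingTriple:
    """One <user, item, rating> triple; the rating is an article count."""

    user_id: str
    item_id: str
    rating: int

    def __post_init__(self) -> None:
        if not self.user_id or not self.item_id:
            raise ValidationError("rating triple requires user and item ids")
        if not isinstance(self.rating, int) or isinstance(self.rating, bool):
            raise ValidationError(
                f"rating for ({self.user_id!r}, {self.item_id!r}) must be an "
                f"integer, got {self.rating!r}"
            )
        if self.rating < 1:
            raise ValidationError(
                f"rating for ({self.user_id!r}, {self.item_id!r}) must be "
                f">= 1, got {self.rating}"
            )


class RatingsDataset:
    """Immutable collection of unique <user, item, rating> triples."""

    def __init__(self, triples: Iterable[RatingTriple] = ()):
        ratings: dict[str, dict[str, int]] = {}
        for t in triples:
            per_user = ratings.setdefault(t.user_id, {})
            if t.item_id in per_user:
                raise ValidationError(
                    f"duplicate (user, item) pair "
                    f"({t.user_id!r}, {t.item_id!r})"
                )
            per_user[t.item_id] = t.rating
        self._ratings = ratings
        self._items = frozenset(
            i for per_user in ratings.values() for i in per_user
        )

    # -- counts ---------------------------------------------------------
    @property
    def n_users(self) -> int:
        return len(self._ratings)

    @property
    def n_items(self) -> int:
        return len(self._items)

    @property
    def n_ratings(self) -> int:
        return sum(len(v) for v in self._ratings.values())

    def __len__(self) -> int:
        return self.n_ratings

    def __bool__(self) -> bool:
        return bool(self._ratings)

    # -- access ---------------------------------------------------------
    def users(self) -> list[str]:
        return sorted(self._ratings)

    def items(self) -> list[str]:
        return sorted(self._items)

    def has_user(self, user_id: str) -> bool:
        return user_id in self._ratings

    def items_of(self, user_id: str) -> frozenset[str]:
        try:
            return frozenset(self._ratings[user_id])
        except KeyError:
            raise KeyError(f"unknown user {user_id!r}") from None

    def rating(self, user_id: str, item_id: str) -> int:
        """Rating for a pair, 0 when the user never rated the item."""
        return self._ratings.get(user_id, {}).get(item_id, 0)

    def triples(self) -> Iterator[RatingTriple]:
        """Triples in deterministic (user_id, item_id) order."""
        for user in sorted(self._ratings):
            per_user = self._ratings[user]
            for item in sorted(per_user):
                yield RatingTriple(user, item, per_user[item])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(t.user_id, t.item_id, t.rating) for t in self.triples()],
            columns=["user_id", "item_id", "rating"],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RatingsDataset):
            return NotImplemented
        return self._ratings == other._ratings

    def __repr__(self) -> str:
        return (
            f"RatingsDataset(n_users={self.n_users}, n_items={self.n_items},"
            f" n_ratings={self.n_ratings})"
        )


@dataclass(frozen=True)
class Lexicon:
    """Mapping from surface terms to ontology identifiers.

    A single term may map to several identifiers (e.g. a DeCS term with
    both a DeCS and a MeSH code); matching emits one annotation per
    identifier.
    """

    terms: dict[str, frozenset[str]] = field(default_factory=dict)
    ontology_tag: str = ""
    n_source_rows: int = 0

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for term, ids in self.terms.items():
            if not term:
                raise ValidationError("lexicon contains an empty term")
            ids = frozenset(ids)
            if not ids or any(not i for i in ids):
                raise ValidationError(
                    f"lexicon term {term!r} has an empty identifier"
                )
            clean[term] = ids
        object.__setattr__(self, "terms", clean)

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def __len__(self) -> int:
        return len(self.terms)

    def __bool__(self) -> bool:
        return bool(self.terms)
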