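"""The relation-graph recommender (RelRA) and a random baseline.

RelRA is content-based: the score of an unrated candidate item for a
user is the fraction of the user's liked items the candidate is related
to in a knowledge graph of item-item relations,

    score(c | L) = |{l in L : {c, l} is an edge}| / |L|,

where L is the set of items the user has rated at least once.  Rating
magnitudes do not enter the score — liking is set membership.  With six
liked items, a candidate related to two of them scores 2/6 and one
related to three scores 3/6; the latter ranks first.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import ConfigurationError, ValidationError
from .types import RatingsDataset


@dataclass(frozen=True)
class RecommendationList:
    """Ranked top-k recommendations for one user."""

    user_id: str
    items: tuple[tuple[str, float], ...]  # (item_id, score), score desc
    k: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        if len(self.items) > self.k:
            raise ValidationError(
                f"recommendation list longer than k={self.k}"
            )
        ids = [i for i, _ in self.items]
        if len(set(ids)) != len(ids):
            raise ValidationError("recommended items must be unique")
        scores = [s for _, s in self.items]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValidationError("scores must be non-increasing")

    def item_ids(self) -> list[str]:
        return [i for i, _ in self.items]


def relra_score(
    liked: frozenset[str] | set[str], candidate: str, graph: nx.Graph
) -> float:
    """Fraction of the liked items the candidate is related to.

    Items absent from the graph contribute nothing to the numerator; the
    denominator is always the full liked-set size.
    """
    if not liked:
        raise ValidationError("relra_score requires a non-empty liked set")
    if candidate in liked:
        raise ValidationError(
            f"candidate {candidate!r} is already in the liked set"
        )
    hits = sum(1 for item in liked if graph.has_edge(candidate, item))
    return hits / len(liked)


def _candidate_pool(
    user: str, train: RatingsDataset, candidates: set[str] | None
) -> tuple[frozenset[str], list[str]]:
    if not train.has_user(user):
        raise ValidationError(f"unknown user {user!r}")
    liked = train.items_of(user)
    pool = set(candidates) if candidates is not None else set(train.items())
    return liked, sorted(pool - liked)


def recommend(
    user: str,
    train: RatingsDataset,
    graph: nx.Graph,
    candidates: set[str] | None = None,
    k: int = 5,
    min_score: float | None = None,
) -> RecommendationList:
    """Rank candidate items for a user by RelRA score.

    The candidate pool defaults to every item in ``train`` the user has
    not rated; items the user rated are always removed.  Ties are broken
    by item identifier so rankings are reproducible.  ``min_score``
    (when given) drops items scoring at or below it — pass 0 to exclude
    zero-score items from the final list.
    """
    if k <= 0:
        raise ConfigurationError(f"k must be positive, got {k}")
    liked, pool = _candidate_pool(user, train, candidates)
    scored = sorted(
        ((item, relra_score(liked, item, graph)) for item in pool),
        key=lambda pair: (-pair[1], pair[0]),
    )
    if min_score is not None:
        scored = [(i, s) for i, s in scored if s > min_score]
    return RecommendationList(user_id=user, items=tuple(scored[:k]), k=k)


def random_recommend(
    user: str,
    train: RatingsDataset,
    candidates: set[str] | None = None,
    k: int = 5,
    seed: int = 0,
) -> RecommendationList:
    """Baseline: uniform sample of min(k, |pool|) candidates, score 0.

    Deterministic for a fixed seed.
    """
    if k <= 0:
        raise ConfigurationError(f"k must be positive, got {k}")
    _, pool = _candidate_pool(user, train, candidates)
    rng = np.random.default_rng(seed)
    size = min(k, len(pool))
    chosen = rng.choice(len(pool), size=size, replace=False)
    return RecommendationList(
        user_id=user,
        items=tuple((pool[i], 0.0) for i in chosen),
        k=k,
    )
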