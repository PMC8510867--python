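"""Top@k evaluation protocol for implicit-feedback recommenders.

Protocol: filter users to a minimum number of rated items (default 20),
split each user's items at random into 80% train / 20% test, recommend
top-k items from the pool of items the user has not trained on, and
score the list against the held-out items with Precision@k, Recall@k
and MRR, macro-averaged over users.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .ratings import filter_min_ratings
from .recommend import random_recommend, recommend
from .types import RatingsDataset, RatingTriple

# A recommender: (user, train set, candidate pool, k) -> ranked item ids.
RecommenderFn = Callable[[str, RatingsDataset, set[str], int], Sequence[str]]


class EmptyRelevantSetError(ValidationError):
    """Signals that a user has no held-out items to score against."""


def _user_seed(seed: int, user: str, salt: int = 0) -> np.random.SeedSequence:
    # stable across runs and independent of user iteration order
    digest = hashlib.sha256(user.encode("utf-8")).digest()
    return np.random.SeedSequence(
        [seed, int.from_bytes(digest[:4], "big"), salt]
    )


def split_dataset(
    dataset: RatingsDataset, train_frac: float = 0.8, seed: int = 0
) -> tuple[RatingsDataset, RatingsDataset]:
    """Per-user random holdout split.

    Each user's items are partitioned independently: ceil(train_frac * n)
    items go to train, the rest to test, so every user appears in both
    partitions (the test part may be empty for very small n).  The union
    of the two parts reconstructs the input; the split is deterministic
    for a fixed seed and independent of user order.
    """
    if not 0 < train_frac < 1:
        raise ConfigurationError(
            f"train_frac must lie strictly between 0 and 1, got {train_frac}"
        )
    train_triples: list[RatingTriple] = []
    test_triples: list[RatingTriple] = []
    for user in dataset.users():
        items = sorted(dataset.items_of(user))
        if len(items) < 2:
            raise ValidationError(
                f"user {user!r} has fewer than 2 rated items; apply "
                f"filter_min_ratings before splitting"
            )
        rng = np.random.default_rng(_user_seed(seed, user))
        order = rng.permutation(len(items))
        n_train = math.ceil(train_frac * len(items))
        for pos, idx in enumerate(order):
            item = items[idx]
            triple = RatingTriple(user, item, dataset.rating(user, item))
            (train_triples if pos < n_train else test_triples).append(triple)
    return RatingsDataset(train_triples), RatingsDataset(test_triples)


def split_kfold(
    dataset: RatingsDataset, folds: int = 5, seed: int = 0
) -> list[tuple[RatingsDataset, RatingsDataset]]:
    """Per-user k-fold splits: one (train, test) pair per fold.

    Each user's items are permuted once and cut into ``folds``
    near-equal chunks; fold f holds out chunk f.  The test partitions
    of all folds tile the dataset exactly.
    """
    if folds < 2:
        raise ConfigurationError(f"folds must be >= 2, got {folds}")
    fold_train: list[list[RatingTriple]] = [[] for _ in range(folds)]
    fold_test: list[list[RatingTriple]] = [[] for _ in range(folds)]
    for user in dataset.users():
        items = sorted(dataset.items_of(user))
        if len(items) < folds:
            raise ValidationError(
                f"user {user!r} has fewer than {folds} rated items; apply "
                f"filter_min_ratings before splitting"
            )
        rng = np.random.default_rng(_user_seed(seed, user))
        order = rng.permutation(len(items))
        for pos, idx in enumerate(order):
            item = items[idx]
            triple = RatingTriple(user, item, dataset.rating(user, item))
            for f in range(folds):
                (fold_test if pos % folds == f else fold_train)[f].append(
                    triple
                )
    return [
        (RatingsDataset(fold_train[f]), RatingsDataset(fold_test[f]))
        for f in range(folds)
    ]


# ---------------------------------------------------------------------------
# Per-user metrics
# ---------------------------------------------------------------------------

def _check_ranked(recommended: Sequence[str], k: int) -> list[str]:
    if k <= 0:
        raise ConfigurationError(f"k must be positive, got {k}")
    if len(set(recommended)) != len(recommended):
        raise ValidationError("recommended list contains duplicate items")
    return list(recommended)[:k]


def precision_at_k(
    recommended: Sequence[str], relevant: set[str], k: int
) -> float:
    """|top-k ∩ relevant| / k; the denominator stays k even when fewer
    than k items were returned."""
    top = _check_ranked(recommended, k)
    return len(set(top) & set(relevant)) / k


def recall_at_k(
    recommended: Sequence[str], relevant: set[str], k: int
) -> float:
    """|top-k ∩ relevant| / |relevant|; an empty relevant set is an
    error the caller is expected to treat as "skip this user"."""
    if not relevant:
        raise EmptyRelevantSetError("relevant set is empty; skip this user")
    top = _check_ranked(recommended, k)
    return len(set(top) & set(relevant)) / len(relevant)


def mrr_at_k(recommended: Sequence[str], relevant: set[str], k: int) -> float:
    """Reciprocal rank of the first relevant item in the top-k, else 0."""
    top = _check_ranked(recommended, k)
    for rank, item in enumerate(top, start=1):
        if item in relevant:
            return 1.0 / rank
    return 0.0


# ---------------------------------------------------------------------------
# Full protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlgorithmMetrics:
    precision_at_k: float
    recall_at_k: float
    mrr: float


@dataclass(frozen=True)
class EvalReport:
    """Per-algorithm mean metrics plus the full protocol parameters."""

    k: int
    min_items: int
    train_frac: float
    seed: int
    n_users_evaluated: int
    n_users_skipped: int
    metrics: dict[str, AlgorithmMetrics] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, m in self.metrics.items():
            for value in (m.precision_at_k, m.recall_at_k, m.mrr):
                if not 0.0 <= value <= 1.0:
                    raise ValidationError(
                        f"metric for {name!r} outside [0, 1]: {value}"
                    )

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "min_items": self.min_items,
            "train_frac": self.train_frac,
            "seed": self.seed,
            "n_users_evaluated": self.n_users_evaluated,
            "n_users_skipped": self.n_users_skipped,
            "metrics": {
                name: {
                    "precision_at_k": m.precision_at_k,
                    "recall_at_k": m.recall_at_k,
                    "mrr": m.mrr,
                }
                for name, m in self.metrics.items()
            },
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (name, m.precision_at_k, m.recall_at_k, m.mrr)
                for name, m in self.metrics.items()
            ],
            columns=["algorithm", "precision_at_k", "recall_at_k", "mrr"],
        )


def _resolve_algorithms(
    algorithms: Sequence[str | tuple[str, RecommenderFn]],
    graph: nx.Graph,
    seed: int,
) -> list[tuple[str, RecommenderFn]]:
    resolved: list[tuple[str, RecommenderFn]] = []
    for idx, algo in enumerate(algorithms):
        if isinstance(algo, tuple):
            resolved.append(algo)
        elif algo == "relra":
            def _relra(user, train, candidates, k, _graph=graph):
                return recommend(
                    user, train, _graph, candidates=candidates, k=k
                ).item_ids()

            resolved.append(("relra", _relra))
        elif algo == "random":
            def _random(user, train, candidates, k, _salt=idx):
                user_seed = int(
                    _user_seed(seed, user, salt=1000 + _salt)
                    .generate_state(1)[0]
                )
                return random_recommend(
                    user, train, candidates=candidates, k=k, seed=user_seed
                ).item_ids()

            resolved.append(("random", _random))
        else:
            raise ConfigurationError(
                f"unknown algorithm tag {algo!r}; expected 'relra', "
                f"'random', or a (name, callable) pair"
            )
    names = [n for n, _ in resolved]
    if len(set(names)) != len(names):
        raise ConfigurationError(f"duplicate algorithm names: {names}")
    return resolved


def evaluate(
    dataset: RatingsDataset,
    graph: nx.Graph,
    algorithms: Sequence[str | tuple[str, RecommenderFn]] = ("relra", "random"),
    k: int = 5,
    min_items: int = 20,
    train_frac: float = 0.8,
    seed: int = 0,
    folds: int = 1,
) -> EvalReport:
    """Run the full top@k comparison protocol.

    For each surviving user, every algorithm ranks the candidate pool
    (all items of the filtered dataset minus the user's train items) and
    is scored against the user's held-out test items.  Users whose test
    partition is empty are skipped and counted.  Means are macro
    averages over evaluated (user, fold) instances — with the default
    single holdout split (``folds=1``) that is simply each user weighted
    equally.
    """
    if not dataset:
        raise ConfigurationError("cannot evaluate an empty dataset")
    filtered = filter_min_ratings(dataset, min_items)
    if filtered.n_users == 0:
        raise ConfigurationError(
            f"no user has >= {min_items} rated items; nothing to evaluate"
        )
    if folds == 1:
        splits = [split_dataset(filtered, train_frac=train_frac, seed=seed)]
    else:
        splits = split_kfold(filtered, folds=folds, seed=seed)
    universe = set(filtered.items())
    resolved = _resolve_algorithms(algorithms, graph, seed)

    sums = {name: [0.0, 0.0, 0.0] for name, _ in resolved}
    n_instances = 0
    evaluated_users: set[str] = set()
    skipped_users: set[str] = set()
    for train, test in splits:
        for user in train.users():
            relevant = (
                set(test.items_of(user)) if test.has_user(user) else set()
            )
            if not relevant:
                skipped_users.add(user)
                continue
            n_instances += 1
            evaluated_users.add(user)
            candidates = universe - train.items_of(user)
            for name, fn in resolved:
                ranked = list(fn(user, train, candidates, k))
                sums[name][0] += precision_at_k(ranked, relevant, k)
                sums[name][1] += recall_at_k(ranked, relevant, k)
                sums[name][2] += mrr_at_k(ranked, relevant, k)
    if n_instances == 0:
        raise ConfigurationError(
            "every user's test partition is empty; nothing to evaluate"
        )
    return EvalReport(
        k=k,
        min_items=min_items,
        train_frac=train_frac,
        seed=seed,
        n_users_evaluated=len(evaluated_users),
        n_users_skipped=len(skipped_users - evaluated_users),
        metrics={
            name: AlgorithmMetrics(
                precision_at_k=s[0] / n_instances,
                recall_at_k=s[1] / n_instances,
                mrr=s[2] / n_instances,
            )
            for name, s in sums.items()
        },
    )
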