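"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library's own code paths: normalization is
re-derived from first principles, matching is a quadratic scan, and
counting is a triple loop over (document, author, entity) incidence.
"""

from __future__ import annotations

import unicodedata


def naive_normalize(text: str, fold_case: bool, fold_diacritics: bool) -> str:
    chars = []
    for ch in text:
        if fold_diacritics:
            base = [
                c
                for c in unicodedata.normalize("NFD", ch)
                if not unicodedata.combining(c)
            ]
            if len(base) == 1:
                ch = base[0]
        if fold_case and len(ch.lower()) == 1:
            ch = ch.lower()
        chars.append(ch)
    return "".join(chars)


def naive_leftmost_longest(
    terms: dict[str, frozenset[str]],
    text: str,
    fold_case: bool = True,
    fold_diacritics: bool = False,
) -> list[tuple[int, int]]:
    """All-positions scan + boundary filter + greedy leftmost-longest."""
    norm_text = naive_normalize(text, fold_case, fold_diacritics)
    occurrences: set[tuple[int, int]] = set()
    for term in terms:
        norm_term = naive_normalize(term, fold_case, fold_diacritics)
        for start in range(len(norm_text) - len(norm_term) + 1):
            if norm_text[start : start + len(norm_term)] != norm_term:
                continue
            end = start + len(norm_term)
            if start > 0 and norm_text[start - 1].isalnum():
                continue
            if end < len(norm_text) and norm_text[end].isalnum():
                continue
            occurrences.add((start, end))
    chosen: list[tuple[int, int]] = []
    last_end = 0
    for begin, end in sorted(occurrences, key=lambda s: (s[0], -s[1])):
        if begin >= last_end:
            chosen.append((begin, end))
            last_end = end
    return chosen


def brute_force_ratings(docs, annotations) -> dict[tuple[str, str], int]:
    """Triple loop over (doc, author, entity) incidence."""
    entities = {}
    for ann in annotations:
        entities.setdefault(ann.doc_id, set()).add(ann.entity_id)
    counts: dict[tuple[str, str], int] = {}
    for doc in docs:
        for author in set(doc.authors):
            for entity in entities.get(doc.doc_id, ()):
                counts[(author, entity)] = counts.get((author, entity), 0) + 1
    return counts


def brute_force_relra(
    liked: set[str], candidate: str, edges: set[tuple[str, str]]
) -> float:
    """Double loop over (candidate, liked) pairs against a raw edge list."""
    hits = 0
    for item in liked:
        for a, b in edges:
            if {a, b} == {candidate, item}:
                hits += 1
                break
    return hits / len(liked)
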