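"""Dictionary-based entity recognition and linking.

Implements MER-style matching: given a lexicon mapping ontology terms to
identifiers, recognize every lexicon term in a text and link each match
to its identifiers.  No training data is needed — the lexicon *is* the
model, which makes the approach language-agnostic (the same machinery
annotates English, Portuguese and Spanish abstracts, given the matching
DeCS/ontology lexicon).

Matching semantics:

* multi-pattern search via an Aho-Corasick automaton built over
  normalized terms (case folding on by default; diacritic folding off by
  default, since Portuguese/Spanish terms carry meaningful diacritics);
* matches only at word boundaries — a hit must not be flanked by letters
  or digits, so ``ARS`` never fires inside ``SARS`` while hyphenated
  terms like ``COVID-19`` match as units;
* overlaps resolved by the leftmost-longest rule;
* a term with several identifiers emits one annotation per identifier at
  the same span.

Normalization is performed per code point and is length-preserving, so
match offsets always refer to the original text.
"""

from __future__ import annotations

import logging
import unicodedata
from collections import deque
from dataclasses import dataclass, field
from typing import Iterator

from .errors import ConfigurationError
from .types import Document, EntityAnnotation, Lexicon

logger = logging.getLogger("litrec")


def normalize_text(
    text: str, fold_case: bool = True, fold_diacritics: bool = False
) -> str:
    """Normalize per code point, preserving length (and thus offsets).

    Code points whose folded form would change the string length (rare
    cases such as the dotted capital I) are left untouched.
    """
    out: list[str] = []
    for ch in text:
        c = ch
        if fold_diacritics:
            stripped = "".join(
                x
                for x in unicodedata.normalize("NFD", c)
                if not unicodedata.combining(x)
            )
            if len(stripped) == 1:
                c = stripped
        if fold_case:
            low = c.lower()
            if len(low) == 1:
                c = low
        out.append(c)
    return "".join(out)


class _AhoCorasick:
    """Classic Aho-Corasick automaton over unicode code points."""

    __slots__ = ("_goto", "_fail", "_out")

    def __init__(self, patterns: list[str]):
        self._goto: list[dict[str, int]] = [{}]
        self._out: list[list[int]] = [[]]  # pattern lengths ending here
        for pat in patterns:
            node = 0
            for ch in pat:
                nxt = self._goto[node].get(ch)
                if nxt is None:
                    self._goto.append({})
                    self._out.append([])
                    nxt = len(self._goto) - 1
                    self._goto[node][ch] = nxt
                node = nxt
            self._out[node].append(len(pat))

        self._fail = [0] * len(self._goto)
        queue: deque[int] = deque(self._goto[0].values())
        while queue:
            node = queue.popleft()
            for ch, child in self._goto[node].items():
                queue.append(child)
                f = self._fail[node]
                while f and ch not in self._goto[f]:
                    f = self._fail[f]
                fallback = self._goto[f].get(ch, 0)
                self._fail[child] = fallback if fallback != child else 0
                self._out[child].extend(self._out[self._fail[child]])

    def iter_matches(self, text: str) -> Iterator[tuple[int, int]]:
        """Yield (begin, end) for every pattern occurrence in ``text``."""
        node = 0
        for i, ch in enumerate(text):
            while node and ch not in self._goto[node]:
                node = self._fail[node]
            node = self._goto[node].get(ch, 0)
            for length in self._out[node]:
                yield i + 1 - length, i + 1


@dataclass(frozen=True)
class Matcher:
    """Compiled multi-pattern index over normalized lexicon terms.

    Terms that collide after normalization merge their identifier sets.
    Rebuilding from the same lexicon and flags yields identical match
    behaviour.
    """

    term_ids: dict[str, frozenset[str]]  # normalized term -> identifiers
    fold_case: bool
    fold_diacritics: bool
    ontology_tag: str = ""
    _automaton: _AhoCorasick = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if self._automaton is None:
            object.__setattr__(
                self, "_automaton", _AhoCorasick(sorted(self.term_ids))
            )


def build_matcher(
    lexicon: Lexicon,
    fold_case: bool = True,
    fold_diacritics: bool = False,
) -> Matcher:
    """Compile a lexicon into a deterministic matcher."""
    if not lexicon:
        raise ConfigurationError("cannot build a matcher from an empty lexicon")
    term_ids: dict[str, set[str]] = {}
    for term, ids in lexicon.terms.items():
        norm = normalize_text(term, fold_case, fold_diacritics)
        term_ids.setdefault(norm, set()).update(ids)
    return Matcher(
        term_ids={t: frozenset(ids) for t, ids in term_ids.items()},
        fold_case=fold_case,
        fold_diacritics=fold_diacritics,
        ontology_tag=lexicon.ontology_tag,
    )


def _is_boundary(text: str, begin: int, end: int) -> bool:
    # a match must not be flanked by letters/digits
    if begin > 0 and text[begin - 1].isalnum():
        return False
    if end < len(text) and text[end].isalnum():
        return False
    return True


def match_text(matcher: Matcher, text: str) -> list[EntityAnnotation]:
    """Find lexicon terms in ``text``.

    Returns non-overlapping, boundary-respecting matches chosen by the
    leftmost-longest rule, sorted by begin offset; one annotation per
    identifier of the matched term.
    """
    norm = normalize_text(text, matcher.fold_case, matcher.fold_diacritics)
    candidates = sorted(
        (
            (b, e)
            for b, e in matcher._automaton.iter_matches(norm)
            if _is_boundary(text, b, e)
        ),
        key=lambda span: (span[0], -span[1]),
    )
    annotations: list[EntityAnnotation] = []
    last_end = 0
    for begin, end in candidates:
        if begin < last_end:
            continue
        last_end = end
        for entity_id in sorted(matcher.term_ids[norm[begin:end]]):
            annotations.append(
                EntityAnnotation(
                    doc_id="",
                    begin=begin,
                    end=end,
                    surface=text[begin:end],
                    entity_id=entity_id,
                    ontology=matcher.ontology_tag,
                )
            )
    return annotations


def annotate_document(matcher: Matcher, doc: Document) -> list[EntityAnnotation]:
    """Match the lexicon against a document's abstract.

    Offsets are relative to the abstract; every annotation carries the
    document id.  An empty abstract yields an empty list with a warning.
    """
    if not doc.abstract:
        logger.warning("document %r has an empty abstract", doc.doc_id)
        return []
    return [ann.with_doc(doc.doc_id) for ann in match_text(matcher, doc.abstract)]
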