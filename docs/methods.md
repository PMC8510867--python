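# Methods

## Problem setting

The toolkit models literature-based recommendation as implicit
feedback: an author "likes" a biomedical entity when they have written
an article whose abstract mentions it. Recommendation then asks which
entities an author has not yet written about are most worth suggesting.
The content signal is a knowledge graph of item–item relations (for
real corpora, the output of a relation-extraction system run over a
*different* document sample than the one the ratings came from, to
avoid leaking co-occurrence structure into the recommender).

## Entity annotation

Dictionary matching with no learned components: the lexicon is the
model. Implementation is an Aho-Corasick automaton over normalized
terms, with three policy decisions that were genuinely open:

* **Overlap resolution** — leftmost-longest, non-overlapping. A
  dictionary matcher reports all occurrences; emitting overlaps would
  double-count nested terms ("respiratory syndrome" inside "acute
  respiratory syndrome"), so the longest match starting leftmost wins.
* **Word boundaries** — a match may not be flanked by letters or
  digits. This blocks `ARS` firing inside `SARS` while letting
  hyphenated units like `COVID-19` match whole (the hyphen is a
  non-alphanumeric code point inside the term, not a boundary
  requirement around it).
* **Normalization** — case folding on by default; diacritic folding
  off by default because Portuguese and Spanish lexicon entries carry
  meaningful diacritics. Both are per-code-point and length-preserving
  so offsets always refer to the original text; the rare code points
  whose folded form changes length are left unfolded. Terms that
  collide after normalization merge their identifier sets.

A term mapping to several identifiers emits one annotation per
identifier at the same span, because rating construction is
per-identifier. Offsets are 0-based half-open code-point offsets
(PubAnnotation convention).

## Rating construction

`rating(u, i)` counts *distinct* documents: repeated mentions within
one abstract count once, and all authors of a document receive equal
credit (no position weighting — author order carries field-specific
conventions the data cannot disambiguate). Matching is done on the
abstract field only (titles excluded); items from different ontologies
share one universe keyed by CURIE. This yields the exact conservation
law used as a test oracle:

    Σ_(u,i) rating(u,i) = Σ_d |authors(d)| · |distinct entities(d)|.

The ≥ 20-items evaluation filter is applied in a single pass. Dropping
users never changes another user's item count, so cascading cannot
remove further users; the filtered item universe simply shrinks to the
items that retain at least one user.

## RelRA scoring

score(c | L) = (number of liked items adjacent to c) / |L|. Decisions:

* The denominator is the full liked-set size, fixed per user — both
  worked-example candidates are divided by the same 6. Rating
  magnitudes do not weight the score; liking is set membership.
* The relation graph is simple and undirected: multiple extracted
  relations between the same pair (different labels or provenance)
  count once, relation direction and labels are ignored by scoring
  (preserved in I/O), and self-relations are dropped on load since an
  item trivially related to itself would distort scores.
* Ties (equal scores) break by item identifier ascending, so rankings
  are reproducible across hash seeds and platforms.
* The library returns zero-score items in the ranking (they can fill a
  top-k); the CLI excludes them from the final report by default via
  `--min-score 0`, since a zero score carries no relational evidence.
* The candidate pool defaults to every item of the dataset the user
  has not rated; callers may restrict it.

The random baseline samples min(k, |pool|) candidates uniformly
without replacement from a seeded generator.

## Evaluation protocol

Per-user random holdout: each user's items are permuted by a
user-keyed seeded generator (stable under user iteration order) and
⌈0.8·n⌉ go to train, the remainder to test. The "cross-validation,
80 %/20 %" wording of the protocol does not pin a fold structure, so
holdout repeated over seeds is the default and per-user k-fold is
available (`folds` / `--folds`) for callers who want tiling test sets.
Users whose test partition is empty (possible only for very small n)
are skipped and counted in the report. Metrics are the standard top-k
implicit-feedback forms — Precision@k with denominator k, Recall@k
with denominator |held-out set|, MRR as the reciprocal rank of the
first held-out item within the top k — macro-averaged over evaluated
users, with relevance defined as membership in the user's held-out
items. Each user's candidate pool is the filtered dataset's item
universe minus that user's train items; the random baseline draws a
per-user seed derived from the run seed and a hash of the user key.

## Synthetic corpus

The generator emulates the planted structure the recommender is meant
to exploit: every author has a preferred topic; each document belongs
to one topic and is authored by 1–3 same-topic authors; each document
mentions 4–8 entities drawn from the document's topic with probability
0.85 (else uniformly from the other topics), each 1–2 times; relations
are sampled independently per entity pair with probability 0.35 within
a topic and 0.02 across topics. Defaults — 30 authors, 240 documents,
6 topics × 15 entities — describe a small specialist community sized
so that after the ≥ 20-items filter essentially the whole author
population survives with item sets substantially larger than k = 5,
while a full 10-seed evaluation stays in the seconds range.

Abstracts are synthetic token streams, not natural language: filler
words interleaved with entity surface terms at recorded offsets. Every
surface term contains a unique digit-bearing token and terms are
emitted whitespace-delimited, so dictionary matching provably recovers
exactly the planted spans — which is what makes planted occurrence
counts usable as an end-to-end oracle. Generated lexicons include
multi-word and diacritic-bearing terms to exercise the
Portuguese/Spanish matching path. What this does **not** emulate, and
passing tests therefore do not establish for real corpora: natural
prose (abbreviations, inflection, punctuation-adjacent mentions),
ambiguous or nested terminology, author-name homonymy and synonymy,
heavy-tailed author productivity and entity frequency distributions,
and noisy relation extraction. Results on the synthetic corpus
validate the machinery and the direction of the RelRA-vs-random
comparison, not absolute metric levels on real literature.

The packaged worked example (`fig3_fixture`) plants one user with six
liked entities and three candidates related to exactly 2, 3 and 0 of
them, giving scores 2/6, 3/6 and 0. The six liked identifiers are
synthetic stand-ins; only the candidates and their relation counts
define the example.

## Numerical and degenerate-input choices

* All scores and metrics are exact small-integer ratios in floating
  point; no tolerances are needed beyond float division.
* Documents with no authors are legal inputs (warning logged) and
  contribute no ratings; empty abstracts annotate to an empty list.
* An empty relation file is an empty graph, not an error; items absent
  from the graph score 0 as candidates and contribute 0 as liked items.
* The ratings writer orders rows by (user, item) and the corpus writer
  sorts JSON keys, so identical inputs produce byte-identical outputs.
* Author names are exact string keys: no disambiguation is attempted.

## Known limitations

* No approximate matching, abbreviation handling, or cross-ontology
  identifier unification (e.g. DeCS↔MeSH) — a term unmatched by the
  lexicon is invisible to the whole pipeline.
* RelRA is purely structural over an unweighted graph; relation types,
  multiplicities and confidence scores are ignored, and there is no
  collaborative-filtering or hybrid component.
* The evaluation excludes cold-start users by design (the ≥ 20-items
  filter) and offers no significance testing between algorithms.
* Parallel-language versions of one article must be collapsed to a
  single document record by the caller; the builder treats every
  document row as a distinct article.
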