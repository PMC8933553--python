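# Methods

This note documents the models and procedures implemented in `trialkg`,
the defaults that matter, and the choices made where the design was
genuinely open.

## Graph schema and validation

The graph is strongly typed: a declarative `SchemaSpec` fixes the 18 node
types (with a per-type "study-specific" flag), the 21 relation types with
their head/tail types, and a cardinality class per relation. Cardinality
classes are `exactly_one`, `at_most_one` or `many`, attached to the
endpoint role they constrain. The one-to-one relations (every
event/baseline/drop/outcome group and every outcome belongs to exactly one
study; every adverse event maps to exactly one organ; every baseline/drop
record and period hangs off exactly one parent) are derived from the
semantics of the source tables: a result group row names exactly one study,
a withdrawal row names exactly one period. Optional relations
(outcome→cluster, analysis→method, measurement→outcome-group,
analysis→outcome) are `at_most_one`, since the source fields can be empty.
`validate_graph` reports violations rather than raising, so a partially
broken graph can be inspected; assembly skips input rows with broken
references (logged per row) and therefore always emits a valid graph.

Node ids are prefixed with their type (`study:NCT…`, `drugterm:losartan`)
because raw registry identifiers are unique only within tables. Attribute
values are stored as text or numbers; the TSV export writes a per-attribute
declared-type sidecar so a round trip through disk is the identity — this
is asserted, not assumed, in the tests. Empty-string attribute values are
treated as absent; builders never store them.

## Study filter

The filter is a fixed three-stage cascade: drop studies with no
intervention of type "Drug", then (among the rest) studies with no
outcome-analysis rows, then studies with no condition rows. Stage counts
are order-dependent and reported as such. "Has outcome analyses" is read
strictly as analysis rows, not outcome rows. The kept set is a set
operation over id columns, hence invariant to input row order.

## Adverse-event cascade

Stages, each followed by a case-insensitive dictionary lookup that stops
the cascade on a hit:

0. direct lookup;
1. removal of balanced parenthesized spans (outermost; unbalanced
   parentheses are left untouched — nesting behaviour is unspecified in
   registry data, and outermost removal is the conservative reading);
2. removal of auxiliary words/phrases and time frames, from a pluggable
   pattern list seeded with laterality markers, study-phase labels and
   `for/at/within <number> <time-unit>` patterns;
3. lowercasing, stop-word removal and lemmatization (a pinned stop-word
   list and lemma table ship in `resources/`; regular plurals are handled
   by suffix rules, irregular medical vocabulary by the table —
   determinism requires pinning rather than depending on an external
   NLP toolkit's model files);
4. rescue: map to the nearest dictionary term within Levenshtein
   distance ≤ 3 ("less than 4" read literally), exhaustive over the
   dictionary with a length-difference prefilter, ties broken by smaller
   distance then lexicographically smallest term.

Edit distance is plain Levenshtein (unit-cost insert/delete/substitute, no
transpositions). After a match, level-1 terms are rolled up to their
level-2 parent, giving one node per clinical event rather than per
granular synonym. Unmatched terms become nodes under their fully processed
surface form, with `matched=false` recorded — the artifact runs on an open
stand-in dictionary, so there is no licensing reason to hide the flag. If
one term is reported under different organ systems, the node takes the
majority organ (ties broken lexicographically); rows with a missing organ
fall back to a designated "unknown organ system" node with a warning.

## Drug mentions

Tagging is deterministic lexicon matching: case-insensitive, word-boundary
(no adjacent alphanumerics), longest-match-first, non-overlapping, left to
right. Taggable surfaces are lexicon entries whose tree code passes the
drug-class filter, uncoded curated entries, and known abbreviations. The
class filter accepts dotted codes whose first segment starts with `D` and
which are neither equal to nor dotted descendants of the excluded classes
`D26.310` (combinations), `D26` (preparations), `D23.101` (biomarkers),
`D26.255` (dosage forms); descent is by dotted prefix because the code
tree is hierarchical by dotted prefix.

Mention resolution order: curation override → abbreviation expansion →
lexicon canonical term → generic name → the (expanded) surface itself, so
investigational identifiers absent from the lexicon normalize to
themselves. The studied/used split is a configurable rule: a canonical
term is *studied* for a study when some mention comes from an intervention
record or from the **title** of an arm-defining result group (titles name
the arm's intervention), and *used* when it only appears in free-text
descriptions or non-arm groups — real placebo-arm descriptions routinely
mention rescue medication, which is precisely the auxiliary case. The two
edge sets are disjoint per study; studied wins on conflict. Event-group
sourced mentions additionally produce drug→event-group edges.

## Method names

Three steps: squash (lowercase, strip spaces/punctuation); single-linkage
connected components over squashed forms at edit distance ≤ 3 (single
linkage is the minimal closure of the stated pairwise rule; the chain
a–b–c merges even when a–c is distant, which is flagged as an
interpretation); then merge components whose canonical names have equal
token multisets, catching word-order variants whose squashed forms are
far apart. Each merged component is named by the member raw name with the
highest occurrence count, ties broken lexicographically. A curation
override (raw → forced canonical) applies last, standing in for the manual
correction pass. Semantically different tests with nearby spellings (e.g.
ANOVA vs ANCOVA) would merge under the distance rule alone; the override
hook is the intended remedy, and the synthetic corpus deliberately uses
method bases that are pairwise out of reach.

## Outcome mining and clustering

Abbreviation extraction implements the Schwartz–Hearst candidate rules:
a parenthesized short form of ≤ 2 words, length 2–10, containing a letter,
first character alphanumeric; the long form is found right-to-left in a
window of at most `min(|sf|+5, 2|sf|)` preceding words such that every
short-form character matches in order with the first match word-initial.
Definitions are filtered by eleven instrument words matched as whole words
after punctuation splitting — so "level-dependent" contains "level"
(hyphenated compounds count; this was an open reading and is the more
permissive choice). Variant-override folding and manual additions produce
the standard-outcome set; linking is case-insensitive substring containment
against title or description, and an outcome may link to several standards.

Clustering is repeated-bisection spherical k-means over TF-IDF vectors
(lowercase alphanumeric tokens, the pinned stop-word list, smoothed IDF,
L2-normalized rows), maximizing the summed norm of cluster composite
vectors — the I2-style criterion of the classic document-clustering
toolkits, reimplemented here because the original is a closed binary. Each
bisection takes the best of 8 runs: one deterministic farthest-pair
seeding (the least-similar document pair), the rest random from the seeded
generator; the cluster whose split gains the most criterion is bisected
next. Per cluster, the descriptive percentage of a word is its share of
the squared centroid weights (its contribution to within-cluster
similarity) and the discriminating percentage is its share of the squared
difference between the cluster centroid and the complement centroid; the
top five of each are reported in non-increasing order. For a single
cluster the complement centroid is zero, making the two lists coincide.
The cluster count defaults to `min(200, number of titles)` and is a
parameter, since synthetic corpora are far smaller than a full registry.

## Embeddings

TransE with score `-||v_h + v_r - v_t||` (L2 by default, L1 available).
Training minimizes the margin ranking loss against corrupted negatives by
mini-batch SGD in numpy. Negative sampling corrupts head or tail with
equal probability, uniformly over nodes of the type the relation's schema
permits at that endpoint — stricter than vanilla uniform corruption, and
the right null model for a strongly typed graph (corrupting a
study→condition edge with a measurement node would be trivially
detectable). Entity vectors are renormalized to unit norm after every
epoch; relation vectors are normalized once at initialization.
Initialization is uniform on `±6/√dim`. Defaults: dim 200, margin 1.0,
learning rate 0.01, 200 epochs, one negative per positive, batch 256 —
desk-scale settings in the style of the common KG-embedding toolkits; all
are configurable and everything is deterministic given the seed (tests
and the acceptance script train at dim 16–48 for 30–120 epochs on graphs
of ~200–1,000 nodes, which completes in about a second).

Retrieval is exact top-k by cosine similarity between two node types, with
ties broken by id pair, alongside the mean pairwise similarity of the two
types as the baseline statistic. Repurposing candidates exclude any
condition/drug pair connected through a shared study (study-mediated
co-occurrence via Study-Condition and Study-StudiedDrug/UsedDrug), then
rank the rest by cosine.

## Synthetic corpus

The generator emulates the relational inputs: studies with planted
completeness roles driving the filter cascade (defaults: 60 studies, of
which 20 lack drug interventions, 10 lack analyses, 3 lack conditions —
most exclusions at the drug stage, mirroring the character of the real
cascade at desk scale); reported events whose terms are dictionary
canonicals or variants generated by the cascade's own transformation
classes (parentheticals, listed auxiliary phrases, stop-word/plural
inflections, letter-level misspellings of ≤ 3 edits); drug surfaces drawn
from generic/brand/abbreviation forms of a curated invented lexicon (plus
planted non-drug tree-code entries the tagger must ignore); method-name
variants around pairwise-distant bases; outcome titles drawn from
well-separated topic vocabularies, some defining standard measures via
"(ABBR)" patterns; and co-study structure (two conditions sharing a drug
neighborhood, one additionally treated by a target drug never co-studied
with the other) for the embedding and repurposing checks.

Every planted variant is verified recoverable at generation time using
the text primitives and an independent nearest-term computation — never by
calling the cascade under test — and falls back to the exact term if a
random draw cannot be verified; "unmatchable" terms are planted at a
configurable rate and verified to be out of reach. The AE hierarchy has
levels 1 and 2 only, since only the level-1→2 roll-up is in scope.

What the corpus does **not** emulate: statistical realism of measurements
and p-values, free-text noise beyond the planted transformation classes
(typos in multi-word phrases that cross token boundaries, OCR artifacts,
clinical shorthand), ambiguous drug surfaces shared by two products, or
dictionary scale (dozens of terms, not tens of thousands). Passing tests
therefore demonstrate that the procedures are implemented correctly and
recover everything the stated transformation classes can produce — not
that recovery on real registry text would be complete.

## Numerical and degenerate-input choices

- Dictionary and lexicon matching fold case everywhere; ties in the
  edit-distance rescue break by (distance, lexicographic term).
- Duplicate (group, event) pairs after normalization merge into one edge,
  summing affected counts and keeping the max at-risk count.
- Empty AE terms and empty method tables raise; empty event/outcome
  tables yield empty outputs; `k` outside `[1, n_titles]` raises.
- The filter, assembly and export iterate in sorted order throughout, so
  outputs are independent of input row order and byte-reproducible.
- Float attributes are serialized with `repr` to round-trip exactly.

## Known limitations

- The studied/used rule is syntactic; a drug named in an arm title that
  is actually a comparator background therapy will be labeled studied.
- Single-linkage method merging can chain distinct tests if the name
  space is dense; the override file is the remedy.
- Standard-outcome linking is substring containment and does not attempt
  semantic deduplication beyond the override file.
- TransE ignores node attributes by construction; attribute-aware
  embedding is out of scope.
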