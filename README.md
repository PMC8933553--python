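# trialkg

Build, validate and embed a **knowledge graph of clinical trials** from
AACT-style relational tables (AACT is the public relational database of
studies registered at ClinicalTrials.gov).

Registries store each trial across dozens of normalized tables, which makes
cross-trial inference — "which drugs were studied for which conditions, with
which adverse events and outcomes?" — awkward. `trialkg` turns those tables
into a typed heterogeneous graph with **18 node types** (Study, Condition,
DrugTerm, EventGroup, AdverseEvent, Organ, BaselineGroup, BaselineRecord,
DropGroup, Period, DropRecord, OutcomeGroup, Method, OutcomeMeasurement,
OutcomeAnalysis, Outcome, StandardOutcome, ClusterOutcome) and **21 relation
types**, then trains translational embeddings over the topology for
similarity retrieval and drug-repurposing candidate ranking.

## What the pipeline does

1. **Study filter.** Keep studies with drug interventions, outcome analyses
   and conditions, in that fixed stage order, reporting per-stage exclusion
   counts.
2. **Adverse-event normalization.** A cascade maps reported AE terms onto a
   leveled dictionary (a MedDRA-style hierarchy): direct lookup → strip
   parentheticals → remove auxiliary words/phrases ("left", "Baseline
   Phase", "for 12 hours") → stop-word removal + lemmatization → nearest
   dictionary term within Levenshtein distance ≤ 3. Matched terms at the
   most granular level are rolled up to their level-2 parent, so "Eye
   itching" and "Ocular itching" collapse onto one "itchy eyes" node, each
   linked to exactly one organ-system node.
3. **Drug normalization.** A deterministic lexicon tagger (case-insensitive,
   word-boundary, longest-match) finds drug mentions in intervention names
   and group titles/descriptions; a tree-code class filter keeps codes in
   the chemicals-and-drugs branch while excluding preparation / combination /
   biomarker / dosage-form classes; abbreviation → canonical term → generic
   name resolution collapses "losartan potassium", "cozaar" and "losartan"
   onto one drug-term node. Per study, drugs split into *StudiedDrug*
   (intervention or arm-title mentions) and *UsedDrug* (auxiliary mentions,
   e.g. rescue pain medication).
4. **Method normalization.** Statistical test names are squashed (lowercase,
   punctuation removed), merged by single-linkage over edit distance ≤ 3,
   refined by merging names with identical word multisets ("paired t-test"
   vs "t-test, paired"), and each group is named by its highest-frequency
   spelling.
5. **Outcome mining and clustering.** The Schwartz–Hearst rules extract
   abbreviation/definition pairs from outcome titles ("Gingival Health
   Measured by Bleeding Index (BI)" → "Bleeding Index"); definitions
   containing one of eleven instrument words (scale, index, score, test,
   questionnaire, value, count, inventory, assessment, level, rate) become
   standard-outcome nodes linked by substring containment. All titles are
   additionally clustered by repeated-bisection spherical clustering of
   TF-IDF vectors, each cluster summarized by 5 descriptive and 5
   discriminating words with percentages.
6. **Embedding analysis.** A TransE model (score `-||v_h + v_r - v_t||`,
   margin ranking loss, typed negative sampling, numpy SGD) embeds the
   graph; cosine similarity over the embeddings drives retrieval, and
   repurposing candidates are condition/drug pairs with high similarity and
   no existing co-study link.

A seeded synthetic-data module generates AACT-like tables, an open stand-in
AE hierarchy and a drug lexicon, with known ground truth behind every
planted paraphrase — so the whole pipeline is testable without downloads or
licensed vocabularies.

## Worked example

```bash
trialkg pipeline --out demo --seed 7
```

```
pipeline complete: 934 nodes, 1500 edges, manifest in demo
```

The manifest records the filter cascade: of 60 generated studies, 20 were
excluded for lacking drug interventions, 10 for lacking outcome analyses
and 3 for lacking conditions, keeping 27:

```json
"kept_studies": 27,
"exclusions": {
 "no_drug_intervention": 20,
 "no_outcome_analysis": 10,
 "no_condition": 3
}
```

`trialkg stats --graph demo/graph` prints per-type node counts (27 Study,
12 Condition, 14 DrugTerm, 24 AdverseEvent, 8 Organ, 54 Outcome, ...) and
per-relation unique-head/unique-tail/edge counts. Repurposing retrieval
ranks condition–drug pairs by embedding cosine similarity after removing
co-studied pairs:

```bash
trialkg repurpose --embeddings demo/embeddings.tsv --graph demo/graph -k 5
```

```
mean Condition-DrugTerm cosine similarity: -0.003
0.522   condition:essential hypertension        drugterm:ibuprofen
0.500   condition:type 2 diabetes mellitus      drugterm:telaprevir
0.293   condition:chronic hepatitis c           drugterm:diclofenac
0.135   condition:rheumatoid arthritis          drugterm:sertraline
0.105   condition:psoriasis                     drugterm:ibuprofen
```

Pairs score far above the type-pair mean (−0.003) exactly when the two
nodes share study neighborhoods; the generator plants such structure (two
conditions treated with the same drug set), and the planted pair surfaces
at the top of this list. Other subcommands (`synth`, `build`, `validate`,
`normalize-ae`, `normalize-drugs`, `normalize-methods`, `extract-outcomes`,
`cluster-outcomes`, `embed`, `retrieve`) run each stage independently; see
`trialkg --help`.

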