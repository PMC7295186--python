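# Methods

This note records the model underlying `litjump`, the defaults that matter,
the numerical choices, and what the synthetic-data tests do and do not
demonstrate.

## Model and assumptions

The pipeline treats an abstract corpus as a weekly stream of bags of
normalized tokens. All statistics are **document-level presence/absence**:
a protein mentioned five times in one abstract counts once. This matches
the downstream use (co-mentioning between terms and entities) and makes
every count a simple set cardinality over posting sets.

The core modelling assumption is distributional: phrases that are used in
the same documents as known disease proteins — or in the same *company* of
other phrases — carry disease relevance even when the disease itself is not
named. Relevance is therefore anchored twice: once through the core-protein
set (Fisher-ranked co-mentioning with the disease) and once through the
concept weights (average PMI of a concept with that core set).

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `K` | 100 | core-set size. The anchor set for concept weighting. On corpora whose protein universe is small (e.g. the synthetic corpus with 10 planted disease proteins), `K` must be set near the number of genuinely associated proteins: a too-large `K` dilutes the core set with unassociated proteins whose near-zero co-mention PMI drives all concept weights negative. |
| `n_range` | (2, 6) | n-gram lengths. Unigrams are excluded: single words are covered by NER and dominated by noise; concepts of interest are multi-word phrases. |
| `min_df` | 5 | minimum document frequency for an n-gram. |
| `min_co`, `min_ratio`, `filter_alpha` | 3, 2.0, 0.01 | the disease over-representation filter: co-document count, observed/expected ratio, one-sided Fisher p. |
| `string_threshold` | 0.8 | token-set string similarity needed for an edge. Tokens match when equal after roman/arabic numeral aliasing or within one edit (tokens of length ≥ 4); similarity is the maximum bipartite matching size divided by the longer phrase's length. |
| `context_threshold` | 0.5 | cosine (after log1p) between over-representation matrix rows, excluding the pair's own columns. |
| `lam` | 0.5 | convex combination of the two similarities for MCL edge weights; the edge *exists* when either measure passes its threshold (union rule), so both act simultaneously. |
| `inflation` | 2.0 | MCL inflation; self-loops are set to each node's maximum incident weight (1.0 for isolated nodes). |
| `W`, `M` | 260, 40 | combined relevance window (five years of weeks) and the number of top weekly scores blended. Weights decrease linearly, u_i = (M+1−i)/Σ(M+1−j), so they sum to 1 and a constant series reproduces its constant. Missing weeks count as zero inside the window, capping what a single week can contribute at u₁ ≈ 4.9 % of its article score. |
| `jump_alpha` | 0.05 | weekly high-jumper report threshold. |
| pooling rule | max(5, round(0.1·r)) | half-width of the rank window used to pool historical jumps around initial rank r: tight near the top (where a 3-place gain is already rare), wide in the tail (where jumps of hundreds of places occur). |

## Numerical choices

* **Log base.** Concept weights use log₁₀, fixing the interpretation
  "weight 1 ⇔ ten times the expected co-mentioning".
* **Zero co-mention floor.** If a concept never co-occurs with a core
  protein, its observed count is floored at 0.5 before the log so the PMI
  stays finite (applied only when obs = 0).
* **Degenerate Fisher margins.** If one entity is mentioned in no
  document, the one-sided p-value is 1 by convention (logged).
* **Empirical jump p-values** use the add-one estimator
  (1 + #{history ≥ j})/(1 + N): no jump receives p = 0, and the estimate is
  valid (conservative) under exchangeability. The evaluation week is
  excluded from its own null history. Only upward jumps are tested;
  no multiple-testing correction is applied across the weekly protein
  universe (flagged in the config as `multiple_testing: none`).
* **Ties.** All rankings break ties by ascending protein id; MCL cluster
  representatives break document-frequency ties lexicographically. Both
  make reruns bit-identical.
* **MCL convergence.** Expansion (power 2) and inflation iterate until the
  largest entry change is below 1e-6 or 200 rounds; at the cap the current
  hard partition is returned with a warning. Attractors that retain flow
  into one another are merged, and every column is assigned to its maximal
  attractor, so the output partitions the node set even without full
  convergence.
* **Top-M weighting.** Only the linear scheme is implemented; the config
  key `top_m_weighting` exists so an alternative (e.g. geometric) is an
  explicit, validated choice rather than a silent change.
* **Week indexing.** Calendar dates map to Monday-aligned ISO weeks counted
  from the first ISO week of 1970 — monotone with calendar time, which is
  all the windowing requires.

## The synthetic corpus: what it emulates, and what it does not

`litjump.synthetic` generates the study conditions used throughout the
tests: 60 weeks × 50 abstracts of 15–30 filler tokens; five phrase families
each consisting of a canonical phrase, a word-order variant, a one-edit
misspelling, a *context member* (shares the family's partner phrases but
never co-occurs with the other members), and two partner phrases; a protein
universe of 1 star + 9 disease-linked proteins (disease-topic mention rate
0.12–0.6), 40 background proteins (0.01), and a 100-protein zero-score tail
mentioned only outside disease-topic documents; disease-topic probability
0.3 per document with disease-term rate 0.6 (0.02 in background documents);
and one jumper event — a quiescent tail protein that appears at week 50 in
a single document packed with members and partners of four families. These
sizes keep a full 20-seed recovery study within a few minutes on one CPU
while leaving every planted effect well above the filter thresholds in
expectation.

The generator reproduces the *statistical* skeleton the method relies on —
document-level co-occurrence structure, phrase variants, context sharing,
rank dynamics — and nothing else. Filler tokens are arbitrary symbols, not
English; there is no grammar, no abbreviation ambiguity, no synonym
polysemy, no NER false positives, and the corpus is two orders of magnitude
smaller than a real abstract database. Passing recovery tests therefore
show that the pipeline's statistics and clustering behave as designed under
controlled conditions; they do not certify NER quality or threshold choices
on real text.

Planted partner phrases are deliberately not assigned to any ground-truth
family: they exist to create shared context, and the clustering may
legitimately keep them separate or attach them to the family they serve.
Family recovery is scored on the member/context keys only; a planted key
dropped by the over-representation filter is scored as unrecovered.

## Design decisions that were genuinely open

* **"Simultaneously" combining two similarities** is realized as the union
  edge rule plus the λ-combination for flow weights. Alternatives
  (intersection rule, product weights) would demand both signals at once
  and empirically shatter variant groups whose context evidence is weak.
* **Jumper scenario.** The planted jumper is a protein absent from
  disease-topic literature before its week. An early design gave the
  jumper a small ongoing topic rate, but a protein already drifting in the
  upper ranks cannot exhibit a large jump, which contradicts the scenario
  the detector targets (a sudden first strong association); the quiescent
  design, with the deep static tail it requires, models that scenario
  directly.
* **Singleton concepts are kept.** An n-gram with no similar partner
  becomes a one-member concept rather than being dropped; it may still
  carry weight and contribute to scores.
* **Core selection uses raw p-values** (no multiple-testing correction):
  the top-K ranking only needs the order, which any monotone correction
  preserves.

## Known limitations

* The all-pairs context-similarity step is dense O(n²·d); it is intended
  for the filtered catalog (10²–10⁴ n-grams), not for millions.
* Concepts may mix antonyms ("increased/decreased glucose") by design;
  polarity-sensitive applications need a downstream split.
* Entity dictionaries are matched case-insensitively after tokenization;
  short ambiguous gene symbols will produce false positives on real text.
* With fewer mentioned proteins than `K`, the core set is truncated with a
  warning, and concept weights then average over fewer anchors.
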