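# litjump

Data-driven literature-relevance scoring and rank-jump surveillance for
early drug-target discovery.

Keeping up with a disease area like type 2 diabetes means triaging hundreds
of potentially relevant abstracts per week — including the ones that never
mention the disease by name because they discuss its underlying molecular
biology (insulin resistance, glucose homeostasis, a co-morbidity). `litjump`
implements a pipeline that learns the relevant terminology from the corpus
itself instead of relying on a fixed vocabulary, scores every article with
it, tracks per-protein relevance ranks week by week, and raises a flag when
a protein's rank jumps by an amount that is statistically surprising given
how jumps from similar ranks have behaved historically. It is written for
computational biologists and text-mining engineers who run weekly literature
surveillance over a MEDLINE-style abstract stream.

## Method

1. **Core proteins.** Dictionary NER finds protein and disease mentions in
   each abstract. For every protein *P* a 2×2 document-level contingency
   table against the disease *T* is tested with a one-sided Fisher's exact
   test; the *K* = 100 proteins with the smallest p-values are the *core
   proteins*.
2. **n-grams.** All token windows of length 2–6 occurring in ≥ 5 documents
   (and not bounded by stopwords) are extracted with exact posting sets,
   then filtered to those over-represented in disease-mentioning documents
   (co-document count ≥ 3, observed/expected ratio ≥ 2, Fisher p ≤ 0.01).
3. **Semantic concepts.** Two similarity measures are built between
   n-grams: a string similarity that absorbs spelling variants and word
   rearrangements ("type 2 diabetes" ↔ "diabetes type ii"), and a context
   similarity — cosine between rows of the pairwise over-representation
   matrix *R*ᵢⱼ = co(i,j)·D / (dfᵢ·dfⱼ) — that links phrases used in the
   same company even if they never co-occur ("leptin treatment" ↔
   "elevated leptin"). Edges where either measure passes its threshold are
   clustered with the Markov cluster algorithm (MCL, inflation 2.0) into
   *semantic concepts*.
4. **Concept weights and article scores.** Each concept *c* is weighted by
   its average pointwise mutual information with the core set:
   *w*(*c*) = (1/K) Σₚ log₁₀(obs(*c*,*p*) / exp(*c*,*p*)), so *w* = 1 means
   "co-mentioned ten times as often as expected by random". An article's
   score is the sum of the weights of the distinct concepts it contains —
   fully explainable, concept by concept.
5. **Protein relevance and ranks.** A protein's weekly score is the highest
   score of an article mentioning it that week. Its combined (five-year)
   relevance at week *t* blends the top *M* = 40 of the last *W* = 260
   weekly scores with linearly decreasing weights, so relevance must be
   sustained rather than come from a single conference week. Proteins are
   ranked (1 = most relevant) every week.
6. **High-jumpers.** A rank change *j* = r₀ − r₁ from initial rank r₀ is
   assigned the empirical p-value
   p = (1 + #{historical jumps ≥ *j* starting near r₀}) / (1 + N),
   pooling history over the rank window r₀ ± max(5, 0.1·r₀). Upward jumps
   with small p are the week's *high-jumpers* — proteins suddenly mentioned
   in a highly relevant article.

A seeded synthetic-corpus generator plants phrase families (with spelling
and word-order variants and context-sharing members), core proteins with
controlled disease co-mention rates, and a single jumper event, so every
stage of the pipeline can be validated against known ground truth.

## Worked example

Run the full staged pipeline on the built-in synthetic corpus (3,001
abstracts over 60 weeks, 150 proteins, 5 planted phrase families, one
planted jumper):

```sh
cat > demo.yaml <<EOF
workdir: demo_out
K: 10
seed: 0
EOF
litjump run-all -c demo.yaml
```

The top of `demo_out/concepts.tsv` shows the recovered concepts and their
PMI weights:

```
concept_id  representative     weight    abstract_count
C00001      oral challenge     0.533709  193
C00004      beta cell          0.466914  178
C00003      adipose tissue     0.465210  187
```

A weight near 0.5 means those phrases appear with the core proteins about
10^0.5 ≈ 3 times as often as chance. `demo_out/high_jumpers.tsv` contains
the planted jump, found at its planted week:

```
week  protein_id  initial_rank  new_rank  jump  p_value      trigger_doc_id
50    tp50        101           47        54    0.000970874  jump_tp50_050
```

Protein `tp50` had never been mentioned in a disease-relevant context
(static rank 101); one article packed with high-weight concepts lifted it
54 places, a jump never seen from that rank band in 49 weeks of history
(p = 1/1030 ≈ 0.00097). The triggering article is explainable down to its
matched phrases:

```sh
$ litjump explain-article jump_tp50_050 --workdir demo_out
article jump_tp50_050: score 1.821
   +0.4669  C00004  [beta cell]        matched: glucose homeostasis, islet function
   +0.4652  C00003  [adipose tissue]   matched: adipose tissue, insulin resistance
   +0.4623  C00002  [hepatic steatosis] matched: lipid metabolism, lipoprotein lipase
   +0.4270  C00005  [energy expenditure] matched: hypothalamic neurons, leptin signaling
```

`demo_out/roc.tsv` reports AUC = 1.0 for recovering the planted
disease-linked proteins from the combined relevance scores.

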