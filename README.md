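# netphen

Network-based prioritization of disease candidate genes from text-mined
phenotype profiles, scored with a random-set enrichment statistic.

## The problem

After a mapping or association study points at a genomic region, tens to
hundreds of positional candidate genes remain, many of unknown function.
`netphen` ranks such candidates by asking how strongly the literature
around each candidate's *protein complex* resembles the textual description
of the disease:

1. **Phenotype profiles.** Every biomedical document (a disease catalogue
   entry, an abstract, an annotation note) arrives as term-annotated counts
   over a controlled vocabulary. Terms are filtered — by one source
   vocabulary (MeSH, ICD9CM, GO) or by a whitelist of semantic types — and
   weighted by TF-IDF: `w(t, d) = (n_td / n_d) · ln(E / df_t)`.
2. **Semantic similarity.** The element-level score of document *e* is the
   cosine coefficient `S_e = cos(v_disease, v_e) ∈ [0, 1]` between the
   disease vector and the document vector, both in the same idf space.
3. **Candidate complexes.** Each candidate gene is expanded into the gene
   plus its first-order interaction partners whose combined confidence
   score (STRING-style, 150–999, a noisy-OR over evidence channels) meets a
   threshold. The complex collects the `m` documents linked to its member
   genes. The text-mining evidence channel can be excluded and the combined
   scores recomputed, avoiding circularity with literature-derived profiles.
4. **Random-set score.** With `S_1..S_E` the full profile and `C` the
   complex's document set, the enrichment is the set mean
   `X̄ = (1/m) Σ_{e∈C} S_e`. Under uniform sampling of `m` documents
   without replacement, exactly

       μ = (1/E) Σ S_e,    Var(X̄) = (σ²/m) · (E − m)/(E − 1)

   with population variance σ², and the disease relevance score is
   `Z = (X̄ − μ) / √Var(X̄)` — standard normal under the null of no
   association, large and positive when the complex's literature is
   enriched for disease-like documents.
5. **Validation.** Each known disease–gene pair becomes a test case: a
   100-gene positional test set around the causal gene (50 upstream, 49
   downstream flanking genes; telomere deficits compensated), known
   disease–gene annotations masked, candidates ranked by `Z` and classified
   against discriminator cut-offs taken from the empirical null `Z`
   distribution, yielding recall, precision, MCC, ROC/AUC and top-1/top-5
   recovery counts.

A fully seeded synthetic-world generator (documents, vocabulary, gene
links, scored interaction network, diseases with planted causal modules)
makes the whole pipeline testable end to end without any external data.

## Worked example

Generate a synthetic world (5 planted disease modules among 360 genes at
the default noisy signal level) and run the evaluation protocol at an
interaction-confidence threshold of 700:

```sh
netphen simulate --seed 7 --out-dir demo/world
# world written to demo/world (907 documents, 714 edges)

netphen validate --world-dir demo/world --threshold 700 --seed 1 \
    --out-dir demo/eval
```

which prints the evaluation summary (also written to
`demo/eval/evaluation.json`):

```json
{"auc": 0.8261261261261261, "rank_auc": 0.8265765765765766,
 "coverage": 1.0, "top1_fraction": 0.4, "top5_fraction": 0.6,
 "best_cutoff": 3.081659964112, "best_mcc": 0.44521262977849774,
 "best_precision": 1.0, "best_recall": 0.2}
```

Read: across the 5 test cases the discriminator-sweep ROC has AUC 0.83
(matching the grid-free rank-statistic AUC 0.83); every causal gene was
scorable (coverage 1.0); 2 of 5 causal genes ranked first and 3 of 5 in
the top five of their 100-gene test sets; the cut-off maximizing MCC
(z ≈ 3.08) classifies with precision 1.0 at recall 0.2. Other subcommands:
`build-profiles` (element-level similarities of one disease), `score`
(relevance scores of every gene), `sweep-thresholds` (the same protocol
across a confidence-threshold grid).

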