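# Methods

## Model and procedure

`netphen` scores the association between a disease and a candidate gene in
four stages.

**Phenotype profiles.** Documents are term-annotated counts over a
controlled vocabulary; the package never performs concept recognition
itself (a deliberately simple leftmost-longest dictionary matcher,
`naive_concept_map`, is available for ad-hoc free text). Before weighting,
terms are filtered either to one source vocabulary or to a whitelist of
semantic types; filtering can empty a document, and empty documents are
*retained* — they are still linked documents, contribute similarity 0, and
keep the complex set size `m` honest. TF-IDF uses the classical form
`tf = count / document length`, `idf = ln(E / df)` with natural log and no
smoothing; `df` is recounted on the *filtered* cohort, so the filter
choice defines the vector space. Disease records are weighted with the idf
table of the gene-document cohort they are compared against: similarities
must live in a single space. A term present in every document has idf 0
and vanishes from every vector.

**Similarity.** The element-level score `S_e` is the cosine coefficient of
the disease vector and the vector of document `e`. Weights are
non-negative, so `S_e ∈ [0, 1]`; any zero-norm vector gives similarity 0
rather than NaN (an empty document carries no signal). Pearson correlation
over the full vocabulary dimension is available as a sensitivity
alternative only; cosine is the measure used throughout.

**Candidate complexes.** A complex is the seed gene plus first-order
neighbours with combined confidence ≥ threshold. Combined scores follow
the STRING convention: integers in 150–999, interpretable as probabilities
s/1000 integrated across evidence channels by a noisy-OR after removing a
prior probability of random interaction. `recombine_excluding` inverts
this: remaining channels are prior-corrected
(`p_i = max(0, (s_i/1000 − prior)/(1 − prior))`), combined as
`1 − Π(1 − p_i)`, and the prior is re-added. The prior defaults to 0.063,
a documented convention for this score family, and is configurable; with a
single remaining channel the operation is an identity for any prior.
Genes absent from the network form singleton complexes — prioritization is
not restricted to genes with known interactions; genes whose complex links
no documents (`m = 0`) are unscorable and reported separately as coverage
loss. A document linked to several members counts once by default (the
random-set model draws sets of distinct documents; double counting would
break the variance formula); a multiset variant is exposed for comparison.

**Random-set score.** Conditional on the full profile `{S_e}`, the mean of
a uniform random `m`-subset drawn without replacement has exact moments
`μ = mean(S)` and `Var(X̄) = (σ²/m)(E − m)/(E − 1)` with *population*
variance σ² (the finite-population correction of simple random sampling);
these are verified against exhaustive enumeration over all `C(E, m)`
subsets in the tests, which pins the variance convention. The relevance
score is `Z = (X̄ − μ)/√Var(X̄)`. Degenerate cases — constant profile, or
`m = E` where `X̄ ≡ μ` — carry no distinguishable signal and are defined
as `Z = 0` and flagged.

**Evaluation protocol.** Each known disease–gene pair yields a positional
test set of 100 candidates *including* the causal gene: 50 upstream and 49
downstream flanking genes, deficits near a telomere compensated on the
opposite side. (The alternative reading — causal + 50/50 = 101 genes — is
available via `full_flanks=True`; the 100-gene reading keeps the set size
invariant exact.) Before scoring, every candidate gene's links to disease
phenotype records are removed, so known disease annotations cannot leak
into profiles. Candidates are ranked by descending `Z` with ties taking
the worst rank (conservative); a case with an unscorable causal gene is
excluded from top-k numerators but kept in denominators and reported as
coverage. Discriminator cut-offs are empirical quantiles of a null `Z`
sample obtained by scoring random document sets with sizes matched to the
observed complexes (1000 replicates per disease by default). A grid value
`q ∈ (0, 1]` is the *fraction of the null that passes*: the cut-off is the
quantile at level `1 − q`, so `q = 1` is the all-pass cut-off (recall 1 by
construction) and `q = 0.001` passes only the extreme upper tail. The
sweep yields confusion counts (`tp`/`fn` from causal genes above/below the
cut-off, `fp`/`tn` from non-causal candidates), recall, precision, MCC
(defined 0 whenever a confusion marginal is empty), ROC points anchored at
(0,0) and (1,1), trapezoidal AUC, and the cut-off maximizing MCC. The
sweep AUC is cross-checked against the rank-statistic (Mann–Whitney) AUC
computed independently via scikit-learn.

## Synthetic worlds

The generator emulates the statistical structure of the real inputs:
gene–document link tables, term annotations with vocabulary and
semantic-type metadata, a channel-scored interaction network, disease
records and a truth table. Key choices:

- **Zipf background** (exponent 1.1) for background term usage, mimicking
  the heavy skew of controlled-vocabulary frequencies in biomedical
  corpora.
- **Planted modules**: cliques of 6 genes with within-module combined
  scores 850–990 (carried on the experimental channel); background edges
  appear with probability 0.01 at scores 150–500 on the text-mining
  channel, so excluding that channel removes exactly the background.
- **Signal blocks**: each module owns a disjoint block of 12 terms; a
  fraction `signal_frac` of each module document's tokens comes from its
  block, and each disease record shares the block of exactly one module,
  whose hub is the causal gene. `signal_frac = 1` with disjoint blocks is
  the perfect-signal limit; `signal_frac = 0` (or `null_world`) removes
  the signal entirely.
- **Default signal level 0.05** (1–3 signal tokens in a 20–60-token
  document). At this level prioritization is good but imperfect — ROC AUC
  around 0.8, top-1 recovery around 0.3–0.5 — the difficulty regime
  reported for real corpora, so that metric machinery is exercised away
  from its saturation points.
- **Module genes are literature-rich** (2–5 documents each) while
  background genes have 0–5; disease-implicated genes are in reality
  well studied, and this guarantees causal genes remain scorable at every
  threshold.
- **Gene order**: same-module genes are placed ≥ `n_genes / module_size`
  positions apart (complex partners are rarely chromosomal neighbours),
  and each disease's causal hub is chosen as the member whose 100-gene
  positional window contains no module partner. This makes the
  perfect-signal recovery property exact rather than tie-prone.
- **Disease records are cohort documents** and the causal gene is linked
  to its disease's record — the leakage that the protocol's masking step
  must remove; tests rely on this to exercise masking.
- A single mandatory seed is expanded through `SeedSequence.spawn` into
  per-component substreams (terms, documents, network, diseases, order).

What the generator does **not** emulate: natural language (terms are
symbols, not words), hierarchical vocabulary structure, citation dynamics,
gene-length or study-bias effects, overlapping complexes, and score
correlations between evidence channels. Passing tests therefore
demonstrate correctness of the statistical machinery and faithful
qualitative behaviour (signal recovery, null calibration, threshold
trends), not performance on any real corpus.

## Numerical choices and edge cases

- Cosine clamps floating-point overshoot to 1.0; zero-norm → 0.
- `Z` degeneracy (σ² = 0 or m ≥ E) → 0, flagged.
- Quantile convention for discriminators as above (fraction passed).
- Ties in ranking: worst rank (`#{z_j ≥ z_causal}`).
- Trapezoidal AUC on de-duplicated, endpoint-anchored ROC points; the
  default 500-point quantile grid keeps the gap to the rank-based AUC
  around 10⁻³ on the synthetic benchmark.
- Edges are canonicalized to (min, max) endpoint order; conflicting
  duplicate rows are an error, identical duplicates are collapsed.
- Recombined combined-scores below 150 drop the edge (lowest reportable
  confidence), mirroring how scored networks are distributed.

## Problem sizes

The shipped tests and the acceptance script run entirely on generated
worlds of 360–700 genes, ~900–2100 documents and 5 diseases, with 5000
null replicates for calibration and 20 replicate worlds for null recovery
rates. These sizes give Monte-Carlo error comfortably inside the asserted
bands (e.g. sd of the null-z mean ≈ 0.014 against a ±0.05 band) while the
whole suite completes in well under a minute.

## Known limitations

- The enrichment z is exactly calibrated in its first two moments for any
  profile, but its finite-`m` distribution is skewed when the similarity
  distribution is skewed; ranking genes with very different `m` against
  each other therefore carries a mild structural bias (visible as
  null-world AUC slightly above 0.5) that the original protocol shares.
- Per-channel score recombination assumes channel independence (noisy-OR)
  and a single global prior.
- The evaluation treats each test case independently; diseases sharing
  causal genes are not pooled.
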