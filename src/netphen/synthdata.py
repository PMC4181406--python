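"""Synthetic worlds with planted disease modules.

A *world* bundles everything the prioritization pipeline consumes: a
term-annotated document cohort with gene links, a confidence-scored
interaction network, disease phenotype records, a disease–causal-gene truth
table and a positional gene order.  Signal is planted as *modules*: small
groups of genes that are densely connected at high confidence and whose
linked documents draw part of their terms from a module-specific block of
"signal" terms.  Each disease record shares the signal block of exactly one
module, and that module's hub gene is the disease's causal gene.

Background documents draw terms from a Zipf-skewed frequency distribution
(exponent ~1.1), mimicking the heavy skew of controlled-vocabulary usage in
biomedical corpora.  Disease records are part of the document cohort and the
causal gene is linked to its disease's record — the annotation leakage that
the validation protocol's masking step removes.

Same-module genes are placed at least ``n_genes / module_size`` positions
apart in the gene order, reflecting that members of a protein complex are
rarely chromosomal neighbours; a causal gene's positional test set therefore
contains background genes rather than its own interaction partners.

All randomness flows from a single mandatory seed, expanded into independent
per-component substreams so that changing one component's draws never
perturbs the others.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .network import PpiEdge, CHANNELS
from .textmine import DocumentAnnotation, DocumentCohort, TermRecord

__all__ = [
    "SynthConfig",
    "World",
    "RELEVANT_SEMANTIC_TYPES",
    "IRRELEVANT_SEMANTIC_TYPES",
    "generate_world",
    "null_world",
]

#: Semantic types retained by the default semantic-type filter.
RELEVANT_SEMANTIC_TYPES = (
    "Disease or Syndrome",
    "Sign or Symptom",
    "Gene or Genome",
    "Cell Function",
    "Pathologic Function",
)

#: Semantic types a curator would drop as irrelevant to phenotype.
IRRELEVANT_SEMANTIC_TYPES = (
    "governmental or regulatory activity",
    "Intellectual Product",
)

VOCABS = ("MeSH", "ICD9CM", "GO")


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters of a synthetic world.

    The defaults describe a mid-sized corpus with a deliberately noisy
    planted signal: 5 disease modules of 6 genes among 360 genes, documents
    of 20–60 term tokens, and 5% of a signal document's tokens drawn from
    its module's signal block.  At these settings prioritization is good but
    imperfect (ROC AUC around 0.8, top-1 recovery around 0.3–0.5), the
    difficulty regime reported for real corpora; ``signal_frac=1.0`` with
    its disjoint per-module blocks gives the perfect-signal limit and
    ``signal_frac=0.0`` (or :func:`null_world`) the no-signal null.
    """

    seed: int
    n_terms: int = 500
    n_genes: int = 360
    n_chromosomes: int = 2
    docs_per_gene: tuple[int, int] = (0, 5)
    module_docs_per_gene: tuple[int, int] = (2, 5)
    n_modules: int = 5
    module_size: int = 6
    n_diseases: int = 5
    signal_frac: float = 0.05
    disease_signal_frac: float | None = None   # None -> signal_frac
    signal_block_size: int = 12
    zipf_exponent: float = 1.1
    doc_length: tuple[int, int] = (20, 60)
    within_module_score: tuple[int, int] = (850, 990)
    background_score: tuple[int, int] = (150, 500)
    background_edge_prob: float = 0.01
    vocab_probs: tuple[float, float, float] = (0.55, 0.25, 0.30)
    irrelevant_type_frac: float = 0.15

    def __post_init__(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise ConfigurationError(
                f"{self.n_modules} modules of {self.module_size} genes do "
                f"not fit in {self.n_genes} genes")
        if self.n_diseases > self.n_modules:
            raise ConfigurationError(
                f"{self.n_diseases} diseases need at least as many modules "
                f"({self.n_modules} available)")
        if not (0.0 <= self.signal_frac <= 1.0):
            raise ConfigurationError("signal_frac must lie in [0, 1]")
        if self.n_modules * self.signal_block_size >= self.n_terms:
            raise ConfigurationError(
                "signal blocks exhaust the vocabulary; increase n_terms")
        if self.n_genes < self.n_chromosomes * 101:
            raise ConfigurationError(
                "need >= 101 genes per chromosome for 100-gene test sets")


@dataclass
class World:
    """One generated dataset (see module docstring)."""

    cohort: DocumentCohort
    edges: list[PpiEdge]
    disease_docs: dict[str, DocumentAnnotation]
    truth: list[tuple[str, str]]
    gene_order: list[tuple[str, str, int]]
    config: SynthConfig | None
    modules: list[list[str]] = field(default_factory=list)


def _zipf_probs(n: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    p = ranks ** (-exponent)
    return p / p.sum()


def _draw_doc(
    rng: np.random.Generator,
    length: int,
    background_terms: np.ndarray,
    background_p: np.ndarray,
    signal_terms: np.ndarray | None,
    signal_frac: float,
) -> dict[str, int]:
    n_signal = int(round(signal_frac * length)) if signal_terms is not None \
        else 0
    tokens: list[str] = []
    if n_signal > 0:
        tokens.extend(rng.choice(signal_terms, size=n_signal))
    n_back = length - n_signal
    if n_back > 0:
        tokens.extend(rng.choice(background_terms, size=n_back,
                                 p=background_p))
    return dict(Counter(tokens))


def generate_world(config: SynthConfig) -> World:
    """Generate a complete world; byte-identical for identical (seed, config)."""
    ss = np.random.SeedSequence(config.seed)
    rng_terms, rng_docs, rng_net, rng_dis, rng_order = (
        np.random.default_rng(s) for s in ss.spawn(5))

    # --- vocabulary -------------------------------------------------------
    n_signal_terms = config.n_modules * config.signal_block_size
    n_background = config.n_terms - n_signal_terms
    term_ids = [f"T{i:05d}" for i in range(config.n_terms)]
    term_table: dict[str, TermRecord] = {}
    all_types = RELEVANT_SEMANTIC_TYPES + IRRELEVANT_SEMANTIC_TYPES
    n_rel = len(RELEVANT_SEMANTIC_TYPES)
    type_p = np.concatenate([
        np.full(n_rel, (1 - config.irrelevant_type_frac) / n_rel),
        np.full(len(IRRELEVANT_SEMANTIC_TYPES),
                config.irrelevant_type_frac / len(IRRELEVANT_SEMANTIC_TYPES)),
    ])
    for tid in term_ids:
        vocabs = {v for v, p in zip(VOCABS, config.vocab_probs)
                  if rng_terms.random() < p}
        if not vocabs:
            vocabs = {"MeSH"}
        sty = str(rng_terms.choice(np.asarray(all_types, dtype=object),
                                   p=type_p))
        term_table[tid] = TermRecord(term_id=tid,
                                     source_vocabs=frozenset(vocabs),
                                     semantic_type=sty)
    background_terms = np.asarray(term_ids[:n_background], dtype=object)
    background_p = _zipf_probs(n_background, config.zipf_exponent)
    blocks = [np.asarray(term_ids[n_background + i * config.signal_block_size:
                                  n_background + (i + 1) * config.signal_block_size],
                         dtype=object)
              for i in range(config.n_modules)]

    # --- genes and modules ------------------------------------------------
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    modules = [genes[i * config.module_size:(i + 1) * config.module_size]
               for i in range(config.n_modules)]
    module_of = {g: i for i, mod in enumerate(modules) for g in mod}

    # --- documents and gene links -----------------------------------------
    annotations: list[DocumentAnnotation] = []
    gene_links: dict[str, set[str]] = {g: set() for g in genes}
    doc_counter = 0
    lo_len, hi_len = config.doc_length
    for g in genes:
        mod = module_of.get(g)
        lo, hi = (config.module_docs_per_gene if mod is not None
                  else config.docs_per_gene)
        n_docs = int(rng_docs.integers(lo, hi + 1))
        for _ in range(n_docs):
            doc_id = f"D{doc_counter:06d}"
            doc_counter += 1
            length = int(rng_docs.integers(lo_len, hi_len + 1))
            counts = _draw_doc(
                rng_docs, length, background_terms, background_p,
                blocks[mod] if mod is not None else None,
                config.signal_frac)
            annotations.append(DocumentAnnotation(doc_id=doc_id,
                                                  counts=counts))
            gene_links[g].add(doc_id)

    # --- interaction network ----------------------------------------------
    edges: list[PpiEdge] = []
    lo_w, hi_w = config.within_module_score
    for mod in modules:
        for i in range(len(mod)):
            for j in range(i + 1, len(mod)):
                score = int(rng_net.integers(lo_w, hi_w + 1))
                ch = {c: 0 for c in CHANNELS}
                ch["experimental"] = score
                edges.append(PpiEdge(protein_a=mod[i], protein_b=mod[j],
                                     channel_scores=ch,
                                     combined_score=score))
    module_pairs = {(min(a, b), max(a, b))
                    for mod in modules
                    for a in mod for b in mod if a != b}
    lo_b, hi_b = config.background_score
    n = config.n_genes
    iu, ju = np.triu_indices(n, k=1)
    mask = rng_net.random(iu.size) < config.background_edge_prob
    for a_idx, b_idx in zip(iu[mask], ju[mask]):
        a, b = genes[a_idx], genes[b_idx]
        if (a, b) in module_pairs:
            continue
        score = int(rng_net.integers(lo_b, hi_b + 1))
        ch = {c: 0 for c in CHANNELS}
        ch["textmining"] = score
        edges.append(PpiEdge(protein_a=a, protein_b=b,
                             channel_scores=ch, combined_score=score))

    # --- gene order --------------------------------------------------------
    # module gene (i, j) sits at global slot j*stride + i: same-module genes
    # are >= stride apart, so a 100-gene window holds no module partners
    stride = config.n_genes // config.module_size
    positions: dict[int, str] = {}
    for i, mod in enumerate(modules):
        for j, g in enumerate(mod):
            positions[j * stride + i] = g
    free_slots = [s for s in range(config.n_genes) if s not in positions]
    background_genes = [g for g in genes if g not in module_of]
    order_bg = list(background_genes)
    rng_order.shuffle(order_bg)
    for slot, g in zip(free_slots, order_bg):
        positions[slot] = g
    per_chrom = config.n_genes // config.n_chromosomes
    gene_order: list[tuple[str, str, int]] = []
    for slot in range(config.n_genes):
        chrom_idx = min(slot // per_chrom, config.n_chromosomes - 1)
        gene_order.append((positions[slot], f"chr{chrom_idx + 1}",
                           slot - chrom_idx * per_chrom))

    # --- disease records (part of the cohort) -----------------------------
    # the causal "hub" of each disease module is the member whose 100-gene
    # positional test set contains no other module member, so that at full
    # planted signal rank 1 is decided by the hub alone
    from .validation import GeneOrder

    order = GeneOrder(gene_order)
    dis_frac = (config.disease_signal_frac
                if config.disease_signal_frac is not None
                else config.signal_frac)
    disease_docs: dict[str, DocumentAnnotation] = {}
    truth: list[tuple[str, str]] = []
    for d in range(config.n_diseases):
        disease_id = f"DIS{d:03d}"
        length = int(rng_dis.integers(lo_len, hi_len + 1))
        counts = _draw_doc(rng_dis, length, background_terms, background_p,
                           blocks[d], dis_frac)
        ann = DocumentAnnotation(doc_id=disease_id, counts=counts)
        disease_docs[disease_id] = ann
        annotations.append(ann)
        hub = _pick_hub(modules[d], order)
        truth.append((disease_id, hub))
        # known disease-gene annotation: the leakage masking must remove
        gene_links[hub].add(disease_id)

    cohort = DocumentCohort(annotations=annotations, term_table=term_table,
                            gene_links=gene_links)
    return World(cohort=cohort, edges=edges, disease_docs=disease_docs,
                 truth=truth, gene_order=gene_order, config=config,
                 modules=[list(m) for m in modules])


def _pick_hub(module: list[str], order: "object") -> str:
    """Module member whose positional test set holds fewest module partners."""
    from .validation import build_test_set

    best_gene = module[0]
    best_overlap = None
    others = set(module)
    for g in module:
        case = build_test_set(g, order, disease_id="_hub_probe")
        overlap = len((others - {g}) & set(case.candidates))
        if best_overlap is None or overlap < best_overlap:
            best_gene, best_overlap = g, overlap
            if overlap == 0:
                break
    return best_gene


def null_world(config: SynthConfig) -> World:
    """Same generator with all planted signal forced to zero."""
    return generate_world(replace(config, signal_frac=0.0,
                                  disease_signal_frac=0.0))
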