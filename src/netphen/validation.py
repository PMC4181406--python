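"""Evaluation protocol: positional test sets, masking, ranking and metrics.

A *test case* is a known disease–causal-gene pair.  Its *test set* contains
100 candidate genes drawn from the causal gene's chromosomal neighbourhood
(the causal gene plus 50 upstream and 49 downstream flanking genes by
positional index; a deficit near a telomere is compensated on the other
side).  This mimics a mapped locus within which the causal gene must be
singled out.  Before scoring, each candidate gene's links to disease
phenotype records are masked so that known disease–gene annotations cannot
leak into the phenotype profiles.

Candidates are ranked by descending relevance z-score (ties take the worst
rank) and, independently, classified against a sweep of discriminator
cut-offs taken from the empirical null z distribution.  The sweep yields
confusion counts, recall, precision, Matthews correlation coefficient, ROC
points and the trapezoidal AUC; the cut-off maximizing MCC summarizes
operating performance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

import networkx as nx

from .errors import ConfigurationError, DataIntegrityError
from .network import candidate_complex
from .scoring import (RelevanceScore, null_quantiles, sample_null_scores,
                      score_all_genes)
from .similarity import build_profile
from .textmine import (DocumentCohort, TermVector, VocabularyFilter,
                       apply_filter, inverse_document_frequencies,
                       weight_document)

logger = logging.getLogger(__name__)

__all__ = [
    "TestCase",
    "GeneOrder",
    "EvaluationResult",
    "EvaluationSweep",
    "ScoredTestCase",
    "RankSummary",
    "ProtocolResult",
    "build_test_set",
    "mask_associations",
    "evaluate",
    "rank_auc",
    "rank_causal",
    "default_quantile_grid",
    "run_validation_protocol",
]

#: Number of candidate genes per test set.
TEST_SET_SIZE = 100


@dataclass
class TestCase:
    """One disease–causal-gene pair with its positional candidate set."""

    disease_id: str
    causal_gene: str
    candidates: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.causal_gene not in self.candidates:
            raise DataIntegrityError(
                f"causal gene {self.causal_gene!r} not among candidates")
        if len(set(self.candidates)) != len(self.candidates):
            raise DataIntegrityError("duplicate candidate genes in test set")


class GeneOrder:
    """Positional order of genes along chromosomes.

    Only the relative order matters; positions are used solely to sort.
    """

    def __init__(self, records: Sequence[tuple[str, str, int]]):
        by_chrom: dict[str, list[tuple[int, str]]] = {}
        for gene, chrom, pos in records:
            by_chrom.setdefault(chrom, []).append((pos, gene))
        self._order: dict[str, list[str]] = {}
        self._locate: dict[str, tuple[str, int]] = {}
        for chrom, items in by_chrom.items():
            items.sort()
            genes = [g for _, g in items]
            self._order[chrom] = genes
            for idx, g in enumerate(genes):
                if g in self._locate:
                    raise DataIntegrityError(
                        f"gene {g!r} appears on more than one chromosome")
                self._locate[g] = (chrom, idx)

    def chromosome(self, chrom: str) -> list[str]:
        return self._order[chrom]

    def locate(self, gene: str) -> tuple[str, int]:
        try:
            return self._locate[gene]
        except KeyError:
            raise DataIntegrityError(
                f"gene {gene!r} absent from the gene-order table") from None

    def records(self) -> list[tuple[str, str, int]]:
        return [(g, chrom, i)
                for chrom, genes in self._order.items()
                for i, g in enumerate(genes)]


def build_test_set(
    causal: str,
    order: GeneOrder,
    disease_id: str = "",
    flank: int = 50,
    full_flanks: bool = False,
) -> TestCase:
    """Positional test set around a causal gene.

    Default reading: the test set holds ``2*flank`` genes in total *including*
    the causal gene — ``flank`` upstream and ``flank − 1`` downstream flanking
    genes, a telomere deficit on one side being compensated on the other.
    With ``full_flanks=True`` the set is causal + ``flank`` on each side
    (``2*flank + 1`` genes), the alternative off-by-one reading.
    """
    chrom, idx = order.locate(causal)
    genes = order.chromosome(chrom)
    n = len(genes)
    if n < 2 * flank + 1:
        raise ConfigurationError(
            f"chromosome {chrom!r} has {n} genes; need >= {2 * flank + 1} "
            "to build a test set")
    up_target = flank
    down_target = flank if full_flanks else flank - 1
    up = min(up_target, idx)
    down = min(down_target, n - 1 - idx)
    # compensate telomere deficits on the opposite side
    if up < up_target:
        down = min(down + (up_target - up), n - 1 - idx)
    if down < down_target:
        up = min(up + (down_target - down), idx)
    candidates = tuple(genes[idx - up: idx + down + 1])
    assert len(candidates) == up_target + down_target + 1
    return TestCase(disease_id=disease_id, causal_gene=causal,
                    candidates=candidates)


def mask_associations(
    cohort: DocumentCohort,
    test_gene: str,
    disease_doc_ids: set[str],
) -> DocumentCohort:
    """Remove the test gene's links to disease phenotype records.

    Only ``test_gene``'s link set changes; annotations and the term table are
    shared with the input cohort.  Idempotent.
    """
    links = dict(cohort.gene_links)
    if test_gene in links:
        links[test_gene] = links[test_gene] - disease_doc_ids
    return DocumentCohort(annotations=cohort.annotations,
                          term_table=cohort.term_table,
                          gene_links=links)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class EvaluationResult:
    """Confusion counts and derived metrics at one discriminator cut-off."""

    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    recall: float = field(init=False)
    precision: float = field(init=False)
    mcc: float = field(init=False)

    def __post_init__(self) -> None:
        self.recall = self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0
        self.precision = self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0
        denom = ((self.tp + self.fp) * (self.tp + self.fn)
                 * (self.tn + self.fp) * (self.tn + self.fn))
        if denom == 0:
            self.mcc = 0.0
        else:
            self.mcc = ((self.tp * self.tn - self.fp * self.fn)
                        / math.sqrt(denom))

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if self.fp + self.tn else 0.0


@dataclass
class EvaluationSweep:
    """Results of the full discriminator sweep."""

    results: list[EvaluationResult]
    roc: list[tuple[float, float]]       # (1 - specificity, sensitivity)
    auc: float
    best: EvaluationResult               # cut-off maximizing MCC
    coverage: float                      # fraction of causal genes scorable


@dataclass
class ScoredTestCase:
    """A test case with the z-score of every scorable candidate."""

    case: TestCase
    z: dict[str, float]
    unscorable: tuple[str, ...] = ()

    @property
    def causal_scorable(self) -> bool:
        return self.case.causal_gene in self.z


def evaluate(
    scored_cases: Sequence[ScoredTestCase],
    discriminators: Sequence[float],
) -> EvaluationSweep:
    """Confusion metrics over a sweep of z-score cut-offs.

    A causal gene scoring at or above a cut-off is a true positive, below a
    false negative; non-causal candidates at or above are false positives,
    below true negatives.  Unscorable candidates are excluded from the
    confusion matrix and reported as coverage loss.  ROC points are anchored
    at (0,0) and (1,1) and integrated trapezoidally.
    """
    if not scored_cases:
        raise ConfigurationError("no scored test cases to evaluate")
    if len(discriminators) == 0:
        raise ConfigurationError("no discriminator cut-offs supplied")
    causal_z: list[float] = []
    other_z: list[float] = []
    n_causal = 0
    for sc in scored_cases:
        n_causal += 1
        for gene, z in sc.z.items():
            if gene == sc.case.causal_gene:
                causal_z.append(z)
            else:
                other_z.append(z)
    coverage = len(causal_z) / n_causal
    causal_arr = np.asarray(causal_z, dtype=float)
    other_arr = np.asarray(other_z, dtype=float)
    results: list[EvaluationResult] = []
    for c in discriminators:
        tp = int(np.count_nonzero(causal_arr >= c))
        fn = causal_arr.size - tp
        fp = int(np.count_nonzero(other_arr >= c))
        tn = other_arr.size - fp
        results.append(EvaluationResult(cutoff=float(c), tp=tp, fp=fp,
                                        tn=tn, fn=fn))
    points = sorted({(r.fpr, r.recall) for r in results} | {(0.0, 0.0),
                                                            (1.0, 1.0)})
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    auc = float(np.trapezoid(ys, xs))
    best = max(results, key=lambda r: r.mcc)
    return EvaluationSweep(results=results, roc=points, auc=auc, best=best,
                           coverage=coverage)


def rank_auc(scored_cases: Sequence[ScoredTestCase]) -> float:
    """Rank-based (Mann–Whitney) AUC on the pooled candidate scores.

    Independent of the discriminator grid; used to cross-check the sweep AUC.
    """
    labels: list[int] = []
    scores: list[float] = []
    for sc in scored_cases:
        for gene, z in sc.z.items():
            labels.append(1 if gene == sc.case.causal_gene else 0)
            scores.append(z)
    return float(roc_auc_score(labels, scores))


@dataclass
class RankSummary:
    """Per-case causal-gene ranks and top-k summary fractions."""

    ranks: dict[tuple[str, str], int | None]   # (disease, causal) -> rank
    top1_fraction: float
    top5_fraction: float
    coverage: float


def rank_causal(scored_cases: Sequence[ScoredTestCase]) -> RankSummary:
    """Rank each causal gene among its candidates by descending z.

    Ties take the worst (largest) rank.  A case whose causal gene is
    unscorable is counted as not prioritized: excluded from the top-k
    numerators but kept in the denominators, with the loss reported as a
    coverage fraction.
    """
    if not scored_cases:
        raise ConfigurationError("no scored test cases to rank")
    ranks: dict[tuple[str, str], int | None] = {}
    top1 = top5 = scorable = 0
    for sc in scored_cases:
        key = (sc.case.disease_id, sc.case.causal_gene)
        if not sc.causal_scorable:
            ranks[key] = None
            continue
        scorable += 1
        zc = sc.z[sc.case.causal_gene]
        # worst-rank ties: count every candidate scoring >= the causal gene
        rank = sum(1 for z in sc.z.values() if z >= zc)
        ranks[key] = rank
        if rank == 1:
            top1 += 1
        if rank <= 5:
            top5 += 1
    n = len(scored_cases)
    return RankSummary(ranks=ranks,
                       top1_fraction=top1 / n,
                       top5_fraction=top5 / n,
                       coverage=scorable / n)


# ---------------------------------------------------------------------------
# End-to-end protocol
# ---------------------------------------------------------------------------

def default_quantile_grid(n: int = 500) -> np.ndarray:
    """Cumulative quantile grid from 0.1% to 100% (fraction of null passed)."""
    return np.linspace(0.001, 1.0, n)


@dataclass
class ProtocolResult:
    """Everything the validation protocol produces for one configuration."""

    scored_cases: list[ScoredTestCase]
    sweep: EvaluationSweep
    ranks: RankSummary
    discriminators: np.ndarray
    rank_auc: float


def run_validation_protocol(
    cohort: DocumentCohort,
    disease_docs: Mapping[str, "object"],
    truth: Sequence[tuple[str, str]],
    gene_order: GeneOrder,
    graph: nx.Graph,
    vocab_filter: VocabularyFilter,
    threshold: int,
    seed: int,
    quantile_grid: Sequence[float] | None = None,
    n_null_per_disease: int = 1000,
    mask: bool = True,
    flank: int = 50,
    full_flanks: bool = False,
) -> ProtocolResult:
    """Run the full prioritization-and-evaluation pipeline.

    For every (disease, causal gene) pair in ``truth``: filter and TF-IDF
    weight the cohort, weight the disease record in the same idf space,
    build the similarity profile, construct the positional test set, mask
    candidate genes' links to disease records, build each candidate's
    complex at ``threshold`` and score it.  Null z-scores (random document
    sets with sizes matched to the observed complexes) provide the
    discriminator cut-offs for the evaluation sweep.
    """
    if quantile_grid is None:
        quantile_grid = default_quantile_grid()
    rng = np.random.default_rng(seed)
    disease_doc_ids = set(disease_docs.keys())

    filtered = apply_filter(cohort.annotations, cohort.term_table,
                            vocab_filter)
    idf = inverse_document_frequencies(filtered)
    vectors = [weight_document(a, idf) for a in filtered]
    filtered_by_id = {a.doc_id: a for a in filtered}

    scored_cases: list[ScoredTestCase] = []
    null_z: list[np.ndarray] = []
    for disease_id, causal in truth:
        if disease_id not in filtered_by_id:
            raise DataIntegrityError(
                f"disease document {disease_id!r} absent from the cohort")
        disease_vec = weight_document(filtered_by_id[disease_id], idf)
        profile = build_profile(disease_vec, vectors, disease_id=disease_id)
        case = build_test_set(causal, gene_order, disease_id=disease_id,
                              flank=flank, full_flanks=full_flanks)
        links = cohort.gene_links
        if mask:
            # same effect as mask_associations per candidate, without
            # re-validating the whole cohort for each of the 100 genes
            links = dict(cohort.gene_links)
            for gene in case.candidates:
                if gene in links:
                    links[gene] = links[gene] - disease_doc_ids
        complexes = [candidate_complex(g, graph, threshold, links)
                     for g in case.candidates]
        report = score_all_genes(profile, complexes)
        scored_cases.append(ScoredTestCase(
            case=case,
            z={s.gene_id: s.z for s in report.scores},
            unscorable=tuple(report.unscorable),
        ))
        sizes = [cx.m for cx in complexes if cx.m > 0]
        if sizes:
            null_z.append(sample_null_scores(profile, sizes,
                                             n_null_per_disease, rng))
    if not null_z:
        raise ConfigurationError("no scorable candidate in any test case")
    discriminators = null_quantiles(np.concatenate(null_z), quantile_grid)
    sweep = evaluate(scored_cases, discriminators)
    ranks = rank_causal(scored_cases)
    try:
        r_auc = rank_auc(scored_cases)
    except ValueError:
        r_auc = float("nan")  # e.g. no scorable causal gene at all
    return ProtocolResult(scored_cases=scored_cases, sweep=sweep,
                          ranks=ranks, discriminators=discriminators,
                          rank_auc=r_auc)
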