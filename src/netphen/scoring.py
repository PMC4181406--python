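"""Random-set enrichment scoring of candidate complexes.

The disease relevance of a candidate gene is the standardized enrichment of
the element-level similarities of its complex's linked documents.  Write
S_1..S_E for the similarity of each cohort document to the disease record,
and C for the set of m documents linked to the complex.  The unstandardized
signal is the set mean

    X̄ = (1/m) Σ_{e ∈ C} S_e.

Conditional on the full score vector, the exact first two moments of X̄ under
uniform sampling of m documents without replacement from the E-document
cohort are

    μ       = (1/E) Σ_e S_e
    Var(X̄) = (σ²/m) · (E − m)/(E − 1),   σ² = (1/E) Σ_e S_e² − μ²

(the finite-population correction of simple random sampling), and the
disease relevance score is the z-score Z = (X̄ − μ)/√Var(X̄).  Under the
null hypothesis of no association Z is asymptotically standard normal; large
positive Z favours enrichment.  Degenerate situations (constant scores, or
m = E where X̄ ≡ μ) carry no signal and are reported as Z = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, DataIntegrityError, UnscorableGeneError
from .network import CandidateComplex
from .similarity import SimilarityProfile

logger = logging.getLogger(__name__)

__all__ = [
    "RelevanceScore",
    "ScoringReport",
    "random_set_moments",
    "random_set_score",
    "score_all_genes",
    "sample_null_scores",
    "null_quantiles",
]


@dataclass
class RelevanceScore:
    """Enrichment of one (disease, gene) pair.

    ``degenerate`` flags the zero-variance / m = E conventions where Z is
    defined as 0.
    """

    disease_id: str
    gene_id: str
    m: int
    x_bar: float
    mu: float
    var: float
    z: float
    degenerate: bool = False


@dataclass
class ScoringReport:
    """Scores for every scorable gene plus the genes that could not be scored."""

    scores: list[RelevanceScore]
    unscorable: list[str]


def random_set_moments(scores: np.ndarray, m: int) -> tuple[float, float]:
    """Exact mean and variance of the mean of a uniform random m-subset.

    ``scores`` is the full element-score vector (length E); sampling is
    without replacement.  Returns (μ, Var(X̄)).
    """
    e_total = scores.size
    if e_total < 2:
        raise ConfigurationError(f"cohort size E={e_total}, need >= 2")
    if not (1 <= m <= e_total):
        raise ConfigurationError(f"set size m={m} outside [1, E={e_total}]")
    mu = float(scores.mean())
    sigma2 = float(scores.var())  # population variance
    var = (sigma2 / m) * (e_total - m) / (e_total - 1)
    return mu, var


def random_set_score(
    profile: SimilarityProfile,
    complex_: CandidateComplex,
) -> RelevanceScore:
    """Score one candidate complex against a similarity profile."""
    if complex_.m == 0:
        raise UnscorableGeneError(complex_.seed_gene)
    e_total = profile.e_total
    if e_total < 2:
        raise ConfigurationError(f"profile has E={e_total} scores, need >= 2")
    missing = [d for d in set(complex_.linked_docs) if d not in profile.scores]
    if missing:
        raise DataIntegrityError(
            f"gene {complex_.seed_gene!r}: linked documents "
            f"{sorted(missing)[:5]} absent from the similarity profile")
    all_scores = np.fromiter(profile.scores.values(), dtype=float,
                             count=e_total)
    x_bar = float(np.mean([profile.scores[d] for d in complex_.linked_docs]))
    m = complex_.m
    if m >= e_total:
        mu = float(all_scores.mean())
        return RelevanceScore(profile.disease_id, complex_.seed_gene, m,
                              x_bar, mu, 0.0, 0.0, degenerate=True)
    mu, var = random_set_moments(all_scores, m)
    if var <= 0.0:
        return RelevanceScore(profile.disease_id, complex_.seed_gene, m,
                              x_bar, mu, 0.0, 0.0, degenerate=True)
    z = (x_bar - mu) / np.sqrt(var)
    return RelevanceScore(profile.disease_id, complex_.seed_gene, m,
                          x_bar, mu, float(var), float(z))


def score_all_genes(
    profile: SimilarityProfile,
    complexes: Sequence[CandidateComplex],
) -> ScoringReport:
    """Score every scorable complex; report m = 0 genes separately."""
    scores: list[RelevanceScore] = []
    unscorable: list[str] = []
    for cx in complexes:
        if cx.m == 0:
            unscorable.append(cx.seed_gene)
            continue
        scores.append(random_set_score(profile, cx))
    if unscorable:
        logger.info("%d genes unscorable (m = 0): %s%s",
                    len(unscorable), unscorable[:5],
                    "..." if len(unscorable) > 5 else "")
    return ScoringReport(scores=scores, unscorable=unscorable)


def sample_null_scores(
    profile: SimilarityProfile,
    m: int | Sequence[int],
    n_replicates: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """z-scores of uniformly random document sets drawn from the profile.

    ``m`` may be a single set size or a collection of observed sizes; in the
    latter case each replicate draws its size uniformly from the collection,
    matching the null distribution to the sizes actually scored.  Degenerate
    draws (m = E, zero variance) contribute z = 0.
    """
    e_total = profile.e_total
    scores = np.fromiter(profile.scores.values(), dtype=float, count=e_total)
    sizes = np.atleast_1d(np.asarray(m, dtype=int))
    if sizes.size == 0:
        raise ConfigurationError("no set sizes supplied for null sampling")
    if np.any((sizes < 1) | (sizes > e_total)):
        raise ConfigurationError(
            f"null set sizes must lie in [1, E={e_total}]")
    out = np.empty(n_replicates, dtype=float)
    mu = float(scores.mean())
    sigma2 = float(scores.var())
    for i in range(n_replicates):
        mi = int(sizes[rng.integers(sizes.size)]) if sizes.size > 1 \
            else int(sizes[0])
        if mi >= e_total or sigma2 <= 0.0:
            out[i] = 0.0
            continue
        draw = rng.choice(e_total, size=mi, replace=False)
        var = (sigma2 / mi) * (e_total - mi) / (e_total - 1)
        out[i] = (scores[draw].mean() - mu) / np.sqrt(var)
    return out


def null_quantiles(
    null_z: Iterable[float],
    grid: Sequence[float],
) -> np.ndarray:
    """Discriminator cut-offs from the empirical null z distribution.

    A grid value q in (0, 1] is the *cumulative fraction of the null that
    passes* the cut-off, so the cut-off is the empirical quantile at level
    1 − q: q = 1 passes everything (cut-off = minimum of the null sample),
    small q passes only the extreme upper tail.  Swept from 0.001 to 1 this
    traces the ROC curve from strict to lenient.
    """
    z = np.asarray(list(null_z), dtype=float)
    if z.size == 0:
        raise ConfigurationError("empty null z-score stream")
    if z.size < 1000:
        logger.warning("only %d null z-scores; quantile cut-offs will be "
                       "coarse (>= 1000 recommended)", z.size)
    grid_arr = np.asarray(grid, dtype=float)
    if np.any((grid_arr <= 0.0) | (grid_arr > 1.0)):
        raise ConfigurationError("quantile grid values must lie in (0, 1]")
    return np.quantile(z, 1.0 - grid_arr)
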