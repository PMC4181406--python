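"""Semantic similarity between a disease profile and every cohort document.

The element-level score S_e of document e is the cosine coefficient between
the TF-IDF-weighted term vector of the disease record and that of document e,
both weighted in the same idf space.  Because TF-IDF weights are
non-negative, every S_e lies in [0, 1]; a document sharing no terms with the
disease record scores exactly 0, as does any empty document (zero-norm
convention).

Pearson correlation over the full vocabulary dimension is offered as an
alternative measure for sensitivity analyses only; cosine is the default and
the measure used everywhere downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ConfigurationError
from .textmine import TermVector

logger = logging.getLogger(__name__)

__all__ = ["SimilarityProfile", "cosine", "pearson", "build_profile"]


@dataclass
class SimilarityProfile:
    """Element-level scores {S_e} of one disease against a document cohort."""

    disease_id: str
    scores: dict[str, float]

    @property
    def e_total(self) -> int:
        """Cohort size E."""
        return len(self.scores)


def cosine(a: TermVector, b: TermVector) -> float:
    """Cosine coefficient of two sparse term vectors; 0 if either is empty."""
    if not a.weights or not b.weights:
        return 0.0
    # iterate the smaller support
    small, large = (a.weights, b.weights) if len(a.weights) <= len(b.weights) \
        else (b.weights, a.weights)
    dot = 0.0
    for term, w in small.items():
        other = large.get(term)
        if other is not None:
            dot += w * other
    if dot == 0.0:
        return 0.0
    value = dot / (a.norm * b.norm)
    # guard floating-point overshoot so scores stay in [0, 1]
    return min(value, 1.0)


def pearson(a: TermVector, b: TermVector, dim: int) -> float:
    """Pearson correlation over a ``dim``-dimensional vocabulary space.

    Sensitivity-analysis alternative to :func:`cosine`; absent terms count
    as zeros, so the ambient dimension must be given explicitly.
    """
    if dim < 2:
        raise ConfigurationError("pearson requires vocabulary dimension >= 2")
    if not a.weights or not b.weights:
        return 0.0
    sum_a = sum(a.weights.values())
    sum_b = sum(b.weights.values())
    mean_a = sum_a / dim
    mean_b = sum_b / dim
    dot = 0.0
    small, large = (a.weights, b.weights) if len(a.weights) <= len(b.weights) \
        else (b.weights, a.weights)
    for term, w in small.items():
        other = large.get(term)
        if other is not None:
            dot += w * other
    cov = dot / dim - mean_a * mean_b
    var_a = sum(w * w for w in a.weights.values()) / dim - mean_a * mean_a
    var_b = sum(w * w for w in b.weights.values()) / dim - mean_b * mean_b
    if var_a <= 0.0 or var_b <= 0.0:
        return 0.0
    return cov / math.sqrt(var_a * var_b)


def build_profile(
    disease: TermVector,
    cohort_vectors: Sequence[TermVector],
    disease_id: str | None = None,
) -> SimilarityProfile:
    """Score the disease vector against every cohort document.

    Returns one S_e per document, keyed by doc_id, order-independent.  An
    empty disease vector yields an all-zero profile (and a logged warning:
    downstream enrichment scores will be degenerate).
    """
    if len(cohort_vectors) == 0:
        raise ConfigurationError("cannot build a profile on an empty cohort")
    if not disease.weights:
        logger.warning(
            "disease vector %r is empty after filtering/weighting; "
            "all similarities are 0 and scoring will be degenerate",
            disease.doc_id)
    scores = {v.doc_id: cosine(disease, v) for v in cohort_vectors}
    return SimilarityProfile(
        disease_id=disease_id if disease_id is not None else disease.doc_id,
        scores=scores)
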