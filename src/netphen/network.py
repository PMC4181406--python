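"""Candidate complexes from a confidence-scored protein interaction network.

Each candidate gene is expanded into a *candidate complex*: the gene itself
plus its first-order interaction partners whose combined confidence score
meets a threshold.  Combined scores follow the STRING convention — integers
in [150, 999], a noisy-OR integration of per-evidence-channel probabilities
after removal of a prior expectation of random interaction.  The text-mining
channel (literature co-mention) can be excluded and the combined score
recomputed, which avoids circularity when phenotype profiles themselves come
from the literature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import ConfigurationError, DataIntegrityError

logger = logging.getLogger(__name__)

__all__ = [
    "CHANNELS",
    "SCORE_MIN",
    "SCORE_MAX",
    "PpiEdge",
    "CandidateComplex",
    "build_graph",
    "candidate_complex",
    "recombine_excluding",
    "exclude_channel",
]

#: Evidence channels in canonical spelling and order.
CHANNELS = (
    "neighborhood",
    "fusion",
    "cooccurrence",
    "coexpression",
    "experimental",
    "database",
    "textmining",
)

SCORE_MIN = 150
SCORE_MAX = 999


@dataclass
class PpiEdge:
    """One undirected interaction with per-channel and combined scores.

    Endpoints are stored in canonical (min, max) order so that (a, b) and
    (b, a) compare equal.
    """

    protein_a: str
    protein_b: str
    channel_scores: dict[str, int]
    combined_score: int

    def __post_init__(self) -> None:
        if self.protein_a > self.protein_b:
            self.protein_a, self.protein_b = self.protein_b, self.protein_a
        if self.protein_a == self.protein_b:
            raise DataIntegrityError(
                f"self-interaction {self.protein_a!r} is not allowed")
        if not (SCORE_MIN <= self.combined_score <= SCORE_MAX):
            raise DataIntegrityError(
                f"edge ({self.protein_a}, {self.protein_b}): combined score "
                f"{self.combined_score} outside [{SCORE_MIN}, {SCORE_MAX}]")
        for name, s in self.channel_scores.items():
            if not (0 <= s <= SCORE_MAX):
                raise DataIntegrityError(
                    f"edge ({self.protein_a}, {self.protein_b}): channel "
                    f"{name!r} score {s} outside [0, {SCORE_MAX}]")

    @property
    def key(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


@dataclass
class CandidateComplex:
    """A seed gene, its retained partners, and their linked documents.

    ``linked_docs`` is the (by default duplicate-collapsed) collection of
    document ids linked to any member gene; ``m = len(linked_docs)`` is the
    set size entering the enrichment statistic.  Complexes with m = 0 are
    retained but unscorable.
    """

    seed_gene: str
    members: frozenset[str]
    threshold: int
    linked_docs: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.seed_gene not in self.members:
            raise DataIntegrityError(
                f"seed gene {self.seed_gene!r} not among complex members")

    @property
    def m(self) -> int:
        return len(self.linked_docs)

    @property
    def size(self) -> int:
        """Number of member genes (including the seed)."""
        return len(self.members)


def build_graph(edges: Iterable[PpiEdge]) -> nx.Graph:
    """Load edges into an undirected graph with score attributes.

    Identical duplicate rows are collapsed; duplicates with conflicting
    scores raise :class:`DataIntegrityError`.
    """
    g = nx.Graph()
    for e in edges:
        if g.has_edge(e.protein_a, e.protein_b):
            prev = g.edges[e.protein_a, e.protein_b]
            if (prev["combined_score"] != e.combined_score
                    or prev["channel_scores"] != e.channel_scores):
                raise DataIntegrityError(
                    f"conflicting duplicate edge {e.key}: combined "
                    f"{prev['combined_score']} vs {e.combined_score}")
            continue
        g.add_edge(e.protein_a, e.protein_b,
                   combined_score=e.combined_score,
                   channel_scores=e.channel_scores)
    return g


def candidate_complex(
    seed: str,
    graph: nx.Graph,
    threshold: int,
    links: Mapping[str, set[str]],
    collapse_duplicates: bool = True,
) -> CandidateComplex:
    """Build the candidate complex of ``seed`` at a confidence threshold.

    Members are the seed plus every first-order neighbour whose combined
    score is >= ``threshold``.  A seed absent from the network yields a
    singleton complex — prioritization is not limited to genes with known
    interactions.  Linked documents are the union over members of their
    gene-linked documents; with ``collapse_duplicates`` (default) a document
    linked to several members counts once, otherwise once per member.
    """
    if not (SCORE_MIN <= threshold <= SCORE_MAX):
        raise ConfigurationError(
            f"threshold {threshold} outside [{SCORE_MIN}, {SCORE_MAX}]")
    members = {seed}
    if graph.has_node(seed):
        for nbr in graph.neighbors(seed):
            if graph.edges[seed, nbr]["combined_score"] >= threshold:
                members.add(nbr)
    docs: list[str] = []
    for gene in members:
        docs.extend(links.get(gene, ()))
    if collapse_duplicates:
        docs = list(set(docs))
    return CandidateComplex(
        seed_gene=seed,
        members=frozenset(members),
        threshold=threshold,
        linked_docs=tuple(sorted(docs)),
    )


def recombine_excluding(
    edge: PpiEdge,
    excluded_channel: str | None = None,
    prior: float = 0.063,
) -> int:
    """Noisy-OR recombination of channel scores with one channel left out.

    Each remaining channel score s is read as a probability s/1000,
    prior-corrected to max(0, (s/1000 − prior)/(1 − prior)), the corrected
    probabilities are combined as 1 − ∏(1 − p_i), the prior is re-added, and
    the result is returned on the 0–1000 integer scale.  With a single
    remaining channel the operation is an identity for any prior.
    """
    if not (0.0 <= prior < 1.0):
        raise ConfigurationError(f"prior {prior} outside [0, 1)")
    if excluded_channel is not None and excluded_channel not in CHANNELS:
        raise ConfigurationError(
            f"unknown channel {excluded_channel!r}; known: {CHANNELS}")
    missing = set(CHANNELS) - set(edge.channel_scores)
    if missing:
        raise DataIntegrityError(
            f"edge {edge.key}: missing channel scores {sorted(missing)}")
    prod = 1.0
    for name in CHANNELS:
        if name == excluded_channel:
            continue
        p = edge.channel_scores[name] / 1000.0
        p_corr = max(0.0, (p - prior) / (1.0 - prior))
        prod *= 1.0 - p_corr
    p_comb = 1.0 - prod
    p_star = p_comb + prior * (1.0 - p_comb)
    return round(1000.0 * p_star)


def exclude_channel(
    edges: Sequence[PpiEdge],
    channel: str,
    prior: float = 0.063,
    floor: int = SCORE_MIN,
) -> list[PpiEdge]:
    """Recompute combined scores with one evidence channel removed.

    Edges whose recombined score falls below ``floor`` (default 150, the
    lowest reportable confidence) are dropped, mirroring how scored networks
    are distributed.  The excluded channel's score is zeroed in the output.
    """
    out: list[PpiEdge] = []
    dropped = 0
    for e in edges:
        s = recombine_excluding(e, excluded_channel=channel, prior=prior)
        if s < floor:
            dropped += 1
            continue
        channel_scores = dict(e.channel_scores)
        channel_scores[channel] = 0
        out.append(PpiEdge(
            protein_a=e.protein_a,
            protein_b=e.protein_b,
            channel_scores=channel_scores,
            combined_score=min(s, SCORE_MAX),
        ))
    if dropped:
        logger.info("exclude_channel(%s): dropped %d edges below %d",
                    channel, dropped, floor)
    return out
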