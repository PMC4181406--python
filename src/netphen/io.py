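"""Readers and writers for every table dialect the pipeline touches.

All tables are UTF-8, tab-separated with a header row, except the
STRING-style links file which is whitespace-tolerant and keeps the upstream
header spelling (including the historical misspelling ``cooccurence``).
Readers validate eagerly and report malformed rows with line numbers;
duplicate rows are deduplicated with a warning where the format allows it.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import DataIntegrityError
from .network import CHANNELS, PpiEdge
from .scoring import RelevanceScore
from .textmine import DocumentAnnotation, TermRecord, TermVector

logger = logging.getLogger(__name__)

__all__ = [
    "read_annotations", "write_annotations",
    "read_term_table", "write_term_table",
    "read_gene_links", "write_gene_links",
    "read_string_links", "write_string_links",
    "read_truth", "write_truth",
    "read_gene_order", "write_gene_order",
    "write_scores", "write_evaluation_json",
    "write_term_matrix", "read_term_matrix",
    "write_world", "read_world",
]

# STRING distributes this header with "cooccurence"; we canonicalize on read
_STRING_HEADER_ALIASES = {"cooccurence": "cooccurrence"}


def _require_columns(df: pd.DataFrame, required: Sequence[str],
                     path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataIntegrityError(
            f"{path}: missing required column(s) {missing}; "
            f"found {list(df.columns)}")


# ---------------------------------------------------------------------------
# Annotations and terms
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> list[DocumentAnnotation]:
    """doc_id / term_id / count triples -> per-document annotations."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"doc_id": str, "term_id": str})
    _require_columns(df, ["doc_id", "term_id", "count"], path)
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = df.index[counts.isna() | (counts < 1)]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:5]]  # +2: header + 1-based
        raise DataIntegrityError(
            f"{path}: non-positive or non-numeric counts at line(s) {lines}")
    df["count"] = counts.astype(int)
    dupes = df.duplicated(subset=["doc_id", "term_id"])
    if dupes.any():
        logger.warning("%s: %d duplicate (doc_id, term_id) rows summed",
                       path, int(dupes.sum()))
        df = df.groupby(["doc_id", "term_id"], as_index=False,
                        sort=False)["count"].sum()
    out = []
    for doc_id, grp in df.groupby("doc_id", sort=True):
        out.append(DocumentAnnotation(
            doc_id=str(doc_id),
            counts=dict(zip(grp["term_id"], grp["count"]))))
    return out


def write_annotations(annotations: Sequence[DocumentAnnotation],
                      path: str | Path) -> None:
    rows = [(a.doc_id, t, c)
            for a in annotations for t, c in sorted(a.counts.items())]
    # empty documents round-trip through the cohort writer's document list,
    # not through count rows
    pd.DataFrame(rows, columns=["doc_id", "term_id", "count"]).to_csv(
        path, sep="\t", index=False)


def read_term_table(path: str | Path) -> dict[str, TermRecord]:
    """term_id / pipe-joined vocabularies / semantic_type."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["term_id", "source_vocabs", "semantic_type"], path)
    out: dict[str, TermRecord] = {}
    for i, row in df.iterrows():
        tid = row["term_id"]
        if tid in out:
            raise DataIntegrityError(
                f"{path}: duplicate term_id {tid!r} at line {int(i) + 2}")
        out[tid] = TermRecord(
            term_id=tid,
            source_vocabs=frozenset(str(row["source_vocabs"]).split("|")),
            semantic_type=row["semantic_type"])
    return out


def write_term_table(terms: Mapping[str, TermRecord],
                     path: str | Path) -> None:
    rows = [(t.term_id, "|".join(sorted(t.source_vocabs)), t.semantic_type)
            for t in sorted(terms.values(), key=lambda t: t.term_id)]
    pd.DataFrame(rows, columns=["term_id", "source_vocabs",
                                "semantic_type"]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene links
# ---------------------------------------------------------------------------

def read_gene_links(
    path: str | Path,
    known_genes: set[str] | None = None,
) -> dict[str, set[str]]:
    """gene2pubmed-style table (optional tax_id, gene_id, doc_id).

    Rows naming genes outside ``known_genes`` (when given) are skipped,
    counted and logged; duplicate (gene, doc) pairs are deduplicated with a
    warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["gene_id", "doc_id"], path)
    dupes = df.duplicated(subset=["gene_id", "doc_id"])
    if dupes.any():
        logger.warning("%s: %d duplicate (gene_id, doc_id) rows deduplicated",
                       path, int(dupes.sum()))
        df = df[~dupes]
    skipped = 0
    out: dict[str, set[str]] = {}
    for gene, doc in zip(df["gene_id"], df["doc_id"]):
        if known_genes is not None and gene not in known_genes:
            skipped += 1
            continue
        out.setdefault(gene, set()).add(doc)
    if skipped:
        logger.warning("%s: skipped %d rows naming unknown genes",
                       path, skipped)
    return out


def write_gene_links(links: Mapping[str, set[str]], path: str | Path,
                     tax_id: str | None = None) -> None:
    rows = [(gene, doc) for gene in sorted(links)
            for doc in sorted(links[gene])]
    df = pd.DataFrame(rows, columns=["gene_id", "doc_id"])
    if tax_id is not None:
        df.insert(0, "tax_id", tax_id)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# STRING-style links
# ---------------------------------------------------------------------------

def read_string_links(path: str | Path) -> list[PpiEdge]:
    """Whitespace-separated STRING links dialect; tolerant of 'cooccurence'."""
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+", dtype={"protein1": str,
                                              "protein2": str})
    df = df.rename(columns=_STRING_HEADER_ALIASES)
    _require_columns(df, ["protein1", "protein2", *CHANNELS,
                          "combined_score"], path)
    edges: list[PpiEdge] = []
    seen: dict[tuple[str, str], int] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        edge = PpiEdge(
            protein_a=row.protein1,
            protein_b=row.protein2,
            channel_scores={c: int(getattr(row, c)) for c in CHANNELS},
            combined_score=int(row.combined_score))
        prev = seen.get(edge.key)
        if prev is not None:
            if edges[prev].combined_score != edge.combined_score or \
                    edges[prev].channel_scores != edge.channel_scores:
                raise DataIntegrityError(
                    f"{path}: conflicting duplicate edge {edge.key} "
                    f"at line {i + 2}")
            continue
        seen[edge.key] = len(edges)
        edges.append(edge)
    return edges


def write_string_links(edges: Sequence[PpiEdge], path: str | Path) -> None:
    # emit the upstream header spelling so files round-trip with STRING tools
    header = ["protein1", "protein2", "neighborhood", "fusion",
              "cooccurence", "coexpression", "experimental", "database",
              "textmining", "combined_score"]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(" ".join(header) + "\n")
        for e in sorted(edges, key=lambda e: e.key):
            scores = [str(e.channel_scores.get(c, 0)) for c in CHANNELS]
            fh.write(" ".join([e.protein_a, e.protein_b, *scores,
                               str(e.combined_score)]) + "\n")


# ---------------------------------------------------------------------------
# Truth, gene order, scores, evaluation
# ---------------------------------------------------------------------------

def read_truth(path: str | Path) -> list[tuple[str, str]]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["disease_id", "gene_id"], path)
    return list(zip(df["disease_id"], df["gene_id"]))


def write_truth(truth: Sequence[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(truth, columns=["disease_id", "gene_id"]).to_csv(
        path, sep="\t", index=False)


def read_gene_order(path: str | Path) -> list[tuple[str, str, int]]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t",
                     dtype={"gene_id": str, "chromosome": str})
    _require_columns(df, ["gene_id", "chromosome", "position"], path)
    pos = pd.to_numeric(df["position"], errors="coerce")
    bad = df.index[pos.isna()]
    if len(bad):
        raise DataIntegrityError(
            f"{path}: non-numeric position at line(s) "
            f"{[int(i) + 2 for i in bad[:5]]}")
    return list(zip(df["gene_id"], df["chromosome"], pos.astype(int)))


def write_gene_order(order: Sequence[tuple[str, str, int]],
                     path: str | Path) -> None:
    pd.DataFrame(order, columns=["gene_id", "chromosome",
                                 "position"]).to_csv(
        path, sep="\t", index=False)


def write_scores(scores: Sequence[RelevanceScore], path: str | Path,
                 complex_sizes: Mapping[str, int] | None = None) -> None:
    """Score table sorted by descending z with 1-based worst-tie ranks."""
    ordered = sorted(scores, key=lambda s: -s.z)
    zs = [s.z for s in ordered]
    rows = []
    for s in ordered:
        rank = sum(1 for z in zs if z >= s.z)
        rows.append((s.disease_id, s.gene_id, s.m,
                     complex_sizes.get(s.gene_id, "")
                     if complex_sizes else "",
                     s.x_bar, s.z, rank))
    pd.DataFrame(rows, columns=["disease_id", "gene_id", "m",
                                "complex_size", "x_bar", "z",
                                "rank"]).to_csv(path, sep="\t", index=False)


def write_evaluation_json(summary: Mapping[str, object],
                          path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, default=_default)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Sparse document-term matrix (MatrixMarket)
# ---------------------------------------------------------------------------

def write_term_matrix(vectors: Sequence[TermVector],
                      path: str | Path) -> None:
    """MTX export with sidecar ``<path>.rows`` / ``<path>.cols`` indices."""
    path = Path(path)
    terms = sorted({t for v in vectors for t in v.weights})
    t_index = {t: j for j, t in enumerate(terms)}
    mat = scipy.sparse.lil_matrix((len(vectors), len(terms)))
    for i, v in enumerate(vectors):
        for t, w in v.weights.items():
            mat[i, t_index[t]] = w
    scipy.io.mmwrite(str(path), mat.tocoo())
    Path(f"{path}.rows").write_text(
        "\n".join(v.doc_id for v in vectors) + "\n", encoding="utf-8")
    Path(f"{path}.cols").write_text(
        "\n".join(terms) + ("\n" if terms else ""), encoding="utf-8")


def read_term_matrix(path: str | Path) -> list[TermVector]:
    path = Path(path)
    mtx_path = path if path.suffix == ".mtx" or path.exists() \
        else path.with_suffix(".mtx")
    mat = scipy.io.mmread(str(mtx_path)).tocsr()
    doc_ids = Path(f"{path}.rows").read_text(
        encoding="utf-8").splitlines()
    terms = Path(f"{path}.cols").read_text(encoding="utf-8").splitlines()
    out = []
    for i, doc_id in enumerate(doc_ids):
        row = mat.getrow(i).tocoo()
        out.append(TermVector(
            doc_id=doc_id,
            weights={terms[j]: float(w) for j, w in zip(row.col, row.data)}))
    return out


# ---------------------------------------------------------------------------
# Whole synthetic worlds
# ---------------------------------------------------------------------------

_WORLD_FILES = {
    "annotations": "annotations.tsv",
    "terms": "terms.tsv",
    "gene_links": "gene_links.tsv",
    "string_links": "string_links.txt",
    "truth": "truth.tsv",
    "gene_order": "gene_order.tsv",
    "diseases": "disease_docs.tsv",
}


def write_world(world, out_dir: str | Path) -> None:
    """Write every table of a synthetic world under one directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_annotations(world.cohort.annotations,
                      out / _WORLD_FILES["annotations"])
    # empty documents carry no count rows; record the full document list
    Path(out / "documents.txt").write_text(
        "\n".join(world.cohort.doc_ids) + "\n", encoding="utf-8")
    write_term_table(world.cohort.term_table, out / _WORLD_FILES["terms"])
    write_gene_links(world.cohort.gene_links, out / _WORLD_FILES["gene_links"])
    write_string_links(world.edges, out / _WORLD_FILES["string_links"])
    write_truth(world.truth, out / _WORLD_FILES["truth"])
    write_gene_order(world.gene_order, out / _WORLD_FILES["gene_order"])
    Path(out / _WORLD_FILES["diseases"]).write_text(
        "disease_id\n" + "".join(f"{d}\n" for d in sorted(world.disease_docs)),
        encoding="utf-8")


def read_world(in_dir: str | Path):
    """Read a directory written by :func:`write_world` back into a World."""
    from .synthdata import World, SynthConfig  # local: avoid hard coupling
    from .textmine import DocumentCohort

    p = Path(in_dir)
    annotations = read_annotations(p / _WORLD_FILES["annotations"])
    by_id = {a.doc_id: a for a in annotations}
    all_docs = Path(p / "documents.txt").read_text(
        encoding="utf-8").splitlines()
    annotations = [by_id.get(d, DocumentAnnotation(doc_id=d, counts={}))
                   for d in all_docs]
    terms = read_term_table(p / _WORLD_FILES["terms"])
    links = read_gene_links(p / _WORLD_FILES["gene_links"])
    edges = read_string_links(p / _WORLD_FILES["string_links"])
    truth = read_truth(p / _WORLD_FILES["truth"])
    order = read_gene_order(p / _WORLD_FILES["gene_order"])
    # genes without linked documents carry no link rows; restore their
    # empty link sets from the gene-order table
    for gene, _, _ in order:
        links.setdefault(gene, set())
    disease_ids = pd.read_csv(p / _WORLD_FILES["diseases"],
                              sep="\t", dtype=str)["disease_id"].tolist()
    by_id = {a.doc_id: a for a in annotations}
    cohort = DocumentCohort(annotations=annotations, term_table=terms,
                            gene_links=links)
    return World(cohort=cohort, edges=edges,
                 disease_docs={d: by_id[d] for d in disease_ids},
                 truth=truth, gene_order=order,
                 config=None, modules=[])
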