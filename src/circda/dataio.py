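"""Readers and writers for the pipeline's external formats.

All inputs are plain text: a two-column TSV of (circRNA id, disease name)
associations, FASTA sequences, a two-column TSV circRNA->gene map, and a
two-column TSV child->parent edge list describing a MeSH-like disease
hierarchy. Matrices are written as labeled TSV, lossless to >= 10 significant
digits on round trip.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

from .containers import (
    AssociationMatrix,
    DiseaseDAG,
    EntityIndex,
    GeneAssociationMatrix,
    SequenceStore,
    normalize_disease_name,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_associations",
    "read_gene_map",
    "read_fasta",
    "read_dag",
    "write_matrix",
    "read_matrix",
    "write_associations",
]

_NUCLEOTIDES = frozenset("ACGT")


def _two_column_rows(path: str | Path) -> list[tuple[int, str, str]]:
    """Parse a two-column tab-delimited file into (line number, col1, col2)."""
    path = Path(path)
    rows: list[tuple[int, str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(
                    f"{path}: malformed row at line {lineno}: expected two "
                    f"tab-separated fields, got {line!r}"
                )
            rows.append((lineno, parts[0].strip(), parts[1].strip()))
    if not rows:
        raise ValueError(f"{path}: no data rows found")
    return rows


def read_associations(
    path: str | Path, index: EntityIndex | None = None
) -> AssociationMatrix:
    """Read a (circRNA id, disease name) pair list into a binary adjacency.

    Duplicate pairs collapse to a single 1-cell. With ``index=None`` the
    entity index is built from first appearance order; otherwise every pair
    must map into the supplied index.
    """
    rows = _two_column_rows(path)
    pairs = [(c, normalize_disease_name(d)) for _, c, d in rows]
    if index is None:
        circ_ids = tuple(dict.fromkeys(c for c, _ in pairs))
        diseases = tuple(dict.fromkeys(d for _, d in pairs))
        index = EntityIndex(circ_ids, diseases)
    values = np.zeros((index.n, index.m), dtype=np.int8)
    for (lineno, _, _), (c, d) in zip(rows, pairs):
        if not index.has_circrna(c) or not index.has_disease(d):
            raise ValueError(
                f"{path}: line {lineno}: pair ({c!r}, {d!r}) not in the "
                "supplied entity index"
            )
        values[index.circrna_index(c), index.disease_index(d)] = 1
    logger.info(
        "read %d pairs -> %d unique associations over %d circRNAs x %d diseases",
        len(pairs), int(values.sum()), index.n, index.m,
    )
    return AssociationMatrix(values, index)


def write_associations(acd: AssociationMatrix, path: str | Path) -> None:
    """Write the 1-cells back out as a two-column pair list (row-major)."""
    with open(path, "w") as fh:
        for i, j in acd.positive_pairs():
            fh.write(f"{acd.index.circrna_ids[i]}\t{acd.index.disease_names[j]}\n")


def read_gene_map(
    path: str | Path, circrna_ids: Sequence[str] | None = None
) -> GeneAssociationMatrix:
    """Read a (circRNA id, gene symbol) map into the binary A_cg matrix.

    When ``circrna_ids`` is given, rows follow that ordering and pairs whose
    circRNA is not listed are skipped with a logged count (they cannot be
    placed in the analysis).
    """
    rows = _two_column_rows(path)
    genes = tuple(dict.fromkeys(g for _, _, g in rows))
    if circrna_ids is None:
        circ = tuple(dict.fromkeys(c for _, c, _ in rows))
    else:
        circ = tuple(circrna_ids)
    lookup_c = {c: i for i, c in enumerate(circ)}
    lookup_g = {g: j for j, g in enumerate(genes)}
    values = np.zeros((len(circ), len(genes)), dtype=np.int8)
    skipped = 0
    for _, c, g in rows:
        if c not in lookup_c:
            skipped += 1
            continue
        values[lookup_c[c], lookup_g[g]] = 1
    if skipped:
        logger.warning("gene map: %d pairs referenced circRNAs outside the index", skipped)
    return GeneAssociationMatrix(values, circ, genes)


def read_fasta(path: str | Path) -> SequenceStore:
    """Read circRNA sequences, normalizing to the {A,C,G,T} alphabet.

    Uppercases, maps U->T, and drops any other character with a per-record
    logged count. Records empty after cleaning are skipped with a warning.
    """
    store = SequenceStore()
    for record in SeqIO.parse(str(path), "fasta"):
        raw = str(record.seq).upper().replace("U", "T")
        cleaned = "".join(ch for ch in raw if ch in _NUCLEOTIDES)
        n_dropped = len(raw) - len(cleaned)
        if not cleaned:
            logger.warning("record %s empty after cleaning; skipped", record.id)
            continue
        if n_dropped:
            logger.info("record %s: dropped %d non-ACGT characters", record.id, n_dropped)
            store.dropped[record.id] = n_dropped
        store.sequences[record.id] = cleaned
    if not store.sequences:
        logger.warning("FASTA %s yielded no usable sequences", path)
    return store


def read_dag(path: str | Path) -> DiseaseDAG:
    """Read child->parent edges and compute each node's ancestor closure.

    Raises on any cycle (listing one offending cycle). Every node appearing
    in the file gets a closure containing itself; diseases not mentioned in
    the file simply have no entry.
    """
    rows = _two_column_rows(path)
    graph = nx.DiGraph()
    for lineno, child, parent in rows:
        child_n = normalize_disease_name(child)
        parent_n = normalize_disease_name(parent)
        if child_n == parent_n:
            raise ValueError(f"{path}: line {lineno}: self-loop on {child!r}")
        graph.add_edge(child_n, parent_n)
    try:
        cycle = nx.find_cycle(graph)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        desc = " -> ".join(str(edge[0]) for edge in cycle) + f" -> {cycle[-1][1]}"
        raise ValueError(f"{path}: hierarchy contains a cycle: {desc}")
    # edges point child->parent, so graph-descendants are DAG ancestors
    ancestors = {
        node: frozenset({node}) | frozenset(nx.descendants(graph, node))
        for node in graph.nodes
    }
    return DiseaseDAG(ancestors=ancestors, nodes=frozenset(graph.nodes))


def write_matrix(
    path: str | Path,
    values: np.ndarray,
    row_labels: Sequence[str],
    col_labels: Sequence[str],
    header_comments: Iterable[str] = (),
) -> None:
    """Write a labeled (possibly rectangular) matrix as TSV.

    Values are rendered with 12 significant digits so a write/read round trip
    is lossless well past the 10-digit contract.
    """
    frame = pd.DataFrame(np.asarray(values), index=list(row_labels), columns=list(col_labels))
    with open(path, "w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        frame.to_csv(fh, sep="\t", float_format="%.12g")


def read_matrix(
    path: str | Path,
    expect_rows: Sequence[str] | None = None,
    expect_cols: Sequence[str] | None = None,
) -> tuple[np.ndarray, tuple[str, ...], tuple[str, ...]]:
    """Read a labeled TSV matrix; optionally enforce expected labels."""
    frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    rows = tuple(str(r) for r in frame.index)
    cols = tuple(str(c) for c in frame.columns)
    if expect_rows is not None and rows != tuple(expect_rows):
        raise ValueError(f"{path}: row labels do not match the expected labels")
    if expect_cols is not None and cols != tuple(expect_cols):
        raise ValueError(f"{path}: column labels do not match the expected labels")
    return frame.to_numpy(dtype=float), rows, cols
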