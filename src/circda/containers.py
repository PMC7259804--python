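"""Shared in-memory containers for the association-prediction pipeline.

Entities are held in an :class:`EntityIndex` that fixes a 0-based ordering of
circRNA ids and disease names for the lifetime of a run; every matrix in the
pipeline is tied to such an index (or to explicit label tuples) rather than to
raw integer positions. Files carry labels, never indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "EntityIndex",
    "AssociationMatrix",
    "GeneAssociationMatrix",
    "SequenceStore",
    "DiseaseDAG",
    "SimilarityMatrix",
    "normalize_disease_name",
]


def normalize_disease_name(name: str) -> str:
    """Canonical form of a disease name: trimmed and case-folded.

    circRNA identifiers keep their case (circBase ids are case-sensitive by
    convention); disease names in the curated association lists mix cases, so
    they are folded before matching.
    """
    return name.strip().casefold()


@dataclass(frozen=True)
class EntityIndex:
    """Stable ordering of the n circRNAs and m diseases of one analysis."""

    circrna_ids: tuple[str, ...]
    disease_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.circrna_ids) == 0 or len(self.disease_names) == 0:
            raise ValueError("index needs at least one circRNA and one disease")
        if len(set(self.circrna_ids)) != len(self.circrna_ids):
            raise ValueError("duplicate circRNA ids in index")
        if len(set(self.disease_names)) != len(self.disease_names):
            raise ValueError("duplicate disease names in index")
        object.__setattr__(
            self, "_circ_lookup", {c: i for i, c in enumerate(self.circrna_ids)}
        )
        object.__setattr__(
            self, "_dis_lookup", {d: j for j, d in enumerate(self.disease_names)}
        )

    @property
    def n(self) -> int:
        """Number of circRNAs."""
        return len(self.circrna_ids)

    @property
    def m(self) -> int:
        """Number of diseases."""
        return len(self.disease_names)

    def circrna_index(self, circ_id: str) -> int:
        return self._circ_lookup[circ_id]

    def disease_index(self, name: str) -> int:
        return self._dis_lookup[normalize_disease_name(name)]

    def has_circrna(self, circ_id: str) -> bool:
        return circ_id in self._circ_lookup

    def has_disease(self, name: str) -> bool:
        return normalize_disease_name(name) in self._dis_lookup


def _check_binary(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values)
    if not np.isin(values, (0, 1)).all():
        raise ValueError("association matrix entries must be 0 or 1")
    return values.astype(np.int8)


@dataclass
class AssociationMatrix:
    """Binary circRNA (rows) x disease (columns) adjacency A_cd."""

    values: np.ndarray
    index: EntityIndex

    def __post_init__(self) -> None:
        self.values = _check_binary(self.values)
        if self.values.shape != (self.index.n, self.index.m):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match index "
                f"({self.index.n}, {self.index.m})"
            )

    @property
    def n_positive(self) -> int:
        return int(self.values.sum())

    def positive_pairs(self) -> list[tuple[int, int]]:
        """Known associations Z^p as (circRNA index, disease index), row-major."""
        return [tuple(p) for p in np.argwhere(self.values == 1)]

    def unknown_pairs(self) -> list[tuple[int, int]]:
        """The 0-cells: candidate pool of unconfirmed associations."""
        return [tuple(p) for p in np.argwhere(self.values == 0)]


@dataclass
class GeneAssociationMatrix:
    """Binary circRNA (rows) x gene (columns) adjacency A_cg."""

    values: np.ndarray
    circrna_ids: tuple[str, ...]
    gene_symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = _check_binary(self.values)
        if len(set(self.gene_symbols)) != len(self.gene_symbols):
            raise ValueError("duplicate gene symbols")
        if self.values.shape != (len(self.circrna_ids), len(self.gene_symbols)):
            raise ValueError("gene matrix shape does not match labels")


@dataclass
class SequenceStore:
    """Nucleotide sequences keyed by circRNA id, normalized to {A,C,G,T}.

    ``dropped`` records, per id, how many characters outside the alphabet were
    removed during cleaning. Ids may cover only a subset of an EntityIndex;
    downstream similarity code flags the missing ones rather than imputing.
    """

    sequences: dict[str, str] = field(default_factory=dict)
    dropped: dict[str, int] = field(default_factory=dict)

    def __contains__(self, circ_id: str) -> bool:
        return circ_id in self.sequences

    def __getitem__(self, circ_id: str) -> str:
        return self.sequences[circ_id]

    def __len__(self) -> int:
        return len(self.sequences)

    def ids(self) -> list[str]:
        return list(self.sequences)


@dataclass
class DiseaseDAG:
    """Ancestor closures of a MeSH-like disease hierarchy.

    ``ancestors[d]`` is N_d: the node d itself plus everything reachable via
    child->parent edges. Diseases absent from the hierarchy simply have no
    entry; the fusion rules fall back to the interaction-profile kernel for
    them.
    """

    ancestors: dict[str, frozenset[str]]
    nodes: frozenset[str]

    def has(self, name: str) -> bool:
        return normalize_disease_name(name) in self.ancestors

    def closure(self, name: str) -> frozenset[str]:
        return self.ancestors[normalize_disease_name(name)]


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity with labels and an optional missing mask.

    ``missing[i, j]`` is True where the similarity is undefined (e.g. one of
    the two circRNAs has no sequence); the stored value there is a 0.0
    placeholder that consumers must not interpret as a true zero.
    """

    values: np.ndarray
    labels: tuple[str, ...]
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("similarity matrix must be square and match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("similarity matrix is not symmetric within 1e-10")
        if self.missing is not None:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.values.shape:
                raise ValueError("missing mask shape mismatch")

    @property
    def k(self) -> int:
        return len(self.labels)

    def available(self) -> np.ndarray:
        """Boolean matrix: True where the entry is defined."""
        if self.missing is None:
            return np.ones_like(self.values, dtype=bool)
        return ~self.missing
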