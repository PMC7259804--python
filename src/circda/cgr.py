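"""Chaos Game Representation of nucleotide sequences and grid descriptors.

A sequence over {A,C,G,T} is mapped into the unit square by the iterated
contraction

    P_0 = (0.5, 0.5),    P_i = P_{i-1} + nu * (g_i - P_{i-1}),

where g_i is the corner assigned to the i-th nucleotide (A=(0,0), C=(0,1),
G=(1,1), T=(1,0)) and nu is the contribution factor, 0.5 by default. For
nu = 0.5 the map is injective and each position encodes the full prefix, so
the sequence can be recovered exactly from the trajectory (each P_i sits in
the quadrant of its corner g_i).

The square is then partitioned into 2^s x 2^s cells; each cell is summarized
by the accumulated x-coordinates, accumulated y-coordinates, and the z-score
of its occupancy count — positional information in (X, Y) and a k-mer-like
nonlinear signature in Z. Flattening the per-cell triples gives a 3*4^s
descriptor per sequence; descriptors are compared by Pearson correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import EntityIndex, SequenceStore, SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CORNERS",
    "CGRTrajectory",
    "GridDescriptor",
    "map_sequence",
    "invert_trajectory",
    "grid_descriptor",
    "descriptor_matrix",
    "sequence_similarity_matrix",
]

CORNERS: dict[str, tuple[float, float]] = {
    "A": (0.0, 0.0),
    "C": (0.0, 1.0),
    "G": (1.0, 1.0),
    "T": (1.0, 0.0),
}

# quadrant (x >= 0.5, y >= 0.5) -> nucleotide, used for inversion
_QUADRANT = {(0, 0): "A", (0, 1): "C", (1, 1): "G", (1, 0): "T"}


@dataclass(frozen=True)
class CGRTrajectory:
    """Ordered unit-square positions P_0..P_{n_seq} for one sequence."""

    positions: np.ndarray  # (n_seq + 1, 2)
    nu: float = 0.5

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 1:
            raise ValueError("trajectory must be a (k, 2) array with k >= 1")
        if (pos < 0).any() or (pos > 1).any():
            raise ValueError("trajectory positions must lie in the unit square")

    @property
    def n_seq(self) -> int:
        return self.positions.shape[0] - 1


def map_sequence(seq: str, nu: float = 0.5) -> CGRTrajectory:
    """Map a nucleotide string to its CGR trajectory.

    Raises on characters outside {A,C,G,T}; alphabet cleaning belongs to the
    I/O layer, not here.
    """
    if not 0 < nu < 1:
        raise ValueError("nu must lie in (0, 1)")
    bad = set(seq) - CORNERS.keys()
    if bad:
        raise ValueError(f"sequence contains non-ACGT characters: {sorted(bad)}")
    positions = np.empty((len(seq) + 1, 2))
    positions[0] = (0.5, 0.5)
    p = positions[0]
    for i, ch in enumerate(seq, start=1):
        g = CORNERS[ch]
        p = (p[0] + nu * (g[0] - p[0]), p[1] + nu * (g[1] - p[1]))
        positions[i] = p
    return CGRTrajectory(positions=positions, nu=nu)


def invert_trajectory(traj: CGRTrajectory) -> str:
    """Recover the original sequence from a nu=0.5 trajectory.

    With nu >= 0.5 every update lands inside the quadrant of its corner, so
    each position independently identifies its nucleotide; the i-th symbol is
    read off P_i alone and the recovery is exact for any length.
    """
    if traj.nu < 0.5:
        raise ValueError("inversion by quadrant requires nu >= 0.5")
    chars = []
    for x, y in traj.positions[1:]:
        chars.append(_QUADRANT[(int(x >= 0.5), int(y >= 0.5))])
    return "".join(chars)


@dataclass(frozen=True)
class GridDescriptor:
    """Per-cell (X, Y, Z) summary of a trajectory on a 2^s x 2^s grid.

    Cells are ordered row-major by y-row (bottom row first), x within a row.
    ``vector`` interleaves (X, Y, Z) per cell, giving length 3 * 4^s.
    """

    s: int
    counts: np.ndarray  # Num_i, length 4^s
    x_sums: np.ndarray  # X_i
    y_sums: np.ndarray  # Y_i
    z_scores: np.ndarray  # Z_i

    @property
    def n_cells(self) -> int:
        return 4**self.s

    @property
    def vector(self) -> np.ndarray:
        return np.column_stack([self.x_sums, self.y_sums, self.z_scores]).ravel()


def grid_descriptor(
    traj: CGRTrajectory, s: int = 3, coord_stat: str = "sum"
) -> GridDescriptor:
    """Summarize a trajectory on the 2^s x 2^s grid.

    Cells are the half-open boxes [a/2^s, (a+1)/2^s) x [b/2^s, (b+1)/2^s),
    with the top/right edge closed on the last row/column, so every point
    falls in exactly one cell. P_0 encodes no nucleotide and is excluded, so
    counts total n_seq. X/Y accumulate coordinates (``coord_stat="mean"``
    averages instead); Z is the population z-score of the counts, all zeros
    when every cell holds the same count.
    """
    if s < 1:
        raise ValueError("grid exponent s must be >= 1")
    if coord_stat not in ("sum", "mean"):
        raise ValueError("coord_stat must be 'sum' or 'mean'")
    side = 2**s
    n_cells = side * side
    pts = traj.positions[1:]
    if pts.shape[0] == 0:
        logger.warning("empty trajectory: returning all-zero grid descriptor")
        zeros = np.zeros(n_cells)
        return GridDescriptor(s=s, counts=zeros.copy(), x_sums=zeros.copy(),
                              y_sums=zeros.copy(), z_scores=zeros.copy())
    ix = np.minimum((pts[:, 0] * side).astype(int), side - 1)
    iy = np.minimum((pts[:, 1] * side).astype(int), side - 1)
    cell = iy * side + ix
    counts = np.bincount(cell, minlength=n_cells).astype(float)
    x_sums = np.bincount(cell, weights=pts[:, 0], minlength=n_cells)
    y_sums = np.bincount(cell, weights=pts[:, 1], minlength=n_cells)
    if coord_stat == "mean":
        occupied = counts > 0
        x_sums = np.where(occupied, x_sums / np.maximum(counts, 1), 0.0)
        y_sums = np.where(occupied, y_sums / np.maximum(counts, 1), 0.0)
    std = counts.std()  # population std over cells
    z_scores = (counts - counts.mean()) / std if std > 0 else np.zeros(n_cells)
    return GridDescriptor(s=s, counts=counts, x_sums=x_sums, y_sums=y_sums,
                          z_scores=z_scores)


def descriptor_matrix(
    store: SequenceStore,
    ids: tuple[str, ...],
    s: int = 3,
    nu: float = 0.5,
    coord_stat: str = "sum",
) -> tuple[np.ndarray, np.ndarray]:
    """Stack flattened grid descriptors for ``ids`` present in the store.

    Returns (descriptors, has_sequence): descriptors has one row per id in
    order, zero-filled for absent ids; has_sequence flags availability.
    """
    n_cells = 4**s
    out = np.zeros((len(ids), 3 * n_cells))
    have = np.zeros(len(ids), dtype=bool)
    for i, circ_id in enumerate(ids):
        if circ_id in store:
            traj = map_sequence(store[circ_id], nu=nu)
            out[i] = grid_descriptor(traj, s=s, coord_stat=coord_stat).vector
            have[i] = True
    return out, have


def _pearson_rows(descriptors: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of matrix rows with degenerate handling.

    Rows with zero variance correlate 0 with everything except an identical
    row, which scores 1 (the similarity of a sequence with itself must be 1
    even for pathological single-cell trajectories).
    """
    centered = descriptors - descriptors.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    degenerate = norms == 0
    if degenerate.any():
        logger.info("%d descriptors have zero variance", int(degenerate.sum()))
    safe = np.where(degenerate, 1.0, norms)
    corr = (centered @ centered.T) / np.outer(safe, safe)
    corr = np.clip(corr, -1.0, 1.0)
    for i in np.flatnonzero(degenerate):
        for j in range(descriptors.shape[0]):
            same = np.array_equal(descriptors[i], descriptors[j])
            corr[i, j] = corr[j, i] = 1.0 if same else 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


def sequence_similarity_matrix(
    store: SequenceStore,
    index: EntityIndex,
    s: int = 3,
    nu: float = 0.5,
    coord_stat: str = "sum",
) -> SimilarityMatrix:
    """Pearson correlation of grid descriptors for every circRNA pair.

    Pairs where either circRNA lacks a sequence are flagged in the missing
    mask (placeholder value 0.0) rather than silently scored; the fusion rule
    consumes the mask. Values lie in [-1, 1]; the diagonal is 1 wherever a
    sequence exists.
    """
    descriptors, have = descriptor_matrix(store, index.circrna_ids, s=s, nu=nu,
                                          coord_stat=coord_stat)
    k = index.n
    values = np.zeros((k, k))
    idx = np.flatnonzero(have)
    if idx.size:
        sub = _pearson_rows(descriptors[idx])
        values[np.ix_(idx, idx)] = sub
    missing = ~np.logical_and.outer(have, have)
    values[missing] = 0.0
    return SimilarityMatrix(values=values, labels=index.circrna_ids, missing=missing)
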