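"""Similarity kernels and the two fusion rules.

Diseases are compared two ways: by overlap of their ancestor closures in a
MeSH-like hierarchy (semantic similarity) and by a Gaussian kernel on their
binary association profiles (interaction-profile kernel, GIP). circRNAs are
compared three ways: a GIP kernel on their association profiles, a gene-based
similarity through the circRNA-gene adjacency, and the Pearson similarity of
chaos-game grid descriptors computed in :mod:`circda.cgr`. Rule-based fusion
averages whichever attributes are available for a pair and falls back to the
profile kernel otherwise.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .containers import DiseaseDAG, EntityIndex, GeneAssociationMatrix, SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "semantic_contribution",
    "semantic_similarity_matrix",
    "gip_width",
    "gip_kernel_matrix",
    "gene_based_similarity",
    "fuse_disease_similarity",
    "fuse_circrna_similarity",
]


def semantic_contribution(
    r: str, dag: DiseaseDAG, diseases: tuple[str, ...], universe: str = "with_dag"
) -> float:
    """Contribution value of hierarchy node ``r``.

    S(r) = ln(1 + n(DAGs(r)) / n(disease)), where n(DAGs(r)) counts the
    disease DAGs (among ``diseases``) whose ancestor closure contains r. The
    denominator counts diseases with a DAG by default; ``universe="all"``
    counts every disease in the analysis instead. Generic nodes shared by
    many DAGs thus contribute more — the weighting is frequency-based, unlike
    depth-decay schemes.
    """
    if r not in dag.nodes:
        raise KeyError(f"node {r!r} does not appear in the disease hierarchy")
    with_dag = [d for d in diseases if dag.has(d)]
    n_disease = len(diseases) if universe == "all" else len(with_dag)
    if n_disease == 0:
        return 0.0
    n_dags = sum(1 for d in with_dag if r in dag.closure(d))
    return math.log(1.0 + n_dags / n_disease)


def semantic_similarity_matrix(
    dag: DiseaseDAG, index: EntityIndex, universe: str = "with_dag"
) -> tuple[SimilarityMatrix, np.ndarray]:
    """Pairwise semantic similarity of all diseases, plus has-DAG flags.

    For diseases i, j with ancestor closures N_i, N_j and contribution S(r):

        sem(i, j) = sum_{r in N_i & N_j} 2 S(r) / (sum_{N_i} S + sum_{N_j} S)

    The diagonal is 1 by construction and set explicitly. Diseases without a
    DAG are flagged (and masked); pairs whose denominator vanishes (every
    shared node contributing 0) score 0 with a log entry.
    """
    m = index.m
    has_dag = np.array([dag.has(d) for d in index.disease_names])
    values = np.zeros((m, m))
    contrib: dict[str, float] = {}

    def s_of(r: str) -> float:
        if r not in contrib:
            contrib[r] = semantic_contribution(r, dag, index.disease_names, universe)
        return contrib[r]

    closures = {
        j: dag.closure(d) for j, d in enumerate(index.disease_names) if has_dag[j]
    }
    totals = {j: sum(s_of(r) for r in cl) for j, cl in closures.items()}
    flagged_idx = list(closures)
    for a, i in enumerate(flagged_idx):
        for j in flagged_idx[a:]:
            denom = totals[i] + totals[j]
            if denom == 0:
                logger.info(
                    "semantic similarity undefined for (%s, %s); set to 0",
                    index.disease_names[i], index.disease_names[j],
                )
                values[i, j] = values[j, i] = 0.0
                continue
            shared = closures[i] & closures[j]
            num = sum(2.0 * s_of(r) for r in shared)
            values[i, j] = values[j, i] = num / denom
        values[i, i] = 1.0
    missing = ~np.logical_and.outer(has_dag, has_dag)
    return (
        SimilarityMatrix(values=values, labels=index.disease_names, missing=missing),
        has_dag,
    )


def gip_width(profiles: np.ndarray) -> float:
    """Kernel width tau = 1 / mean squared norm of the binary profiles.

    When every profile is all-zero the mean norm vanishes; tau falls back to
    1 with a warning (the kernel then scores every pair 1, which downstream
    fusion tolerates).
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] == 0:
        raise ValueError("profiles must be a non-empty 2-D array")
    mean_sq = float((profiles**2).sum(axis=1).mean())
    if mean_sq == 0:
        logger.warning("all-zero interaction profiles: kernel width tau set to 1")
        return 1.0
    return 1.0 / mean_sq


def gip_kernel_matrix(profiles: np.ndarray, tau: float | None = None) -> np.ndarray:
    """Gaussian interaction-profile kernel K(i,j) = exp(-tau ||p_i - p_j||^2).

    ``tau=None`` computes the width from the profiles themselves. The result
    is symmetric with unit diagonal and entries in (0, 1].
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2:
        raise ValueError("profiles must share a common dimension")
    if tau is None:
        tau = gip_width(profiles)
    if tau <= 0:
        raise ValueError("kernel width tau must be positive")
    if profiles.shape[0] == 1:
        return np.ones((1, 1))
    sq = squareform(pdist(profiles, metric="sqeuclidean"))
    kernel = np.exp(-tau * sq)
    np.fill_diagonal(kernel, 1.0)
    return kernel


def gene_based_similarity(
    acg: GeneAssociationMatrix, mode: str = "normalized"
) -> SimilarityMatrix:
    """circRNA similarity through shared genes: R = A_cg . K_g . A_cg^T.

    K_g is the GIP kernel on gene profiles (columns of A_cg). The raw product
    is unbounded, so the default returns the symmetric diagonal normalization
    R(i,j)/sqrt(R(i,i) R(j,j)) — unit diagonal for every circRNA with at
    least one gene, 0 rows for those with none; ``mode="raw"`` returns the
    plain product.
    """
    if mode not in ("normalized", "raw"):
        raise ValueError("mode must be 'normalized' or 'raw'")
    a = np.asarray(acg.values, dtype=float)
    gene_kernel = gip_kernel_matrix(a.T)  # gene profiles are columns of A_cg
    raw = a @ gene_kernel @ a.T
    raw = (raw + raw.T) / 2.0  # enforce exact symmetry against float noise
    if mode == "raw":
        return SimilarityMatrix(values=raw, labels=acg.circrna_ids)
    diag = np.diag(raw).copy()
    ok = diag > 0
    scale = np.zeros_like(diag)
    scale[ok] = 1.0 / np.sqrt(diag[ok])
    values = raw * np.outer(scale, scale)
    np.fill_diagonal(values, np.where(ok, 1.0, 0.0))
    return SimilarityMatrix(values=values, labels=acg.circrna_ids)


def fuse_disease_similarity(
    sem: SimilarityMatrix, gip: SimilarityMatrix, has_dag: np.ndarray
) -> SimilarityMatrix:
    """Disease fusion: mean of semantic and GIP where both diseases have a
    DAG, the GIP value otherwise."""
    if sem.labels != gip.labels:
        raise ValueError("semantic and GIP matrices carry different labels")
    both = np.logical_and.outer(has_dag, has_dag)
    values = np.where(both, (sem.values + gip.values) / 2.0, gip.values)
    return SimilarityMatrix(values=values, labels=sem.labels)


def fuse_circrna_similarity(
    gene: SimilarityMatrix,
    gip: SimilarityMatrix,
    seq: SimilarityMatrix,
    mode: str = "mask",
) -> SimilarityMatrix:
    """circRNA fusion: mean of gene, GIP and sequence similarity where the
    sequence value is available, mean of gene and GIP otherwise.

    ``mode="mask"`` (default) uses the explicit availability mask carried by
    the sequence matrix, so a genuine zero correlation still participates.
    ``mode="zero_sentinel"`` reproduces the literal rule "use the sequence
    term iff it is nonzero", conflating missing data with true zeros.
    Negative correlations pass through unclamped.
    """
    if not (gene.labels == gip.labels == seq.labels):
        raise ValueError("similarity matrices carry different labels")
    if mode == "mask":
        avail = seq.available()
    elif mode == "zero_sentinel":
        avail = seq.values != 0
    else:
        raise ValueError("mode must be 'mask' or 'zero_sentinel'")
    three = (gene.values + gip.values + seq.values) / 3.0
    two = (gene.values + gip.values) / 2.0
    values = np.where(avail, three, two)
    return SimilarityMatrix(values=values, labels=gene.labels)
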