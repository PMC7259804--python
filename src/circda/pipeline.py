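"""High-level assembly: dataset bundle, config, and fused similarities.

This is the glue the CLI, the cross-validation harness and the examples all
share: load (or generate) the four inputs, compute every attribute-specific
similarity, fuse them, and hand the fused matrices to the classifier layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cgr, kernels
from .containers import (
    AssociationMatrix,
    DiseaseDAG,
    GeneAssociationMatrix,
    SequenceStore,
    SimilarityMatrix,
)
from .dataio import read_associations, read_dag, read_fasta, read_gene_map
from .model import ClassifierConfig

__all__ = ["PipelineConfig", "DatasetBundle", "load_bundle", "build_similarities"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the pipeline, with the defaults used throughout.

    nu: CGR contribution factor (0.5 — the invertible midpoint map).
    s: grid exponent (3 — an 8x8 grid, 192-dim descriptors).
    coord_stat: per-cell coordinate accumulation, "sum" or "mean".
    semantic_universe: denominator of the contribution value — diseases
        with a DAG ("with_dag") or all diseases ("all").
    gene_mode: "normalized" (unit-diagonal gene similarity) or "raw".
    seq_fusion_mode: "mask" (explicit availability mask) or "zero_sentinel".
    k: cross-validation folds. fold_safe: rebuild profile kernels from
    training-fold associations only.
    """

    nu: float = 0.5
    s: int = 3
    coord_stat: str = "sum"
    semantic_universe: str = "with_dag"
    gene_mode: str = "normalized"
    seq_fusion_mode: str = "mask"
    k: int = 5
    fold_safe: bool = False
    seed: int = 0
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)

    def summary(self) -> list[str]:
        """Key=value lines for provenance headers."""
        items = {
            "nu": self.nu, "s": self.s, "coord_stat": self.coord_stat,
            "semantic_universe": self.semantic_universe,
            "gene_mode": self.gene_mode, "seq_fusion_mode": self.seq_fusion_mode,
            "k": self.k, "fold_safe": self.fold_safe, "seed": self.seed,
            "classifier": self.classifier.kind, "C": self.classifier.C,
            "gamma": self.classifier.gamma,
            "standardize": self.classifier.standardize,
        }
        return [f"{key}={value}" for key, value in items.items()]


@dataclass
class DatasetBundle:
    """The four inputs of one analysis."""

    associations: AssociationMatrix
    sequences: SequenceStore
    gene_map: GeneAssociationMatrix
    dag: DiseaseDAG | None = None


def load_bundle(
    associations: str | Path,
    fasta: str | Path,
    genes: str | Path,
    dag: str | Path | None = None,
) -> DatasetBundle:
    """Read the four input files into a bundle sharing one entity index."""
    acd = read_associations(associations)
    store = read_fasta(fasta)
    acg = read_gene_map(genes, circrna_ids=acd.index.circrna_ids)
    disease_dag = read_dag(dag) if dag is not None else None
    return DatasetBundle(associations=acd, sequences=store, gene_map=acg,
                         dag=disease_dag)


def build_similarities(
    bundle: DatasetBundle,
    config: PipelineConfig | None = None,
    acd_values: np.ndarray | None = None,
    seq_sim: SimilarityMatrix | None = None,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Compute the fused circRNA and disease similarity matrices (S^C, S^D).

    ``acd_values`` overrides the association matrix used for the two
    interaction-profile kernels — the fold-safe cross-validation path passes
    the training-fold adjacency here so test-fold labels never reach the
    kernels. ``seq_sim`` lets callers reuse a precomputed sequence similarity
    (it does not depend on associations, so it is fold-invariant).
    """
    config = config or PipelineConfig()
    acd = bundle.associations
    index = acd.index
    values = acd.values if acd_values is None else np.asarray(acd_values)
    if values.shape != acd.values.shape:
        raise ValueError("acd_values must match the association matrix shape")

    # disease side: semantic similarity (where DAGs exist) + profile kernel
    disease_gip = SimilarityMatrix(
        values=kernels.gip_kernel_matrix(values.T.astype(float)),
        labels=index.disease_names,
    )
    if bundle.dag is not None:
        sem, has_dag = kernels.semantic_similarity_matrix(
            bundle.dag, index, universe=config.semantic_universe
        )
    else:
        sem = SimilarityMatrix(
            values=np.zeros((index.m, index.m)),
            labels=index.disease_names,
            missing=np.ones((index.m, index.m), dtype=bool),
        )
        has_dag = np.zeros(index.m, dtype=bool)
    s_d = kernels.fuse_disease_similarity(sem, disease_gip, has_dag)

    # circRNA side: gene-based + profile kernel + sequence descriptors
    gene_sim = kernels.gene_based_similarity(bundle.gene_map, mode=config.gene_mode)
    circ_gip = SimilarityMatrix(
        values=kernels.gip_kernel_matrix(values.astype(float)),
        labels=index.circrna_ids,
    )
    if seq_sim is None:
        seq_sim = cgr.sequence_similarity_matrix(
            bundle.sequences, index, s=config.s, nu=config.nu,
            coord_stat=config.coord_stat,
        )
    s_c = kernels.fuse_circrna_similarity(
        gene_sim, circ_gip, seq_sim, mode=config.seq_fusion_mode
    )
    return s_c, s_d
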