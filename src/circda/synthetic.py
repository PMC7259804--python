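"""Synthetic datasets with the block structure the method assumes.

The generator plants a joint block structure: circRNAs and diseases are
assigned to latent blocks, associations appear with high probability inside
a block and low probability outside, same-block circRNAs share gene targets
and (in structured mode) a dinucleotide bias that raises their chaos-game
descriptor correlation, and same-block diseases sit under a shared subtree
of the hierarchy. Every signal the real pipeline fuses therefore carries the
same latent labels, so an end-to-end run on synthetic data should recover
the planted associations well above chance.

Defaults are the study conditions used by the package's own validation:
60 circRNAs x 12 diseases in 3 blocks, within-block association probability
0.9 against a 0.02 background, 30 genes, sequence lengths 200-1000 nt, and
20% of diseases left without a hierarchy entry to exercise the fusion
fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .containers import (
    AssociationMatrix,
    DiseaseDAG,
    EntityIndex,
    GeneAssociationMatrix,
    SequenceStore,
    normalize_disease_name,
)
from .dataio import write_associations
from .pipeline import DatasetBundle

__all__ = [
    "SyntheticConfig",
    "random_sequences",
    "planted_association_matrix",
    "random_dag",
    "random_gene_map",
    "generate_dataset",
    "write_dataset",
]

_ALPHABET = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; see the module docstring for the defaults."""

    n_circrna: int = 60
    m_disease: int = 12
    g_genes: int = 30
    n_blocks: int = 3
    signal: float = 0.9
    noise: float = 0.02
    seq_len_min: int = 200
    seq_len_max: int = 1000
    dag_missing_frac: float = 0.2
    genes_per_circrna: int = 2
    structured: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.noise < self.signal <= 1:
            raise ValueError("need 0 <= noise < signal <= 1")
        for name in ("n_circrna", "m_disease", "g_genes", "n_blocks"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.seq_len_min < 1 or self.seq_len_max < self.seq_len_min:
            raise ValueError("invalid sequence length range")

    def rngs(self, n: int) -> list[np.random.Generator]:
        """Deterministically derive n child generators from the master seed."""
        seqs = np.random.SeedSequence(self.seed).spawn(n)
        return [np.random.default_rng(s) for s in seqs]


def _blocks(count: int, n_blocks: int) -> np.ndarray:
    """Round-robin block assignment: stable, near-equal sizes."""
    return np.arange(count) % n_blocks


def circrna_labels(config: SyntheticConfig) -> tuple[str, ...]:
    return tuple(f"circ_{i:04d}" for i in range(config.n_circrna))


def disease_labels(config: SyntheticConfig) -> tuple[str, ...]:
    return tuple(f"disease_{j:03d}" for j in range(config.m_disease))


def random_sequences(config: SyntheticConfig) -> SequenceStore:
    """I.i.d. or block-biased random nucleotide sequences.

    Structured mode draws each sequence from a block-specific first-order
    Markov chain (a random transition matrix per block), so same-block
    sequences share a dinucleotide signature and correlate more strongly in
    grid-descriptor space than sequences from different blocks.
    """
    rng = config.rngs(4)[0]
    blocks = _blocks(config.n_circrna, config.n_blocks)
    transition = None
    if config.structured:
        # sharply peaked rows make block signatures well separated
        transition = rng.dirichlet(alpha=[0.4] * 4, size=(config.n_blocks, 4))
    store = SequenceStore()
    for i, circ_id in enumerate(circrna_labels(config)):
        length = int(rng.integers(config.seq_len_min, config.seq_len_max + 1))
        if transition is None:
            seq = "".join(rng.choice(_ALPHABET, size=length))
        else:
            t = transition[blocks[i]]
            states = np.empty(length, dtype=int)
            states[0] = rng.integers(4)
            for p in range(1, length):
                states[p] = rng.choice(4, p=t[states[p - 1]])
            seq = "".join(_ALPHABET[states])
        store.sequences[circ_id] = seq
    return store


def planted_association_matrix(
    config: SyntheticConfig,
) -> tuple[AssociationMatrix, np.ndarray, np.ndarray]:
    """Binary adjacency with planted blocks, plus the latent block labels.

    Cell (i, j) is 1 with probability ``signal`` when circRNA i and disease j
    share a block and ``noise`` otherwise. Returns (matrix, circRNA block
    labels, disease block labels).
    """
    rng = config.rngs(4)[1]
    circ_blocks = _blocks(config.n_circrna, config.n_blocks)
    dis_blocks = _blocks(config.m_disease, config.n_blocks)
    same = circ_blocks[:, None] == dis_blocks[None, :]
    prob = np.where(same, config.signal, config.noise)
    values = (rng.random(prob.shape) < prob).astype(np.int8)
    index = EntityIndex(circrna_labels(config), disease_labels(config))
    return AssociationMatrix(values, index), circ_blocks, dis_blocks


def random_dag(config: SyntheticConfig) -> DiseaseDAG:
    """Random disease hierarchy; a configurable fraction has no entry.

    Structured mode hangs same-block diseases under a shared branch node of
    a common root, so within-block semantic similarity exceeds between-block
    similarity. Unstructured mode attaches each disease to a uniformly
    chosen earlier disease. Acyclic by construction.
    """
    rng = config.rngs(4)[2]
    diseases = [normalize_disease_name(d) for d in disease_labels(config)]
    n_missing = int(round(config.dag_missing_frac * len(diseases)))
    missing = set(rng.choice(len(diseases), size=n_missing, replace=False))
    present = [d for j, d in enumerate(diseases) if j not in missing]
    ancestors: dict[str, frozenset[str]] = {}
    if config.structured:
        blocks = _blocks(config.m_disease, config.n_blocks)
        root = "mesh_root"
        ancestors[root] = frozenset({root})
        for b in range(config.n_blocks):
            branch = f"mesh_branch_{b}"
            ancestors[branch] = frozenset({branch, root})
        for j, d in enumerate(diseases):
            if j in missing:
                continue
            branch = f"mesh_branch_{blocks[j]}"
            ancestors[d] = frozenset({d}) | ancestors[branch]
    else:
        for pos, d in enumerate(present):
            if pos == 0:
                ancestors[d] = frozenset({d})
            else:
                parent = present[int(rng.integers(pos))]
                ancestors[d] = frozenset({d}) | ancestors[parent]
    return DiseaseDAG(ancestors=ancestors, nodes=frozenset(ancestors))


def random_gene_map(config: SyntheticConfig) -> GeneAssociationMatrix:
    """Sparse circRNA-gene adjacency; blocks share gene pools when structured.

    Genes are split into per-block pools; each circRNA receives
    ``genes_per_circrna`` genes from its block's pool (structured) or from
    all genes (unstructured).
    """
    rng = config.rngs(4)[3]
    genes = tuple(f"GENE{g:03d}" for g in range(config.g_genes))
    gene_blocks = _blocks(config.g_genes, config.n_blocks)
    circ_blocks = _blocks(config.n_circrna, config.n_blocks)
    values = np.zeros((config.n_circrna, config.g_genes), dtype=np.int8)
    for i in range(config.n_circrna):
        if config.structured:
            pool = np.flatnonzero(gene_blocks == circ_blocks[i])
        else:
            pool = np.arange(config.g_genes)
        take = min(config.genes_per_circrna, pool.size)
        chosen = rng.choice(pool, size=take, replace=False)
        values[i, chosen] = 1
    return GeneAssociationMatrix(values, circrna_labels(config), genes)


def generate_dataset(
    config: SyntheticConfig | None = None,
) -> tuple[DatasetBundle, np.ndarray, np.ndarray]:
    """Full bundle (associations, sequences, genes, DAG) plus block labels."""
    config = config or SyntheticConfig()
    acd, circ_blocks, dis_blocks = planted_association_matrix(config)
    bundle = DatasetBundle(
        associations=acd,
        sequences=random_sequences(config),
        gene_map=random_gene_map(config),
        dag=random_dag(config),
    )
    return bundle, circ_blocks, dis_blocks


def write_dataset(bundle: DatasetBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the four inputs in the exact formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "associations": outdir / "associations.tsv",
        "fasta": outdir / "sequences.fasta",
        "genes": outdir / "gene_map.tsv",
        "dag": outdir / "dag.tsv",
    }
    write_associations(bundle.associations, paths["associations"])
    with open(paths["fasta"], "w") as fh:
        for circ_id, seq in bundle.sequences.sequences.items():
            fh.write(f">{circ_id}\n")
            for start in range(0, len(seq), 70):
                fh.write(seq[start : start + 70] + "\n")
    with open(paths["genes"], "w") as fh:
        acg = bundle.gene_map
        for i, j in np.argwhere(acg.values == 1):
            fh.write(f"{acg.circrna_ids[i]}\t{acg.gene_symbols[j]}\n")
    with open(paths["dag"], "w") as fh:
        dag = bundle.dag
        if dag is not None:
            # emit child -> immediate-dominating-parent edges; the reader only
            # needs edges whose closure reproduces `ancestors`
            for node in sorted(dag.ancestors):
                above = dag.ancestors[node] - {node}
                for parent in sorted(above):
                    # keep only parents not implied through another ancestor
                    if not any(
                        parent in dag.ancestors[mid] - {mid}
                        for mid in above
                        if mid != parent
                    ):
                        fh.write(f"{node}\t{parent}\n")
    return paths
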