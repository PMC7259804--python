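"""Attribute-specific similarities and their fusion on a small planted dataset.

Generates a synthetic dataset (blocks of circRNAs/diseases with correlated
associations, sequences, genes and hierarchy placement), computes each
similarity source, and shows that fused within-block similarity exceeds
between-block similarity — the structure the classifier later exploits.
"""

import numpy as np

from circda.pipeline import PipelineConfig, build_similarities
from circda.synthetic import SyntheticConfig, generate_dataset

config = SyntheticConfig(n_circrna=30, m_disease=9, n_blocks=3, seed=4)
bundle, circ_blocks, dis_blocks = generate_dataset(config)
acd = bundle.associations
print(f"dataset: {acd.index.n} circRNAs x {acd.index.m} diseases, "
      f"{acd.n_positive} known associations")

s_c, s_d = build_similarities(bundle, PipelineConfig())

def block_contrast(values, blocks):
    same = blocks[:, None] == blocks[None, :]
    off = ~np.eye(len(blocks), dtype=bool)
    return values[same & off].mean(), values[~same].mean()

within_c, between_c = block_contrast(s_c.values, circ_blocks)
within_d, between_d = block_contrast(s_d.values, dis_blocks)
print(f"fused circRNA similarity : within-block {within_c:.3f}  between {between_c:.3f}")
print(f"fused disease similarity : within-block {within_d:.3f}  between {between_d:.3f}")
# Within-block means exceed between-block means for both fused matrices:
# every fused attribute carries the same latent block labels.
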