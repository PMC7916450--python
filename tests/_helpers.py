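"""Shared test helpers."""

import numpy as np

from genofabric.preprocess import GeneSpotTensor


def make_tensor(gene_values, phenotype: str = "P") -> GeneSpotTensor:
    """Build a GeneSpotTensor directly from per-gene spot-by-replica rows."""
    genes = list(gene_values)
    blocks = [np.asarray(gene_values[g], dtype=float) for g in genes]
    gene_ptr = np.concatenate([[0], np.cumsum([b.shape[0] for b in blocks])])
    return GeneSpotTensor(phenotype, genes, gene_ptr, np.vstack(blocks))
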