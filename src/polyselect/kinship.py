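"""Genomic relationship matrix (GRM).

The GRM is the covariance kernel of the polygenic random effect
``u ~ N(0, G sigma_a^2)`` used by the generation-proxy scan, RRBLUP and
the mixed-model GWAS.  Default construction is VanRaden method 1:
dosages centered by twice the allele frequency and the cross-product
scaled by ``sum 2 p (1 - p)``; a per-marker-averaged centered kernel is
available as an alternative scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, allele_frequencies

__all__ = ["GRM", "compute_grm", "write_grm_tsv"]


@dataclass
class GRM:
    matrix: np.ndarray
    sample_ids: list[str]
    n_markers_used: int

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.sample_ids):
            raise ValueError("GRM must be square and match sample ids")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        self.matrix = (m + m.T) / 2.0


def centered_dosages(g: GenotypeMatrix, maf_floor: float = 0.0):
    """Mean-imputed, 2p-centered dosage matrix W and the VanRaden scale.

    Returns (W, scale, kept_index) where ``scale = sum 2 p (1-p)`` over
    the retained (MAF >= maf_floor, polymorphic) variants.
    """
    freq = allele_frequencies(g)
    maf = np.minimum(freq, 1 - freq)
    keep = np.flatnonzero(~np.isnan(maf) & (maf > 0) & (maf >= maf_floor))
    if keep.size == 0:
        raise ValueError("no polymorphic variants available for the GRM")
    d = g.dosages[:, keep].astype(float)
    p = freq[keep]
    miss = g.dosages[:, keep] == MISSING
    if miss.any():
        d[miss] = np.broadcast_to(2 * p, d.shape)[miss]
    W = d - 2 * p
    scale = float(np.sum(2 * p * (1 - p)))
    return W, scale, keep


def compute_grm(
    g: GenotypeMatrix, maf_floor: float = 0.0, scale: str = "vanraden"
) -> GRM:
    """VanRaden method-1 GRM (default) or centered per-marker kernel.

    Missing dosages are mean-imputed per variant; variants with MAF
    below ``maf_floor`` (or monomorphic) are excluded from the kernel.
    ``scale='centered'`` divides the centered cross-product by the
    marker count instead of ``sum 2 p (1-p)``.
    """
    W, vr_scale, keep = centered_dosages(g, maf_floor)
    if scale == "vanraden":
        denom = vr_scale
    elif scale == "centered":
        denom = W.shape[1]
    else:
        raise ValueError("scale must be 'vanraden' or 'centered'")
    G = W @ W.T / denom
    return GRM(G, list(g.samples), int(keep.size))


def write_grm_tsv(grm: GRM, path) -> None:
    """Write the GRM in long `id id value` format."""
    ids = grm.sample_ids
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1):
            rows.append((ids[i], ids[j], grm.matrix[i, j]))
    pd.DataFrame(rows, columns=["id1", "id2", "value"]).to_csv(
        path, sep="\t", index=False, float_format="%.8g"
    )
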