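"""Generation Proxy Selection Mapping (GPSM).

GPSM regresses a generation proxy -- each animal's age at a fixed
reference date -- on allele dosage, one variant at a time, under a
linear mixed model with a genomic relationship kernel.  Because the
polygenic term absorbs the drift covariance between relatives,
significant variants mark allele-frequency change along the pedigree
beyond drift expectation, i.e. ongoing (trait-agnostic) selection.
Multiple testing is controlled by FDR q-values; q < 0.1 is the
conventional discovery rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .genotype_io import GenotypeMatrix
from .kinship import GRM
from .lmm import EigenGRM, fit_null_reml, lmm_scan

__all__ = ["gpsm_scan", "fdr_qvalues"]


def gpsm_scan(
    g: GenotypeMatrix,
    samples: pd.DataFrame,
    grm: GRM | EigenGRM,
    mode: str = "p3d",
    include_sex: bool = False,
    fdr_method: str = "bh",
) -> pd.DataFrame:
    """Scan all variants for association with the generation proxy.

    The response is ``age_at_reference`` (days).  Fixed effects are an
    intercept, plus sex if ``include_sex``.  Returns per-variant
    records with ``beta, se, stat, p, q``; monomorphic variants carry
    NaN and are excluded from the FDR step.
    """
    if "age_at_reference" not in samples.columns:
        raise ValueError("sample table lacks age_at_reference")
    if list(samples["id"]) != list(g.samples):
        raise ValueError("sample table and genotype matrix are misaligned")
    y = samples["age_at_reference"].to_numpy(dtype=float)
    covar = None
    if include_sex:
        covar = (samples["sex"].to_numpy() == "F").astype(float)[:, None]
    records = lmm_scan(g, y, grm, covariates=covar, mode=mode)
    records["q"] = fdr_qvalues(records["p"].to_numpy(), method=fdr_method)
    return records


def fdr_qvalues(p: np.ndarray, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (default), or Storey's
    lambda=0.5 variant.

    NaN p-values propagate to NaN q-values and do not enter the
    correction.  Values must lie in (0, 1].
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if not ok.any():
        return out
    pv = p[ok]
    if (pv <= 0).any() or (pv > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(pv, method="fdr_bh")
    if method == "storey":
        pi0 = min(1.0, float(np.mean(pv > 0.5)) / 0.5) if len(pv) else 1.0
        q = np.minimum(q * pi0, 1.0)
    elif method != "bh":
        raise ValueError("fdr method must be 'bh' or 'storey'")
    out[ok] = q
    return out
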