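"""Linear mixed model machinery shared by the generation-proxy scan,
RRBLUP and the mixed-model GWAS.

Model: ``y = X b + u + e`` with ``u ~ N(0, G sigma_a^2)`` and
``e ~ N(0, I sigma_e^2)``.  Variance components are estimated by REML,
profiled over the ratio ``delta = sigma_e^2 / sigma_a^2`` after a single
eigendecomposition of G (the EMMA rotation).  Per-variant association
tests either reuse the null-model components for every variant (P3D /
EMMAX approximation, the fast path appropriate for dense scans) or
re-optimise them per variant (exact mode).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotype_io import MISSING, GenotypeMatrix
from .kinship import GRM

__all__ = ["VarianceComponents", "EigenGRM", "fit_null_reml", "lmm_scan"]

# profiled variance ratio delta = sigma_e2/sigma_a2, bounded on log10;
# the lower bound keeps V = sigma_a2 (G + delta I) invertible to working
# precision even for a rank-deficient kernel
_LOG_DELTA_BOUNDS = (-5.0, 8.0)


@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_e2: float
    loglik: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.sigma_a2, self.sigma_e2, self.loglik]).all():
            raise ValueError("variance components must be finite")
        if self.sigma_a2 < 0 or self.sigma_e2 <= 0:
            raise ValueError("sigma_a2 must be >= 0 and sigma_e2 > 0")

    @property
    def heritability(self) -> float:
        return self.sigma_a2 / (self.sigma_a2 + self.sigma_e2)


class EigenGRM:
    """Eigendecomposition of a GRM, reusable across fits on one sample set."""

    def __init__(self, grm: GRM, tol: float = 1e-8):
        vals, vecs = np.linalg.eigh(grm.matrix)
        scale = max(abs(vals[-1]), 1.0)
        if vals[0] < -tol * scale:
            raise ValueError(
                f"GRM is not PSD within tolerance (min eigenvalue {vals[0]:g})"
            )
        self.values = np.clip(vals, 0.0, None)
        self.vectors = vecs
        self.sample_ids = list(grm.sample_ids)

    @property
    def n(self) -> int:
        return len(self.values)

    def rotate(self, a: np.ndarray) -> np.ndarray:
        return self.vectors.T @ a


def _reml_profile(d, yr, Xr):
    """Profiled REML pieces at rotated data; returns a function of delta."""
    n, p = Xr.shape
    _, ldet_xx = np.linalg.slogdet(Xr.T @ Xr)

    def pieces(delta: float):
        w = 1.0 / (d + delta)
        Xw = Xr * w[:, None]
        XtWX = Xr.T @ Xw
        XtWy = Xw.T @ yr
        beta = np.linalg.solve(XtWX, XtWy)
        r = yr - Xr @ beta
        rss = float(np.sum(w * r * r))
        sigma_a2 = rss / (n - p)
        _, ldet_xwx = np.linalg.slogdet(XtWX)
        loglik = -0.5 * (
            (n - p) * np.log(2 * np.pi * sigma_a2)
            + np.sum(np.log(d + delta))
            + ldet_xwx
            - ldet_xx
            + (n - p)
        )
        return loglik, sigma_a2, beta

    return pieces


def fit_null_reml(
    y: np.ndarray,
    covariates: np.ndarray | None,
    grm: GRM | EigenGRM,
) -> VarianceComponents:
    """REML variance components for ``y = X b + u + e``.

    ``covariates`` is the fixed-effect design (an intercept is appended
    if no constant column is present; pass None for intercept-only).
    The likelihood is profiled over ``delta = sigma_e^2 / sigma_a^2`` by
    bounded 1-D optimisation on log10(delta) after the EMMA rotation.
    """
    eig = grm if isinstance(grm, EigenGRM) else EigenGRM(grm)
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) != eig.n:
        raise ValueError("response length must match GRM dimension")
    if not np.isfinite(y).all():
        raise ValueError("response must be finite")
    X = _design(covariates, len(y))
    yr = eig.rotate(y)
    Xr = eig.rotate(X)
    pieces = _reml_profile(eig.values, yr, Xr)

    res = optimize.minimize_scalar(
        lambda t: -pieces(10.0 ** t)[0],
        bounds=_LOG_DELTA_BOUNDS,
        method="bounded",
        options={"xatol": 1e-6},
    )
    delta = 10.0 ** res.x
    loglik, sigma_a2, _ = pieces(delta)
    return VarianceComponents(
        sigma_a2=float(sigma_a2),
        sigma_e2=float(sigma_a2 * delta),
        loglik=float(loglik),
    )


def _design(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.any(np.all(X == X[0], axis=0) & (X[0] != 0)):
        X = np.column_stack([np.ones(len(X)), X])
    return X


def _impute_columns(dosages: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages per variant (float output)."""
    d = dosages.astype(float)
    miss = dosages == MISSING
    if miss.any():
        d[miss] = np.nan
        col_mean = np.nanmean(np.where(miss, np.nan, d), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(miss)
        d[idx] = col_mean[idx[1]]
    return d


def lmm_scan(
    g: GenotypeMatrix,
    y: np.ndarray,
    grm: GRM | EigenGRM,
    covariates: np.ndarray | None = None,
    mode: str = "p3d",
) -> pd.DataFrame:
    """Per-variant Wald tests of the dosage effect under the LMM.

    Returns a DataFrame with one row per variant: ``chrom, pos, id,
    beta, se, stat, p`` (effect per ALT-allele copy, in units of the
    response).  Monomorphic variants get NaN results.  ``mode='p3d'``
    reuses the null variance components for every variant; ``'exact'``
    re-optimises them with the variant in the fixed effects.
    """
    if mode not in ("p3d", "exact"):
        raise ValueError("mode must be 'p3d' or 'exact'")
    eig = grm if isinstance(grm, EigenGRM) else EigenGRM(grm)
    y = np.asarray(y, dtype=float)
    if len(y) != g.n_samples or eig.n != g.n_samples:
        raise ValueError("sample sets of genotypes, response and GRM differ")
    X = _design(covariates, len(y))
    yr = eig.rotate(y)
    Xr = eig.rotate(X)
    D = _impute_columns(g.dosages)
    poly = D.std(axis=0) > 0
    Gr = eig.rotate(D)

    if mode == "p3d":
        vc = fit_null_reml(y, covariates, eig)
        delta = vc.sigma_e2 / max(vc.sigma_a2, 1e-12)
        beta, se = _wald_all(eig.values, yr, Xr, Gr, vc.sigma_a2, delta)
        out_vc = None
    else:
        beta = np.empty(g.n_variants)
        se = np.empty(g.n_variants)
        out_vc = np.empty((g.n_variants, 2))
        for j in range(g.n_variants):
            if not poly[j]:
                beta[j] = se[j] = np.nan
                out_vc[j] = np.nan
                continue
            Xj = np.column_stack([Xr, Gr[:, j]])
            pieces = _reml_profile(eig.values, yr, Xj)
            res = optimize.minimize_scalar(
                lambda t: -pieces(10.0 ** t)[0],
                bounds=_LOG_DELTA_BOUNDS,
                method="bounded",
                options={"xatol": 1e-6},
            )
            delta_j = 10.0 ** res.x
            _, sa2, _ = pieces(delta_j)
            b, s = _wald_all(
                eig.values, yr, Xr, Gr[:, j][:, None], sa2, delta_j
            )
            beta[j], se[j] = b[0], s[0]
            out_vc[j] = (sa2, sa2 * delta_j)

    beta[~poly] = np.nan
    se[~poly] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = beta / se
        p = stats.chi2.sf(stat**2, df=1)
    records = g.variants[["chrom", "pos", "id"]].copy()
    records["beta"] = beta
    records["se"] = se
    records["stat"] = stat
    records["p"] = p
    if out_vc is not None:
        records["sigma_a2"] = out_vc[:, 0]
        records["sigma_e2"] = out_vc[:, 1]
    return records


def _wald_all(d, yr, Xr, Gr, sigma_a2, delta):
    """Vectorised GLS Wald pieces for each column of Gr, given VCs.

    V = sigma_a2 * (D + delta I) in the rotated basis; the dosage
    coefficient and its SE come from the partitioned GLS solution.
    """
    w = 1.0 / (d + delta)
    Xw = Xr * w[:, None]
    XtWX = Xr.T @ Xw
    XtWX_inv = np.linalg.inv(XtWX)
    XtWy = Xw.T @ yr
    # per-variant cross products
    gWy = Gr.T @ (w * yr)
    gWX = Gr.T @ Xw  # (m, p)
    gWg = np.einsum("ij,i,ij->j", Gr, w, Gr)
    adj = np.einsum("jp,pq,jq->j", gWX, XtWX_inv, gWX)
    denom = gWg - adj
    num = gWy - gWX @ (XtWX_inv @ XtWy)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = num / denom
        se = np.sqrt(sigma_a2 / denom)
    return beta, se
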