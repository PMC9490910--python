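"""Mixed-model GWAS for teat-number traits, significance thresholds from
independent-marker counts, inflation diagnostics, and single-variant
multi-trait pleiotropy profiling.

The association model is ``Y = W a + X b + Z u + e``: year and season of
birth as fixed-effect factors, a per-variant substitution effect, and a
polygenic term with GRM covariance.  The scan shares the P3D/exact
machinery of the generation-proxy scan.  Genome-wide significant /
suggestive thresholds are ``0.05/N`` and ``1/N`` with N the number of
LD-independent markers; the genomic inflation factor lambda is the
median association chi-square over the null median 0.4549.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix
from .kinship import GRM
from .lmm import EigenGRM, lmm_scan

__all__ = [
    "year_season_factors",
    "mlm_gwas",
    "bonferroni_thresholds",
    "classify_hits",
    "genomic_inflation",
    "single_variant_multitrait",
]

CHI2_1_MEDIAN = 0.45493642311957283  # median of chi-square with 1 df


def year_season_factors(samples: pd.DataFrame) -> np.ndarray:
    """Dummy columns for birth year and season as separate factors.

    Season is parsed from the ``year_season`` label (``<year>_S<k>``,
    with season 1 = December-February).
    """
    year = samples["birth_year"].astype(int)
    season = samples["year_season"].astype(str).str.extract(r"_S(\d)")[0].astype(int)
    dy = pd.get_dummies(year, prefix="y", drop_first=True)
    ds = pd.get_dummies(season, prefix="s", drop_first=True)
    return pd.concat([dy, ds], axis=1).to_numpy(dtype=float)


def mlm_gwas(
    g: GenotypeMatrix,
    samples: pd.DataFrame,
    trait: str,
    grm: GRM | EigenGRM,
    mode: str = "p3d",
) -> pd.DataFrame:
    """Per-variant mixed-model Wald tests of ``trait``.

    Fixed effects: intercept, birth-year and season factors.  Returns
    per-variant records (chrom, pos, id, beta, se, stat, p).
    """
    if trait not in samples.columns:
        raise ValueError(f"trait {trait!r} not in sample table")
    if list(samples["id"]) != list(g.samples):
        raise ValueError("sample table and genotype matrix are misaligned")
    y = samples[trait].to_numpy(dtype=float)
    covar = year_season_factors(samples)
    return lmm_scan(g, y, grm, covariates=covar, mode=mode)


def bonferroni_thresholds(n_independent: int) -> tuple[float, float]:
    """(genome-wide, suggestive) p thresholds 0.05/N and 1/N."""
    if n_independent < 1:
        raise ValueError("independent marker count must be >= 1")
    return 0.05 / n_independent, 1.0 / n_independent


def classify_hits(records: pd.DataFrame, n_independent: int) -> pd.DataFrame:
    """Label each record significant / suggestive / null.

    Significant: p <= 0.05/N (inclusive).  Suggestive: 0.05/N < p < 1/N.
    """
    gw, sugg = bonferroni_thresholds(n_independent)
    p = records["p"].to_numpy(dtype=float)
    label = np.where(
        np.isnan(p), "missing",
        np.where(p <= gw, "significant", np.where(p < sugg, "suggestive", "null")),
    )
    out = records.copy()
    out["class"] = label
    return out


def genomic_inflation(p: np.ndarray) -> float:
    """Genomic inflation factor: median chi2(p) / median of chi2_1."""
    p = np.asarray(p, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no p-values")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def single_variant_multitrait(
    g: GenotypeMatrix,
    samples: pd.DataFrame,
    variant_id: str,
    traits: list,
    use_covariates: bool = True,
) -> pd.DataFrame:
    """Per-trait linear regression of phenotypes on one variant's dosage.

    For each trait: OLS of phenotype on dosage with (optionally) birth
    year and season factors, plus the per-genotype-class phenotype
    means and standard errors.  Raises on a monomorphic variant.
    """
    hits = np.flatnonzero(g.variants["id"].to_numpy() == variant_id)
    if hits.size == 0:
        raise ValueError(f"variant {variant_id!r} not found")
    j = int(hits[0])
    dose = g.dosages[:, j].astype(float)
    called = g.dosages[:, j] != MISSING
    if len(np.unique(dose[called])) < 2:
        raise ValueError(f"variant {variant_id!r} is monomorphic")
    covar = year_season_factors(samples) if use_covariates else None

    rows = []
    for trait in traits:
        y = samples[trait].to_numpy(dtype=float)
        ok = called & ~np.isnan(y)
        X = np.column_stack(
            [np.ones(ok.sum()), dose[ok]]
            + ([covar[ok]] if covar is not None else [])
        )
        yv = y[ok]
        beta, _, rank, _ = np.linalg.lstsq(X, yv, rcond=None)
        resid = yv - X @ beta
        dof = ok.sum() - rank
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.pinv(X.T @ X)
        b, se = float(beta[1]), float(np.sqrt(cov[1, 1]))
        t = b / se
        p = 2 * stats.t.sf(abs(t), dof)
        row = {"trait": trait, "beta": b, "se": se, "stat": t, "p": p}
        for cls in (0, 1, 2):
            mask = ok & (dose == cls)
            n = int(mask.sum())
            row[f"mean_{cls}"] = float(y[mask].mean()) if n else np.nan
            row[f"se_{cls}"] = (
                float(y[mask].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            )
            row[f"n_{cls}"] = n
        rows.append(row)
    return pd.DataFrame(rows)
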