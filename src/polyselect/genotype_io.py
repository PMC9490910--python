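"""Genotype and phenotype input, and SNP quality control.

Genotypes live in a :class:`GenotypeMatrix`: a samples x variants dosage
matrix (count of ALT alleles, 0/1/2, ``-1`` for missing) with a variant
table and the sample identifiers attached by index.  VCF reading goes
through :mod:`cyvcf2`; only biallelic SNPs are retained.

Quality control mirrors a standard imputed-sequence pipeline: imputation
dosage-R2, call rate, minor-allele frequency, an exact Hardy-Weinberg
test, and a mean-depth rule.  Filters combine as AND and the report
breaks removals down per rule so either reading of a compound criterion
is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "QCConfig",
    "read_vcf",
    "read_phenotypes",
    "hwe_exact_test",
    "apply_qc",
    "allele_frequencies",
    "count_independent_markers",
]

logger = logging.getLogger(__name__)

#: Sentinel for a missing dosage.
MISSING = -1

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Samples x variants ALT-dosage matrix with attached metadata.

    Attributes
    ----------
    dosages : ndarray of int8, shape (n_samples, n_variants)
        Count of ALT alleles per genotype; ``MISSING`` (-1) where no call.
    variants : DataFrame
        One row per variant: ``chrom, pos, id, ref, alt`` and optionally
        ``dr2`` (imputation dosage-R2) and ``mean_depth``.
    samples : list of str
        Sample identifiers, row-aligned with ``dosages``.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError(
                f"{self.dosages.shape[1]} dosage columns but "
                f"{len(self.variants)} variant rows"
            )
        if self.dosages.shape[0] != len(self.samples):
            raise ValueError("dosage rows must match sample list")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or missing")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def take_variants(self, index) -> "GenotypeMatrix":
        """Subset to the given variant indices (order preserved)."""
        idx = np.asarray(index)
        return GenotypeMatrix(
            self.dosages[:, idx],
            self.variants.iloc[idx].reset_index(drop=True),
            list(self.samples),
        )

    def take_samples(self, index) -> "GenotypeMatrix":
        idx = np.asarray(index)
        return GenotypeMatrix(
            self.dosages[idx],
            self.variants,
            [self.samples[i] for i in idx],
        )


@dataclass
class QCConfig:
    """Thresholds for SNP quality control.

    ``depth_rule`` selects the direction of the mean-depth filter:
    ``"retain_ge"`` keeps sites with mean depth >= ``depth_threshold``
    (the conventional low-coverage exclusion); ``"retain_lt"`` keeps
    sites below it.
    """

    min_dr2: float = 0.8
    min_call_rate: float = 0.9
    min_maf: float = 0.01
    hwe_min_p: float = 1e-5
    depth_rule: str = "retain_ge"
    depth_threshold: float = 3.0

    def __post_init__(self) -> None:
        if not 0 <= self.min_dr2 <= 1:
            raise ValueError("min_dr2 must be in [0,1]")
        if not 0 <= self.min_call_rate <= 1:
            raise ValueError("min_call_rate must be in [0,1]")
        if not 0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0,0.5]")
        if not 0 <= self.hwe_min_p <= 1:
            raise ValueError("hwe_min_p must be in [0,1]")
        if self.depth_rule not in ("retain_ge", "retain_lt"):
            raise ValueError("depth_rule must be 'retain_ge' or 'retain_lt'")


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Biallelic SNP records are parsed; multiallelic sites and indels are
    skipped with a logged count.  Missing genotypes map to ``MISSING``.
    ``DR2`` and ``DP`` INFO fields, when present, populate the ``dr2``
    and ``mean_depth`` variant columns.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    rows = []
    cols: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        # gts012: 0/1/2 dosage, 3 = missing
        g = rec.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        cols.append(g)
        rows.append(
            {
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "id": rec.ID or f"{rec.CHROM}_{rec.POS}",
                "ref": rec.REF,
                "alt": rec.ALT[0],
                "dr2": rec.INFO.get("DR2", np.nan),
                "mean_depth": rec.INFO.get("DP", np.nan),
            }
        )
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    if not rows:
        raise ValueError(f"no biallelic SNP records in {path}")
    variants = pd.DataFrame(rows)
    if variants["dr2"].isna().all():
        variants = variants.drop(columns="dr2")
    if variants["mean_depth"].isna().all():
        variants = variants.drop(columns="mean_depth")
    dosages = np.column_stack(cols).astype(np.int8)
    gm = GenotypeMatrix(dosages, variants, samples)
    gm.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    return gm


def read_phenotypes(path) -> pd.DataFrame:
    """Read a tab-delimited sample table (id, sex, birth metadata, traits)."""
    tab = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in tab.columns:
        raise ValueError("phenotype table must have an 'id' column")
    if "birth_date" in tab.columns:
        tab["birth_date"] = pd.to_datetime(tab["birth_date"])
    return tab


from functools import lru_cache


@lru_cache(maxsize=4096)
def _hwe_het_probs(n: int, n_rare: int) -> dict:
    """Normalised probabilities of each heterozygote count given the
    sample size and minor-allele count (recurrence from the mode)."""
    mid = n_rare * (2 * n - n_rare) // (2 * n)
    if mid % 2 != n_rare % 2:
        mid += 1
    probs = {mid: 1.0}
    het = mid
    while het >= 2:
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        probs[het - 2] = probs[het] * het * (het - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        het -= 2
    het = mid
    while het <= n_rare - 2:
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        probs[het + 2] = probs[het] * 4.0 * hom_r * hom_c / ((het + 2) * (het + 1))
        het += 2
    total = sum(probs.values())
    return {h: v / total for h, v in probs.items()}


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test (Wigginton et al. 2005).

    Returns the sum of probabilities of all heterozygote-count
    configurations (with the observed allele counts fixed) whose
    probability does not exceed that of the observed configuration.
    Returns NaN for an empty sample.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        return float("nan")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    probs = _hwe_het_probs(n, n_rare)
    p_obs = probs.get(n_Aa, 0.0)
    p = sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12))
    return min(1.0, p)


def hwe_exact_vector(dosages: np.ndarray) -> np.ndarray:
    """Exact HWE p per variant column of a dosage matrix."""
    out = np.empty(dosages.shape[1])
    for j in range(dosages.shape[1]):
        col = dosages[:, j]
        col = col[col != MISSING]
        out[j] = hwe_exact_test(
            int(np.sum(col == 0)), int(np.sum(col == 1)), int(np.sum(col == 2))
        )
    return out


def apply_qc(g: GenotypeMatrix, cfg: QCConfig | None = None):
    """Filter variants by QC rules; return (filtered matrix, report).

    Rules combine as AND: a variant is retained only if it passes every
    rule for which the required annotation is available.  The report is
    a DataFrame with one row per rule giving the number of variants
    failing that rule (before combination), plus totals.
    """
    cfg = cfg or QCConfig()
    d = g.dosages
    n_var = g.n_variants
    called = d != MISSING
    n_called = called.sum(axis=0)

    fail = {}
    if "dr2" in g.variants.columns:
        fail["dr2"] = g.variants["dr2"].to_numpy() < cfg.min_dr2
    call_rate = n_called / d.shape[0]
    fail["call_rate"] = call_rate < cfg.min_call_rate

    freq = allele_frequencies(g)
    maf = np.minimum(freq, 1 - freq)
    fail["maf"] = np.where(np.isnan(maf), True, maf < cfg.min_maf)

    hwe_p = hwe_exact_vector(d)
    fail["hwe"] = np.where(np.isnan(hwe_p), True, hwe_p < cfg.hwe_min_p)

    if "mean_depth" in g.variants.columns:
        depth = g.variants["mean_depth"].to_numpy(dtype=float)
        if cfg.depth_rule == "retain_ge":
            fail["depth"] = depth < cfg.depth_threshold
        else:
            fail["depth"] = depth >= cfg.depth_threshold

    any_fail = np.zeros(n_var, dtype=bool)
    for f in fail.values():
        any_fail |= np.asarray(f, dtype=bool)
    keep = ~any_fail
    report = pd.DataFrame(
        {
            "rule": list(fail) + ["any", "retained"],
            "n_removed": [int(np.sum(f)) for f in fail.values()]
            + [int(any_fail.sum()), int(keep.sum())],
        }
    )
    if keep.sum() == 0:
        logger.warning("apply_qc removed every variant")
    return g.take_variants(np.flatnonzero(keep)), report


def allele_frequencies(g: GenotypeMatrix, subset=None) -> np.ndarray:
    """ALT-allele frequency per variant, ignoring missing genotypes.

    ``subset`` is an optional sample index/mask.  A column with no
    called genotypes yields NaN.
    """
    d = g.dosages
    if subset is not None:
        subset = np.asarray(subset)
        if subset.size == 0 or (subset.dtype == bool and not subset.any()):
            raise ValueError("sample subset is empty")
        d = d[subset]
    called = d != MISSING
    n_alleles = 2 * called.sum(axis=0)
    alt = np.where(called, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_alleles > 0, alt / n_alleles, np.nan)


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage columns, pairwise-complete."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    sx = xv.std()
    sy = yv.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.mean((xv - xv.mean()) * (yv - yv.mean())) / (sx * sy)
    return float(r * r)


def count_independent_markers(
    g: GenotypeMatrix, r2_threshold: float = 0.4, window_snps: int = 50
) -> int:
    """Count LD-independent markers by greedy left-to-right pruning.

    Scanning variants in map order, a variant is dropped when its
    genotype r^2 with any retained variant among the previous
    ``window_snps`` retained markers on the same chromosome exceeds
    ``r2_threshold``.  The retained count estimates the effective number
    of independent tests used for Bonferroni thresholds.
    """
    if g.n_variants == 0:
        raise ValueError("need at least one variant")
    d = g.dosages
    chroms = g.variants["chrom"].to_numpy()
    no_missing = not (d == MISSING).any()
    if no_missing:
        # standardise once so r^2 is a plain dot product
        z = d.astype(float)
        z -= z.mean(axis=0)
        sd = z.std(axis=0)
        sd[sd == 0] = np.inf
        z /= sd
        z /= np.sqrt(d.shape[0])
    kept: list[int] = []
    n = 0
    for j in range(g.n_variants):
        window = [k for k in kept[-window_snps:] if chroms[k] == chroms[j]]
        if window:
            if no_missing:
                r = z[:, window].T @ z[:, j]
                high = bool(np.any(r * r > r2_threshold))
            else:
                high = any(
                    _pairwise_r2(d[:, j], d[:, k]) > r2_threshold for k in window
                )
            if high:
                continue
        kept.append(j)
        n += 1
    return n
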