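"""Selection-signature scans: runs of homozygosity, windowed nucleotide
diversity, theta-pi ratio and FST between phenotype-extreme groups, and
cohort phenotype t-tests.

ROH detection follows the PLINK scanning-window scheme: a 50-SNP window
slides along each sample's chromosome, a window is "compliant" when it
contains at most ``max_het`` heterozygous and ``max_missing`` missing
calls, and a SNP is in the homozygous state when the fraction of
compliant windows covering it reaches the hit threshold.  Maximal
in-state runs that satisfy the minimum SNP count, length, density and
gap criteria are emitted as segments.

The group scans use 50 kb windows advanced in 10 kb steps (coordinates
0-based half-open in all outputs): per-site diversity
``pi = 2c(n-c)/(n(n-1))`` summed over the window and divided by the
window length in bp; the Weir-Cockerham (default) or Hudson FST as a
ratio of sums; and the diversity contrast ``ln(pi_hi / pi_lo)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "ROHParams",
    "PopPair",
    "detect_roh",
    "roh_hotspots",
    "make_windows",
    "window_pi",
    "window_fst",
    "pi_ratio",
    "window_scan",
    "top_fraction_windows",
    "top_k_threshold",
    "cohort_welch_tests",
    "extreme_group_pair",
]


@dataclass
class ROHParams:
    """PLINK-style ROH parameters; defaults follow the standard protocol
    (50-SNP window, 1 het allowed, 1 Mb minimum length, at least 65
    SNPs, 1 SNP per 50 kb density, 1 Mb maximum inter-SNP gap)."""

    window_snps: int = 50
    max_het: int = 1
    max_missing: int = 5
    min_length: float = 1e6
    min_snps: int = 65
    min_density_bp: float = 50_000.0  # at least one SNP per this many bp
    max_gap: float = 1e6
    hit_threshold: float = 0.05


@dataclass
class PopPair:
    """A phenotype-extreme contrast pair (e.g. large- vs small-teat groups)."""

    ids_hi: list
    ids_lo: list
    trait: str = ""
    mean_hi: float = float("nan")
    se_hi: float = float("nan")
    mean_lo: float = float("nan")
    se_lo: float = float("nan")

    def __post_init__(self) -> None:
        if not self.ids_hi or not self.ids_lo:
            raise ValueError("both groups must be nonempty")
        if set(self.ids_hi) & set(self.ids_lo):
            raise ValueError("groups must be disjoint")


def _in_state_flags(het: np.ndarray, miss: np.ndarray, p: ROHParams) -> np.ndarray:
    """Fraction-of-compliant-windows state flags for one sample/chromosome."""
    m = len(het)
    if m < p.window_snps:
        return np.zeros(m, dtype=bool)
    het_c = np.concatenate([[0], np.cumsum(het)])
    mis_c = np.concatenate([[0], np.cumsum(miss)])
    n_win = m - p.window_snps + 1
    starts = np.arange(n_win)
    ok = (
        (het_c[starts + p.window_snps] - het_c[starts] <= p.max_het)
        & (mis_c[starts + p.window_snps] - mis_c[starts] <= p.max_missing)
    )
    ok_c = np.concatenate([[0], np.cumsum(ok)])
    idx = np.arange(m)
    w_lo = np.maximum(0, idx - p.window_snps + 1)
    w_hi = np.minimum(n_win - 1, idx)
    n_cover = w_hi - w_lo + 1
    n_ok = ok_c[w_hi + 1] - ok_c[w_lo]
    return (n_ok / n_cover) >= p.hit_threshold


def _runs_to_segments(pos: np.ndarray, flags: np.ndarray, p: ROHParams):
    """Maximal in-state runs split at large gaps, filtered by criteria."""
    segs = []
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return segs
    breaks = np.flatnonzero(
        (np.diff(idx) > 1) | (np.diff(pos[idx]) > p.max_gap)
    )
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    for a, b in zip(starts, ends):
        i0, i1 = idx[a], idx[b]
        n_snps = i1 - i0 + 1
        length = pos[i1] - pos[i0] + 1
        if n_snps < p.min_snps or length < p.min_length:
            continue
        if length / n_snps > p.min_density_bp:
            continue
        segs.append((int(pos[i0]), int(pos[i1]), int(n_snps), int(length)))
    return segs


def detect_roh(g: GenotypeMatrix, params: ROHParams | None = None) -> pd.DataFrame:
    """Detect runs of homozygosity per sample.

    Returns a DataFrame with columns ``sample, chrom, start, end,
    n_snps, length`` (start/end 1-based inclusive bp, as in the VCF).
    """
    p = params or ROHParams()
    var = g.variants
    out = []
    for chrom, sub in var.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"positions not sorted on chromosome {chrom}")
        cols = sub.index.to_numpy()
        block = g.dosages[:, cols]
        for si, sample in enumerate(g.samples):
            row = block[si]
            het = (row == 1).astype(np.int64)
            miss = (row == MISSING).astype(np.int64)
            flags = _in_state_flags(het, miss, p)
            for start, end, n_snps, length in _runs_to_segments(pos, flags, p):
                out.append((sample, chrom, start, end, n_snps, length))
    return pd.DataFrame(
        out, columns=["sample", "chrom", "start", "end", "n_snps", "length"]
    )


def top_k_threshold(values: np.ndarray, fraction: float) -> tuple[float, int]:
    """Value of the k-th largest element with k = max(1, ceil(fraction*n)).

    Flagging everything >= this threshold yields exactly k flags when
    values are distinct; ties at the threshold are all included.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    n = v.size
    if n == 0:
        raise ValueError("no defined values")
    k = max(1, int(np.ceil(fraction * n)))
    thr = np.sort(v)[n - k]
    return float(thr), k


def roh_hotspots(
    segments: pd.DataFrame,
    variants: pd.DataFrame,
    n_samples: int,
    top_fraction: float = 0.005,
):
    """Per-SNP ROH occurrence and the hotspot SNP set.

    Occurrence is the fraction of samples whose ROH cover each SNP.
    Hotspots are the SNPs at or above the top-``top_fraction`` quantile
    of occurrences (k-th-largest rule, ties included); an all-zero
    occurrence vector yields an empty hotspot set.
    """
    occ = np.zeros(len(variants))
    chrom_index = {}
    for chrom, sub in variants.groupby("chrom", sort=False):
        chrom_index[chrom] = (sub.index.to_numpy(), sub["pos"].to_numpy())
    if len(segments):
        for (sample, chrom), sub in segments.groupby(["sample", "chrom"], sort=False):
            if chrom not in chrom_index:
                continue
            cols, pos = chrom_index[chrom]
            covered = np.zeros(len(pos), dtype=bool)
            for start, end in zip(sub["start"], sub["end"]):
                i0 = np.searchsorted(pos, start, side="left")
                i1 = np.searchsorted(pos, end, side="right")
                covered[i0:i1] = True
            occ[cols[covered]] += 1
    occ = occ / n_samples
    if occ.max() <= 0:
        return occ, np.array([], dtype=int)
    thr, _ = top_k_threshold(occ, top_fraction)
    hotspots = np.flatnonzero((occ >= thr) & (occ > 0))
    return occ, hotspots


def make_windows(
    variants: pd.DataFrame, window: int = 50_000, step: int = 10_000
) -> pd.DataFrame:
    """Sliding windows (0-based half-open) covering each chromosome's SNPs."""
    rows = []
    for chrom, sub in variants.groupby("chrom", sort=False):
        last = int(sub["pos"].max())
        start = 0
        while start < last:
            rows.append((chrom, start, start + window))
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _site_pi(dosages: np.ndarray) -> np.ndarray:
    """Per-site nucleotide diversity 2c(n-c)/(n(n-1)) from called alleles."""
    called = dosages != MISSING
    n_al = 2 * called.sum(axis=0)
    c = np.where(called, dosages, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(
            n_al >= 2, 2.0 * c * (n_al - c) / (n_al * (n_al - 1.0)), 0.0
        )
    return pi


def _window_sums(
    variants: pd.DataFrame, windows: pd.DataFrame, values: np.ndarray
):
    """Sum ``values`` (per SNP) and count SNPs inside each window."""
    sums = np.zeros(len(windows))
    counts = np.zeros(len(windows), dtype=int)
    for chrom, wsub in windows.groupby("chrom", sort=False):
        vsub = variants.index[variants["chrom"] == chrom].to_numpy()
        pos = variants.loc[vsub, "pos"].to_numpy()
        vals = values[vsub]
        cs = np.concatenate([[0.0], np.cumsum(vals)])
        # SNP at 1-based pos falls in [start, end) on the 0-based axis
        i0 = np.searchsorted(pos - 1, wsub["start"].to_numpy(), side="left")
        i1 = np.searchsorted(pos - 1, wsub["end"].to_numpy(), side="left")
        sums[wsub.index.to_numpy()] = cs[i1] - cs[i0]
        counts[wsub.index.to_numpy()] = i1 - i0
    return sums, counts


def window_pi(
    g: GenotypeMatrix, group, windows: pd.DataFrame
) -> pd.DataFrame:
    """Windowed nucleotide diversity for a sample group.

    Window pi is the sum of per-site pi over SNPs in the window divided
    by the window length in bp.  Returns the windows with ``n_snps``
    and ``pi`` columns appended.
    """
    idx = _group_index(g, group)
    pi_site = _site_pi(g.dosages[idx])
    sums, counts = _window_sums(g.variants, windows, pi_site)
    out = windows.copy()
    out["n_snps"] = counts
    out["pi"] = sums / (out["end"] - out["start"])
    return out


def _group_index(g: GenotypeMatrix, group) -> np.ndarray:
    group = list(group)
    if not group:
        raise ValueError("group is empty")
    lookup = {s: i for i, s in enumerate(g.samples)}
    try:
        return np.array([lookup[s] for s in group])
    except KeyError as e:
        raise ValueError(f"sample {e.args[0]!r} not in genotype matrix") from None


def weir_cockerham_components(d1: np.ndarray, d2: np.ndarray):
    """Per-SNP Weir-Cockerham (1984) a, b, c variance components for two
    populations, from dosage matrices (samples x variants)."""
    comp = []
    for d in (d1, d2):
        called = d != MISSING
        n = called.sum(axis=0).astype(float)
        alt = np.where(called, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / (2 * n), np.nan)
            h = np.where(n > 0, (np.where(called, d, 0) == 1).sum(axis=0) / n, np.nan)
        comp.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = comp
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1))
            * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - s2 * (r - 1) / r
            - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0
    valid = (n1 >= 1) & (n2 >= 1) & ~np.isnan(pbar)
    poly = valid & (pbar > 0) & (pbar < 1)
    return a, b, c, poly


def hudson_components(d1: np.ndarray, d2: np.ndarray):
    """Per-SNP Hudson FST numerator/denominator (Bhatia et al. 2013)."""
    comp = []
    for d in (d1, d2):
        called = d != MISSING
        n = called.sum(axis=0).astype(float)
        alt = np.where(called, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, alt / (2 * n), np.nan)
        comp.append((2 * n, p))
    (n1, p1), (n2, p2) = comp
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (n1 - 1)
            - p2 * (1 - p2) / (n2 - 1)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
    poly = (n1 > 1) & (n2 > 1) & ~np.isnan(den) & (den > 0)
    return num, den, poly


def window_fst(
    g: GenotypeMatrix,
    pair: PopPair,
    windows: pd.DataFrame,
    estimator: str = "weir_cockerham",
) -> pd.DataFrame:
    """Windowed FST between the pair's groups as a ratio of sums.

    Windows without a polymorphic site get NaN.
    """
    i_hi = _group_index(g, pair.ids_hi)
    i_lo = _group_index(g, pair.ids_lo)
    if len(i_hi) < 2 or len(i_lo) < 2:
        raise ValueError("each group needs at least two samples")
    d1, d2 = g.dosages[i_hi], g.dosages[i_lo]
    if estimator == "weir_cockerham":
        a, b, c, poly = weir_cockerham_components(d1, d2)
        num = np.where(poly, a, 0.0)
        den = np.where(poly, a + b + c, 0.0)
    elif estimator == "hudson":
        num_s, den_s, poly = hudson_components(d1, d2)
        num = np.where(poly, num_s, 0.0)
        den = np.where(poly, den_s, 0.0)
    else:
        raise ValueError("estimator must be 'weir_cockerham' or 'hudson'")
    num_w, _ = _window_sums(g.variants, windows, num)
    den_sum, _ = _window_sums(g.variants, windows, den)
    n_poly, _ = _window_sums(g.variants, windows, poly.astype(float))
    out = windows.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        out["fst"] = np.where(den_sum > 0, num_w / den_sum, np.nan)
    out["n_polymorphic"] = n_poly.astype(int)
    return out


def pi_ratio(pi_hi: np.ndarray, pi_lo: np.ndarray) -> np.ndarray:
    """ln(pi_hi / pi_lo); NaN (flagged undefined) when either side is 0."""
    pi_hi = np.asarray(pi_hi, dtype=float)
    pi_lo = np.asarray(pi_lo, dtype=float)
    if pi_hi.shape != pi_lo.shape:
        raise ValueError("window vectors must align")
    if (pi_hi < 0).any() or (pi_lo < 0).any():
        raise ValueError("negative diversity values")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where((pi_hi > 0) & (pi_lo > 0), np.log(pi_hi / pi_lo), np.nan)


def window_scan(
    g: GenotypeMatrix,
    pair: PopPair,
    window: int = 50_000,
    step: int = 10_000,
    estimator: str = "weir_cockerham",
    fraction: float = 0.01,
    tails: str = "both",
) -> pd.DataFrame:
    """Full windowed scan: pi per group, FST, pi-ratio and top flags."""
    windows = make_windows(g.variants, window, step)
    hi = window_pi(g, pair.ids_hi, windows)
    lo = window_pi(g, pair.ids_lo, windows)
    fst = window_fst(g, pair, windows, estimator)
    out = windows.copy()
    out["n_snps"] = hi["n_snps"]
    out["pi_hi"] = hi["pi"]
    out["pi_lo"] = lo["pi"]
    out["fst"] = fst["fst"]
    out["pi_ratio"] = pi_ratio(hi["pi"].to_numpy(), lo["pi"].to_numpy())
    out = top_fraction_windows(out, "fst", fraction, "upper", "is_top_fst")
    out = top_fraction_windows(
        out, "pi_ratio", fraction, tails, "is_top_piratio"
    )
    return out


def top_fraction_windows(
    stats_df: pd.DataFrame,
    metric: str,
    fraction: float = 0.01,
    tails: str = "upper",
    flag_column: str | None = None,
) -> pd.DataFrame:
    """Flag windows in the extreme ``fraction`` of a metric.

    ``upper`` flags values at or above the k-th largest (k =
    max(1, ceil(fraction*n)) over defined values; ties included).
    ``both`` flags fraction/2 in each tail.  NaN metric values are
    never flagged; if every value is undefined the flag set is empty.
    """
    flag_column = flag_column or f"is_top_{metric}"
    vals = stats_df[metric].to_numpy(dtype=float)
    out = stats_df.copy()
    defined = ~np.isnan(vals)
    flags = np.zeros(len(vals), dtype=bool)
    if defined.any():
        if tails == "upper":
            thr, _ = top_k_threshold(vals, fraction)
            flags = defined & (vals >= thr)
        elif tails == "both":
            hi_thr, _ = top_k_threshold(vals, fraction / 2)
            lo_thr, _ = top_k_threshold(-vals, fraction / 2)
            flags = defined & ((vals >= hi_thr) | (vals <= -lo_thr))
        else:
            raise ValueError("tails must be 'upper' or 'both'")
    out[flag_column] = flags
    return out


def cohort_welch_tests(samples: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Welch two-sample t-tests of a trait between every birth-year pair.

    Returns a long table (year1, year2, n1, n2, mean1, mean2, t, p)
    with Satterthwaite degrees of freedom; pairs where either cohort
    has fewer than two records get NaN.
    """
    if trait not in samples.columns:
        raise ValueError(f"trait {trait!r} not in sample table")
    years = sorted(samples["birth_year"].unique())
    rows = []
    groups = {
        y: samples.loc[samples["birth_year"] == y, trait].dropna().to_numpy()
        for y in years
    }
    for i, y1 in enumerate(years):
        for y2 in years[i + 1:]:
            a, b = groups[y1], groups[y2]
            if len(a) < 2 or len(b) < 2:
                t = p = np.nan
            else:
                t, p = stats.ttest_ind(a, b, equal_var=False)
            rows.append(
                (y1, y2, len(a), len(b),
                 a.mean() if len(a) else np.nan,
                 b.mean() if len(b) else np.nan,
                 t, p)
            )
    return pd.DataFrame(
        rows, columns=["year1", "year2", "n1", "n2", "mean1", "mean2", "t", "p"]
    )


def extreme_group_pair(
    samples: pd.DataFrame,
    trait: str = "total_teats",
    n_per_group: int = 45,
    hi_year_max: int | None = None,
    lo_year: int | None = None,
    sex: str | None = "F",
) -> PopPair:
    """Build the phenotype-extreme contrast pair.

    The high group takes the ``n_per_group`` largest trait values among
    animals born up to ``hi_year_max`` (default: the second birth year
    present); the low group the smallest values among animals born in
    ``lo_year`` (default: the last birth year).  Restricted to one sex
    when ``sex`` is given, mirroring a sow-based contrast.
    """
    tab = samples
    if sex is not None:
        tab = tab[tab["sex"] == sex]
    years = sorted(tab["birth_year"].unique())
    if hi_year_max is None:
        hi_year_max = years[min(1, len(years) - 1)]
    if lo_year is None:
        lo_year = years[-1]
    early = tab[tab["birth_year"] <= hi_year_max].sort_values(
        trait, ascending=False
    )
    late = tab[tab["birth_year"] == lo_year].sort_values(trait)
    hi = early.head(n_per_group)
    lo = late.head(n_per_group)
    if hi.empty or lo.empty:
        raise ValueError("extreme groups are empty; check year bounds")
    return PopPair(
        ids_hi=hi["id"].tolist(),
        ids_lo=lo["id"].tolist(),
        trait=trait,
        mean_hi=float(hi[trait].mean()),
        se_hi=float(hi[trait].std(ddof=1) / np.sqrt(len(hi))) if len(hi) > 1 else np.nan,
        mean_lo=float(lo[trait].mean()),
        se_lo=float(lo[trait].std(ddof=1) / np.sqrt(len(lo))) if len(lo) > 1 else np.nan,
    )
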