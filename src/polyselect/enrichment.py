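"""QTL-category and gene annotation of candidate regions, with a
bootstrap enrichment test.

Candidate intervals (e.g. merged top-FST windows or padded association
hits) are intersected with a BED-like QTL table (chrom, start, end,
category); a category's richness factor is the fraction of its QTL
entries touched by at least one candidate.  Significance comes from a
bootstrap null: each replicate re-places the same number of intervals,
with the same length distribution, uniformly on the genome, and the
bootstrap p is the plus-one fraction of replicates whose per-category
overlap count reaches the observed one, Benjamini-Hochberg adjusted
across categories.

All intervals are 0-based half-open internally.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "read_qtl_table",
    "annotate_regions",
    "bootstrap_qtl_enrichment",
    "annotate_genes",
    "merge_intervals",
]

logger = logging.getLogger(__name__)


def read_qtl_table(path) -> pd.DataFrame:
    """Read a BED-like QTL table: chrom, start, end, category[, source_id]."""
    tab = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "category"}
    if not required.issubset(tab.columns):
        tab = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "category", "source_id"][
                : len(pd.read_csv(path, sep="\t", header=None, nrows=1).columns)
            ],
        )
    _check_intervals(tab)
    return tab


def _check_intervals(tab: pd.DataFrame) -> None:
    if (tab["start"] > tab["end"]).any():
        raise ValueError("interval start exceeds end")


def merge_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent intervals into maximal disjoint ones."""
    rows = []
    for chrom, sub in intervals.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _overlap_mask(qtls: pd.DataFrame, candidates: pd.DataFrame) -> np.ndarray:
    """Boolean per-QTL: intersects any candidate by >= 1 bp."""
    hit = np.zeros(len(qtls), dtype=bool)
    cand_by_chrom = {
        str(c): (sub["start"].to_numpy(), sub["end"].to_numpy())
        for c, sub in candidates.groupby("chrom", sort=False)
    }
    unmatched = 0
    q_chrom = qtls["chrom"].astype(str).to_numpy()
    q_start = qtls["start"].to_numpy()
    q_end = qtls["end"].to_numpy()
    for i in range(len(qtls)):
        entry = cand_by_chrom.get(q_chrom[i])
        if entry is None:
            unmatched += 1
            continue
        cs, ce = entry
        if np.any((cs < q_end[i]) & (ce > q_start[i])):
            hit[i] = True
    if unmatched and unmatched == len(qtls):
        logger.warning(
            "no QTL chromosome matched any candidate chromosome (%d records)",
            unmatched,
        )
    return hit


def annotate_regions(
    candidates: pd.DataFrame, qtls: pd.DataFrame
) -> pd.DataFrame:
    """Per-category counts of QTLs overlapped by candidate intervals.

    A QTL counts once if any candidate intersects it by at least 1 bp.
    Returns (category, n_overlap, n_total, richness_factor).
    """
    _check_intervals(candidates)
    _check_intervals(qtls)
    hit = _overlap_mask(qtls, candidates)
    out = (
        pd.DataFrame({"category": qtls["category"], "hit": hit})
        .groupby("category", sort=True)
        .agg(n_overlap=("hit", "sum"), n_total=("hit", "size"))
        .reset_index()
    )
    out["richness_factor"] = out["n_overlap"] / out["n_total"]
    return out


def _chrom_sizes_from(
    candidates: pd.DataFrame, qtls: pd.DataFrame
) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for tab in (candidates, qtls):
        for c, e in zip(tab["chrom"].astype(str), tab["end"]):
            sizes[c] = max(sizes.get(c, 0), int(e))
    return sizes


def bootstrap_qtl_enrichment(
    candidates: pd.DataFrame,
    qtls: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    chrom_sizes: dict | None = None,
) -> pd.DataFrame:
    """Bootstrap test of per-category QTL enrichment.

    Each replicate places ``len(candidates)`` intervals with the
    observed length multiset uniformly on the genome (chromosome chosen
    with probability proportional to the placeable span, so no interval
    crosses a chromosome boundary); ``p_boot`` is the plus-one fraction
    of replicates with overlap count >= observed, BH-adjusted to
    ``p_adj`` across categories.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    if chrom_sizes is None:
        chrom_sizes = _chrom_sizes_from(candidates, qtls)
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    lengths = (candidates["end"] - candidates["start"]).to_numpy()
    if lengths.size and lengths.max() > sizes.max():
        raise ValueError("a candidate is longer than every chromosome")

    observed = annotate_regions(candidates, qtls)
    cats = observed["category"].tolist()
    obs_counts = observed["n_overlap"].to_numpy()

    rng = np.random.default_rng(seed)
    ge_counts = np.zeros(len(cats), dtype=int)
    for _ in range(B):
        rows = []
        for L in lengths:
            span = np.maximum(sizes - L, 0.0)
            if span.sum() <= 0:
                raise ValueError("candidate longer than any chromosome")
            ci = rng.choice(len(chroms), p=span / span.sum())
            start = rng.integers(0, int(span[ci]) + 1)
            rows.append((chroms[ci], int(start), int(start + L)))
        placed = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        rep = annotate_regions(placed, qtls)
        ge_counts += (rep["n_overlap"].to_numpy() >= obs_counts).astype(int)

    p_boot = (1 + ge_counts) / (1 + B)
    _, p_adj, _, _ = multipletests(p_boot, method="fdr_bh")
    out = observed.copy()
    out["p_boot"] = p_boot
    out["p_adj"] = np.maximum(p_adj, p_boot)
    return out


def annotate_genes(candidates: pd.DataFrame, gff_path) -> pd.DataFrame:
    """Genes (GFF3 ``gene`` features) intersecting candidate intervals.

    Returns one row per (candidate, gene) pair with the overlap in bp.
    Parsing goes through :mod:`gffutils`; unparseable lines are skipped
    with a log message.
    """
    import gffutils

    _check_intervals(candidates)
    kept = []
    with open(gff_path) as fh:
        for ln, line in enumerate(fh, 1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                kept.append(stripped)
                continue
            parts = stripped.split("\t")
            if len(parts) < 9 or not parts[3].isdigit() or not parts[4].isdigit():
                logger.warning("skipping malformed GFF line %d", ln)
                continue
            kept.append(stripped)
    db = gffutils.create_db(
        "\n".join(kept),
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.id
        name = feat.attributes.get("Name", [gene_id])[0]
        # GFF is 1-based inclusive; convert to 0-based half-open
        genes.append((feat.seqid, feat.start - 1, feat.end, gene_id, name))
    rows = []
    for chrom, gs, ge, gid, name in genes:
        sub = candidates[candidates["chrom"].astype(str) == str(chrom)]
        for ci, (cs, ce) in enumerate(zip(sub["start"], sub["end"])):
            ov = min(ge, ce) - max(gs, cs)
            if ov > 0:
                rows.append(
                    (chrom, cs, ce, gid, name, gs, ge, ov)
                )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "candidate_start", "candidate_end",
            "gene_id", "gene_name", "gene_start", "gene_end", "overlap_bp",
        ],
    )
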