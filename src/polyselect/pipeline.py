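"""End-to-end orchestration: simulate/load and QC genotypes, build the
GRM, run the generation-proxy scan, the Ghat tests, ROH and windowed
scans, the mixed-model GWAS, intersect the evidence tracks, and
(optionally) annotate/enrich against a QTL table.

A single configuration mapping (or YAML file) drives the run; every
stage writes its table(s) as TSV plus a JSON summary with the counts a
report would quote (variants passing QC, discoveries at q < 0.1, top
windows, significant GWAS loci, ...), and the run is a pure function of
(inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import genotype_io as gio
from . import ghat as ghat_mod
from . import gpsm as gpsm_mod
from . import gwas as gwas_mod
from . import selection_scan as scan_mod
from . import simdata
from .kinship import compute_grm
from .lmm import EigenGRM

__all__ = [
    "PipelineConfigError",
    "PipelineDependencyError",
    "run_pipeline",
    "intersect_evidence",
    "load_config",
]

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    """Invalid or inconsistent configuration."""


class PipelineDependencyError(RuntimeError):
    """A stage is enabled whose upstream stage did not run."""


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "polyselect_run",
    "simulate": {},          # SimConfig overrides; set to None to load inputs
    "inputs": None,           # {"vcf": ..., "phenotypes": ...}
    "qc": {"enabled": True},
    "grm": {"maf_floor": 0.0},
    "gpsm": {"enabled": True, "mode": "p3d", "q_threshold": 0.1},
    "ghat": {
        "enabled": True,
        "traits": ["total_teats", "left_teats", "right_teats"],
        "n_perm": 1000,
    },
    "roh": {"enabled": True, "top_fraction": 0.005},
    "scan": {
        "enabled": True,
        "trait": "total_teats",
        "window": 50_000,
        "step": 10_000,
        "fraction": 0.01,
        "n_per_group": 45,
        "tails": "both",
    },
    "gwas": {
        "enabled": True,
        "traits": ["total_teats", "left_teats", "right_teats"],
        "mode": "p3d",
        "r2_threshold": 0.4,
        "r2_window_snps": 50,
    },
    "compare": {"enabled": True, "pad": 25_000},
    "enrich": {"enabled": False, "qtl_table": None, "B": 1000},
    "pleio": {"enabled": True, "variant": None, "traits": None},
}


def load_config(source) -> dict:
    """Merge a config mapping or YAML file over the defaults."""
    if source is None:
        user = {}
    elif isinstance(source, dict):
        user = source
    else:
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    cfg = {}
    for key, val in DEFAULT_CONFIG.items():
        if isinstance(val, dict) and isinstance(user.get(key), dict):
            cfg[key] = {**val, **user[key]}
        elif key in user:
            cfg[key] = user[key]
        else:
            cfg[key] = val if not isinstance(val, dict) else dict(val)
    unknown = set(user) - set(DEFAULT_CONFIG)
    if unknown:
        raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def _write_summary(out: Path, stage: str, payload: dict) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    with open(out / f"{stage}_summary.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=default)


def run_pipeline(config=None, out_dir=None) -> Path:
    """Execute the enabled stages in dependency order.

    Returns a dict of in-memory stage results; ``results["out_dir"]``
    is the run directory holding all TSV outputs and JSON stage
    summaries.  Raises :class:`PipelineConfigError` for bad
    configuration and :class:`PipelineDependencyError` when an enabled
    stage's upstream output is missing.
    """
    cfg = load_config(config)
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    results: dict = {}

    # ---- input stage: simulate or load -------------------------------
    if cfg.get("inputs"):
        paths = cfg["inputs"]
        geno = gio.read_vcf(paths["vcf"])
        samples = gio.read_phenotypes(paths["phenotypes"])
        samples = samples.set_index("id").loc[geno.samples].reset_index()
        truth = None
    elif cfg.get("simulate") is not None:
        try:
            sim_cfg = simdata.SimConfig(**{**cfg["simulate"], "seed": seed})
        except (TypeError, ValueError) as e:
            raise PipelineConfigError(f"bad simulate block: {e}") from e
        geno, samples, truth = simdata.simulate(sim_cfg)
        simdata.write_fixture(geno, samples, truth, out / "fixture", cfg=sim_cfg)
    else:
        raise PipelineConfigError("config must provide 'simulate' or 'inputs'")
    _write_summary(out, "input", {
        "n_samples": geno.n_samples, "n_variants": geno.n_variants,
        "seed": seed, "simulated": truth is not None,
    })

    # truth indices refer to this pre-QC variant table
    results["variants_prefilter"] = geno.variants

    # ---- QC ----------------------------------------------------------
    if cfg["qc"].get("enabled", True):
        qc_kwargs = {k: v for k, v in cfg["qc"].items() if k != "enabled"}
        qc_cfg = gio.QCConfig(**qc_kwargs)
        geno, report = gio.apply_qc(geno, qc_cfg)
        report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        _write_summary(out, "qc", {
            "n_variants_retained": geno.n_variants,
            "per_rule": report.set_index("rule")["n_removed"].to_dict(),
        })
    results["geno"], results["samples"], results["truth"] = geno, samples, truth

    # ---- GRM ---------------------------------------------------------
    grm = compute_grm(geno, maf_floor=cfg["grm"].get("maf_floor", 0.0))
    eig = EigenGRM(grm)
    _write_summary(out, "grm", {
        "n_markers_used": grm.n_markers_used,
        "mean_diag": float(np.mean(np.diag(grm.matrix))),
    })
    results["grm"], results["eig"] = grm, eig

    # ---- GPSM --------------------------------------------------------
    if cfg["gpsm"].get("enabled", True):
        rec = gpsm_mod.gpsm_scan(
            geno, samples, eig, mode=cfg["gpsm"].get("mode", "p3d")
        )
        rec.to_csv(out / "gpsm.tsv", sep="\t", index=False)
        qthr = cfg["gpsm"].get("q_threshold", 0.1)
        n_sig = int((rec["q"] < qthr).sum())
        _write_summary(out, "gpsm", {
            "n_tested": int(rec["p"].notna().sum()),
            "n_significant_q": n_sig, "q_threshold": qthr,
        })
        results["gpsm"] = rec

    # ---- Ghat --------------------------------------------------------
    if cfg["ghat"].get("enabled", True):
        years = sorted(samples["birth_year"].unique())
        early = cfg["ghat"].get("early") or [years[0]]
        late = cfg["ghat"].get("late") or [years[-1]]
        delta = ghat_mod.allele_freq_change(geno, samples, early, late)
        rows = []
        ghat_results = {}
        for ti, trait in enumerate(cfg["ghat"]["traits"]):
            alpha = ghat_mod.rrblup_effects(geno, samples, trait, grm=eig)
            res = ghat_mod.ghat_permutation_test(
                delta, alpha,
                n_perm=int(cfg["ghat"].get("n_perm", 1000)),
                seed=seed * 1000 + ti,
                trait=trait, cohort_early=early, cohort_late=late,
            )
            ghat_results[trait] = res
            rows.append({
                "trait": trait, "ghat": res.ghat, "p_two_sided": res.p_value,
                "p_one_sided": res.p_one_sided, "n_perm": res.n_perm,
                "n_markers": res.n_markers,
            })
        ghat_tab = pd.DataFrame(rows)
        ghat_tab.to_csv(out / "ghat.tsv", sep="\t", index=False)
        _write_summary(out, "ghat", {
            r["trait"]: {"ghat": r["ghat"], "p_two_sided": r["p_two_sided"]}
            for r in rows
        })
        results["ghat"] = ghat_tab
        results["ghat_results"] = ghat_results

    # ---- ROH ---------------------------------------------------------
    if cfg["roh"].get("enabled", True):
        roh_kwargs = {
            k: v for k, v in cfg["roh"].items()
            if k not in ("enabled", "top_fraction")
        }
        segs = scan_mod.detect_roh(geno, scan_mod.ROHParams(**roh_kwargs))
        segs.to_csv(out / "roh_segments.tsv", sep="\t", index=False)
        occ, hot = scan_mod.roh_hotspots(
            segs, geno.variants, geno.n_samples,
            top_fraction=cfg["roh"].get("top_fraction", 0.005),
        )
        hot_tab = geno.variants.iloc[hot][["chrom", "pos", "id"]].copy()
        hot_tab["occurrence"] = occ[hot]
        hot_tab.to_csv(out / "roh_hotspots.tsv", sep="\t", index=False)
        _write_summary(out, "roh", {
            "n_segments": len(segs), "n_hotspot_snps": len(hot),
            "max_occurrence": float(occ.max()) if len(occ) else 0.0,
        })
        results["roh"] = segs

    # ---- windowed scan -----------------------------------------------
    if cfg["scan"].get("enabled", True):
        pair = scan_mod.extreme_group_pair(
            samples, trait=cfg["scan"].get("trait", "total_teats"),
            n_per_group=int(cfg["scan"].get("n_per_group", 45)),
        )
        win = scan_mod.window_scan(
            geno, pair,
            window=int(cfg["scan"]["window"]), step=int(cfg["scan"]["step"]),
            fraction=float(cfg["scan"]["fraction"]),
            tails=cfg["scan"].get("tails", "both"),
        )
        win.to_csv(out / "scan_windows.tsv", sep="\t", index=False)
        _write_summary(out, "scan", {
            "n_windows": len(win),
            "n_top_fst": int(win["is_top_fst"].sum()),
            "n_top_piratio": int(win["is_top_piratio"].sum()),
            "group_hi_mean": pair.mean_hi, "group_lo_mean": pair.mean_lo,
        })
        results["scan"] = win

    # ---- GWAS --------------------------------------------------------
    if cfg["gwas"].get("enabled", True):
        n_ind = gio.count_independent_markers(
            geno,
            r2_threshold=float(cfg["gwas"]["r2_threshold"]),
            window_snps=int(cfg["gwas"]["r2_window_snps"]),
        )
        gw_thr, sugg_thr = gwas_mod.bonferroni_thresholds(n_ind)
        gwas_tables = {}
        summary = {"n_independent_markers": n_ind,
                   "genome_wide_threshold": gw_thr,
                   "suggestive_threshold": sugg_thr}
        for trait in cfg["gwas"]["traits"]:
            rec = gwas_mod.mlm_gwas(
                geno, samples, trait, eig, mode=cfg["gwas"].get("mode", "p3d")
            )
            rec = gwas_mod.classify_hits(rec, n_ind)
            rec.to_csv(out / f"gwas_{trait}.tsv", sep="\t", index=False)
            gwas_tables[trait] = rec
            summary[trait] = {
                "lambda": gwas_mod.genomic_inflation(rec["p"].dropna()),
                "n_significant": int((rec["class"] == "significant").sum()),
                "n_suggestive": int((rec["class"] == "suggestive").sum()),
            }
        _write_summary(out, "gwas", summary)
        results["gwas"] = gwas_tables
        results["n_independent"] = n_ind

    # ---- comparison (GWAS x scan) ------------------------------------
    if cfg["compare"].get("enabled", True):
        if "gwas" not in results:
            raise PipelineDependencyError("compare stage requires the gwas stage")
        if "scan" not in results:
            raise PipelineDependencyError("compare stage requires the scan stage")
        trait = cfg["scan"].get("trait", "total_teats")
        rec = results["gwas"].get(trait)
        if rec is None:
            rec = next(iter(results["gwas"].values()))
        hits = rec[rec["class"] == "significant"]
        common = intersect_evidence(
            hits, results["scan"], pad=int(cfg["compare"]["pad"])
        )
        common.to_csv(out / "common_regions.tsv", sep="\t", index=False)
        _write_summary(out, "compare", {
            "n_gwas_hits": len(hits), "n_common_regions": len(common),
        })
        results["common"] = common

    # ---- enrichment --------------------------------------------------
    if cfg["enrich"].get("enabled", False):
        if cfg["enrich"].get("qtl_table") is None:
            raise PipelineConfigError("enrich stage requires qtl_table")
        if "scan" not in results:
            raise PipelineDependencyError("enrich stage requires the scan stage")
        qtls = enr.read_qtl_table(cfg["enrich"]["qtl_table"])
        flagged = results["scan"]
        cand = enr.merge_intervals(
            flagged[flagged["is_top_fst"] | flagged["is_top_piratio"]]
        )
        tab = enr.bootstrap_qtl_enrichment(
            cand, qtls, B=int(cfg["enrich"]["B"]), seed=seed
        )
        tab.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        _write_summary(out, "enrich", {
            "n_candidates": len(cand),
            "n_categories_padj_lt_0.05": int((tab["p_adj"] < 0.05).sum()),
        })
        results["enrichment"] = tab

    # ---- pleiotropy profile ------------------------------------------
    if cfg["pleio"].get("enabled", True):
        if "gwas" not in results:
            raise PipelineDependencyError("pleio stage requires the gwas stage")
        variant = cfg["pleio"].get("variant")
        trait = cfg["scan"].get("trait", "total_teats")
        rec = results["gwas"].get(trait)
        if rec is None:
            rec = next(iter(results["gwas"].values()))
        if variant is None:
            ok = rec.dropna(subset=["p"])
            variant = ok.loc[ok["p"].idxmin(), "id"]
        traits = cfg["pleio"].get("traits") or (
            [trait] + [t for t in simdata.ECON_TRAITS if t in samples.columns]
        )
        prof = gwas_mod.single_variant_multitrait(geno, samples, variant, traits)
        prof.insert(0, "variant", variant)
        prof.to_csv(out / "pleiotropy.tsv", sep="\t", index=False)
        _write_summary(out, "pleio", {
            "variant": variant,
            "betas": {r["trait"]: r["beta"] for _, r in prof.iterrows()},
        })
        results["pleio"] = prof

    results["out_dir"] = out
    return results


def intersect_evidence(
    gwas_hits: pd.DataFrame,
    scan_windows: pd.DataFrame,
    pad: int = 25_000,
) -> pd.DataFrame:
    """Regions supported by both the GWAS and the windowed-scan track.

    Flagged scan windows are merged into maximal regions; GWAS hits
    (rows with ``chrom``/``pos``) are padded by ``pad`` bp on each side
    and merged; the intersection of the two tracks is returned with the
    number of contributing hits and windows per region.
    """
    flagged = scan_windows
    if "is_top_fst" in scan_windows.columns or "is_top_piratio" in scan_windows.columns:
        mask = np.zeros(len(scan_windows), dtype=bool)
        for col in ("is_top_fst", "is_top_piratio"):
            if col in scan_windows.columns:
                mask |= scan_windows[col].to_numpy(dtype=bool)
        flagged = scan_windows[mask]
    if flagged.empty or gwas_hits.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_hits", "n_windows"])
    scan_regions = enr.merge_intervals(flagged[["chrom", "start", "end"]])
    hit_iv = pd.DataFrame({
        "chrom": gwas_hits["chrom"].to_numpy(),
        "start": np.maximum(gwas_hits["pos"].to_numpy() - 1 - pad, 0),
        "end": gwas_hits["pos"].to_numpy() + pad,
    })
    hit_regions = enr.merge_intervals(hit_iv)
    rows = []
    for chrom, ssub in scan_regions.groupby("chrom", sort=False):
        hsub = hit_regions[hit_regions["chrom"] == chrom]
        for _, s in ssub.iterrows():
            for _, h in hsub.iterrows():
                lo = max(s["start"], h["start"])
                hi = min(s["end"], h["end"])
                if hi > lo:
                    n_hits = int(np.sum(
                        (gwas_hits["chrom"].to_numpy() == chrom)
                        & (gwas_hits["pos"].to_numpy() - 1 >= s["start"] - pad)
                        & (gwas_hits["pos"].to_numpy() - 1 < s["end"] + pad)
                    ))
                    n_windows = int(np.sum(
                        (flagged["chrom"].to_numpy() == chrom)
                        & (flagged["start"].to_numpy() < hi)
                        & (flagged["end"].to_numpy() > lo)
                    ))
                    rows.append((chrom, int(lo), int(hi), n_hits, n_windows))
    # scan and hit tracks are each disjoint after merging, so the
    # pairwise intersections are maximal and non-overlapping already
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_hits", "n_windows"]
    )
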