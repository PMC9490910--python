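"""Forward-in-time simulator of a closed breeding population under
directional polygenic selection.

The simulator emulates a nucleus pig herd genotyped across consecutive
birth-year cohorts: founder genotypes are drawn site-wise from a Beta
allele-frequency spectrum, haplotypes are formed by random phasing, and
each cohort is bred from truncation-selected parents of the previous two
cohorts (overlapping generations), with crossover-based gamete formation
giving realistic local linkage disequilibrium.  A polygenic "selected"
index drives parent choice; an integer teat-count trait is genetically
coupled to it through one or more injected antagonistic pleiotropic QTL,
so that sustained selection on the index drags teat number in the
direction of ``pleiotropy_sign``.  Economic traits (litter size/weight at
weaning, days/backfat/loin area at 100 kg analogues) are linear in the
pleiotropic-locus dosage with configurable signs.

Ground truth (QTL positions, effects, per-year allele frequencies) is
retained in :class:`SimTruth` for parameter-recovery tests, and fixtures
round-trip through VCF + TSV via :func:`write_fixture`.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_founders",
    "simulate_breeding",
    "assign_phenotypes",
    "simulate",
    "write_fixture",
]

ECON_TRAITS = ("LSW", "LWW", "D100", "B100", "L100")
# sign of each economic trait's dependence on the pleiotropic locus,
# relative to the locus's effect on teat number: D100/B100 move with the
# teat trend, LSW/LWW/L100 against it.
ECON_SIGNS = {"LSW": -1.0, "LWW": -1.0, "D100": 1.0, "B100": 1.0, "L100": -1.0}
ECON_BASE = {"LSW": 10.0, "LWW": 60.0, "D100": 160.0, "B100": 12.0, "L100": 40.0}
ECON_NOISE_SD = {"LSW": 2.0, "LWW": 8.0, "D100": 8.0, "B100": 2.0, "L100": 4.0}


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the simulated herd.

    Defaults emulate the cohort structure of a factory-farmed boar-line
    nucleus herd: roughly a thousand genotyped animals born across nine
    birth-year cohorts (2009-2017), predominantly female, under strong
    truncation selection on a polygenic index, with three antagonistic
    pleiotropic QTL coupling the index to teat number (one per region,
    mirroring the three pleiotropic genome regions such a herd shows).
    """

    n_founders: int = 600
    birth_years: tuple = tuple(range(2009, 2018))
    n_offspring_per_year: int = 600
    n_genotyped_per_year: int = 110
    prop_female: float = 0.8
    n_snps: int = 5000
    n_chromosomes: int = 10
    chrom_length_bp: int = 5_000_000
    founder_maf_beta: tuple = (0.8, 0.8)
    n_qtl_selected: int = 20
    n_qtl_teat: int = 60
    n_qtl_pleiotropic: int = 3
    pleiotropy_sign: int = -1
    h2_selected: float = 0.8
    h2_teat: float = 0.4
    selection_fraction: float = 0.2
    # floors on the number of parents per sex, so truncation intensity
    # cannot collapse the effective population size
    min_sires: int = 50
    min_dams: int = 250
    drift_only: bool = False
    seed: int = 0
    # mean number of extra crossovers beyond the obligate one per chromosome
    extra_crossover_rate: float = 3.0
    teat_base: float = 14.0

    def __post_init__(self) -> None:
        counts = (
            self.n_founders,
            self.n_offspring_per_year,
            self.n_genotyped_per_year,
            self.n_snps,
            self.n_chromosomes,
            self.chrom_length_bp,
            self.n_qtl_selected,
            self.n_qtl_teat,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if self.n_genotyped_per_year > self.n_offspring_per_year:
            raise ValueError("cannot genotype more animals than are born")
        if self.n_qtl_pleiotropic > min(self.n_qtl_selected, self.n_qtl_teat):
            raise ValueError("n_qtl_pleiotropic exceeds a QTL set size")
        if self.n_qtl_pleiotropic < 0:
            raise ValueError("n_qtl_pleiotropic must be >= 0")
        if list(self.birth_years) != sorted(set(self.birth_years)):
            raise ValueError("birth_years must be strictly increasing")
        if not 0 < self.prop_female < 1:
            raise ValueError("prop_female must be in (0,1)")
        if not 0 < self.h2_selected <= 1 or not 0 < self.h2_teat <= 1:
            raise ValueError("heritabilities must be in (0,1]")
        if not 0 < self.selection_fraction <= 1:
            raise ValueError("selection_fraction must be in (0,1]")
        if self.pleiotropy_sign not in (-1, 1):
            raise ValueError("pleiotropy_sign must be +1 or -1")
        a, b = self.founder_maf_beta
        if a <= 0 or b <= 0:
            raise ValueError("founder_maf_beta parameters must be positive")

    @property
    def reference_date(self) -> datetime.date:
        """Reference date for ages: Dec 21 of the last birth year."""
        return datetime.date(self.birth_years[-1], 12, 21)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SimTruth:
    """Simulator ground truth for parameter-recovery tests."""

    qtl_indices_selected: np.ndarray
    qtl_effects_selected: np.ndarray
    qtl_indices_teat: np.ndarray
    qtl_effects_teat: np.ndarray
    pleiotropic_indices: np.ndarray
    per_year_allele_freq: np.ndarray  # (n_years, n_variants)
    birth_years: tuple

    def __post_init__(self) -> None:
        f = self.per_year_allele_freq
        if f.shape[0] != len(self.birth_years):
            raise ValueError("per_year_allele_freq rows must match birth_years")
        ok = np.isnan(f) | ((f >= 0) & (f <= 1))
        if not ok.all():
            raise ValueError("allele frequencies must lie in [0,1]")


def _variant_table(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_snps // cfg.n_chromosomes)
    per_chrom[: cfg.n_snps % cfg.n_chromosomes] += 1
    rows = []
    for c, n in enumerate(per_chrom, start=1):
        pos = np.sort(rng.choice(np.arange(1, cfg.chrom_length_bp), size=n, replace=False))
        for p in pos:
            rows.append((str(c), int(p)))
    tab = pd.DataFrame(rows, columns=["chrom", "pos"])
    tab["id"] = [f"snp_{c}_{p}" for c, p in zip(tab.chrom, tab.pos)]
    tab["ref"] = "A"
    tab["alt"] = "G"
    return tab


def simulate_founders(cfg: SimConfig) -> GenotypeMatrix:
    """Draw founder genotypes: per site, Binomial(2, p) with p ~ Beta(a, b).

    Sites are laid out in map order on ``n_chromosomes`` chromosomes with
    uniform random positions.  Reproducible for a given (cfg, seed).
    """
    rng = np.random.default_rng([cfg.seed, 1])
    variants = _variant_table(cfg, rng)
    a, b = cfg.founder_maf_beta
    p = rng.beta(a, b, size=cfg.n_snps)
    dosages = rng.binomial(2, p, size=(cfg.n_founders, cfg.n_snps)).astype(np.int8)
    samples = [f"F{i:04d}" for i in range(cfg.n_founders)]
    gm = GenotypeMatrix(dosages, variants, samples)
    gm.drawn_freq = p  # type: ignore[attr-defined]
    return gm


def _phase(dosages: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random phasing of genotypes into a (n, 2, m) haplotype array."""
    n, m = dosages.shape
    h1 = (dosages == 2).astype(np.int8)
    het = dosages == 1
    coin = rng.integers(0, 2, size=(n, m)).astype(np.int8)
    h1 = h1 + np.where(het, coin, 0).astype(np.int8)
    h2 = dosages - h1
    return np.stack([h1, h2], axis=1).astype(np.int8)


def _chrom_slices(variants: pd.DataFrame) -> list[slice]:
    slices = []
    chroms = variants["chrom"].to_numpy()
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            slices.append(slice(start, i))
            start = i
    return slices


def _gamete(
    hap: np.ndarray,
    slices: list[slice],
    positions: np.ndarray,
    chrom_len: int,
    xo_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Form one gamete from a parent's (2, m) haplotypes.

    Each chromosome receives at least one crossover, at uniform bp
    positions, plus Poisson(``xo_rate``) extras; the starting haplotype
    is chosen at random per chromosome.
    """
    m = hap.shape[1]
    out = np.empty(m, dtype=np.int8)
    for sl in slices:
        pos = positions[sl]
        n_xo = 1 + rng.poisson(xo_rate)
        breaks = np.sort(rng.integers(1, chrom_len, size=n_xo))
        # haplotype index switches at each break
        switch_counts = np.searchsorted(breaks, pos, side="right")
        which = (rng.integers(0, 2) + switch_counts) % 2
        seg = hap[:, sl]
        out[sl] = np.where(which == 0, seg[0], seg[1])
    return out


def _draw_truth(
    cfg: SimConfig, founder_freq: np.ndarray, rng: np.random.Generator
) -> tuple:
    """Choose QTL positions and effects for the selected and teat traits.

    Selected-trait QTL model loci under sustained directional selection
    that are still sweeping through the study window: they are placed on
    sites with founder MAF in [0.2, 0.45], the minor allele is favoured
    (so each has headroom to rise), and effect magnitudes are large
    relative to the polygenic background.  Teat-only QTL sit anywhere
    segregating (MAF >= 0.05) with modest effects of random sign.
    Pleiotropic QTL belong to both sets; their teat effect is tied to
    the allele favoured by selection with the sign of
    ``pleiotropy_sign``.
    """
    maf = np.minimum(founder_freq, 1 - founder_freq)
    segregating = np.flatnonzero(maf >= 0.05)
    sweepable = np.flatnonzero((maf >= 0.2) & (maf <= 0.45))
    if len(sweepable) < cfg.n_qtl_selected:
        raise ValueError("too few intermediate-frequency sites for selected QTL")
    pleio = rng.choice(sweepable, size=cfg.n_qtl_pleiotropic, replace=False)
    sel_only = rng.choice(
        np.setdiff1d(sweepable, pleio),
        size=cfg.n_qtl_selected - cfg.n_qtl_pleiotropic,
        replace=False,
    )
    sel_idx = np.sort(np.concatenate([pleio, sel_only]))
    teat_pool = np.setdiff1d(segregating, sel_idx)
    if len(teat_pool) < cfg.n_qtl_teat - cfg.n_qtl_pleiotropic:
        raise ValueError("too few segregating sites for teat QTL")
    teat_only = rng.choice(
        teat_pool, size=cfg.n_qtl_teat - cfg.n_qtl_pleiotropic, replace=False
    )
    teat_idx = np.sort(np.concatenate([pleio, teat_only]))

    sel_map = {}
    pleio_set = set(pleio.tolist())
    for j in sel_idx:
        # favour the minor allele: the swept variant is still rising
        sgn = 1.0 if founder_freq[j] <= 0.5 else -1.0
        mag = 3.0 if j in pleio_set else rng.uniform(2.5, 4.0)
        sel_map[j] = mag * sgn
    teat_eff = np.empty(len(teat_idx))
    for k, j in enumerate(teat_idx):
        if j in pleio_set:
            # pleiotropy tied to the allele favoured by selection here
            teat_eff[k] = cfg.pleiotropy_sign * 2.5 * np.sign(sel_map[j])
        else:
            teat_eff[k] = rng.uniform(0.05, 0.35) * rng.choice([-1.0, 1.0])
    return (
        sel_idx,
        np.array([sel_map[j] for j in sel_idx]),
        teat_idx,
        teat_eff,
        np.sort(pleio),
    )


def _selected_phenotype(
    gv: np.ndarray, h2: float, gv_var: float, rng: np.random.Generator
) -> np.ndarray:
    if h2 >= 1.0:
        return gv.copy()
    noise_sd = np.sqrt(gv_var * (1 - h2) / h2) if gv_var > 0 else 1.0
    return gv + rng.normal(0, noise_sd, size=gv.shape)


def simulate_breeding(cfg: SimConfig, founders: GenotypeMatrix):
    """Breed the cohort series from the founders.

    For each birth year, sires and dams are truncation-selected on the
    polygenic selected-trait phenotype (top ``selection_fraction`` per
    sex, subject to the ``min_sires``/``min_dams`` floors; random under
    ``drift_only``) from the previous two cohorts (founders seed the
    first two years).  The whole cohort breeds, but only a random
    ``n_genotyped_per_year`` animals per cohort enter the returned
    study sample, as in a partially genotyped herd.  Returns the study
    genotypes, a sample table with pedigree and birth metadata, and the
    :class:`SimTruth` ground truth (per-year frequencies computed on
    the full cohorts).
    """
    rng = np.random.default_rng([cfg.seed, 2])
    variants = founders.variants
    positions = variants["pos"].to_numpy()
    slices = _chrom_slices(variants)
    m = founders.n_variants

    founder_freq = founders.dosages.mean(axis=0) / 2.0
    sel_idx, sel_eff, teat_idx, teat_eff, pleio = _draw_truth(cfg, founder_freq, rng)

    founder_hap = _phase(founders.dosages, rng)
    founder_gv = founders.dosages[:, sel_idx].astype(float) @ sel_eff
    gv_var = max(float(np.var(founder_gv)), 1e-12)

    # pool entries: (hap array, sex array, phenotype array, id list)
    founder_sex = np.array(
        ["F" if s else "M" for s in rng.random(cfg.n_founders) < cfg.prop_female]
    )
    # guarantee both sexes among founders
    if (founder_sex == "M").sum() == 0:
        founder_sex[0] = "M"
    if (founder_sex == "F").sum() == 0:
        founder_sex[0] = "F"
    founder_pheno = _selected_phenotype(founder_gv, cfg.h2_selected, gv_var, rng)

    cohorts = []  # per birth year: dict with hap, sex, pheno, ids
    prev = [
        {
            "hap": founder_hap,
            "sex": founder_sex,
            "pheno": founder_pheno,
            "ids": np.array(founders.samples),
        }
    ]

    all_rows = []
    all_dosages = []
    per_year_freq = np.empty((len(cfg.birth_years), m))

    for yi, year in enumerate(cfg.birth_years):
        pool = {
            k: np.concatenate([c[k] for c in prev])
            if k != "hap"
            else np.concatenate([c["hap"] for c in prev], axis=0)
            for k in ("hap", "sex", "pheno", "ids")
        }
        sires, dams = _select_parents(cfg, pool, rng)
        n_off = cfg.n_offspring_per_year
        sire_pick = rng.integers(0, len(sires["ids"]), size=n_off)
        dam_pick = rng.integers(0, len(dams["ids"]), size=n_off)

        hap = np.empty((n_off, 2, m), dtype=np.int8)
        for i in range(n_off):
            hap[i, 0] = _gamete(
                sires["hap"][sire_pick[i]], slices, positions,
                cfg.chrom_length_bp, cfg.extra_crossover_rate, rng,
            )
            hap[i, 1] = _gamete(
                dams["hap"][dam_pick[i]], slices, positions,
                cfg.chrom_length_bp, cfg.extra_crossover_rate, rng,
            )
        dosages = hap.sum(axis=1).astype(np.int8)
        per_year_freq[yi] = dosages.mean(axis=0) / 2.0

        gv = dosages[:, sel_idx].astype(float) @ sel_eff
        pheno = _selected_phenotype(gv, cfg.h2_selected, gv_var, rng)
        sex = np.array(
            ["F" if s else "M" for s in rng.random(n_off) < cfg.prop_female]
        )
        if (sex == "M").sum() == 0:
            sex[0] = "M"
        if (sex == "F").sum() == 0:
            sex[0] = "F"
        ids = np.array([f"Y{year}_{i:04d}" for i in range(n_off)])

        months = rng.integers(1, 13, size=n_off)
        days = rng.integers(1, 29, size=n_off)
        ref = cfg.reference_date
        # only a subset of each cohort is genotyped and enters the study
        # sample; the whole cohort breeds
        genotyped = np.sort(
            rng.choice(n_off, size=cfg.n_genotyped_per_year, replace=False)
        )
        for i in genotyped:
            bdate = datetime.date(year, int(months[i]), int(days[i]))
            if bdate > ref:
                bdate = ref
            all_rows.append(
                {
                    "id": ids[i],
                    "sex": sex[i],
                    "birth_date": bdate.isoformat(),
                    "birth_year": year,
                    "year_season": _year_season(bdate),
                    "age_at_reference": (ref - bdate).days,
                    "sire_id": sires["ids"][sire_pick[i]],
                    "dam_id": dams["ids"][dam_pick[i]],
                    "selected_trait": pheno[i],
                }
            )
        all_dosages.append(dosages[genotyped])

        cohort = {"hap": hap, "sex": sex, "pheno": pheno, "ids": ids}
        cohorts.append(cohort)
        prev = cohorts[-2:] if len(cohorts) >= 2 else [cohorts[-1], *prev][:2]

    samples = pd.DataFrame(all_rows)
    geno = GenotypeMatrix(
        np.vstack(all_dosages), variants, samples["id"].tolist()
    )
    truth = SimTruth(
        qtl_indices_selected=sel_idx,
        qtl_effects_selected=sel_eff,
        qtl_indices_teat=teat_idx,
        qtl_effects_teat=teat_eff,
        pleiotropic_indices=pleio,
        per_year_allele_freq=per_year_freq,
        birth_years=tuple(cfg.birth_years),
    )
    return geno, samples, truth


def _select_parents(cfg: SimConfig, pool: dict, rng: np.random.Generator):
    out = []
    for sex, floor in (("M", cfg.min_sires), ("F", cfg.min_dams)):
        mask = pool["sex"] == sex
        n_sex = int(mask.sum())
        if n_sex == 0:
            raise ValueError(
                f"no candidate parents of sex {sex}; selection_fraction or "
                "cohort sizes too small"
            )
        n_keep = min(
            n_sex, max(1, floor, int(round(cfg.selection_fraction * n_sex)))
        )
        idx = np.flatnonzero(mask)
        if cfg.drift_only:
            chosen = rng.choice(idx, size=n_keep, replace=False)
        else:
            order = np.argsort(pool["pheno"][idx])[::-1]
            chosen = idx[order[:n_keep]]
        out.append({k: pool[k][chosen] for k in ("hap", "sex", "pheno", "ids")})
    return out[0], out[1]


def _year_season(d: datetime.date) -> str:
    # seasons: 1 Dec-Feb (December keeps its own calendar year), 2 Mar-May,
    # 3 Jun-Aug, 4 Sep-Nov
    season = {12: 1, 1: 1, 2: 1, 3: 2, 4: 2, 5: 2, 6: 3, 7: 3, 8: 3,
              9: 4, 10: 4, 11: 4}[d.month]
    return f"{d.year}_S{season}"


def assign_phenotypes(
    cfg: SimConfig,
    genotypes: GenotypeMatrix,
    truth: SimTruth,
    samples: pd.DataFrame,
) -> pd.DataFrame:
    """Attach teat-count and economic-trait phenotypes to the sample table.

    The teat count is a liability-threshold trait: liability = base +
    genetic value + Gaussian noise scaled to ``h2_teat``, rounded and
    clipped to the integer range 10-18; the left-teat count is a
    binomial split of the total.  Economic traits are linear in the
    first pleiotropic locus's dosage, with signs chosen so that
    D100/B100 analogues follow the teat trend while LSW/LWW/L100
    analogues oppose it, plus Gaussian noise.
    """
    rng = np.random.default_rng([cfg.seed, 3])
    out = samples.copy()
    d = genotypes.dosages.astype(float)

    if "selected_trait" not in out.columns:
        gv = d[:, truth.qtl_indices_selected] @ truth.qtl_effects_selected
        out["selected_trait"] = _selected_phenotype(
            gv, cfg.h2_selected, max(float(np.var(gv)), 1e-12), rng
        )

    teat_gv = d[:, truth.qtl_indices_teat] @ truth.qtl_effects_teat
    teat_gv_c = teat_gv - teat_gv.mean()
    gvar = max(float(np.var(teat_gv_c)), 1e-12)
    if cfg.h2_teat >= 1.0:
        liab = cfg.teat_base + teat_gv_c
    else:
        noise_sd = np.sqrt(gvar * (1 - cfg.h2_teat) / cfg.h2_teat)
        liab = cfg.teat_base + teat_gv_c + rng.normal(0, noise_sd, size=len(out))
    total = np.clip(np.rint(liab), 10, 18).astype(int)
    left = rng.binomial(total, 0.5)
    out["left_teats"] = left
    out["right_teats"] = total - left
    out["total_teats"] = total

    # economic traits load on every pleiotropic locus, oriented by that
    # locus's teat effect, so any pleiotropic region shows the same
    # teat-vs-economic sign pattern
    econ_gv = np.zeros(len(out))
    for j in truth.pleiotropic_indices:
        k = int(np.flatnonzero(truth.qtl_indices_teat == j)[0])
        teat_dir = float(np.sign(truth.qtl_effects_teat[k])) or 1.0
        dose = d[:, int(j)]
        econ_gv += teat_dir * (dose - dose.mean())
    for trait in ECON_TRAITS:
        sd = ECON_NOISE_SD[trait]
        out[trait] = (
            ECON_BASE[trait]
            + ECON_SIGNS[trait] * 0.3 * sd * econ_gv
            + rng.normal(0, sd, size=len(out))
        )
    return out


def _ascertain(cfg: SimConfig, geno: GenotypeMatrix, truth: SimTruth):
    """Subset to panel-eligible variants, as a released SNP set would be.

    Keeps variants whose sample MAF and exact-HWE p pass the standard
    panel QC (MAF >= 0.01, HWE p >= 1e-5) so that the emitted fixture
    is already clean; truth indices are remapped and QTL that drop off
    the panel (e.g. swept to fixation) are removed from the truth.
    """
    from .genotype_io import allele_frequencies, hwe_exact_vector

    freq = allele_frequencies(geno)
    maf = np.minimum(freq, 1 - freq)
    hwe = hwe_exact_vector(geno.dosages)
    keep = np.flatnonzero((maf >= 0.01) & (hwe >= 1e-5))
    new_index = np.full(geno.n_variants, -1)
    new_index[keep] = np.arange(len(keep))

    def remap(idx, *arrays):
        kept = new_index[idx] >= 0
        return (new_index[idx][kept],) + tuple(a[kept] for a in arrays)

    sel_idx, sel_eff = remap(truth.qtl_indices_selected, truth.qtl_effects_selected)
    teat_idx, teat_eff = remap(truth.qtl_indices_teat, truth.qtl_effects_teat)
    (pleio_idx,) = remap(truth.pleiotropic_indices)
    new_truth = SimTruth(
        qtl_indices_selected=sel_idx,
        qtl_effects_selected=sel_eff,
        qtl_indices_teat=teat_idx,
        qtl_effects_teat=teat_eff,
        pleiotropic_indices=pleio_idx,
        per_year_allele_freq=truth.per_year_allele_freq[:, keep],
        birth_years=truth.birth_years,
    )
    return geno.take_variants(keep), new_truth


def simulate(cfg: SimConfig, ascertain: bool = True):
    """Run the full simulation: founders, breeding, phenotypes.

    Returns (genotypes, samples, truth) for the born cohorts.
    Phenotypes are assigned from the full QTL set before the panel
    ascertainment subset (``ascertain=True``) is taken, so trait
    architecture does not depend on panel membership.
    """
    founders = simulate_founders(cfg)
    geno, samples, truth = simulate_breeding(cfg, founders)
    samples = assign_phenotypes(cfg, geno, truth, samples)
    if ascertain:
        geno, truth = _ascertain(cfg, geno, truth)
    return geno, samples, truth


def write_fixture(
    genotypes: GenotypeMatrix,
    samples: pd.DataFrame,
    truth: SimTruth,
    out_dir,
    cfg: SimConfig | None = None,
    dr2: float | None = 0.99,
    mean_depth: float | None = 20.0,
) -> dict:
    """Write VCF + phenotype + truth tables and a manifest to ``out_dir``.

    The VCF is v4.2 with GT genotypes and optional DR2 / DP INFO values
    (constant per site by default, present so QC paths are exercisable).
    Returns the manifest dict (also written as JSON).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vcf_path = out / "genotypes.vcf"
    _write_vcf(genotypes, vcf_path, dr2=dr2, mean_depth=mean_depth)

    pheno_path = out / "phenotypes.tsv"
    samples.to_csv(pheno_path, sep="\t", index=False)

    qtl_path = out / "truth_qtl.tsv"
    qtl_rows = []
    pleio = set(truth.pleiotropic_indices.tolist())
    for j, e in zip(truth.qtl_indices_selected, truth.qtl_effects_selected):
        qtl_rows.append(("selected", int(j), float(e), int(j in pleio)))
    for j, e in zip(truth.qtl_indices_teat, truth.qtl_effects_teat):
        qtl_rows.append(("teat", int(j), float(e), int(j in pleio)))
    pd.DataFrame(
        qtl_rows, columns=["trait", "variant_index", "effect", "pleiotropic"]
    ).to_csv(qtl_path, sep="\t", index=False)

    freq_path = out / "truth_allele_freq.tsv"
    freq = pd.DataFrame(
        truth.per_year_allele_freq.T,
        columns=[str(y) for y in truth.birth_years],
    )
    freq.insert(0, "variant_id", genotypes.variants["id"])
    freq.to_csv(freq_path, sep="\t", index=False, float_format="%.6f")

    manifest = {
        "files": [p.name for p in (vcf_path, pheno_path, qtl_path, freq_path)],
        "n_samples": genotypes.n_samples,
        "n_variants": genotypes.n_variants,
    }
    if cfg is not None:
        manifest["seed"] = cfg.seed
        manifest["config_hash"] = cfg.config_hash()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _write_vcf(g: GenotypeMatrix, path, dr2=None, mean_depth=None) -> None:
    var = g.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=polyselect-simdata\n")
        for c in var["chrom"].unique():
            length = int(var.loc[var.chrom == c, "pos"].max()) + 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        if dr2 is not None:
            fh.write(
                '##INFO=<ID=DR2,Number=1,Type=Float,'
                'Description="Imputation dosage R-squared">\n'
            )
        if mean_depth is not None:
            fh.write(
                '##INFO=<ID=DP,Number=1,Type=Integer,Description="Mean depth">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        dos = g.dosages
        for j in range(g.n_variants):
            info = []
            if dr2 is not None:
                info.append(f"DR2={dr2:g}")
            if mean_depth is not None:
                info.append(f"DP={int(round(mean_depth))}")
            row = var.iloc[j]
            gts = "\t".join(_GT[int(x)] for x in dos[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t{';'.join(info) or '.'}\tGT\t{gts}\n"
            )
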