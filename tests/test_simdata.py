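"""Breeding-simulator behaviour: founder spectrum, Mendelian transmission,
selection response, phenotype construction and fixture round-trips."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polyselect import (
    SimConfig,
    assign_phenotypes,
    simulate,
    simulate_breeding,
    simulate_founders,
    write_fixture,
)
from polyselect.genotype_io import MISSING

from .conftest import small_config


class TestFounders:
    def test_concentrated_beta_gives_half_frequencies(self):
        cfg = small_config(founder_maf_beta=(1e6, 1e6), n_snps=1000, n_founders=400)
        founders = simulate_founders(cfg)
        freq = founders.dosages.mean(axis=0) / 2
        assert np.abs(founders.drawn_freq - 0.5).max() < 0.01
        assert np.abs(freq.mean() - 0.5) < 0.02

    def test_deterministic_given_seed(self):
        cfg = small_config(seed=99)
        a = simulate_founders(cfg)
        b = simulate_founders(cfg)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        pd.testing.assert_frame_equal(a.variants, b.variants)

    def test_sample_frequency_tracks_drawn_frequency(self):
        cfg = small_config(n_founders=100, n_snps=2000, n_chromosomes=4)
        founders = simulate_founders(cfg)
        p = founders.drawn_freq
        freq = founders.dosages.mean(axis=0) / 2
        sd = np.sqrt(np.maximum(p * (1 - p), 1e-12) / (2 * cfg.n_founders))
        within = np.abs(freq - p) <= 4 * sd + 1e-9
        assert within.mean() >= 0.99

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError):
            small_config(founder_maf_beta=(0, 1))


class TestBreeding:
    def test_full_run_is_deterministic(self):
        cfg = small_config(seed=4)
        g1, s1, t1 = simulate(cfg)
        g2, s2, t2 = simulate(cfg)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)
        pd.testing.assert_frame_equal(s1, s2)
        np.testing.assert_array_equal(
            t1.per_year_allele_freq, t2.per_year_allele_freq
        )

    def test_mendelian_consistency(self):
        # full genotyping so every parent of later cohorts is observable
        cfg = small_config(n_genotyped_per_year=80, seed=7)
        founders = simulate_founders(cfg)
        geno, samples, _ = simulate_breeding(cfg, founders)
        lookup = {s: i for i, s in enumerate(geno.samples)}
        flookup = {s: i for i, s in enumerate(founders.samples)}

        def dosage_of(sample_id):
            if sample_id in lookup:
                return geno.dosages[lookup[sample_id]]
            return founders.dosages[flookup[sample_id]]

        checked = 0
        for _, row in samples.iterrows():
            child = geno.dosages[lookup[row["id"]]]
            sire = dosage_of(row["sire_id"])
            dam = dosage_of(row["dam_id"])
            # a homozygous parent must transmit its allele
            bad = ((sire == 0) & (dam == 0) & (child != 0)) | (
                (sire == 2) & (dam == 2) & (child != 2)
            ) | ((sire == 0) & (dam == 2) & (child != 1)) | (
                (sire == 2) & (dam == 0) & (child != 1)
            )
            assert not bad.any()
            checked += 1
        assert checked == len(samples)

    def test_selection_raises_favourable_frequency(self):
        ok = 0
        total = 0
        for seed in range(3):
            cfg = small_config(seed=seed)
            _, _, truth = simulate(cfg)
            years = np.arange(len(truth.birth_years))
            for k, j in enumerate(truth.qtl_indices_selected):
                traj = truth.per_year_allele_freq[:, j] * np.sign(
                    truth.qtl_effects_selected[k]
                )
                if np.std(traj) == 0:
                    continue
                rho = stats.spearmanr(years, traj).statistic
                ok += rho > 0
                total += 1
        assert ok / total >= 0.9

    def test_drift_only_mode_has_no_directional_response(self):
        # favourable-allele frequency change at QTL matches matched
        # neutral sites under drift (two-sample t over replicates)
        qtl_changes, neutral_changes = [], []
        for seed in range(20):
            cfg = small_config(seed=200 + seed, drift_only=True)
            _, _, truth = simulate(cfg)
            d = truth.per_year_allele_freq[-1] - truth.per_year_allele_freq[0]
            signed = d[truth.qtl_indices_selected] * np.sign(
                truth.qtl_effects_selected
            )
            qtl_changes.append(signed.mean())
            neutral = np.setdiff1d(
                np.arange(len(d)), truth.qtl_indices_selected
            )
            neutral_changes.append(d[neutral].mean())
        t, p = stats.ttest_ind(qtl_changes, neutral_changes)
        assert p > 0.01

    def test_antagonistic_pleiotropy_pulls_teat_trait_down(self):
        down = 0
        up = 0
        for seed in range(10):
            cfg = small_config(seed=seed, pleiotropy_sign=-1)
            _, samples, _ = simulate(cfg)
            ym = samples.groupby("birth_year")["total_teats"].mean()
            slope_teat = np.polyfit(ym.index, ym.values, 1)[0]
            ys = samples.groupby("birth_year")["selected_trait"].mean()
            slope_sel = np.polyfit(ys.index, ys.values, 1)[0]
            down += slope_teat < 0
            up += slope_sel > 0
        assert down >= 8
        assert up == 10

    def test_impossible_parent_supply_rejected(self):
        cfg = small_config(n_founders=5, prop_female=0.99, seed=1)
        founders = simulate_founders(cfg)
        # all-female founder guard flips one; with 5 founders the male
        # pool is a single animal, which is allowed — but zero males in
        # a sex column triggers the error path, exercised directly:
        from polyselect.simdata import _select_parents

        pool = {
            "hap": np.zeros((3, 2, 4), dtype=np.int8),
            "sex": np.array(["F", "F", "F"]),
            "pheno": np.zeros(3),
            "ids": np.array(["a", "b", "c"]),
        }
        with pytest.raises(ValueError, match="sex"):
            _select_parents(cfg, pool, np.random.default_rng(0))


class TestPhenotypes:
    def test_h2_one_means_no_noise(self):
        cfg = small_config(h2_selected=1.0, seed=3)
        founders = simulate_founders(cfg)
        geno, samples, truth = simulate_breeding(cfg, founders)
        gv = geno.dosages[:, truth.qtl_indices_selected].astype(float) @ (
            truth.qtl_effects_selected
        )
        np.testing.assert_allclose(samples["selected_trait"].to_numpy(), gv)

    def test_left_plus_right_equals_total(self, small_sim):
        _, samples, _ = small_sim
        assert (
            samples["left_teats"] + samples["right_teats"]
            == samples["total_teats"]
        ).all()

    def test_teat_counts_in_range(self, small_sim):
        _, samples, _ = small_sim
        assert samples["total_teats"].between(10, 18).all()

    def test_midparent_regression_recovers_heritability(self):
        # offspring-on-midparent regression slope estimates h2; run under
        # drift with full genotyping so parent phenotypes are observable
        cfg = small_config(
            drift_only=True,
            h2_selected=0.5,
            n_offspring_per_year=500,
            n_genotyped_per_year=500,
            n_founders=300,
            birth_years=(2009, 2010, 2011, 2012),
            seed=17,
        )
        founders = simulate_founders(cfg)
        geno, samples, truth = simulate_breeding(cfg, founders)
        pheno = dict(zip(samples["id"], samples["selected_trait"]))
        rows = [
            (pheno[r.id], (pheno[r.sire_id] + pheno[r.dam_id]) / 2)
            for r in samples.itertuples()
            if r.sire_id in pheno and r.dam_id in pheno
        ]
        assert len(rows) >= 1000
        child, mid = np.array(rows).T
        slope = np.polyfit(mid, child, 1)[0]
        assert abs(slope - cfg.h2_selected) < 0.15

    def test_invalid_h2_rejected(self):
        with pytest.raises(ValueError):
            small_config(h2_teat=0)


class TestFixture:
    def test_manifest_hash_tracks_config(self, tmp_path):
        a = small_config(seed=1)
        b = small_config(seed=1, h2_teat=0.41)
        assert a.config_hash() == small_config(seed=1).config_hash()
        assert a.config_hash() != b.config_hash()

    def test_written_fixture_is_complete(self, tmp_path, small_sim):
        g, samples, truth = small_sim
        manifest = write_fixture(g, samples, truth, tmp_path, cfg=small_config())
        for name in manifest["files"]:
            assert (tmp_path / name).exists()
        saved = json.loads((tmp_path / "manifest.json").read_text())
        assert saved["n_variants"] == g.n_variants

    def test_year_season_labels(self, small_sim):
        _, samples, _ = small_sim
        months = pd.to_datetime(samples["birth_date"]).dt.month
        seasons = samples["year_season"].str.extract(r"_S(\d)")[0].astype(int)
        expected = months.map(
            {12: 1, 1: 1, 2: 1, 3: 2, 4: 2, 5: 2, 6: 3, 7: 3, 8: 3, 9: 4, 10: 4, 11: 4}
        )
        assert (seasons == expected).all()
        assert (samples["age_at_reference"] >= 0).all()
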