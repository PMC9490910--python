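"""ROH detection and hotspots, windowed diversity/FST statistics,
quantile flagging and cohort t-tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polyselect import (
    PopPair,
    ROHParams,
    cohort_welch_tests,
    detect_roh,
    extreme_group_pair,
    make_windows,
    pi_ratio,
    roh_hotspots,
    top_fraction_windows,
    window_fst,
    window_pi,
)
from polyselect.genotype_io import MISSING
from polyselect.selection_scan import (
    _in_state_flags,
    _site_pi,
    hudson_components,
    top_k_threshold,
    weir_cockerham_components,
)

from .conftest import matrix_from


def single_sample_matrix(genos, positions, chrom="1"):
    d = np.asarray(genos, dtype=np.int8)[None, :]
    return matrix_from(d, chrom=[chrom] * len(genos), pos=positions)


def brute_force_roh(genos, positions, p: ROHParams):
    """Independent re-implementation: per-SNP state via explicit window
    loops, then direct scan over candidate runs."""
    m = len(genos)
    het = [1 if g == 1 else 0 for g in genos]
    mis = [1 if g == MISSING else 0 for g in genos]
    if m < p.window_snps:
        flags = [False] * m
    else:
        windows = []
        for s in range(m - p.window_snps + 1):
            w_het = sum(het[s:s + p.window_snps])
            w_mis = sum(mis[s:s + p.window_snps])
            windows.append(w_het <= p.max_het and w_mis <= p.max_missing)
        flags = []
        for i in range(m):
            cover = [
                windows[s]
                for s in range(max(0, i - p.window_snps + 1), min(len(windows), i + 1))
            ]
            flags.append(sum(cover) / len(cover) >= p.hit_threshold)
    segments = []
    run = []
    for i in range(m):
        if flags[i]:
            if run and positions[i] - positions[run[-1]] > p.max_gap:
                segments.append(run)
                run = []
            run.append(i)
        elif run:
            segments.append(run)
            run = []
    if run:
        segments.append(run)
    out = []
    for run in segments:
        n_snps = len(run)
        length = positions[run[-1]] - positions[run[0]] + 1
        if n_snps < p.min_snps or length < p.min_length:
            continue
        if length / n_snps > p.min_density_bp:
            continue
        out.append((positions[run[0]], positions[run[-1]], n_snps, length))
    return out


class TestROH:
    def test_long_homozygous_run_detected(self):
        pos = np.arange(100) * 20_000 + 1  # 100 SNPs spanning ~2 Mb
        g = single_sample_matrix(np.zeros(100, dtype=int), pos)
        segs = detect_roh(g)
        assert len(segs) == 1
        assert segs.iloc[0]["n_snps"] == 100

    def test_minimum_snp_count_enforced(self):
        pos = np.arange(64) * 20_000 + 1
        g = single_sample_matrix(np.zeros(64, dtype=int), pos)
        assert len(detect_roh(g)) == 0

    def test_heterozygous_sample_yields_nothing(self):
        pos = np.arange(200) * 10_000 + 1
        g = single_sample_matrix(np.ones(200, dtype=int), pos)
        assert len(detect_roh(g)) == 0

    def test_unsorted_positions_rejected(self):
        g = single_sample_matrix([0, 0, 0], [300, 100, 200])
        with pytest.raises(ValueError):
            detect_roh(g)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        m = 500
        pos = np.sort(rng.choice(np.arange(1, 6_000_000), size=m, replace=False))
        # mosaic of long homozygous stretches and noisy regions
        genos = np.zeros(m, dtype=int)
        i = 0
        while i < m:
            block = rng.integers(30, 160)
            kind = rng.random()
            if kind < 0.5:
                seg = rng.choice([0, 2], size=block)
                # occasional het/missing contamination
                n_bad = rng.integers(0, 4)
                bad = rng.choice(block, size=min(n_bad, block), replace=False)
                seg[bad] = rng.choice([1, MISSING], size=len(bad))
            else:
                seg = rng.integers(0, 3, size=block)
            genos[i:i + block] = seg[: m - i]
            i += block
        g = single_sample_matrix(genos, pos)
        p = ROHParams()
        got = detect_roh(g, p)
        expected = brute_force_roh(list(genos), list(pos), p)
        got_tuples = [
            (r.start, r.end, r.n_snps, r.length) for r in got.itertuples()
        ]
        assert got_tuples == expected


class TestHotspots:
    def variants(self, m=200):
        pos = np.arange(m) * 10_000 + 1
        return pd.DataFrame(
            {"chrom": "1", "pos": pos, "id": [f"v{i}" for i in range(m)]}
        )

    def test_no_segments_no_hotspots(self):
        occ, hot = roh_hotspots(pd.DataFrame(columns=["sample", "chrom", "start", "end"]), self.variants(), 10)
        assert (occ == 0).all() and len(hot) == 0

    def test_universal_segment_flags_all_ties(self):
        var = self.variants(100)
        segs = pd.DataFrame(
            [(f"s{i}", "1", 1, 10_000_000) for i in range(5)],
            columns=["sample", "chrom", "start", "end"],
        )
        occ, hot = roh_hotspots(segs, var, 5)
        assert (occ == 1).all()
        assert len(hot) == 100  # all tied at the threshold

    def test_matches_brute_force_interval_stabbing(self):
        rng = np.random.default_rng(3)
        var = self.variants(300)
        pos = var["pos"].to_numpy()
        rows = []
        for s in range(20):
            for _ in range(rng.integers(0, 4)):
                a = rng.integers(1, 2_900_000)
                b = a + rng.integers(10_000, 500_000)
                rows.append((f"s{s}", "1", a, b))
        segs = pd.DataFrame(rows, columns=["sample", "chrom", "start", "end"])
        occ, _ = roh_hotspots(segs, var, 20)
        brute = np.zeros(len(pos))
        for s in range(20):
            cover = np.zeros(len(pos), dtype=bool)
            sub = segs[segs["sample"] == f"s{s}"]
            for r in sub.itertuples():
                cover |= (pos >= r.start) & (pos <= r.end)
            brute += cover
        np.testing.assert_allclose(occ, brute / 20)


class TestWindowPi:
    def test_monomorphic_window_is_zero(self):
        g = matrix_from(np.zeros((10, 5), dtype=np.int8), pos=np.arange(5) * 1000 + 1)
        win = make_windows(g.variants)
        out = window_pi(g, g.samples, win)
        assert (out["pi"] == 0).all()

    def test_single_site_closed_form(self):
        # 10 diploids at p=0.5: c=10 of n_al=20 alleles
        d = np.array([[1]] * 10, dtype=np.int8)
        g = matrix_from(d, pos=[100])
        win = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [50_000]})
        out = window_pi(g, g.samples, win)
        expected_site = 2 * 10 * 10 / (20 * 19)
        assert out["pi"][0] == pytest.approx(expected_site / 50_000)

    def test_sample_duplication_follows_closed_form(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.3, size=(8, 1)).astype(np.int8)
        g1 = matrix_from(d, pos=[100])
        g2 = matrix_from(np.vstack([d, d]), pos=[100])
        win = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [50_000]})
        pi1 = window_pi(g1, g1.samples, win)["pi"][0]
        pi2 = window_pi(g2, g2.samples, win)["pi"][0]
        c = d.sum()
        n = 16
        expected1 = 2 * c * (n - c) / (n * (n - 1)) / 50_000
        c2, n2 = 2 * c, 32
        expected2 = 2 * c2 * (n2 - c2) / (n2 * (n2 - 1)) / 50_000
        assert pi1 == pytest.approx(expected1)
        assert pi2 == pytest.approx(expected2)

    def test_window_sums_are_additive(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, rng.uniform(0.1, 0.9, 50), size=(12, 50)).astype(np.int8)
        pos = np.sort(rng.choice(np.arange(1, 100_000), 50, replace=False))
        g = matrix_from(d, pos=pos)
        whole = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [100_000]})
        halves = pd.DataFrame(
            {"chrom": ["1", "1"], "start": [0, 50_000], "end": [50_000, 100_000]}
        )
        w = window_pi(g, g.samples, whole)
        h = window_pi(g, g.samples, halves)
        total_site_sum = w["pi"][0] * 100_000
        halves_sum = (h["pi"] * 50_000).sum()
        assert halves_sum == pytest.approx(total_site_sum)


def wc_oracle(n1, p1, h1, n2, p2, h2):
    """Textbook two-population Weir-Cockerham components."""
    r = 2
    nbar = (n1 + n2) / 2
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


class TestFST:
    def make_pair(self, d1, d2):
        d = np.vstack([d1, d2])
        g = matrix_from(d, pos=np.arange(d.shape[1]) * 1000 + 1)
        pair = PopPair(
            ids_hi=g.samples[: len(d1)], ids_lo=g.samples[len(d1):]
        )
        return g, pair

    def test_identical_groups_near_zero(self):
        rng = np.random.default_rng(4)
        base = rng.binomial(2, rng.uniform(0.2, 0.8, 400), size=(100, 400)).astype(np.int8)
        g, pair = self.make_pair(base[:50], base[50:])
        win = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [500_000]})
        out = window_fst(g, pair, win)
        assert abs(out["fst"][0]) < 0.02

    def test_fixed_difference_is_maximal(self):
        d1 = np.full((45, 3), 2, dtype=np.int8)
        d2 = np.zeros((45, 3), dtype=np.int8)
        g, pair = self.make_pair(d1, d2)
        win = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [50_000]})
        wc = window_fst(g, pair, win, "weir_cockerham")["fst"][0]
        hu = window_fst(g, pair, win, "hudson")["fst"][0]
        assert hu == pytest.approx(1.0, abs=1e-12)
        assert wc == pytest.approx(1.0, abs=1e-9)

    def test_weir_cockerham_matches_textbook_oracle(self):
        rng = np.random.default_rng(5)
        d1 = rng.binomial(2, rng.uniform(0.05, 0.95, 200), size=(37, 200)).astype(np.int8)
        d2 = rng.binomial(2, rng.uniform(0.05, 0.95, 200), size=(51, 200)).astype(np.int8)
        a, b, c, poly = weir_cockerham_components(d1, d2)
        for j in range(200):
            n1, n2 = 37, 51
            p1 = d1[:, j].mean() / 2
            p2 = d2[:, j].mean() / 2
            h1 = (d1[:, j] == 1).mean()
            h2 = (d2[:, j] == 1).mean()
            ao, bo, co = wc_oracle(n1, p1, h1, n2, p2, h2)
            assert a[j] == pytest.approx(ao, abs=1e-10)
            assert b[j] == pytest.approx(bo, abs=1e-10)
            assert c[j] == pytest.approx(co, abs=1e-10)

    def test_estimators_agree_on_balanced_drift_groups(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0.1, 0.9, 500)
        d1 = rng.binomial(2, p, size=(45, 500)).astype(np.int8)
        d2 = rng.binomial(2, p, size=(45, 500)).astype(np.int8)
        g, pair = self.make_pair(d1, d2)
        win = pd.DataFrame({"chrom": ["1"], "start": [0], "end": [600_000]})
        wc = window_fst(g, pair, win, "weir_cockerham")["fst"][0]
        hu = window_fst(g, pair, win, "hudson")["fst"][0]
        assert abs(wc - hu) < 0.05

    def test_small_group_rejected(self):
        d1 = np.zeros((1, 5), dtype=np.int8)
        d2 = np.zeros((5, 5), dtype=np.int8)
        g, pair = self.make_pair(d1, d2)
        with pytest.raises(ValueError):
            window_fst(g, pair, make_windows(g.variants))


class TestPiRatioAndFlags:
    def test_pi_ratio_closed_forms(self):
        hi = np.array([1.0, np.e * 2.0, 0.5])
        lo = np.array([1.0, 2.0, 0.0])
        r = pi_ratio(hi, lo)
        assert r[0] == pytest.approx(0.0)
        assert r[1] == pytest.approx(1.0)
        assert np.isnan(r[2])

    def test_negative_pi_rejected(self):
        with pytest.raises(ValueError):
            pi_ratio(np.array([-1.0]), np.array([1.0]))

    def test_top_fraction_exact_count(self):
        df = pd.DataFrame({"chrom": "1", "start": 0, "end": 1, "m": np.arange(100.0)})
        out = top_fraction_windows(df, "m", 0.01, "upper")
        assert out["is_top_m"].sum() == 1
        assert out.loc[out["is_top_m"], "m"].item() == 99.0

    def test_ties_all_flagged(self):
        vals = np.array([1.0] * 5 + [2.0] * 5)
        df = pd.DataFrame({"chrom": "1", "start": 0, "end": 1, "m": vals})
        out = top_fraction_windows(df, "m", 0.1, "upper")
        assert out["is_top_m"].sum() == 5

    def test_both_tails_fraction(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            {"chrom": "1", "start": 0, "end": 1, "m": rng.normal(size=1000)}
        )
        out = top_fraction_windows(df, "m", 0.02, "both")
        assert out["is_top_m"].sum() == pytest.approx(20, abs=2)

    def test_all_nan_flags_nothing(self):
        df = pd.DataFrame({"chrom": "1", "start": 0, "end": 1, "m": [np.nan] * 4})
        out = top_fraction_windows(df, "m", 0.5)
        assert out["is_top_m"].sum() == 0


class TestWelch:
    def sample_table(self, groups):
        rows = []
        for year, values in groups.items():
            for i, v in enumerate(values):
                rows.append({"id": f"{year}_{i}", "birth_year": year, "nt": v})
        return pd.DataFrame(rows)

    def test_identical_cohorts(self):
        vals = list(np.random.default_rng(8).normal(14, 1, 30))
        tab = self.sample_table({2009: vals, 2010: vals})
        out = cohort_welch_tests(tab, "nt")
        assert out["t"][0] == pytest.approx(0.0, abs=1e-12)
        assert out["p"][0] == pytest.approx(1.0)

    def test_separated_cohort_means_are_significant(self):
        rng = np.random.default_rng(9)
        tab = self.sample_table(
            {2009: 14.16 + rng.normal(0, 0.07, 45), 2017: 12.0 + rng.normal(0, 1e-9, 45)}
        )
        out = cohort_welch_tests(tab, "nt")
        assert out["p"][0] < 1e-3

    def test_matches_scipy_closed_form(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.5, 2, 35)
        tab = self.sample_table({2009: a, 2010: b})
        out = cohort_welch_tests(tab, "nt")
        t, p = stats.ttest_ind(a, b, equal_var=False)
        assert out["t"][0] == pytest.approx(t, abs=1e-12)
        assert out["p"][0] == pytest.approx(p, abs=1e-12)

    def test_undersized_cohort_gives_nan(self):
        tab = self.sample_table({2009: [14.0], 2010: [13.0, 12.5]})
        out = cohort_welch_tests(tab, "nt")
        assert np.isnan(out["t"][0])


class TestGroupConstruction:
    def test_extreme_groups_are_disjoint_and_ordered(self, small_sim):
        _, samples, _ = small_sim
        pair = extreme_group_pair(samples, "total_teats", n_per_group=10)
        assert not set(pair.ids_hi) & set(pair.ids_lo)
        assert pair.mean_hi >= pair.mean_lo
        sub = samples[samples["id"].isin(pair.ids_hi)]
        assert (sub["sex"] == "F").all()
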