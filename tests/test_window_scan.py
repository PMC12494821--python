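import numpy as np
import pytest

from statewise_burden.burden_tests import burden_logistic_test, lambda_gc
from statewise_burden.io_formats import GenotypeMatrix
from statewise_burden.weights_annotation import beta_weight
from statewise_burden.window_scan import (
    Window,
    enumerate_windows,
    estimate_effective_tests,
    secondary_window_analysis,
    window_burden_scan,
)
from tests.conftest import make_variants


class TestEnumerateWindows:
    def test_100kb_chromosome_5kb_windows(self):
        wins = enumerate_windows({"chr1": 100_000}, sizes_kb=(5,))
        # starts at 0, 2500, ..., 97500: 39 full windows plus clipped tail
        assert len(wins) == 40
        full = [w for w in wins if w.end - w.start + 1 == 5000]
        assert len(full) == 39
        assert wins[0].start == 1 and wins[0].end == 5000
        assert wins[-1].start == 97_501 and wins[-1].end == 100_000

    def test_size_exceeding_chromosome_gives_single_clipped_window(self):
        wins = enumerate_windows({"chr1": 3_000}, sizes_kb=(5,))
        assert len(wins) == 1
        assert (wins[0].start, wins[0].end) == (1, 3000)

    def test_two_sizes_disjoint_union(self):
        wins5 = enumerate_windows({"chr1": 100_000}, sizes_kb=(5,))
        wins10 = enumerate_windows({"chr1": 100_000}, sizes_kb=(10,))
        both = enumerate_windows({"chr1": 100_000}, sizes_kb=(5, 10))
        assert len(both) == len(wins5) + len(wins10)
        assert {w.size_kb for w in both} == {5, 10}

    def test_rejects_nonpositive_size(self):
        with pytest.raises(ValueError):
            enumerate_windows({"chr1": 1000}, sizes_kb=(0,))


def _scan_fixture(rng, n=400, m=60, span=10_000):
    positions = np.sort(rng.choice(span, m, replace=False)) + 1
    variants = make_variants(positions)
    maf = rng.uniform(0.005, 0.04, m)
    g = rng.binomial(2, maf[None, :].repeat(n, axis=0)).astype(np.int8)
    gm = GenotypeMatrix(g, [f"s{i}" for i in range(n)])
    for v, f in zip(variants, maf):
        v.maf = float(f)
    y = np.zeros(n)
    y[: n // 2] = 1
    return gm, variants, maf, y


class TestWindowScan:
    def test_single_window_matches_direct_burden_test(self, rng):
        gm, variants, maf, y = _scan_fixture(rng)
        wins = [Window("chr1", 1, 10_000, 10)]
        res, _ = window_burden_scan(
            gm, variants, np.arange(len(variants)), wins, y, method="wald", maf=maf
        )
        w = beta_weight(maf)
        burden = np.maximum(gm.data, 0).astype(float) @ w
        direct = burden_logistic_test(burden, y)
        assert res[0].p == pytest.approx(direct.p, rel=1e-6)
        assert res[0].n_variants == len(variants)

    def test_score_and_wald_agree_on_moderate_counts(self, rng):
        gm, variants, maf, y = _scan_fixture(rng, n=800, m=80)
        wins = enumerate_windows({"chr1": 10_000}, sizes_kb=(5,))
        r_w, _ = window_burden_scan(gm, variants, np.arange(80), wins, y, method="wald", maf=maf)
        r_s, _ = window_burden_scan(gm, variants, np.arange(80), wins, y, method="score", maf=maf)
        assert len(r_w) == len(r_s)
        for a, b in zip(r_w, r_s):
            assert a.p == pytest.approx(b.p, abs=0.03)

    def test_sparse_windows_not_tested(self, rng):
        gm, variants, maf, y = _scan_fixture(rng, m=2, span=2_000)
        wins = enumerate_windows({"chr1": 100_000}, sizes_kb=(5,))
        res, _ = window_burden_scan(gm, variants, np.arange(2), wins, y, maf=maf, min_variants=3)
        assert res == []

    def test_null_scan_lambda_calibrated(self, rng):
        n, m = 400, 3000
        positions = np.sort(rng.choice(1_500_000, m, replace=False)) + 1
        variants = make_variants(positions)
        maf = rng.uniform(0.005, 0.04, m)
        for v, f in zip(variants, maf):
            v.maf = float(f)
        g = rng.binomial(2, maf[None, :].repeat(n, axis=0)).astype(np.int8)
        gm = GenotypeMatrix(g, [f"s{i}" for i in range(n)])
        y = np.zeros(n)
        y[: n // 2] = 1
        wins = enumerate_windows({"chr1": 1_500_000}, sizes_kb=(5, 10, 15))
        res, lam = window_burden_scan(gm, variants, np.arange(m), wins, y, maf=maf)
        assert len(res) > 1000
        assert 0.85 < lam < 1.15


class TestEffectiveTests:
    def test_single_window_n_eff_near_one(self, rng):
        gm, variants, maf, y = _scan_fixture(rng, n=300, m=30)
        wins = [Window("chr1", 1, 10_000, 10)]
        n_eff, thr, _ = estimate_effective_tests(
            gm, variants, np.arange(30), wins, y, n_perm=800, seed=1, maf=maf
        )
        assert 0.8 <= n_eff <= 1.2
        assert thr == pytest.approx(0.05 / n_eff)

    def test_duplicated_windows_halve_effective_count(self, rng):
        m_windows = 24
        n = 500
        variants, mafs, cols = [], [], []
        for k in range(m_windows):
            base = k * 10_000
            pos = np.sort(rng.choice(4_000, 8, replace=False)) + base + 1
            variants.extend(make_variants(pos))
            mafs.extend(rng.uniform(0.01, 0.04, 8))
        maf = np.array(mafs)
        g = rng.binomial(2, maf[None, :].repeat(n, axis=0)).astype(np.int8)
        gm = GenotypeMatrix(g, [f"s{i}" for i in range(n)])
        for v, f in zip(variants, maf):
            v.maf = float(f)
        y = np.zeros(n)
        y[: n // 2] = 1
        wins = [Window("chr1", k * 10_000 + 1, k * 10_000 + 5_000, 5) for k in range(m_windows)]
        n_eff_once, _, _ = estimate_effective_tests(
            gm, variants, np.arange(maf.size), wins, y, n_perm=1500, seed=2, maf=maf
        )
        n_eff_dup, _, _ = estimate_effective_tests(
            gm, variants, np.arange(maf.size), wins + wins, y, n_perm=1500, seed=2, maf=maf
        )
        assert 0.4 <= n_eff_dup / (2 * m_windows) <= 0.6
        assert 0.7 * m_windows <= n_eff_once <= 1.3 * m_windows

    def test_too_few_permutations_rejected(self, rng):
        gm, variants, maf, y = _scan_fixture(rng)
        wins = [Window("chr1", 1, 10_000, 10)]
        with pytest.raises(ValueError):
            estimate_effective_tests(gm, variants, np.arange(len(variants)), wins, y, n_perm=50, maf=maf)

    def test_permutation_null_pvalues_uniform(self, rng):
        """Scan p-values under permuted outcomes follow the uniform law."""
        from scipy import stats

        gm, variants, maf, y = _scan_fixture(rng, n=600, m=40)
        wins = [Window("chr1", 1, 5_000, 5), Window("chr1", 5_001, 10_000, 5)]
        from statewise_burden._logistic import fit_null, score_scan

        null = fit_null(y)
        idx = np.arange(40)
        w = beta_weight(maf)
        B = np.maximum(gm.data, 0).astype(float) * w
        pvals = []
        for _ in range(50):
            y_perm = rng.permutation(y)
            sub = B[:, [i for i, v in enumerate(variants) if v.pos <= 5000]].sum(axis=1)
            _, p, _ = score_scan(null, sub[:, None], outcomes=y_perm[:, None])
            pvals.append(p.ravel()[0])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestSecondaryAnalysis:
    def test_no_repeat_variants_identity(self, rng):
        gm, variants, maf, y = _scan_fixture(rng)
        win = Window("chr1", 1, 10_000, 10)
        report = secondary_window_analysis(win, gm, variants, np.arange(len(variants)), y, maf=maf)
        assert report["non_repeat"]["p"] == pytest.approx(report["full"]["p"], rel=1e-9)

    def test_fisher_boundary_assignment_is_strict(self, rng):
        gm, variants, maf, y = _scan_fixture(rng)
        win = Window("chr1", 1, 10_000, 10)
        report = secondary_window_analysis(win, gm, variants, np.arange(len(variants)), y, maf=maf)
        sig_n = report["significant_subset"]["n_variants"]
        nonsig_n = report["nonsignificant_subset"]["n_variants"]
        n_sig_from_table = sum(1 for f in report["fisher"] if f["p"] < 0.05)
        assert sig_n == n_sig_from_table
        assert sig_n + nonsig_n == report["full"]["n_variants"]

    def test_repeat_masking_removes_repeat_variants(self, rng):
        gm, variants, maf, y = _scan_fixture(rng)
        for v in variants[:20]:
            v.annotations["repeat"] = "SINE"
        win = Window("chr1", 1, 10_000, 10)
        report = secondary_window_analysis(win, gm, variants, np.arange(len(variants)), y, maf=maf)
        assert report["non_repeat"]["n_variants"] == report["full"]["n_variants"] - sum(
            1 for v in variants if v.annotations.get("repeat")
        )

    def test_selected_subset_is_winners_curse_enriched(self, rng):
        """Under the null, the p<0.05 Fisher partition has a burden p at
        least as extreme as the full window in most replicates."""
        wins_hit = 0
        total = 0
        for rep in range(30):
            gm, variants, maf, y = _scan_fixture(rng, n=300, m=40)
            win = Window("chr1", 1, 10_000, 10)
            report = secondary_window_analysis(win, gm, variants, np.arange(40), y, maf=maf)
            if report["significant_subset"]["flag"] == "empty":
                continue
            total += 1
            if report["significant_subset"]["p"] <= report["full"]["p"] + 1e-12:
                wins_hit += 1
        if total >= 10:
            assert wins_hit >= 0.8 * total
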