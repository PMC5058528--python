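"""EM haplotype frequencies from dominant phenotypes, LR test, FDR, scans."""

import numpy as np
import pytest
from scipy import stats

from hostscan.ld_dominant import (
    LDResult,
    PhenotypeTable2x2,
    _log_likelihood,
    em_haplotype_freqs_dominant,
    fdr_adjust,
    ld_scan,
    ld_test,
)

from conftest import toy_matrix


def grid_search_mle(counts, rounds=5):
    """Independent zooming grid-search ML over (pA, pB, D).

    Parametrizes D by its relative position t in the admissible interval so
    every grid point is a valid haplotype-frequency vector; zooms around the
    best cells of a dense first pass.  Returns (lnl, D).
    """
    cn = np.asarray(counts, dtype=float)

    def lnl_grid(pA, pB, t):
        PA, PB, T = np.meshgrid(pA, pB, t, indexing="ij")
        lo = -np.minimum(PA * PB, (1 - PA) * (1 - PB))
        hi = np.minimum(PA * (1 - PB), (1 - PA) * PB)
        D = lo + T * (hi - lo)
        h00 = (1 - PA) * (1 - PB) + D
        h01 = (1 - PA) * PB - D
        h10 = PA * (1 - PB) - D
        p_aa = h00 ** 2
        p_ap = (h00 + h01) ** 2 - p_aa
        p_pa = (h00 + h10) ** 2 - p_aa
        p_pp = 1 - p_aa - p_ap - p_pa
        L = (cn[0] * np.log(np.clip(p_pp, 1e-300, None))
             + cn[1] * np.log(np.clip(p_pa, 1e-300, None))
             + cn[2] * np.log(np.clip(p_ap, 1e-300, None))
             + cn[3] * np.log(np.clip(p_aa, 1e-300, None)))
        return L, D

    pA = np.linspace(0.001, 0.999, 161)
    pB = np.linspace(0.001, 0.999, 161)
    t = np.linspace(0.0, 1.0, 161)
    best = None
    for _ in range(rounds):
        L, D = lnl_grid(pA, pB, t)
        k = np.unravel_index(np.argmax(L), L.shape)
        best = (float(L[k]), float(D[k]))
        cA, cB, cT = pA[k[0]], pB[k[1]], t[k[2]]
        wA = (pA[1] - pA[0]) * 2
        wB = (pB[1] - pB[0]) * 2
        wT = (t[1] - t[0]) * 2
        pA = np.clip(np.linspace(cA - wA, cA + wA, 41), 1e-4, 1 - 1e-4)
        pB = np.clip(np.linspace(cB - wB, cB + wB, 41), 1e-4, 1 - 1e-4)
        t = np.clip(np.linspace(cT - wT, cT + wT, 41), 0.0, 1.0)
    return best


def random_dominant_table(rng, n=100):
    """Phenotype counts from a random haplotype-frequency vector under HWE."""
    h = rng.dirichlet([1, 1, 1, 1])
    hap = rng.choice(4, size=(n, 2), p=h)       # 0: AB, 1: Ab, 2: aB, 3: ab
    pres_a = (hap <= 1).any(axis=1)
    pres_b = ((hap % 2) == 0).any(axis=1)
    return PhenotypeTable2x2(
        int((pres_a & pres_b).sum()), int((pres_a & ~pres_b).sum()),
        int((~pres_a & pres_b).sum()), int((~pres_a & ~pres_b).sum()))


class TestEMAgainstGridOracle:
    def test_independent_loci_give_small_d(self):
        rng = np.random.default_rng(0)
        n = 4000
        a = rng.random(n) < 0.6
        b = rng.random(n) < 0.4
        tab = PhenotypeTable2x2(int((a & b).sum()), int((a & ~b).sum()),
                                int((~a & b).sum()), int((~a & ~b).sum()))
        res = em_haplotype_freqs_dominant(tab)
        assert abs(res.D) < 0.01

    def test_coupling_only_phenotype_classes(self):
        """Only (pp) and (aa) observed: D-hat = p(1-p) at the coupling MLE."""
        tab = PhenotypeTable2x2(60, 0, 0, 40)
        res = em_haplotype_freqs_dominant(tab)
        p = 1.0 - np.sqrt(0.4)
        assert res.D == pytest.approx(p * (1 - p), abs=1e-6)
        lnl_or, d_or = grid_search_mle(tab.as_array())
        assert res.lnl >= lnl_or - 1e-6
        assert res.D == pytest.approx(d_or, abs=1e-4)

    def test_random_tables_match_grid_oracle(self):
        """EM MLE vs the zooming grid on 20 random tables at n = 100."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            tab = random_dominant_table(rng)
            res = em_haplotype_freqs_dominant(tab)
            lnl_or, d_or = grid_search_mle(tab.as_array())
            assert res.lnl >= lnl_or - 1e-6
            assert abs(res.lnl - lnl_or) < 1e-4 + 1e-6
            assert abs(res.D - d_or) < 1e-4

    def test_em_likelihood_monotone(self):
        """Every EM step from a poor start increases the log-likelihood."""
        from hostscan.ld_dominant import _em_update
        counts = np.array([40.0, 25.0, 20.0, 15.0])
        h = np.array([0.7, 0.1, 0.1, 0.1])
        lnl = _log_likelihood(counts, h)
        for _ in range(200):
            h = _em_update(counts, h)
            new = _log_likelihood(counts, h)
            assert new >= lnl - 1e-10
            lnl = new

    def test_d_respects_marginal_bounds(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            tab = random_dominant_table(rng, n=60)
            res = em_haplotype_freqs_dominant(tab)
            pa = res.h11 + res.h10
            pb = res.h11 + res.h01
            lo = -min(pa * pb, (1 - pa) * (1 - pb))
            hi = min(pa * (1 - pb), (1 - pa) * pb)
            assert lo - 1e-9 <= res.D <= hi + 1e-9

    def test_parameter_recovery_at_n500(self):
        """Median |D-hat - D| <= 0.03 when phenotypes come from known h."""
        rng = np.random.default_rng(11)
        errors = []
        for _ in range(30):
            h = rng.dirichlet([2, 2, 2, 2])
            d_true = h[0] - (h[0] + h[1]) * (h[0] + h[2])
            hap = rng.choice(4, size=(500, 2), p=h)
            pres_a = (hap <= 1).any(axis=1)
            pres_b = ((hap % 2) == 0).any(axis=1)
            tab = PhenotypeTable2x2(
                int((pres_a & pres_b).sum()), int((pres_a & ~pres_b).sum()),
                int((~pres_a & pres_b).sum()), int((~pres_a & ~pres_b).sum()))
            res = em_haplotype_freqs_dominant(tab)
            errors.append(abs(res.D - d_true))
        assert np.median(errors) <= 0.03


class TestLRTest:
    def test_zero_d_gives_p_one(self):
        res = LDResult(0.35, 0.35, 0.15, 0.15, lnl=-10.0, lnl0=-10.0,
                       converged=True, n=50)
        lr, p = ld_test(res)
        assert lr == 0.0 and p == 1.0

    def test_chi_square_quantile(self):
        res = LDResult(0.4, 0.3, 0.2, 0.1, lnl=-8.0, lnl0=-8.0 - 3.841 / 2,
                       converged=True, n=50)
        lr, p = ld_test(res)
        assert p == pytest.approx(0.05, abs=2e-4)

    def test_ascent_failure_raises(self):
        res = LDResult(0.4, 0.3, 0.2, 0.1, lnl=-9.0, lnl0=-8.0,
                       converged=True, n=50)
        with pytest.raises(ValueError):
            ld_test(res)

    def test_type_one_error_calibrated(self):
        """Independent loci, 1000 pairs: rejections at 5% within binomial CI."""
        rng = np.random.default_rng(42)
        n, npairs = 100, 1000
        pa = rng.uniform(0.1, 0.9, npairs)
        pb = rng.uniform(0.1, 0.9, npairs)
        xa = rng.random((n, npairs)) < (1 - (1 - pa) ** 2)
        xb = rng.random((n, npairs)) < (1 - (1 - pb) ** 2)
        from hostscan.ld_dominant import _em_batch, _null_fit
        counts = np.stack([(xa & xb).sum(0), (xa & ~xb).sum(0),
                           (~xa & xb).sum(0), (~xa & ~xb).sum(0)]).astype(float)
        _, lnl, conv = _em_batch(counts)
        _, lnl0 = _null_fit(counts)
        p = stats.chi2.sf(np.maximum(2 * (lnl - lnl0), 0), 1)
        rate = (p < 0.05).mean()
        lo, hi = stats.binom.interval(0.95, npairs, 0.05)
        assert lo / npairs <= rate <= hi / npairs


class TestFdr:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_bh_step_up_hand_example(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04, 0.05], "bh")
        np.testing.assert_allclose(q, [0.05] * 5)

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(0)
        p = np.sort(rng.random(50))
        for method in ("bh", "pike_robust"):
            q = fdr_adjust(p, method)
            assert (np.diff(q) >= -1e-12).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([])


class TestScan:
    def test_duplicated_column_near_maximal_lr(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 2, size=(60, 2))
        calls[:, 1] = calls[:, 0]
        m = toy_matrix(calls, sizes=[100, 100], primers=["P1", "P2"])
        out = ld_scan(m, pairs="all")
        assert len(out) == 1
        assert out["q"].iloc[0] < 1e-6

    def test_null_flag_fraction_controlled(self):
        rng = np.random.default_rng(2)
        calls = (rng.random((80, 40)) < rng.uniform(0.2, 0.8, 40)).astype(int)
        m = toy_matrix(calls)
        out = ld_scan(m, pairs="all")
        frac = (out.loc[out["converged"], "q"] <= 0.05).mean()
        assert frac <= 0.05 + 0.02

    def test_same_size_cross_primer_selection(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 2, size=(30, 4))
        m = toy_matrix(calls, sizes=[100, 100, 100, 200],
                       primers=["P1", "P2", "P1", "P2"])
        out = ld_scan(m, pairs="same_size_cross_primer")
        pairs = set(map(tuple, out[["locusA", "locusB"]].to_numpy()))
        # only the two same-size cross-primer combinations qualify
        assert len(pairs) == 2
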