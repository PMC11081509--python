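"""CCG machinery and the five pairwise inference algorithms."""

import numpy as np
import pytest

import spikeconn as sc
from spikeconn.pairwise import (SynWindow, compute_ccg,
                                hollow_gaussian_baseline, infer_ci,
                                infer_dsttc, infer_glmcc, infer_sccg,
                                infer_te, fit_glmcc_ccg)
from spikeconn.spike_trains import SpikeTrainSet
from conftest import make_poisson_set, make_planted_network


class TestComputeCcg:
    def test_constructed_lag(self):
        a = np.array([1.0, 2.0, 3.0])
        sts = SpikeTrainSet(["i", "j"], [a, a + 0.002], 10.0)
        ccg = compute_ccg(sts, "i", "j", t_max_ms=50.0, bin_width_ms=1.0)
        assert ccg.counts[ccg.lags_ms == 2.0][0] == 3
        assert ccg.counts.sum() == 3

    def test_mirror_symmetry(self):
        sts = make_poisson_set(2, 5.0, 60.0, seed=1)
        ab = compute_ccg(sts, "u0", "u1")
        ba = compute_ccg(sts, "u1", "u0")
        np.testing.assert_array_equal(ab.counts, ba.counts[::-1])

    def test_independent_poisson_expectation(self, poisson_pair):
        # E[count per bin] = r_i * r_j * T * delta
        ccg = compute_ccg(poisson_pair, "u0", "u1", t_max_ms=50.0,
                          bin_width_ms=1.0)
        r = poisson_pair.rates_hz()
        expected = r[0] * r[1] * poisson_pair.duration_s * 0.001
        assert ccg.counts.mean() == pytest.approx(expected, rel=0.1)

    def test_empty_train_warns(self):
        sts = SpikeTrainSet(["a", "b"], [np.empty(0), np.array([0.5])], 1.0)
        with pytest.warns(UserWarning):
            ccg = compute_ccg(sts, "a", "b")
        assert ccg.counts.sum() == 0


class TestHollowGaussianBaseline:
    def test_constant_ccg_preserved(self):
        ccg = compute_ccg(make_poisson_set(2, 1.0, 10.0), "u0", "u1")
        ccg.counts[:] = 7
        base = hollow_gaussian_baseline(ccg, sigma_ms=10.0,
                                        hollow_fraction=0.6)
        interior = base[30:-30]
        np.testing.assert_allclose(interior, 7.0, rtol=1e-9)

    def test_delta_input_matches_direct_convolution(self):
        ccg = compute_ccg(make_poisson_set(2, 1.0, 10.0), "u0", "u1",
                          t_max_ms=50.0, bin_width_ms=1.0)
        ccg.counts[:] = 0
        center = ccg.counts.size // 2
        ccg.counts[center] = 1
        h, sigma = 0.6, 10.0
        base = hollow_gaussian_baseline(ccg, sigma, h)
        # direct-convolution oracle: hollowed, renormalized unit-mass kernel
        x = np.arange(-51, 52) * 1.0
        g = np.exp(-0.5 * (x / sigma) ** 2)
        g /= g.sum()
        g0 = g[51]
        expected_center = (1 - h) * g0 / (1 - h * g0)
        assert base[center] == pytest.approx(expected_center, rel=1e-6)

    def test_zero_hollow_fraction_is_plain_smoothing(self):
        ccg = compute_ccg(make_poisson_set(2, 4.0, 50.0, seed=2),
                          "u0", "u1")
        a = hollow_gaussian_baseline(ccg, 10.0, 0.0)
        from scipy.ndimage import gaussian_filter1d
        b = gaussian_filter1d(ccg.counts.astype(float), 10.0,
                              mode="nearest")
        # same up to edge conventions
        assert np.allclose(a[25:-25], b[25:-25], rtol=0.02)


class TestInferCi:
    def test_planted_pair_strong_z(self):
        rng = np.random.default_rng(3)
        dur = 600.0
        a = np.sort(rng.uniform(0, dur, 600))
        bg = rng.uniform(0, dur, 600)
        fire = a[rng.random(a.size) < 0.3] + 0.002
        b = np.unique(np.concatenate([bg, fire]))
        b = b[b < dur]
        sts = SpikeTrainSet(["i", "j"], [a, b], dur)
        res = infer_ci(sts, n_surrogates=30, seed=4)
        assert res.S[0, 1] > 5.0
        assert res.W[0, 1] > 0

    def test_deterministic_given_seed(self):
        sts = make_poisson_set(4, 3.0, 60.0, seed=5)
        r1 = infer_ci(sts, n_surrogates=10, seed=6)
        r2 = infer_ci(sts, n_surrogates=10, seed=6)
        np.testing.assert_array_equal(np.nan_to_num(r1.S),
                                      np.nan_to_num(r2.S))

    def test_surrogate_count_validated(self):
        sts = make_poisson_set(2, 3.0, 30.0)
        with pytest.raises(ValueError):
            infer_ci(sts, n_surrogates=1)

    def test_surrogate_null_attached(self):
        sts = make_poisson_set(3, 3.0, 40.0, seed=21)
        res = infer_ci(sts, n_surrogates=6, seed=22)
        null = res.surrogate_null
        assert null.n_surrogates == 6
        assert null.mu_surr.shape == (3, 3)
        assert np.all(null.sd_surr[res.offdiag_mask()] >= 0)


class TestInferSccg:
    def test_null_center_score(self):
        # C_w == Lambda_w exactly -> two-sided p ~ 0.5, score ~ 0.2-0.3
        from scipy import stats as st
        lam = 10.0
        p_plus = st.poisson.sf(10 - 1, lam)
        p_minus = st.poisson.cdf(10, lam)
        assert -np.log10(min(p_plus, p_minus)) < 0.45

    def test_planted_signs(self, planted_fixture):
        sts, adj = planted_fixture
        res = infer_sccg(sts)
        exc = np.argwhere(adj > 0)
        inh = np.argwhere(adj < 0)
        assert np.mean([res.W[i, j] > 0 for i, j in exc]) >= 0.9
        assert np.mean([res.S[i, j] > 3 for i, j in exc]) >= 0.8
        assert np.mean([res.W[i, j] < 0 for i, j in inh]) >= 0.8

    def test_window_must_fit_span(self):
        sts = make_poisson_set(2, 3.0, 30.0)
        with pytest.raises(ValueError):
            infer_sccg(sts, window=SynWindow(0.5, 80.0), t_max_ms=50.0)


class TestInferDsttc:
    def test_shifted_copy_gives_unity(self):
        a = np.arange(1.0, 9.0, 1.0)
        sts = SpikeTrainSet(["i", "j"], [a, a + 0.001], 10.0)
        res = infer_dsttc(sts, dt_ms=5.0, n_surrogates=5, seed=7)
        assert res.W[0, 1] == pytest.approx(1.0)

    def test_matches_brute_force_formula(self):
        # brute-force oracle over all spike pairs and window unions
        i = np.array([1.0, 2.0])
        j = np.array([1.002, 3.0])
        dur, dt = 10.0, 0.005
        sts = SpikeTrainSet(["i", "j"], [i, j], dur)

        def coverage_after(t):
            iv = [(x, min(x + dt, dur)) for x in t]
            merged = []
            for s, e in iv:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], e)
                else:
                    merged.append((s, e))
            return sum(e - s for s, e in merged) / dur

        def coverage_before(t):
            iv = [(max(x - dt, 0.0), x) for x in t]
            merged = []
            for s, e in iv:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], e)
                else:
                    merged.append((s, e))
            return sum(e - s for s, e in merged) / dur

        p_plus = np.mean([np.any((j > x) & (j <= x + dt)) for x in i])
        t_plus = coverage_after(j)
        p_minus = np.mean([np.any((i >= x - dt) & (i < x)) for x in j])
        t_minus = coverage_before(i)
        oracle = 0.5 * ((p_plus - t_plus) / (1 - p_plus * t_plus)
                        + (p_minus - t_minus) / (1 - p_minus * t_minus))
        res = infer_dsttc(sts, dt_ms=5.0, n_surrogates=5, seed=8)
        assert res.W[0, 1] == pytest.approx(oracle, abs=1e-9)

    def test_independent_pairs_near_zero(self):
        sts = make_poisson_set(12, 2.0, 100.0, seed=9)
        res = infer_dsttc(sts, n_surrogates=5, seed=10)
        off = res.offdiag_mask()
        assert abs(np.nanmean(res.W[off])) < 0.02


class TestGlmcc:
    def test_parameter_recovery_coverage(self):
        rng = np.random.default_rng(11)
        lags = np.arange(-50, 51).astype(float)
        f_fwd = np.where(lags >= 1.0, np.exp(-(lags - 1.0) / 4.0), 0.0)
        cover = 0
        for rep in range(100):
            lam = np.exp(np.log(20.0) + 1.5 * f_fwd)
            y = rng.poisson(lam)
            fit = fit_glmcc_ccg(y, lags, 1.0)
            if abs(fit.J_fwd - 1.5) < 1.96 * fit.se_fwd:
                cover += 1
        assert cover >= 90

    def test_null_wald_calibration(self):
        rng = np.random.default_rng(12)
        lags = np.arange(-50, 51).astype(float)
        hits = 0
        n = 200
        for rep in range(n):
            y = rng.poisson(np.full(lags.size, 15.0))
            fit = fit_glmcc_ccg(y, lags, 1.0)
            if abs(fit.J_fwd) / fit.se_fwd > 1.96:
                hits += 1
        se = np.sqrt(0.05 * 0.95 / n)
        assert abs(hits / n - 0.05) < 3 * se + 1e-9

    def test_role_reversal_swaps_couplings(self):
        sts, adj = make_planted_network(n_units=4, n_exc_edges=1,
                                        n_inh_edges=0, duration_s=300.0,
                                        seed=13)
        res = infer_glmcc(sts)
        i, j = np.argwhere(adj > 0)[0]
        # the fitted forward coupling i->j should dominate j->i
        assert res.W[i, j] > res.W[j, i]
        rev = SpikeTrainSet(list(sts.unit_ids),
                            [np.sort(sts.duration_s - t)
                             for t in sts.spikes], sts.duration_s)
        res_rev = infer_glmcc(rev)
        # time reversal swaps pre/post roles of the planted edge
        assert res_rev.W[j, i] > res_rev.W[i, j]

    def test_planted_signs(self, planted_fixture):
        sts, adj = planted_fixture
        res = infer_glmcc(sts)
        exc = np.argwhere(adj > 0)
        inh = np.argwhere(adj < 0)
        assert np.mean([res.W[i, j] > 0 for i, j in exc]) >= 0.9
        assert np.mean([res.W[i, j] < 0 for i, j in inh]) >= 0.8


class TestInferTe:
    def test_deterministic_copy_is_one_bit(self):
        # x_j(t) = x_i(t-1) with iid Bernoulli(1/2) bins -> TE = 1 bit
        rng = np.random.default_rng(14)
        n_bins = 20000
        x = rng.integers(0, 2, n_bins)
        ti = np.flatnonzero(x) * 0.001 + 0.0002
        tj = (np.flatnonzero(x) + 1) * 0.001 + 0.0002
        tj = tj[tj < 20.0]
        sts = SpikeTrainSet(["i", "j"], [ti, tj], 20.0)
        res = infer_te(sts, bin_width_ms=1.0, delay_range_ms=(1, 3),
                       n_surrogates=3, seed=15)
        assert res.params["history_bins"] == 1
        te = abs(res.W[0, 1])
        assert te == pytest.approx(1.0, abs=0.05)

    def test_te_nonnegative_and_surrogate_centering(self):
        sts = make_poisson_set(5, 8.0, 50.0, seed=16)
        res = infer_te(sts, n_surrogates=8, seed=17,
                       delay_range_ms=(1, 5))
        off = res.offdiag_mask()
        assert np.all(np.abs(res.W[off]) >= 0)  # TE magnitude >= 0
        # scores are centered: mean |z| modest on independent data
        assert abs(np.nanmean(res.S[off])) < 1.0

    def test_insufficient_bins_rejected(self):
        sts = make_poisson_set(2, 5.0, 0.5, seed=18)
        with pytest.raises(ValueError):
            infer_te(sts, bin_width_ms=1.0)


class TestMethodContracts:
    @pytest.mark.parametrize("runner", [
        lambda s: infer_ci(s, n_surrogates=5, seed=1),
        lambda s: infer_sccg(s),
        lambda s: infer_dsttc(s, n_surrogates=5, seed=1),
        lambda s: infer_te(s, n_surrogates=4, seed=1,
                           delay_range_ms=(1, 5)),
    ], ids=["CI", "sCCG", "dSTTC", "TE"])
    def test_finite_offdiagonal_scores(self, runner):
        sts = make_poisson_set(5, 4.0, 40.0, seed=19)
        res = runner(sts)
        off = res.offdiag_mask()
        assert np.all(np.isfinite(res.S[off]))
        assert np.all(np.isnan(np.diag(res.S)))
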