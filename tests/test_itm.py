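import numpy as np
import pytest

from eegfx import (DelayGrid, kappa_series, mean_kappa, kappa_itcr_series,
                   itm_features, EEGRecord, extract_epoch)
from eegfx.itm import UndefinedFeatureWarning, _fmt_ms

from _oracles import naive_mean_kappa, naive_mean_itcr


class TestKappaSeries:
    def test_ramp_hand_value(self):
        # V(t) = t uV at 250 Hz, lag 2 samples = 8 ms: every |dV| = 2,
        # kappa = ln 2 / ln 8 at every timepoint
        ks = kappa_series(np.arange(100.0), delay=2, fs=250.0)
        assert ks.n_valid == ks.n_total == 98
        np.testing.assert_allclose(ks.values, np.log(2) / np.log(8),
                                   rtol=0, atol=1e-12)

    def test_constant_signal_all_excluded(self):
        ks = kappa_series(np.full(50, 7.0), delay=1, fs=250.0)
        assert ks.n_valid == 0
        with pytest.warns(UndefinedFeatureWarning):
            assert np.isnan(mean_kappa(ks))

    def test_matches_naive_loop_on_noise(self, rng):
        x = rng.standard_normal(400) * 20
        for delay in (1, 3, 7):
            ks = kappa_series(x, delay, fs=250.0)
            mean, n_valid, excluded = naive_mean_kappa(x, delay, 250.0)
            assert ks.n_valid == n_valid
            assert ks.n_total - ks.n_valid == excluded
            assert mean_kappa(ks) == pytest.approx(mean, rel=1e-12)

    def test_one_ms_lag_rejected(self):
        with pytest.raises(ValueError, match="1 ms"):
            kappa_series(np.arange(100.0), delay=1, fs=1000.0)

    def test_delay_bounds(self):
        with pytest.raises(ValueError):
            kappa_series(np.arange(10.0), delay=10, fs=250.0)
        with pytest.raises(ValueError):
            kappa_series(np.arange(10.0), delay=0, fs=250.0)

    def test_base_invariance(self, rng):
        # kappa is a ratio of logs, so the base cancels
        x = rng.standard_normal(200) * 15
        ks = kappa_series(x, 2, fs=250.0)
        dv = np.abs(x[2:] - x[:-2])
        dv = dv[dv > 0]
        base10 = np.log10(dv) / np.log10(8.0)
        np.testing.assert_allclose(ks.values, base10, rtol=1e-12)

    def test_scaling_changes_within_lead_kappa(self, rng):
        x = rng.standard_normal(500) * 10
        k1 = mean_kappa(kappa_series(x, 2, fs=250.0))
        k2 = mean_kappa(kappa_series(5 * x, 2, fs=250.0))
        assert k1 != pytest.approx(k2, abs=1e-6)


class TestMeanKappa:
    def test_small_cases(self):
        from eegfx import KappaSeries
        s = KappaSeries(values=np.array([0.2, 0.4]), n_total=5, n_valid=2,
                        delay=1)
        assert mean_kappa(s) == pytest.approx(0.3)
        c = KappaSeries(values=np.full(4, 0.7), n_total=4, n_valid=4, delay=1)
        assert mean_kappa(c) == pytest.approx(0.7)


class TestKappaItcr:
    def test_identical_leads_exactly_one(self, rng):
        x = rng.standard_normal(300) * 12
        ks = kappa_itcr_series(x, x.copy(), delay=3)
        assert ks.n_valid > 0
        assert float(ks.values.min()) == 1.0
        assert float(ks.values.max()) == 1.0
        assert mean_kappa(ks) == 1.0

    def test_identical_leads_scale_together_invariant(self, rng):
        x = rng.standard_normal(300) * 12
        ks = kappa_itcr_series(3 * x, 3 * x, delay=2)
        assert mean_kappa(ks) == 1.0

    def test_ramp_pair_hand_value(self):
        # source step 4 uV, dest step 2 uV at lag 1: ln 4 / ln 2 = 2
        src = 4.0 * np.arange(50)
        dst = 2.0 * np.arange(50)
        ks = kappa_itcr_series(src, dst, delay=1)
        np.testing.assert_allclose(ks.values, 2.0, atol=1e-12)

    def test_matches_naive_loop(self, rng):
        a = rng.standard_normal(400) * 8
        b = rng.standard_normal(400) * 25
        for delay in (1, 5):
            ks = kappa_itcr_series(a, b, delay)
            mean, n_valid, excluded = naive_mean_itcr(a, b, delay)
            assert ks.n_valid == n_valid
            assert ks.n_total - ks.n_valid == excluded
            assert mean_kappa(ks) == pytest.approx(mean, rel=1e-12)

    def test_unit_denominator_difference_excluded(self):
        # |dV_dest| = 1 uV makes log|dV_dest| = 0: the guard must drop it
        src = np.array([0.0, 3.0, 6.0, 9.0])
        dst = np.array([0.0, 1.0, 2.0, 3.0])   # every lag-1 step is 1 uV
        ks = kappa_itcr_series(src, dst, delay=1)
        assert ks.n_valid == 0
        assert ks.n_total == 3

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            kappa_itcr_series(np.arange(10.0), np.arange(9.0), 1)

    def test_ordered_pairs_not_reciprocal(self, rng):
        # mean of ratios l1/l2 is not 1 / (mean of ratios l2/l1)
        a = rng.standard_normal(2000) * 5
        b = rng.standard_normal(2000) * 40
        ab = mean_kappa(kappa_itcr_series(a, b, 2))
        ba = mean_kappa(kappa_itcr_series(b, a, 2))
        assert ab != pytest.approx(1.0 / ba, rel=1e-3)


class TestDelayGrid:
    def test_defaults(self):
        w = DelayGrid.within_default(250.0)
        assert w.delays == (1, 2, 4, 8, 16)
        assert w.delays_ms == (4.0, 8.0, 16.0, 32.0, 64.0)
        b = DelayGrid.between_default(250.0)
        assert b.delays == (1, 6, 32, 178, 1000)
        assert b.delays_ms[0] == 4.0 and b.delays_ms[-1] == 4000.0

    def test_validation(self):
        with pytest.raises(ValueError):
            DelayGrid((2, 1), 250.0)
        with pytest.raises(ValueError):
            DelayGrid((0, 1), 250.0)
        with pytest.raises(ValueError):
            DelayGrid((), 250.0)


class TestITMFeatures:
    def test_counts_10_leads(self, rng, epoch_factory):
        ep = epoch_factory(rng.standard_normal((10, 500)) * 10)
        grid = DelayGrid((1, 2, 4, 8, 16), 250.0)
        fs = itm_features(ep, grid, grid)
        assert len(fs.within) == 50
        assert len(fs.between) == 450
        assert len(fs) == 500
        s = fs.to_series()
        assert len(s) == 500
        assert "itm_w_1_4" in s.index
        assert "itm_b_1_2_4" in s.index

    def test_single_lead_no_between(self, rng, epoch_factory):
        ep = epoch_factory(rng.standard_normal((1, 300)))
        grid = DelayGrid((1, 2), 250.0)
        fs = itm_features(ep, grid, grid)
        assert len(fs.between) == 0
        assert len(fs.within) == 2

    def test_undefined_features_warn(self, epoch_factory):
        ep = epoch_factory(np.zeros((2, 300)) + 5.0)
        grid = DelayGrid((1,), 250.0)
        with pytest.warns(UndefinedFeatureWarning):
            fs = itm_features(ep, grid, grid)
        assert np.isnan(list(fs.within.values())).all()

    def test_delay_exceeding_epoch_rejected(self, rng, epoch_factory):
        ep = epoch_factory(rng.standard_normal((2, 100)))
        with pytest.raises(ValueError, match="epoch length"):
            itm_features(ep, DelayGrid((1, 200), 250.0),
                         DelayGrid((1,), 250.0))

    def test_ms_formatting(self):
        assert _fmt_ms(4.0) == "4"
        assert _fmt_ms(2.5) == "2.5"
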