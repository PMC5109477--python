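import math

import numpy as np
import pytest

from fluctcorr import ctc
from fluctcorr.errors import BinningError
from fluctcorr.synthetic import (
    OUNetworkSpec,
    brute_force_lagged_correlation,
    simulate_ou_network,
)

from conftest import make_fluct


class TestConnectivityFluctuation:
    def test_equal_series_zero(self):
        base = np.random.default_rng(0).standard_normal((50, 1, 3))
        fl = make_fluct(np.concatenate([base, base], axis=1))
        v = ctc.connectivity_fluctuation(fl, 0, 1)
        assert np.abs(v).max() == 0

    def test_constant_difference(self):
        deltas = np.zeros((4, 2, 3))
        deltas[::2, 0, 0] = 1.0
        deltas[1::2, 0, 0] = -1.0
        deltas[::2, 1, 1] = 1.0
        deltas[1::2, 1, 1] = -1.0
        fl = make_fluct(deltas)
        v = ctc.connectivity_fluctuation(fl, 0, 1)
        np.testing.assert_allclose(v[0], [1.0, -1.0, 0.0])

    def test_matches_subtraction_oracle(self):
        fl = make_fluct(np.random.default_rng(1).standard_normal((30, 4, 3)))
        v = ctc.connectivity_fluctuation(fl, 1, 3)
        for t in range(30):
            np.testing.assert_array_equal(v[t], fl.deltas[t, 1] - fl.deltas[t, 3])

    def test_same_site_rejected(self):
        fl = make_fluct(np.random.default_rng(2).standard_normal((10, 2, 3)))
        with pytest.raises(ValueError):
            ctc.connectivity_fluctuation(fl, 1, 1)


class TestDelayedAutocorrelation:
    def test_zero_lag_is_one(self):
        v = np.random.default_rng(3).standard_normal((100, 3))
        curve = ctc.delayed_autocorrelation(v, dt=1.0, max_lag=10.0)
        assert curve.values[0] == 1.0
        assert curve.normalized

    def test_ou_closed_form_decay(self):
        lam = 0.5
        spec = OUNetworkSpec(1, np.array([[lam]]), np.array([[1.0]]),
                             dt=0.01, n_steps=200_000, seed=21)
        fl = simulate_ou_network(spec)
        curve = ctc.delayed_autocorrelation(fl.deltas[:, 0], fl.dt, max_lag=4.0,
                                            lag_stride=0.1)
        # C(tau) ~ exp(-lam tau); value at 2 ps within 10% of 1/e
        at2 = curve.values[np.argmin(np.abs(curve.lags - 2.0))]
        assert at2 == pytest.approx(math.exp(-1.0), rel=0.10)

    def test_white_noise_bound(self):
        rng = np.random.default_rng(4)
        n = 20_000
        v = rng.standard_normal((n, 3))
        curve = ctc.delayed_autocorrelation(v, dt=1.0, max_lag=5.0)
        assert np.abs(curve.values[1:]).max() < 3.0 / math.sqrt(n)

    def test_max_lag_beyond_duration_rejected(self):
        v = np.random.default_rng(5).standard_normal((50, 3))
        with pytest.raises(ValueError):
            ctc.delayed_autocorrelation(v, dt=1.0, max_lag=60.0)


class TestDecayTime:
    def test_exponential_closed_form(self):
        lags = np.arange(0, 100) * 0.1
        curve = ctc.DelayedCorrelationCurve(
            lags=lags, values=np.exp(-lags / 3.0), pair=("self", "self"),
            normalized=True,
        )
        assert ctc.decay_time(curve) == pytest.approx(3.0, abs=0.01)

    def test_never_crossing_flag(self):
        lags = np.arange(0, 10, dtype=float)
        curve = ctc.DelayedCorrelationCurve(
            lags=lags, values=1.0 - 0.01 * lags, pair=("self", "self"), normalized=True
        )
        assert ctc.decay_time(curve) is None

    def test_ou_decay_matches_inverse_rate(self):
        lam = 0.5
        spec = OUNetworkSpec(1, np.array([[lam]]), np.array([[1.0]]),
                             dt=0.01, n_steps=200_000, seed=22)
        fl = simulate_ou_network(spec)
        curve = ctc.delayed_autocorrelation(fl.deltas[:, 0], fl.dt, max_lag=8.0,
                                            lag_stride=0.05)
        assert ctc.decay_time(curve) == pytest.approx(1.0 / lam, rel=0.10)

    def test_unnormalized_rejected(self):
        curve = ctc.DelayedCorrelationCurve(
            lags=np.array([0.0, 1.0]), values=np.array([5.0, 1.0]),
            pair=(0, 1), normalized=False, normalization="none",
        )
        with pytest.raises(ValueError):
            ctc.decay_time(curve)


class TestDelayedCrossCorrelation:
    def test_zero_lag_exchange_symmetry(self):
        fl = make_fluct(np.random.default_rng(6).standard_normal((200, 4, 3)))
        for i in range(4):
            for j in range(i + 1, 4):
                a = ctc.delayed_cross_correlation(fl, i, j, np.array([0.0]),
                                                  normalization="none")
                b = ctc.delayed_cross_correlation(fl, j, i, np.array([0.0]),
                                                  normalization="none")
                assert abs(a.values[0] - b.values[0]) < 1e-12

    def test_pure_delay_peak(self):
        rng = np.random.default_rng(7)
        d = 5
        n = 20_000
        x = rng.standard_normal((n + d, 3))
        deltas = np.stack([x[d : n + d], x[:n]], axis=1)  # site1(t) = site0(t - d)
        fl = make_fluct(deltas)
        lags = np.arange(0.0, 11.0)
        fwd = ctc.delayed_cross_correlation(fl, 0, 1, lags, normalization="pearson")
        bwd = ctc.delayed_cross_correlation(fl, 1, 0, lags, normalization="pearson")
        assert np.argmax(fwd.values) == d
        assert fwd.values[d] == pytest.approx(1.0, abs=0.02)
        assert np.abs(bwd.values[1:]).max() < 0.05

    def test_direct_equals_brute_force(self):
        fl = make_fluct(np.random.default_rng(8).standard_normal((200, 5, 3)))
        lags = np.array([0.0, 1.0, 3.0, 7.0])
        for i in range(5):
            for j in range(5):
                curve = ctc.delayed_cross_correlation(fl, i, j, lags,
                                                      normalization="none")
                for lag, value in zip(lags, curve.values):
                    oracle = brute_force_lagged_correlation(fl, i, j, int(lag))
                    assert abs(value - oracle) < 1e-10

    def test_self_curve_equals_autocorrelation(self):
        fl = make_fluct(np.random.default_rng(9).standard_normal((500, 2, 3)))
        lags = np.arange(0.0, 20.0)
        self_curve = ctc.delayed_cross_correlation(fl, 1, 1, lags)
        auto = ctc.delayed_autocorrelation(fl.deltas[:, 1], fl.dt, max_lag=19.0)
        np.testing.assert_allclose(self_curve.values, auto.values, atol=1e-12)

    def test_direct_vs_binned_agreement(self, chain_fluct):
        fl, _edges = chain_fluct
        lags = np.arange(0, 41, 4) * fl.dt
        direct = ctc.delayed_cross_correlation(fl, 0, 1, lags, estimator="direct")
        binned = ctc.delayed_cross_correlation(fl, 0, 1, lags, estimator="binned")
        assert np.abs(direct.values - binned.values).max() < 0.05

    def test_binned_too_few_samples(self):
        fl = make_fluct(np.random.default_rng(10).standard_normal((100, 2, 3)))
        with pytest.raises(BinningError, match="bins"):
            ctc.delayed_cross_correlation(fl, 0, 1, np.array([0.0, 1.0]),
                                          estimator="binned", n_bins=20)

    def test_time_reversal_swaps_directions(self):
        deltas = np.random.default_rng(11).standard_normal((300, 3, 3))
        fl = make_fluct(deltas)
        rev = make_fluct(deltas[::-1])
        lags = np.array([0.0, 2.0, 5.0])
        a = ctc.delayed_cross_correlation(fl, 0, 2, lags, normalization="none")
        b = ctc.delayed_cross_correlation(rev, 2, 0, lags, normalization="none")
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)

    def test_non_multiple_lag_rejected(self):
        fl = make_fluct(np.random.default_rng(12).standard_normal((100, 2, 3)), dt=0.5)
        with pytest.raises(ValueError, match="multiple"):
            ctc.delayed_cross_correlation(fl, 0, 1, np.array([0.0, 0.7]))


class TestCausalityScan:
    def test_two_site_unidirectional(self):
        from fluctcorr.synthetic import make_driver_follower_chain

        fl, edges = make_driver_follower_chain(2, 0.5, 1.0, 0.05, 100_000, seed=31)
        got = ctc.causality_scan(fl, lag=1.0)
        assert [(e.driver, e.follower) for e in got] == edges

    def test_symmetric_coupling_no_edge(self):
        # equal bidirectional coupling: asymmetry is pure noise
        lam, c = 1.0, 0.4
        A = np.array([[lam, -c], [-c, lam]])
        hits = 0
        for seed in range(10):
            spec = OUNetworkSpec(2, A, np.eye(2), dt=0.05, n_steps=50_000, seed=seed)
            fl = simulate_ou_network(spec)
            if ctc.causality_scan(fl, lag=1.0):
                hits += 1
        assert hits == 0

    def test_independent_sites_empty(self):
        spec = OUNetworkSpec(3, np.eye(3), np.eye(3), dt=0.05, n_steps=50_000, seed=41)
        fl = simulate_ou_network(spec)
        assert ctc.causality_scan(fl, lag=1.0) == []

    def test_chain_recovery(self, chain_fluct):
        fl, edges = chain_fluct
        got = ctc.causality_scan(fl, lag=1.0)
        assert {(e.driver, e.follower) for e in got} == set(edges)
        for e in got:
            assert e.asymmetry > 0
            assert e.c_forward > e.c_backward

    def test_sorted_by_asymmetry(self, chain_fluct):
        fl, _ = chain_fluct
        got = ctc.causality_scan(fl, lag=1.0, min_strength=0.0, min_asymmetry=0.0)
        asym = [e.asymmetry for e in got]
        assert asym == sorted(asym, reverse=True)

    def test_pairs_subset(self, chain_fluct):
        fl, _ = chain_fluct
        got = ctc.causality_scan(fl, lag=1.0, pairs=[(0, 1)])
        assert [(e.driver, e.follower) for e in got] == [(0, 1)]

    def test_lag_validation(self, chain_fluct):
        fl, _ = chain_fluct
        with pytest.raises(ValueError):
            ctc.causality_scan(fl, lag=0.0)
        with pytest.raises(ValueError):
            ctc.causality_scan(fl, lag=fl.duration + 1.0)

    def test_edges_to_graph(self, chain_fluct):
        fl, edges = chain_fluct
        g = ctc.edges_to_graph(ctc.causality_scan(fl, lag=1.0))
        assert g.number_of_edges() == len(edges)
        for _u, _v, data in g.edges(data=True):
            assert data["asymmetry"] > 0
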