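"""Train amplitudes, cumulative-EPSC RRP back-extrapolation, P_train,
depression decay and paired-pulse ratio."""

import math

import numpy as np
import pytest

from nmjphys import (ReleaseModelParams, analyze_train, depression_decay_fit,
                     estimate_rrp, p_train, paired_pulse_ratio,
                     simulate_evoked_train, train_amplitudes)
from nmjphys.errors import ParameterError
from nmjphys.trace import Trace


def _params(**kw):
    defaults = dict(n_pool=100, p_r=0.5, q_mean=1.0, q_cv=0.0,
                    replenish_rate=0.0, noise_sd=0.0)
    defaults.update(kw)
    return ReleaseModelParams(**defaults)


class TestTrainAmplitudes:
    def test_noiseless_round_trip_exact(self):
        ss, truth = simulate_evoked_train(_params(q_cv=0.3), seed=2, n_sweeps=3)
        for sw, st, expect in zip(ss.sweeps, ss.stimulus_times, truth["amplitudes"]):
            got = train_amplitudes(sw, st)
            np.testing.assert_allclose(got, expect, atol=1e-9)

    def test_all_zero_sweep(self):
        ss, _ = simulate_evoked_train(_params(), seed=0, n_sweeps=1)
        zero = ss.sweeps[0].with_samples(np.zeros_like(ss.sweeps[0].samples))
        assert np.array_equal(train_amplitudes(zero, ss.stimulus_times[0]), np.zeros(30))

    def test_constant_offset_invariance(self):
        ss, truth = simulate_evoked_train(_params(), seed=6, n_sweeps=1)
        shifted = ss.sweeps[0].with_samples(ss.sweeps[0].samples - 2.5)
        np.testing.assert_allclose(train_amplitudes(shifted, ss.stimulus_times[0]),
                                   truth["amplitudes"][0], atol=1e-9)

    def test_cumulative_increments_are_amplitudes(self):
        ss, _ = simulate_evoked_train(_params(q_cv=0.3, replenish_rate=600), seed=8)
        res = analyze_train(ss, quantal_size=1.0)
        np.testing.assert_allclose(np.diff(res.cumulative), res.amplitudes[1:], rtol=1e-12)


class TestEstimateRRP:
    def test_depletion_closed_form_recovers_pool(self):
        # amplitudes q*p*N*(1-p)^(i-1): cumulative -> N*q, slope -> 0
        p, N, q = 0.5, 100.0, 1.0
        i = np.arange(1, 31)
        amps = q * p * N * (1 - p) ** (i - 1)
        fit = estimate_rrp(amps, q)
        assert fit.rrp_quanta == pytest.approx(N, abs=0.1)
        assert abs(fit.fit_slope) < 1e-3

    def test_constant_amplitudes_have_zero_intercept(self):
        fit = estimate_rrp(np.full(30, 2.0), 1.0)
        assert fit.fit_intercept_nA == pytest.approx(0.0, abs=1e-9)
        assert fit.rrp_quanta == pytest.approx(0.0, abs=1e-9)

    def test_quantal_scale_invariance(self):
        amps = np.linspace(3.0, 1.0, 30)
        a = estimate_rrp(amps, 0.05)
        b = estimate_rrp(amps * 7.0, 0.05 * 7.0)
        assert b.rrp_quanta == pytest.approx(a.rrp_quanta, rel=1e-12)

    def test_noiseless_simulation_recovers_pool_within_0_1pct(self):
        ss, truth = simulate_evoked_train(_params(p_r=0.4), seed=3, n_sweeps=1)
        amps = train_amplitudes(ss.sweeps[0], ss.stimulus_times[0])
        fit = estimate_rrp(amps, truth["q_mean"])
        assert fit.rrp_quanta == pytest.approx(100.0, rel=1e-3)

    def test_replenishment_noise_median_matches_recursion_oracle(self):
        """With replenishment the back-extrapolated intercept has a known
        deterministic offset: the pool recursion pool' = (1-p)*pool + R gives
        cumulative(n) = R*n + (N - R/p)*(1 - (1-p)^n), so the fitted
        intercept converges to N - R/p quanta, not N.  The stochastic median
        over 50 seeds must sit within 15% of that closed-form value."""
        N, pr, rate = 200, 0.3, 1200.0
        R = rate / 60.0                      # vesicles per 60-Hz interval
        oracle = N - R / pr                  # = 133.3 quanta
        p = _params(n_pool=N, p_r=pr, replenish_rate=rate, q_cv=0.3)
        est = []
        for seed in range(50):
            _, truth = simulate_evoked_train(p, seed=seed, n_sweeps=5)
            amps = truth["amplitudes"].mean(axis=0)
            est.append(estimate_rrp(amps, p.q_mean).rrp_quanta)
        assert abs(np.median(est) - oracle) / oracle <= 0.15

    def test_bias_on_replenishment_free_pools(self):
        """Back-extrapolation cannot exceed the true pool by more than
        sampling error; measure the bias explicitly."""
        p = _params(p_r=0.4, q_cv=0.3)
        est = [estimate_rrp(
            simulate_evoked_train(p, seed=s, n_sweeps=5)[1]["amplitudes"].mean(axis=0),
            p.q_mean).rrp_quanta for s in range(30)]
        bias = np.mean(est) - 100.0
        assert abs(bias) < 5.0   # < 5% of the 100-vesicle pool

    def test_bad_quantal_size_rejected(self):
        with pytest.raises(ParameterError):
            estimate_rrp(np.ones(30), 0.0)


class TestPTrain:
    def test_simple_ratio(self):
        amps = np.zeros(30)
        amps[0] = 20.0
        assert p_train(amps, 100.0).value == pytest.approx(0.2)

    def test_exhaustion_gives_unity(self):
        ss, truth = simulate_evoked_train(_params(p_r=1.0), seed=1, n_sweeps=1)
        amps = train_amplitudes(ss.sweeps[0], ss.stimulus_times[0])
        fit = estimate_rrp(amps, 1.0)
        assert p_train(amps, fit.fit_intercept_nA).value == pytest.approx(1.0, rel=1e-6)

    def test_recovers_release_probability(self):
        # depletion model: E[P_train] ~ p_r; mean over 100 seeds within 3 SE
        p = _params(p_r=0.2, n_pool=300)
        vals = []
        for seed in range(100):
            _, truth = simulate_evoked_train(p, seed=seed, n_sweeps=1)
            amps = truth["amplitudes"][0]
            fit = estimate_rrp(amps, p.q_mean)
            vals.append(p_train(amps, fit.fit_intercept_nA).value)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 0.2) <= 3 * se

    def test_monotone_in_release_probability(self):
        """P_train falls with p_r on matched simulations — the signature of
        reduced release probability the train method is meant to expose."""
        means = []
        for pr in (0.15, 0.3, 0.5):
            vals = []
            for seed in range(30):
                _, truth = simulate_evoked_train(_params(p_r=pr, n_pool=300), seed=seed,
                                                 n_sweeps=1)
                amps = truth["amplitudes"][0]
                fit = estimate_rrp(amps, 1.0)
                vals.append(p_train(amps, fit.fit_intercept_nA).value)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_undefined_and_clipped_flags(self):
        amps = np.r_[5.0, np.zeros(29)]
        with pytest.warns(UserWarning):
            assert p_train(amps, 0.0).flag == "undefined"
        with pytest.warns(UserWarning):
            res = p_train(amps, 2.0)
        assert res.flag == "clipped" and res.value == 1.0


class TestDepressionDecay:
    def test_recovers_own_model_exactly(self):
        i = np.arange(1, 31, dtype=float)
        amps = 1.5 + 4.0 * np.exp(-(i - 2) / 3.0)
        fit = depression_decay_fit(amps)
        assert fit.decay_constant == pytest.approx(3.0, abs=1e-6)

    def test_constant_amplitudes_flag_no_decay(self):
        assert depression_decay_fit(np.full(30, 2.0)).flag == "no-decay"

    def test_depletion_sim_matches_geometric_decay_constant(self):
        # depletion decay a_i ~ (1-p)^(i-1): tau = -1/ln(1-p)
        p = 0.3
        tau_true = -1.0 / math.log(1.0 - p)
        taus = []
        for seed in range(50):
            _, truth = simulate_evoked_train(_params(p_r=p, n_pool=400, q_cv=0.2),
                                             seed=seed, n_sweeps=5)
            taus.append(depression_decay_fit(truth["amplitudes"].mean(axis=0)).decay_constant)
        assert abs(np.median(taus) - tau_true) / tau_true <= 0.2


class TestPairedPulse:
    def test_identical_and_scaled_responses(self):
        ss, _ = simulate_evoked_train(_params(), "paired_pulse", seed=0,
                                      n_sweeps=1, interval_s=0.05)
        sw, st = ss.sweeps[0], ss.stimulus_times[0]
        dt = sw.dt
        # build a sweep with two identical EPSCs, then one with an 80% second pulse
        y = np.zeros_like(sw.samples)
        for t_i, scale in zip(st, (1.0, 1.0)):
            j = int(round(t_i / dt))
            y[j + 10] = -scale * 2.0
        assert paired_pulse_ratio(sw.with_samples(y), st) == pytest.approx(1.0)
        y2 = y.copy()
        y2[int(round(st[1] / dt)) + 10] = -1.6
        assert paired_pulse_ratio(sw.with_samples(y2), st) == pytest.approx(0.8)

    def test_depletion_oracle_one_minus_p(self):
        p = _params(n_pool=200)
        ratios = []
        for seed in range(100):
            ss, _ = simulate_evoked_train(p, "paired_pulse", seed=seed,
                                          n_sweeps=3, interval_s=0.05)
            ratios += [paired_pulse_ratio(sw, st)
                       for sw, st in zip(ss.sweeps, ss.stimulus_times)]
        se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(np.mean(ratios) - 0.5) <= 3 * se

    def test_requires_exactly_two_stimuli(self):
        tr = Trace(np.zeros(1000), dt=1e-4, channel="current_nA")
        with pytest.raises(ParameterError):
            paired_pulse_ratio(tr, [0.01, 0.02, 0.03])
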