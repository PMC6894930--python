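import numpy as np
import pandas as pd
import pytest
from scipy.special import kolmogorov

from _oracles import exact_bootstrap_t50_sd, exact_ks_permutation_p
from calgate import (
    ResponseCall,
    bootstrap_lag,
    cumulative_profile,
    ks_compare,
    ks_pvalue,
    magnitude_peak,
    magnitude_sensory,
    pulse_pair_stats,
    rise_time,
)
from calgate.response_stats import CumulativeProfile, kolmogorov_tail


def responders(latencies):
    return [ResponseCall(True, int(100 + round(l * 10)), l) for l in latencies]


def nonresponders(n):
    return [ResponseCall(False) for _ in range(n)]


class TestCumulativeProfile:
    def test_no_responders_curve_is_zero(self):
        prof = cumulative_profile(nonresponders(10))
        assert np.allclose(prof.curve, 0.0)
        assert prof.response_fraction == 0.0

    def test_counting_oracle(self):
        prof = cumulative_profile(responders([1.0, 1.0, 3.0]) + nonresponders(1))
        assert prof.curve[prof.times < 1.0].max() == 0.0
        t = prof.times
        assert np.all(prof.curve[(t >= 1.0) & (t < 3.0)] == 0.5)
        assert np.all(prof.curve[t >= 3.0] == 0.75)
        assert prof.response_fraction == 0.75

    def test_curve_nondecreasing_and_bounded(self):
        rng = np.random.default_rng(0)
        prof = cumulative_profile(
            responders(rng.uniform(0, 9, 25)) + nonresponders(15)
        )
        assert np.all(np.diff(prof.curve) >= 0)
        assert prof.curve[-1] == pytest.approx(25 / 40)

    def test_empty_call_list_rejected(self):
        with pytest.raises(ValueError):
            cumulative_profile([])

    def test_profile_estimator_converges_to_generating_law(self):
        """With known onsets the profile converges to CDF × responder
        fraction (sup-norm ≤ 0.05 at n = 500)."""
        from calgate.synthetic import SyntheticConfig, latency_cdf

        cfg = SyntheticConfig(n_traces=500, seed=21)
        rng = np.random.default_rng(21)
        responder = rng.random(500) < cfg.responder_fraction
        law, p = cfg.latency_law
        lats = p["offset"] + rng.lognormal(p["mu"], p["sigma"], 500)
        calls = [
            ResponseCall(True, int(100 + round(l * 10)), round(l * 10) / 10)
            if r
            else ResponseCall(False)
            for r, l in zip(responder, lats)
        ]
        prof = cumulative_profile(calls)
        expected = cfg.responder_fraction * latency_cdf(cfg, prof.times)
        assert np.max(np.abs(prof.curve - expected)) <= 0.05


class TestKS:
    def test_identical_profiles_give_zero_distance(self):
        a = cumulative_profile(responders([1.0, 2.0]) + nonresponders(2))
        res = ks_compare(a, a)
        assert res.D == 0.0
        assert res.p == 1.0

    def test_printed_worked_example(self):
        assert ks_pvalue(0.470, 28, 24) == pytest.approx(0.007, abs=1e-3)

    def test_tail_series_matches_reference_kolmogorov(self):
        for lam in (0.3, 0.5, 1.0, 1.5, 2.0, 3.0):
            assert kolmogorov_tail(lam) == pytest.approx(kolmogorov(lam), abs=1e-9)

    def test_symmetry_and_monotonicity_in_D(self):
        a = cumulative_profile(responders([1.0, 2.0, 3.0]))
        b = cumulative_profile(responders([4.0, 5.0, 6.0]))
        assert ks_compare(a, b).D == ks_compare(b, a).D
        ps = [ks_pvalue(d, 30, 30) for d in np.linspace(0.05, 0.9, 12)]
        assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))

    def test_disjoint_latency_sets_reach_full_distance(self):
        a = cumulative_profile(responders([1.0, 1.5]))
        b = cumulative_profile(responders([5.0, 6.0]))
        res = ks_compare(a, b)
        assert res.D == 1.0
        exact = exact_ks_permutation_p([1.0, 1.5], [5.0, 6.0])
        # the asymptotic tail is an approximation at these tiny n; it must
        # land in the neighborhood of the exact permutation p
        assert res.p == pytest.approx(exact, abs=0.1)

    def test_nonresponder_mass_contributes_to_distance(self):
        # same latencies, different response probabilities: D is the
        # probability gap, which latencies alone would miss
        a = cumulative_profile(responders([1.0] * 8) + nonresponders(2))
        b = cumulative_profile(responders([1.0] * 2) + nonresponders(8))
        assert ks_compare(a, b).D == pytest.approx(0.6)

    def test_mismatched_horizon_rejected(self):
        a = cumulative_profile(responders([1.0]), duration_s=10.0)
        b = cumulative_profile(responders([1.0]), duration_s=5.0)
        with pytest.raises(ValueError):
            ks_compare(a, b)


class TestBootstrapLag:
    def test_degenerate_distributions_give_zero_lag_and_sem(self):
        a = responders([1.0] * 5)
        res = bootstrap_lag(a, a, n_resamples=200, seed=0)
        assert res.lag_s == 0.0
        assert res.sem_s == 0.0

    def test_constant_groups_bootstrap_is_constant(self):
        up = responders([1.0] * 4)
        down = responders([3.0] * 4)
        res = bootstrap_lag(up, down, n_resamples=1000, seed=1)
        assert res.lag_s == pytest.approx(2.0)
        assert res.sem_s == 0.0
        assert res.n_failed == 0

    def test_undefined_when_half_never_responds(self):
        up = responders([1.0] * 4)
        down = responders([2.0]) + nonresponders(3)  # 25% < 50%
        res = bootstrap_lag(up, down, n_resamples=100, seed=2)
        assert res.lag_s is None
        assert res.sem_s is None

    def test_failed_resamples_counted_and_excluded(self):
        up = responders([1.0] * 4)
        down = responders([2.0, 3.0]) + nonresponders(2)  # exactly 50%
        res = bootstrap_lag(up, down, n_resamples=500, seed=3)
        assert res.lag_s is not None
        assert res.n_failed > 0
        assert len(res.lags) == res.n_resamples - res.n_failed

    def test_sem_matches_exhaustive_enumeration(self):
        """Bootstrap SD converges to the exact resampling SD (groups ≤ 5)."""
        up = [0.5, 1.0, 1.5, 2.0]
        down = [1.0, 2.0, 3.0, 4.0]
        exact = np.sqrt(
            exact_bootstrap_t50_sd(up) ** 2 + exact_bootstrap_t50_sd(down) ** 2
        )
        res = bootstrap_lag(
            responders(up), responders(down), n_resamples=20000, seed=4
        )
        assert res.sem_s == pytest.approx(exact, rel=0.02)


class TestMagnitudesAndRise:
    def test_flat_trace_has_zero_magnitude(self):
        x = np.zeros(300)
        assert magnitude_sensory(x, 100, 200) == 0.0
        assert magnitude_peak(x, 100, 200) == 0.0

    def test_step_magnitude_arithmetic(self):
        x = np.zeros(300)
        x[100:200] = 0.8
        assert magnitude_sensory(x, 100, 200) == pytest.approx(0.8)

    def test_triangular_transient_peak(self):
        x = np.zeros(300)
        x[100:150] = np.linspace(0, 1.4, 50)
        x[150:200] = np.linspace(1.4, 0, 50)
        assert magnitude_peak(x, 100, 200) == pytest.approx(1.4)

    def test_inhibitory_magnitude_is_negative(self):
        x = np.ones(300)
        x[100:] = 0.2
        assert magnitude_sensory(x, 100, 200) < 0

    def test_windows_unavailable_rejected(self):
        with pytest.raises(IndexError):
            magnitude_sensory(np.zeros(300), 5, 200)

    def test_rise_time_linear_ramp(self):
        # linear 10 s ramp: t66 − t33 = 3.3 s on the frame grid
        x = np.zeros(300)
        x[100:200] = np.linspace(0, 1, 100)
        call = ResponseCall(True, 100, 0.0)
        rt = rise_time(x, call, 100, 200)
        assert rt == pytest.approx(3.3, abs=0.11)

    def test_rise_time_instantaneous_step_is_zero(self):
        x = np.zeros(300)
        x[120:200] = 1.0
        call = ResponseCall(True, 120, 2.0)
        assert rise_time(x, call, 100, 200) == 0.0

    def test_rise_time_exponential_matches_scan_oracle(self):
        tau = 2.0
        t = np.arange(300) / 10.0
        x = np.where(t >= 10.0, 1.0 - np.exp(-(t - 10.0) / tau), 0.0)
        call = ResponseCall(True, 100, 0.0)
        peak = x[100:200].max()
        t33 = next(i for i in range(100, 300) if x[i] >= 0.33 * peak)
        t66 = next(i for i in range(100, 300) if x[i] >= 0.66 * peak)
        assert rise_time(x, call, 100, 200) == pytest.approx((t66 - t33) / 10.0)

    def test_rise_time_undefined_for_nonresponder(self):
        with pytest.raises(ValueError):
            rise_time(np.zeros(300), ResponseCall(False), 100, 200)


class TestPulsePairs:
    def test_perfectly_repeatable_responses(self):
        rows = []
        for a in range(10):
            mag = 0.5 + 0.1 * a
            for pulse in (1, 2):
                rows.append(
                    dict(animal=a, pulse=pulse, responded=True,
                         magnitude=mag, latency_s=1.0 + 0.2 * a)
                )
        out = pulse_pair_stats(pd.DataFrame(rows))
        assert out["contingency"].loc[True, True] == 10
        assert out["contingency"].to_numpy().sum() == 10
        assert out["r_magnitude"] == pytest.approx(1.0)
        assert out["r_latency"] == pytest.approx(1.0)

    def test_independent_bernoulli_counts_within_binomial_bounds(self):
        rng = np.random.default_rng(14)
        rows = []
        for a in range(200):
            for pulse in (1, 2):
                rows.append(
                    dict(animal=a, pulse=pulse,
                         responded=bool(rng.random() < 0.5))
                )
        out = pulse_pair_stats(pd.DataFrame(rows))
        table = out["contingency"].to_numpy()
        # each cell ~ Binomial(200, 0.25); 99% bounds
        lo, hi = 50 - 2.58 * np.sqrt(200 * 0.25 * 0.75), 50 + 2.58 * np.sqrt(200 * 0.25 * 0.75)
        assert np.all((table >= lo) & (table <= hi))

    def test_no_complete_pairs_rejected(self):
        df = pd.DataFrame([dict(animal=0, pulse=1, responded=True)])
        with pytest.raises(ValueError):
            pulse_pair_stats(df)
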