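import dataclasses

import numpy as np
import pytest

from _oracles import brute_force_activation, brute_force_inhibition
from calgate import (
    DetectionParams,
    SyntheticConfig,
    detect_activation,
    detect_ensemble,
    detect_inhibition,
    generate_ensemble,
    generate_null_buffer,
    threshold_sweep,
)
from calgate.preprocess import compute_dff, minmax_scale, smooth

ONSET, OFFSET = 100, 200


def noisy_trace(rng, n=300, sd=0.05):
    return rng.normal(0.0, sd, n)


class TestActivation:
    def test_flat_noiseless_trace_is_nonresponse(self):
        call = detect_activation(np.zeros(300), ONSET, OFFSET)
        assert not call.responded
        assert call.baseline_degenerate

    def test_hard_step_onset_matches_brute_force(self):
        rng = np.random.default_rng(5)
        x = noisy_trace(rng)
        x[ONSET + 30 :] += 10 * 0.05  # 10 baseline SDs
        xs = smooth(x)
        call = detect_activation(xs, ONSET, OFFSET)
        expected = brute_force_activation(xs, ONSET, OFFSET)
        assert call.responded
        assert call.onset_frame == expected
        # step at +30: detection within the smoothing/look-ahead lead
        assert ONSET + 25 <= call.onset_frame <= ONSET + 30

    def test_latency_in_seconds_uses_frame_rate(self):
        x = np.zeros(300)
        x[ONSET + 20 :] = 1.0
        call = detect_activation(smooth(x), ONSET, OFFSET, frame_rate=10.0)
        assert call.latency_s == pytest.approx((call.onset_frame - ONSET) / 10.0)

    def test_normalized_trace_input_is_smoothed_automatically(self):
        raw = np.full(300, 100.0)
        raw[ONSET + 30 :] = 200.0
        nt = compute_dff(raw, ONSET)
        call = detect_activation(nt, ONSET, OFFSET)
        assert call.responded

    def test_onset_near_trace_end_not_eligible(self):
        # response whose look-ahead window would run past the trace end
        x = np.zeros(250)
        x[245:] = 5.0
        call = detect_activation(x, ONSET, 250, DetectionParams())
        assert not call.responded

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_equivalence_random_traces(self, seed):
        """Implementation and naive per-frame evaluation agree exactly."""
        rng = np.random.default_rng(seed)
        x = noisy_trace(rng)
        if seed % 2:
            onset = ONSET + int(rng.integers(0, 80))
            x[onset:] += rng.uniform(0.05, 0.5)
        xs = smooth(x)
        call = detect_activation(xs, ONSET, OFFSET)
        expected = brute_force_activation(xs, ONSET, OFFSET)
        assert (call.onset_frame if call.responded else None) == expected


class TestInhibition:
    def test_flat_trace_is_nonresponse(self):
        # constant traces cannot be scaled; feed an already-scaled flat trace
        call = detect_inhibition(np.full(300, 0.5), ONSET, OFFSET)
        assert not call.responded

    def test_linear_decline_onset_matches_brute_force(self):
        rng = np.random.default_rng(8)
        x = 1.0 + rng.normal(0, 0.02, 300)
        decline = np.linspace(0, 1, 50)
        x[ONSET : ONSET + 50] -= decline
        x[ONSET + 50 :] -= 1.0
        s = minmax_scale(x).scaled
        call = detect_inhibition(s, ONSET, OFFSET)
        expected = brute_force_inhibition(s, ONSET, OFFSET)
        assert call.responded
        assert call.onset_frame == expected
        assert abs(call.onset_frame - ONSET) <= 3

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_equivalence_random_traces(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = 1.0 + rng.normal(0, 0.03, 300)
        if seed % 2:
            onset = ONSET + int(rng.integers(0, 60))
            x[onset:] -= rng.uniform(0.3, 1.0)
        s = minmax_scale(x).scaled
        call = detect_inhibition(s, ONSET, OFFSET)
        expected = brute_force_inhibition(s, ONSET, OFFSET)
        assert (call.onset_frame if call.responded else None) == expected


class TestMonotonicity:
    @pytest.mark.parametrize("seed", range(4))
    def test_raising_multipliers_never_adds_or_advances_responses(self, seed):
        rng = np.random.default_rng(200 + seed)
        x = noisy_trace(rng, sd=0.1)
        x[ONSET + 25 :] += 0.4
        xs = smooth(x)
        prev = detect_activation(xs, ONSET, OFFSET, DetectionParams())
        for mult in (2.5, 3.0, 4.0, 6.0):
            p = DetectionParams(act_mag_mult=mult)
            call = detect_activation(xs, ONSET, OFFSET, p)
            if call.responded:
                assert prev.responded
                assert call.onset_frame >= prev.onset_frame
            prev = call

    def test_noiseless_step_recovery(self):
        """With zero noise every responder onset is recovered within the
        smoothing + forward-difference lead (3 frames)."""
        cfg = SyntheticConfig(
            n_traces=30, responder_fraction=1.0, noise_sd=0.0,
            rise_shape=("step", {}), peak_jitter_sd=0.0, seed=1,
        )
        ens, truth = generate_ensemble(cfg)
        calls = detect_ensemble(ens)
        for call, true_onset in zip(calls, truth.onset_frame):
            if true_onset >= ens.stim_offset:
                continue
            assert call.responded
            assert true_onset - 3 <= call.onset_frame <= true_onset


@pytest.fixture(scope="module")
def null_ensemble():
    return generate_null_buffer(SyntheticConfig(n_traces=60, seed=9))


class TestThresholdSweep:
    def test_counts_monotone_in_magnitude_multiplier(self, null_ensemble):
        counts = threshold_sweep(
            null_ensemble, [0.5, 1.0, 2.0, 3.0], [1.0], "activation"
        )
        col = counts[:, 0]
        assert np.all(np.diff(col) <= 0)

    def test_responder_plateau_around_default_thresholds(self):
        cfg = SyntheticConfig(n_traces=60, responder_fraction=0.5, seed=10)
        ens, truth = generate_ensemble(cfg)
        counts = threshold_sweep(
            ens, [2.0, 2.5, 3.0], [0.5, 1.0, 1.5], "activation"
        )
        n_resp = int(truth.responder.sum())
        # counts stay near the true responder number across the band
        assert np.all(np.abs(counts - n_resp) <= 0.1 * ens.n_traces)

    def test_counts_insensitive_to_derivative_multiplier_at_default_magnitude(self):
        cfg = SyntheticConfig(n_traces=60, responder_fraction=0.5, seed=11)
        ens, _ = generate_ensemble(cfg)
        counts = threshold_sweep(ens, [2.0], [0.0, 0.25, 0.5, 0.75, 1.0], "activation")
        assert counts.max() - counts.min() <= 2

    def test_inhibition_sweep_monotone(self):
        cfg = SyntheticConfig(
            n_traces=40, responder_fraction=0.5, polarity="inhibition", seed=12
        )
        ens, _ = generate_ensemble(cfg)
        counts = threshold_sweep(ens, [1.0, 2.0, 3.0], [0.25, 0.5, 1.0], "inhibition")
        assert np.all(np.diff(counts, axis=0) <= 0)
        assert np.all(np.diff(counts, axis=1) <= 0)

    def test_empty_grid_rejected(self, null_ensemble):
        with pytest.raises(ValueError):
            threshold_sweep(null_ensemble, [], [1.0], "activation")


class TestEnsembleDetection:
    def test_excluded_traces_skipped(self, small_ensemble):
        traces = small_ensemble.traces.copy()
        traces[1, 0] = np.nan
        ens = dataclasses.replace(small_ensemble, traces=traces, excluded=None)
        calls = detect_ensemble(ens)
        assert calls[1] is None
        assert calls[0].responded and calls[2].responded
        assert not calls[3].responded
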