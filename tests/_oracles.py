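"""Independent brute-force oracles used to validate the library.

These re-state the detection criteria and small statistics naively (frame
by frame, explicit loops, no shared code with the package) so tests can
compare the optimized implementations against a transparently correct
evaluation.
"""

from __future__ import annotations

from collections import Counter
from itertools import combinations_with_replacement
from math import ceil, factorial, prod

import numpy as np


def brute_force_activation(
    x,
    stim_onset,
    stim_offset,
    prestim=100,
    mag_window=12,
    mag_mult=2.0,
    deriv_mult=1.0,
):
    """Naive per-frame evaluation of the activation rule; onset frame or None."""
    x = list(map(float, x))
    base = x[stim_onset - prestim : stim_onset]
    mu = sum(base) / len(base)
    sd = (sum((v - mu) ** 2 for v in base) / (len(base) - 1)) ** 0.5
    diffs = [x[i + 1] - x[i] for i in range(len(x) - 1)]
    dbase = diffs[stim_onset - prestim : stim_onset - 1]
    dmu = sum(dbase) / len(dbase)
    dsd = (sum((v - dmu) ** 2 for v in dbase) / (len(dbase) - 1)) ** 0.5
    for t in range(stim_onset, stim_offset):
        if t + mag_window > len(x) - 1:
            break
        window = x[t : t + mag_window + 1]
        if sum(window) / len(window) > mu + mag_mult * sd and diffs[t] > dmu + deriv_mult * dsd:
            return t
    return None


def brute_force_inhibition(
    s,
    stim_onset,
    stim_offset,
    prestim=100,
    mag_window=10,
    mag_mult=2.0,
    long_mult=0.5,
    short_window=5,
    short_mult=1.15,
):
    """Naive per-frame evaluation of the inhibition rule on a scaled trace."""
    s = list(map(float, s))
    base = s[stim_onset - prestim : stim_onset]
    mu = sum(base) / len(base)
    sd = (sum((v - mu) ** 2 for v in base) / (len(base) - 1)) ** 0.5
    diffs = [s[i + 1] - s[i] for i in range(len(s) - 1)]
    dbase = diffs[stim_onset - prestim : stim_onset - 1]
    dmu = sum(dbase) / len(dbase)
    dsd = (sum((v - dmu) ** 2 for v in dbase) / (len(dbase) - 1)) ** 0.5
    for t in range(stim_onset, stim_offset):
        if t + max(mag_window, short_window) > len(s) - 1:
            break
        window = s[t : t + mag_window + 1]
        if not sum(window) / len(window) < mu - mag_mult * sd:
            continue
        d_long = (s[t + mag_window] - s[t]) / mag_window
        d_short = (s[t + short_window] - s[t]) / short_window
        if d_long < dmu - long_mult * dsd or d_short < dmu - short_mult * dsd:
            return t
    return None


def time_to_half_naive(latencies, n_total, frame_rate=10.0):
    """First frame time at which >= half of n_total trials responded."""
    lats = sorted(latencies)
    for k, t in enumerate(lats, start=1):
        if k >= 0.5 * n_total:
            return ceil(t * frame_rate - 1e-9) / frame_rate
    return None


def exact_bootstrap_t50_sd(latencies, frame_rate=10.0):
    """Exact SD of the 50%-response time over all with-replacement resamples.

    Enumerates the C(2n−1, n) distinct resample multisets of a group of n
    all-responding trials with their multinomial probabilities.
    """
    n = len(latencies)
    vals, weights = [], []
    for combo in combinations_with_replacement(range(n), n):
        counts = Counter(combo)
        w = factorial(n) / prod(factorial(c) for c in counts.values()) / n**n
        vals.append(time_to_half_naive([latencies[i] for i in combo], n, frame_rate))
        weights.append(w)
    vals = np.array(vals, dtype=float)
    weights = np.array(weights)
    mean = float((vals * weights).sum())
    return float(np.sqrt((weights * (vals - mean) ** 2).sum()))


def exact_ks_permutation_p(a, b):
    """Exact permutation p-value of the two-sample KS statistic (tiny n)."""
    from itertools import combinations

    a, b = list(a), list(b)
    pooled = a + b
    n1, n2 = len(a), len(b)

    def ks_stat(xs, ys):
        grid = sorted(set(xs + ys))
        return max(
            abs(
                sum(x <= g for x in xs) / n1 - sum(y <= g for y in ys) / n2
            )
            for g in grid
        )

    observed = ks_stat(a, b)
    count = total = 0
    for idx in combinations(range(n1 + n2), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n1 + n2) if i not in idx]
        total += 1
        if ks_stat(xs, ys) >= observed - 1e-12:
            count += 1
    return count / total
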