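"""Population statistics on response calls.

Cumulative response-time profiles summarize an ensemble of single-trial
calls as the fraction of *all* trials (responders and non-responders) that
have responded by time t after stimulus onset; the asymptote of the curve
is the response probability.  Two profiles are compared with a two-sample
Kolmogorov–Smirnov statistic on these fraction-of-trials curves, so the
test is sensitive to differences in latency and in response probability at
once.  Non-responding trials count in the denominator but never contribute
a latency (right-censored mass at the horizon).

The KS p-value is the asymptotic Kolmogorov tail
``Q(λ) = 2 Σ_{k≥1} (−1)^{k−1} exp(−2 k² λ²)`` evaluated at
``λ = √(n₁n₂/(n₁+n₂)) · D``, with the series truncated once terms fall
below 1e−12.

The lag between an upstream and a downstream neuron population is the
difference of their 50%-response times (first frame at which at least half
of all trials have responded, no interpolation), with a standard error
taken as the SD of the lag over bootstrap resamples of whole trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import NormalizedTrace
from .response_detect import ResponseCall

__all__ = [
    "CumulativeProfile",
    "KSResult",
    "BootstrapLag",
    "cumulative_profile",
    "ks_compare",
    "ks_pvalue",
    "kolmogorov_tail",
    "bootstrap_lag",
    "magnitude_sensory",
    "magnitude_peak",
    "rise_time",
    "pulse_pair_stats",
]


@dataclass
class CumulativeProfile:
    """Fraction of all trials responded as a function of time since onset."""

    latencies_s: np.ndarray
    n_total: int
    duration_s: float = 10.0
    frame_rate: float = 10.0

    def __post_init__(self) -> None:
        self.latencies_s = np.sort(np.asarray(self.latencies_s, dtype=float))
        if self.n_total < 1:
            raise ValueError("profile needs at least one trial")
        if self.latencies_s.size > self.n_total:
            raise ValueError("more latencies than trials")
        if self.latencies_s.size and self.latencies_s[0] < 0:
            raise ValueError("latencies must be non-negative")

    @property
    def times(self) -> np.ndarray:
        """Frame-grid evaluation times, 0 … duration inclusive."""
        n = int(round(self.duration_s * self.frame_rate))
        return np.arange(n + 1) / self.frame_rate

    @property
    def curve(self) -> np.ndarray:
        """Cumulative responded fraction evaluated on :attr:`times`."""
        return (
            np.searchsorted(self.latencies_s, self.times, side="right")
            / self.n_total
        )

    @property
    def response_fraction(self) -> float:
        return float(
            np.sum(self.latencies_s <= self.duration_s) / self.n_total
        )

    def time_to_fraction(self, frac: float = 0.5) -> float | None:
        """First grid time at which the curve reaches ``frac``; None if never."""
        hit = np.flatnonzero(self.curve >= frac)
        return float(self.times[hit[0]]) if hit.size else None


@dataclass
class KSResult:
    D: float
    p: float
    n1: int
    n2: int


@dataclass
class BootstrapLag:
    """50%-response-time difference (downstream − upstream) and its SE."""

    lag_s: float | None
    sem_s: float | None
    n_resamples: int
    seed: int
    n_failed: int = 0
    lags: np.ndarray | None = field(default=None, repr=False)


def cumulative_profile(
    calls: list[ResponseCall],
    duration_s: float = 10.0,
    frame_rate: float = 10.0,
) -> CumulativeProfile:
    """Build a cumulative response-time profile from per-trace calls.

    Excluded traces should be filtered out beforehand (pass the calls that
    correspond to analyzed trials); non-responders enter ``n_total`` only.
    """
    calls = [c for c in calls if c is not None]
    if not calls:
        raise ValueError("cannot build a profile from an empty call list")
    lats = [
        c.latency_s
        for c in calls
        if c.responded and c.latency_s is not None and c.latency_s <= duration_s
    ]
    return CumulativeProfile(
        latencies_s=np.array(lats),
        n_total=len(calls),
        duration_s=duration_s,
        frame_rate=frame_rate,
    )


def kolmogorov_tail(lam: float, tol: float = 1e-12, max_terms: int = 100_000) -> float:
    """Kolmogorov distribution tail Q(λ) = 2 Σ (−1)^{k−1} e^{−2k²λ²}."""
    if lam <= 0:
        return 1.0
    total = 0.0
    for k in range(1, max_terms + 1):
        term = np.exp(-2.0 * k * k * lam * lam)
        total += term if k % 2 else -term
        if term < tol:
            break
    return float(min(1.0, max(0.0, 2.0 * total)))


def ks_pvalue(d: float, n1: int, n2: int) -> float:
    """Asymptotic two-sample KS p-value at statistic ``d``."""
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    n_e = n1 * n2 / (n1 + n2)
    return kolmogorov_tail(np.sqrt(n_e) * d)


def ks_compare(a: CumulativeProfile, b: CumulativeProfile) -> KSResult:
    """Two-sample KS comparison of two cumulative response-time profiles.

    D is the maximum absolute gap between the fraction-of-all-trials curves
    on the shared frame grid over [0, duration]; n₁, n₂ are total trial
    counts (responders + non-responders).
    """
    if a.duration_s != b.duration_s or a.frame_rate != b.frame_rate:
        raise ValueError("profiles must share duration and frame rate")
    d = float(np.max(np.abs(a.curve - b.curve)))
    return KSResult(D=d, p=ks_pvalue(d, a.n_total, b.n_total), n1=a.n_total, n2=b.n_total)


def _time_to_half(
    latencies: np.ndarray, n_total: int, duration_s: float, frame_rate: float
) -> float | None:
    """First frame time at which >= 50% of trials have responded."""
    if latencies.size * 2 < n_total:
        return None
    need = 0.5 * n_total
    lats = np.sort(latencies)
    # responder count first reaches `need` at the ceil(need)-th latency,
    # rounded up to the frame grid
    k = int(np.ceil(need)) if need % 1 else int(need)
    t = lats[k - 1]
    t_grid = np.ceil(t * frame_rate - 1e-9) / frame_rate
    return float(t_grid) if t_grid <= duration_s else None


def bootstrap_lag(
    upstream: list[ResponseCall],
    downstream: list[ResponseCall],
    n_resamples: int = 1000,
    seed: int = 0,
    duration_s: float = 10.0,
    frame_rate: float = 10.0,
) -> BootstrapLag:
    """Bootstrap the 50%-response-time lag between two populations.

    The point estimate subtracts the time at which 50% of upstream trials
    have responded from the same time for the downstream trials.  Whole
    trials (responders and non-responders alike) are resampled with
    replacement, ``n_resamples`` times, recomputing both 50% times;
    resamples in which either group never reaches 50% are counted in
    ``n_failed`` and excluded from the SD.
    """
    ups = [c for c in upstream if c is not None]
    downs = [c for c in downstream if c is not None]
    if not ups or not downs:
        raise ValueError("both populations must be nonempty")

    def lat_array(calls: list[ResponseCall]) -> np.ndarray:
        return np.array(
            [
                c.latency_s if (c.responded and c.latency_s is not None and c.latency_s <= duration_s) else np.nan
                for c in calls
            ]
        )

    lu, ld = lat_array(ups), lat_array(downs)

    def t50(lat: np.ndarray) -> float | None:
        return _time_to_half(
            lat[~np.isnan(lat)], lat.size, duration_s, frame_rate
        )

    tu, td = t50(lu), t50(ld)
    if tu is None or td is None:
        return BootstrapLag(
            lag_s=None, sem_s=None, n_resamples=n_resamples, seed=seed
        )
    rng = np.random.default_rng(seed)
    lags = []
    n_failed = 0
    for _ in range(n_resamples):
        ru = lu[rng.integers(0, lu.size, lu.size)]
        rd = ld[rng.integers(0, ld.size, ld.size)]
        ttu, ttd = t50(ru), t50(rd)
        if ttu is None or ttd is None:
            n_failed += 1
            continue
        lags.append(ttd - ttu)
    lags = np.array(lags)
    sem = float(np.std(lags, ddof=1)) if lags.size > 1 else 0.0
    return BootstrapLag(
        lag_s=float(td - tu),
        sem_s=sem,
        n_resamples=n_resamples,
        seed=seed,
        n_failed=n_failed,
        lags=lags,
    )


def _dff(trace: NormalizedTrace | np.ndarray) -> np.ndarray:
    return trace.dff if isinstance(trace, NormalizedTrace) else np.asarray(trace, float)


def magnitude_sensory(
    trace: NormalizedTrace | np.ndarray, stim_onset: int, stim_offset: int
) -> float:
    """Late-pulse minus immediate-pre-stimulus mean ΔF/F₀ (sign free).

    Mean of the final 10 in-pulse frames minus the mean of the 10 frames
    immediately before stimulus onset; negative for inhibitory responses.
    """
    x = _dff(trace)
    if stim_onset < 10 or stim_offset - stim_onset < 10 or stim_offset > x.size:
        raise IndexError("need 10 frames before onset and 10 inside the pulse")
    return float(
        x[stim_offset - 10 : stim_offset].mean() - x[stim_onset - 10 : stim_onset].mean()
    )


def magnitude_peak(
    trace: NormalizedTrace | np.ndarray, stim_onset: int, stim_offset: int
) -> float:
    """Maximum ΔF/F₀ within the stimulus pulse (adaptation-robust)."""
    x = _dff(trace)
    if stim_offset > x.size:
        raise IndexError("stimulus window exceeds trace")
    return float(x[stim_onset:stim_offset].max())


def rise_time(
    trace: NormalizedTrace | np.ndarray,
    call: ResponseCall,
    stim_onset: int,
    stim_offset: int,
    frame_rate: float = 10.0,
) -> float:
    """33%→66%-of-peak rise time of a responding trace, in seconds.

    The peak is the maximum ΔF/F₀ within the pulse; the crossing times are
    the first frames at or after the detected onset reaching 33% and 66% of
    that peak.
    """
    if not call.responded or call.onset_frame is None:
        raise ValueError("rise time is undefined for non-responders")
    x = _dff(trace)
    peak = float(x[stim_onset:stim_offset].max())
    if peak <= 0:
        raise ValueError("rise time requires a positive peak magnitude")
    start = call.onset_frame

    def first_crossing(frac: float) -> int:
        idx = np.flatnonzero(x[start:] >= frac * peak)
        if idx.size == 0:
            raise ValueError(f"trace never reaches {frac:.0%} of peak after onset")
        return start + int(idx[0])

    t33 = first_crossing(0.33)
    t66 = first_crossing(0.66)
    return (t66 - t33) / frame_rate


def pulse_pair_stats(calls_df: pd.DataFrame) -> dict:
    """Contingency and correlation structure of paired stimulus pulses.

    ``calls_df`` needs columns ``animal, pulse, responded`` and optionally
    ``magnitude`` and ``latency_s``.  Animals with exactly one pulse-1 and
    one pulse-2 trial are analyzed.  Returns the 2×2 contingency of
    (pulse-1 responded) × (pulse-2 responded) and, among double responders,
    Pearson correlations of magnitudes and latencies.
    """
    pairs = []
    for animal, grp in calls_df.groupby("animal"):
        p1 = grp[grp["pulse"] == 1]
        p2 = grp[grp["pulse"] == 2]
        if len(p1) == 1 and len(p2) == 1:
            pairs.append((p1.iloc[0], p2.iloc[0]))
    if not pairs:
        raise ValueError("no animals with a complete pulse pair")
    table = np.zeros((2, 2), dtype=int)
    mags, lats = [], []
    for a, b in pairs:
        r1, r2 = bool(a["responded"]), bool(b["responded"])
        table[int(r1), int(r2)] += 1
        if r1 and r2:
            if "magnitude" in a and pd.notna(a.get("magnitude")) and pd.notna(b.get("magnitude")):
                mags.append((a["magnitude"], b["magnitude"]))
            if "latency_s" in a and pd.notna(a.get("latency_s")) and pd.notna(b.get("latency_s")):
                lats.append((a["latency_s"], b["latency_s"]))

    def corr(xy: list[tuple[float, float]]) -> float | None:
        if len(xy) < 2:
            return None
        arr = np.array(xy, dtype=float)
        if arr[:, 0].std() == 0 or arr[:, 1].std() == 0:
            return None
        return float(np.corrcoef(arr[:, 0], arr[:, 1])[0, 1])

    contingency = pd.DataFrame(
        table,
        index=pd.Index([False, True], name="pulse1_responded"),
        columns=pd.Index([False, True], name="pulse2_responded"),
    )
    return {
        "n_pairs": len(pairs),
        "contingency": contingency,
        "r_magnitude": corr(mags),
        "r_latency": corr(lats),
    }
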