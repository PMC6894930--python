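"""Response calling on normalized calcium traces.

Two dual-threshold rules operate on the pre-stimulus baseline statistics of
each trace:

* **Activation** (AWA/AIA/ASE/ASH-style): a trace responds at the first
  frame t inside the stimulus window where (i) the mean smoothed ΔF/F₀ over
  frames t … t+12 exceeds the baseline mean by 2 baseline SDs, and (ii) the
  forward-difference derivative at t exceeds the baseline derivative mean by
  1 baseline-derivative SD.

* **Inhibition** (ASK/AWC-style): the trace is first min–max scaled; it
  responds at the first frame t where (i) the mean scaled value over
  t … t+10 falls 2 SDs below the baseline mean, and (ii) the mean derivative
  over t … t+10 falls 0.5 SDs below the baseline derivative mean, or the
  mean derivative over t … t+5 falls 1.15 SDs below it.

All inequalities are strict; a frame whose look-ahead window would run past
the end of the trace is not an eligible onset.  The window means may extend
past the stimulus offset (the rules look forward), just not past the trace.

``threshold_sweep`` reproduces the diagnostic used to justify the default
multipliers: response counts across a grid of (magnitude SD multiple,
derivative SD multiple) pairs, in which the chosen thresholds sit at an
inflection between admitting baseline noise and discarding true responses.

The mean derivative over frames t … t+w is the mean of the forward
differences in that span, i.e. ``(x[t+w] − x[t]) / w``.  Baseline derivative
statistics use the differences lying entirely inside the baseline window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .preprocess import (
    NormalizedTrace,
    ScaledTrace,
    compute_dff,
    minmax_scale,
    smooth_trace,
)
from .trace_io import TraceEnsemble

__all__ = [
    "DetectionParams",
    "ResponseCall",
    "detect_activation",
    "detect_inhibition",
    "detect_ensemble",
    "threshold_sweep",
]


@dataclass
class DetectionParams:
    """Thresholds and windows of the dual-criterion response rules.

    Window lengths are in frames at the acquisition rate; multipliers are
    SD multiples applied to the pre-stimulus baseline statistics.
    ``act_deriv_mult`` defaults to 1 (the operative rule); the threshold
    justification discusses a value of 2, so it is a parameter rather than
    a constant.
    """

    prestim_window: int = 100
    act_window: int = 12
    act_mag_mult: float = 2.0
    act_deriv_mult: float = 1.0
    inh_window: int = 10
    inh_mag_mult: float = 2.0
    inh_deriv_long_mult: float = 0.5
    inh_deriv_short_window: int = 5
    inh_deriv_short_mult: float = 1.15
    #: half-open frame range searched for onsets; None = stimulus window
    search_window: tuple[int, int] | None = None
    #: ddof for baseline SDs (1 = sample SD)
    ddof: int = 1

    def __post_init__(self) -> None:
        for name in ("prestim_window", "act_window", "inh_window", "inh_deriv_short_window"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in (
            "act_mag_mult",
            "act_deriv_mult",
            "inh_mag_mult",
            "inh_deriv_long_mult",
            "inh_deriv_short_mult",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ResponseCall:
    """Per-trace detection outcome."""

    responded: bool
    onset_frame: int | None = None
    latency_s: float | None = None
    magnitude: float | None = None
    rise_time_s: float | None = None
    #: True when the baseline SD was exactly zero (thresholds degenerate to
    #: strict exceedance of the baseline mean)
    baseline_degenerate: bool = False

    def __post_init__(self) -> None:
        if self.responded != (self.onset_frame is not None):
            raise ValueError("responded flag must match presence of onset_frame")
        if self.latency_s is not None and self.latency_s < 0:
            raise ValueError("latency cannot be negative")


def _baseline_stats(
    x: np.ndarray, stim_onset: int, prestim: int, ddof: int
) -> tuple[float, float, float, float]:
    """Mean/SD of baseline values and of baseline forward differences."""
    if stim_onset - prestim < 0:
        raise IndexError(f"need {prestim} baseline frames before {stim_onset}")
    base = x[stim_onset - prestim : stim_onset]
    d = np.diff(x)
    # differences with both endpoints inside the baseline window
    dbase = d[stim_onset - prestim : stim_onset - 1]
    sd = float(np.std(base, ddof=ddof)) if base.size > ddof else 0.0
    dsd = float(np.std(dbase, ddof=ddof)) if dbase.size > ddof else 0.0
    return float(base.mean()), sd, float(dbase.mean()), dsd


def _resolve_search(
    params: DetectionParams, stim_onset: int, stim_offset: int
) -> tuple[int, int]:
    if params.search_window is not None:
        return params.search_window
    return stim_onset, stim_offset


def detect_activation(
    trace: NormalizedTrace | np.ndarray,
    stim_onset: int,
    stim_offset: int,
    params: DetectionParams | None = None,
    frame_rate: float = 10.0,
) -> ResponseCall:
    """Call an activation response on a smoothed ΔF/F₀ trace.

    ``trace`` may be a :class:`NormalizedTrace` (smoothed if its flag says
    so, otherwise smoothed here) or a bare array assumed already smoothed.
    """
    params = params or DetectionParams()
    if isinstance(trace, NormalizedTrace):
        if not trace.smoothed:
            trace = smooth_trace(trace)
        x = trace.dff
    else:
        x = np.asarray(trace, dtype=float)
    mu, sd, dmu, dsd = _baseline_stats(x, stim_onset, params.prestim_window, params.ddof)
    d = np.diff(x)
    w = params.act_window
    lo, hi = _resolve_search(params, stim_onset, stim_offset)
    hi = min(hi, x.size - w)  # look-ahead must stay inside the trace
    mag_thr = mu + params.act_mag_mult * sd
    der_thr = dmu + params.act_deriv_mult * dsd
    for t in range(lo, hi):
        if x[t : t + w + 1].mean() > mag_thr and d[t] > der_thr:
            return ResponseCall(
                responded=True,
                onset_frame=t,
                latency_s=(t - stim_onset) / frame_rate,
                baseline_degenerate=(sd == 0.0),
            )
    return ResponseCall(responded=False, baseline_degenerate=(sd == 0.0))


def detect_inhibition(
    trace: ScaledTrace | np.ndarray,
    stim_onset: int,
    stim_offset: int,
    params: DetectionParams | None = None,
    frame_rate: float = 10.0,
) -> ResponseCall:
    """Call an inhibition response on a min–max-scaled trace.

    Baseline statistics are computed on the scaled trace's pre-stimulus
    frames.  The magnitude criterion uses the ``inh_window``-frame forward
    mean; the timing criterion is a disjunction of a long-window and a
    short-window derivative test.
    """
    params = params or DetectionParams()
    x = trace.scaled if isinstance(trace, ScaledTrace) else np.asarray(trace, dtype=float)
    mu, sd, dmu, dsd = _baseline_stats(x, stim_onset, params.prestim_window, params.ddof)
    w = params.inh_window
    ws = params.inh_deriv_short_window
    lo, hi = _resolve_search(params, stim_onset, stim_offset)
    hi = min(hi, x.size - max(w, ws))
    mag_thr = mu - params.inh_mag_mult * sd
    long_thr = dmu - params.inh_deriv_long_mult * dsd
    short_thr = dmu - params.inh_deriv_short_mult * dsd
    for t in range(lo, hi):
        if x[t : t + w + 1].mean() >= mag_thr:
            continue
        d_long = (x[t + w] - x[t]) / w
        d_short = (x[t + ws] - x[t]) / ws
        if d_long < long_thr or d_short < short_thr:
            return ResponseCall(
                responded=True,
                onset_frame=t,
                latency_s=(t - stim_onset) / frame_rate,
                baseline_degenerate=(sd == 0.0),
            )
    return ResponseCall(responded=False, baseline_degenerate=(sd == 0.0))


def _prepared_traces(
    ensemble: TraceEnsemble, polarity: str, params: DetectionParams
) -> list[np.ndarray | None]:
    """Smoothed ΔF/F₀ (activation) or scaled smoothed ΔF/F₀ (inhibition)
    per trace; ``None`` for excluded rows."""
    out: list[np.ndarray | None] = []
    for i in range(ensemble.n_traces):
        if ensemble.excluded[i]:
            out.append(None)
            continue
        nt = smooth_trace(
            compute_dff(
                ensemble.traces[i], ensemble.stim_onset, params.prestim_window
            )
        )
        if polarity == "activation":
            out.append(nt.dff)
        elif polarity == "inhibition":
            out.append(minmax_scale(nt.dff).scaled)
        else:
            raise ValueError(f"unknown polarity {polarity!r}")
    return out


def detect_ensemble(
    ensemble: TraceEnsemble,
    polarity: str = "activation",
    params: DetectionParams | None = None,
) -> list[ResponseCall | None]:
    """Run the full preprocessing + detection chain on every trace.

    Returns one :class:`ResponseCall` per trace, ``None`` for excluded rows.
    Activation traces are ΔF/F₀-normalized then smoothed; inhibition traces
    are additionally min–max scaled.
    """
    params = params or DetectionParams()
    detect = detect_activation if polarity == "activation" else detect_inhibition
    calls: list[ResponseCall | None] = []
    for x in _prepared_traces(ensemble, polarity, params):
        if x is None:
            calls.append(None)
            continue
        calls.append(
            detect(
                x,
                ensemble.stim_onset,
                ensemble.stim_offset,
                params,
                ensemble.frame_rate,
            )
        )
    return calls


def threshold_sweep(
    ensemble: TraceEnsemble,
    mag_mult_grid: list[float],
    deriv_mult_grid: list[float],
    polarity: str = "activation",
    params: DetectionParams | None = None,
) -> np.ndarray:
    """Response counts over a grid of threshold multipliers.

    Returns a matrix of shape ``(len(mag_mult_grid), len(deriv_mult_grid))``
    whose (i, j) entry is the number of traces called responses with the
    magnitude multiplier ``mag_mult_grid[i]`` and derivative multiplier
    ``deriv_mult_grid[j]``.  For inhibition the grid value replaces the
    long-window derivative multiplier and the short-window disjunct is
    disabled, so counts are monotone in both grid axes.
    """
    if not mag_mult_grid or not deriv_mult_grid:
        raise ValueError("multiplier grids must be nonempty")
    params = params or DetectionParams()
    prepared = _prepared_traces(ensemble, polarity, params)
    counts = np.zeros((len(mag_mult_grid), len(deriv_mult_grid)), dtype=int)
    for i, m in enumerate(mag_mult_grid):
        for j, dm in enumerate(deriv_mult_grid):
            if polarity == "activation":
                p = replace(params, act_mag_mult=m, act_deriv_mult=dm)
                detect = detect_activation
            else:
                p = replace(
                    params,
                    inh_mag_mult=m,
                    inh_deriv_long_mult=dm,
                    inh_deriv_short_mult=np.inf,
                )
                detect = detect_inhibition
            n = 0
            for x in prepared:
                if x is None:
                    continue
                if detect(
                    x, ensemble.stim_onset, ensemble.stim_offset, p,
                    ensemble.frame_rate,
                ).responded:
                    n += 1
            counts[i, j] = n
    return counts
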