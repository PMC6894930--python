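"""Trace preprocessing: ΔF/F₀ normalization, smoothing, scaling, bleach fit.

The detection statistics operate on derived forms of the raw fluorescence:

* ``compute_dff`` — ΔF/F₀ with F₀ the *median* of the pre-stimulus baseline
  (100 frames = 10 s at 10 fps by default);
* ``smooth`` — 5-point centered running mean (frame t = mean of t−2 … t+2);
* ``minmax_scale`` — affine rescale to [0, 1], used before inhibition
  calling so downward transitions are comparable across cells;
* ``bleach_correct`` — divide out a least-squares line fitted to the
  non-stimulus epochs, for recordings dominated by photobleaching drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NormalizedTrace",
    "ScaledTrace",
    "DegenerateBaselineError",
    "DegenerateScaleError",
    "DegenerateFitError",
    "compute_dff",
    "smooth",
    "smooth_trace",
    "minmax_scale",
    "bleach_correct",
]


class DegenerateBaselineError(Exception):
    """Baseline F₀ is zero; ΔF/F₀ is undefined."""


class DegenerateScaleError(Exception):
    """Trace is constant over the scaling window; min–max scale undefined."""


class DegenerateFitError(Exception):
    """Fitted bleach line is non-positive somewhere; division undefined."""


@dataclass
class NormalizedTrace:
    """A ΔF/F₀ trace plus the baseline it was normalized against."""

    dff: np.ndarray
    f0: float
    smoothed: bool = False
    prestim_window: int = 100


@dataclass
class ScaledTrace:
    """A min–max-scaled trace (values span [0, 1] over ``scale_window``)."""

    scaled: np.ndarray
    scale_window: tuple[int, int]


def compute_dff(
    raw: np.ndarray, stim_onset: int, prestim_window: int = 100
) -> NormalizedTrace:
    """Normalize a raw trace to ΔF/F₀.

    F₀ is the median of the ``prestim_window`` frames immediately before
    ``stim_onset``; ``dff[t] = (raw[t] − F₀) / F₀``.
    """
    raw = np.asarray(raw, dtype=float)
    if prestim_window < 1 or stim_onset - prestim_window < 0:
        raise IndexError(
            f"need {prestim_window} baseline frames before frame {stim_onset}"
        )
    f0 = float(np.median(raw[stim_onset - prestim_window : stim_onset]))
    if f0 == 0:
        raise DegenerateBaselineError("baseline median F0 is zero")
    return NormalizedTrace(
        dff=(raw - f0) / f0,
        f0=f0,
        smoothed=False,
        prestim_window=prestim_window,
    )


def smooth(x: np.ndarray) -> np.ndarray:
    """5-point centered running mean; truncated window at the edges.

    Interior frame t becomes the mean of frames t−2 … t+2.  Within two
    frames of either end the mean runs over the frames that exist, so the
    output has the same length as the input and a constant trace is a
    fixed point.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:  # convolve "same" would widen very short inputs
        return np.array(
            [x[max(0, t - 2) : t + 3].mean() for t in range(x.size)]
        )
    kernel = np.ones(5)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / counts


def smooth_trace(trace: NormalizedTrace) -> NormalizedTrace:
    """Return a smoothed copy of a :class:`NormalizedTrace`."""
    return NormalizedTrace(
        dff=smooth(trace.dff),
        f0=trace.f0,
        smoothed=True,
        prestim_window=trace.prestim_window,
    )


def minmax_scale(
    x: np.ndarray, scale_window: tuple[int, int] | None = None
) -> ScaledTrace:
    """Affinely rescale so min = 0 and max = 1 over ``scale_window``.

    ``scale_window`` is a half-open frame range; the default is the full
    trace.  Raises :class:`DegenerateScaleError` on a constant window.
    """
    x = np.asarray(x, dtype=float)
    if scale_window is None:
        scale_window = (0, x.size)
    lo, hi = scale_window
    seg = x[lo:hi]
    if seg.size == 0:
        raise DegenerateScaleError("empty scaling window")
    mn, mx = float(seg.min()), float(seg.max())
    if mx == mn:
        raise DegenerateScaleError("trace is constant over the scaling window")
    return ScaledTrace(scaled=(x - mn) / (mx - mn), scale_window=(lo, hi))


def bleach_correct(
    x: np.ndarray, stim_windows: list[tuple[int, int]]
) -> np.ndarray:
    """Remove linear photobleaching drift by dividing out a fitted line.

    A least-squares line L is fitted to all frames outside the (half-open)
    ``stim_windows``; the corrected trace is ``(x − L) / L``, i.e. the
    fluorescence change relative to the bleaching baseline.
    """
    x = np.asarray(x, dtype=float)
    t = np.arange(x.size)
    mask = np.ones(x.size, dtype=bool)
    for lo, hi in stim_windows:
        mask[lo:hi] = False
    if mask.sum() < 2:
        raise DegenerateFitError("need at least 2 non-stimulus frames")
    slope, intercept = np.polyfit(t[mask], x[mask], 1)
    line = slope * t + intercept
    if np.any(line <= 0):
        raise DegenerateFitError("fitted bleach line is non-positive")
    return (x - line) / line
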