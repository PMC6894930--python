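"""Trace-ensemble data model and plain-text readers/writers.

A :class:`TraceEnsemble` bundles the raw fluorescence traces recorded around a
set of stimulus pulses (one row per pulse) with the acquisition metadata the
downstream analysis needs: frame rate, the stimulus window, and per-trace
labels (neuron, condition, animal, pulse index, experimental block).

On disk an ensemble is a pair of files:

* ``<stem>.csv`` — the trace matrix, rows = pulses, columns = frames, plain
  decimal numbers, no header;
* ``<stem>.meta.yaml`` — a YAML sidecar with ``frame_rate``, ``stim_onset``,
  ``stim_offset``, ``n_frames`` and a ``rows`` table carrying the per-trace
  labels and exclusion flags.

Traces containing non-finite values (NaN insertions from upstream tracking)
are flagged ``excluded`` and skipped by the analysis, but are never dropped
from the file or renumbered.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TraceEnsemble",
    "EnsembleFormatError",
    "EnsembleConsistencyError",
    "EnsembleBoundsError",
    "read_ensemble",
    "write_ensemble",
]

#: per-trace metadata columns, in canonical order
META_COLUMNS = ["neuron", "condition", "animal", "pulse", "block"]


class EnsembleFormatError(Exception):
    """The on-disk files are missing or not in the expected format."""


class EnsembleConsistencyError(Exception):
    """Trace matrix and sidecar metadata disagree."""


class EnsembleBoundsError(Exception):
    """Stimulus window or baseline window does not fit inside the traces."""


@dataclass
class TraceEnsemble:
    """A set of per-pulse fluorescence traces plus acquisition metadata.

    Parameters
    ----------
    traces
        Raw fluorescence, shape ``(n_traces, n_frames)``, arbitrary units.
    frame_rate
        Acquisition rate in frames per second (default 10, the standard
        100 ms exposure duty cycle).
    stim_onset, stim_offset
        Frame indices delimiting the stimulus window, 0-based, half-open
        ``[stim_onset, stim_offset)``.
    meta
        DataFrame with one row per trace and columns ``neuron, condition,
        animal, pulse, block``.
    excluded
        Boolean flags, one per trace.  Traces containing non-finite values
        are always flagged in addition to any caller-supplied flags.
    """

    traces: np.ndarray
    stim_onset: int
    stim_offset: int
    frame_rate: float = 10.0
    meta: pd.DataFrame | None = None
    excluded: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2:
            raise EnsembleFormatError(
                f"trace matrix must be 2-D, got shape {self.traces.shape}"
            )
        n = self.traces.shape[0]
        if self.frame_rate <= 0:
            raise EnsembleConsistencyError("frame_rate must be positive")
        if not (0 <= self.stim_onset < self.stim_offset):
            raise EnsembleBoundsError(
                f"need 0 <= stim_onset < stim_offset, got "
                f"[{self.stim_onset}, {self.stim_offset})"
            )
        if n > 0 and self.stim_offset > self.n_frames:
            raise EnsembleBoundsError(
                f"stim_offset {self.stim_offset} exceeds trace length "
                f"{self.n_frames}"
            )
        if self.meta is None:
            self.meta = pd.DataFrame(
                {
                    "neuron": ["unknown"] * n,
                    "condition": ["unknown"] * n,
                    "animal": [i // 2 for i in range(n)],
                    "pulse": [i % 2 + 1 for i in range(n)],
                    "block": [0] * n,
                }
            )
        self.meta = self.meta.reset_index(drop=True)
        if list(self.meta.columns) != META_COLUMNS:
            missing = set(META_COLUMNS) - set(self.meta.columns)
            if missing:
                raise EnsembleConsistencyError(
                    f"metadata missing columns: {sorted(missing)}"
                )
            self.meta = self.meta[META_COLUMNS]
        if len(self.meta) != n:
            raise EnsembleConsistencyError(
                f"{len(self.meta)} metadata rows for {n} traces"
            )
        if n and not self.meta["pulse"].isin([1, 2]).all():
            raise EnsembleConsistencyError("pulse index must be 1 or 2")
        nonfinite = (
            ~np.isfinite(self.traces).all(axis=1)
            if n
            else np.zeros(0, dtype=bool)
        )
        if self.excluded is None:
            self.excluded = nonfinite
        else:
            self.excluded = np.asarray(self.excluded, dtype=bool) | nonfinite
        if self.excluded.shape != (n,):
            raise EnsembleConsistencyError("one exclusion flag per trace required")

    # -- conveniences -----------------------------------------------------

    @property
    def n_traces(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    @property
    def included_indices(self) -> np.ndarray:
        """Row indices that survive the NaN / manual exclusion filter."""
        return np.flatnonzero(~self.excluded)

    def stim_window_s(self) -> tuple[float, float]:
        return (
            self.stim_onset / self.frame_rate,
            self.stim_offset / self.frame_rate,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TraceEnsemble):
            return NotImplemented
        return (
            self.traces.shape == other.traces.shape
            and np.array_equal(self.traces, other.traces, equal_nan=True)
            and self.stim_onset == other.stim_onset
            and self.stim_offset == other.stim_offset
            and self.frame_rate == other.frame_rate
            and np.array_equal(self.excluded, other.excluded)
            and self.meta.astype(object).equals(other.meta.astype(object))
        )


def _sidecar_path(path: str | os.PathLike) -> Path:
    path = Path(path)
    return path.with_suffix(".meta.yaml")


def read_ensemble(path: str | os.PathLike) -> TraceEnsemble:
    """Read a trace CSV plus its ``.meta.yaml`` sidecar.

    Raises
    ------
    EnsembleFormatError
        If the sidecar is missing or either file cannot be parsed.
    EnsembleConsistencyError
        If the sidecar row table and the trace matrix disagree.
    EnsembleBoundsError
        If the stimulus window lies outside the traces.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not path.exists():
        raise EnsembleFormatError(f"trace file not found: {path}")
    if not sidecar.exists():
        raise EnsembleFormatError(f"metadata sidecar not found: {sidecar}")
    try:
        with open(sidecar) as fh:
            md = yaml.safe_load(fh)
    except yaml.YAMLError as exc:  # pragma: no cover - malformed YAML
        raise EnsembleFormatError(f"cannot parse sidecar {sidecar}: {exc}")
    if not isinstance(md, dict):
        raise EnsembleFormatError(f"sidecar {sidecar} is not a mapping")
    for key in ("frame_rate", "stim_onset", "stim_offset", "rows"):
        if key not in md:
            raise EnsembleFormatError(f"sidecar missing required key {key!r}")

    text = path.read_text()
    if text.strip():
        traces = np.loadtxt(io.StringIO(text), delimiter=",", ndmin=2)
    else:
        traces = np.zeros((0, int(md.get("n_frames", 0))))

    rows = md["rows"] or []
    if len(rows) != traces.shape[0]:
        raise EnsembleConsistencyError(
            f"sidecar lists {len(rows)} rows but trace file has "
            f"{traces.shape[0]}"
        )
    if rows:
        meta = pd.DataFrame(rows)
        if "excluded" in meta.columns:
            excluded = meta.pop("excluded").to_numpy(dtype=bool)
        else:
            excluded = np.zeros(len(rows), dtype=bool)
    else:
        meta = pd.DataFrame(columns=META_COLUMNS)
        excluded = np.zeros(0, dtype=bool)
    return TraceEnsemble(
        traces=traces,
        frame_rate=float(md["frame_rate"]),
        stim_onset=int(md["stim_onset"]),
        stim_offset=int(md["stim_offset"]),
        meta=meta,
        excluded=excluded,
    )


def write_ensemble(ensemble: TraceEnsemble, path: str | os.PathLike) -> None:
    """Write the trace CSV and its sidecar; ``read_ensemble`` round-trips.

    Values are written with 17 significant digits so float64 traces are
    reproduced bit-exactly on re-read.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if ensemble.n_traces:
        np.savetxt(path, ensemble.traces, delimiter=",", fmt="%.17g")
    else:
        path.write_text("")
    rows = []
    for i in range(ensemble.n_traces):
        row = {k: _plain(ensemble.meta.iloc[i][k]) for k in META_COLUMNS}
        row["excluded"] = bool(ensemble.excluded[i])
        rows.append(row)
    md = {
        "frame_rate": float(ensemble.frame_rate),
        "stim_onset": int(ensemble.stim_onset),
        "stim_offset": int(ensemble.stim_offset),
        "n_frames": int(ensemble.n_frames),
        "rows": rows,
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(md, fh, sort_keys=False)


def _plain(value):
    """Coerce numpy scalars to plain Python for YAML serialization."""
    if isinstance(value, np.generic):
        return value.item()
    return value
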