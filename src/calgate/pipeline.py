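"""End-to-end orchestration: synthesize → preprocess → detect → stats.

A single plain-text (YAML) run configuration names one or more conditions —
each either a synthetic-ensemble specification or a path to an on-disk
ensemble — plus detection parameters and statistics options.  The run
writes, per condition, the ensemble (synthetic sources only), a per-trace
calls table and a cumulative profile, then a KS comparison row for every
condition pair and optionally a bootstrap lag, all as CSV, together with a
run manifest recording the seed and a hash of the configuration.  All
randomness flows from the single top-level seed through named per-stage
substreams, so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .response_detect import DetectionParams, ResponseCall, detect_ensemble
from .response_stats import (
    bootstrap_lag,
    cumulative_profile,
    ks_compare,
    magnitude_peak,
    magnitude_sensory,
    rise_time,
)
from .preprocess import compute_dff, smooth_trace
from .synthetic import SyntheticConfig, generate_ensemble
from .trace_io import TraceEnsemble, read_ensemble, write_ensemble

__all__ = ["run_pipeline", "calls_to_frame", "substream_seed"]


def substream_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the run seed (< 2^31)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def calls_to_frame(
    ensemble: TraceEnsemble, calls: list[ResponseCall | None]
) -> pd.DataFrame:
    """Per-trace calls table: metadata, flags, latencies and magnitudes.

    ``magnitude_peak`` (max ΔF/F₀ in the pulse) and ``magnitude`` (late
    pulse minus pre-stimulus mean, sign free) are reported for every
    analyzed trace; rise time only for responders with a positive peak.
    """
    rows = []
    for i in range(ensemble.n_traces):
        row = {"trace": i, **ensemble.meta.iloc[i].to_dict()}
        row["excluded"] = bool(ensemble.excluded[i])
        call = calls[i]
        if call is None:
            row.update(
                responded=False, onset_frame=np.nan, latency_s=np.nan,
                magnitude=np.nan, magnitude_peak=np.nan, rise_time_s=np.nan,
            )
            rows.append(row)
            continue
        nt = smooth_trace(
            compute_dff(ensemble.traces[i], ensemble.stim_onset)
        )
        mag = magnitude_sensory(nt, ensemble.stim_onset, ensemble.stim_offset)
        peak = magnitude_peak(nt, ensemble.stim_onset, ensemble.stim_offset)
        rt = np.nan
        if call.responded and peak > 0:
            try:
                rt = rise_time(
                    nt, call, ensemble.stim_onset, ensemble.stim_offset,
                    ensemble.frame_rate,
                )
            except ValueError:
                rt = np.nan
        row.update(
            responded=call.responded,
            onset_frame=call.onset_frame if call.responded else np.nan,
            latency_s=call.latency_s if call.responded else np.nan,
            magnitude=mag,
            magnitude_peak=peak,
            rise_time_s=rt,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _load_condition(
    name: str, spec, seed: int, out_dir: Path
) -> TraceEnsemble:
    """Materialize one condition: synthetic spec (mapping) or path (str)."""
    if isinstance(spec, str):
        return read_ensemble(spec)
    spec = dict(spec or {})
    if "latency_law" in spec and isinstance(spec["latency_law"], list):
        law, p = spec["latency_law"]
        spec["latency_law"] = (law, p)
    if "rise_shape" in spec and isinstance(spec["rise_shape"], list):
        shape, p = spec["rise_shape"]
        spec["rise_shape"] = (shape, p)
    spec.setdefault("condition", name)
    spec.setdefault("seed", substream_seed(seed, f"synthesize:{name}"))
    cfg = SyntheticConfig(**spec)
    ensemble, truth = generate_ensemble(cfg)
    write_ensemble(ensemble, out_dir / f"{name}.csv")
    truth.to_csv(out_dir / f"{name}.truth.csv", index=False)
    return ensemble


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute a full run from a configuration mapping.

    Returns the manifest (also written to ``manifest.txt``).  Raises
    ``ValueError`` for malformed configurations; data-stage errors
    propagate from the responsible module.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    det_cfg = config.get("detection") or {}
    polarity = det_cfg.get("polarity", "activation")
    params = DetectionParams(**(det_cfg.get("params") or {}))
    stats_cfg = config.get("stats") or {}
    duration_s = float(stats_cfg.get("duration_s", 10.0))
    n_resamples = int(stats_cfg.get("n_resamples", 1000))

    conditions = config.get("conditions") or {}
    if not conditions:
        raise ValueError("run configuration lists no conditions")

    calls_by_cond: dict[str, list] = {}
    profiles = {}
    outputs = []
    for name, spec in conditions.items():
        ensemble = _load_condition(name, spec, seed, out_dir)
        calls = detect_ensemble(ensemble, polarity, params)
        table = calls_to_frame(ensemble, calls)
        table.to_csv(out_dir / f"{name}.calls.csv", index=False)
        outputs.append(f"{name}.calls.csv")
        analyzed = [c for c in calls if c is not None]
        calls_by_cond[name] = analyzed
        prof = cumulative_profile(analyzed, duration_s, ensemble.frame_rate)
        profiles[name] = prof
        pd.DataFrame({"time_s": prof.times, "fraction_responded": prof.curve}).to_csv(
            out_dir / f"{name}.profile.csv", index=False
        )
        outputs.append(f"{name}.profile.csv")

    comp_rows = []
    for a, b in combinations(profiles, 2):
        ks = ks_compare(profiles[a], profiles[b])
        comp_rows.append(
            {"group_a": a, "group_b": b, "D": ks.D, "p": ks.p,
             "n1": ks.n1, "n2": ks.n2}
        )
    if comp_rows:
        pd.DataFrame(comp_rows).to_csv(out_dir / "comparisons.csv", index=False)
        outputs.append("comparisons.csv")

    lag_cfg = stats_cfg.get("lag")
    if lag_cfg:
        up, down = lag_cfg["upstream"], lag_cfg["downstream"]
        lag = bootstrap_lag(
            calls_by_cond[up],
            calls_by_cond[down],
            n_resamples=n_resamples,
            seed=substream_seed(seed, "lag"),
            duration_s=duration_s,
        )
        pd.DataFrame(
            [
                {
                    "upstream": up,
                    "downstream": down,
                    "lag_s": lag.lag_s,
                    "sem_s": lag.sem_s,
                    "n_resamples": lag.n_resamples,
                    "n_failed": lag.n_failed,
                    "seed": lag.seed,
                }
            ]
        ).to_csv(out_dir / "lag.csv", index=False)
        outputs.append("lag.csv")

    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "calgate_version": __version__,
        "seed": seed,
        "config_sha256": config_hash,
        "polarity": polarity,
        "duration_s": duration_s,
        "outputs": sorted(outputs),
    }
    with open(out_dir / "manifest.txt", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
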