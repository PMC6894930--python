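"""Conductance-based model of a bistable AND-gate interneuron.

The interneuron (AIA) is modeled as a single compartment whose intrinsic
steady-state current–voltage relation is N-shaped: a cubic

    I_ss(V) = a · (V − V_rest)(V − V_mid)(V − V_depol)

with stable zeros at the resting potential (≈ −80 mV) and a depolarized
plateau (≈ −20 mV) separated by an unstable zero.  The negative-slope
region between the stable states gives the cell a high-resistance regime
and all-or-none switching: a depolarizing current exceeding the knee
(saddle-node) of the left branch annihilates the resting fixed point and
the voltage jumps to the plateau.

Two synaptic conductances implement the coincidence (AND-gate) logic:

* a gap junction to a presynaptic sensory neuron, current
  ``g_gap · (V_awa − V)`` — the only depolarizing drive;
* a glutamate-gated chloride conductance ``g_cl · s_cl · (V − E_Cl)`` with
  ``E_Cl`` near rest, acting as a shunt: when open it lowers input
  resistance and linearizes the I–V relation (monostable), when closed the
  intrinsic bistability is exposed.

The membrane equation integrated here is

    C dV/dt = −I_ss(V) − g_cl·s_cl·(V − E_Cl) + g_gap·(V_awa − V) + I_inj(t)

with C in pF, conductances in nS, voltages in mV, currents in pA and time
in ms.  A sigmoid of V serves as a normalized calcium-indicator proxy.

Calibration: the three zeros are placed at −80, −50 and −20 mV and the
cubic scale ``a`` is set so the left-branch knee current is 2.2 pA — between
the 2 pA step that must fail to switch the cell and the 3 pA step that
must switch it, and just below where 15 s current ramps transition
(≈ 2 pA to the nearest pA).  ``scripts/calibrate_membrane.py`` regenerates
the constant from these anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "MembraneModel",
    "StimulusProtocol",
    "SimResult",
    "IntegrationError",
    "knee_current",
    "find_fixed_points",
    "simulate",
    "step_threshold",
    "ramp_threshold",
    "and_gate_truth_table",
    "hysteresis_regime",
]

class IntegrationError(Exception):
    """The membrane integration produced a non-finite state."""


@dataclass
class MembraneModel:
    """Parameters of the bistable membrane and its AND-gate conductances."""

    capacitance_pF: float = 2.0
    #: cubic scale of the intrinsic I–V, pA/mV³ (sets the knee current)
    iv_scale: float = 2.117e-4
    v_rest: float = -80.0
    v_unstable: float = -50.0
    v_depol: float = -20.0
    g_cl_nS: float = 1.0
    e_cl_mV: float = -80.0
    g_gap_nS: float = 0.1
    #: presynaptic command voltages for the gap junction
    v_awa_on_mV: float = -15.0
    v_awa_off_mV: float = -80.0
    #: calcium-proxy sigmoid: 1 / (1 + exp(−(V − v_half)/slope))
    ca_v_half: float = -50.0
    ca_slope: float = 5.0

    def i_intrinsic(self, v: float | np.ndarray):
        """Intrinsic steady-state current I_ss(V), pA (outward positive)."""
        return self.iv_scale * (v - self.v_rest) * (v - self.v_unstable) * (
            v - self.v_depol
        )

    def i_net(
        self,
        v: float,
        i_inj: float = 0.0,
        s_cl: float = 0.0,
        v_awa: float | None = None,
    ) -> float:
        """Net membrane current C·dV/dt (pA) at voltage ``v``."""
        i = -self.i_intrinsic(v) + i_inj
        if s_cl:
            i -= self.g_cl_nS * s_cl * (v - self.e_cl_mV)
        if v_awa is not None:
            i += self.g_gap_nS * (v_awa - v)
        return i

    def calcium_proxy(self, v: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(v - self.ca_v_half) / self.ca_slope))


def knee_current(model: MembraneModel) -> float:
    """Saddle-node (knee) current of the resting branch, pA.

    The smallest sustained injected current for which the resting fixed
    point no longer exists (shunt closed, no gap drive).
    """
    # local max of the cubic on the resting branch, found analytically for
    # the default root spacing and polished numerically for generality
    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda v: -model.i_intrinsic(v),
        bounds=(model.v_rest, model.v_unstable),
        method="bounded",
    )
    return float(-res.fun)


@dataclass
class StimulusProtocol:
    """Ordered current-injection segments: steps and linear ramps.

    Each segment is ``("step", duration_s, pA)`` or
    ``("ramp", duration_s, start_pA, end_pA)``.
    """

    segments: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        for seg in self.segments:
            if seg[0] not in ("step", "ramp"):
                raise ValueError(f"unknown segment kind {seg[0]!r}")
            if seg[1] <= 0:
                raise ValueError("segment durations must be positive")

    @property
    def duration_s(self) -> float:
        return sum(seg[1] for seg in self.segments)

    def current(self, dt_ms: float) -> np.ndarray:
        """Injected current sampled at ``dt_ms``, one value per solver step."""
        chunks = []
        for seg in self.segments:
            n = int(round(seg[1] * 1000.0 / dt_ms))
            if seg[0] == "step":
                chunks.append(np.full(n, float(seg[2])))
            else:
                _, dur, i0, i1 = seg
                chunks.append(i0 + (i1 - i0) * (np.arange(n) + 0.5) / n)
        return np.concatenate(chunks) if chunks else np.zeros(0)

    @classmethod
    def step_series(
        cls,
        start_pA: float = -1.0,
        stop_pA: float = 8.0,
        increment_pA: float = 1.0,
        step_s: float = 5.0,
        pre_pulse_pA: float = -10.0,
        pre_pulse_s: float = 1.0,
    ) -> "StimulusProtocol":
        """Square-pulse series with a hyperpolarizing reset pre-pulse."""
        segments: list[tuple] = []
        i = start_pA
        while i <= stop_pA + 1e-9:
            segments.append(("step", pre_pulse_s, pre_pulse_pA))
            segments.append(("step", step_s, i))
            i += increment_pA
        return cls(segments)

    @classmethod
    def ramp(cls, peak_pA: float, duration_s: float = 15.0) -> "StimulusProtocol":
        return cls([("ramp", duration_s, 0.0, peak_pA)])


@dataclass
class SimResult:
    t_s: np.ndarray
    v_mV: np.ndarray
    ca: np.ndarray
    i_pA: np.ndarray
    dt_ms: float


def find_fixed_points(
    model: MembraneModel,
    i_inj: float = 0.0,
    s_cl: float = 0.0,
    v_awa: float | None = None,
    v_range: tuple[float, float] = (-120.0, 20.0),
    grid_mV: float = 0.1,
) -> list[tuple[float, bool]]:
    """All steady states in ``v_range`` with their stability.

    Zeros of the net membrane current are bracketed on a voltage grid and
    polished by bisection to |I| < 1e−6 pA; a fixed point is stable when
    the net current has negative slope there (dI_net/dV < 0).
    """
    lo, hi = v_range
    grid = np.arange(lo, hi + grid_mV, grid_mV)
    vals = np.array([model.i_net(v, i_inj, s_cl, v_awa) for v in grid])
    out: list[tuple[float, bool]] = []
    for k in range(len(grid) - 1):
        a, b = vals[k], vals[k + 1]
        if a == 0.0 and grid[k] not in [fp for fp, _ in out]:
            root = float(grid[k])
        elif a * b < 0:
            root = float(
                brentq(
                    lambda v: model.i_net(v, i_inj, s_cl, v_awa),
                    grid[k],
                    grid[k + 1],
                    xtol=1e-10,
                )
            )
        else:
            continue
        eps = 1e-4
        slope = (
            model.i_net(root + eps, i_inj, s_cl, v_awa)
            - model.i_net(root - eps, i_inj, s_cl, v_awa)
        ) / (2 * eps)
        out.append((root, slope < 0))
    return out


def resting_potential(
    model: MembraneModel, s_cl: float = 0.0, v_awa: float | None = None
) -> float:
    """Most hyperpolarized stable fixed point at zero injected current."""
    stable = [v for v, ok in find_fixed_points(model, 0.0, s_cl, v_awa) if ok]
    if not stable:
        raise ValueError("model has no stable fixed point at rest")
    return min(stable)


def simulate(
    model: MembraneModel,
    protocol: StimulusProtocol,
    dt_ms: float = 0.1,
    v0: float | None = None,
    s_cl: float = 0.0,
    v_awa: float | None = None,
) -> SimResult:
    """Integrate the membrane equation under a current protocol.

    Fixed-step classical Runge–Kutta (RK4); the injected current is held
    at its mid-step sample within each step, which is exact for steps and
    O(dt²) for ramps.  Raises :class:`IntegrationError` on non-finite
    state.
    """
    i_pA = protocol.current(dt_ms)
    n = i_pA.size
    v = np.empty(n + 1)
    v[0] = resting_potential(model, s_cl, v_awa) if v0 is None else v0

    a = model.iv_scale
    v1, v2, v3 = model.v_rest, model.v_unstable, model.v_depol
    g_cl = model.g_cl_nS * s_cl
    e_cl = model.e_cl_mV
    g_gap = model.g_gap_nS if v_awa is not None else 0.0
    va = v_awa if v_awa is not None else 0.0
    inv_c = 1.0 / model.capacitance_pF
    h = dt_ms

    def f(vv: float, ii: float) -> float:
        cur = -a * (vv - v1) * (vv - v2) * (vv - v3) + ii
        cur -= g_cl * (vv - e_cl)
        cur += g_gap * (va - vv)
        return cur * inv_c

    x = v[0]
    with np.errstate(over="ignore", invalid="ignore"):
        for k in range(n):
            ii = i_pA[k]
            k1 = f(x, ii)
            k2 = f(x + 0.5 * h * k1, ii)
            k3 = f(x + 0.5 * h * k2, ii)
            k4 = f(x + h * k3, ii)
            x = x + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            v[k + 1] = x
    if not np.all(np.isfinite(v)):
        bad = int(np.flatnonzero(~np.isfinite(v))[0])
        raise IntegrationError(
            f"non-finite membrane potential at step {bad} "
            f"(t = {bad * dt_ms / 1000.0:.4f} s); reduce dt or check parameters"
        )
    t_s = np.arange(n + 1) * (dt_ms / 1000.0)
    return SimResult(
        t_s=t_s,
        v_mV=v,
        ca=model.calcium_proxy(v),
        i_pA=np.concatenate([i_pA, i_pA[-1:]]) if n else np.zeros(1),
        dt_ms=dt_ms,
    )


def step_threshold(
    model: MembraneModel,
    steps_pA: np.ndarray | None = None,
    step_s: float = 5.0,
    pre_pulse_pA: float = -10.0,
    pre_pulse_s: float = 1.0,
    dt_ms: float = 0.1,
    s_cl: float = 0.0,
    v_awa: float | None = None,
) -> float | None:
    """Smallest step current that switches the cell to the plateau.

    Each step is preceded by a hyperpolarizing reset pre-pulse and started
    from rest; a step switches when the voltage crosses the zero-input
    unstable fixed point during the step.  Returns ``None`` when no step
    in the series switches.
    """
    if steps_pA is None:
        steps_pA = np.arange(-1.0, 8.0 + 1e-9, 1.0)
    fps = find_fixed_points(model, 0.0, s_cl, v_awa)
    unstable = [v for v, ok in fps if not ok]
    if not unstable:
        return None  # no separatrix: the cell is not bistable here
    v_sep = unstable[0]
    v0 = resting_potential(model, s_cl, v_awa)
    for i_step in steps_pA:
        protocol = StimulusProtocol(
            [("step", pre_pulse_s, pre_pulse_pA), ("step", step_s, float(i_step))]
        )
        res = simulate(model, protocol, dt_ms=dt_ms, v0=v0, s_cl=s_cl, v_awa=v_awa)
        step_start = int(round(pre_pulse_s * 1000.0 / dt_ms))
        if np.any(res.v_mV[step_start:] > v_sep):
            return float(i_step)
    return None


def ramp_threshold(
    model: MembraneModel,
    peak_pA: float,
    duration_s: float = 15.0,
    dt_ms: float = 0.1,
    s_cl: float = 0.0,
    v_awa: float | None = None,
) -> float | None:
    """Instantaneous current at the ramp-evoked transition, pA.

    The transition is the first crossing of the zero-input unstable fixed
    point during a linear 0 → ``peak_pA`` ramp; returns the injected
    current at that moment, or ``None`` if the cell never switches.
    """
    fps = find_fixed_points(model, 0.0, s_cl, v_awa)
    unstable = [v for v, ok in fps if not ok]
    if not unstable:
        return None
    v_sep = unstable[0]
    protocol = StimulusProtocol.ramp(peak_pA, duration_s)
    res = simulate(model, protocol, dt_ms=dt_ms, s_cl=s_cl, v_awa=v_awa)
    crossed = np.flatnonzero(res.v_mV > v_sep)
    if crossed.size == 0:
        return None
    k = int(crossed[0])
    return float(res.i_pA[min(k, res.i_pA.size - 1)])


def and_gate_truth_table(
    model: MembraneModel,
    sim_s: float = 10.0,
    dt_ms: float = 0.1,
    plateau_tol_mV: float = 5.0,
) -> dict[tuple[bool, bool], dict]:
    """Plateau outcome for all (AWA drive × glutamate release) combinations.

    AWA drive on sets the gap-junction command to the depolarized level;
    glutamate release on closes the chloride shunt (s_cl = 0), off leaves
    it open (s_cl = 1).  Each combination starts from the tonic resting
    state (shunt open, AWA at rest) and runs for ``sim_s``; the plateau
    flag is true when the final voltage lies within ``plateau_tol_mV`` of
    the depolarized stable fixed point under the same conductances.
    """
    v_start = resting_potential(model, s_cl=1.0, v_awa=model.v_awa_off_mV)
    table: dict[tuple[bool, bool], dict] = {}
    for awa_on, glut_released in product([False, True], repeat=2):
        v_awa = model.v_awa_on_mV if awa_on else model.v_awa_off_mV
        s_cl = 0.0 if glut_released else 1.0
        res = simulate(
            model,
            StimulusProtocol([("step", sim_s, 0.0)]),
            dt_ms=dt_ms,
            v0=v_start,
            s_cl=s_cl,
            v_awa=v_awa,
        )
        stable = [v for v, ok in find_fixed_points(model, 0.0, s_cl, v_awa) if ok]
        v_plateau = max(stable) if stable else None
        v_final = float(res.v_mV[-1])
        plateau = (
            v_plateau is not None
            and v_plateau > model.v_unstable
            and abs(v_final - v_plateau) < plateau_tol_mV
        )
        table[(awa_on, glut_released)] = {
            "plateau": plateau,
            "v_final_mV": v_final,
            "v_plateau_mV": v_plateau,
        }
    return table


def hysteresis_regime(model: MembraneModel, s_cl: float = 0.0) -> str:
    """Whether the plateau outlasts the stimulus at zero input.

    Returns ``"persistent"`` when the depolarized branch is a stable fixed
    point at 0 pA (the cell stays up after a suprathreshold step returns
    to baseline) and ``"transient"`` otherwise.
    """
    stable = [v for v, ok in find_fixed_points(model, 0.0, s_cl) if ok]
    depol = [v for v in stable if v > model.v_unstable]
    return "persistent" if depol else "transient"
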