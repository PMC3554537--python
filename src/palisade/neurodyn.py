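"""Single-neuron Morris-Lecar dynamics with spike-frequency adaptation.

Each neuron is a one-compartment Morris-Lecar oscillator in its class-I
(SNIC-onset) regime, with the fast inward conductance labeled "sodium":

    C dV/dt = -g_Na m_inf(V) (V - E_Na) - g_K w (V - E_K) - g_L (V - E_L)
              - g_AHP z (V - E_K) - I_syn
    dw/dt   = phi (w_inf(V) - w) / tau_w(V)

with sigmoidal steady states ``m_inf = 0.5 (1 + tanh((V - V1)/V2))``,
``w_inf = 0.5 (1 + tanh((V - V3)/V4))`` and ``tau_w = 1/cosh((V - V3)/(2 V4))``.
Pyramidal neurons additionally carry a phenomenological spike-frequency
adaptation gate ``z`` driving a K-like current ``g_AHP z (V - E_K)``: ``z``
jumps by ``delta_z`` at every spike (clipped at 1) and decays exponentially
with ``tau_z`` in between.

Units: mV, ms, uF/cm^2, mS/cm^2, uA/cm^2.  Spikes are upward crossings of
``spike_threshold`` guarded by a latch so a plateau is counted once.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "MLParams",
    "AdaptParams",
    "NeuronState",
    "IntegratorConfig",
    "ml_derivatives",
    "adaptation_step",
    "step_network",
    "simulate_single",
    "resting_state",
    "calibrate_intact_rates",
    "CalibrationError",
]


@dataclass(frozen=True)
class MLParams:
    """Morris-Lecar membrane parameters (canonical class-I set)."""

    C: float = 20.0  # uF/cm^2
    g_Na: float = 4.0  # mS/cm^2, fast inward (instantaneous activation)
    g_K: float = 8.0
    g_L: float = 2.0
    E_Na: float = 120.0  # mV
    E_K: float = -84.0
    E_L: float = -60.0
    V1: float = -1.2
    V2: float = 18.0
    V3: float = 12.0
    V4: float = 17.4
    phi: float = 1.0 / 15.0  # 1/ms
    spike_threshold: float = 0.0  # mV

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if min(self.g_Na, self.g_K, self.g_L) < 0:
            raise ValueError("conductances must be >= 0")
        if self.V2 <= 0 or self.V4 <= 0:
            raise ValueError("activation slopes V2, V4 must be > 0")

    def m_inf(self, V):
        return 0.5 * (1.0 + np.tanh((V - self.V1) / self.V2))

    def w_inf(self, V):
        return 0.5 * (1.0 + np.tanh((V - self.V3) / self.V4))

    def tau_w(self, V):
        return 1.0 / np.cosh((V - self.V3) / (2.0 * self.V4))


@dataclass(frozen=True)
class AdaptParams:
    """Spike-frequency adaptation (pyramidal neurons only; g_AHP = 0 for IN)."""

    g_AHP: float = 0.5  # mS/cm^2
    tau_z: float = 200.0  # ms
    delta_z: float = 0.05  # per-spike increment of the gate, clipped at 1

    def __post_init__(self) -> None:
        if self.g_AHP < 0:
            raise ValueError("g_AHP must be >= 0")
        if self.tau_z <= 0:
            raise ValueError("tau_z must be > 0")


# IN neurons share membrane parameters but have no adaptation current.
NO_ADAPTATION = AdaptParams(g_AHP=0.0)


@dataclass
class NeuronState:
    """State of one neuron (or, with array fields, of a population)."""

    V: np.ndarray | float
    w: np.ndarray | float
    z: np.ndarray | float = 0.0
    in_spike: np.ndarray | bool = False


@dataclass(frozen=True)
class IntegratorConfig:
    """Fixed-step integration settings.

    ``dt = 0.05`` ms resolves the ~1 ms spike upstroke; gating variables use
    exponential Euler so they stay in [0, 1] for any dt.
    """

    dt: float = 0.05  # ms
    total_time: float = 1000.0  # ms
    record_stride: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


def ml_derivatives(
    state: NeuronState,
    params: MLParams,
    adapt: AdaptParams = NO_ADAPTATION,
    I_total: np.ndarray | float = 0.0,
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """(dV/dt, dw/dt) at the given state.

    ``I_total`` is the total applied (synaptic + afferent) current with the
    convention ``I = g (V - E)``, so depolarizing current is negative.
    """
    V, w, z = state.V, state.w, state.z
    if not (np.all(np.isfinite(V)) and np.all(np.isfinite(w)) and np.all(np.isfinite(z))):
        raise FloatingPointError("non-finite neuron state")
    I_ion = (
        params.g_Na * params.m_inf(V) * (V - params.E_Na)
        + params.g_K * w * (V - params.E_K)
        + params.g_L * (V - params.E_L)
        + adapt.g_AHP * z * (V - params.E_K)
    )
    dV = -(I_ion + I_total) / params.C
    dw = params.phi * (params.w_inf(V) - w) / params.tau_w(V)
    return dV, dw


def adaptation_step(
    z: np.ndarray | float, adapt: AdaptParams, dt: float, spiked: np.ndarray | bool
) -> np.ndarray | float:
    """One update of the adaptation gate: exponential decay, plus the
    per-spike increment (applied after the decay), clipped at 1."""
    z = z * np.exp(-dt / adapt.tau_z)
    z = z + np.asarray(spiked, dtype=float) * adapt.delta_z
    return np.minimum(z, 1.0)


def step_network(
    state: NeuronState,
    params: MLParams,
    adapt: AdaptParams,
    I_total: np.ndarray | float,
    dt: float,
) -> tuple[NeuronState, np.ndarray | bool]:
    """Advance all neurons one step; returns (new state, spike flags).

    Forward Euler on V, exponential Euler on the gating variables.  A spike is
    an upward crossing of ``spike_threshold`` while the ``in_spike`` latch is
    clear; the latch clears on the downward crossing.
    """
    dV, _ = ml_derivatives(state, params, adapt, I_total)
    V_new = state.V + dt * dV
    if not np.all(np.isfinite(V_new)):
        raise FloatingPointError("NaN/Inf membrane potential during integration")
    # exponential Euler keeps w in [0, 1]
    decay = np.exp(-dt * params.phi / params.tau_w(state.V))
    w_new = params.w_inf(state.V) + (state.w - params.w_inf(state.V)) * decay

    above = V_new >= params.spike_threshold
    spiked = above & ~np.asarray(state.in_spike)
    latch = above
    z_new = adaptation_step(state.z, adapt, dt, spiked)
    return NeuronState(V=V_new, w=w_new, z=z_new, in_spike=latch), spiked


def resting_state(params: MLParams, tol: float = 1e-10) -> NeuronState:
    """Resting fixed point (V*, w_inf(V*)) with no applied current."""
    from scipy.optimize import brentq

    def f(V: float) -> float:
        w = params.w_inf(V)
        s = NeuronState(V=V, w=w)
        return ml_derivatives(s, params)[0]

    # the rest point is the lowest-V zero of dV/dt; bracket it by scanning
    grid = np.arange(-100.0, params.spike_threshold, 1.0)
    vals = np.array([f(v) for v in grid])
    sign_change = np.flatnonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))
    if sign_change.size == 0:
        raise RuntimeError("no resting fixed point below threshold")
    k = sign_change[0]
    V_star = brentq(f, grid[k], grid[k + 1])
    if abs(f(V_star)) > 1e-6:
        raise RuntimeError("failed to locate resting fixed point")
    _ = tol
    return NeuronState(V=float(V_star), w=float(params.w_inf(V_star)))


def simulate_single(
    params: MLParams,
    adapt: AdaptParams = NO_ADAPTATION,
    I: float = 0.0,
    total_time: float = 1000.0,
    dt: float = 0.05,
    record: bool = False,
) -> dict:
    """Integrate one neuron under a constant applied current.

    ``I`` follows the helper convention that positive is depolarizing (it is
    applied as ``I_total = -I``).  Returns spike times and, optionally, the
    recorded (t, V) trace.
    """
    state = resting_state(params)
    spikes: list[float] = []
    n_steps = int(round(total_time / dt))
    trace_t, trace_v = [], []
    for k in range(n_steps):
        state, spiked = step_network(state, params, adapt, -I, dt)
        if spiked:
            spikes.append((k + 1) * dt)
        if record:
            trace_t.append((k + 1) * dt)
            trace_v.append(float(state.V))
    out = {"spike_times": np.asarray(spikes), "final_state": state}
    if record:
        out["t"] = np.asarray(trace_t)
        out["V"] = np.asarray(trace_v)
    return out


class CalibrationError(RuntimeError):
    """Raised when the afferent-drive search cannot reach the target rates."""


def calibrate_intact_rates(
    params=None,
    side_length: int = 20,
    sim_time_ms: float = 10_000.0,
    target_py_hz: float = 5.0,
    target_in_hz: float = 10.0,
    tol_py: float = 0.5,
    tol_in: float = 1.0,
    max_rounds: int = 6,
    seed: int = 0,
    verbose: bool = False,
):
    """Calibrate per-type afferent peak conductances for the intact network.

    Alternating scalar bisection on the PY and IN afferent peak conductances
    until the time-averaged intact rates hit ``target_py_hz`` (+/- ``tol_py``)
    and ``target_in_hz`` (+/- ``tol_in``) on a reduced lattice.  Firing rates
    increase monotonically with afferent drive over the bracket, which the
    search verifies at its endpoints.

    Returns ``(params, diagnostics)`` where ``params`` carries the calibrated
    ``ghat_aff_py`` / ``ghat_aff_in``.
    """
    from .engine import measure_intact_rates
    from .params import SimParams

    if params is None:
        params = SimParams()

    def rates(p) -> tuple[float, float]:
        return measure_intact_rates(p, side_length=side_length, sim_time_ms=sim_time_ms, seed=seed)

    history = []
    for rnd in range(max_rounds):
        for which, target, tol in (("py", target_py_hz, tol_py), ("in", target_in_hz, tol_in)):
            attr = f"ghat_aff_{which}"
            lo, hi = 0.0, 2.0 * getattr(params.afferent, attr) + 0.5
            r_hi = rates(replace_afferent(params, attr, hi))
            r_hi_t = r_hi[0] if which == "py" else r_hi[1]
            if r_hi_t < target:
                hi *= 4.0
                r_hi = rates(replace_afferent(params, attr, hi))
                r_hi_t = r_hi[0] if which == "py" else r_hi[1]
                if r_hi_t < target:
                    raise CalibrationError(
                        f"cannot bracket {attr}: rate {r_hi_t:.2f} Hz < target {target} Hz "
                        f"at upper bound {hi}"
                    )
            for _ in range(12):
                mid = 0.5 * (lo + hi)
                r = rates(replace_afferent(params, attr, mid))
                r_t = r[0] if which == "py" else r[1]
                history.append((attr, mid, r))
                if abs(r_t - target) <= 0.5 * tol:
                    break
                if r_t < target:
                    lo = mid
                else:
                    hi = mid
            params = replace_afferent(params, attr, mid)
            if verbose:
                print(f"round {rnd} {attr}={mid:.4f} rates={r}")
        r_py, r_in = rates(params)
        if abs(r_py - target_py_hz) <= tol_py and abs(r_in - target_in_hz) <= tol_in:
            return params, {"rates": (r_py, r_in), "history": history, "rounds": rnd + 1}
    raise CalibrationError(
        f"calibration did not converge: final rates PY={r_py:.2f} Hz IN={r_in:.2f} Hz"
    )


def replace_afferent(params, attr: str, value: float):
    return replace(params, afferent=replace(params.afferent, **{attr: value}))
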