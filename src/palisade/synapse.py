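"""Synaptic conductance dynamics, short-term depression and afferent drive.

Synaptic transmission is deterministic: on a presynaptic spike the conductance
rises instantaneously by the (scaled, depressed) peak value and then relaxes
exponentially to zero.  PY->PY synapses carry both an AMPA component and an
NMDA component modeled as the difference of a slow and a fast exponential
trace; both are attenuated by the same short-term depression variable ``D``
(per presynaptic neuron) and multiplied by the same homeostatic scaling factor
``s``.  GABAergic synapses have a single exponential conductance and no
depression (``D = 1`` held fixed).

Depression follows the standard release-depletion form: ``D -> (1 - d) D`` at
each presynaptic spike, recovering between spikes as ``dD/dt = (1 - D)/tau_D``.

Afferent ("rest of the cortex") excitation is an independent homogeneous
Poisson conductance train per neuron, 100 Hz in the intact state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .netgen import IN_IN, IN_PY, PY_IN, PY_PY

__all__ = [
    "SynParams",
    "SynapseState",
    "AfferentProcess",
    "on_presyn_spike",
    "decay_step",
    "synaptic_current",
    "afferent_events",
    "nmda_norm",
]


@dataclass(frozen=True)
class SynParams:
    """Kinetic constants and per-kind initial peak conductances."""

    tau_AMPA: float = 5.0  # ms
    tau_GABA: float = 10.0  # ms
    tau_NMDA_fast: float = 5.0  # ms
    tau_NMDA_slow: float = 100.0  # ms
    tau_D: float = 1000.0  # ms, recovery from short-term depression
    d: float = 0.5  # depression strength per spike
    E_exc: float = 0.0  # mV (AMPA and NMDA)
    E_GABA: float = -80.0  # mV
    nmda_ratio: float = 0.25  # NMDA single-event peak as a fraction of AMPA's
    # initial peak conductances by synapse kind, mS/cm^2
    ghat: dict = field(
        default_factory=lambda: {PY_PY: 0.25, IN_PY: 0.25, PY_IN: 0.09, IN_IN: 0.25}
    )

    def __post_init__(self) -> None:
        for name in ("tau_AMPA", "tau_GABA", "tau_NMDA_fast", "tau_NMDA_slow", "tau_D"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.tau_NMDA_slow <= self.tau_NMDA_fast:
            raise ValueError("tau_NMDA_slow must exceed tau_NMDA_fast")
        if not 0.0 <= self.d <= 1.0:
            raise ValueError("depression strength d must be in [0, 1]")
        if any(g < 0 for g in self.ghat.values()):
            raise ValueError("peak conductances must be >= 0")


def nmda_norm(params: SynParams) -> float:
    """Normalization so a single event's NMDA peak equals ``nmda_ratio * ghat``.

    The dual-exponential ``x_slow - x_fast`` (equal unit increments) peaks at
    ``t* = ln(ts/tf) tf ts/(ts - tf)`` with value ``e^(-t*/ts) - e^(-t*/tf)``.
    """
    tf, ts = params.tau_NMDA_fast, params.tau_NMDA_slow
    t_star = np.log(ts / tf) * tf * ts / (ts - tf)
    peak = np.exp(-t_star / ts) - np.exp(-t_star / tf)
    return params.nmda_ratio / peak


@dataclass
class SynapseState:
    """Per-synapse state (scalar fields; the network engine vectorizes these).

    ``g`` is the AMPA conductance for excitatory kinds and the GABA
    conductance for inhibitory kinds; ``x_fast``/``x_slow`` are the NMDA
    traces (excitatory kinds only); ``D`` is the depression efficacy and ``s``
    the homeostatic scaling factor applied to the initial peak conductance.
    """

    g: float = 0.0
    x_fast: float = 0.0
    x_slow: float = 0.0
    D: float = 1.0
    s: float = 1.0


def _is_excitatory(kind: int) -> bool:
    return kind in (PY_PY, PY_IN)


def on_presyn_spike(state: SynapseState, params: SynParams, kind: int) -> SynapseState:
    """Apply one presynaptic spike: instantaneous conductance rise, then
    depression update (excitatory kinds only)."""
    amp = params.ghat[kind] * state.s
    if _is_excitatory(kind):
        amp *= state.D
        state.g += amp
        if kind == PY_PY:  # NMDA only at PY->PY synapses
            inc = amp * nmda_norm(params)
            state.x_fast += inc
            state.x_slow += inc
        state.D *= 1.0 - params.d
    else:
        state.g += amp  # GABA: D held at 1
    return state


def decay_step(state: SynapseState, params: SynParams, kind: int, dt: float) -> SynapseState:
    """Exponential relaxation of all conductance traces over ``dt``; ``D``
    recovers toward 1 with time constant ``tau_D``."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    tau_g = params.tau_AMPA if _is_excitatory(kind) else params.tau_GABA
    state.g *= np.exp(-dt / tau_g)
    state.x_fast *= np.exp(-dt / params.tau_NMDA_fast)
    state.x_slow *= np.exp(-dt / params.tau_NMDA_slow)
    state.D = 1.0 - (1.0 - state.D) * np.exp(-dt / params.tau_D)
    return state


def synaptic_current(state: SynapseState, V_post: float, params: SynParams, kind: int) -> float:
    """Total postsynaptic current ``sum_c g_c (V_post - E_c)``; negative is
    inward (depolarizing)."""
    if _is_excitatory(kind):
        g_nmda = state.x_slow - state.x_fast
        return (state.g + g_nmda) * (V_post - params.E_exc)
    return state.g * (V_post - params.E_GABA)


@dataclass(frozen=True)
class AfferentProcess:
    """Poisson afferent excitation from un-modeled cortex.

    ``rate_hz`` is 100 Hz in the intact state; deafferentation multiplies it
    by the trauma rate factor (default 0.1).  Peak conductances are per
    postsynaptic type and set by intact-rate calibration.
    """

    rate_hz: float = 100.0
    # peak conductances from intact-rate calibration (see docs/methods.md)
    ghat_aff_py: float = 2.17  # mS/cm^2
    ghat_aff_in: float = 3.56
    tau_aff: float = 5.0  # ms
    E_aff: float = 0.0  # mV

    def __post_init__(self) -> None:
        if self.rate_hz < 0:
            raise ValueError("rate must be >= 0")
        if self.tau_aff <= 0:
            raise ValueError("tau_aff must be > 0")


def afferent_events(
    process: AfferentProcess, t0: float, t1: float, rng: np.random.Generator
) -> np.ndarray:
    """Homogeneous Poisson event times (ms) in ``[t0, t1)`` at ``rate_hz``."""
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    rate_per_ms = process.rate_hz / 1000.0
    n = rng.poisson(rate_per_ms * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))
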