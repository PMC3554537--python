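"""Versioned default parameter sets for the network model.

All defaults live here so a run's configuration is fully determined by one
object.  Membrane parameters are the canonical class-I Morris-Lecar set (see
:mod:`palisade.neurodyn`); synaptic kinetics are standard AMPA/NMDA/GABA
values; the afferent peak conductances are the output of
:func:`palisade.neurodyn.calibrate_intact_rates`, frozen here so that the
intact network fires at PY ~5 Hz and IN ~10 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .neurodyn import AdaptParams, MLParams, NO_ADAPTATION
from .synapse import AfferentProcess, SynParams

PARAMS_VERSION = 1


@dataclass(frozen=True)
class SimParams:
    """Complete biophysical parameter bundle for a network simulation."""

    ml_py: MLParams = field(default_factory=MLParams)
    ml_in: MLParams = field(default_factory=MLParams)  # shared membrane params
    adapt: AdaptParams = field(default_factory=AdaptParams)  # PY only; IN has g_AHP = 0
    syn: SynParams = field(default_factory=SynParams)
    afferent: AfferentProcess = field(default_factory=AfferentProcess)
    dt_ms: float = 0.05

    def __post_init__(self) -> None:
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be > 0")

    def with_dt(self, dt_ms: float) -> "SimParams":
        return replace(self, dt_ms=dt_ms)


__all__ = ["SimParams", "PARAMS_VERSION", "NO_ADAPTATION"]
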