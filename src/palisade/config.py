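"""Flat JSON configuration for whole experiments.

One document with sections ``network`` / ``neuron`` / ``synapse`` / ``trauma``
/ ``hsp`` / ``analysis`` / ``run`` fully determines a simulation; round-trip
``parse(serialize(cfg)) == cfg`` is guaranteed (and tested).  All defaults are
embedded so an empty document is a valid full configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .analysis import BurstCriteria
from .netgen import LatticeConfig
from .neurodyn import AdaptParams, MLParams
from .params import SimParams
from .synapse import AfferentProcess, SynParams
from .trauma_hsp import HSPConfig, TraumaConfig

__all__ = ["RunConfig", "FullConfig", "serialize", "parse", "config_hash"]


@dataclass(frozen=True)
class RunConfig:
    """Phase clocking and output switches for :func:`palisade.run.run_simulation`.

    Phases: intact settle -> trauma at t=0 of the post-intact phase -> HSP
    evolution until the steady-state criterion (network PY rate within
    ``steady_tol_hz`` of the HSP target for ``steady_windows`` consecutive
    windows) or ``hsp_max_s`` -> measurement window with recording.
    """

    settle_ms: float = 2000.0
    hsp_max_s: float = 120.0
    steady_window_s: float = 10.0
    steady_tol_hz: float = 0.75
    steady_windows: int = 2
    measure_ms: float = 50_000.0
    write_raster: bool = False
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.measure_ms <= 0:
            raise ValueError("measure_ms must be > 0")
        if self.hsp_max_s < 0 or self.settle_ms < 0:
            raise ValueError("phase durations must be >= 0")


@dataclass(frozen=True)
class FullConfig:
    network: LatticeConfig = field(default_factory=LatticeConfig)
    sim: SimParams = field(default_factory=SimParams)
    trauma: TraumaConfig = field(default_factory=TraumaConfig)
    hsp: HSPConfig = field(default_factory=HSPConfig)
    burst: BurstCriteria = field(default_factory=BurstCriteria)
    run: RunConfig = field(default_factory=RunConfig)


_SECTIONS: dict[str, Any] = {
    "network": LatticeConfig,
    "trauma": TraumaConfig,
    "hsp": HSPConfig,
    "analysis": BurstCriteria,
    "run": RunConfig,
}
_NEURON_PARTS = {"ml_py": MLParams, "ml_in": MLParams, "adapt": AdaptParams}
_SYN_PARTS = {"syn": SynParams, "afferent": AfferentProcess}


def _as_plain(obj: Any) -> Any:
    d = dataclasses.asdict(obj)
    # JSON object keys must be strings (SynParams.ghat uses int kind codes)
    for k, v in d.items():
        if isinstance(v, dict):
            d[k] = {str(kk): vv for kk, vv in v.items()}
    return d


def serialize(cfg: FullConfig) -> str:
    doc: dict[str, Any] = {}
    doc["network"] = _as_plain(cfg.network)
    doc["neuron"] = {name: _as_plain(getattr(cfg.sim, name)) for name in _NEURON_PARTS}
    doc["neuron"]["dt_ms"] = cfg.sim.dt_ms
    doc["synapse"] = {name: _as_plain(getattr(cfg.sim, name)) for name in _SYN_PARTS}
    doc["trauma"] = _as_plain(cfg.trauma)
    doc["hsp"] = _as_plain(cfg.hsp)
    doc["analysis"] = _as_plain(cfg.burst)
    doc["run"] = _as_plain(cfg.run)
    return json.dumps(doc, indent=2, sort_keys=True)


def _build(cls: Any, data: dict) -> Any:
    if cls is SynParams and "ghat" in data:
        data = {**data, "ghat": {int(k): v for k, v in data["ghat"].items()}}
    return cls(**data)


def parse(text: str | dict) -> FullConfig:
    doc = json.loads(text) if isinstance(text, str) else dict(text)
    network = _build(LatticeConfig, doc.get("network", {}))
    neuron = dict(doc.get("neuron", {}))
    dt_ms = neuron.pop("dt_ms", SimParams().dt_ms)
    sim_kwargs: dict[str, Any] = {"dt_ms": dt_ms}
    for name, cls in _NEURON_PARTS.items():
        sim_kwargs[name] = _build(cls, neuron.get(name, {}))
    synapse = doc.get("synapse", {})
    for name, cls in _SYN_PARTS.items():
        sim_kwargs[name] = _build(cls, synapse.get(name, {}))
    return FullConfig(
        network=network,
        sim=SimParams(**sim_kwargs),
        trauma=_build(TraumaConfig, doc.get("trauma", {})),
        hsp=_build(HSPConfig, doc.get("hsp", {})),
        burst=_build(BurstCriteria, doc.get("analysis", {})),
        run=_build(RunConfig, doc.get("run", {})),
    )


def load(path: str | Path) -> FullConfig:
    return parse(Path(path).read_text())


def save(cfg: FullConfig, path: str | Path) -> None:
    Path(path).write_text(serialize(cfg))


def config_hash(cfg: FullConfig) -> str:
    return hashlib.sha256(serialize(cfg).encode()).hexdigest()[:16]
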