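"""Experiment orchestration: single runs and parameter sweeps.

A run executes the standard protocol — build the network, settle the intact
state, deafferent at t = 0, let homeostatic plasticity evolve to its
post-traumatic steady state, then record a measurement window and analyze it
— and returns a :class:`RunRecord` with the summary metrics.  A sweep executes
a grid of such runs with independent replicate seeds and aggregates the
metrics into a table.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import analysis
from .config import FullConfig, config_hash, serialize
from .engine import NetworkEngine, SpikeData
from .netgen import PY_PY, build_network
from .trauma_hsp import apply_trauma, partition_random, partition_segregated

__all__ = ["RunRecord", "ExperimentSpec", "run_simulation", "sweep", "set_path"]


@dataclass
class RunRecord:
    """Provenance and summary of one simulation run."""

    config_hash: str
    seed: int
    phase_durations_s: dict
    metrics: dict
    hsp_converged: bool
    output_paths: dict = field(default_factory=dict)
    spikes: SpikeData | None = None
    engine: Any = None  # retained for in-process inspection when requested


def _scaling_stats(eng: NetworkEngine, deaff_mask: np.ndarray) -> dict:
    """Mean/SD of the PY->PY scaling factor, overall and by presynaptic
    deafferentation status (synapse-weighted, as the conductances are)."""
    net = eng.network
    is_pp = net.kind == PY_PY
    doms = eng.dmap.syn_domain[is_pp]
    s = eng.s_exc[doms]
    pre_deaff = deaff_mask[net.pre[is_pp]]
    out = {
        "s_mean": float(s.mean()),
        "s_sd": float(s.std()),
        "s_mean_from_deaff": float(s[pre_deaff].mean()) if pre_deaff.any() else float("nan"),
        "s_mean_from_intact": float(s[~pre_deaff].mean()) if (~pre_deaff).any() else float("nan"),
    }
    # percent change relative to the intact model (s was 1 everywhere)
    out["pct_change_mean"] = 100.0 * (out["s_mean"] - 1.0)
    return out


def run_simulation(cfg: FullConfig, keep_spikes: bool = False, keep_engine: bool = False) -> RunRecord:
    """Execute one full protocol run as configured.

    ``keep_spikes`` retains the measurement raster on the record (in memory)
    in addition to any file outputs.
    """
    t_wall = time.time()
    rc = cfg.run
    rng = np.random.default_rng(rc.seed)
    network = build_network(replace(cfg.network, seed=rc.seed), rng=rng)
    trauma_rng = np.random.default_rng(rc.seed + 1)
    deaff_mask = apply_trauma(network, cfg.trauma, trauma_rng)
    if cfg.trauma.sever_boundary:
        network = analysis.sever_boundary_connections(network, deaff_mask)
    if cfg.hsp.segregated:
        dmap = partition_segregated(network, deaff_mask)
    else:
        dmap = partition_random(network, cfg.hsp.M, np.random.default_rng(rc.seed + 2))
    eng = NetworkEngine(network, cfg.sim, hsp=cfg.hsp, dmap=dmap, seed=rc.seed + 3)

    phases = {}
    t0 = time.time()
    if rc.settle_ms > 0:
        eng.run(rc.settle_ms)
    phases["settle"] = time.time() - t0

    eng.apply_deafferentation(deaff_mask, cfg.trauma.deaff_rate_factor)

    # HSP evolution to steady state: PY rate near target for consecutive windows
    t0 = time.time()
    converged = False
    ok_windows = 0
    elapsed_s = 0.0
    while elapsed_s < rc.hsp_max_s:
        res = eng.run(rc.steady_window_s * 1000.0, hsp_active=True)
        elapsed_s += rc.steady_window_s
        if abs(res["py_rate_hz"] - cfg.hsp.r_target) <= rc.steady_tol_hz:
            ok_windows += 1
            if ok_windows >= rc.steady_windows:
                converged = True
                break
        else:
            ok_windows = 0
    phases["hsp"] = time.time() - t0
    hsp_sim_s = elapsed_s

    # measurement window
    t0 = time.time()
    t_meas_start = eng.t_ms
    res = eng.run(rc.measure_ms, record=True, hsp_active=True)
    phases["measure"] = time.time() - t0
    spikes: SpikeData = res["spikes"]

    # analysis
    region = analysis.sampling_region(cfg.trauma.pattern, network)
    counts = analysis.bin_raster(
        spikes.times_ms - t_meas_start,
        spikes.ids,
        cfg.burst.bin_ms,
        region.neuron_indices,
        total_time_ms=rc.measure_ms,
    )
    events = analysis.detect_bursts(counts, cfg.burst)
    metrics = {
        "py_rate_hz": res["py_rate_hz"],
        "in_rate_hz": res["in_rate_hz"],
        "n_bursts": len(events),
        "burst_rate_hz": analysis.burst_rate(events, rc.measure_ms),
        "hsp_sim_s": hsp_sim_s,
        "wall_s": time.time() - t_wall,
    }
    metrics.update(
        analysis.intra_burst_stats(events, cfg.burst, region.neuron_indices, network.is_inh)
    )
    metrics.update(_scaling_stats(eng, deaff_mask))

    record = RunRecord(
        config_hash=config_hash(cfg),
        seed=rc.seed,
        phase_durations_s=phases,
        metrics=metrics,
        hsp_converged=converged,
    )
    if rc.out_dir:
        out = Path(rc.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(serialize(cfg))
        summary = {
            "config_hash": record.config_hash,
            "seed": rc.seed,
            "hsp_converged": converged,
            "metrics": metrics,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        record.output_paths["summary"] = str(out / "summary.json")
        if rc.write_raster:
            pd.DataFrame(
                {"time_ms": spikes.times_ms - t_meas_start, "neuron_index": spikes.ids}
            ).to_csv(out / "raster.csv", index=False)
            record.output_paths["raster"] = str(out / "raster.csv")
    if keep_spikes:
        record.spikes = SpikeData(spikes.times_ms - t_meas_start, spikes.ids)
    if keep_engine:
        record.engine = eng
    return record


def set_path(cfg: FullConfig, path: str, value: Any) -> FullConfig:
    """Return a config with the dotted field ``path`` (e.g. ``trauma.f_d``)
    replaced by ``value``."""
    head, _, rest = path.partition(".")
    section = getattr(cfg, head)
    if not rest:
        return dataclasses.replace(cfg, **{head: value})
    new_section = (
        set_path(section, rest, value)
        if "." in rest
        else dataclasses.replace(section, **{rest: value})
    )
    return dataclasses.replace(cfg, **{head: new_section})


@dataclass(frozen=True)
class ExperimentSpec:
    """A sweep: base config, axes of dotted paths to value lists, replicates."""

    base: FullConfig = field(default_factory=FullConfig)
    axes: tuple = ()  # tuple of (dotted_path, tuple_of_values)
    replicates: int = 3
    seed: int = 0
    out_dir: str | None = None


def sweep(spec: ExperimentSpec, keep_spikes: bool = False) -> pd.DataFrame:
    """Run the full grid; one row per (point, replicate) with all metrics.

    Individual point failures are isolated: the row records the error and the
    remaining points still run.
    """
    names = [a[0] for a in spec.axes]
    grids = [a[1] for a in spec.axes]
    rows = []
    ss = np.random.SeedSequence(spec.seed)
    for values in product(*grids) if grids else [()]:
        for rep in range(spec.replicates):
            run_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))
            row = dict(zip(names, values))
            row["replicate"] = rep
            row["seed"] = run_seed
            try:
                cfg = spec.base
                for name, value in zip(names, values):
                    cfg = set_path(cfg, name, value)
                cfg = set_path(cfg, "run.seed", run_seed)
                rec = run_simulation(cfg, keep_spikes=keep_spikes)
                row.update(rec.metrics)
                row["hsp_converged"] = rec.hsp_converged
                row["error"] = ""
            except Exception as exc:  # noqa: BLE001 - isolate point failures
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    table = pd.DataFrame(rows)
    if spec.out_dir:
        out = Path(spec.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "sweep.csv", index=False)
    return table
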