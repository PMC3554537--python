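"""Burst detection and spatial statistics of simulated spike rasters.

A *paroxysmal burst* — the model analogue of an interictal epileptiform
discharge — is detected on a subset of recorded neurons by partitioning time
into non-overlapping 100-ms bins and flagging every bin in which (a) at least
a fraction ``f_min`` of the recorded neurons fired and (b) those active
neurons fired at a mean rate above ``r_min``.  Consecutive supra-threshold
bins are merged into a single event so the burst rate does not scale with
burst duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .netgen import Network, footprint_sites

__all__ = [
    "BurstCriteria",
    "BurstEvent",
    "SamplingRegion",
    "bin_raster",
    "detect_bursts",
    "burst_rate",
    "intra_burst_stats",
    "cross_covariance",
    "boundary_neurons",
    "sampling_region",
    "spatial_rate_profile",
    "rate_map",
    "sever_boundary_connections",
]


@dataclass(frozen=True)
class BurstCriteria:
    bin_ms: float = 100.0
    f_min: float = 0.5  # minimal active fraction of recorded neurons
    r_min: float = 15.0  # Hz, minimal mean rate of the active neurons
    merge_adjacent: bool = True

    def __post_init__(self) -> None:
        if self.bin_ms <= 0:
            raise ValueError("bin_ms must be > 0")
        if not 0.0 < self.f_min <= 1.0:
            raise ValueError("f_min must be in (0, 1]")
        if self.r_min < 0:
            raise ValueError("r_min must be >= 0")


@dataclass
class BurstEvent:
    start_bin: int
    end_bin: int  # inclusive
    participants: np.ndarray  # indices into the recorded set
    spike_counts: np.ndarray  # per-participant spike count over the event

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin + 1


@dataclass(frozen=True)
class SamplingRegion:
    """Recorded neuron subset used for burst detection."""

    pattern: str
    neuron_indices: np.ndarray = field(repr=False)

    @property
    def size(self) -> int:
        return self.neuron_indices.size


def bin_raster(
    spike_times_ms: np.ndarray,
    spike_ids: np.ndarray,
    bin_ms: float,
    recorded: np.ndarray,
    total_time_ms: float | None = None,
) -> np.ndarray:
    """Spike-count matrix ``counts[neuron, bin]`` over the recorded subset.

    Bins are left-closed, ``[t, t + bin_ms)``; spikes from neurons outside the
    recorded set are ignored.
    """
    spike_times_ms = np.asarray(spike_times_ms, dtype=float)
    spike_ids = np.asarray(spike_ids)
    recorded = np.asarray(recorded)
    if total_time_ms is None:
        total_time_ms = float(spike_times_ms.max()) + bin_ms if spike_times_ms.size else bin_ms
    n_bins = int(np.ceil(total_time_ms / bin_ms))
    row = np.full(int(spike_ids.max(initial=0)) + int(recorded.max(initial=0)) + 1, -1, np.int64)
    row[recorded] = np.arange(recorded.size)
    rows = row[spike_ids]
    keep = (rows >= 0) & (spike_times_ms < n_bins * bin_ms)
    cols = (spike_times_ms[keep] // bin_ms).astype(np.int64)
    counts = np.zeros((recorded.size, n_bins), dtype=np.int64)
    np.add.at(counts, (rows[keep], cols), 1)
    return counts


def detect_bursts(counts: np.ndarray, criteria: BurstCriteria) -> list[BurstEvent]:
    """Detect paroxysmal bursts from a binned spike-count matrix.

    A bin is supra-threshold iff the fraction of recorded neurons with at
    least one spike is >= ``f_min`` *and* the mean firing rate of those active
    neurons (count / bin duration) exceeds ``r_min``.
    """
    n_rec, n_bins = counts.shape
    active = counts > 0
    frac = active.sum(axis=0) / n_rec
    with np.errstate(invalid="ignore"):
        mean_rate = np.where(
            active.any(axis=0),
            counts.sum(axis=0) / np.maximum(active.sum(axis=0), 1) / (criteria.bin_ms / 1000.0),
            0.0,
        )
    supra = (frac >= criteria.f_min) & (mean_rate > criteria.r_min)

    events: list[BurstEvent] = []
    k = 0
    while k < n_bins:
        if not supra[k]:
            k += 1
            continue
        start = k
        if criteria.merge_adjacent:
            while k + 1 < n_bins and supra[k + 1]:
                k += 1
        end = k
        seg = counts[:, start : end + 1].sum(axis=1)
        participants = np.flatnonzero(seg > 0)
        events.append(
            BurstEvent(
                start_bin=start,
                end_bin=end,
                participants=participants,
                spike_counts=seg[participants],
            )
        )
        k += 1
    return events


def burst_rate(events: list[BurstEvent], total_time_ms: float) -> float:
    """Events per second of recorded time."""
    if total_time_ms <= 0:
        raise ValueError("total_time_ms must be > 0")
    return len(events) / (total_time_ms / 1000.0)


def intra_burst_stats(
    events: list[BurstEvent],
    criteria: BurstCriteria,
    recorded: np.ndarray,
    is_inh: np.ndarray,
) -> dict:
    """Mean spikes and mean firing rate per participating neuron per burst,
    separately for PY and IN neurons.  Silent recorded neurons do not dilute
    the averages.  Returns NaNs (flagged) when there are no events."""
    out = {"n_bursts": len(events)}
    rec_inh = np.asarray(is_inh)[np.asarray(recorded)]
    for label, want_inh in (("py", False), ("in", True)):
        spikes, rates = [], []
        for ev in events:
            sel = rec_inh[ev.participants] == want_inh
            if sel.any():
                c = ev.spike_counts[sel]
                spikes.append(c.mean())
                rates.append(c.mean() / (ev.n_bins * criteria.bin_ms / 1000.0))
        out[f"spikes_per_neuron_{label}"] = float(np.mean(spikes)) if spikes else float("nan")
        out[f"rate_per_neuron_{label}"] = float(np.mean(rates)) if rates else float("nan")
    return out


def cross_covariance(
    counts: np.ndarray,
    pairs: np.ndarray,
    max_lag: int = 10,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pair-averaged normalized cross-covariance of binned spike counts.

    For each (i, j) pair the mean-subtracted count vectors are correlated at
    lags ``-max_lag..max_lag`` and normalized by the product of the two
    standard deviations (correlation-coefficient convention, so a train with
    itself gives exactly 1 at lag 0).  Zero-variance trains are skipped.
    Returns ``(lags, mean curve, n_pairs_used)``.
    """
    counts = np.asarray(counts, dtype=float)
    n_bins = counts.shape[1]
    lags = np.arange(-max_lag, max_lag + 1)
    x = counts - counts.mean(axis=1, keepdims=True)
    sd = counts.std(axis=1)
    acc = np.zeros(lags.size)
    used = 0
    for i, j in pairs:
        if sd[i] == 0 or sd[j] == 0:
            continue
        full = np.correlate(x[i], x[j], mode="full") / n_bins  # lag = j leads negative
        mid = n_bins - 1
        acc += full[mid - max_lag : mid + max_lag + 1] / (sd[i] * sd[j])
        used += 1
    if used == 0:
        return lags, np.full(lags.size, np.nan), 0
    return lags, acc / used, used


def boundary_neurons(network: Network, deaff_mask: np.ndarray) -> np.ndarray:
    """Intact neurons within one synaptic footprint of a *boundary*
    deafferented neuron (a deafferented neuron with at least one intact
    neuron inside its own footprint)."""
    deaff_mask = np.asarray(deaff_mask, dtype=bool)
    side, half = network.side, network.config.footprint_half
    coords = network.coords

    # boundary deafferented neurons: deafferented with an intact neuron
    # inside their own footprint
    boundary_deaff = np.zeros(network.n_neurons, dtype=bool)
    for i in np.flatnonzero(deaff_mask):
        sites = footprint_sites(tuple(coords[i]), half, side)
        if np.any(~deaff_mask[sites[:, 0] * side + sites[:, 1]]):
            boundary_deaff[i] = True

    # intact neurons whose footprint contains a boundary deafferented neuron
    # (footprints are asymmetric, so membership is tested from the intact side)
    result = []
    for i in np.flatnonzero(~deaff_mask):
        sites = footprint_sites(tuple(coords[i]), half, side)
        if np.any(boundary_deaff[sites[:, 0] * side + sites[:, 1]]):
            result.append(i)
    return np.array(result, dtype=np.int64)


def sampling_region(
    pattern: str,
    network: Network,
    block: int = 20,
    n_lines: int = 5,
) -> SamplingRegion:
    """Recorded subset for burst detection.

    Focal: ``n_lines`` adjacent full rows centered on the lattice midline,
    spanning the lattice perpendicular to the trauma boundary (the axis along
    which bursts propagate).  Diffuse: a centered ``block x block`` square.
    """
    side = network.side
    coords = network.coords
    if pattern == "focal":
        if n_lines > side:
            raise ValueError("sampling region exceeds lattice")
        r0 = (side - n_lines) // 2
        mask = (coords[:, 0] >= r0) & (coords[:, 0] < r0 + n_lines)
    elif pattern == "diffuse":
        if block > side:
            raise ValueError("sampling region exceeds lattice")
        lo = (side - block) // 2
        mask = (
            (coords[:, 0] >= lo)
            & (coords[:, 0] < lo + block)
            & (coords[:, 1] >= lo)
            & (coords[:, 1] < lo + block)
        )
    else:
        raise ValueError("pattern must be 'focal' or 'diffuse'")
    return SamplingRegion(pattern=pattern, neuron_indices=np.flatnonzero(mask))


def spatial_rate_profile(
    spike_times_ms: np.ndarray,
    spike_ids: np.ndarray,
    network: Network,
    total_time_ms: float,
    strip_half_width: int = 5,
) -> np.ndarray:
    """Mean PY firing rate (Hz) vs column position along the trauma axis.

    PY neurons inside the center-symmetric horizontal strip (rows within
    ``strip_half_width`` of the midline) are averaged per column; the profile
    length equals the lattice side.
    """
    side = network.side
    coords = network.coords
    mid = side / 2.0
    in_strip = (np.abs(coords[:, 0] + 0.5 - mid) <= strip_half_width) & ~network.is_inh
    counts = np.bincount(np.asarray(spike_ids), minlength=network.n_neurons).astype(float)
    rates = counts / (total_time_ms / 1000.0)
    profile = np.full(side, np.nan)
    for c in range(side):
        sel = in_strip & (coords[:, 1] == c)
        if sel.any():
            profile[c] = rates[sel].mean()
    return profile


def rate_map(
    spike_times_ms: np.ndarray,
    spike_ids: np.ndarray,
    network: Network,
    total_time_ms: float,
) -> np.ndarray:
    """2D time-averaged firing-rate map (Hz) over the lattice."""
    counts = np.bincount(np.asarray(spike_ids), minlength=network.n_neurons).astype(float)
    return (counts / (total_time_ms / 1000.0)).reshape(network.side, network.side)


def sever_boundary_connections(network: Network, deaff_mask: np.ndarray) -> Network:
    """Remove every synapse whose pre and post neurons differ in
    deafferentation status (both directions); within-group synapses are kept."""
    deaff_mask = np.asarray(deaff_mask, dtype=bool)
    keep = deaff_mask[network.pre] == deaff_mask[network.post]
    return network.with_synapses(network.pre[keep], network.post[keep], network.kind[keep])
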