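"""Deafferentation trauma, firing-rate estimation, homeostatic synaptic
plasticity (HSP) schemes, and microdomain partitioning of synaptic input.

Trauma is modeled as deafferentation: a fraction ``f_d`` of neurons (PY and
IN alike; the "trauma volume") has its afferent Poisson rate multiplied by
``deaff_rate_factor`` (default 0.1, i.e. 100 Hz -> 10 Hz).  *Focal* trauma
deafferents a contiguous block of whole lattice columns anchored at the left
edge; *diffuse* trauma deafferents a uniform random subset.

HSP multiplies the initial peak conductance of every synapse onto a PY neuron
by a scaling factor ``s``.  For glutamatergic (AMPA + NMDA) conductances

    ds/dt = kappa [ max(0, 1 - u/r_t) - max(0, v/r_t - 1) ]

and for GABA conductances the same expression with opposite sign.  The
upregulating drive ``u`` is the mean firing rate of the presynaptic PY
partners of the synapse's microdomain (the glia/TNF-alpha-like arm, local to
each astrocytic microdomain) and the downregulating drive ``v`` is the
postsynaptic neuron's own rate.  Four schemes vary these drives:

========================  =======================  =====================
scheme                    u (up)                   v (down)
========================  =======================  =====================
``local``                 domain presynaptic mean  postsynaptic rate
``global``                global PY mean           global PY mean
``global_up_local_down``  global PY mean           postsynaptic rate
``global_up_no_down``     global PY mean           (term dropped)
========================  =======================  =====================

Each PY neuron's incoming synapses are exactly partitioned into ``M``
microdomains, either at random (round-robin over a shuffled order, sizes
differing by at most one) or *segregated* into two domains keyed by the
presynaptic neuron's deafferentation status.  A domain with no glutamatergic
synapse has no activity to sense and is frozen (inactive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .netgen import Network

__all__ = [
    "TraumaConfig",
    "HSPConfig",
    "MicrodomainMap",
    "RateEstimate",
    "apply_trauma",
    "estimate_rates",
    "partition_random",
    "partition_segregated",
    "domain_presyn_means",
    "hsp_step",
    "scaling_percentage",
    "SCHEMES",
]

SCHEMES = ("local", "global", "global_up_local_down", "global_up_no_down")


@dataclass(frozen=True)
class TraumaConfig:
    pattern: str = "focal"  # "focal" | "diffuse"
    f_d: float = 0.5  # trauma volume: fraction of deafferented neurons
    deaff_rate_factor: float = 0.1  # afferent-rate multiplier when deafferented
    sever_boundary: bool = False  # control: cut all intact<->deafferented synapses
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in ("focal", "diffuse"):
            raise ValueError("pattern must be 'focal' or 'diffuse'")
        if not 0.0 <= self.f_d <= 1.0:
            raise ValueError("f_d must be in [0, 1]")
        if not 0.0 <= self.deaff_rate_factor <= 1.0:
            raise ValueError("deaff_rate_factor must be in [0, 1]")


@dataclass(frozen=True)
class HSPConfig:
    scheme: str = "local"
    kappa: float = 0.1  # 1/s, convergence rate (accelerated for desk-scale runs)
    r_target: float = 5.0  # Hz, target PY firing rate
    tau_rate: float = 1.0  # s, rate-estimator time constant
    s_min: float = 0.0
    s_max: float = 5.0
    M: int = 1  # microdomains per PY neuron
    segregated: bool = False  # two-domain intact/deafferented partition
    dt_hsp_ms: float = 100.0  # update cadence of the scaling factors

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.r_target <= 0:
            raise ValueError("r_target must be > 0")
        if self.tau_rate <= 0:
            raise ValueError("tau_rate must be > 0")
        if not self.s_min <= 1.0 <= self.s_max:
            raise ValueError("s bounds must bracket the initial value 1")
        if self.M < 1:
            raise ValueError("M must be >= 1")


@dataclass
class MicrodomainMap:
    """Exact partition of every PY neuron's incoming synapses into domains.

    ``syn_domain[k]`` is the global domain index of synapse ``k`` (-1 for
    synapses onto IN neurons, which are never scaled).  ``domain_post`` gives
    each domain's postsynaptic neuron and ``active`` flags domains holding at
    least one glutamatergic synapse.  ``pre_indptr``/``pre_indices`` list each
    domain's *unique* presynaptic PY neurons (CSR layout) for the presynaptic
    rate average.
    """

    n_domains: int
    syn_domain: np.ndarray  # (n_syn,) int64
    domain_post: np.ndarray  # (n_domains,) int64
    active: np.ndarray  # (n_domains,) bool
    pre_indptr: np.ndarray  # (n_domains + 1,) int64
    pre_indices: np.ndarray  # unique presynaptic PY neurons, concatenated

    def domain_sizes(self) -> np.ndarray:
        return np.bincount(self.syn_domain[self.syn_domain >= 0], minlength=self.n_domains)

    def synapses_in_domain(self, domain: int) -> np.ndarray:
        return np.flatnonzero(self.syn_domain == domain)


def apply_trauma(network: Network, config: TraumaConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Boolean mask of deafferented neurons.

    Focal: the smallest left-anchored block of whole columns holding at least
    ``ceil(f_d * N)`` neurons.  Diffuse: a uniform random subset of exactly
    ``ceil(f_d * N)`` neurons.  Both PY and IN neurons are included.
    """
    n = network.n_neurons
    n_deaff = int(np.ceil(config.f_d * n))
    mask = np.zeros(n, dtype=bool)
    if n_deaff == 0:
        return mask
    if config.pattern == "focal":
        side = network.side
        n_cols = int(np.ceil(n_deaff / side))
        mask = network.coords[:, 1] < n_cols
    else:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        mask[rng.choice(n, size=n_deaff, replace=False)] = True
    return mask


@dataclass
class RateEstimate:
    """Per-neuron firing-rate estimates (Hz) plus derived averages."""

    r: np.ndarray  # (N,)
    py_mask: np.ndarray  # (N,) bool, True for PY neurons

    @property
    def r_glob(self) -> float:
        """Global PY-mean firing rate."""
        return float(self.r[self.py_mask].mean())


def estimate_rates(
    spike_times_ms: np.ndarray,
    spike_ids: np.ndarray,
    n_neurons: int,
    py_mask: np.ndarray,
    tau_rate_s: float = 2.0,
    dt_ms: float = 100.0,
    t_end_ms: float | None = None,
    r0: np.ndarray | None = None,
) -> RateEstimate:
    """Exponential-moving-average firing-rate estimator.

    The rate trace ``r_i`` decays as ``exp(-dt/tau)`` per step of ``dt_ms``
    and jumps by ``1000/tau_ms`` per spike, so for a stationary train it is an
    unbiased estimate of the rate in Hz.  Returns the estimate at ``t_end_ms``
    (default: last spike time rounded up to a step).
    """
    if tau_rate_s <= 0:
        raise ValueError("tau_rate must be > 0")
    tau_ms = tau_rate_s * 1000.0
    spike_times_ms = np.asarray(spike_times_ms, dtype=float)
    spike_ids = np.asarray(spike_ids)
    if t_end_ms is None:
        t_end_ms = float(spike_times_ms.max()) if spike_times_ms.size else dt_ms
    n_steps = int(np.ceil(t_end_ms / dt_ms))
    r = np.zeros(n_neurons) if r0 is None else np.array(r0, dtype=float)
    decay = np.exp(-dt_ms / tau_ms)
    bins = np.minimum((spike_times_ms // dt_ms).astype(np.int64), n_steps - 1)
    order = np.argsort(bins, kind="stable")
    bins, ids = bins[order], spike_ids[order]
    boundaries = np.searchsorted(bins, np.arange(n_steps + 1))
    for k in range(n_steps):
        r *= decay
        lo, hi = boundaries[k], boundaries[k + 1]
        if hi > lo:
            np.add.at(r, ids[lo:hi], 1000.0 / tau_ms)
    return RateEstimate(r=r, py_mask=np.asarray(py_mask, dtype=bool))


def _build_map(network: Network, dom_of_syn: np.ndarray, n_domains: int, domain_post: np.ndarray) -> MicrodomainMap:
    glut = ~network.is_inh[network.pre]
    active = np.zeros(n_domains, dtype=bool)
    valid = dom_of_syn >= 0
    np.logical_or.at(active, dom_of_syn[valid & glut], True)

    # unique presynaptic PY neurons per domain, CSR
    sel = valid & glut
    doms, pres = dom_of_syn[sel], network.pre[sel]
    pairs = np.unique(np.column_stack([doms, pres]), axis=0) if doms.size else np.empty((0, 2), np.int64)
    counts = np.bincount(pairs[:, 0], minlength=n_domains) if pairs.size else np.zeros(n_domains, int)
    indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    return MicrodomainMap(
        n_domains=n_domains,
        syn_domain=dom_of_syn,
        domain_post=domain_post,
        active=active,
        pre_indptr=indptr,
        pre_indices=pairs[:, 1].astype(np.int64),
    )


def partition_random(network: Network, M: int, rng: np.random.Generator) -> MicrodomainMap:
    """Randomly and equally partition each PY neuron's incoming synapses into
    ``M`` microdomains (shuffle, then deal round-robin; sizes differ by <= 1)."""
    if M < 1:
        raise ValueError("M must be >= 1")
    n_syn = network.n_synapses
    dom_of_syn = np.full(n_syn, -1, dtype=np.int64)
    py = network.py_indices
    base = {int(p): i * M for i, p in enumerate(py)}
    domain_post = np.repeat(py, M)
    post_is_py = ~network.is_inh[network.post]
    syn_by_post = np.argsort(network.post[post_is_py], kind="stable")
    syn_idx_all = np.flatnonzero(post_is_py)[syn_by_post]
    posts_sorted = network.post[syn_idx_all]
    starts = np.searchsorted(posts_sorted, py)
    ends = np.searchsorted(posts_sorted, py, side="right")
    for p, lo, hi in zip(py, starts, ends):
        syns = syn_idx_all[lo:hi].copy()
        rng.shuffle(syns)
        dom_of_syn[syns] = base[int(p)] + np.arange(syns.size) % M
    return _build_map(network, dom_of_syn, len(py) * M, domain_post)


def partition_segregated(network: Network, deaff_mask: np.ndarray) -> MicrodomainMap:
    """Two microdomains per PY neuron keyed by presynaptic deafferentation
    status: domain 0 holds synapses from intact presynaptic neurons, domain 1
    those from deafferented ones.  Empty domains are allowed (inactive)."""
    deaff_mask = np.asarray(deaff_mask, dtype=bool)
    n_syn = network.n_synapses
    dom_of_syn = np.full(n_syn, -1, dtype=np.int64)
    py = network.py_indices
    post_rank = np.full(network.n_neurons, -1, dtype=np.int64)
    post_rank[py] = np.arange(py.size)
    onto_py = post_rank[network.post] >= 0
    dom_of_syn[onto_py] = 2 * post_rank[network.post[onto_py]] + deaff_mask[
        network.pre[onto_py]
    ].astype(np.int64)
    domain_post = np.repeat(py, 2)
    return _build_map(network, dom_of_syn, 2 * py.size, domain_post)


def domain_presyn_means(rates: RateEstimate, dmap: MicrodomainMap) -> np.ndarray:
    """Per-domain mean firing rate over the domain's unique presynaptic PY
    neurons (each partner weighted equally); NaN where a domain has none."""
    counts = np.diff(dmap.pre_indptr)
    sums = np.zeros(dmap.n_domains)
    dom_of_pre = np.repeat(np.arange(dmap.n_domains), counts)
    np.add.at(sums, dom_of_pre, rates.r[dmap.pre_indices])
    out = np.full(dmap.n_domains, np.nan)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    return out


def hsp_step(
    s_exc: np.ndarray,
    s_gaba: np.ndarray,
    rates: RateEstimate,
    config: HSPConfig,
    dmap: MicrodomainMap,
    dt_s: float,
) -> dict:
    """Advance the per-domain scaling factors by ``dt_s`` seconds (in place).

    Returns a diagnostics dict with the number of bound-clipping events.
    Inactive domains are frozen; HSP applies only to synapses onto PY neurons
    (by construction of the microdomain map).
    """
    rt = config.r_target
    if config.scheme == "local":
        u = domain_presyn_means(rates, dmap)
        v = rates.r[dmap.domain_post]
    elif config.scheme == "global":
        u = np.full(dmap.n_domains, rates.r_glob)
        v = np.full(dmap.n_domains, rates.r_glob)
    elif config.scheme == "global_up_local_down":
        u = np.full(dmap.n_domains, rates.r_glob)
        v = rates.r[dmap.domain_post]
    elif config.scheme == "global_up_no_down":
        u = np.full(dmap.n_domains, rates.r_glob)
        v = None
    else:  # pragma: no cover
        raise ValueError(config.scheme)

    drive = np.maximum(0.0, 1.0 - u / rt)
    if v is not None:
        drive = drive - np.maximum(0.0, v / rt - 1.0)
    drive = np.where(dmap.active, np.nan_to_num(drive), 0.0)

    clipped = 0
    for s, sign in ((s_exc, 1.0), (s_gaba, -1.0)):
        new = s + sign * config.kappa * drive * dt_s
        lo, hi = new < config.s_min, new > config.s_max
        clipped += int(lo.sum() + hi.sum())
        np.clip(new, config.s_min, config.s_max, out=s)
    return {"clipped": clipped}


def scaling_percentage(g: np.ndarray | float, g_intact: np.ndarray | float) -> np.ndarray | float:
    """Percent change of a conductance relative to its intact-model value."""
    g_intact = np.asarray(g_intact, dtype=float)
    if np.any(g_intact <= 0):
        raise ValueError("intact conductance must be > 0")
    return 100.0 * (np.asarray(g, dtype=float) - g_intact) / g_intact
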