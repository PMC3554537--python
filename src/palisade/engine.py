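"""Vectorized network integration kernel.

The per-synapse dynamics of :mod:`palisade.synapse` are linear exponential
decays with kind-wise time constants, so the network state can be held as
per-neuron *summed* conductance traces (AMPA, NMDA fast/slow, GABA, afferent)
that decay with precomputed factors and receive increments when a presynaptic
neuron spikes.  Short-term depression depends only on the presynaptic spike
train and is therefore one variable per presynaptic neuron.  Homeostatic
scaling factors live per (PY neuron, microdomain) with separate glutamatergic
and GABAergic channels; the kernel reads them, and
:func:`palisade.trauma_hsp.hsp_step` updates them between kernel calls at the
HSP cadence.

The inner loop is compiled with numba; equivalence with the reference
single-synapse / single-neuron operations is covered by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .netgen import IN_IN, IN_PY, PY_IN, PY_PY, LatticeConfig, Network, build_network
from .neurodyn import resting_state
from .params import SimParams
from .synapse import nmda_norm
from .trauma_hsp import (
    HSPConfig,
    MicrodomainMap,
    RateEstimate,
    hsp_step,
    partition_random,
)

__all__ = ["NetworkEngine", "SpikeData", "measure_intact_rates"]


@dataclass
class SpikeData:
    """Spike raster: parallel arrays of times (ms) and neuron indices."""

    times_ms: np.ndarray
    ids: np.ndarray

    @property
    def n_spikes(self) -> int:
        return self.times_ms.size

    def concat(self, other: "SpikeData") -> "SpikeData":
        return SpikeData(
            np.concatenate([self.times_ms, other.times_ms]),
            np.concatenate([self.ids, other.ids]),
        )


@njit(cache=True)
def _seed_rng(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True, fastmath=True)
def _run_chunk(
    n_steps,
    dt,
    t0,
    # neuron state
    V,
    w,
    z,
    latch,
    # conductance traces and per-pre depression
    gA,
    gG,
    xf,
    xs,
    gaff,
    D,
    r_ema,
    counts,
    # gating lookup tables on the voltage grid [v_min, v_max]
    v_min,
    inv_dv,
    m_inf_tab,
    w_inf_tab,
    w_dec_tab,
    # membrane scalars
    C,
    gNa,
    gK,
    gL,
    ENa,
    EK,
    EL,
    Vth,
    # adaptation
    gAHP,
    dec_z,
    delta_z,
    # synapse scalars
    decA,
    decG,
    decF,
    decS,
    decD,
    decAff,
    d_depr,
    E_exc,
    E_GABA,
    E_aff,
    nnorm,
    g_pp,
    g_ip,
    g_pi,
    g_ii,
    # rate estimator
    dec_r,
    rate_bump,
    # connectivity (CSR by presynaptic neuron)
    indptr,
    syn_post,
    syn_kind,
    syn_domain,
    # homeostatic scaling per domain
    s_exc,
    s_gaba,
    # per-neuron drive
    is_inh,
    aff_rate_ms,
    aff_next_t,
    ghat_aff,
    # recording
    record,
    spike_t,
    spike_i,
):
    n = V.size
    n_rec = 0
    cap = spike_t.size
    n_tab = m_inf_tab.size
    for step in range(n_steps):
        t = t0 + (step + 1) * dt
        for i in range(n):
            # afferent Poisson drive: next-event sampling
            while aff_next_t[i] <= t:
                gaff[i] += ghat_aff[i]
                aff_next_t[i] += -np.log(1.0 - np.random.random()) / aff_rate_ms[i]
            # decay conductance traces, depression recovery, rate estimator
            gA[i] *= decA
            gG[i] *= decG
            xf[i] *= decF
            xs[i] *= decS
            gaff[i] *= decAff
            D[i] = 1.0 - (1.0 - D[i]) * decD
            r_ema[i] *= dec_r

            Vi = V[i]
            # linear interpolation into the gating tables
            x = (Vi - v_min) * inv_dv
            if x < 0.0:
                x = 0.0
            elif x > n_tab - 2:
                x = float(n_tab - 2)
            k0 = int(x)
            frac = x - k0
            m_inf = m_inf_tab[k0] + frac * (m_inf_tab[k0 + 1] - m_inf_tab[k0])
            w_inf = w_inf_tab[k0] + frac * (w_inf_tab[k0 + 1] - w_inf_tab[k0])
            w_dec = w_dec_tab[k0] + frac * (w_dec_tab[k0 + 1] - w_dec_tab[k0])
            I_ion = (
                gNa * m_inf * (Vi - ENa)
                + gK * w[i] * (Vi - EK)
                + gL * (Vi - EL)
                + gAHP[i] * z[i] * (Vi - EK)
            )
            I_syn = (
                (gA[i] + xs[i] - xf[i]) * (Vi - E_exc)
                + gG[i] * (Vi - E_GABA)
                + gaff[i] * (Vi - E_aff)
            )
            Vn = Vi + dt * (-(I_ion + I_syn) / C)
            if not np.isfinite(Vn):
                return n_rec, 1, t
            w[i] = w_inf + (w[i] - w_inf) * w_dec
            z[i] *= dec_z
            above = Vn >= Vth
            spiked = above and not latch[i]
            latch[i] = above
            V[i] = Vn
            if spiked:
                counts[i] += 1
                r_ema[i] += rate_bump
                if record:
                    if n_rec < cap:
                        spike_t[n_rec] = t
                        spike_i[n_rec] = i
                        n_rec += 1
                    else:
                        return n_rec, 2, t
                inhib = is_inh[i]
                if not inhib:
                    z[i] = min(1.0, z[i] + delta_z)
                    Deff = D[i]
                else:
                    Deff = 1.0
                for k in range(indptr[i], indptr[i + 1]):
                    p = syn_post[k]
                    kind = syn_kind[k]
                    if kind == 0:  # PY->PY: AMPA + NMDA, depressed, HSP-scaled
                        amp = g_pp * s_exc[syn_domain[k]] * Deff
                        gA[p] += amp
                        inc = amp * nnorm
                        xf[p] += inc
                        xs[p] += inc
                    elif kind == 1:  # IN->PY: GABA, HSP-scaled, no depression
                        gG[p] += g_ip * s_gaba[syn_domain[k]]
                    elif kind == 2:  # PY->IN: AMPA, depressed, not scaled
                        gA[p] += g_pi * Deff
                    else:  # IN->IN
                        gG[p] += g_ii
                if not inhib:
                    D[i] *= 1.0 - d_depr
    return n_rec, 0, t0 + n_steps * dt


class NetworkEngine:
    """Stateful network simulation bound to one built network.

    Drives the numba kernel in chunks; when HSP is active the chunk length is
    the HSP cadence and the scaling factors are updated between chunks from
    the kernel's exponential-moving-average rate estimates.
    """

    def __init__(
        self,
        network: Network,
        params: SimParams | None = None,
        hsp: HSPConfig | None = None,
        dmap: MicrodomainMap | None = None,
        seed: int = 0,
    ) -> None:
        self.network = network
        self.params = params or SimParams()
        self.hsp = hsp or HSPConfig()
        rng = np.random.default_rng(seed)
        if dmap is None:
            dmap = partition_random(network, self.hsp.M, rng)
        self.dmap = dmap
        self._seed_seq = np.random.SeedSequence(seed)
        self.t_ms = 0.0

        n = network.n_neurons
        p = self.params
        rest = resting_state(p.ml_py)
        self.V = np.full(n, rest.V)
        self.w = np.full(n, rest.w)
        self.z = np.zeros(n)
        self.latch = np.zeros(n, dtype=np.bool_)
        self.gA = np.zeros(n)
        self.gG = np.zeros(n)
        self.xf = np.zeros(n)
        self.xs = np.zeros(n)
        self.gaff = np.zeros(n)
        self.D = np.ones(n)
        # rate estimator initialized at the intact operating point
        self.r_ema = np.where(network.is_inh, 10.0, 5.0).astype(float)
        self.counts = np.zeros(n, dtype=np.int64)
        self.s_exc = np.ones(dmap.n_domains)
        self.s_gaba = np.ones(dmap.n_domains)
        self.is_inh = network.is_inh.astype(np.bool_)
        self.gAHP = np.where(network.is_inh, 0.0, p.adapt.g_AHP)

        # afferent drive: intact rates; apply_deafferentation() rescales
        self.aff_rate_hz = np.full(n, p.afferent.rate_hz)
        self.ghat_aff = np.where(
            network.is_inh, p.afferent.ghat_aff_in, p.afferent.ghat_aff_py
        ).astype(float)
        self.deaff_mask = np.zeros(n, dtype=bool)
        # next-event times of the per-neuron afferent Poisson processes
        self.aff_next_t = rng.exponential(
            1000.0 / np.maximum(self.aff_rate_hz, 1e-12), size=n
        )

        # CSR connectivity keyed by presynaptic neuron
        order = np.argsort(network.pre, kind="stable")
        self.syn_post = network.post[order].astype(np.int64)
        self.syn_kind = network.kind[order].astype(np.int64)
        self.syn_domain = dmap.syn_domain[order].astype(np.int64)
        self.indptr = np.searchsorted(network.pre[order], np.arange(n + 1)).astype(np.int64)

    # ------------------------------------------------------------------
    def apply_deafferentation(self, mask: np.ndarray, rate_factor: float) -> None:
        mask = np.asarray(mask, dtype=bool)
        self.deaff_mask = mask
        self.aff_rate_hz = np.where(
            mask, self.params.afferent.rate_hz * rate_factor, self.params.afferent.rate_hz
        )
        # the Poisson process is memoryless: redraw next events at the new rates
        rng = np.random.default_rng(self._next_seed())
        self.aff_next_t = self.t_ms + rng.exponential(
            1000.0 / np.maximum(self.aff_rate_hz, 1e-12), size=mask.size
        )

    def rate_estimate(self) -> RateEstimate:
        return RateEstimate(r=self.r_ema.copy(), py_mask=~self.network.is_inh)

    def _next_seed(self) -> int:
        return int(self._seed_seq.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))

    def run(
        self,
        duration_ms: float,
        record: bool = False,
        hsp_active: bool = False,
        chunk_ms: float | None = None,
    ) -> dict:
        """Advance the network by ``duration_ms``.

        Returns a dict with the per-neuron spike counts accumulated during
        this call, the mean PY/IN rates over the call, and (if ``record``)
        the spike raster.
        """
        p = self.params
        dt = p.dt_ms
        if chunk_ms is None:
            chunk_ms = self.hsp.dt_hsp_ms if hsp_active else 1000.0
        syn = p.syn
        ml = p.ml_py
        ad = p.adapt
        aff = p.afferent
        decA = np.exp(-dt / syn.tau_AMPA)
        decG = np.exp(-dt / syn.tau_GABA)
        decF = np.exp(-dt / syn.tau_NMDA_fast)
        decS = np.exp(-dt / syn.tau_NMDA_slow)
        decD = np.exp(-dt / syn.tau_D)
        decAff = np.exp(-dt / aff.tau_aff)
        dec_z = np.exp(-dt / ad.tau_z)
        tau_rate_ms = self.hsp.tau_rate * 1000.0
        dec_r = np.exp(-dt / tau_rate_ms)
        rate_bump = 1000.0 / tau_rate_ms
        nnorm = nmda_norm(syn)
        aff_rate_ms = np.maximum(self.aff_rate_hz, 1e-12) / 1000.0

        # gating lookup tables on a fine voltage grid (linear interpolation)
        v_min, v_max, dv = -120.0, 120.0, 0.05
        v_grid = np.arange(v_min, v_max + dv, dv)
        m_inf_tab = ml.m_inf(v_grid)
        w_inf_tab = ml.w_inf(v_grid)
        w_dec_tab = np.exp(-dt * ml.phi / ml.tau_w(v_grid))

        counts_before = self.counts.copy()
        all_times: list[np.ndarray] = []
        all_ids: list[np.ndarray] = []
        _seed_rng(self._next_seed())

        remaining = duration_ms
        while remaining > 1e-9:
            this_ms = min(chunk_ms, remaining)
            n_steps = int(round(this_ms / dt))
            if n_steps == 0:
                break
            cap = int(self.network.n_neurons * this_ms * 0.6) + 16 if record else 1
            spike_t = np.empty(cap, dtype=np.float64)
            spike_i = np.empty(cap, dtype=np.int64)
            n_rec, err, t_end = _run_chunk(
                n_steps, dt, self.t_ms,
                self.V, self.w, self.z, self.latch,
                self.gA, self.gG, self.xf, self.xs, self.gaff, self.D,
                self.r_ema, self.counts,
                v_min, 1.0 / dv, m_inf_tab, w_inf_tab, w_dec_tab,
                ml.C, ml.g_Na, ml.g_K, ml.g_L, ml.E_Na, ml.E_K, ml.E_L,
                ml.spike_threshold,
                self.gAHP, dec_z, ad.delta_z,
                decA, decG, decF, decS, decD, decAff, syn.d,
                syn.E_exc, syn.E_GABA, aff.E_aff, nnorm,
                syn.ghat[PY_PY], syn.ghat[IN_PY], syn.ghat[PY_IN], syn.ghat[IN_IN],
                dec_r, rate_bump,
                self.indptr, self.syn_post, self.syn_kind, self.syn_domain,
                self.s_exc, self.s_gaba,
                self.is_inh, aff_rate_ms, self.aff_next_t,
                self.ghat_aff,
                record, spike_t, spike_i,
            )
            if err == 1:
                raise FloatingPointError(
                    f"non-finite membrane potential at t={t_end:.2f} ms; reduce dt"
                )
            if err == 2:
                raise RuntimeError("spike buffer overflow (mean rate above 600 Hz)")
            if record:
                all_times.append(spike_t[:n_rec].copy())
                all_ids.append(spike_i[:n_rec].copy())
            self.t_ms = t_end
            remaining -= this_ms
            if hsp_active and self.hsp.kappa > 0:
                hsp_step(
                    self.s_exc,
                    self.s_gaba,
                    self.rate_estimate(),
                    self.hsp,
                    self.dmap,
                    this_ms / 1000.0,
                )

        delta = self.counts - counts_before
        dur_s = duration_ms / 1000.0
        py, inh = ~self.network.is_inh, self.network.is_inh
        out = {
            "counts": delta,
            "duration_ms": duration_ms,
            "py_rate_hz": float(delta[py].mean() / dur_s),
            "in_rate_hz": float(delta[inh].mean() / dur_s),
        }
        if record:
            out["spikes"] = SpikeData(
                np.concatenate(all_times) if all_times else np.empty(0),
                np.concatenate(all_ids) if all_ids else np.empty(0, dtype=np.int64),
            )
        return out


def measure_intact_rates(
    params: SimParams,
    side_length: int = 20,
    sim_time_ms: float = 10_000.0,
    settle_ms: float = 2_000.0,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean (PY, IN) firing rates of an intact default-connectivity network."""
    config = LatticeConfig(side_length=side_length, seed=seed)
    network = build_network(config)
    eng = NetworkEngine(network, params=params, seed=seed)
    eng.run(settle_ms)
    res = eng.run(sim_time_ms)
    return res["py_rate_hz"], res["in_rate_hz"]
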