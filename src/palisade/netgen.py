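"""Construction of the 2D lattice network with footprint-limited connectivity.

The cortical sheet is modeled as a ``side_length x side_length`` square lattice.
Eighty percent of sites hold pyramidal (PY) neurons and every ``in_stride``-th
site (row-major) holds an inhibitory interneuron (IN).  Each neuron may form
synapses only with peers inside its *synaptic footprint*: the ``(2a) x (2a)``
block of sites centered on it (offsets ``[-a, a-1]`` per axis, clipped at the
lattice edge; an even-sided block cannot be symmetric about a site, so this
left-heavy convention is used throughout).  Within the footprint every
candidate (pre, post) pair is connected independently with a probability that
depends on the presynaptic type; probabilities are renormalized when the
footprint is rescaled so the expected in-degree is footprint-size invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

# synapse kind codes
PY_PY, IN_PY, PY_IN, IN_IN = 0, 1, 2, 3
KIND_NAMES = {PY_PY: "PY->PY", IN_PY: "IN->PY", PY_IN: "PY->IN", IN_IN: "IN->IN"}

DEFAULT_FOOTPRINT_HALF = 5

# Back-derived defaults: an interior PY neuron at the default footprint (a=5)
# sees 79 PY and 20 IN candidate partners; p = 55/79 and 12/20 reproduce the
# target mean in-degrees of 55 excitatory and 12 inhibitory synapses.
DEFAULT_P_EXC = 55.0 / 79.0
DEFAULT_P_INH = 12.0 / 20.0


@dataclass(frozen=True)
class LatticeConfig:
    """Geometry, composition and connectivity parameters of the lattice."""

    side_length: int = 80
    in_stride: int = 5
    footprint_half: int = DEFAULT_FOOTPRINT_HALF
    p_exc: float = DEFAULT_P_EXC
    p_inh: float = DEFAULT_P_INH
    max_exc_per_py: int = 75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side_length < 2:
            raise ValueError("side_length must be >= 2")
        if self.in_stride < 2:
            raise ValueError("in_stride must be >= 2")
        if not 1 <= self.footprint_half <= self.side_length:
            raise ValueError("footprint_half must be in [1, side_length]")
        for name in ("p_exc", "p_inh"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.max_exc_per_py < 0:
            raise ValueError("max_exc_per_py must be >= 0")

    @property
    def n_neurons(self) -> int:
        return self.side_length**2


@dataclass
class Network:
    """Lattice neurons plus (optionally) a directed synapse list.

    Neuron ``i`` sits at row ``i // side``, column ``i % side``.  Synapses are
    stored as parallel arrays ``pre``, ``post``, ``kind``.
    """

    config: LatticeConfig
    is_inh: np.ndarray  # (N,) bool
    pre: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    post: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    kind: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))

    @property
    def side(self) -> int:
        return self.config.side_length

    @property
    def n_neurons(self) -> int:
        return self.is_inh.size

    @property
    def n_synapses(self) -> int:
        return self.pre.size

    @property
    def coords(self) -> np.ndarray:
        """(N, 2) array of (row, col) lattice coordinates."""
        idx = np.arange(self.n_neurons)
        return np.column_stack([idx // self.side, idx % self.side])

    @property
    def py_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.is_inh)

    @property
    def in_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_inh)

    def interior_mask(self) -> np.ndarray:
        """Neurons whose footprint is not clipped by the lattice edge."""
        a, side = self.config.footprint_half, self.side
        r, c = self.coords[:, 0], self.coords[:, 1]
        return (r >= a) & (r <= side - a) & (c >= a) & (c <= side - a)

    def with_synapses(self, pre: np.ndarray, post: np.ndarray, kind: np.ndarray) -> "Network":
        return replace(self, pre=pre, post=post, kind=kind)

    # -- serialization -------------------------------------------------------
    def neuron_table(self) -> pd.DataFrame:
        coords = self.coords
        return pd.DataFrame(
            {
                "index": np.arange(self.n_neurons),
                "x": coords[:, 1],
                "y": coords[:, 0],
                "type": np.where(self.is_inh, "IN", "PY"),
            }
        )

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pre_index": self.pre,
                "post_index": self.post,
                "kind": [KIND_NAMES[k] for k in self.kind],
            }
        )

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.neuron_table().to_csv(directory / "neurons.csv", index=False)
        self.edge_table().to_csv(directory / "edges.csv", index=False)


def build_lattice(config: LatticeConfig) -> Network:
    """Lay neurons on the lattice: site ``i`` is IN iff ``i % in_stride == in_stride - 1``."""
    idx = np.arange(config.n_neurons)
    is_inh = (idx % config.in_stride) == (config.in_stride - 1)
    return Network(config=config, is_inh=is_inh)


def footprint_sites(coord: tuple[int, int], half: int, side: int) -> np.ndarray:
    """Candidate partner coordinates of the neuron at ``coord``.

    Returns the lattice sites in the neuron-centered ``(2*half) x (2*half)``
    block (offsets ``[-half, half-1]``), clipped at the edges and excluding the
    neuron's own site, as an (n, 2) array of (row, col).
    """
    r, c = coord
    if not (0 <= r < side and 0 <= c < side):
        raise ValueError(f"coordinate {coord} not on a {side}x{side} lattice")
    r0, r1 = max(0, r - half), min(side, r + half)
    c0, c1 = max(0, c - half), min(side, c + half)
    rows, cols = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    sites = np.column_stack([rows.ravel(), cols.ravel()])
    return sites[~((sites[:, 0] == r) & (sites[:, 1] == c))]


def interior_candidate_counts(half: int, in_stride: int) -> tuple[float, float]:
    """Average (PY, IN) candidate counts inside an unclipped footprint.

    IN sites form column stripes (one column in every ``in_stride``) when the
    side length is a multiple of the stride, so a ``(2*half)``-wide window
    holds ``(2*half)**2 / in_stride`` IN sites on average.  The PY count
    excludes the neuron's own (PY) site.
    """
    block = (2 * half) ** 2
    n_in = block / in_stride
    n_py = block - n_in - 1
    return n_py, n_in


def effective_probabilities(config: LatticeConfig) -> tuple[float, float]:
    """Per-candidate probabilities after footprint-size renormalization.

    ``p_exc`` / ``p_inh`` are defined at the default footprint half-length;
    for other footprints they are rescaled by the ratio of interior candidate
    counts so the expected in-degree is unchanged.
    """
    if config.footprint_half == DEFAULT_FOOTPRINT_HALF:
        return config.p_exc, config.p_inh
    n_py_ref, n_in_ref = interior_candidate_counts(DEFAULT_FOOTPRINT_HALF, config.in_stride)
    n_py_cur, n_in_cur = interior_candidate_counts(config.footprint_half, config.in_stride)
    p_exc = config.p_exc * n_py_ref / n_py_cur
    p_inh = config.p_inh * n_in_ref / n_in_cur
    if p_exc > 1.0 or p_inh > 1.0:
        raise ValueError(
            "footprint renormalization drives a connection probability above 1 "
            f"(p_exc={p_exc:.3f}, p_inh={p_inh:.3f}); use a larger footprint"
        )
    return p_exc, p_inh


def sample_connections(network: Network, rng: np.random.Generator | None = None) -> Network:
    """Draw the directed synapse list for a built lattice.

    Every (pre, post) candidate pair inside the post neuron's footprint is
    connected independently with probability ``p_exc`` (PY pre) or ``p_inh``
    (IN pre); incoming PY->PY synapses above ``max_exc_per_py`` are randomly
    pruned down to the cap.
    """
    config = network.config
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p_exc, p_inh = effective_probabilities(config)
    side, half = config.side_length, config.footprint_half
    is_inh = network.is_inh
    n = network.n_neurons

    # vectorized over all postsynaptic neurons, one footprint offset at a time
    all_posts = np.arange(n, dtype=np.int64)
    post_r, post_c = all_posts // side, all_posts % side
    pres: list[np.ndarray] = []
    posts: list[np.ndarray] = []
    for dr in range(-half, half):
        for dc in range(-half, half):
            if dr == 0 and dc == 0:
                continue
            rr, cc = post_r + dr, post_c + dc
            valid = (rr >= 0) & (rr < side) & (cc >= 0) & (cc < side)
            cand = np.where(valid, rr * side + cc, 0)
            p = np.where(is_inh[cand], p_inh, p_exc)
            sel = valid & (rng.random(n) < p)
            pres.append(cand[sel])
            posts.append(all_posts[sel])
    pre = np.concatenate(pres)
    post = np.concatenate(posts)
    order = np.lexsort((pre, post))
    pre, post = pre[order], post[order]

    # prune incoming PY->PY synapses above the cap
    exc_onto_py = ~is_inh[pre] & ~is_inh[post]
    indeg = np.bincount(post[exc_onto_py], minlength=n)
    offenders = np.flatnonzero(indeg > config.max_exc_per_py)
    if offenders.size:
        drop = np.zeros(pre.size, dtype=bool)
        for p_idx in offenders:
            syns = np.flatnonzero(exc_onto_py & (post == p_idx))
            excess = syns.size - config.max_exc_per_py
            drop[rng.choice(syns, size=excess, replace=False)] = True
        pre, post = pre[~drop], post[~drop]
    kind = np.empty(pre.size, dtype=np.int8)
    pre_in, post_in = is_inh[pre], is_inh[post]
    kind[~pre_in & ~post_in] = PY_PY
    kind[pre_in & ~post_in] = IN_PY
    kind[~pre_in & post_in] = PY_IN
    kind[pre_in & post_in] = IN_IN
    return network.with_synapses(pre, post, kind)


def build_network(config: LatticeConfig, rng: np.random.Generator | None = None) -> Network:
    """Convenience: :func:`build_lattice` followed by :func:`sample_connections`."""
    return sample_connections(build_lattice(config), rng=rng)


def degree_stats(network: Network, subset: str = "all_py") -> dict:
    """In-degree statistics per presynaptic type for a neuron subset.

    ``subset`` is ``"all_py"`` or ``"interior_py"``.  Returns, for each of
    ``"exc"`` (PY pre) and ``"inh"`` (IN pre): mean, sd, max and a histogram
    ``(counts, bin_edges)`` of the in-degree over the subset.
    """
    if network.n_synapses == 0 and network.n_neurons == 0:
        raise ValueError("empty network")
    if subset == "all_py":
        members = network.py_indices
    elif subset == "interior_py":
        members = np.flatnonzero(~network.is_inh & network.interior_mask())
    else:
        raise ValueError(f"unknown subset {subset!r}")
    if members.size == 0:
        raise ValueError(f"subset {subset!r} is empty")

    out: dict = {"subset": subset, "n_neurons": int(members.size)}
    n = network.n_neurons
    for label, pre_is_inh in (("exc", False), ("inh", True)):
        sel = network.is_inh[network.pre] == pre_is_inh if network.n_synapses else np.empty(0, bool)
        indeg_all = np.bincount(network.post[sel], minlength=n) if sel.any() else np.zeros(n, int)
        indeg = indeg_all[members]
        hist, edges = np.histogram(indeg, bins=np.arange(indeg.max() + 2))
        out[label] = {
            "mean": float(indeg.mean()),
            "sd": float(indeg.std()),
            "max": int(indeg.max()),
            "hist": hist,
            "bin_edges": edges,
        }
    return out
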