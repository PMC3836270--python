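"""Sparse-network engine with the per-millisecond EXT -> NEUR -> SYN cycle.

The simulator is clock-driven at a fixed 1 ms resolution.  Every step runs
three phases, mirroring the state machine of the digital architecture this
package models:

EXT
    External events (weight injections from outside the network, e.g. a
    stimulation schedule or a closed-loop partner) are routed into the
    target neurons' current accumulators.
NEUR
    Every neuron's membrane is advanced with the hardware-scaled update,
    reading the currents as of the end of EXT; in the same phase all
    current accumulators decay by ``1 - 1/tau_syn`` and the depression
    level of every synapse whose presynaptic neuron did *not* spike decays
    by ``1 - 1/tau_reg``.
SYN
    For every neuron that spiked, each outgoing synapse computes its
    effective weight from the pre-update depression level, injects it into
    the postsynaptic accumulator, and deepens its depression.  Injected
    weights are therefore first seen by the membrane one step later: the
    synaptic latency is exactly one millisecond.

In-memory connectivity is adjacency lists; the flat row encoding used by
the hardware's sparse matrices (each presynaptic row terminated by the
virtual-neuron address Nn+1) is provided as an import/export format.

Neuron indices are 0-based in the API; all file formats are 1-based, with
the virtual terminator at Nn+1, matching the hardware convention.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .neuron import (
    FLOAT_MODE,
    IzhikevichParams,
    NeuronState,
    NumericMode,
    quantize,
)
from .synapse import SynapseParams, SynapseState

logger = logging.getLogger(__name__)

STEP_MS = 1  # native model resolution; the update equations assume dt = 1 ms

# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

Edge = Tuple[int, SynapseParams, SynapseState]


@dataclass
class Connectivity:
    """Adjacency lists: for each presynaptic neuron an ordered list of
    (postsynaptic index, SynapseParams, SynapseState) triples."""

    n_neurons: int
    adjacency: List[List[Edge]]

    def __post_init__(self) -> None:
        if len(self.adjacency) != self.n_neurons:
            raise ValueError(
                f"adjacency has {len(self.adjacency)} rows for {self.n_neurons} neurons"
            )
        for pre, row in enumerate(self.adjacency):
            for post, params, state in row:
                if not (0 <= post < self.n_neurons):
                    raise ValueError(
                        f"synapse {pre}->{post}: postsynaptic index out of range "
                        f"[0, {self.n_neurons - 1}]"
                    )

    @property
    def n_synapses(self) -> int:
        return sum(len(row) for row in self.adjacency)

    def edges(self) -> Iterable[Tuple[int, int, SynapseParams, SynapseState]]:
        for pre, row in enumerate(self.adjacency):
            for post, params, state in row:
                yield pre, post, params, state


@dataclass(frozen=True)
class ExternalEvent:
    """A scheduled weight injection: at step ``t`` add ``weight`` to the
    matching current accumulator of neuron ``target`` (0-based)."""

    t: int
    target: int
    weight: float

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"event time must be >= 0, got {self.t}")


@dataclass
class SpikeRaster:
    """Ordered (time_ms, neuron) spike events over a finite duration."""

    events: List[Tuple[int, int]]
    duration: int
    n_neurons: int
    traces: Optional[pd.DataFrame] = None

    def spike_times(self, neuron: int) -> List[int]:
        return [t for t, i in self.events if i == neuron]

    def counts(self) -> np.ndarray:
        c = np.zeros(self.n_neurons, dtype=int)
        for _, i in self.events:
            c[i] += 1
        return c

    def to_dataframe(self) -> pd.DataFrame:
        """1-based neuron ids, the raster CSV convention."""
        return pd.DataFrame(
            {
                "time_ms": [t for t, _ in self.events],
                "neuron_id": [i + 1 for _, i in self.events],
            }
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "SpikeRaster":
        df = pd.read_csv(path)
        for col in ("time_ms", "neuron_id"):
            if col not in df.columns:
                raise ValueError(f"raster CSV {path} lacks required column {col!r}")
        events = [(int(t), int(i) - 1) for t, i in zip(df["time_ms"], df["neuron_id"])]
        events.sort()
        n = max((i for _, i in events), default=-1) + 1
        dur = max((t for t, _ in events), default=-1) + 1
        return cls(events=events, duration=dur, n_neurons=n)

    def plot(self, path: Union[str, Path]) -> None:
        """Raster plot (one row per neuron) written to an image file."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(10, 0.5 * max(self.n_neurons, 4) + 1))
        for nid in range(self.n_neurons):
            ts = self.spike_times(nid)
            ax.vlines(np.asarray(ts) / 1000.0, nid + 0.6, nid + 1.4, lw=0.5)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("neuron")
        ax.set_ylim(0.5, self.n_neurons + 0.5)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


@dataclass
class Network:
    """A simulatable network: neurons plus sparse synaptic connectivity.

    ``inv_tau_syn`` is the per-millisecond decay rate of the per-neuron
    current accumulators (scalar, applied to both I_exc and I_inh).  The
    accumulators live on neurons — as in the hardware RAM layout, which
    stores three currents per neuron — so the decay rate is a neuron-level
    quantity; the SynapseParams field of the same name is carried through
    configs and checked for consistency at build time.
    """

    neurons: List[Tuple[IzhikevichParams, NeuronState]]
    connectivity: Connectivity
    mode: NumericMode = FLOAT_MODE
    inv_tau_syn: float = 0.01
    names: Optional[List[str]] = None
    step_ms: int = STEP_MS
    overflow_count: int = 0

    def __post_init__(self) -> None:
        if self.step_ms != STEP_MS:
            raise ValueError("the model's native resolution is fixed at 1 ms")
        if self.connectivity.n_neurons != len(self.neurons):
            raise ValueError("connectivity size does not match neuron count")

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    @property
    def n_synapses(self) -> int:
        return self.connectivity.n_synapses

    def neuron_index(self, name: str) -> int:
        if self.names is None:
            raise ValueError("network has no neuron names")
        return self.names.index(name)


# ---------------------------------------------------------------------------
# capacity model
# ---------------------------------------------------------------------------


def cycle_count(Nn: int, Ns: int) -> int:
    """Computation-core cycles needed per millisecond: 21 Nn + 10 Ns.

    10 Nn cycles for the EXT phase, 11 Nn for NEUR, 10 Ns for SYN.
    """
    if Nn < 0 or Ns < 0:
        raise ValueError("neuron and synapse counts must be non-negative")
    return 10 * Nn + 11 * Nn + 10 * Ns


def fits_capacity(Nn: int, Ns: int, Nc: int) -> bool:
    """True iff the network's cycle budget fits in Nc cycles per ms."""
    if Nc <= 0:
        raise ValueError(f"available cycles must be positive, got {Nc}")
    return cycle_count(Nn, Ns) <= Nc


# ---------------------------------------------------------------------------
# compiled array engine
# ---------------------------------------------------------------------------


class _Compiled:
    """Array view of a Network used by the stepping loop.

    Synapse arrays are ordered by (presynaptic index, adjacency position),
    and same-target injections are accumulated in that order, so results
    are bit-for-bit reproducible and independent of the sparse layout.
    """

    def __init__(self, net: Network):
        self.net = net
        self.mode = net.mode
        n = net.n_neurons
        q = self._q
        self.a = q(np.array([p.a for p, _ in net.neurons]))
        self.b = q(np.array([p.b for p, _ in net.neurons]))
        self.c = q(np.array([p.c for p, _ in net.neurons]))
        self.d = q(np.array([p.d for p, _ in net.neurons]))
        self.v_thresh = q(np.array([p.v_thresh for p, _ in net.neurons]))
        self.v = q(np.array([s.v for _, s in net.neurons]))
        self.u = q(np.array([s.u for _, s in net.neurons]))
        self.I_bias = q(np.array([s.I_bias for _, s in net.neurons]))
        self.I_exc = q(np.array([s.I_exc for _, s in net.neurons]))
        self.I_inh = q(np.array([s.I_inh for _, s in net.neurons]))
        edges = list(net.connectivity.edges())
        self.pre = np.array([e[0] for e in edges], dtype=np.intp)
        self.post = np.array([e[1] for e in edges], dtype=np.intp)
        self.W = q(np.array([e[2].W_syn for e in edges]))
        self.P = q(np.array([e[2].P for e in edges]))
        self.inv_tau_reg = q(np.array([e[2].inv_tau_reg for e in edges]))
        self.delta = q(np.array([e[3].delta for e in edges]))
        self.exc_mask = self.W > 0
        self.inh_mask = self.W < 0
        self.its = float(q(np.array([net.inv_tau_syn]))[0])
        self.overflow = 0

    # quantize an array per the network mode; counts saturation events
    def _q(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        m = self.mode
        if m.kind == "floating":
            return x
        s = m.scale
        if m.rounding_policy == "round-nearest":
            n = np.floor(x * s + 0.5)
        else:
            n = np.floor(x * s)
        lo = -(1 << (m.integer_bits + m.fraction_bits))
        hi = (1 << (m.integer_bits + m.fraction_bits)) - 1
        over = (n < lo) | (n > hi)
        if over.any():
            self.overflow += int(over.sum())
            if m.overflow_policy == "saturate":
                n = np.clip(n, lo, hi)
            else:
                span = hi - lo + 1
                n = (n - lo) % span + lo
        return n / s

    def step(self, externals: Sequence[ExternalEvent] = ()) -> np.ndarray:
        """One EXT -> NEUR -> SYN cycle; returns indices of spiking neurons."""
        q = self._q
        n = self.v.shape[0]
        # EXT: route external weight injections
        for ev in externals:
            if not (0 <= ev.target < n):
                raise IndexError(
                    f"external event targets neuron {ev.target}, network has {n}"
                )
            if ev.weight > 0:
                self.I_exc[ev.target] += ev.weight
            elif ev.weight < 0:
                self.I_inh[ev.target] += ev.weight
        if self.mode.kind == "fixed" and externals:
            self.I_exc = q(self.I_exc)
            self.I_inh = q(self.I_inh)
        # NEUR: membrane update from pre-decay currents, then decays
        v, u = self.v, self.u
        v_new = q(v * v / 32 + 5.0 * v + 109.375 - u
                  + self.I_bias + self.I_exc + self.I_inh)
        u_new = q(u + self.a * (self.b * v - u))
        spiked = v_new >= self.v_thresh
        self.v = np.where(spiked, self.c, v_new)
        self.u = np.where(spiked, q(u_new + self.d), u_new)
        self.I_exc = q(self.I_exc * (1.0 - self.its))
        self.I_inh = q(self.I_inh * (1.0 - self.its))
        if self.pre.size:
            pre_spiked = spiked[self.pre]
            # depression: Eq-12 increment on spike rows, recovery elsewhere
            Ws = q(self.W * (1.0 - self.delta))
            self.delta = np.where(
                pre_spiked,
                q(self.delta + self.P * (1.0 - self.delta)),
                q(self.delta * (1.0 - self.inv_tau_reg)),
            )
            # SYN: inject effective weights of spiking presynaptic neurons
            fire_exc = pre_spiked & self.exc_mask
            fire_inh = pre_spiked & self.inh_mask
            if fire_exc.any():
                np.add.at(self.I_exc, self.post[fire_exc], Ws[fire_exc])
            if fire_inh.any():
                np.add.at(self.I_inh, self.post[fire_inh], Ws[fire_inh])
            if self.mode.kind == "fixed":
                self.I_exc = q(self.I_exc)
                self.I_inh = q(self.I_inh)
        return np.nonzero(spiked)[0]

    def writeback(self) -> None:
        """Copy array state back into the Network's dataclasses."""
        net = self.net
        for i, (params, state) in enumerate(net.neurons):
            state.v = float(self.v[i])
            state.u = float(self.u[i])
            state.I_exc = float(self.I_exc[i])
            state.I_inh = float(self.I_inh[i])
        k = 0
        for row in net.connectivity.adjacency:
            for _, _, sstate in row:
                sstate.delta = float(self.delta[k])
                k += 1
        net.overflow_count += self.overflow


# ---------------------------------------------------------------------------
# stepping API
# ---------------------------------------------------------------------------


def step(net: Network, externals: Sequence[ExternalEvent] = ()) -> List[int]:
    """Advance the network by one millisecond in place.

    Returns the (0-based) indices of neurons that spiked this step.
    All events in ``externals`` are treated as belonging to this step.
    """
    compiled = _Compiled(net)
    spiked = compiled.step(externals)
    compiled.writeback()
    return [int(i) for i in spiked]


@dataclass(frozen=True)
class RecordOptions:
    """What to sample every step besides spikes."""

    v: bool = False
    u: bool = False
    currents: bool = False

    @property
    def any(self) -> bool:
        return self.v or self.u or self.currents


def run(
    net: Network,
    duration_ms: int,
    externals: Sequence[ExternalEvent] = (),
    record: RecordOptions = RecordOptions(),
) -> SpikeRaster:
    """Simulate for ``duration_ms`` steps and return the spike raster.

    Deterministic given (network, externals, mode).  When trace recording
    is requested the raster's ``traces`` DataFrame holds one row per step
    with per-neuron columns (v_1 .. v_n etc., 1-based names).  The network
    object is updated in place to its final state.
    """
    if duration_ms < 1:
        raise ValueError(f"duration must be >= 1 ms, got {duration_ms}")
    by_step: dict = {}
    for ev in externals:
        if ev.t >= duration_ms:
            raise ValueError(f"external event at t={ev.t} beyond duration {duration_ms}")
        by_step.setdefault(ev.t, []).append(ev)
    compiled = _Compiled(net)
    events: List[Tuple[int, int]] = []
    trace_rows = [] if record.any else None
    t0 = time.perf_counter()
    for t in range(duration_ms):
        spiked = compiled.step(by_step.get(t, ()))
        for i in spiked:
            events.append((t, int(i)))
        if trace_rows is not None:
            row = [t]
            if record.v:
                row.extend(compiled.v.tolist())
            if record.u:
                row.extend(compiled.u.tolist())
            if record.currents:
                row.extend(compiled.I_exc.tolist())
                row.extend(compiled.I_inh.tolist())
            trace_rows.append(row)
    elapsed = time.perf_counter() - t0
    compiled.writeback()
    if compiled.overflow:
        logger.warning("fixed-point overflow saturations: %d", compiled.overflow)
    logger.info(
        "simulated %d ms in %.2f s (real-time factor %.1fx)",
        duration_ms, elapsed, (duration_ms / 1000.0) / elapsed if elapsed > 0 else float("inf"),
    )
    traces = None
    if trace_rows is not None:
        cols = ["time_ms"]
        n = net.n_neurons
        if record.v:
            cols += [f"v_{i+1}" for i in range(n)]
        if record.u:
            cols += [f"u_{i+1}" for i in range(n)]
        if record.currents:
            cols += [f"I_exc_{i+1}" for i in range(n)]
            cols += [f"I_inh_{i+1}" for i in range(n)]
        traces = pd.DataFrame(trace_rows, columns=cols)
    return SpikeRaster(
        events=events, duration=duration_ms, n_neurons=net.n_neurons, traces=traces
    )


# ---------------------------------------------------------------------------
# flat (virtual-neuron terminated) encoding and CSV I/O
# ---------------------------------------------------------------------------


def encode_flat(conn: Connectivity) -> Tuple[List[List[int]], List[List[float]], List[List[float]]]:
    """Flat sparse-matrix rows: 1-based postsynaptic addresses terminated by
    the virtual neuron Nn+1, with positionally aligned weight and
    dissipation rows (terminator slots carry 0)."""
    vn = conn.n_neurons + 1
    addr_rows, w_rows, p_rows = [], [], []
    for row in conn.adjacency:
        addr_rows.append([post + 1 for post, _, _ in row] + [vn])
        w_rows.append([params.W_syn for _, params, _ in row] + [0.0])
        p_rows.append([params.P for _, params, _ in row] + [0.0])
    return addr_rows, w_rows, p_rows


def decode_flat(
    addr_rows: Sequence[Sequence[int]],
    w_rows: Sequence[Sequence[float]],
    p_rows: Sequence[Sequence[float]],
    inv_tau_syn: float = 0.01,
    inv_tau_reg: float = 0.0002,
) -> Connectivity:
    """Inverse of :func:`encode_flat`; rows must end with the terminator."""
    n = len(addr_rows)
    vn = n + 1
    adjacency: List[List[Edge]] = []
    for pre, (addrs, ws, ps) in enumerate(zip(addr_rows, w_rows, p_rows)):
        if not addrs or addrs[-1] != vn:
            raise ValueError(f"row {pre + 1} does not end with virtual neuron {vn}")
        row: List[Edge] = []
        for addr, w, p in zip(addrs[:-1], ws[:-1], ps[:-1]):
            if addr == vn:
                raise ValueError(f"row {pre + 1}: terminator before end of row")
            if not (1 <= addr <= n):
                raise ValueError(f"row {pre + 1}: address {addr} out of range [1, {n}]")
            row.append(
                (
                    addr - 1,
                    SynapseParams(W_syn=w, P=p, inv_tau_syn=inv_tau_syn,
                                  inv_tau_reg=inv_tau_reg),
                    SynapseState(),
                )
            )
        adjacency.append(row)
    return Connectivity(n_neurons=n, adjacency=adjacency)


def _write_rows(path: Path, rows: Sequence[Sequence]) -> None:
    with open(path, "w") as fh:
        for row in rows:
            fh.write(",".join(str(x) for x in row) + "\n")


def _read_rows(path: Path, cast) -> List[List]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                rows.append([cast(x) for x in line.split(",")])
    return rows


def export_connectivity_csv(
    conn: Connectivity, conn_path, weight_path, dissipation_path
) -> None:
    """Three positionally aligned CSVs (addresses / weights / dissipation),
    one row per presynaptic neuron, terminator included."""
    addr_rows, w_rows, p_rows = encode_flat(conn)
    _write_rows(Path(conn_path), addr_rows)
    _write_rows(Path(weight_path), w_rows)
    _write_rows(Path(dissipation_path), p_rows)


def import_connectivity_csv(
    conn_path, weight_path, dissipation_path,
    inv_tau_syn: float = 0.01, inv_tau_reg: float = 0.0002,
) -> Connectivity:
    addr_rows = _read_rows(Path(conn_path), int)
    w_rows = _read_rows(Path(weight_path), float)
    p_rows = _read_rows(Path(dissipation_path), float)
    return decode_flat(addr_rows, w_rows, p_rows,
                       inv_tau_syn=inv_tau_syn, inv_tau_reg=inv_tau_reg)
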