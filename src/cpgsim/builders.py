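"""Reference CPG networks of the leech-heartbeat system and variants.

Three builders cover the networks whose parameters are established for this
family of oscillators:

* ``build_elemental`` — the half-center (elemental) oscillator: two
  regular-spiking neurons coupled by mutual inhibition with
  activity-dependent depression.  Two parameter sets are provided: the
  leech-heartbeat fit (W_syn = -5.1, P = 1.49 %, I_bias = 8) and the
  rat-spinal-cord fit (W_syn = -7, P = 12 %, I_bias = 7).
* ``build_segmental`` — the eight-neuron segmental oscillator: two
  elemental oscillators (L3/R3 and L4/R4) coupled through two pairs of
  coordination neurons (L1/R1, L2/R2); 12 inhibitory synapses,
  W_syn = -7, P = 2.65 %.
* ``build_chain`` — a chain of segmental oscillators; each CPG contributes
  two extra inhibitory synapses coupling its L3/R3 to the next CPG's
  L3/R3 (8 neurons and 14 synapses per CPG in the wrapped accounting).

Symmetry breaking: a perfectly symmetric half-center started from identical
states stays synchronous forever, so the default initial membrane
potentials are spread evenly over 20 mV below the reset potential
(v_i = c - 20 i/(n-1), u_i = b v_i); depression levels and synaptic
currents start at zero.  An optional seeded jitter adds a uniform
perturbation to the initial v instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .neuron import FLOAT_MODE, IzhikevichParams, NeuronState, NumericMode, RS_PARAMS
from .network import Connectivity, Edge, Network
from .synapse import SynapseParams, SynapseState

#: Neuron labels of the segmental oscillator, fixed order.
SEGMENTAL_NAMES = ["L1", "L2", "L3", "L4", "R1", "R2", "R3", "R4"]

#: Named coordination wirings (8 synapses each; the 4 cross-midline
#: synapses L3<->R3, L4<->R4 are always present).  ``reciprocal`` couples
#: each coordination neuron to an ipsilateral oscillator neuron by mutual
#: inhibition, as in the biological timing network; ``ring`` is a directed
#: inhibitory loop through the coordination neurons.
SEGMENTAL_ADJACENCIES: Dict[str, List[Tuple[str, str]]] = {
    "reciprocal": [
        ("L1", "L3"), ("L3", "L1"), ("L2", "L4"), ("L4", "L2"),
        ("R1", "R3"), ("R3", "R1"), ("R2", "R4"), ("R4", "R2"),
    ],
    "ring": [
        ("L3", "L1"), ("L1", "L4"), ("L4", "L2"), ("L2", "L3"),
        ("R3", "R1"), ("R1", "R4"), ("R4", "R2"), ("R2", "R3"),
    ],
}

_CROSS_MIDLINE = [("L3", "R3"), ("R3", "L3"), ("L4", "R4"), ("R4", "L4")]

#: Default synapse time constants shared by all reference networks:
#: 1/tau_syn = 0.01 /ms (tau = 100 ms) and 1/tau_reg = 0.0002 /ms
#: (tau = 5000 ms).
DEFAULT_INV_TAU_SYN = 0.01
DEFAULT_INV_TAU_REG = 0.0002


@dataclass(frozen=True)
class CPGConfig:
    """Builder configuration; ``None`` fields resolve to variant defaults."""

    variant: str = "elemental-leech"
    izh: IzhikevichParams = RS_PARAMS
    I_bias: Optional[float] = None
    W_syn: Optional[float] = None
    P: Optional[float] = None
    inv_tau_syn: float = DEFAULT_INV_TAU_SYN
    inv_tau_reg: float = DEFAULT_INV_TAU_REG
    segmental_adjacency: str = "reciprocal"
    chain_length: int = 1
    chain_wrap: bool = True
    mode: NumericMode = FLOAT_MODE
    init_spread_mv: float = 20.0
    jitter_seed: Optional[int] = None


_VARIANT_DEFAULTS = {
    # variant: (I_bias, W_syn, P)
    "elemental-leech": (8.0, -5.1, 0.0149),
    "elemental-rat": (7.0, -7.0, 0.12),
    "segmental-leech": (8.0, -7.0, 0.0265),
    "chain": (8.0, -7.0, 0.0265),
}


def _resolve(config: CPGConfig, variant: str) -> Tuple[float, float, float]:
    if variant not in _VARIANT_DEFAULTS:
        raise ValueError(
            f"unknown variant {variant!r}; expected one of {sorted(_VARIANT_DEFAULTS)}"
        )
    bias, w, p = _VARIANT_DEFAULTS[variant]
    return (
        bias if config.I_bias is None else config.I_bias,
        w if config.W_syn is None else config.W_syn,
        p if config.P is None else config.P,
    )


def _initial_states(
    config: CPGConfig, n: int, I_bias: float
) -> List[NeuronState]:
    """Evenly spread initial v below the reset potential; u at b*v."""
    c, b = config.izh.c, config.izh.b
    spread = config.init_spread_mv
    vs = [c - (spread * i / (n - 1) if n > 1 else 0.0) for i in range(n)]
    if config.jitter_seed is not None:
        rng = np.random.default_rng(config.jitter_seed)
        vs = [c - float(x) for x in rng.uniform(0.0, spread, size=n)]
    return [NeuronState(v=v, u=b * v, I_bias=I_bias) for v in vs]


def _synapse(config: CPGConfig, W: float, P: float) -> Tuple[SynapseParams, SynapseState]:
    return (
        SynapseParams(
            W_syn=W, P=P,
            inv_tau_syn=config.inv_tau_syn, inv_tau_reg=config.inv_tau_reg,
        ),
        SynapseState(),
    )


def build_elemental(config: CPGConfig = CPGConfig()) -> Network:
    """Two-neuron half-center oscillator with mutual inhibition."""
    variant = config.variant if config.variant.startswith("elemental") else "elemental-leech"
    I_bias, W, P = _resolve(config, variant)
    if W >= 0:
        raise ValueError(f"half-center synapses must be inhibitory, got W_syn={W}")
    states = _initial_states(config, 2, I_bias)
    adjacency: List[List[Edge]] = [
        [(1, *_synapse(config, W, P))],
        [(0, *_synapse(config, W, P))],
    ]
    return Network(
        neurons=[(config.izh, s) for s in states],
        connectivity=Connectivity(n_neurons=2, adjacency=adjacency),
        mode=config.mode,
        inv_tau_syn=config.inv_tau_syn,
        names=["N1", "N2"],
    )


def _segmental_edges(config: CPGConfig, W: float, P: float) -> List[List[Edge]]:
    if config.segmental_adjacency not in SEGMENTAL_ADJACENCIES:
        raise ValueError(
            f"unknown segmental adjacency {config.segmental_adjacency!r}; "
            f"expected one of {sorted(SEGMENTAL_ADJACENCIES)}"
        )
    idx = {name: i for i, name in enumerate(SEGMENTAL_NAMES)}
    pairs = _CROSS_MIDLINE + SEGMENTAL_ADJACENCIES[config.segmental_adjacency]
    adjacency: List[List[Edge]] = [[] for _ in SEGMENTAL_NAMES]
    for src, dst in pairs:
        adjacency[idx[src]].append((idx[dst], *_synapse(config, W, P)))
    return adjacency


def build_segmental(config: CPGConfig = CPGConfig(variant="segmental-leech")) -> Network:
    """Eight-neuron segmental oscillator, 12 inhibitory synapses."""
    I_bias, W, P = _resolve(config, "segmental-leech")
    if W >= 0:
        raise ValueError(f"segmental synapses must be inhibitory, got W_syn={W}")
    states = _initial_states(config, 8, I_bias)
    return Network(
        neurons=[(config.izh, s) for s in states],
        connectivity=Connectivity(n_neurons=8, adjacency=_segmental_edges(config, W, P)),
        mode=config.mode,
        inv_tau_syn=config.inv_tau_syn,
        names=list(SEGMENTAL_NAMES),
    )


def build_chain(config: CPGConfig = CPGConfig(variant="chain")) -> Network:
    """Chain of segmental CPGs coupled L3->L3' and R3->R3'.

    With wrapping (default) the last CPG couples back to the first, so
    every CPG owns 8 neurons and 14 synapses; without wrapping the final
    CPG contributes no forward couplings.
    """
    if config.chain_length < 1:
        raise ValueError(f"chain_length must be >= 1, got {config.chain_length}")
    I_bias, W, P = _resolve(config, "chain")
    n_cpg = config.chain_length
    n = 8 * n_cpg
    states = _initial_states(config, n, I_bias)
    idx = {name: i for i, name in enumerate(SEGMENTAL_NAMES)}
    adjacency: List[List[Edge]] = [[] for _ in range(n)]
    names: List[str] = []
    for k in range(n_cpg):
        base = 8 * k
        names.extend(f"{nm}.{k + 1}" for nm in SEGMENTAL_NAMES)
        seg = _segmental_edges(config, W, P)
        for pre, row in enumerate(seg):
            adjacency[base + pre].extend((base + post, p, s) for post, p, s in row)
        nxt = (k + 1) % n_cpg
        if nxt != k or n_cpg == 1:
            if config.chain_wrap or k + 1 < n_cpg:
                for nm in ("L3", "R3"):
                    adjacency[base + idx[nm]].append(
                        (8 * nxt + idx[nm], *_synapse(config, W, P))
                    )
    return Network(
        neurons=[(config.izh, s) for s in states],
        connectivity=Connectivity(n_neurons=n, adjacency=adjacency),
        mode=config.mode,
        inv_tau_syn=config.inv_tau_syn,
        names=names,
    )


def build(config: CPGConfig) -> Network:
    """Dispatch on ``config.variant``."""
    if config.variant.startswith("elemental"):
        return build_elemental(config)
    if config.variant == "segmental-leech":
        return build_segmental(config)
    if config.variant == "chain":
        return build_chain(config)
    raise ValueError(f"unknown variant {config.variant!r}")
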