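"""Synapse model: exponential current decay with activity-dependent depression.

Each synapse carries a fixed weight ``W_syn`` whose sign routes its effect
(positive -> excitatory accumulator, negative -> inhibitory accumulator)
and a depression level ``delta`` in [0, 1] emulating vesicle depletion:

* every presynaptic spike injects the *effective* weight
  ``W_s = W_syn * (1 - delta)`` into the postsynaptic current accumulator
  and then deepens the depression, ``delta <- delta + P (1 - delta)``;
* on spike-free steps the depression recovers exponentially,
  ``delta <- delta (1 - 1/tau_reg)``;
* the postsynaptic current accumulators decay every millisecond,
  ``I <- I (1 - 1/tau_syn)``.

Spike steps apply the depression increment only and spike-free steps apply
the recovery only — the two update rules are mutually exclusive, mirroring
the two-column behavior table of the synapse computation core.

With ``P = 0`` the model reduces to a plain exponentially-decaying
current synapse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Tuple

from .neuron import NeuronState


@dataclass(frozen=True)
class SynapseParams:
    """Per-synapse constants.

    W_syn : synaptic weight (model current units); sign encodes E/I.
    P : dissipation fraction per presynaptic spike, in [0, 1].
    inv_tau_syn : current decay rate 1/tau_syn per ms, in (0, 1).
    inv_tau_reg : depression recovery rate 1/tau_reg per ms, in [0, 1).
    """

    W_syn: float
    P: float = 0.0
    inv_tau_syn: float = 0.01
    inv_tau_reg: float = 0.0002

    def __post_init__(self) -> None:
        if not (0.0 <= self.P <= 1.0):
            raise ValueError(f"P must lie in [0, 1], got {self.P}")
        if not (0.0 < self.inv_tau_syn < 1.0):
            raise ValueError(f"inv_tau_syn must lie in (0, 1), got {self.inv_tau_syn}")
        if not (0.0 <= self.inv_tau_reg < 1.0):
            raise ValueError(f"inv_tau_reg must lie in [0, 1), got {self.inv_tau_reg}")
        if not math.isfinite(self.W_syn):
            raise ValueError(f"W_syn must be finite, got {self.W_syn}")


@dataclass
class SynapseState:
    """Dynamic per-synapse variable: the depression level delta in [0, 1]."""

    delta: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.delta <= 1.0):
            raise ValueError(f"delta must lie in [0, 1], got {self.delta}")


def effective_weight(params: SynapseParams, state: SynapseState) -> float:
    """Depressed weight W_s = W_syn (1 - delta).

    Same sign as W_syn, magnitude never above |W_syn|; zero when the
    synapse is exhausted (delta = 1).
    """
    return params.W_syn * (1.0 - state.delta)


def depress_on_spike(state: SynapseState, params: SynapseParams) -> SynapseState:
    """Depression deepens by the dissipation fraction of the remaining pool.

    delta' = delta + P (1 - delta).  Maps [0, 1] into itself for any
    P in [0, 1]; delta = 1 is a fixed point (exhausted synapse).
    """
    return replace(state, delta=state.delta + params.P * (1.0 - state.delta))


def decay_depression(state: SynapseState, params: SynapseParams) -> SynapseState:
    """Exponential recovery toward zero on a spike-free step.

    delta' = delta (1 - 1/tau_reg); monotone non-increasing.
    """
    return replace(state, delta=state.delta * (1.0 - params.inv_tau_reg))


def decay_current(I: float, params: SynapseParams) -> float:
    """One-millisecond decay of a current accumulator: I (1 - 1/tau_syn)."""
    if not math.isfinite(I):
        raise ValueError(f"current must be finite, got {I!r}")
    return I * (1.0 - params.inv_tau_syn)


def inject_spike(post_state: NeuronState, weight: float) -> NeuronState:
    """Route a weight into the matching accumulator of the target neuron.

    Positive weights add to I_exc, negative to I_inh, zero is a no-op —
    so I_exc stays >= 0 and I_inh stays <= 0 without clipping.
    """
    if not math.isfinite(weight):
        raise ValueError(f"weight must be finite, got {weight!r}")
    if weight > 0:
        return replace(post_state, I_exc=post_state.I_exc + weight)
    if weight < 0:
        return replace(post_state, I_inh=post_state.I_inh + weight)
    return post_state
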