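"""Single-neuron model: hardware-scaled Izhikevich update and fixed-point tools.

The membrane model is the two-variable Izhikevich regular-spiking (RS)
neuron.  Two update forms are provided:

``hw_step``
    The hardware-scaled difference equation used by the digital CPG
    implementation this package reproduces.  The canonical quadratic
    (``0.04 v^2 + 5 v + 140``) is rescaled so every coefficient is a power
    of two or exactly representable in a binary fraction, and the
    forward-Euler step (dt = 1 ms) is folded in::

        v[n+1] = v[n]^2/32 + 5 v[n] + 109.375 - u[n] + I_bias + I_exc + I_inh
        u[n+1] = u[n] + a (b v[n] - u[n])

    followed by the after-spike reset ``v <- c, u <- u + d`` whenever the
    computed membrane value reaches the threshold.  All reference networks
    are simulated with this form.

``canonical_step``
    Forward Euler on the textbook equations, kept as a diagnostic
    reference; it is not used by the network builders.

Fixed-point (signed Q9.16, 26-bit) quantization mirrors the arithmetic of
the digital hardware: 1 sign bit, 9 integer bits, 16 fractional bits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Literal, Tuple

logger = logging.getLogger(__name__)

V_PEAK_MARKER = 30.0  # plotting marker for spike steps when requested

# ---------------------------------------------------------------------------
# parameter / state containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IzhikevichParams:
    """Izhikevich model constants.

    a : recovery rate (1/ms). b : recovery sensitivity to v (dimensionless).
    c : post-spike reset potential (mV). d : post-spike recovery increment.
    v_thresh : spike threshold applied to the *computed* membrane value (mV).
    """

    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 8.0
    v_thresh: float = 30.0

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError(f"a must be positive, got {self.a}")
        if not (self.v_thresh > self.c):
            raise ValueError(
                f"v_thresh ({self.v_thresh}) must exceed reset c ({self.c})"
            )


#: Regular-spiking parameter set used by all reference CPG networks.
RS_PARAMS = IzhikevichParams(a=0.02, b=0.2, c=-65.0, d=8.0)


@dataclass
class NeuronState:
    """Dynamic per-neuron variables.

    The input current is split into a constant bias and two signed synaptic
    accumulators: ``I_exc`` collects positive weights (never negative),
    ``I_inh`` collects negative weights (never positive).  The split is
    enforced by weight routing at injection time, not by clipping here.
    """

    v: float
    u: float
    I_bias: float = 0.0
    I_exc: float = 0.0
    I_inh: float = 0.0

    def total_current(self) -> float:
        return self.I_bias + self.I_exc + self.I_inh


# ---------------------------------------------------------------------------
# numeric mode / Q9.16 quantization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NumericMode:
    """Arithmetic mode of the simulator.

    ``floating`` computes in IEEE double precision.  ``fixed`` quantizes
    every state variable (v, u, currents, depression level, effective
    weight) to the signed Q(integer_bits).(fraction_bits) grid after each
    update, emulating the hardware datapath.
    """

    kind: Literal["floating", "fixed"] = "floating"
    total_bits: int = 26
    sign_bits: int = 1
    integer_bits: int = 9
    fraction_bits: int = 16
    overflow_policy: Literal["saturate", "wrap"] = "saturate"
    rounding_policy: Literal["round-nearest", "truncate-toward-negative"] = (
        "round-nearest"
    )

    def __post_init__(self) -> None:
        if self.kind == "fixed":
            if self.sign_bits + self.integer_bits + self.fraction_bits != self.total_bits:
                raise ValueError(
                    "sign_bits + integer_bits + fraction_bits must equal total_bits"
                )

    @property
    def scale(self) -> int:
        return 1 << self.fraction_bits

    @property
    def max_value(self) -> float:
        """Largest representable value, 2^integer_bits - 2^-fraction_bits."""
        return (1 << self.integer_bits) - 1.0 / self.scale

    @property
    def min_value(self) -> float:
        return -float(1 << self.integer_bits)


FLOAT_MODE = NumericMode(kind="floating")
FIXED_MODE = NumericMode(kind="fixed")


def quantize(x: float, mode: NumericMode) -> float:
    """Nearest representable fixed-point value under the mode's policies.

    Out-of-range inputs saturate to the format limits or wrap modularly,
    per ``overflow_policy``.  In floating mode this is the identity.
    """
    if mode.kind == "floating":
        return x
    if not math.isfinite(x):
        raise ValueError(f"cannot quantize non-finite value {x!r}")
    s = mode.scale
    if mode.rounding_policy == "round-nearest":
        n = math.floor(x * s + 0.5)  # round half toward +inf, hardware style
    else:
        n = math.floor(x * s)
    lo = -(1 << (mode.integer_bits + mode.fraction_bits))
    hi = (1 << (mode.integer_bits + mode.fraction_bits)) - 1
    if n < lo or n > hi:
        if mode.overflow_policy == "saturate":
            n = min(max(n, lo), hi)
        else:  # wrap, two's-complement style
            span = hi - lo + 1
            n = (n - lo) % span + lo
    return n / s


def quantize_params(params: "IzhikevichParams", mode: NumericMode) -> "IzhikevichParams":
    """Parameters as stored in the fixed-point RAM (identity in float mode)."""
    if mode.kind == "floating":
        return params
    return replace(
        params,
        a=quantize(params.a, mode),
        b=quantize(params.b, mode),
        c=quantize(params.c, mode),
        d=quantize(params.d, mode),
        v_thresh=quantize(params.v_thresh, mode),
    )


# ---------------------------------------------------------------------------
# update operations
# ---------------------------------------------------------------------------


def _check_finite(state: NeuronState) -> None:
    for name in ("v", "u", "I_bias", "I_exc", "I_inh"):
        if not math.isfinite(getattr(state, name)):
            raise ValueError(f"non-finite neuron state field {name}={getattr(state, name)!r}")


def hw_step(
    state: NeuronState, params: IzhikevichParams, mode: NumericMode = FLOAT_MODE
) -> Tuple[NeuronState, bool]:
    """One 1-ms update of the hardware-scaled model.

    Both v and u are advanced from the *old* state; the reset applies after
    u has been updated (``u <- u_new + d``).  Current accumulators are not
    touched here — decay and injection belong to the network step.

    Returns the new state and whether the neuron spiked.
    """
    _check_finite(state)
    q = (lambda x: x) if mode.kind == "floating" else (lambda x: quantize(x, mode))
    v, u = state.v, state.u
    v_new = q(v * v / 32 + 5.0 * v + 109.375 - u + state.I_bias + state.I_exc + state.I_inh)
    u_new = q(u + params.a * (params.b * v - u))
    if v_new >= params.v_thresh:
        out = replace(state, v=q(params.c), u=q(u_new + params.d))
        return out, True
    return replace(state, v=v_new, u=u_new), False


def canonical_step(
    state: NeuronState,
    params: IzhikevichParams,
    dt: float = 1.0,
    mode: NumericMode = FLOAT_MODE,
) -> Tuple[NeuronState, bool]:
    """Forward-Euler step of the textbook Izhikevich equations.

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I ;  du/dt = a (b v - u), with the
    same after-spike reset as ``hw_step``.  Diagnostic only.
    """
    if not dt > 0:
        raise ValueError(f"dt must be positive, got {dt}")
    _check_finite(state)
    q = (lambda x: x) if mode.kind == "floating" else (lambda x: quantize(x, mode))
    v, u = state.v, state.u
    I = state.total_current()
    v_new = q(v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + I))
    u_new = q(u + dt * (params.a * (params.b * v - u)))
    if v_new >= params.v_thresh:
        return replace(state, v=q(params.c), u=q(u_new + params.d)), True
    return replace(state, v=v_new, u=u_new), False
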