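"""Simulation configuration: YAML/JSON loading, validation, serialization.

A minimal config is a single line::

    variant: elemental-leech

Everything else defaults to the reference parameter set of the chosen
variant.  Quantities accept the forms in which they are usually quoted:

* dissipation fraction ``P``: a fraction (``0.0149``) or a percentage
  string (``"1.49%"``);
* time constants: either the reciprocal rate (``inv_tau_reg: 0.0002``,
  per ms) or the constant itself in ms (``tau_reg: 5000``).

Loaded configs are fully resolved (all defaults applied) and echoed to the
log so that every run records the complete parameter provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Union

import yaml

from .builders import CPGConfig, SEGMENTAL_ADJACENCIES, _VARIANT_DEFAULTS, build
from .neuron import FIXED_MODE, FLOAT_MODE, IzhikevichParams, NumericMode
from .network import ExternalEvent, Network, RecordOptions

logger = logging.getLogger(__name__)


def parse_fraction(value: Union[str, float, int], name: str = "P") -> float:
    """'1.49%' -> 0.0149 ; plain numbers pass through unchanged."""
    if isinstance(value, str):
        s = value.strip()
        if s.endswith("%"):
            return float(s[:-1]) / 100.0
        return float(s)
    return float(value)


def _rate_from(spec: dict, rate_key: str, tau_key: str, default: float) -> float:
    """Resolve 1/tau given either the reciprocal or tau in ms."""
    if rate_key in spec and tau_key in spec:
        raise ValueError(f"give either {rate_key} or {tau_key}, not both")
    if rate_key in spec:
        return float(spec[rate_key])
    if tau_key in spec:
        tau = float(spec[tau_key])
        if tau <= 0:
            raise ValueError(f"{tau_key} must be positive, got {tau}")
        return 1.0 / tau
    return default


@dataclass(frozen=True)
class SimulationConfig:
    """Resolved simulation description."""

    cpg: CPGConfig
    duration_s: float = 300.0
    record: RecordOptions = RecordOptions()
    externals: List[ExternalEvent] = field(default_factory=list)

    def build_network(self) -> Network:
        return build(self.cpg)


_KNOWN_KEYS = {
    "variant", "I_bias", "W_syn", "P", "inv_tau_syn", "tau_syn",
    "inv_tau_reg", "tau_reg", "segmental_adjacency", "chain_length",
    "chain_wrap", "mode", "duration_s", "record", "externals_file",
    "jitter_seed", "init_spread_mv", "izhikevich",
}


def _numeric_mode(name: str) -> NumericMode:
    if name in ("float", "floating"):
        return FLOAT_MODE
    if name == "fixed":
        return FIXED_MODE
    raise ValueError(f"mode: expected 'float' or 'fixed', got {name!r}")


def load_config(path: Union[str, Path]) -> SimulationConfig:
    """Load and validate a YAML (or JSON) simulation config."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping, got {type(raw).__name__}")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    if "variant" not in raw:
        raise ValueError(f"{path}: missing required key 'variant'")
    variant = str(raw["variant"])
    if variant not in _VARIANT_DEFAULTS:
        raise ValueError(
            f"{path}: variant: unknown value {variant!r}; "
            f"expected one of {sorted(_VARIANT_DEFAULTS)}"
        )

    izh = IzhikevichParams()
    if "izhikevich" in raw:
        izh = IzhikevichParams(**{k: float(v) for k, v in raw["izhikevich"].items()})

    cpg = CPGConfig(
        variant=variant,
        izh=izh,
        I_bias=None if "I_bias" not in raw else float(raw["I_bias"]),
        W_syn=None if "W_syn" not in raw else float(raw["W_syn"]),
        P=None if "P" not in raw else parse_fraction(raw["P"]),
        inv_tau_syn=_rate_from(raw, "inv_tau_syn", "tau_syn", 0.01),
        inv_tau_reg=_rate_from(raw, "inv_tau_reg", "tau_reg", 0.0002),
        segmental_adjacency=str(raw.get("segmental_adjacency", "reciprocal")),
        chain_length=int(raw.get("chain_length", 1)),
        chain_wrap=bool(raw.get("chain_wrap", True)),
        mode=_numeric_mode(str(raw.get("mode", "float"))),
        init_spread_mv=float(raw.get("init_spread_mv", 20.0)),
        jitter_seed=None if raw.get("jitter_seed") is None else int(raw["jitter_seed"]),
    )
    if cpg.segmental_adjacency not in SEGMENTAL_ADJACENCIES:
        raise ValueError(
            f"{path}: segmental_adjacency: unknown value "
            f"{cpg.segmental_adjacency!r}; expected one of "
            f"{sorted(SEGMENTAL_ADJACENCIES)}"
        )

    rec = raw.get("record", {}) or {}
    record = RecordOptions(
        v=bool(rec.get("v", False)),
        u=bool(rec.get("u", False)),
        currents=bool(rec.get("currents", False)),
    )

    externals: List[ExternalEvent] = []
    if raw.get("externals_file"):
        epath = Path(raw["externals_file"])
        if not epath.is_absolute():
            epath = path.parent / epath
        if not epath.exists():
            raise FileNotFoundError(f"externals file not found: {epath}")
        import pandas as pd

        df = pd.read_csv(epath)
        for col in ("time_ms", "neuron_id", "weight"):
            if col not in df.columns:
                raise ValueError(f"{epath}: externals CSV lacks column {col!r}")
        externals = [
            ExternalEvent(t=int(r.time_ms), target=int(r.neuron_id) - 1,
                          weight=float(r.weight))
            for r in df.itertuples()
        ]

    cfg = SimulationConfig(
        cpg=cpg,
        duration_s=float(raw.get("duration_s", 300.0)),
        record=record,
        externals=externals,
    )
    if cfg.duration_s * 1000 < 1:
        raise ValueError(f"{path}: duration_s must be at least 0.001")
    logger.info("resolved config %s: %s", path, serialize_config(cfg))
    return cfg


def serialize_config(cfg: SimulationConfig) -> dict:
    """Round-trippable plain-dict form of a resolved config."""
    c = cfg.cpg
    out = {
        "variant": c.variant,
        "I_bias": c.I_bias,
        "W_syn": c.W_syn,
        "P": c.P,
        "inv_tau_syn": c.inv_tau_syn,
        "inv_tau_reg": c.inv_tau_reg,
        "segmental_adjacency": c.segmental_adjacency,
        "chain_length": c.chain_length,
        "chain_wrap": c.chain_wrap,
        "mode": "fixed" if c.mode.kind == "fixed" else "float",
        "init_spread_mv": c.init_spread_mv,
        "jitter_seed": c.jitter_seed,
        "izhikevich": {
            "a": c.izh.a, "b": c.izh.b, "c": c.izh.c, "d": c.izh.d,
            "v_thresh": c.izh.v_thresh,
        },
        "duration_s": cfg.duration_s,
        "record": {"v": cfg.record.v, "u": cfg.record.u,
                   "currents": cfg.record.currents},
    }
    return {k: v for k, v in out.items() if v is not None}


def save_config(cfg: SimulationConfig, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(serialize_config(cfg), fh, sort_keys=False)
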