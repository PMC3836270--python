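"""Burst segmentation and rhythm statistics for spike trains.

Bursts are detected with the standard interspike-interval (ISI) threshold
method: a burst is a maximal run of spikes whose consecutive ISIs are all
<= ``max_isi``, kept only if it contains at least ``min_spikes`` spikes.
For the CPG rhythms this package targets, intra-burst ISIs are ~80 ms and
inter-burst gaps are seconds, so the segmentation is insensitive to the
exact threshold; the defaults are max_isi = 300 ms, min_spikes = 4.

Per-burst quantities follow the usual electrophysiology conventions:

* period — start-to-start interval to the next burst of the same train (s);
* duty cycle — burst duration / period, as a percentage;
* mean spike frequency — (spike count - 1) / duration (Hz);
* instantaneous frequency — 1000 / ISI (Hz); the initial, peak and final
  frequencies are 1000 / first ISI, max over ISIs, and 1000 / last ISI.

Summaries report mean +/- SD over bursts after discarding the first
``discard_first`` bursts (startup transient; default 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .builders import CPGConfig, build
from .network import RecordOptions, SpikeRaster, run


@dataclass(frozen=True)
class Burst:
    """One detected burst: its ordered spike times in ms."""

    spike_times: Tuple[float, ...]

    @property
    def start(self) -> float:
        return self.spike_times[0]

    @property
    def end(self) -> float:
        return self.spike_times[-1]

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)

    def isis(self) -> np.ndarray:
        return np.diff(self.spike_times)


@dataclass(frozen=True)
class Summary:
    """Mean +/- SD over bursts."""

    mean: float
    sd: float
    n: int

    def __str__(self) -> str:
        return f"{self.mean:.3g} ± {self.sd:.2g} (n={self.n})"


@dataclass(frozen=True)
class BurstStats:
    """Rhythm statistics of one spike train.

    period/duty_cycle are computed per burst against the next burst's
    start, so the last burst contributes duration and frequencies only.
    """

    n_bursts: int
    period: Summary          # s
    duty_cycle: Summary      # %
    mean_freq: Summary       # Hz
    initial_freq: Summary    # Hz
    peak_freq: Summary       # Hz
    final_freq: Summary      # Hz

    def to_dict(self) -> dict:
        out = {"n_bursts": self.n_bursts}
        for name in ("period", "duty_cycle", "mean_freq",
                     "initial_freq", "peak_freq", "final_freq"):
            s: Summary = getattr(self, name)
            out[f"{name}_mean"] = s.mean
            out[f"{name}_sd"] = s.sd
            out[f"{name}_n"] = s.n
        return out


def detect_bursts(
    train: Sequence[float], max_isi: float = 300.0, min_spikes: int = 4
) -> List[Burst]:
    """Maximal ISI-threshold runs with at least ``min_spikes`` spikes.

    ``train`` must be sorted ascending (ms).  Returned bursts are disjoint
    and ordered; every burst's spikes are a subset of the input.
    """
    train = list(train)
    if any(b < a for a, b in zip(train, train[1:])):
        raise ValueError("spike train must be sorted ascending")
    if min_spikes < 1:
        raise ValueError(f"min_spikes must be >= 1, got {min_spikes}")
    bursts: List[Burst] = []
    runlist: List[float] = []
    for t in train:
        if runlist and t - runlist[-1] > max_isi:
            if len(runlist) >= min_spikes:
                bursts.append(Burst(tuple(runlist)))
            runlist = []
        runlist.append(t)
    if len(runlist) >= min_spikes:
        bursts.append(Burst(tuple(runlist)))
    return bursts


def _summary(values: Sequence[float]) -> Summary:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return Summary(math.nan, math.nan, 0)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return Summary(float(arr.mean()), sd, int(arr.size))


def burst_stats(bursts: Sequence[Burst], discard_first: int = 2) -> BurstStats:
    """Summaries over bursts after dropping the startup transient.

    Needs at least ``discard_first + 2`` bursts (two are required for one
    period measurement).
    """
    if len(bursts) < discard_first + 2:
        raise ValueError(
            f"need at least {discard_first + 2} bursts "
            f"({discard_first} discarded + 2 for a period), got {len(bursts)}"
        )
    kept = list(bursts[discard_first:])
    periods_ms = [b2.start - b1.start for b1, b2 in zip(kept, kept[1:])]
    duty = [100.0 * b.duration / p for b, p in zip(kept, periods_ms)]
    mean_f, init_f, peak_f, final_f = [], [], [], []
    for b in kept:
        isis = b.isis()
        mean_f.append(1000.0 * (b.n_spikes - 1) / b.duration)
        init_f.append(1000.0 / isis[0])
        peak_f.append(float((1000.0 / isis).max()))
        final_f.append(1000.0 / isis[-1])
    return BurstStats(
        n_bursts=len(kept),
        period=_summary([p / 1000.0 for p in periods_ms]),
        duty_cycle=_summary(duty),
        mean_freq=_summary(mean_f),
        initial_freq=_summary(init_f),
        peak_freq=_summary(peak_f),
        final_freq=_summary(final_f),
    )


def raster_stats(
    raster: SpikeRaster,
    neuron: int = 0,
    max_isi: float = 300.0,
    min_spikes: int = 4,
    discard_first: int = 2,
) -> BurstStats:
    """Detect bursts on one neuron of a raster and summarize them."""
    bursts = detect_bursts(raster.spike_times(neuron), max_isi=max_isi,
                           min_spikes=min_spikes)
    return burst_stats(bursts, discard_first=discard_first)


def sweep_tau_reg(
    config: CPGConfig,
    inv_tau_reg_values: Sequence[float],
    duration_s: float = 300.0,
    neuron: Optional[int] = None,
    max_isi: float = 300.0,
    min_spikes: int = 4,
    discard_first: int = 2,
) -> List[Tuple[float, Optional[BurstStats]]]:
    """One simulation + burst analysis per depression-recovery rate.

    Everything but ``inv_tau_reg`` is held fixed.  The analysed neuron
    defaults to L3 for segmental/chain networks and the first neuron
    otherwise.  Settings whose rhythm yields too few bursts to summarize
    report ``None`` rather than raising.
    """
    from dataclasses import replace as _replace

    results: List[Tuple[float, Optional[BurstStats]]] = []
    for val in inv_tau_reg_values:
        if val <= 0:
            raise ValueError(f"inv_tau_reg values must be positive, got {val}")
        net = build(_replace(config, inv_tau_reg=val))
        nid = neuron
        if nid is None:
            nid = net.names.index("L3") if net.names and "L3" in net.names else 0
        raster = run(net, int(round(duration_s * 1000)))
        try:
            stats = raster_stats(raster, neuron=nid, max_isi=max_isi,
                                 min_spikes=min_spikes, discard_first=discard_first)
        except ValueError:
            stats = None
        results.append((val, stats))
    return results


def stats_frame(stats_by_label: dict) -> pd.DataFrame:
    """Tabulate {label: BurstStats | None} as a tidy DataFrame."""
    rows = []
    for label, st in stats_by_label.items():
        row = {"label": label}
        if st is not None:
            row.update(st.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
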