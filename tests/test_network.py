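"""Network engine: step semantics, oracle equivalence, encodings, capacity."""

import numpy as np
import pytest

from cpgsim import (
    Connectivity,
    ExternalEvent,
    Network,
    NeuronState,
    RS_PARAMS,
    SpikeRaster,
    SynapseParams,
    SynapseState,
    cycle_count,
    decode_flat,
    encode_flat,
    export_connectivity_csv,
    fits_capacity,
    import_connectivity_csv,
    run,
    step,
)
from cpgsim.cli import random_network

from _dense import DenseReference


def _single_neuron(I_bias=0.0):
    return Network(
        neurons=[(RS_PARAMS, NeuronState(v=-65.0, u=-13.0, I_bias=I_bias))],
        connectivity=Connectivity(n_neurons=1, adjacency=[[]]),
    )


def _chain_pair(weight=200.0):
    """A -> B with a strong excitatory synapse; both quiescent without input."""
    adjacency = [
        [(1, SynapseParams(W_syn=weight, P=0.0), SynapseState())],
        [],
    ]
    return Network(
        neurons=[
            (RS_PARAMS, NeuronState(v=-65.0, u=-13.0)),
            (RS_PARAMS, NeuronState(v=-65.0, u=-13.0)),
        ],
        connectivity=Connectivity(n_neurons=2, adjacency=adjacency),
    )


class TestStepSemantics:
    def test_empty_network_steps_cleanly(self):
        net = Network(
            neurons=[], connectivity=Connectivity(n_neurons=0, adjacency=[])
        )
        assert step(net) == []
        assert run(net, 10).events == []

    def test_quiescent_neuron_never_fires(self):
        raster = run(_single_neuron(I_bias=0.0), 5000)
        assert raster.events == []

    def test_external_injection_elicits_spike_without_propagation(self):
        net = _single_neuron()
        spiked = step(net, [ExternalEvent(t=0, target=0, weight=150.0)])
        assert spiked == [0]

    def test_one_step_synaptic_latency(self):
        """A spike at step n first moves the postsynaptic membrane at n+1."""
        net = _chain_pair()
        first = step(net, [ExternalEvent(t=0, target=0, weight=150.0)])
        assert first == [0]  # B unaffected within A's spike step
        v_b_before = net.neurons[1][1].v
        second = step(net)  # injected weight now reaches B's membrane
        assert 1 in second
        assert net.neurons[1][1].v == RS_PARAMS.c  # B reset after its spike
        # and B had not moved from its quiescent trajectory before that
        lone = _single_neuron()
        step(lone)
        assert v_b_before == lone.neurons[0][1].v

    def test_invalid_external_target_rejected(self):
        with pytest.raises(IndexError, match="targets neuron"):
            step(_single_neuron(), [ExternalEvent(t=0, target=5, weight=1.0)])

    def test_event_beyond_duration_rejected(self):
        with pytest.raises(ValueError, match="beyond duration"):
            run(_single_neuron(), 10, [ExternalEvent(t=10, target=0, weight=1.0)])

    def test_duration_must_be_positive(self):
        with pytest.raises(ValueError, match="duration"):
            run(_single_neuron(), 0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_reference_bit_for_bit(self, seed):
        """Sparse engine vs naive dense-matrix loop: identical rasters and
        identical final state over 1000 steps, float mode."""
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(3, 15))
        s = int(rng.integers(1, min(40, n * n)))
        externals = [
            ExternalEvent(t=int(rng.integers(0, 1000)),
                          target=int(rng.integers(0, n)),
                          weight=float(rng.uniform(-20, 20)))
            for _ in range(20)
        ]
        net = random_network(n, s, seed=seed)
        ref = DenseReference(net)
        raster = run(net, 1000, externals=externals)
        ref_events = ref.run(1000, externals=externals)
        assert raster.events == ref_events
        assert [st.v for _, st in net.neurons] == ref.v
        assert [st.u for _, st in net.neurons] == ref.u

    def test_repeated_single_steps_equal_run(self):
        net_a = random_network(8, 15, seed=7)
        net_b = random_network(8, 15, seed=7)
        raster = run(net_a, 200)
        events = []
        for t in range(200):
            for i in step(net_b):
                events.append((t, i))
        assert events == raster.events

    def test_run_is_deterministic(self):
        r1 = run(random_network(10, 20, seed=3), 500)
        r2 = run(random_network(10, 20, seed=3), 500)
        assert r1.events == r2.events


class TestRaster:
    def test_every_spike_recorded_exactly_once(self):
        raster = run(random_network(10, 20, seed=11, i_bias_range=(4, 10)), 2000)
        assert len(set(raster.events)) == len(raster.events)
        assert sum(raster.counts()) == len(raster.events)
        assert raster.events == sorted(raster.events)

    def test_csv_round_trip(self, tmp_path):
        raster = run(random_network(6, 12, seed=5, i_bias_range=(4, 10)), 1500)
        assert raster.events, "fixture should produce spikes"
        path = tmp_path / "raster.csv"
        raster.to_csv(path)
        back = SpikeRaster.from_csv(path)
        assert back.events == raster.events

    def test_traces_recorded_when_requested(self):
        from cpgsim import RecordOptions

        raster = run(_single_neuron(I_bias=8.0), 50, record=RecordOptions(v=True, u=True))
        assert raster.traces is not None
        assert list(raster.traces.columns) == ["time_ms", "v_1", "u_1"]
        assert len(raster.traces) == 50


class TestFlatEncoding:
    def test_round_trip_identity(self):
        net = random_network(9, 18, seed=2)
        addr, w, p = encode_flat(net.connectivity)
        assert all(row[-1] == 10 for row in addr)  # virtual neuron Nn+1
        back = decode_flat(addr, w, p)
        orig = list(net.connectivity.edges())
        got = list(back.edges())
        assert [(a, b) for a, b, _, _ in orig] == [(a, b) for a, b, _, _ in got]
        assert [sp.W_syn for _, _, sp, _ in orig] == [sp.W_syn for _, _, sp, _ in got]
        assert [sp.P for _, _, sp, _ in orig] == [sp.P for _, _, sp, _ in got]

    def test_csv_round_trip(self, tmp_path):
        net = random_network(7, 14, seed=4)
        paths = [tmp_path / f"{nm}.csv" for nm in ("conn", "w", "p")]
        export_connectivity_csv(net.connectivity, *paths)
        back = import_connectivity_csv(*paths)
        assert [(a, b) for a, b, _, _ in back.edges()] == [
            (a, b) for a, b, _, _ in net.connectivity.edges()
        ]

    def test_missing_terminator_rejected(self):
        with pytest.raises(ValueError, match="virtual neuron"):
            decode_flat([[1]], [[0.5]], [[0.0]])

    def test_out_of_range_address_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            decode_flat([[5, 3], [3]], [[1.0, 0.0], [0.0]], [[0.0, 0.0], [0.0]])


class TestCapacity:
    @pytest.mark.parametrize(
        "nn, ns, expected",
        [(0, 0, 0), (8, 14, 308), (8, 12, 288), (1920, 3360, 73920)],
    )
    def test_cycle_count(self, nn, ns, expected):
        assert cycle_count(nn, ns) == expected

    @pytest.mark.parametrize(
        "nn, ns, nc, ok",
        [(8, 14, 308, True), (8, 14, 307, False), (1920, 3360, 100_000, True)],
    )
    def test_fits_capacity(self, nn, ns, nc, ok):
        assert fits_capacity(nn, ns, nc) is ok

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            cycle_count(-1, 0)
        with pytest.raises(ValueError):
            fits_capacity(1, 1, 0)
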