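"""Shared fixtures: reference-network simulations reused across tests."""

import pytest

from cpgsim import build_elemental, build_segmental, raster_stats, run


@pytest.fixture(scope="session")
def elemental_raster():
    """Leech elemental oscillator, 300 s at 1 ms steps (default build)."""
    return run(build_elemental(), 300_000)


@pytest.fixture(scope="session")
def elemental_stats(elemental_raster):
    """Burst statistics of both half-center neurons."""
    return {
        nid: raster_stats(elemental_raster, neuron=nid) for nid in (0, 1)
    }


@pytest.fixture(scope="session")
def segmental_raster():
    """Leech segmental oscillator, 300 s at 1 ms steps (default build)."""
    return run(build_segmental(), 300_000)


@pytest.fixture(scope="session")
def segmental_stats_l3(segmental_raster):
    net = build_segmental()
    return raster_stats(segmental_raster, neuron=net.neuron_index("L3"))
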