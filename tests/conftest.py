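import numpy as np
import pytest

from lakescape import hydro, synth


@pytest.fixture(scope="session")
def lake():
    """One synthetic lake shared across tests: DEM, shoreline, flow, network."""
    dem = synth.make_lake_dem(seed=0)
    filled = hydro.fill_sinks(dem)
    flow = hydro.flow_field(filled)
    threshold = max(1, int(0.01 * dem.valid().sum()))
    net = hydro.extract_stream_network(flow, threshold)
    ring = hydro.extract_shoreline(dem, synth.WATER_LEVEL)
    return {"dem": dem, "filled": filled, "flow": flow, "net": net, "ring": ring}


@pytest.fixture(scope="session")
def study(lake):
    """Lake plus default site layout and the four sample-level partitions."""
    sites = synth.place_sites(lake["ring"], seed=0)
    site_parts = synth.assign_partitions(sites, lake["dem"])
    parts = {k: synth.expand_partition(p, 3) for k, p in site_parts.items()}
    return {**lake, "sites": sites, "site_parts": site_parts, "parts": parts}


@pytest.fixture
def rng():
    return np.random.default_rng(42)
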