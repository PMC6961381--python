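import numpy as np
import pytest

import nestedgamma as ng
from nestedgamma import network as nw
from nestedgamma.neurons import NeuronModel, Compartment, ChannelSpec


@pytest.fixture(scope="session")
def pc_model():
    return ng.build_pc()


@pytest.fixture(scope="session")
def pv_model():
    return ng.build_interneuron("PV")


@pytest.fixture(scope="session")
def sst_model():
    return ng.build_interneuron("SST")


@pytest.fixture(scope="session")
def passive_cell():
    """Single leaky compartment: R = 1/g_L, tau = C/g_L, no spikes ever."""
    comp = Compartment("soma", 20.0, 20.0,
                       channels=[ChannelSpec("leak", 0.05, 0.0)])
    return NeuronModel("PV", [comp], E_leak=-65.0)


@pytest.fixture(scope="session")
def network_with_sst():
    return nw.build_network(with_sst=True)


@pytest.fixture(scope="session")
def network_without_sst():
    return nw.build_network(with_sst=False)


@pytest.fixture(scope="session")
def theta_run(network_with_sst):
    """One noise-free theta-driven run without CA3 input, reused widely."""
    proto = nw.StimulusProtocol(duration=1700.0, noise_sigma=0.0, seed=0)
    return nw.run_simulation(network_with_sst, proto, ca3_events=None)


@pytest.fixture(scope="session")
def pairing_runs(network_with_sst, network_without_sst):
    """Three seeds of the pairing experiment for each SST condition."""
    proto = nw.StimulusProtocol()
    out = {}
    for key, net in (("with", network_with_sst), ("without", network_without_sst)):
        _, summary = nw.run_repetitions(net, proto, n=3, base_seed=0)
        out[key] = summary
    return out


def make_trace(values, dt=0.1, unit="mV"):
    return ng.Trace(np.asarray(values, dtype=float), dt=dt, unit=unit)
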