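import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from pbmkit import synth
from pbmkit.energy_model import BindingModel, DinucCorrection, EnergyMatrix
from pbmkit.pbm_io import ProbeTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_truth():
    """A moderate-affinity L=5 ground-truth model."""
    return synth.make_binding_model(L=5, seed=42)


@pytest.fixture
def tiny_probes():
    """Three hand-written probes with background."""
    return ProbeTable(
        probe_ids=["p1", "p2", "p3"],
        sequences=["ACGTACGTACGT", "TTTTACGTCCCC", "GGGGGGGGGGGG"],
        signal=np.array([10.0, 20.0, 5.0]),
        background=np.array([1.0, 2.0, 1.5]),
        array_id="tiny",
    )


@pytest.fixture
def sim_probes(small_truth):
    """A small simulated array usable by fitting and k-mer summaries."""
    cfg = synth.SimConfig(truth=small_truth, n_probes=300, probe_length=25,
                          noise_sd=0.1, seed=7)
    return synth.simulate_pbm(cfg)


@pytest.fixture
def random_model(rng):
    """A random dependent binding model for gradient/oracle checks."""
    return BindingModel(
        energy=EnergyMatrix(rng.uniform(-1, 1, (5, 4))),
        dinuc=DinucCorrection(rng.uniform(-0.5, 0.5, (4, 16))),
        mu=0.3, w1=0.8, b1=-0.2,
    )
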