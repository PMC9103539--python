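import importlib.util
import sys
from pathlib import Path

import pytest

import ernascan as es


def _load_oracles():
    spec = importlib.util.spec_from_file_location(
        "oracles", Path(__file__).parent / "oracles.py"
    )
    module = importlib.util.module_from_spec(spec)
    sys.modules.setdefault("oracles", module)
    spec.loader.exec_module(module)
    return module


oracles_module = _load_oracles()


@pytest.fixture(scope="session")
def oracles():
    return oracles_module


@pytest.fixture(scope="session")
def default_config():
    return es.SimConfig(seed=42)


@pytest.fixture(scope="session")
def default_fixture(default_config):
    """The seed-42 synthetic locus, reads and ground truth."""
    sim = es.simulate_locus(default_config)
    reads = es.simulate_reads(sim.sequence, sim.truth, default_config)
    return sim, reads


@pytest.fixture(scope="session")
def screen_result(default_fixture):
    sim, reads = default_fixture
    return es.run_screen(
        peaks=sim.peaks,
        locus=sim.locus,
        repeats=sim.repeats,
        transcripts=sim.transcripts,
        locus_sequence=sim.sequence,
        reads=reads,
    )
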