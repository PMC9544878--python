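import pytest

from msea.examples import structured_demo
from msea.synthetic_data import simulate_reference, simulate_run, spike_in_spec
from msea.workflow import run_pipeline


@pytest.fixture(scope="session")
def demo():
    return structured_demo()


@pytest.fixture(scope="session")
def demo_result(demo):
    return run_pipeline(demo.run, demo.metabolites, demo.pathways)


@pytest.fixture(scope="session")
def spike_run():
    """One canonical spike-in run (seed 5) with its references and truth."""
    spec = spike_in_spec(seed=5)
    refs = simulate_reference(spec)
    run, truth = simulate_run(spec, refs)
    return spec, refs, run, truth


@pytest.fixture(scope="session")
def spike_result(spike_run):
    spec, refs, run, truth = spike_run
    return run_pipeline(run, refs.metabolites, refs.pathways)
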