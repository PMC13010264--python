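import numpy as np
import pytest

from cellodyn import kinetics as K
from cellodyn import synthetic


@pytest.fixture(scope="session")
def default_phantom():
    return synthetic.FibrilPhantom()


@pytest.fixture(scope="session")
def default_design():
    return K.CompetitionDesign()


@pytest.fixture(scope="session")
def rendered_phantom(default_phantom):
    """(height, modulus, meta) of the default fibril at 2 nm/px."""
    return synthetic.gen_fibril_phantom(default_phantom)


@pytest.fixture(scope="session")
def ablation_run(default_phantom):
    """One processed ablation experiment: (stack, truth, records, qc)."""
    from cellodyn import afm

    scenario = synthetic.DegradationScenario(mode="ablation", seed=7)
    stack, truth = synthetic.gen_ablation_stack(default_phantom, scenario)
    records, qc = afm.process_stack(stack)
    return stack, truth, records, qc


@pytest.fixture(scope="session")
def fragmentation_run(default_phantom):
    from cellodyn import afm

    scenario = synthetic.DegradationScenario(mode="fragmentation", seed=7)
    stack, truth = synthetic.gen_fragmentation_stack(default_phantom, scenario)
    records, qc = afm.process_stack(stack)
    return stack, truth, records, qc
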