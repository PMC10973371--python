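import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make _oracles importable

from sigforge.simulate import SimulationSpec, generate_cohort


@pytest.fixture(scope="session")
def demo_cohort():
    """The canonical 60-patient demo cohort with planted signature."""
    spec = SimulationSpec(n_patients=60, seed=1)
    expr, clin, truth = generate_cohort(spec)
    return spec, expr, clin, truth
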