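import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # lot_oracle helper

import mfclaims as m  # noqa: E402


@pytest.fixture(scope="session")
def small_bundle():
    """A 120-patient synthetic bundle with its ground-truth sidecar."""
    return m.generate_with_truth(m.GeneratorParams(n_patients=120, seed=7))


@pytest.fixture(scope="session")
def pipeline_small():
    """Full pipeline on a 250-patient bundle (shared across tests)."""
    return m.run_pipeline(params=m.GeneratorParams(n_patients=250, seed=11),
                          make_figures=False)
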