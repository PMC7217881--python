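import numpy as np
import pytest

from spectrosig import synthdata as sd


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six probes x 2 trials/category: structure checks, not decoding."""
    specs = [
        sd.ProbeSpec("P00", shaft_id="A", contact_index=0),
        sd.ProbeSpec(
            "P01",
            shaft_id="A",
            contact_index=1,
            signatures=[sd.SignatureSpec(61, 90, 100, 400, 3.0, None)],
        ),
        sd.ProbeSpec(
            "P02",
            shaft_id="A",
            contact_index=2,
            signatures=[sd.SignatureSpec(61, 90, 100, 400, 3.0, "face")],
        ),
        sd.ProbeSpec(
            "P03",
            shaft_id="B",
            contact_index=0,
            signatures=[
                sd.SignatureSpec(61, 90, 100, 400, 3.0, "face"),
                sd.SignatureSpec(9, 14, 200, 700, 0.5, "house"),
            ],
        ),
        sd.ProbeSpec("P04", shaft_id="B", contact_index=1),
        sd.ProbeSpec("P05", shaft_id="B", contact_index=2),
    ]
    return sd.generate_cohort(specs, trials_per_category=2, seed=42)
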