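import numpy as np
import pytest

from wmigcn import ClassSpec, SyntheticSpec, generate_dataset
from wmigcn.io import ECGRecord, LEAD_ORDER


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def tiny_spec(n_per_class=6, n_samples=400, seed=0):
    """A fast, deterministic three-class dataset for unit tests."""
    return SyntheticSpec(
        classes=(
            ClassSpec("SB", beat_rate_hz=1.0, within_cluster_coupling=0.5),
            ClassSpec("SR", beat_rate_hz=1.3, within_cluster_coupling=0.5),
            ClassSpec("ST", beat_rate_hz=2.0, within_cluster_coupling=0.6),
        ),
        n_records_per_class=n_per_class,
        n_samples=n_samples,
        fs=250.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def tiny_dataset():
    records, manifest = generate_dataset(tiny_spec())
    return records, manifest


@pytest.fixture
def random_record(rng):
    sig = rng.standard_normal((12, 600))
    return ECGRecord(record_id="r0", signal=sig, leads=LEAD_ORDER,
                     sampling_rate_hz=250.0, label="A")
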