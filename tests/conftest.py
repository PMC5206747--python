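import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dropfreeze import DropletAssay, DropletRecord

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_assay(
    temps,
    censored=None,
    sample_id="s1",
    treatment="crude",
    volume=0.01,
    plates=1,
):
    """Build a small assay from a list of freezing temperatures."""
    censored = censored or [False] * len(temps)
    per_plate = -(-len(temps) // plates)
    records = [
        DropletRecord(
            plate_id=f"plate{i // per_plate + 1}",
            droplet_id=f"d{i:03d}",
            freeze_temp=float(t),
            censored=bool(c),
        )
        for i, (t, c) in enumerate(zip(temps, censored))
    ]
    return DropletAssay(
        sample_id=sample_id, treatment=treatment, records=records, droplet_volume=volume
    )


@pytest.fixture
def two_droplet_assay():
    return make_assay([-3.0, -5.0])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
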