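import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from icelocus import (
    MechanismParams,
    SectorScheme,
    VideoParams,
    generate_onsets,
    generate_video,
)


@pytest.fixture(scope="session")
def scheme():
    return SectorScheme(5)


@pytest.fixture(scope="session")
def bulk_records():
    """10^5 bulk-generated onsets (uniform in cylinder volume)."""
    params = MechanismParams(
        p_awi=0.0, n_droplets=25_000, cycles_per_droplet=4, seed=11
    )
    records, truth = generate_onsets(params)
    return records, truth


@pytest.fixture(scope="session")
def assay_records():
    """A study-sized experiment: 8 droplets x 4 cycles, AWI-dominated."""
    params = MechanismParams(p_awi=0.6, seed=5)
    return generate_onsets(params)


@pytest.fixture(scope="session")
def freezing_video():
    """One synthetic freezing video with its truth table."""
    params = VideoParams(
        seed=21, onset_r_norm=0.9, onset_theta=np.radians(30.0), n_frames=20
    )
    stack, truth = generate_video(params)
    return params, stack, truth
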