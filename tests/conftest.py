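import numpy as np
import pytest

import synconduct as sc
from synconduct.synthetic import (
    default_on_gc_cell,
    default_on_gc_drive,
    default_stimulus,
)

FS = 10_000.0  # Hz, matching the digitization rate of the recordings


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def stimulus():
    return default_stimulus()


@pytest.fixture(scope="session")
def intensity(stimulus):
    return sc.make_stimulus(stimulus, FS)


@pytest.fixture(scope="session")
def drive_spec():
    return default_on_gc_drive()


@pytest.fixture(scope="session")
def gc_cell():
    return default_on_gc_cell()


@pytest.fixture(scope="session")
def passive_cell():
    return default_on_gc_cell(spiking=False)


@pytest.fixture
def small_sweeps():
    """Three short synthetic sweeps covering all modalities."""
    rng = np.random.default_rng(42)
    return [
        sc.SweepRecord(
            cell_id="cellA",
            modality="extracellular",
            sampling_rate=FS,
            signal=rng.standard_normal(100),
            condition="control",
            trial_index=0,
        ),
        sc.SweepRecord(
            cell_id="cellA",
            modality="current_clamp",
            sampling_rate=FS,
            signal=-60.0 + rng.standard_normal(100),
            condition="IEM",
            trial_index=0,
        ),
        sc.SweepRecord(
            cell_id="cellB",
            modality="voltage_clamp",
            sampling_rate=FS,
            signal=-50.0 * np.ones(80),
            holding_potential=-60.0,
            condition="control",
            trial_index=1,
        ),
    ]
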