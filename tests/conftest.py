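import numpy as np
import pytest

from microcoalesce import (
    AbundanceTable,
    SampleMetadata,
    filter_rare_asvs,
    generate_study,
    run_study,
    track_study,
)


@pytest.fixture(scope="session")
def default_study():
    """Default synthetic survey (seed 1): table, metadata, ground truth."""
    return generate_study(seed=1)


@pytest.fixture(scope="session")
def tracked_study(default_study):
    """Rare-filtered default study plus its source-tracking output."""
    table, meta, truth = default_study
    table = filter_rare_asvs(table)
    estimates, coalescence = track_study(table, meta, seed=1)
    return table, meta, truth, estimates, coalescence


@pytest.fixture(scope="session")
def default_report():
    """Full pipeline report on the default synthetic study (seed 1)."""
    return run_study(seed=1)


@pytest.fixture
def toy_table():
    """4 taxa x 3 samples with easy hand-checked totals."""
    counts = np.array(
        [
            [5, 3, 2],  # total 10
            [2, 2, 1],  # total 5
            [1, 2, 1],  # total 4
            [50000, 30000, 19981],  # total 99981
        ]
    )
    return AbundanceTable([f"t{i}" for i in range(1, 5)], ["s1", "s2", "s3"], counts)


@pytest.fixture
def toy_metadata():
    return [
        SampleMetadata("s1", "gut", "S1", species_code="AN", family="Cyprinidae", delta15N=11.0),
        SampleMetadata("s2", "water", "S1"),
        SampleMetadata("s3", "sediment", "S1"),
    ]
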