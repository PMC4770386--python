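import numpy as np
import pytest

from proteoturn import (
    NoiseModel,
    TurnoverModel,
    generate_proteome,
    simulate_psilac,
)

GRID_7 = (0.5, 1.5, 4, 8, 12, 24, 48)


@pytest.fixture(scope="session")
def small_truth():
    """50-gene proteome with 40% aTIS genes and its ground truth."""
    sequences, truth = generate_proteome(50, atis_fraction=0.4, seed=101)
    return sequences, truth


@pytest.fixture(scope="session")
def cohort_500():
    """500 proteoforms, 7-timepoint grid, sigma 0.1 — the agreement cohort."""
    _, truth = generate_proteome(500, atis_fraction=0.0, seed=42)
    peptides = simulate_psilac(
        truth,
        timepoints=GRID_7,
        noise=NoiseModel(sigma=0.1, missingness=0.0,
                         nonexponential_fraction=0.0),
        seed=43,
    )
    model = TurnoverModel.from_dataframe(
        peptides, accession_col="proteoform_id"
    )
    return truth, model


@pytest.fixture()
def exp_timecourse():
    """Noise-free exponential profile on the 7-point grid (B = -0.05)."""
    from proteoturn import NormalizedTimeCourse

    t = np.array(GRID_7, dtype=float)
    m = np.exp(-0.05 * t)
    return NormalizedTimeCourse("X", t, m, 1 - m)
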