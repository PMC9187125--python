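"""Shared fixtures: tiny hand-built series and small synthetic cohorts."""

import numpy as np
import pytest

from paintraj.cohort import PainObservation, PainSeries


def make_series(patient_id, times, scores):
    obs = [PainObservation(patient_id, float(t), int(y)) for t, y in zip(times, scores)]
    return PainSeries(patient_id, obs)


@pytest.fixture
def zigzag_series():
    """The worked hand-oracle series: scores (6, 2, 5, 1) at (0, 12, 36, 60) h."""
    return make_series("Z1", (0.0, 12.0, 36.0, 60.0), (6, 2, 5, 1))


@pytest.fixture
def linear_series():
    """Exact line: scores (0, 2, 4, 6) at (0, 24, 48, 72) h."""
    return make_series("L1", (0.0, 24.0, 48.0, 72.0), (0, 2, 4, 6))


@pytest.fixture(scope="session")
def wellsep_cohort():
    """One small well-separated synthetic cohort (shared, read-only)."""
    from paintraj import synthetic

    scen = synthetic.well_separated_scenario(n_patients=200, seed=11)
    return synthetic.generate_cohort(scen)
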