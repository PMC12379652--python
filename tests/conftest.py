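import warnings

import numpy as np
import pytest

import cardiomag as cm
from cardiomag.pipeline import extract_cohort
from cardiomag.synthetic import CohortSpec, simulate_cohort

warnings.filterwarnings("ignore", message=".*dropped.*")


@pytest.fixture(scope="session")
def grid():
    return cm.SensorGrid.regular()


@pytest.fixture(scope="session")
def phenotypes():
    return cm.default_phenotypes()


@pytest.fixture(scope="session")
def cohort50_features():
    """Default healthy-vs-CAD cohort, 50 + 50 subjects.

    Recordings are shortened to 8 s per phase (about 8-12 beats) to keep the
    suite fast; beat averaging converges well before that.
    """
    spec = CohortSpec(n_healthy=50, n_cad=50, master_seed=101, duration_s=8.0)
    features, failures = extract_cohort(simulate_cohort(spec))
    assert len(failures) == 0, f"pipeline failed for {failures['subject'].tolist()}"
    return features


def make_beat(data, fs=500.0, peak_index=0, grid_obj=None):
    """Wrap a samples x channels array as an AveragedBeat for unit tests."""
    data = np.asarray(data, dtype=float)
    n_ch = data.shape[1]
    # the grid is only consulted by field-map operations; unit beats with
    # other channel counts may carry the default grid
    g = grid_obj if grid_obj is not None else cm.SensorGrid.regular()
    return cm.AveragedBeat(
        beat=data,
        rms=cm.compute_rms_reference(data),
        fs=fs,
        n_averaged=1,
        grid=g,
        channel_mask=np.ones(n_ch, dtype=bool),
        peak_index=peak_index,
    )
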