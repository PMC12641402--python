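import logging

import numpy as np
import pandas as pd
import pytest

from dysconn import dci as dc
from dysconn import simulate as sim

logging.getLogger("dysconn").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale cohort small enough for per-test use."""
    return sim.default_cohort_spec(
        n_reference=12, n_patients=8, n_regions_per_hemisphere=24, n_timepoints=150
    )


@pytest.fixture(scope="session")
def dmn_effect():
    return sim.PlantedEffect(target="default-mode", baseline_shift=0.5, attenuation=0.6)


@pytest.fixture(scope="session")
def small_study(small_spec, dmn_effect):
    """Eight patients with attenuating default-mode hyperconnectivity."""
    return sim.generate_cohort(small_spec, [dmn_effect], seed=0)


@pytest.fixture(scope="session")
def small_scored(small_study):
    """(norms, tidy DCI table, wide DCC table) for the small study."""
    return dc.score_cohort(small_study)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def parcel_coords():
    """Sixty random parcel centroids shared by transcriptomics tests."""
    r = np.random.default_rng(7)
    return pd.DataFrame(
        r.uniform(0.0, 50.0, (60, 3)),
        columns=["x", "y", "z"],
        index=[f"P{i:03d}" for i in range(60)],
    )
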