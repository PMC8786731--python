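import numpy as np
import pytest
from hypothesis import settings

import trusscage as tc

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    return tc.sample_cohort(4, seed=42)


@pytest.fixture(scope="session")
def default_lattice():
    return tc.generate_cage(tc.CageParams(), seed=0)


@pytest.fixture(scope="session")
def default_run():
    """One full default cohort run (seed 42), shared across tests."""
    cfg = tc.RunConfig(seed=42, export_csv=False, export_vtk=False)
    return tc.run_cohort(cfg, out_dir=None)


def make_strain_field(values, weights=None):
    """StrainField from bare principal-strain values (unit weights)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if weights is None:
        weights = np.ones(n)
    return tc.StrainField(
        strut_id=np.zeros(n, dtype=int),
        s_mm=np.zeros(n),
        theta_rad=np.zeros(n),
        principal_ue=values,
        region=np.array(["anterior"] * n),
        weight_mm2=np.asarray(weights, dtype=float),
    )
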