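import numpy as np
import pytest

import corthick as ct
from corthick.preprocess import transform_predictors


@pytest.fixture(scope="session")
def null_cohort_200():
    """n=200 cohort with no planted effect (thickness independent of predictors)."""
    params = ct.CohortParams(n_subjects=200, seed=3)
    clinical, thickness = ct.simulate_cohort(params, ct.null_effect_spec(),
                                             thickness_seed=3)
    return clinical, thickness


@pytest.fixture(scope="session")
def pain_cohort_500():
    """n=500 cohort with one strong pain-driven component (20 thinned regions)."""
    spec = ct.EffectSpec(
        region_loadings=np.array([[-0.6] * 20 + [0.0] * 46]).T,
        predictor_weights=np.array([[1.0], [0], [0], [0], [0], [0], [0]]),
        noise_sd=0.1)
    params = ct.CohortParams(n_subjects=500, seed=11)
    clinical = ct.generate_clinical_table(params)
    thickness = ct.generate_thickness_matrix(clinical, spec, seed=11)
    return clinical, thickness, spec


@pytest.fixture(scope="session")
def solved_shell():
    """Spherical shell phantom (R1=8, R2=12, 1 mm) with solved potential."""
    vol = ct.make_phantom("spherical_shell", r1_mm=8, r2_mm=12, spacing=1.0)
    return vol, ct.solve_laplace(vol)


def design_of(clinical):
    return transform_predictors(clinical)
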