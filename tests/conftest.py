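import dataclasses

import numpy as np
import pytest

from contourprop.phantom import (AnatomyParams, AnatomyPrior, VariationParams,
                                 make_planning_case, sample_fraction_case)

SMALL_MEANS = {"background": 0.05, "body": 0.30, "bladder": 0.90,
               "rectum": 0.15, "ctv": 0.55}


def small_anatomy(**overrides) -> AnatomyParams:
    """Coarse 32^3 @ 3 mm anatomy (same physical geometry as the default)."""
    base = AnatomyParams(grid_shape=(32, 32, 32), spacing_mm=(3.0, 3.0, 3.0))
    return dataclasses.replace(base, **overrides)


@pytest.fixture(scope="session")
def planning_case():
    return make_planning_case(small_anatomy(seed=3), patient_id="fix0")


@pytest.fixture(scope="session")
def small_pair():
    """Planning case plus one moderately deformed fraction."""
    case = make_planning_case(small_anatomy(seed=5), patient_id="fix1")
    var = VariationParams(bladder_volume_factor_range=(1.15, 1.25),
                          rectum_volume_factor_range=(1.0, 1.1),
                          ctv_shift_sd_mm=0.5, elastic_amplitude_mm=1.0, seed=7)
    return sample_fraction_case(case, var, n_fractions=1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
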