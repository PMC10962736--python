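import numpy as np
import pandas as pd
import pytest

from mtisr.dependence import classify_dependent
from mtisr.diffexpr import run_contrast
from mtisr.io import arm_contrasts
from mtisr.presets import (
    HEART_MODELS,
    bat_coldstress,
    fiber_sunset,
    heart_threemodel,
    s59l_population,
)
from mtisr.simulate import generate_expression_fixture, generate_mask_fixture


def run_model_pipeline(fixture, models, **kwargs):
    """DE + dependence for every model of an expression fixture."""
    stress, dep = {}, {}
    for m in models:
        sc, kc = arm_contrasts(fixture.samples, m)
        s = run_contrast(fixture.matrix, sc, **kwargs)
        k = run_contrast(fixture.matrix, kc, **kwargs)
        stress[m] = s
        dep[m] = classify_dependent(s, k, model=m, **kwargs)
    return stress, dep


@pytest.fixture(scope="session")
def heart_fixture():
    return generate_expression_fixture(heart_threemodel(seed=1))


@pytest.fixture(scope="session")
def heart_pipeline(heart_fixture):
    return run_model_pipeline(heart_fixture, HEART_MODELS)


@pytest.fixture(scope="session")
def bat_fixture():
    return generate_expression_fixture(bat_coldstress(seed=1))


@pytest.fixture(scope="session")
def mask_fixture():
    return generate_mask_fixture(s59l_population(seed=1))


@pytest.fixture(scope="session")
def fiber_fixture():
    return fiber_sunset(seed=1)


@pytest.fixture()
def fiber_annotations(fiber_fixture):
    t = fiber_fixture.truth
    return pd.DataFrame({"label": t["label"], "ub_status": t["group"].str.removeprefix("ub_")})
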