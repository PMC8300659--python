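import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def wt_pipeline_fits():
    """2-site fits of three independent synthetic wild-type experiments."""
    from vimcys.simulate import WT_KINETICS, make_kinetics_plate
    from vimcys.alkylation import build_titration_curve
    from vimcys.titration import fit_pka

    fits = []
    for seed in (1, 2, 3):
        curve = build_titration_curve(make_kinetics_plate(WT_KINETICS, seed=seed))
        fits.append(fit_pka(curve, n_sites=2))
    return fits


@pytest.fixture(scope="session")
def figure6a_lanes():
    from vimcys.simulate import figure6a_design, make_gel_table

    return make_gel_table(figure6a_design(seed=20210707))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
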