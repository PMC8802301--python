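import numpy as np
import pytest
from hypothesis import settings

import hydrotherm as ht

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def cond298():
    return ht.Condition(T=298.0, IS=0.0)


@pytest.fixture(scope="session")
def hexane_model():
    return ht.hexane_like_model()


@pytest.fixture(scope="session")
def adamantane_model():
    return ht.adamantane_like_model()


@pytest.fixture(scope="session")
def flat_model():
    """Featureless potential (zero depth, negligible wall) for closed-form checks."""
    return ht.ModelPotential(
        cm_pos=8.0,
        depth_T_quad=(0.0, 0.0, 0.0),
        wall_pos=0.5,
        wall_height=0.0,
    )


@pytest.fixture(scope="session")
def small_hexane_dataset(cond298):
    """11-window hexane-like study at one condition, reduced sampling budget."""
    proto = ht.hexane_like_protocol(
        temperatures=(298.0,), ionic_strengths=(0.0,), n_samples=8000
    )
    return ht.generate_study(proto, seed=1234)


@pytest.fixture(scope="session")
def small_hexane_pmf(small_hexane_dataset, cond298):
    series = small_hexane_dataset.for_condition(cond298)
    hist = ht.build_histograms(series)
    pmf = ht.wham_solve(hist)
    return ht.subtract_baseline(pmf, (12.0, 13.5))
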