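import numpy as np
import pytest
from hypothesis import settings

from timingprf.fitting import TimingPRF
from timingprf.forward import ForwardDesign
from timingprf.models import ModelSpec
from timingprf.stimuli import make_run

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def run_schedule():
    return make_run()


@pytest.fixture(scope="session")
def shared_design(run_schedule):
    return ForwardDesign(run_schedule)


@pytest.fixture(scope="session")
def estimator_factory(run_schedule, shared_design):
    """Estimators sharing the (expensive) design and grid-prediction caches."""
    cache: dict[tuple, tuple] = {}

    def make(family: str, refine: bool = False, **kw) -> TimingPRF:
        spec = kw.pop("spec", None) or ModelSpec(family)
        est = TimingPRF(spec=spec, schedule=run_schedule, refine=refine, **kw)
        est._design_cache = shared_design
        key = (spec.family, spec.space, spec.scale)
        if key in cache:
            est._grid_cache = cache[key]
        else:
            cache[key] = est._grid_predictions()
        return est

    return make


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
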