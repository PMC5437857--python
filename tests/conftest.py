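import warnings
import zlib

import numpy as np
import pytest

warnings.filterwarnings("ignore", message=".*ArviZ is undergoing a major refactor.*")

from reefvar.inference import McmcConfig, fit_model
from reefvar.synthetic_data import SurveyDesign, generate_survey, paper_like_params


@pytest.fixture(scope="session")
def params():
    """Calibrated paper-like structural parameters."""
    return paper_like_params()


@pytest.fixture()
def rng(request):
    # per-test deterministic stream, independent of execution order
    name_seed = zlib.crc32(request.node.name.encode())
    return np.random.default_rng([20260924, name_seed])


@pytest.fixture(scope="session")
def small_survey(params):
    """A balanced 8-site, 10-year, 7-transect synthetic survey."""
    return generate_survey(params, SurveyDesign.grid(8, 10, 7), seed=11)


@pytest.fixture(scope="session")
def small_posterior(small_survey):
    """A short two-chain fit of the small survey, shared across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_model(
            small_survey,
            mcmc=McmcConfig(chains=2, warmup=400, iters=400),
            seed=5,
        )
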