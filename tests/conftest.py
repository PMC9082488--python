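import dataclasses
import warnings

import numpy as np
import pytest
from hypothesis import settings

from editfit.signal_model import AcquisitionParams
from editfit.synthetic_cohort import (
    DEFAULT_TRUTH_MEANS,
    NoiseConfig,
    default_acquisitions,
    default_catalog,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def acq():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def acq_map():
    # reduced transient count: 128 total per sequence (HERMES 32 per
    # sub-experiment, MEGA 64 per sub-experiment, matching the equal
    # total scan time of the protocol)
    return default_acquisitions(128, 128)


@pytest.fixture(scope="session")
def hermes_catalog():
    return default_catalog("HERMES80")


@pytest.fixture(scope="session")
def mega_catalog():
    return default_catalog("MEGA120")


@pytest.fixture(scope="session")
def truth():
    return dict(DEFAULT_TRUTH_MEANS)


@pytest.fixture(scope="session")
def zero_noise():
    return NoiseConfig(
        noise_sd=0.0,
        drift_hz_per_transient=0.0,
        jitter_hz_sd=0.0,
        phase_jitter_deg_sd=0.0,
        baseline_wobble=0.0,
        eddy_phase_amp_rad=0.0,
    )


@pytest.fixture(scope="session")
def repro_study():
    """Within-subject CVs of both methods across 50 replicate test-retest
    cohorts (12 subjects x 2 scans, default noise).  Shared by the
    reproducibility-pattern tests; this is the most expensive fixture in
    the suite."""
    from editfit.experiments import run_reproducibility_study

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_reproducibility_study(n_seeds=50, base_seed=1)


@pytest.fixture()
def quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
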