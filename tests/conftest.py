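import warnings

import pytest

import krigfield as kf


@pytest.fixture(autouse=True)
def _silence_small_sample_warning():
    # many tests intentionally use tiny training sets; the n < 10 d heuristic
    # warning is informative in production but noise here
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="training set of", category=UserWarning
        )
        yield


@pytest.fixture(scope="session")
def triatomic():
    return kf.make_fixture("triatomic")


@pytest.fixture(scope="session")
def ring16():
    return kf.make_fixture("ring16")


@pytest.fixture(scope="session")
def chain16():
    return kf.make_fixture("chain16")


@pytest.fixture(scope="session")
def triatomic_modes(triatomic):
    return kf.vibrational_analysis(triatomic.geometry, triatomic.hessian)
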