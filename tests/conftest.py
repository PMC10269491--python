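import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ironclock import (  # noqa: E402
    BandLabel,
    ReferentSpec,
    SubjectRecord,
    calibrate,
    generate_referent,
    load_reference_constants,
)


@pytest.fixture(scope="session")
def younger_constants():
    return load_reference_constants(BandLabel.younger)


@pytest.fixture(scope="session")
def older_constants():
    return load_reference_constants(BandLabel.older)


@pytest.fixture(scope="session")
def younger_referent():
    """Default synthetic younger-band calibration sample, n = 10 000."""
    return generate_referent(ReferentSpec(band=BandLabel.younger, n=10_000, seed=7))


@pytest.fixture(scope="session")
def younger_calibration(younger_referent):
    return calibrate(younger_referent)


def mean_subject(constants, subject_id="mean", hiv_status="negative", **overrides):
    """A subject whose every clock input sits at the band mean."""
    fields = dict(
        subject_id=subject_id,
        age=constants.mu["a"],
        hiv_status=hiv_status,
        rtl=constants.mu["RTL"],
        serum_iron=constants.mu["Fe"],
        tibc=constants.mu["TIBC"],
        ferritin=constants.mu["F"],
    )
    fields.update(overrides)
    return SubjectRecord(**fields)
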