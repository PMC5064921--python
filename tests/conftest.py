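import pytest

from scidata import fixtures

FIXTURE_NAMES = ("ph", "refractive_index", "nmr_limonene", "glucose_scf")


@pytest.fixture(scope="session", params=FIXTURE_NAMES)
def fixture_name(request):
    return request.param


@pytest.fixture()
def fixture_doc(fixture_name):
    # fresh instance per test: serialization mutates ids in place
    return fixtures.make_fixture(fixture_name)


@pytest.fixture()
def ph_doc():
    return fixtures.make_fixture("ph")
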