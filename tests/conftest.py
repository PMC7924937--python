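import pytest

import hairpinrep as hr


@pytest.fixture(scope="session")
def library():
    """The packaged 16-strand library with info domains identified."""
    return hr.load_packaged_library()


@pytest.fixture(scope="session")
def buffer_cond():
    return hr.REPLICATION_BUFFER


@pytest.fixture(scope="session")
def info0(library):
    return library.info_domains["0"]


@pytest.fixture(scope="session")
def design_report(library):
    return hr.validate_design(library)
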