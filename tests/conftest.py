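import pytest

from agodyn.seeds import GuideRNA, LibraryMember, classify_library, expand_degenerate
from agodyn.simulate import MIR122_GUIDE, RBNSLibraryConfig


@pytest.fixture(scope="session")
def guide() -> GuideRNA:
    return MIR122_GUIDE


@pytest.fixture(scope="session")
def library_config() -> RBNSLibraryConfig:
    return RBNSLibraryConfig()


@pytest.fixture(scope="session")
def library(library_config):
    return library_config.members()


@pytest.fixture(scope="session")
def library_classes(library, guide):
    return classify_library(library, guide, scan_mode="fixed-register")
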