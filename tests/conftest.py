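import numpy as np
import pytest

from straddlemd.builder import (build_aform_duplex, build_asl, build_scenario,
                                default_template, ASL_SER3)


@pytest.fixture(scope="session")
def template():
    return default_template()


@pytest.fixture(scope="session")
def duplex(template):
    return build_aform_duplex("GCAGG", "CCUGC", template)


@pytest.fixture(scope="session")
def asl(template):
    return build_asl(ASL_SER3, template)


@pytest.fixture(scope="session")
def u36(template):
    """The wild-type frameshift scenario (scene, restraints); session-wide,
    treat as read-only and copy before modifying."""
    return build_scenario("u36", template)


@pytest.fixture()
def u36_scene(u36):
    return u36[0].copy()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20090745)
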