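import logging

import pytest

from hcmnlp import load_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return load_lexicon()


@pytest.fixture(scope="session", autouse=True)
def _quiet_warnings():
    """Keep structured pipeline warnings out of test output noise."""
    logger = logging.getLogger("hcmnlp")
    level = logger.level
    logger.setLevel(logging.ERROR)
    yield
    logger.setLevel(level)
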