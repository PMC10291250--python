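import pytest

import xylemflow as xf


@pytest.fixture(scope="session")
def default_cfg():
    return xf.default_config(seed=0)


@pytest.fixture(scope="session")
def default_study(default_cfg):
    return xf.generate_study(default_cfg)


@pytest.fixture(scope="session")
def default_analysis(default_study):
    return xf.analyze(default_study.tables())
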