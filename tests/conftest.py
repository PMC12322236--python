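import numpy as np
import pytest

from spinprep import FieldConditions, RelaxationParams, build_preset, PRESET_NAMES


@pytest.fixture
def relax():
    return RelaxationParams.from_ratio(0.05, 1.0)


@pytest.fixture
def relax_ratio2():
    return RelaxationParams.from_ratio(0.05, 2.0)


@pytest.fixture
def ideal_fields():
    return FieldConditions(f_sl_nominal=500.0)


@pytest.fixture(params=PRESET_NAMES)
def preset(request):
    return build_preset(request.param)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
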