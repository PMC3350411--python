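import math
from dataclasses import replace

import numpy as np
import pytest

from edemastir.phantom import (
    DarkCoreSpec,
    PhantomSpec,
    build_phantom,
    default_lge_sequence,
    default_stir_sequence,
    render,
)


@pytest.fixture(scope="session")
def noise_free_spec():
    return replace(PhantomSpec(), noise_sigma=0.0, dark_core=DarkCoreSpec())


@pytest.fixture(scope="session")
def noise_free_study(noise_free_spec):
    return build_phantom(noise_free_spec)


@pytest.fixture(scope="session")
def stir_sequence():
    return default_stir_sequence(heart_rate=60.0)


@pytest.fixture(scope="session")
def noise_free_stir(noise_free_study, stir_sequence):
    return render(noise_free_study, stir_sequence)


@pytest.fixture(scope="session")
def noise_free_lge(noise_free_study, noise_free_spec):
    return render(noise_free_study, default_lge_sequence(noise_free_spec))
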