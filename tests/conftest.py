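import numpy as np
import pytest

from phenochip.chip import (
    segment_chip_celldeath,
    segment_chip_mito,
    segment_chip_morphometric,
)
from phenochip.synthetic import FixtureSpec, chip_params_for, generate_chip_stack


@pytest.fixture(scope="session")
def morpho_fixture():
    spec = FixtureSpec.morpho(seed=11)
    stack, gt = generate_chip_stack(spec, "morpho")
    chip = segment_chip_morphometric(stack, chip_params_for(spec, "morpho"))
    return spec, stack, gt, chip


@pytest.fixture(scope="session")
def mito_fixture():
    spec = FixtureSpec.mito(seed=12)
    stack, gt = generate_chip_stack(spec, "mito")
    chip = segment_chip_mito(stack, chip_params_for(spec, "mito"))
    return spec, stack, gt, chip


@pytest.fixture(scope="session")
def viability_fixture():
    spec = FixtureSpec.viability(seed=13)
    stack, gt = generate_chip_stack(spec, "viability")
    chip = segment_chip_celldeath(stack, chip_params_for(spec, "viability"))
    return spec, stack, gt, chip


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_mask(rng, shape=(5, 20, 20), p=0.3):
    return rng.random(shape) < p
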