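"""Shared fixtures: the default filter bank and cached phantom stacks.

Phantom generation is deterministic per preset, so session scope lets
many tests share one realization without re-voxelizing.
"""

import numpy as np
import pytest

from osteotrace.filter_bank import build_bank
from osteotrace.phantom import generate_phantom, preset_spec


@pytest.fixture(scope="session")
def bank():
    return build_bank()


@pytest.fixture(scope="session")
def straight_phantom():
    return generate_phantom(preset_spec("straight_constant"))


@pytest.fixture(scope="session")
def tapered10_phantom():
    return generate_phantom(preset_spec("tapered_ctg10e-3"))


@pytest.fixture(scope="session")
def tilted15_phantom():
    return generate_phantom(preset_spec("tilted15"))


@pytest.fixture(scope="session")
def bridged_phantom():
    return generate_phantom(preset_spec("adjacent_bones_bridged"))


def make_annulus(shape=(64, 64), center=(32.0, 32.0), r_in=10.0, r_out=20.0):
    """Binary annulus mask by pixel-center inclusion."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    d = np.hypot(yy - center[0], xx - center[1])
    return (d >= r_in) & (d <= r_out)
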