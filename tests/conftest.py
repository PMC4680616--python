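"""Shared fixtures: all geometry is generated programmatically at test time.

Session scope keeps mesh generation and joint construction out of the hot
loop; resolutions are kept modest so the full suite runs on one CPU in
minutes.
"""

import numpy as np
import pytest

from vertmech.articulation import make_joint
from vertmech.synthetic import (VertebraParams, make_column, make_vertebra)


@pytest.fixture(scope="session")
def generic_vertebra():
    return make_vertebra(VertebraParams(), resolution=900)


@pytest.fixture(scope="session")
def procoelous_vertebra():
    return make_vertebra(
        VertebraParams(CL=16, CW=14, CH=10, centrum_kind="procoelous",
                       PZW=12, A_PZ=160, TPW=40, NSH=14, NSL=10, LW=10,
                       canal_radius=2.6, facet_diameter=6.0),
        resolution=900)


@pytest.fixture(scope="session")
def generic_column():
    return make_column("protosuchus", n_vertebrae=3, resolution=700)


@pytest.fixture(scope="session")
def generic_joint(generic_column):
    return make_joint(generic_column, 0)


@pytest.fixture(scope="session")
def croc_column():
    return make_column("crocodylus", n_vertebrae=4, resolution=700)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20151104)
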