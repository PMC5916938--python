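import numpy as np
import pytest

from mthelix.imaging import render_density
from mthelix.lattice import (AtomModel, HelicalSymmetry, LatticeSpec,
                             build_microtubule)

SYM_DECORATED_MT = HelicalSymmetry(168.083, 5.50)
SYM_CURVED_COMPLEX = HelicalSymmetry(168.089, 5.57)


@pytest.fixture(scope="session")
def lattice_15r():
    return build_microtubule(LatticeSpec(15, "R", n_dimers_per_pf=3), SYM_DECORATED_MT)


@pytest.fixture(scope="session")
def volume_15r(lattice_15r):
    return render_density(lattice_15r, 4.0, 96)


@pytest.fixture(scope="session")
def single_dimer_unit():
    """One asymmetric unit (alpha+beta dimer) of the 15R lattice."""
    model = build_microtubule(LatticeSpec(15, "R", n_dimers_per_pf=1), SYM_DECORATED_MT)
    keep = (model.pf_index == 0) & (model.dimer_index == 0)
    return AtomModel(model.positions[keep], model.weights[keep],
                     model.pf_index[keep], model.dimer_index[keep],
                     model.monomer_kind[keep])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
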