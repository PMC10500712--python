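import numpy as np
import pytest

from paratensor.constants import ANGSTROM
from paratensor.synthetic import make_observables, make_structure
from paratensor.tensors import (
    ChiTensor,
    ExperimentContext,
    ParamagneticCentre,
    TensorParameters,
    from_parameters,
)

TRUE_POSITION = np.array([2.0, -1.0, 3.0]) * ANGSTROM


@pytest.fixture(scope="session")
def truth_params() -> TensorParameters:
    """Ground-truth anisotropy used by most round-trip fixtures."""
    return TensorParameters(
        axial=30e-32, rhombic=8e-32,
        euler_alpha=0.6, euler_beta=1.1, euler_gamma=0.4,
        position=TRUE_POSITION.copy(),
    )


@pytest.fixture(scope="session")
def truth_chi(truth_params) -> ChiTensor:
    return from_parameters(truth_params)


@pytest.fixture(scope="session")
def ctx() -> ExperimentContext:
    return ExperimentContext(B0=18.8, temperature=298.0, tau_r=4.0e-9,
                             t1e=1.0e-13, mu_eff=9.72)


@pytest.fixture(scope="session")
def centre(truth_chi, ctx) -> ParamagneticCentre:
    return ParamagneticCentre(truth_chi, ctx)


@pytest.fixture(scope="session")
def structure():
    """50-residue single-model synthetic chain."""
    return make_structure(n_residues=50, seed=1)


@pytest.fixture(scope="session")
def pcs_table(structure, centre):
    return make_observables(structure, centre, "PCS")


@pytest.fixture(scope="session")
def rdc_table(structure, centre):
    return make_observables(structure, centre, "RDC")
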