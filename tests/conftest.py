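import numpy as np
import pytest

from isoflok import (
    alpha_curve_oracle,
    alpha_curve_resolvent,
    build_hopf_fixture,
    build_surrogate_cardiomyocyte,
    find_fixed_point,
)
from isoflok.models import derivative_tensors
from isoflok.zoo import surrogate_fixed_points

HOPF_MU, HOPF_OMEGA0 = 0.01, 1.0


@pytest.fixture(scope="session")
def hopf():
    """The reference weakly unstable focus with analytic tensors."""
    model = build_hopf_fixture(mu=HOPF_MU, omega0=HOPF_OMEGA0, c=1.0)
    fp = find_fixed_point(model, np.array([0.1, 0.0]))
    tensors = derivative_tensors(model, fp.x0)
    return model, fp, tensors


@pytest.fixture(scope="session")
def hopf_alpha_grid():
    """Period grid straddling the resonance at 2*pi/omega0."""
    return np.linspace(3.0, 11.0, 25)


@pytest.fixture(scope="session")
def hopf_alpha_resolvent(hopf, hopf_alpha_grid):
    model, fp, tensors = hopf
    return alpha_curve_resolvent(fp, tensors, model, j=0, T_grid=hopf_alpha_grid)


@pytest.fixture(scope="session")
def hopf_alpha_oracle(hopf, hopf_alpha_grid):
    model, fp, _ = hopf
    return alpha_curve_oracle(model, 0, hopf_alpha_grid, fp=fp,
                              eps_pair=(0.02, 0.01))


@pytest.fixture(scope="session")
def cell():
    """The surrogate cardiomyocyte with its rest/depolarized fixed points."""
    model = build_surrogate_cardiomyocyte()
    rest, depo = surrogate_fixed_points(model)
    return model, rest, depo


@pytest.fixture(scope="session")
def cell_alpha(cell):
    model, rest, depo = cell
    tensors = derivative_tensors(model, depo.x0)
    T_grid = np.linspace(4.0, 24.0, 21)
    return alpha_curve_resolvent(depo, tensors, model, j=0, T_grid=T_grid)


@pytest.fixture(scope="session")
def paced_cell_state(cell):
    from isoflok.cardiac import pace_to_steady_state

    model, rest, depo = cell
    return pace_to_steady_state(model)


@pytest.fixture(scope="session")
def neural_ops():
    """Shipped phase-model fixture discretized at a test-scale grid, with its
    stationary density and spectrum."""
    from isoflok.neural import (assemble_fp_operator, fp_fixed_point_spectrum,
                                neural_fixture_phase_model, NEURAL_FIXTURE)

    ph = neural_fixture_phase_model()
    ops = assemble_fp_operator(ph, D=NEURAL_FIXTURE["D"],
                               sigma_c=NEURAL_FIXTURE["sigma_c"], N_grid=200)
    rho0, lam, fp = fp_fixed_point_spectrum(ops)
    return ph, ops, rho0, lam, fp
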