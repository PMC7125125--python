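"""Bidomain tissue: plaques, virtual electrodes, field trials, statistics."""

import copy

import numpy as np
import pytest

from isoflok.bidomain import (
    BidomainSolver,
    FieldProtocol,
    NO_FIELD,
    TissueGrid,
    TrialResult,
    generate_fiber_plaques,
    run_field_trial,
    success_statistics,
)


@pytest.fixture(scope="module")
def small_grid():
    return TissueGrid(nx=40, ny=40, dx=0.0566)


@pytest.fixture(scope="module")
def plaque_grid(small_grid):
    return generate_fiber_plaques(small_grid, n_segments=12, seed=3)


@pytest.fixture(scope="module")
def solver(plaque_grid, cell):
    model, rest, depo = cell
    return BidomainSolver(plaque_grid, model, dt=0.02)


def test_plaque_generation_deterministic_and_calibrated(small_grid):
    g1 = generate_fiber_plaques(small_grid, n_segments=12, seed=3)
    g2 = generate_fiber_plaques(small_grid, n_segments=12, seed=3)
    g3 = generate_fiber_plaques(small_grid, n_segments=12, seed=4)
    assert np.array_equal(g1.plaque_mask, g2.plaque_mask)
    assert not np.array_equal(g1.plaque_mask, g3.plaque_mask)
    assert abs(g1.plaque_summary["mean_length_mm"] - 2.69) < 0.269
    assert np.all(g1.g_ix[g1.plaque_mask] == 0.0)
    g0 = generate_fiber_plaques(small_grid, n_segments=0, seed=1)
    assert not g0.plaque_mask.any()


def test_domain_too_small_rejected():
    tiny = TissueGrid(nx=5, ny=5, dx=0.0283)
    with pytest.raises(ValueError, match="too small"):
        generate_fiber_plaques(tiny, n_segments=3)


def test_rest_state_is_stationary_without_field(solver):
    st = solver.initial_state()
    V0 = st.Vm.copy()
    for _ in range(5):
        st = solver.step(st, NO_FIELD)
    assert np.max(np.abs(st.Vm - V0)) < 1e-10


def test_elliptic_solve_satisfies_discrete_balance(solver):
    st = solver.initial_state()
    rng = np.random.default_rng(0)
    Vm = st.Vm + rng.standard_normal(st.Vm.shape)
    E = 500.0  # mV/cm
    Ve = solver.solve_Ve(Vm, E)
    resid = (solver.Lie @ Ve.ravel() + solver.Li @ Vm.ravel()
             - solver._flux_pattern * E)
    assert np.max(np.abs(resid)) < 1e-6
    assert abs(Ve.mean()) < 1e-10       # zero-mean constraint


def test_virtual_electrodes_localized_at_plaques(small_grid, plaque_grid, cell):
    """Without plaques the interior barely feels the field; with plaques the
    interior response is orders of magnitude larger."""
    model, rest, depo = cell
    fld = FieldProtocol(frequency=100.0, strength=1.76, duration=30.0)
    interior = {}
    for name, grid in [("homog", small_grid), ("plaques", plaque_grid)]:
        sv = BidomainSolver(grid, model, dt=0.02)
        st = sv.initial_state()
        st = sv.run(st, fld, 12.5)
        dV = np.abs(st.Vm - rest.x0[0])
        interior[name] = dV[:, 5:-5].max()
    assert interior["homog"] < 0.01 * interior["plaques"]


def test_resolution_refinement_changes_response_mildly(cell):
    """Halving dx changes the point response by a bounded amount."""
    model, rest, depo = cell
    traces = {}
    for nx, dx in [(30, 0.08), (60, 0.04)]:
        grid = TissueGrid(nx=nx, ny=nx, dx=dx)
        g = generate_fiber_plaques(grid, n_segments=0, seed=0)
        # one hand-placed plaque spanning the same physical stretch
        j = nx // 2
        i0, i1 = int(0.3 * nx), int(0.7 * nx)
        g.g_ix[j, i0:i1] = 0.0
        sv = BidomainSolver(g, model, dt=0.01)
        st = sv.initial_state()
        fld = FieldProtocol(frequency=100.0, strength=1.76, duration=15.0)
        st = sv.run(st, fld, 12.5)
        traces[nx] = st.Vm[j, int(0.3 * nx) + 1]
    rel = abs(traces[30] - traces[60]) / max(abs(traces[60]), 1e-9)
    assert rel < 0.05


def test_field_trial_zero_strength_changes_nothing(solver):
    st = solver.initial_state()
    res = run_field_trial(copy.deepcopy(st), solver,
                          FieldProtocol(frequency=33.0, strength=0.0,
                                        duration=60.0),
                          post_window=20.0)
    # quiescent tissue stays quiescent: nothing blocked (never above -30)
    assert res.block_fraction == 0.0
    assert res.spiral_eliminated


def test_nan_detector(solver):
    st = solver.initial_state()
    st.Vm[5, 5] = np.nan
    with pytest.raises(RuntimeError, match="NaN"):
        solver.step(st, NO_FIELD)


def test_dt_stability_guard(plaque_grid, cell):
    model, rest, depo = cell
    with pytest.raises(ValueError, match="stability"):
        BidomainSolver(plaque_grid, model, dt=5.0)


def test_success_statistics_wilson():
    trials = [TrialResult(True, np.zeros((2, 2), bool), 0.0, None,
                          NO_FIELD)] * 11
    out = success_statistics(trials)
    assert out["successes"] == 11
    assert round(out["lower"], 2) == 0.74
    assert out["upper"] == 1.0
    with pytest.raises(ValueError):
        success_statistics([])
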