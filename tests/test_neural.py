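"""Density pipeline: operator assembly, spectra, input transform,
thresholds, population simulation and order parameter."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from isoflok.core import DenseTensorOps, alpha_from_ops, _eig_sorted
from isoflok.neural import (
    OrderParameterSeries,
    PhaseModel,
    PopulationSimConfig,
    analytic_phase_model,
    assemble_fp_operator,
    desync_threshold_curve,
    fp_fixed_point_spectrum,
    fp_input_transform,
    neural_fixture_phase_model,
    order_parameter,
    simulate_population,
    single_neuron_phase_model,
)


def flat_phase_model(omega=0.8, n_grid=96, Zval=1.0, Vval=0.0):
    th = np.linspace(0, 2 * np.pi, n_grid + 1)[:-1]
    return PhaseModel(omega=omega, theta_grid=th,
                      Z=np.full(n_grid, Zval), V=np.full(n_grid, Vval))


def test_uniform_density_is_fixed_point_for_flat_profiles():
    ops = assemble_fp_operator(flat_phase_model(), D=0.02, sigma_c=0.5,
                               N_grid=96)
    rho = np.full(96, 1 / (2 * np.pi))
    assert np.max(np.abs(ops.F(rho))) < 1e-12


def test_probability_conserved_along_trajectories():
    ph = neural_fixture_phase_model()
    ops = assemble_fp_operator(ph, D=1.0, sigma_c=0.08, N_grid=128)
    rho = np.full(128, 1 / (2 * np.pi))
    rho = rho * (1 + 0.05 * np.cos(ops.theta))
    sol = solve_ivp(lambda t, x: ops.F(x), (0, 100.0), rho,
                    rtol=1e-10, atol=1e-13)
    mass = sol.y.sum(axis=0) * ops.dtheta
    assert np.max(np.abs(mass - mass[0])) < 1e-12
    assert sol.y.min() > -1e-10


def test_zero_coupling_spectrum_matches_circulant_symbol():
    """Z = 1, V flat: the operator is circulant advection-diffusion with the
    discrete symbol -i w sin(kh)/h - 2D(1-cos kh)/h^2."""
    D, omega, N = 0.01, 0.75, 128
    ops = assemble_fp_operator(flat_phase_model(omega=omega), D=D,
                               sigma_c=0.0, N_grid=N)
    rho0, lam, fp = fp_fixed_point_spectrum(ops)
    assert np.max(np.abs(rho0 - 1 / (2 * np.pi))) < 1e-12
    h = ops.dtheta
    for k in (1, 2, 3):
        sym = -1j * omega * np.sin(k * h) / h - 2 * D * (1 - np.cos(k * h)) / h ** 2
        gap = np.min(np.abs(lam - np.conj(sym)))
        assert gap < 1e-10


def test_fixture_has_single_weakly_unstable_pair(neural_ops):
    ph, ops, rho0, lam, fp = neural_ops
    l1 = lam[0]
    assert 0.0 < l1.real < 0.05
    assert lam[1] == pytest.approx(np.conj(l1))
    others = lam[2:]
    assert np.max(others.real) < 1e-6   # conservation zero mode + damped rest
    assert rho0.min() > 0               # near-uniform positive density
    assert rho0.sum() * ops.dtheta == pytest.approx(1.0, abs=1e-12)


def test_input_transform_and_alpha_invariance(neural_ops):
    """The Householder change of variables puts the input on e_1; the alpha
    computed in original coordinates with the distributed input direction
    must match the transformed system's."""
    ph = neural_fixture_phase_model()
    ops = assemble_fp_operator(ph, D=1.0, sigma_c=0.08, N_grid=64)
    rho0, lam, fp = fp_fixed_point_spectrum(ops)
    Vmat, V_inv, r0 = fp_input_transform(rho0, ops)
    e1 = np.zeros(64)
    e1[0] = 1.0
    assert np.max(np.abs(Vmat @ r0 - e1)) < 1e-12
    Jt = Vmat @ ops.J0 @ V_inv
    lam_t = np.sort_complex(np.linalg.eigvals(Jt))
    lam_o = np.sort_complex(np.linalg.eigvals(ops.J0))
    assert np.max(np.abs(lam_t - lam_o)) < 1e-7
    # dense Hessians of the quadratic system, transformed
    N = 64
    H = np.zeros((N, N, N))
    for i in range(N):
        H[i] = np.outer(ops.C1[i], ops.Vw) + np.outer(ops.Vw, ops.C1[i])
    T3 = np.zeros((N,) * 4)
    a_orig = alpha_from_ops(DenseTensorOps(ops.J0, H, T3), r0, lam, 0, 4.0)[0]
    Ht = np.einsum("il,aj,ljk,kb->iab", Vmat, V_inv.T, H, V_inv, optimize=True)
    lam_t2, _, _ = _eig_sorted(Jt)
    a_trans = alpha_from_ops(DenseTensorOps(Jt, Ht, T3), e1, lam_t2, 0, 4.0)[0]
    assert a_trans == pytest.approx(a_orig, rel=1e-8)
    # and the structured contraction path agrees with the dense one
    a_struct = alpha_from_ops(ops, r0, lam, 0, 4.0)[0]
    assert a_struct == pytest.approx(a_orig, rel=1e-10)


def test_input_transform_rejects_vanishing_direction():
    ph = neural_fixture_phase_model()
    ops = assemble_fp_operator(ph, D=1.0, sigma_c=0.08, N_grid=32)
    with pytest.raises(ValueError, match="vanishes"):
        fp_input_transform(np.zeros(32), ops)


def test_desync_threshold_formula():
    curve = _curve([4.0, 8.0], [-0.003, 0.01])
    out = desync_threshold_curve(0.003 + 0.7j, curve, np.array([4.0, 8.0]))
    assert out[0] == pytest.approx(1.0)
    assert np.isnan(out[1])            # Re alpha >= 0: unavailable
    # scaling law: doubling |Re alpha| divides A_crit by sqrt(2)
    out2 = desync_threshold_curve(0.003 + 0.7j, _curve([4.0], [-0.006]),
                                  np.array([4.0]))
    assert out2[0] == pytest.approx(1 / np.sqrt(2))


def _curve(Ts, alphas):
    from isoflok.core import AlphaCurve
    Ts = np.asarray(Ts, float)
    al = np.asarray(alphas, complex)
    return AlphaCurve(j=0, T_grid=Ts, alpha=al, chi=np.abs(al),
                      beta=np.angle(al),
                      resonance_mask=np.zeros(len(Ts), dtype=bool))


def test_population_simulation_deterministic_per_seed():
    ph = neural_fixture_phase_model()
    cfg = dict(N=20, duration=40.0, D=1.0, sigma_c=0.08, model="phase",
               phase=ph)
    s1, r1 = simulate_population(PopulationSimConfig(seed=5, **cfg))
    s2, r2 = simulate_population(PopulationSimConfig(seed=5, **cfg))
    s3, r3 = simulate_population(PopulationSimConfig(seed=6, **cfg))
    assert all(np.array_equal(a, b) for a, b in zip(s1, s2))
    assert np.array_equal(r1["theta"], r2["theta"])
    assert not np.array_equal(r1["theta"], r3["theta"])


def test_noiseless_uncoupled_identical_phases_stay_identical():
    ph = neural_fixture_phase_model()
    cfg = PopulationSimConfig(N=30, duration=60.0, seed=1, D=0.0, sigma_c=0.0,
                              model="phase", phase=ph)
    spikes, rec = simulate_population(cfg)
    assert np.max(np.ptp(rec["theta"], axis=1)) < 1e-12
    tg = np.linspace(20, 60, 50)
    R = order_parameter(spikes, 30, tg)
    assert np.nanmin(R.R) > 1 - 1e-9


def test_seed_required():
    with pytest.raises((ValueError, TypeError)):
        PopulationSimConfig(N=10, duration=10.0, seed=None)


def test_order_parameter_limits():
    # identical spike trains -> R = 1
    base = np.arange(1.0, 100.0, 8.4)
    tg = np.linspace(20, 80, 100)
    R1 = order_parameter([base.copy() for _ in range(10)], 10, tg)
    assert np.nanmin(R1.R) > 1 - 1e-9
    # evenly staggered trains -> R ~ 0 (roots of unity)
    N, T = 16, 8.0
    staggered = [base + (k * T / N) for k in range(N)]
    staggered = [np.arange(1.0 + k * T / N, 100.0, T) for k in range(N)]
    R0 = order_parameter(staggered, N, tg)
    assert R0.mean_R < 0.05
    # independent jittered trains: R = O(1/sqrt N)
    rng = np.random.default_rng(0)
    trains = [np.cumsum(rng.uniform(4, 12, size=30)) for _ in range(64)]
    Rr = order_parameter(trains, 64, np.linspace(40, 120, 100))
    assert Rr.mean_R < 4.0 / np.sqrt(64)
    # neurons with < 2 spikes are excluded and counted
    Rx = order_parameter([base, np.array([5.0])], 2, tg)
    assert Rx.excluded_neurons == 1


def test_single_neuron_phase_reduction_consistency():
    """Adjoint PRC of the conductance neuron: normalization residual and the
    frequency/period identity."""
    from isoflok.zoo import build_neuron_model

    n = build_neuron_model()
    ph = single_neuron_phase_model(n, n_grid=128)
    assert ph.omega * ph.period == pytest.approx(2 * np.pi, rel=1e-10)
    assert 8.0 < ph.period < 8.8
    assert np.all(np.isfinite(ph.Z)) and np.all(np.isfinite(ph.V))
    # PRC scale: voltage perturbations advance the phase by finite amounts
    assert 1e-3 < np.max(np.abs(ph.Z)) < 10.0
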