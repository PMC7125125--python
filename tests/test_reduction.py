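"""Isostable reduction machinery on forced orbits."""

import numpy as np
import pytest

from isoflok import find_fixed_point, forced_periodic_orbit
from isoflok.core import delta_kappa_from_Cjj, reduction_on_orbit
from isoflok.models import ModelSpec, derivative_tensors
from isoflok.stimulus import fourier_spectrum


def sine_stim(T, amp):
    return fourier_spectrum(lambda t: amp * np.sin(2 * np.pi * t / T), T, K=1)


@pytest.fixture(scope="module")
def hopf_reduction(hopf):
    model, fp, _ = hopf
    T, eps = 5.5, 0.05
    orb = forced_periodic_orbit(model, sine_stim(T, eps), fp=fp)
    red = reduction_on_orbit(model, orb, indices=[0, 1], n_theta=96)
    return model, fp, orb, red


def test_normalization_invariants(hopf_reduction):
    model, fp, orb, red = hopf_reduction
    r = red.normalization_residuals
    assert r["Z_normalization"] < 1e-6
    assert r["I0_normalization"] < 1e-8
    assert r["orbit_periodicity"] < 1e-8
    # curves are periodic on the theta grid
    for curve in [red.Z, red.I[0], red.p[0], red.C[(0, 0)]]:
        assert np.max(np.abs(curve[-1] - curve[0])) < 1e-6 * max(
            1.0, np.max(np.abs(curve)))


def test_zero_amplitude_reduction_constants(hopf):
    """At the unforced fixed point the curves are the constant eigen-objects
    and the second-order curve equals its closed-form constant."""
    model, fp, tensors = hopf
    T = 5.5
    orb = forced_periodic_orbit(model, sine_stim(T, 0.0), fp=fp)
    red = reduction_on_orbit(model, orb, indices=[0], n_theta=48)
    Z = red.Z
    assert np.max(np.abs(Z - Z[0])) < 1e-8
    assert Z[0][-1] == pytest.approx(2 * np.pi / T, rel=1e-10)
    J0, H, _ = tensors
    v, w = fp.V[:, 0], fp.W[0, :]
    I0 = w / (v @ w)
    C0 = -np.linalg.solve(J0.T, np.einsum("i,ijk,k->j", I0, H, v))
    got = red.C[(0, 0)][0][:2]
    assert np.max(np.abs(got - C0)) < 1e-8


def test_linear_model_second_order_curves_vanish():
    A = np.array([[-0.2, 1.0], [-1.0, -0.2]])
    m = ModelSpec(n=2, F=lambda x: A @ x, J=lambda x: A,
                  H=lambda x: np.zeros((2, 2, 2)),
                  T3=lambda x: np.zeros((2, 2, 2, 2)), name="lin")
    orb = forced_periodic_orbit(m, sine_stim(4.0, 0.3))
    red = reduction_on_orbit(m, orb, indices=[0], n_theta=48)
    assert np.max(np.abs(red.B[0][:, 0])) < 1e-8
    assert np.max(np.abs(red.C[(0, 0)][:, 0] - red.C[(0, 0)][0, 0])) < 1e-8


def test_exponent_shift_from_C_curve_matches_reforced_orbit(hopf_reduction):
    """First-order exponent-shift prediction from the C_1^1 curve against
    re-solving the orbit under the perturbed stimulus."""
    model, fp, orb, red = hopf_reduction
    T = orb.T
    du = lambda t: 0.004 * np.sin(2 * np.pi * t / T + 0.7)
    dk_pred = delta_kappa_from_Cjj(red.C_first(0, 0), du, T, t_grid=red.t_grid)
    stim2 = fourier_spectrum(
        lambda t: 0.05 * np.sin(2 * np.pi * t / T) + du(t), T, K=1)
    orb2 = forced_periodic_orbit(model, stim2, fp=fp)
    dk_true = orb2.kappa[0] - orb.kappa[0]
    assert abs(dk_pred - dk_true) / abs(dk_true) < 0.10


@pytest.mark.parametrize("case", ["zero", "const-vs-zero-mean", "sin-sin"])
def test_quadrature_identities(case):
    T = 8.0
    t = np.linspace(0, T, 513)
    omega = 2 * np.pi / T
    if case == "zero":
        dk = delta_kappa_from_Cjj(np.sin(omega * t), lambda s: 0.0 * s, T, t)
        assert dk == pytest.approx(0.0, abs=1e-14)
    elif case == "const-vs-zero-mean":
        dk = delta_kappa_from_Cjj(np.full_like(t, 3.7),
                                  lambda s: np.sin(omega * s), T, t)
        assert dk == pytest.approx(0.0, abs=1e-10)
    else:
        dk = delta_kappa_from_Cjj(np.sin(omega * t),
                                  lambda s: np.sin(omega * s), T, t)
        assert dk == pytest.approx(0.5, abs=1e-6)


def test_period_mismatch_rejected():
    with pytest.raises(ValueError, match="mismatch"):
        delta_kappa_from_Cjj(np.zeros(10), lambda s: s, 1.0, np.zeros(11))
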