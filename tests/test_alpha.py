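"""The alpha transfer curve: resolvent route, brute-force oracle, predictions
and the energy-optimal sinusoid rule."""

import numpy as np
import pytest

from isoflok import (
    AlphaCurve,
    alpha_curve_oracle,
    alpha_curve_resolvent,
    find_fixed_point,
    forced_periodic_orbit,
    optimal_sinusoid,
    predict_floquet_shift,
)
from isoflok.core import alpha_from_tensors
from isoflok.models import ModelSpec, derivative_tensors
from isoflok.stimulus import equal_spectrum_family, fourier_spectrum


def test_linear_model_alpha_identically_zero():
    A = np.array([[-0.1, 0.9], [-0.9, -0.1]])
    m = ModelSpec(n=2, F=lambda x: A @ x, J=lambda x: A,
                  H=lambda x: np.zeros((2, 2, 2)),
                  T3=lambda x: np.zeros((2, 2, 2, 2)), name="lin")
    fp = find_fixed_point(m, np.ones(2))
    tensors = derivative_tensors(m, fp.x0)
    curve = alpha_curve_resolvent(fp, tensors, m, 0, np.linspace(2, 12, 10))
    assert np.max(np.abs(curve.alpha)) < 1e-8


def test_scalar_cubic_closed_form():
    """1-D toy x' = lam x + c x^3: the chain reduces to
    alpha(T) = 3 c / (2 (omega^2 + lam^2)) — an independent closed form."""
    lam, c = -0.2, 0.7
    J0 = np.array([[lam]])
    H = np.zeros((1, 1, 1))
    T3 = np.full((1, 1, 1, 1), 6 * c)
    for T in [3.0, 7.0, 15.0]:
        omega = 2 * np.pi / T
        a, _ = alpha_from_tensors(J0, H, T3, np.array([1.0]),
                                  np.array([lam + 0j]), 0, T)
        assert a.real == pytest.approx(1.5 * c / (omega ** 2 + lam ** 2),
                                       rel=1e-12)
        assert a.imag == pytest.approx(0.0, abs=1e-12)


def test_scalar_quadratic_closed_form():
    """With a quadratic term (Hessian h) the chain gives
    alpha = (6 c3 - h^2/lam) / (4 (omega^2 + lam^2))."""
    lam, h, c3 = 0.05, 0.8, -0.3
    J0 = np.array([[lam]])
    H = np.full((1, 1, 1), h)
    T3 = np.full((1, 1, 1, 1), 6 * c3)
    T = 9.0
    omega = 2 * np.pi / T
    a, _ = alpha_from_tensors(J0, H, T3, np.array([1.0]),
                              np.array([lam + 0j]), 0, T)
    expect = (6 * c3 - h ** 2 / lam) / (4 * (omega ** 2 + lam ** 2))
    assert a.real == pytest.approx(expect, rel=1e-10)


def test_conjugate_pair_symmetry(hopf, hopf_alpha_grid):
    model, fp, tensors = hopf
    c1 = alpha_curve_resolvent(fp, tensors, model, 0, hopf_alpha_grid)
    c2 = alpha_curve_resolvent(fp, tensors, model, 1, hopf_alpha_grid)
    assert np.allclose(c1.alpha, np.conj(c2.alpha), atol=1e-12)


def test_resonance_flagging_and_extremum_location(hopf, hopf_alpha_resolvent,
                                                  hopf_alpha_grid):
    model, fp, _ = hopf
    curve = hopf_alpha_resolvent
    # the flagged points straddle 2*pi/Im(lambda_1)
    Tres = 2 * np.pi / fp.eigenvalues[0].imag
    omegas = 2 * np.pi / hopf_alpha_grid
    assert np.array_equal(curve.resonance_mask,
                          np.abs(omegas - 1.0) < 1e-2)
    # |Re alpha| peaks within one grid step of the resonance period
    i = int(np.argmin(curve.alpha.real))
    step = hopf_alpha_grid[1] - hopf_alpha_grid[0]
    assert abs(hopf_alpha_grid[i] - Tres) <= step + 1e-9


def test_oracle_matches_resolvent_off_resonance(hopf_alpha_resolvent,
                                                hopf_alpha_oracle):
    res, orc = hopf_alpha_resolvent, hopf_alpha_oracle
    ok = ~(res.resonance_mask | orc.resonance_mask)
    assert ok.sum() >= 20
    rel = np.abs(res.alpha[ok] - orc.alpha[ok]) / np.maximum(
        np.abs(orc.alpha[ok]), 1e-10)
    assert np.max(rel) <= 0.05


def test_oracle_epsilon_pair_self_consistency(hopf_alpha_oracle):
    """Far from resonance the two raw amplitude estimates differ from each
    other by less than either differs from zero — convergence evidence."""
    orc = hopf_alpha_oracle
    far = ~orc.resonance_mask & (np.abs(2 * np.pi / orc.T_grid - 1.0) > 0.3)
    raw = orc.raw_pair[:, far]
    pair_gap = np.abs(raw[0] - raw[1])
    assert np.all(pair_gap < np.abs(raw[0]))


def test_prediction_zero_stimulus_returns_lambda(hopf, hopf_alpha_resolvent):
    model, fp, _ = hopf
    stim = fourier_spectrum(lambda t: 0.0 * np.asarray(t), 5.0, K=1)
    # grid does not cover T/k for zero-power harmonics: must not matter
    pred = predict_floquet_shift(fp, hopf_alpha_resolvent, stim)
    assert pred.predicted_kappa == fp.eigenvalues[0]


def test_prediction_depends_only_on_power_spectrum(hopf):
    model, fp, tensors = hopf
    T = 5.6
    grid = np.unique(np.concatenate([np.linspace(1.5, 6.2, 40),
                                     [T, T / 2, T / 3]]))
    curve = alpha_curve_resolvent(fp, tensors, model, 0, grid)
    fam = equal_spectrum_family(T, K=3, seeds=[0, 1, 2])
    preds = [predict_floquet_shift(fp, curve, s.scaled(0.02)).predicted_kappa
             for s in fam]
    assert preds[0] == preds[1] == preds[2]   # bit-identical


def test_prediction_inside_guard_band_raises(hopf, hopf_alpha_resolvent):
    model, fp, _ = hopf
    Tres = 2 * np.pi  # resonance of the fixture
    stim = fourier_spectrum(lambda t: 0.1 * np.sin(2 * np.pi * t / Tres),
                            Tres, K=1)
    with pytest.raises(ValueError, match="guard band"):
        predict_floquet_shift(fp, hopf_alpha_resolvent, stim)


def _table_curve(Ts, alphas, j=0):
    Ts = np.asarray(Ts, float)
    al = np.asarray(alphas, complex)
    return AlphaCurve(j=j, T_grid=Ts, alpha=al, chi=np.abs(al),
                      beta=np.angle(al),
                      resonance_mask=np.zeros(len(Ts), dtype=bool))


def test_optimal_sinusoid_table_example():
    fp = _FakeFP(0.01 + 0.9j)
    curve = _table_curve([4.0, 8.0], [-0.5, -1.2])
    opt = optimal_sinusoid(fp, curve, E0=0.1, T_m=10.0)
    assert opt.stabilizable
    assert opt.T_star == 8.0
    assert opt.kappa_lower_bound == pytest.approx(0.01 - 0.24)
    assert opt.amplitude == pytest.approx(np.sqrt(0.2))


def test_optimal_sinusoid_not_stabilizable():
    fp = _FakeFP(0.01 + 0.9j)
    curve = _table_curve([4.0, 8.0], [0.2, 0.4])
    opt = optimal_sinusoid(fp, curve, E0=0.1, T_m=10.0)
    assert not opt.stabilizable
    assert opt.T_star is None


class _FakeFP:
    def __init__(self, lam1):
        self.eigenvalues = np.array([lam1, np.conj(lam1)])


def test_small_eps_second_order_convergence(hopf):
    """|kappa_measured - kappa_predicted| / eps^2 shrinks ~ linearly in eps:
    the prediction is second-order accurate."""
    model, fp, tensors = hopf
    T = 5.2
    curve = alpha_curve_resolvent(fp, tensors, model, 0, np.array([T]))
    errs = []
    eps_list = [0.04, 0.02, 0.01]
    for eps in eps_list:
        stim = fourier_spectrum(
            lambda t: eps * np.sin(2 * np.pi * t / T), T, K=1)
        orb = forced_periodic_orbit(model, stim, fp=fp)
        pred = predict_floquet_shift(fp, curve, stim)
        errs.append(abs(orb.kappa[0] - pred.predicted_kappa) / eps ** 2)
    # normalized error decreases roughly proportionally to eps
    assert errs[1] < 0.7 * errs[0]
    assert errs[2] < 0.7 * errs[1]
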