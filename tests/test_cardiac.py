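"""Single-cell HFES experiments on the surrogate cardiomyocyte."""

import numpy as np
import pytest

from isoflok.cardiac import (
    HFESProtocol,
    PacingProtocol,
    apply_hfes,
    block_threshold_scan,
    c11_vs_amplitude,
    equal_energy_comparison,
    freeze_slow_variables,
    pace_to_steady_state,
)
from isoflok.models import ModelSpec


def test_pacing_protocol_validation():
    with pytest.raises(ValueError):
        PacingProtocol(width=1000.0, interval=100.0)
    p = PacingProtocol()
    assert p.current(2.0) == 9.5
    assert p.current(7.0) == 0.0
    assert p.current(1003.0) == 9.5


def test_pacing_reaches_periodic_response(cell, paced_cell_state):
    model, rest, depo = cell
    # doubling the beat budget barely changes the returned state
    again = pace_to_steady_state(model, max_beats=40)
    assert np.linalg.norm(again - paced_cell_state) < 1e-5
    # zero-amplitude pacing cannot excite: errors out
    with pytest.raises(RuntimeError, match="no action potentials"):
        pace_to_steady_state(model, PacingProtocol(amplitude=0.0),
                             max_beats=3)


def test_block_outcomes_bracket_the_predicted_threshold(cell, cell_alpha,
                                                        paced_cell_state):
    """No block well below A_crit(T); block moderately above it."""
    model, rest, depo = cell
    T = 10.0
    a = cell_alpha.alpha_at(T).real
    A_crit = np.sqrt(depo.eigenvalues[0].real / -a)
    low = apply_hfes(model, paced_cell_state,
                     HFESProtocol("sine", 0.4 * A_crit, T, duration=1250.0))[1]
    high = apply_hfes(model, paced_cell_state,
                      HFESProtocol("sine", 1.25 * A_crit, T, duration=1250.0))[1]
    assert not low.blocked
    assert high.blocked
    assert high.min_V_in_window > low.min_V_in_window


def test_zero_amplitude_cell_repolarizes(cell, paced_cell_state):
    model, rest, depo = cell
    (t, V), out = apply_hfes(model, paced_cell_state,
                             HFESProtocol("sine", 0.0, 10.0, duration=1250.0))
    assert not out.blocked
    assert V[-1] < -60.0


def test_threshold_scan_monotone_and_reproducible(cell, paced_cell_state):
    model, rest, depo = cell
    T_grid = np.array([6.0, 10.0, 14.0])
    kw = dict(A_cap=4.0, A_tol=0.1, duration=1250.0)
    c1 = block_threshold_scan(model, "sine", T_grid, state=paced_cell_state,
                              **kw)
    c2 = block_threshold_scan(model, "sine", T_grid, state=paced_cell_state,
                              **kw)
    assert np.array_equal(c1.A_crit, c2.A_crit)    # deterministic
    assert np.all(np.isfinite(c1.A_crit))
    assert np.all(np.diff(c1.A_crit) < 0)          # decreasing in T


def test_equal_energy_sinusoid_minimum(cell):
    model, rest, depo = cell
    res = equal_energy_comparison(model, T=20.0, E_budget=1.0,
                                  eps_list=[0.5, 1.0], fp=depo)
    for eps in (0.5, 1.0):
        vals = {k: v[eps] for k, v in res.items()}
        assert all(np.isfinite(v) for v in vals.values())
        assert min(vals, key=vals.get) == "sine"
    # all shapes converge to lambda_1 at vanishing amplitude
    res0 = equal_energy_comparison(model, T=20.0, E_budget=1.0,
                                   eps_list=[1e-4], fp=depo)
    lam1 = depo.eigenvalues[0].real
    for k, v in res0.items():
        assert v[1e-4] == pytest.approx(lam1, abs=1e-6)


def test_c11_growth_then_saturation(cell, cell_alpha):
    model, rest, depo = cell
    out = c11_vs_amplitude(model, T=10.0, A_list=[0.05, 0.1, 0.2, 1.2, 2.4],
                           fp=depo, alpha_curve=cell_alpha, n_theta=64)
    rows = [r for r in out["rows"] if r["ok"]]
    assert len(rows) == 5
    # linear growth of the curve at small amplitude (slope test)
    A = np.array([r["A"] for r in rows[:3]])
    amp = np.array([r["c11_amp"] for r in rows[:3]])
    fit = np.polyfit(A, amp, 1)
    r2 = 1 - np.sum((amp - np.polyval(fit, A)) ** 2) / np.sum(
        (amp - amp.mean()) ** 2)
    assert r2 > 0.99
    # saturation at the largest amplitude
    assert out["saturation_ratio"] < 1.0
    # predicted vs measured exponent agree at the smallest amplitude ...
    small = rows[0]
    assert small["kappa_measured"].real == pytest.approx(
        small["kappa_predicted"].real, abs=0.1 * abs(
            small["kappa_predicted"].real))
    # ... and the agreement degrades monotonically with amplitude
    errs = [abs(r["kappa_measured"].real - r["kappa_predicted"].real)
            for r in rows]
    assert errs[-1] > errs[0]


@pytest.fixture(scope="module")
def five_var_cell(cell):
    """Surrogate cell padded with an exactly constant state and a slow
    drift state, for the freezing reduction."""
    model, rest, depo = cell

    def F(x):
        d2 = model.f(x[:2])
        slow = -1e-3 * (x[3] - 0.7) + 1e-4 * (x[0] + 26.0) * 0.0
        return np.array([d2[0] + 0.01 * (x[3] - 0.7), d2[1], 0.0, slow,
                         -0.5 * (x[4] - 0.2)])

    b = np.zeros(5)
    b[0] = 1.0
    return ModelSpec(n=5, F=F, state_names=("V", "w", "c0", "s", "f"),
                     input_direction=b, name="padded-cell")


def test_freeze_nothing_is_identity(five_var_cell):
    pacing = PacingProtocol()
    hfes = HFESProtocol("sine", 2.0, 10.0, duration=500.0)
    reduced, report = freeze_slow_variables(five_var_cell, pacing, hfes,
                                            freeze_set=[],
                                            settle_time=400.0,
                                            average_window=300.0)
    assert reduced is five_var_cell
    assert report["frozen"] == {}


def test_freeze_constant_state_preserves_dynamics(five_var_cell):
    from scipy.integrate import solve_ivp

    pacing = PacingProtocol()
    hfes = HFESProtocol("sine", 2.0, 10.0, duration=800.0)
    reduced, report = freeze_slow_variables(
        five_var_cell, pacing, hfes, freeze_set=[2],
        settle_time=400.0, average_window=300.0)
    assert reduced.n == 4
    assert report["frozen"][2] == pytest.approx(0.0, abs=1e-10)
    x0_full = np.array([-26.0, 11.0, 0.0, 0.7, 0.2])
    x0_red = x0_full[[0, 1, 3, 4]]
    sf = solve_ivp(lambda t, x: five_var_cell.f(x), (0, 100), x0_full,
                   rtol=1e-10, atol=1e-12)
    sr = solve_ivp(lambda t, x: reduced.f(x), (0, 100), x0_red,
                   rtol=1e-10, atol=1e-12)
    assert np.linalg.norm(sf.y[[0, 1, 3, 4], -1] - sr.y[:, -1]) < 1e-8


def test_freeze_slow_state_approximates_blocked_dynamics(five_var_cell):
    from scipy.integrate import solve_ivp

    pacing = PacingProtocol()
    hfes = HFESProtocol("sine", 2.0, 10.0, duration=800.0)
    reduced, report = freeze_slow_variables(
        five_var_cell, pacing, hfes, freeze_set=[2, 3],
        settle_time=400.0, average_window=300.0)
    x0_full = np.array([-26.0, 11.0, 0.0, report["frozen"][3], 0.2])
    keep = report["kept"]

    def forced_full(t, x):
        d = five_var_cell.f(x)
        d[0] += 2.0 * np.sin(2 * np.pi * t / 10.0)
        return d

    def forced_red(t, x):
        d = reduced.f(x)
        d[0] += 2.0 * np.sin(2 * np.pi * t / 10.0)
        return d

    sf = solve_ivp(forced_full, (0, 100), x0_full, rtol=1e-9, atol=1e-11)
    sr = solve_ivp(forced_red, (0, 100), x0_full[keep], rtol=1e-9, atol=1e-11)
    scale = max(1.0, np.abs(sf.y[0]).max())
    assert abs(sf.y[0, -1] - sr.y[0, -1]) / scale < 0.01


def test_freeze_requires_maintained_block(five_var_cell):
    pacing = PacingProtocol()
    weak = HFESProtocol("sine", 0.05, 10.0, duration=800.0)
    with pytest.raises(RuntimeError, match="blocked regime"):
        freeze_slow_variables(five_var_cell, pacing, weak, freeze_set=[2],
                              settle_time=400.0, average_window=300.0)
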