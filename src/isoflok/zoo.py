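"""Shipped vector fields: analytic fixtures and physiological surrogates.

Three families:

* :func:`build_hopf_fixture` — a planar normal form with a weakly unstable
  focus at the origin (eigenvalues ``mu +- i omega0``), cubic saturation,
  optional extra stable directions and an optional similarity transform.
  Every derivative tensor is available analytically, which makes this the
  reference fixture for the reduction machinery.
* :func:`build_neuron_model` — a 3-variable thalamic-type conductance-based
  neuron (transmembrane voltage plus two gating variables).  This is a
  reconstruction of the standard model used in the desynchronization
  literature, shipped behind a config switch; with the default parameters and
  baseline current 5 uA/cm^2 it fires tonically with a period near 8.4 ms.
* :func:`build_surrogate_cardiomyocyte` — a 2-variable excitable cell in
  physical units (mV, ms) with a stable rest state near -80 mV and a weakly
  unstable depolarized spiral point; a stand-in for high-dimensional ionic
  models whose depolarized state can be stabilized by high-frequency forcing.
  The mechanism under study is model-generic, so the surrogate reproduces the
  phase-portrait structure, not a specific cell's currents.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .models import ModelSpec

Array = np.ndarray

__all__ = [
    "build_hopf_fixture",
    "build_neuron_model",
    "build_surrogate_cardiomyocyte",
    "THALAMIC_PARAMS",
    "SURROGATE_PARAMS",
    "MODEL_REGISTRY",
    "get_model",
]


# ---------------------------------------------------------------------------
# Hopf normal-form fixture
# ---------------------------------------------------------------------------

def build_hopf_fixture(
    mu: float = 0.01,
    omega0: float = 1.0,
    c: float = 1.0,
    extra_eigs: Sequence[float] = (),
    transform: Optional[Array] = None,
    seed: Optional[int] = None,
) -> ModelSpec:
    """Weakly unstable focus with cubic saturation.

    Core dynamics (the first two coordinates)::

        x' = mu x - omega0 y - c (x^2 + y^2) x
        y' = omega0 x + mu y - c (x^2 + y^2) y

    so the origin has eigenvalues ``mu +- i omega0``; for ``mu > 0`` and
    ``c > 0`` a stable limit cycle of radius ``sqrt(mu/c)`` bounds the
    instability.  ``extra_eigs`` appends decoupled linear directions with the
    prescribed (real) eigenvalues.  ``transform`` (or a random orthogonal
    transform drawn with ``seed``) conjugates the whole field, preserving the
    spectrum while mixing coordinates; the input direction remains the first
    coordinate of the transformed system.
    """
    if c <= 0:
        raise ValueError("cubic coefficient c must be positive "
                         "(bounded nonlinearity)")
    extra = np.asarray(extra_eigs, dtype=float)
    n = 2 + extra.size

    def F_base(x):
        out = np.empty(n)
        r2 = x[0] ** 2 + x[1] ** 2
        out[0] = mu * x[0] - omega0 * x[1] - c * r2 * x[0]
        out[1] = omega0 * x[0] + mu * x[1] - c * r2 * x[1]
        out[2:] = extra * x[2:]
        return out

    def J_base(x):
        J = np.zeros((n, n))
        J[0, 0] = mu - c * (3 * x[0] ** 2 + x[1] ** 2)
        J[0, 1] = -omega0 - 2 * c * x[0] * x[1]
        J[1, 0] = omega0 - 2 * c * x[0] * x[1]
        J[1, 1] = mu - c * (x[0] ** 2 + 3 * x[1] ** 2)
        for i, lam in enumerate(extra):
            J[2 + i, 2 + i] = lam
        return J

    def H_base(x):
        H = np.zeros((n, n, n))
        H[0, 0, 0] = -6 * c * x[0]
        H[0, 0, 1] = H[0, 1, 0] = -2 * c * x[1]
        H[0, 1, 1] = -2 * c * x[0]
        H[1, 1, 1] = -6 * c * x[1]
        H[1, 0, 1] = H[1, 1, 0] = -2 * c * x[0]
        H[1, 0, 0] = -2 * c * x[1]
        return H

    def T3_base(x):
        T = np.zeros((n, n, n, n))
        T[0, 0, 0, 0] = -6 * c
        for p in [(0, 1, 1), (1, 0, 1), (1, 1, 0)]:
            T[0, p[0], p[1], p[2]] = -2 * c
        T[1, 1, 1, 1] = -6 * c
        for p in [(1, 0, 0), (0, 1, 0), (0, 0, 1)]:
            T[1, p[0], p[1], p[2]] = -2 * c
        return T

    if transform is None and seed is not None:
        rng = np.random.default_rng(seed)
        q, _ = np.linalg.qr(rng.standard_normal((n, n)))
        transform = q
    params = dict(mu=mu, omega0=omega0, c=c, extra_eigs=tuple(extra))

    if transform is None:
        return ModelSpec(n=n, F=F_base, J=J_base, H=H_base, T3=T3_base,
                         name="hopf", params=params)

    S = np.asarray(transform, dtype=float)
    Si = np.linalg.inv(S)

    def F_t(y):
        return S @ F_base(Si @ y)

    def J_t(y):
        return S @ J_base(Si @ y) @ Si

    def H_t(y):
        Hb = H_base(Si @ y)
        # H~_i = sum_l S_il  Si^T H_l Si
        return np.einsum("il,aj,ljk,kb->iab", S, Si.T, Hb, Si)

    def T3_t(y):
        Tb = T3_base(Si @ y)
        return np.einsum("il,aj,ljkm,kb,mc->iabc", S, Si.T, Tb, Si, Si)

    return ModelSpec(n=n, F=F_t, J=J_t, H=H_t, T3=T3_t,
                     name="hopf-transformed", params=params)


# ---------------------------------------------------------------------------
# thalamic-type neuron (reconstruction)
# ---------------------------------------------------------------------------

#: Reconstruction of the 3-variable thalamic neuron used throughout the
#: desynchronization literature.  Conductances in mS/cm^2, potentials in mV,
#: time in ms, currents in uA/cm^2.
THALAMIC_PARAMS = dict(
    C=1.0,            # uF/cm^2
    I_b=5.0,          # uA/cm^2 baseline drive
    g_L=0.05, E_L=-70.0,
    g_Na=3.0, E_Na=50.0,
    g_K=5.0, E_K=-90.0,
    g_T=5.0, E_T=0.0,
)


def build_neuron_model(params: Optional[dict] = None) -> ModelSpec:
    """3-variable thalamic-type neuron: states ``(V, h, r)``.

    ``V`` is the transmembrane voltage (mV), ``h`` the sodium/potassium
    inactivation gate and ``r`` the T-type calcium inactivation gate.  With
    the default parameter block and ``I_b = 5 uA/cm^2`` the model fires
    tonically.  This is a reconstruction (the original parameterization is
    external); it is shipped behind this config switch so alternative blocks
    can be substituted.
    """
    p = dict(THALAMIC_PARAMS)
    if params:
        p.update(params)
    C = p["C"]

    def minf(V):
        return 1.0 / (1.0 + np.exp(-(V + 37.0) / 7.0))

    def hinf(V):
        return 1.0 / (1.0 + np.exp((V + 41.0) / 4.0))

    def rinf(V):
        return 1.0 / (1.0 + np.exp((V + 84.0) / 4.0))

    def pinf(V):
        return 1.0 / (1.0 + np.exp(-(V + 60.0) / 6.2))

    def tauh(V):
        ah = 0.128 * np.exp(-(V + 46.0) / 18.0)
        bh = 4.0 / (1.0 + np.exp(-(V + 23.0) / 5.0))
        return 1.0 / (ah + bh)

    def taur(V):
        return 28.0 + np.exp(-(V + 25.0) / 10.5)

    def F(x):
        V, h, r = x
        I_L = p["g_L"] * (V - p["E_L"])
        I_Na = p["g_Na"] * minf(V) ** 3 * h * (V - p["E_Na"])
        I_K = p["g_K"] * (0.75 * (1.0 - h)) ** 4 * (V - p["E_K"])
        I_T = p["g_T"] * pinf(V) ** 2 * r * (V - p["E_T"])
        dV = (-I_L - I_Na - I_K - I_T + p["I_b"]) / C
        dh = (hinf(V) - h) / tauh(V)
        dr = (rinf(V) - r) / taur(V)
        return np.array([dV, dh, dr])

    return ModelSpec(
        n=3, F=F, state_names=("V [mV]", "h", "r"),
        name="thalamic-neuron", params=p,
    )


# ---------------------------------------------------------------------------
# surrogate cardiomyocyte
# ---------------------------------------------------------------------------

#: Two-variable excitable cell (voltage in mV, recovery current w in mV/ms),
#: calibrated so the phase portrait has (i) a stable rest state near -78 mV,
#: (ii) a saddle threshold near -62 mV and (iii) a weakly unstable
#: depolarized spiral point near -26 mV with lambda_1 ~ 0.012 + 0.031i per ms
#: and Re alpha_1(T) < 0 (so high-frequency forcing can stabilize it).  The
#: tanh^3 term is an odd, saturating voltage nonlinearity centred at the
#: depolarized point: it leaves that point and its linearization untouched
#: but supplies the negative third voltage derivative that makes periodic
#: forcing stabilizing there, while saturating so that the unforced escape
#: back to rest is preserved.
SURROGATE_PARAMS = dict(
    k=2.6e-4,         # cubic conductance scale (1/(mV^2 ms))
    V_rest=-80.0,     # cubic root: resting branch (mV)
    V_thresh=-62.0,   # cubic root: excitation threshold (mV)
    V_peak=-3.0,      # cubic root: action-potential peak (mV)
    c_w=0.215,        # recovery activation slope (1/(mV ms) scaled)
    s_w=0.006,        # recovery rate (1/ms)
    g_sat=1.0,        # saturating-nonlinearity strength (mV/ms)
    sigma=6.0,        # its voltage width (mV)
    V_c=-26.0,        # its centre = depolarized fixed point (mV)
)


def build_surrogate_cardiomyocyte(params: Optional[dict] = None,
                                  check: bool = False) -> ModelSpec:
    """Excitable 2-variable cell: states ``(V [mV], w [mV/ms])``.

    Dynamics (an external current in mV/ms — i.e. A/F with C = 1 uF/cm^2 —
    adds directly to ``dV/dt``)::

        V' = -k (V - V_rest)(V - V_thresh)(V - V_peak)
             - g_sat tanh^3((V - V_c)/sigma) - w + I(t)
        w' = s_w (c_w (V - V_rest) - w)

    With ``check=True`` the build verifies the physiological fixed points
    (stable rest; weakly unstable depolarized spiral with
    ``0 < Re lambda_1 < 0.05`` per ms) and that ``Re alpha_1(T)`` is negative
    somewhere below 40 ms — i.e. that the depolarized state is stabilizable
    by weak periodic forcing — rejecting the parameter block otherwise.
    """
    p = dict(SURROGATE_PARAMS)
    if params:
        p.update(params)
    k, r1, r2, r3 = p["k"], p["V_rest"], p["V_thresh"], p["V_peak"]
    c_w, s_w, g, sig, vc = p["c_w"], p["s_w"], p["g_sat"], p["sigma"], p["V_c"]

    def F(x):
        V, w = x
        u = (V - vc) / sig
        dV = -k * (V - r1) * (V - r2) * (V - r3) - g * np.tanh(u) ** 3 - w
        dw = s_w * (c_w * (V - r1) - w)
        return np.array([dV, dw])

    def _tanh3_derivs(V):
        u = (V - vc) / sig
        f = np.tanh(u)
        fp = 1.0 - f ** 2
        d1 = 3 * f ** 2 * fp / sig
        d2 = 6 * f * fp * (fp - f ** 2) / sig ** 2
        d3 = 6 * (fp ** 3 - 7 * f ** 2 * fp ** 2 + 2 * f ** 4 * fp) / sig ** 3
        return d1, d2, d3

    def _cubic_derivs(V):
        dp = ((V - r2) * (V - r3) + (V - r1) * (V - r3) + (V - r1) * (V - r2))
        d2p = 2 * (3 * V - (r1 + r2 + r3))
        return dp, d2p

    def J(x):
        V, w = x
        dp, _ = _cubic_derivs(V)
        d1, _, _ = _tanh3_derivs(V)
        return np.array([[-k * dp - g * d1, -1.0],
                         [s_w * c_w, -s_w]])

    def H(x):
        V, w = x
        _, d2p = _cubic_derivs(V)
        _, d2, _ = _tanh3_derivs(V)
        Hs = np.zeros((2, 2, 2))
        Hs[0, 0, 0] = -k * d2p - g * d2
        return Hs

    def T3(x):
        V, w = x
        _, _, d3 = _tanh3_derivs(V)
        T = np.zeros((2, 2, 2, 2))
        T[0, 0, 0, 0] = -6 * k - g * d3
        return T

    model = ModelSpec(
        n=2, F=F, J=J, H=H, T3=T3,
        state_names=("V [mV]", "w [mV/ms]"),
        name="surrogate-cardiomyocyte", params=p,
    )
    if check:
        _validate_surrogate(model)
    return model


def surrogate_fixed_points(model: ModelSpec):
    """(rest, depolarized) fixed-point records of the surrogate cell."""
    from .core import find_fixed_point

    p = model.params
    r1, c_w = p["V_rest"], p["c_w"]
    rest = find_fixed_point(model, np.array([r1 + 2.0, c_w * 2.0]))
    depo = find_fixed_point(model, np.array([p["V_c"], c_w * (p["V_c"] - r1)]))
    return rest, depo


def _validate_surrogate(model: ModelSpec, T_m: float = 40.0) -> None:
    from .core import alpha_curve_resolvent, find_fixed_point
    from .models import derivative_tensors

    rest, depo = surrogate_fixed_points(model)
    lam_rest = rest.eigenvalues[0]
    if lam_rest.real >= 0:
        raise ValueError(f"rest state not stable (Re lambda = {lam_rest.real:.4f})")
    lam1 = depo.eigenvalues[0]
    if not (0.0 < lam1.real < 0.05):
        raise ValueError(
            f"depolarized point not weakly unstable (Re lambda_1 = {lam1.real:.4f})")
    if abs(lam1.imag) < 1e-6:
        raise ValueError("depolarized point is not a spiral (real eigenvalues)")
    tensors = derivative_tensors(model, depo.x0)
    curve = alpha_curve_resolvent(depo, tensors, model, j=0,
                                  T_grid=np.linspace(5.0, T_m, 15))
    ok = curve.alpha.real[~curve.resonance_mask]
    if not np.any(ok < 0):
        raise ValueError(
            "Re alpha_1(T) nowhere negative below T_m: depolarized state not "
            "stabilizable by weak periodic forcing; parameter block rejected")


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

MODEL_REGISTRY = {
    "hopf": build_hopf_fixture,
    "thalamic-neuron": build_neuron_model,
    "surrogate-cardiomyocyte": build_surrogate_cardiomyocyte,
}


def get_model(name: str, **kwargs) -> ModelSpec:
    if name not in MODEL_REGISTRY:
        raise KeyError(f"unknown model {name!r}; known: {sorted(MODEL_REGISTRY)}")
    return MODEL_REGISTRY[name](**kwargs)
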