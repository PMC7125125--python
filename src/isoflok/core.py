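"""Floquet-exponent shifts of weakly unstable fixed points under periodic forcing.

The central objects:

* a fixed point ``x0`` of ``x' = F(x)`` with eigenvalues ``lambda_j`` (sorted
  by descending real part, so ``lambda_1`` is the principal, most unstable
  exponent);
* a weak zero-mean ``T``-periodic input ``u`` entering along a unit direction
  ``b``, which induces a ``T``-periodic orbit near ``x0`` whose Floquet
  exponents ``kappa_j`` differ from ``lambda_j`` at second order in the
  forcing amplitude;
* the transfer curve ``alpha_j(T)`` mapping the power in each stimulus
  harmonic to the induced exponent shift,

      kappa_j = lambda_j + sum_k alpha_j(T/k) (a_k^2 + b_k^2).

Two independent routes to ``alpha_j`` are provided: a frequency-domain
resolvent computation (:func:`alpha_curve_resolvent`, exact for the
leading-order chain) and a brute-force measurement from forced periodic
orbits with Richardson extrapolation over two amplitudes
(:func:`alpha_curve_oracle`).  Their agreement is the package's principal
self-check.

Sign/ordering conventions are documented in ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import linear_sum_assignment

from .models import ModelSpec, derivative_tensors
from .stimulus import PeriodicStimulus, fourier_spectrum

Array = np.ndarray

__all__ = [
    "FixedPointRecord",
    "ForcedOrbitRecord",
    "ReductionOnOrbit",
    "AlphaCurve",
    "FloquetPrediction",
    "NewtonError",
    "OrbitEscapeError",
    "find_fixed_point",
    "forced_periodic_orbit",
    "reduction_on_orbit",
    "delta_kappa_from_Cjj",
    "alpha_curve_resolvent",
    "alpha_curve_oracle",
    "predict_floquet_shift",
    "optimal_sinusoid",
]


class NewtonError(RuntimeError):
    """Newton iteration failed to converge; carries the residual history."""

    def __init__(self, msg: str, residuals=None):
        super().__init__(msg)
        self.residuals = list(residuals or [])


class OrbitEscapeError(RuntimeError):
    """The forced orbit left the validity region around the fixed point.

    Signals breakdown of the asymptotic theory (the state moved too far from
    the weakly unstable fixed point), not a numerical failure.
    """


# ---------------------------------------------------------------------------
# fixed points
# ---------------------------------------------------------------------------

@dataclass
class FixedPointRecord:
    """A fixed point with its eigen-structure.

    ``eigenvalues`` are sorted by descending real part so that
    ``eigenvalues[0]`` is the principal (most unstable) exponent; right
    eigenvectors are columns of ``V``, left eigenvectors rows of ``W`` with the
    biorthonormality ``W @ V = I`` (``w_j^T v_k = delta_jk`` under the plain,
    non-conjugating transpose).
    """

    x0: Array
    residual: float
    J0: Array
    eigenvalues: Array       # complex, descending real part
    V: Array                 # right eigenvectors as columns
    W: Array                 # left eigenvectors as rows

    @property
    def lambda1(self) -> complex:
        return complex(self.eigenvalues[0])

    def right(self, j: int) -> Array:
        return self.V[:, j]

    def left(self, j: int) -> Array:
        return self.W[j, :]


def _eig_sorted(J0: Array):
    lam, V = np.linalg.eig(J0)
    order = np.lexsort((-lam.imag, -lam.real))
    lam, V = lam[order], V[:, order]
    W = np.linalg.inv(V)  # rows biorthonormal to columns of V
    return lam, V, W


def find_fixed_point(
    model: ModelSpec,
    x_init: Array,
    tol: float = 1e-10,
    max_iter: int = 60,
) -> FixedPointRecord:
    """Newton solve of ``F(x) = 0`` from ``x_init``, with eigen-decomposition.

    Raises :class:`NewtonError` on non-convergence (with the residual
    history) and ``np.linalg.LinAlgError`` when the Jacobian is singular at an
    iterate.
    """
    x = np.asarray(x_init, dtype=float).copy()
    if not np.all(np.isfinite(model.f(x))):
        raise ValueError("F not finite at x_init")
    residuals = []
    for it in range(max_iter):
        r = model.f(x)
        rn = float(np.linalg.norm(r))
        residuals.append(rn)
        if rn <= tol:
            break
        J = model.jacobian(x)
        try:
            step = np.linalg.solve(J, -r)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular Jacobian at Newton iterate {it} (x = {x})"
            ) from exc
        # damped update if the full step grows the residual
        lam = 1.0
        for _ in range(8):
            xn = x + lam * step
            if np.linalg.norm(model.f(xn)) <= rn or rn <= tol:
                break
            lam *= 0.5
        x = x + lam * step
    else:
        raise NewtonError(
            f"fixed-point Newton did not converge (last residual {residuals[-1]:.3e})",
            residuals,
        )
    J0 = model.jacobian(x)
    lam, V, W = _eig_sorted(J0)
    return FixedPointRecord(
        x0=x, residual=float(np.linalg.norm(model.f(x))), J0=J0,
        eigenvalues=lam, V=V, W=W,
    )


# ---------------------------------------------------------------------------
# forced periodic orbits and their Floquet exponents
# ---------------------------------------------------------------------------

@dataclass
class ForcedOrbitRecord:
    """A stimulus-induced ``T``-periodic orbit with measured Floquet exponents.

    ``t_grid``/``orbit`` sample one period of the state ``x(t)``; ``kappa``
    are ``log(multipliers)/T`` with the imaginary branch chosen by continuity
    from the unforced eigenvalues (matched modulo ``2*pi/T``).
    """

    model: ModelSpec
    stimulus: PeriodicStimulus
    x_start: Array           # point on the orbit at t = 0
    t_grid: Array
    orbit: Array             # shape (n_samples, n)
    monodromy: Array
    multipliers: Array
    kappa: Array             # complex exponents, ordered to match fp eigenvalues
    fp: FixedPointRecord
    converged: bool
    newton_residual: float

    @property
    def T(self) -> float:
        return self.stimulus.T


def _integrate_orbit_and_monodromy(
    model: ModelSpec,
    u: Callable[[Array], Array],
    x0: Array,
    T: float,
    rtol: float,
    atol: float,
    n_samples: int = 0,
):
    n = model.n
    b = model.input_direction

    def rhs(t, z):
        x = z[:n]
        Phi = z[n:].reshape(n, n)
        dx = model.f(x) + b * float(u(t))
        dPhi = model.jacobian(x) @ Phi
        return np.concatenate([dx, dPhi.ravel()])

    z0 = np.concatenate([x0, np.eye(n).ravel()])
    t_eval = np.linspace(0.0, T, n_samples) if n_samples else None
    sol = solve_ivp(rhs, (0.0, T), z0, rtol=rtol, atol=atol,
                    t_eval=t_eval, dense_output=False, method="DOP853")
    if not sol.success:
        raise RuntimeError(f"orbit integration failed: {sol.message}")
    zT = sol.y[:, -1]
    return zT[:n], zT[n:].reshape(n, n), sol.t, sol.y[:n].T


def _match_branches(multipliers: Array, lam: Array, T: float):
    """Pair monodromy multipliers with unforced eigenvalues and pick the
    log branch whose imaginary part is closest to each ``Im(lambda_j)``."""
    omega = 2 * np.pi / T
    k = len(multipliers)
    raw = np.log(np.abs(multipliers)) / T + 1j * np.angle(multipliers) / T
    # candidate exponents for each multiplier: raw + i m omega for branch m
    cost = np.empty((k, k))
    best_branch = np.empty((k, k), dtype=int)
    for i, r in enumerate(raw):
        for j, l in enumerate(lam):
            m = np.round((l.imag - r.imag) / omega)
            cand = r + 1j * m * omega
            cost[i, j] = abs(cand - l)
            best_branch[i, j] = int(m)
    rows, cols = linear_sum_assignment(cost)
    kappa = np.empty(k, dtype=complex)
    for i, j in zip(rows, cols):
        kappa[j] = raw[i] + 1j * best_branch[i, j] * omega
    return kappa


def linear_response_amplitude(fp: FixedPointRecord, stimulus: PeriodicStimulus,
                              b: Array) -> float:
    """Amplitude of the linear steady-state response to the stimulus —
    the natural length scale of the forced orbit."""
    omega = 2 * np.pi / stimulus.T
    n = fp.J0.shape[0]
    amp = 0.0
    for k in range(1, stimulus.K + 1):
        p = np.sqrt(stimulus.harmonic_power[k - 1])
        if p == 0:
            continue
        try:
            resp = np.linalg.solve(1j * k * omega * np.eye(n) - fp.J0, b)
        except np.linalg.LinAlgError:
            continue
        amp += p * np.linalg.norm(resp)
    return float(amp)


def forced_periodic_orbit(
    model: ModelSpec,
    stimulus: PeriodicStimulus,
    x_guess: Optional[Array] = None,
    fp: Optional[FixedPointRecord] = None,
    tol: float = 1e-10,
    max_iter: int = 30,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    n_samples: int = 129,
    validity_factor: float = 10.0,
) -> ForcedOrbitRecord:
    """Newton-on-the-stroboscopic-map solution of the forced periodic orbit.

    The monodromy matrix is obtained from the variational equations
    integrated alongside the state.  If the converged orbit leaves a ball of
    radius ``validity_factor`` times the linear response amplitude around the
    fixed point, :class:`OrbitEscapeError` is raised — the asymptotic theory
    is not trustworthy there.
    """
    T = stimulus.T
    if T <= 0:
        raise ValueError("stimulus period must be positive")
    if fp is None:
        fp = find_fixed_point(model, x_guess if x_guess is not None else
                              np.zeros(model.n))
    x = np.array(x_guess, dtype=float) if x_guess is not None else fp.x0.copy()
    residuals = []
    lin_amp = linear_response_amplitude(fp, stimulus, model.input_direction)
    radius = validity_factor * max(lin_amp, 1e-12)
    M = np.eye(model.n)
    for it in range(max_iter):
        xT, M, _, _ = _integrate_orbit_and_monodromy(
            model, stimulus.sampler, x, T, rtol, atol)
        r = xT - x
        rn = float(np.linalg.norm(r))
        residuals.append(rn)
        if rn <= tol:
            break
        if not np.all(np.isfinite(r)) or rn > 1e6:
            raise NewtonError("stroboscopic Newton diverged", residuals)
        try:
            step = np.linalg.solve(M - np.eye(model.n), -r)
        except np.linalg.LinAlgError as exc:
            raise NewtonError(
                "singular (M - I) in stroboscopic Newton (orbit at a "
                "bifurcation of the stroboscopic map)", residuals) from exc
        x = x + step
    else:
        raise NewtonError(
            f"stroboscopic Newton did not converge (residuals {residuals[-3:]})",
            residuals)

    # final accurate pass with samples
    xT, M, t_grid, orbit = _integrate_orbit_and_monodromy(
        model, stimulus.sampler, x, T, rtol, atol, n_samples=n_samples)
    max_dev = float(np.max(np.linalg.norm(orbit - fp.x0, axis=1)))
    if max_dev > radius:
        raise OrbitEscapeError(
            f"orbit left validity region (max deviation {max_dev:.3e} > "
            f"{radius:.3e}); the asymptotic theory does not apply")
    multipliers = np.linalg.eigvals(M)
    kappa = _match_branches(multipliers, fp.eigenvalues, T)
    return ForcedOrbitRecord(
        model=model, stimulus=stimulus, x_start=x, t_grid=t_grid, orbit=orbit,
        monodromy=M, multipliers=multipliers, kappa=kappa, fp=fp,
        converged=True, newton_residual=float(np.linalg.norm(xT - x)),
    )


# ---------------------------------------------------------------------------
# reduction on an orbit (time-domain adjoint machinery)
# ---------------------------------------------------------------------------

@dataclass
class ReductionOnOrbit:
    """Phase/isostable response machinery sampled on a uniform phase grid.

    All curves live on the autonomous augmentation ``y = (x, s)`` of the
    forced system (``s`` the time-like coordinate), so vectors have ``n+1``
    components.  ``Z`` is the phase response curve (gradient of the phase),
    ``I[j]`` the isostable response curve of coordinate ``j``, ``p[k]`` the
    Floquet eigenfunctions, ``B[k]`` and ``C[(j, k)]`` the second-order
    correction curves; ``B1``/``C1`` expose their first (input-direction)
    components.
    """

    theta_grid: Array
    t_grid: Array
    omega: float
    kappa: Array
    Z: Array                     # (n_theta, n+1)
    I: dict                      # j -> (n_theta, n+1) complex
    p: dict                      # k -> (n_theta, n+1) complex
    B: dict                      # k -> (n_theta, n+1) complex
    C: dict                      # (j, k) -> (n_theta, n+1) complex
    normalization_residuals: dict = field(default_factory=dict)

    def C_first(self, j: int, k: int) -> Array:
        """First component ``C_j^k(theta)`` (the one the input couples to)."""
        return self.C[(j, k)][:, 0]


def _augmented_jacobian(model, x, du_dt):
    """Jacobian of the autonomous augmentation: the time-like column carries
    the stimulus slope u'(t); the time row is zero."""
    n = model.n
    Ja = np.zeros((n + 1, n + 1))
    Ja[:n, :n] = model.jacobian(x)
    Ja[:n, n] = model.input_direction * du_dt
    return Ja


def reduction_on_orbit(
    model: ModelSpec,
    orbit: ForcedOrbitRecord,
    indices: Optional[Sequence[int]] = None,
    n_theta: int = 128,
    rtol: float = 1e-9,
    atol: float = 1e-11,
    degeneracy_tol: float = 1e-8,
) -> ReductionOnOrbit:
    """Adjoint (PRC/IRC), Floquet eigenfunctions and second-order curves on a
    forced periodic orbit.

    The curves solve, on the augmented autonomous system,

        dZ/dt   = -J_a^T Z,                     F_a^T Z = omega,
        dI_j/dt = (kappa_j I - J_a^T) I_j,       v_j^T I_j = 1,
        dB^k/dt = -sum_i Z^i H_i p_k - (J_a^T + kappa_k) B^k,
        dC_j^k/dt = -sum_i I_j^i H_i p_k - (J_a^T + (kappa_k - kappa_j)) C_j^k,

    where the transpose structure of the first-order adjoint equations
    carries over to the second-order ones.  Periodic solutions are obtained
    from the transition matrix of each (in)homogeneous system over one
    period.
    """
    if not orbit.converged:
        raise ValueError("orbit not converged")
    n = model.n
    T = orbit.T
    omega = 2 * np.pi / T
    stim = orbit.stimulus
    kappa = orbit.kappa
    if indices is None:
        indices = list(range(n))
    # reject near-degenerate exponents: eigenfunctions ill-defined
    for a in range(n):
        for c in range(a + 1, n):
            if abs(kappa[a] - kappa[c]) < degeneracy_tol and a in indices and c in indices:
                raise ValueError(
                    f"Floquet exponents {a} and {c} nearly degenerate "
                    f"({kappa[a]:.3e} vs {kappa[c]:.3e}); refine tolerances or "
                    "drop one index")

    ks = np.arange(1, stim.K + 1)

    def uval(t):
        return float(stim.sampler(t))

    def uprime(t):
        ph = 2 * np.pi * ks * t / T
        return float(np.sum(2 * np.pi * ks / T * (-stim.a * np.sin(ph) + stim.b * np.cos(ph))))

    def uprime2(t):
        ph = 2 * np.pi * ks * t / T
        w = (2 * np.pi * ks / T) ** 2
        return float(np.sum(w * (-stim.a * np.cos(ph) - stim.b * np.sin(ph))))

    # --- integrate orbit and augmented transition matrix on the theta grid
    t_grid = np.linspace(0.0, T, n_theta + 1)
    theta_grid = omega * t_grid[:-1]

    def rhs(t, z):
        x = z[:n]
        Phi = z[n:].reshape(n + 1, n + 1)
        dx = model.f(x) + model.input_direction * uval(t)
        Ja = _augmented_jacobian(model, x, uprime(t))
        return np.concatenate([dx, (Ja @ Phi).ravel()])

    z0 = np.concatenate([orbit.x_start, np.eye(n + 1).ravel()])
    sol = solve_ivp(rhs, (0.0, T), z0, t_eval=t_grid, rtol=rtol, atol=atol,
                    method="DOP853")
    if not sol.success:
        raise RuntimeError(f"augmented variational integration failed: {sol.message}")
    xs = sol.y[:n].T                                   # (n_theta+1, n)
    Phis = sol.y[n:].T.reshape(-1, n + 1, n + 1)
    Ma = Phis[-1]
    per_res = float(np.linalg.norm(xs[-1] - xs[0]))
    if per_res > 1e-6 * max(1.0, float(np.linalg.norm(xs[0]))):
        raise RuntimeError(f"orbit periodicity residual {per_res:.2e} too large")

    mult_a, Va = np.linalg.eig(Ma)
    Wa = np.linalg.inv(Va)

    # identify the phase direction (multiplier 1) and the state directions
    idx_phase = int(np.argmin(np.abs(mult_a - 1.0)))
    # map requested state indices to augmented eigen-pairs via exp(kappa T)
    pair_idx = {}
    used = {idx_phase}
    for j in indices:
        target = np.exp(kappa[j] * T)
        order = np.argsort(np.abs(mult_a - target))
        for cand in order:
            if cand not in used:
                pair_idx[j] = int(cand)
                used.add(int(cand))
                break

    y_aug = np.hstack([xs, (t_grid % T)[:, None]])     # augmented states
    Fa = np.array([np.concatenate([model.f(x) + model.input_direction * uval(t), [1.0]])
                   for x, t in zip(xs, t_grid)])

    invPhiT = np.array([np.linalg.inv(Phi).T for Phi in Phis])

    # --- phase response curve: left eigenvector of Ma at multiplier 1
    Z0 = Wa[idx_phase].conj() if np.iscomplexobj(Wa) else Wa[idx_phase]
    Z0 = np.real_if_close(Wa[idx_phase], tol=1e6)
    Z0 = np.real(Z0)
    Z0 = Z0 / (Fa[0] @ Z0) * omega                     # F_a^T Z = omega at t=0
    Z = np.einsum("tij,j->ti", invPhiT, Z0)
    Z = np.real_if_close(Z)
    norm_res_Z = float(np.max(np.abs(np.einsum("ti,ti->t", Fa, np.real(Z)) - omega)))

    # --- isostable response curves and eigenfunctions
    I_curves, p_curves = {}, {}
    vj0 = {}
    for j, aug_j in pair_idx.items():
        v = Va[:, aug_j]
        w = Wa[aug_j]
        w = w / (w @ v)
        vj0[j] = v
        p_t = np.exp(-kappa[j] * t_grid)[:, None] * np.einsum("tij,j->ti", Phis, v)
        I_t = np.exp(kappa[j] * t_grid)[:, None] * np.einsum("tij,j->ti", invPhiT, w)
        # normalization v_j^T I_j = 1 (holds for all t by construction at t=0)
        I_t = I_t / (v @ I_t[0])
        p_curves[j] = p_t
        I_curves[j] = I_t

    # --- Hessians of the augmented field along the orbit
    H_aug = np.zeros((n_theta + 1, n + 1, n + 1, n + 1))
    for ti, (x, t) in enumerate(zip(xs, t_grid)):
        if model.H is not None:
            Hx = np.asarray(model.H(x), dtype=float)
        else:
            _, Hx, _ = derivative_tensors(model, x)
        H_aug[ti, :n, :n, :n] = Hx
        H_aug[ti, :n, n, n] = model.input_direction * uprime2(t)

    def periodic_inhomogeneous(kshift: complex, forcing_at, compat: bool = False):
        """Periodic solution of  q' = -(J_a^T + kshift) q + forcing(t).

        With ``compat=True`` (the resonant k = j case, whose homogeneous
        operator carries the unit multiplier of the phase direction) the
        forcing's secular component is removed by subtracting a constant
        along the time-like coordinate: the adjoint periodic mode is the
        orbit tangent ``F_a(y(t))`` whose time component is 1, and the
        time-like column of the augmented Jacobian vanishes, so this
        correction cannot leak into any state component of the solution —
        it is exactly the constant that drops out of the zero-mean
        exponent-shift integral.
        """
        dim = n + 1
        if compat:
            fs = np.array([forcing_at(t) for t in t_grid])
            mu = np.trapezoid(np.einsum("ti,ti->t", Fa, fs), t_grid) / T
            base_forcing = forcing_at
            e_s = np.zeros(dim, dtype=complex)
            e_s[n] = 1.0

            def forcing_at(t, base=base_forcing, mu=mu, e_s=e_s):
                return base(t) - mu * e_s

        def rhs2(t, zc):
            z = zc[:dim ** 2].reshape(dim, dim)  # homogeneous transition
            q = zc[dim ** 2:]
            x = orbit_interp(t)
            Ja = _augmented_jacobian(model, x, uprime(t))
            A = -(Ja.T + kshift * np.eye(dim))
            return np.concatenate([(A @ z).ravel(), A @ q + forcing_at(t)])

        z0c = np.concatenate([np.eye(dim, dtype=complex).ravel(),
                              np.zeros(dim, dtype=complex)])
        solc = solve_ivp(rhs2, (0.0, T), z0c, t_eval=t_grid, rtol=rtol,
                         atol=atol, method="DOP853")
        if not solc.success:
            raise RuntimeError(f"second-order curve integration failed: {solc.message}")
        Psis = solc.y[:dim ** 2].T.reshape(-1, dim, dim)
        parts = solc.y[dim ** 2:].T
        lhs = np.eye(dim, dtype=complex) - Psis[-1]
        # For k = j (and for B^k) the homogeneous operator has a periodic
        # solution (unit multiplier from the phase direction), so the
        # periodicity system is singular: the solution is defined up to a
        # constant "shift" along that mode, which cancels in the zero-mean
        # correlation that yields the exponent shift.  The minimal-norm
        # least-squares solution picks a canonical representative.
        if abs(np.linalg.det(lhs)) > 1e-8:
            q0 = np.linalg.solve(lhs, parts[-1])
            resid = 0.0
        else:
            q0, *_ = np.linalg.lstsq(lhs, parts[-1], rcond=None)
            resid = float(np.linalg.norm(lhs @ q0 - parts[-1]) /
                          max(np.linalg.norm(parts[-1]), 1e-300))
        return np.einsum("tij,j->ti", Psis, q0) + parts, resid

    # cubic-spline-free orbit interpolation: re-integrate is costly, use
    # dense linear interpolation on the fine grid (adequate: forcing terms
    # below are themselves grid-sampled)
    from scipy.interpolate import CubicSpline
    xs_per = xs.copy()
    xs_per[-1] = xs_per[0]        # close the loop (residual already checked)
    orbit_spline = CubicSpline(t_grid, xs_per, axis=0, bc_type="periodic")

    def orbit_interp(t):
        return orbit_spline(t % T)

    def make_forcing(resp_curve, k):
        """-sum_i resp^i(t) H_i(t) p_k(t) interpolated in t."""
        pk_spline = CubicSpline(t_grid, p_curves[k], axis=0)
        resp_spline = CubicSpline(t_grid, resp_curve, axis=0)
        H_spline = CubicSpline(t_grid, H_aug, axis=0)

        def forcing(t):
            tau = t % T
            resp = resp_spline(tau)
            Ht = H_spline(tau)
            pk = pk_spline(tau)
            return -np.einsum("i,ijk,k->j", resp, Ht, pk)

        return forcing

    B_curves, C_curves = {}, {}
    res = {
        "Z_normalization": norm_res_Z,
        "orbit_periodicity": per_res,
    }
    for k in indices:
        B_curves[k], r = periodic_inhomogeneous(kappa[k], make_forcing(Z, k))
        res[f"B{k}_secular"] = r
    ZT = np.real(Z)
    for j in indices:
        for k in indices:
            Cjk, r = periodic_inhomogeneous(
                kappa[k] - kappa[j], make_forcing(I_curves[j], k),
                compat=(j == k))
            if j == k:
                # The k = j equation admits the adjoint phase mode Z(theta)
                # as a free periodic homogeneous solution; the minimal-norm
                # solve picks an arbitrary amount of it.  Pin the canonical
                # representative by zeroing the tangent pairing
                # <F_a^T C> (the tangent pairs with Z at the constant
                # omega), which leaves the input-facing oscillatory content
                # that determines exponent shifts intact at leading order.
                c_coef = (np.trapezoid(np.einsum("ti,ti->t", Fa, Cjk), t_grid)
                          / np.trapezoid(np.einsum("ti,ti->t", Fa, ZT), t_grid))
                Cjk = Cjk - c_coef * ZT
            C_curves[(j, k)] = Cjk
            res[f"C{j}{k}_secular"] = r
    for j in pair_idx:
        # biorthogonality I_j(theta)^T p_j(theta) = 1 pointwise (reduces to
        # v_j^T I_j = 1 at theta = 0 with v_j = p_j(0))
        res[f"I{j}_normalization"] = float(np.max(np.abs(
            np.einsum("ti,ti->t", I_curves[j], p_curves[j]) - 1.0)))
    return ReductionOnOrbit(
        theta_grid=theta_grid, t_grid=t_grid, omega=omega, kappa=kappa,
        Z=np.real(Z), I=I_curves, p=p_curves, B=B_curves, C=C_curves,
        normalization_residuals=res,
    )


def delta_kappa_from_Cjj(
    Cjj: Array,
    delta_u: Callable[[Array], Array],
    T: float,
    t_grid: Optional[Array] = None,
) -> complex:
    """Floquet-exponent shift ``(1/T) \\int_0^T C_j^j(omega s) du(s) ds``.

    ``Cjj`` is the first component of the second-order curve sampled on
    ``t_grid`` (defaults to a uniform grid over one period, endpoint
    included).
    """
    Cjj = np.asarray(Cjj)
    if t_grid is None:
        t_grid = np.linspace(0.0, T, Cjj.size)
    if Cjj.shape != t_grid.shape:
        raise ValueError("Cjj and t_grid size mismatch (mismatched periods?)")
    du = np.asarray(delta_u(t_grid), dtype=float)
    return complex(np.trapezoid(Cjj * du, t_grid) / T)


# ---------------------------------------------------------------------------
# alpha curves
# ---------------------------------------------------------------------------

@dataclass
class AlphaCurve:
    """The transfer curve ``T -> alpha_j(T)`` for one eigenvalue index.

    ``alpha`` has units of (1/ms) per (input unit)^2.  ``chi``/``beta`` are
    the first-component gain/phase internals of the oscillatory part of
    ``C_j^j``; ``resonance_mask`` flags periods inside the guard band around
    ``2*pi/Im(lambda_i)`` where the resolvents are near-singular (values are
    reported but untrusted).  ``raw_pair`` is filled by the oracle route.
    """

    j: int
    T_grid: Array
    alpha: Array             # complex
    chi: Array
    beta: Array
    resonance_mask: Array
    method: str = "resolvent"
    raw_pair: Optional[Array] = None   # (2, nT) raw oracle estimates
    eps_pair: Optional[tuple] = None

    def alpha_at(self, T: float, allow_flagged: bool = False) -> complex:
        """Linear interpolation of the complex curve at period ``T``."""
        Tg = self.T_grid
        if T < Tg.min() - 1e-12 or T > Tg.max() + 1e-12:
            raise ValueError(f"period {T} outside alpha grid [{Tg.min()}, {Tg.max()}]")
        if not allow_flagged:
            i = int(np.argmin(np.abs(Tg - T)))
            if self.resonance_mask[i]:
                raise ValueError(
                    f"alpha requested at T={T} inside the resonance guard band")
        re = np.interp(T, Tg, self.alpha.real)
        im = np.interp(T, Tg, self.alpha.imag)
        return complex(re, im)


def _resonance_mask(T_grid: Array, eigenvalues: Array, guard: float) -> Array:
    omegas = 2 * np.pi / np.asarray(T_grid)
    ims = np.abs(np.asarray(eigenvalues).imag)
    mask = np.zeros(len(T_grid), dtype=bool)
    for im in ims:
        if im == 0:
            continue
        mask |= np.abs(omegas - im) < guard
    return mask


class DenseTensorOps:
    """Derivative-tensor contractions backed by dense arrays.

    Systems too large for dense Hessian storage (the Fokker-Planck operator)
    supply an object with the same three methods exploiting their structure:

    * ``delta_J(y)``   — Jacobian modulation: matrix with rows ``(H_i y)^T``;
    * ``weighted_H(a, v)`` — ``sum_i a_i H_i v``;
    * ``delta_H(a, y, v)`` — ``sum_i a_i (T3_i : y) v`` (third-derivative
      contraction, i.e. the Hessian modulation along ``y`` applied to ``v``).
    """

    def __init__(self, J0: Array, H: Array, T3: Array):
        self.J0 = np.asarray(J0)
        self.H = np.asarray(H)
        self.T3 = np.asarray(T3)

    def delta_J(self, y: Array) -> Array:
        return np.einsum("ijk,k->ij", self.H, y)

    def weighted_H(self, a: Array, v: Array) -> Array:
        return np.einsum("i,ijk,k->j", a, self.H, v)

    def delta_H(self, a: Array, y: Array, v: Array) -> Array:
        return np.einsum("i,ijkm,m,k->j", a, self.T3, y, v)


def as_tensor_ops(tensors) -> DenseTensorOps:
    if hasattr(tensors, "delta_J"):
        return tensors
    J0, H, T3 = tensors
    return DenseTensorOps(J0, H, T3)


def alpha_from_tensors(
    J0: Array,
    H: Array,
    T3: Array,
    b: Array,
    lam: Array,
    j: int,
    T: float,
) -> tuple[complex, complex]:
    """One-period evaluation of the leading-order resolvent chain.

    Returns ``(alpha_j(T), c1_gain)`` where ``c1_gain`` is the complex
    first-harmonic content of ``C_j^j`` per unit sinusoid (the chi/beta
    internals collapse into it).

    The chain (all solves in the frequency domain, per signed frequency
    ``s = +-i omega``):  linear steady state ``y_s = (sI-J0)^{-1} b u_s``;
    Jacobian modulation ``dJ_s`` with rows ``(H_i y_s)^T``; eigenfunction and
    IRC modulations from resolvents shifted by ``lambda_j``; Hessian
    modulation from the third-derivative contraction; the constant
    ``C_j^{j,0} = -(J0^T)^{-1} sum_i (e_i^T I_j^0) H_i v_j``; and the
    oscillatory balance of the second-order curve.  The exponent shift per
    unit harmonic power is then ``alpha = (C1_- - C1_+)/(4i)``, the factor
    1/2 relative to the bare correlation integral coming from integrating
    the quadratic amplitude dependence of the shift.
    """
    return alpha_from_ops(DenseTensorOps(J0, H, T3), b, lam, j, T)


def alpha_from_ops(
    ops,
    b: Array,
    lam: Array,
    j: int,
    T: float,
) -> tuple[complex, complex]:
    """Resolvent chain evaluated through tensor-contraction operators
    (see :class:`DenseTensorOps`); the input direction ``b`` may be any
    vector (its norm is absorbed into the amplitude convention)."""
    J0 = np.asarray(ops.J0)
    n = J0.shape[0]
    Iden = np.eye(n)
    lam_j = lam[j]
    lam_all, V, W = _eig_sorted(J0)
    # use supplied ordering: find eigenvector matching lam[j]
    jj = int(np.argmin(np.abs(lam_all - lam_j)))
    v = V[:, jj]
    w = W[jj, :]
    I0 = w / (v @ w)        # v^T I0 = 1
    # constant part of C_j^j.  J0^T may carry an exact zero eigenvalue when
    # the system has a conserved quantity (e.g. total probability); the
    # undetermined null component then lies along the conservation covector
    # and drops out of every later contraction, so a least-squares solve is
    # exact.  A genuinely unsolvable balance (nonzero residual) means the
    # method's nonzero-eigenvalue requirement is violated.
    rhs0 = ops.weighted_H(I0, v)
    i_null = int(np.argmin(np.abs(lam_all)))
    if np.abs(lam_all[i_null]) > 1e-12:
        C0 = -np.linalg.solve(J0.T, rhs0)
    else:
        # conserved-quantity deflation: covectors are defined modulo the
        # conservation functional q (left null of J0), so the balance reads
        # J0^T C0 = -rhs0 + beta q with beta fixed by solvability against
        # the right null vector n; the modulo-q ambiguity of C0 cancels in
        # every later contraction because the Jacobian modulation is itself
        # conservative.
        n_null = V[:, i_null]
        q_null = W[i_null, :]
        denom = q_null @ n_null
        if abs(denom) < 1e-12:
            raise np.linalg.LinAlgError(
                "method requires nonzero eigenvalues (defective zero mode in "
                "the constant-balance solve)")
        beta = (rhs0 @ n_null) / denom
        rhs_adj = -rhs0 + beta * q_null
        C0, *_ = np.linalg.lstsq(J0.T.astype(complex), rhs_adj, rcond=None)
        resid = np.linalg.norm(J0.T @ C0 - rhs_adj)
        if resid > 1e-7 * max(np.linalg.norm(rhs0), 1e-300):
            raise np.linalg.LinAlgError(
                "method requires nonzero eigenvalues (J0^T singular in the "
                "constant-balance solve and the balance is unsolvable)")

    omega = 2 * np.pi / T
    C1 = {}
    for sgn in (+1, -1):
        s = 1j * sgn * omega
        u_s = sgn / 2j                      # sin(wt) = e^{iwt}/2i - e^{-iwt}/2i
        y = np.linalg.solve(s * Iden - J0, b.astype(complex)) * u_s
        dJ = ops.delta_J(y)                 # row i = (H_i y)^T
        dp = np.linalg.solve(s * Iden - J0 + lam_j * Iden, dJ @ v)
        dI = np.linalg.solve(s * Iden + J0.T - lam_j * Iden, -(dJ.T @ I0))
        f = -(ops.weighted_H(dI, v)
              + ops.delta_H(I0, y, v)
              + ops.weighted_H(I0, dp)) - dJ.T @ C0
        Chat = np.linalg.solve(s * Iden + J0.T, f)
        # the exponent shift pairs the second-order covector with the input
        # direction; for b = e_1 this is the curve's first component
        C1[sgn] = Chat @ b
    alpha = (C1[-1] - C1[+1]) / 4j
    gain = (C1[-1] - C1[+1]) / 2j           # first-harmonic sine content
    return complex(alpha), complex(gain)


def alpha_curve_resolvent(
    fp: FixedPointRecord,
    tensors,
    model: ModelSpec,
    j: int,
    T_grid: Array,
    guard: float = 1e-2,
) -> AlphaCurve:
    """``alpha_j`` over a period grid via frequency-domain resolvent solves.

    Grid points whose driving frequency falls within ``guard`` (rad/ms) of an
    eigenvalue's imaginary part are flagged in ``resonance_mask`` (resolvents
    near-singular; values untrusted), not silently dropped.
    """
    ops = as_tensor_ops(tensors)
    b = model.input_direction if model is not None else None
    if b is None:
        raise ValueError("an input direction is required")
    T_grid = np.asarray(T_grid, dtype=float)
    alpha = np.empty(len(T_grid), dtype=complex)
    gain = np.empty(len(T_grid), dtype=complex)
    for i, T in enumerate(T_grid):
        alpha[i], gain[i] = alpha_from_ops(ops, b, fp.eigenvalues, j, T)
    mask = _resonance_mask(T_grid, fp.eigenvalues, guard)
    return AlphaCurve(
        j=j, T_grid=T_grid, alpha=alpha,
        chi=np.abs(gain), beta=np.angle(gain),
        resonance_mask=mask, method="resolvent",
    )


def alpha_curve_oracle(
    model: ModelSpec,
    j: int,
    T_grid: Array,
    eps_pair: tuple[float, float] = (0.02, 0.01),
    fp: Optional[FixedPointRecord] = None,
    guard: float = 1e-2,
    scale_by_gain: bool = True,
    rtol: float = 1e-11,
    atol: float = 1e-13,
) -> AlphaCurve:
    """Brute-force measurement of ``alpha_j``: force with ``eps sin(2 pi t/T)``,
    measure ``kappa_j`` from the monodromy of the forced orbit, and set
    ``alpha ~ (kappa_j - lambda_j)/eps^2``; Richardson extrapolation over the
    two amplitudes cancels the O(eps) contamination.

    Near resonance the linear response is amplified, so by default the
    amplitudes are shrunk by the linear gain to keep the orbit inside the
    asymptotic regime.  Grid points where the orbit escapes are returned as
    NaN (marked unavailable).
    """
    if fp is None:
        fp = find_fixed_point(model, np.zeros(model.n))
    T_grid = np.asarray(T_grid, dtype=float)
    lam_j = fp.eigenvalues[j]
    alpha = np.full(len(T_grid), np.nan + 0j, dtype=complex)
    raw = np.full((2, len(T_grid)), np.nan + 0j, dtype=complex)
    for i, T in enumerate(T_grid):
        base = fourier_spectrum(lambda t, T=T: np.sin(2 * np.pi * t / T), T, K=1)
        g = linear_response_amplitude(fp, base, model.input_direction)
        scale = 1.0 / max(1.0, g) if scale_by_gain else 1.0
        est = []
        ok = True
        for eps in eps_pair:
            try:
                orb = forced_periodic_orbit(
                    model, base.scaled(eps * scale), fp=fp,
                    rtol=rtol, atol=atol, n_samples=2)
            except (OrbitEscapeError, NewtonError):
                ok = False
                break
            est.append((orb.kappa[j] - lam_j) / (eps * scale) ** 2)
        if not ok:
            continue
        raw[:, i] = est
        e1, e2 = eps_pair[0] * scale, eps_pair[1] * scale
        alpha[i] = (e1 * est[1] - e2 * est[0]) / (e1 - e2)
    mask = _resonance_mask(T_grid, fp.eigenvalues, guard) | ~np.isfinite(alpha.real)
    return AlphaCurve(
        j=j, T_grid=T_grid, alpha=alpha,
        chi=2 * np.abs(alpha), beta=np.zeros(len(T_grid)),
        resonance_mask=mask, method="oracle", raw_pair=raw, eps_pair=eps_pair,
    )


# ---------------------------------------------------------------------------
# predictions and optimal stimulation
# ---------------------------------------------------------------------------

@dataclass
class FloquetPrediction:
    """``kappa_j = lambda_j + sum_k alpha_j(T/k) (a_k^2 + b_k^2)``."""

    lambda_j: complex
    stimulus: PeriodicStimulus
    K_used: int
    predicted_kappa: complex
    per_harmonic: Array      # complex contributions, k = 1..K_used


def predict_floquet_shift(
    fp: FixedPointRecord,
    alpha: AlphaCurve,
    stimulus: PeriodicStimulus,
    power_floor: float = 1e-12,
) -> FloquetPrediction:
    """Predicted Floquet exponent of the orbit forced by ``stimulus``.

    The prediction depends on the stimulus only through its power spectrum:
    harmonics with ``a_k^2 + b_k^2`` below ``power_floor`` (relative to the
    total) are truncated; harmonics whose ``T/k`` falls inside the resonance
    guard band raise an error naming them.
    """
    lam_j = fp.eigenvalues[alpha.j]
    power = stimulus.harmonic_power
    total = float(np.sum(power))
    contribs = np.zeros(stimulus.K, dtype=complex)
    bad = []
    for k in range(1, stimulus.K + 1):
        pk = power[k - 1]
        if total > 0 and pk < power_floor * total:
            continue
        if pk == 0.0:
            continue
        try:
            a = alpha.alpha_at(stimulus.T / k)
        except ValueError as exc:
            if "guard band" in str(exc):
                bad.append(k)
                continue
            raise
        contribs[k - 1] = a * pk
    if bad:
        raise ValueError(
            f"alpha at T/k inside resonance guard band for harmonics {bad}")
    kappa = lam_j + np.sum(contribs)
    return FloquetPrediction(
        lambda_j=complex(lam_j), stimulus=stimulus, K_used=stimulus.K,
        predicted_kappa=complex(kappa), per_harmonic=contribs,
    )


@dataclass
class OptimalSinusoid:
    stabilizable: bool
    T_star: Optional[float]
    amplitude: Optional[float]      # sqrt(2 E0): pure sinusoid at power E0
    kappa_lower_bound: Optional[float]
    energy: Optional[float]         # M = E0 * T_star
    avg_power: float


def optimal_sinusoid(
    fp: FixedPointRecord,
    alpha1: AlphaCurve,
    E0: float,
    T_m: float,
) -> OptimalSinusoid:
    """Energy-optimal sinusoid at average power ``E0`` with period <= ``T_m``.

    The bound ``Re kappa_1 >= Re lambda_1 + 2 E0 min_{T <= T_m} Re alpha_1(T)``
    is achieved by a pure sinusoid at the minimizing period.  If
    ``min Re alpha_1 >= 0`` the fixed point is not stabilizable by weak
    periodic forcing.  Ties in the argmin break toward the larger period.
    """
    if E0 <= 0:
        raise ValueError("average power E0 must be positive")
    sel = (alpha1.T_grid <= T_m) & ~alpha1.resonance_mask & np.isfinite(alpha1.alpha.real)
    if not np.any(sel):
        raise ValueError("alpha grid has no trusted points below T_m")
    Ts = alpha1.T_grid[sel]
    re = alpha1.alpha.real[sel]
    mn = re.min()
    if mn >= 0:
        return OptimalSinusoid(False, None, None, None, None, E0)
    cand = Ts[np.isclose(re, mn, rtol=0, atol=1e-15)]
    T_star = float(cand.max())     # tie toward larger period
    bound = float(fp.eigenvalues[alpha1.j].real + 2 * E0 * mn)
    amplitude = float(np.sqrt(2 * E0))
    return OptimalSinusoid(True, T_star, amplitude, bound, E0 * T_star, E0)
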