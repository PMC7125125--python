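"""Vector-field model specification and derivative oracles.

A :class:`ModelSpec` bundles everything the reduction machinery needs about a
dynamical system ``x' = F(x) + b u(t)``: the state dimension, an evaluator for
the nominal field ``F``, optional analytic derivative evaluators (Jacobian,
per-component Hessians, per-component third-derivative tensors) and the unit
input direction ``b`` selecting which state receives the scalar stimulus.

When analytic derivatives are absent they are approximated with symmetrised
central differences (:func:`derivative_tensors`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

Array = np.ndarray


@dataclass
class ModelSpec:
    """A vector field with derivative oracles and a designated input direction.

    Parameters
    ----------
    n
        State dimension.
    F
        Evaluator ``x -> dx/dt`` (units of state per ms).
    state_names
        Labels (with units where meaningful), length ``n``.
    J
        Optional analytic Jacobian evaluator ``x -> (n, n)``.
    H
        Optional Hessian evaluator ``x -> (n, n, n)``; ``H(x)[i]`` is the
        (symmetric) Hessian of component ``F_i``.
    T3
        Optional third-derivative evaluator ``x -> (n, n, n, n)``;
        ``T3(x)[i][j, k, m] = d^3 F_i / dx_j dx_k dx_m`` (fully symmetric in
        the last three indices).
    input_direction
        Unit vector ``b``; the forced system is ``x' = F(x) + b u(t)``.
        Defaults to the first coordinate axis.
    params
        Free-form parameter block recorded for provenance.
    """

    n: int
    F: Callable[[Array], Array]
    state_names: Sequence[str] = ()
    J: Optional[Callable[[Array], Array]] = None
    H: Optional[Callable[[Array], Array]] = None
    T3: Optional[Callable[[Array], Array]] = None
    input_direction: Optional[Array] = None
    name: str = "model"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.state_names:
            self.state_names = tuple(f"x{i + 1}" for i in range(self.n))
        if len(self.state_names) != self.n:
            raise ValueError("state_names length must equal n")
        if self.input_direction is None:
            b = np.zeros(self.n)
            b[0] = 1.0
            self.input_direction = b
        else:
            self.input_direction = np.asarray(self.input_direction, dtype=float)
            nrm = np.linalg.norm(self.input_direction)
            if not np.isclose(nrm, 1.0, atol=1e-10):
                raise ValueError("input_direction must have unit norm")

    # -- convenience -------------------------------------------------------
    def f(self, x: Array) -> Array:
        out = np.asarray(self.F(np.asarray(x, dtype=float)), dtype=float)
        if out.shape != (self.n,):
            raise ValueError(f"F returned shape {out.shape}, expected ({self.n},)")
        return out

    def jacobian(self, x: Array, h_rel: float = 1e-6) -> Array:
        """Analytic Jacobian if available, else central differences."""
        if self.J is not None:
            return np.asarray(self.J(np.asarray(x, dtype=float)), dtype=float)
        return _fd_jacobian(self.f, np.asarray(x, dtype=float), h_rel)

    def validate_tensors(self, x: Array, tol: float = 1e-8) -> None:
        """Check the symmetry invariants of analytic H / T3 at ``x``."""
        if self.H is not None:
            H = np.asarray(self.H(x))
            asym = np.max(np.abs(H - np.transpose(H, (0, 2, 1))))
            if asym > tol:
                raise ValueError(f"Hessians not symmetric (max asymmetry {asym:.2e})")
        if self.T3 is not None:
            T = np.asarray(self.T3(x))
            for perm in [(0, 1, 3, 2), (0, 2, 1, 3), (0, 3, 2, 1)]:
                asym = np.max(np.abs(T - np.transpose(T, perm)))
                if asym > tol:
                    raise ValueError(
                        f"third-derivative tensor not symmetric (max {asym:.2e})"
                    )


def _fd_jacobian(f: Callable[[Array], Array], x: Array, h_rel: float) -> Array:
    n = x.size
    J = np.empty((n, n))
    for j in range(n):
        h = h_rel * max(1.0, abs(x[j]))
        e = np.zeros(n)
        e[j] = h
        J[:, j] = (f(x + e) - f(x - e)) / (2 * h)
    return J


def derivative_tensors(
    model: ModelSpec,
    x0: Array,
    h_rel: float = 1e-4,
    discrepancy_warn: float = 1e-4,
):
    """Jacobian, Hessians and third-derivative tensors of ``F`` at ``x0``.

    Central differences with per-coordinate steps ``h_i = h_rel*max(1,|x0_i|)``;
    symmetry is enforced by averaging over index permutations.  When analytic
    evaluators are supplied they are preferred and the finite-difference
    result is used only as a cross-check (a warning is emitted if the two
    disagree beyond ``discrepancy_warn`` relative).

    Returns
    -------
    (J0, H, T3) : arrays of shape (n, n), (n, n, n), (n, n, n, n)
    """
    import warnings

    x0 = np.asarray(x0, dtype=float)
    n = model.n
    if not np.all(np.isfinite(model.f(x0))):
        raise ValueError("F not finite at expansion point")
    steps = h_rel * np.maximum(1.0, np.abs(x0))

    J_num = _fd_jacobian(model.f, x0, h_rel)

    # Hessians: H[i, j, k] = d2 F_i / dx_j dx_k, via differences of Jacobian
    # columns when analytic J exists, else of F directly.
    H_num = np.empty((n, n, n))
    for k in range(n):
        e = np.zeros(n)
        e[k] = steps[k]
        Jp = model.jacobian(x0 + e) if model.J is not None else _fd_jacobian(model.f, x0 + e, h_rel)
        Jm = model.jacobian(x0 - e) if model.J is not None else _fd_jacobian(model.f, x0 - e, h_rel)
        H_num[:, :, k] = (Jp - Jm) / (2 * steps[k])
    H_num = 0.5 * (H_num + np.transpose(H_num, (0, 2, 1)))

    # Third derivatives: difference the Hessian approximation.
    T3_num = np.empty((n, n, n, n))
    for m in range(n):
        e = np.zeros(n)
        e[m] = steps[m]
        Hp = _fd_hessians(model, x0 + e, h_rel)
        Hm = _fd_hessians(model, x0 - e, h_rel)
        T3_num[:, :, :, m] = (Hp - Hm) / (2 * steps[m])
    # symmetrise over the three derivative indices
    T3_num = (
        T3_num
        + np.transpose(T3_num, (0, 1, 3, 2))
        + np.transpose(T3_num, (0, 2, 1, 3))
        + np.transpose(T3_num, (0, 3, 2, 1))
        + np.transpose(T3_num, (0, 2, 3, 1))
        + np.transpose(T3_num, (0, 3, 1, 2))
    ) / 6.0

    if not (np.all(np.isfinite(J_num)) and np.all(np.isfinite(H_num)) and np.all(np.isfinite(T3_num))):
        bad = np.argwhere(~np.isfinite(J_num))
        raise ValueError(f"non-finite derivative entries (first at {bad[:1]})")

    J0, H, T3 = J_num, H_num, T3_num
    if model.J is not None:
        J_ana = np.asarray(model.J(x0), dtype=float)
        _check_discrepancy("Jacobian", J_ana, J_num, discrepancy_warn, warnings)
        J0 = J_ana
    if model.H is not None:
        H_ana = np.asarray(model.H(x0), dtype=float)
        _check_discrepancy("Hessian", H_ana, H_num, discrepancy_warn, warnings)
        H = H_ana
    if model.T3 is not None:
        T_ana = np.asarray(model.T3(x0), dtype=float)
        _check_discrepancy("third-derivative", T_ana, T3_num, discrepancy_warn, warnings)
        T3 = T_ana
    return J0, H, T3


def _fd_hessians(model: ModelSpec, x: Array, h_rel: float) -> Array:
    n = model.n
    steps = h_rel * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n, n))
    for k in range(n):
        e = np.zeros(n)
        e[k] = steps[k]
        Jp = model.jacobian(x + e, h_rel)
        Jm = model.jacobian(x - e, h_rel)
        H[:, :, k] = (Jp - Jm) / (2 * steps[k])
    return 0.5 * (H + np.transpose(H, (0, 2, 1)))


def _check_discrepancy(label, ana, num, thresh, warnings):
    scale = max(np.max(np.abs(ana)), 1.0)
    disc = np.max(np.abs(ana - num)) / scale
    if disc > thresh:
        warnings.warn(
            f"analytic/numeric {label} discrepancy {disc:.2e} exceeds {thresh:.1e}; "
            "analytic evaluator preferred",
            RuntimeWarning,
        )
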