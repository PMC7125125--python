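"""Zero-mean periodic stimuli and their Fourier description.

The Floquet-shift theory only sees a stimulus through its period ``T`` and the
power ``a_k^2 + b_k^2`` in each harmonic, with

    a_k = (2/T) \\int_0^T u(t) cos(2 pi k t / T) dt,
    b_k = (2/T) \\int_0^T u(t) sin(2 pi k t / T) dt.

Two energy conventions are carried side by side: the per-period energy
``M = \\int_0^T u^2 dt`` and the average power ``E0 = M / T``; Parseval gives
``E0 = (1/2) sum_k (a_k^2 + b_k^2)`` for zero-mean signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

Array = np.ndarray

#: quadrature samples per period for Fourier coefficients / energies
N_QUAD = 2048


@dataclass
class PeriodicStimulus:
    """A zero-mean ``T``-periodic scalar input with truncated Fourier spectrum."""

    T: float
    sampler: Callable[[Array], Array]
    K: int
    a: Array  # cosine coefficients, k = 1..K
    b: Array  # sine coefficients,   k = 1..K
    mean: float = 0.0
    energy: float = 0.0       # M = int_0^T u^2 dt
    avg_power: float = 0.0    # E0 = M / T
    parseval_residual: float = 0.0
    label: str = "stimulus"

    def __call__(self, t) -> Array:
        return self.sampler(np.asarray(t, dtype=float))

    @property
    def harmonic_power(self) -> Array:
        """``a_k^2 + b_k^2`` for k = 1..K."""
        return self.a ** 2 + self.b ** 2

    def scaled(self, factor: float) -> "PeriodicStimulus":
        """The stimulus multiplied by a scalar amplitude factor."""
        f = self.sampler
        return PeriodicStimulus(
            T=self.T,
            sampler=lambda t, f=f, factor=factor: factor * f(t),
            K=self.K,
            a=factor * self.a,
            b=factor * self.b,
            mean=factor * self.mean,
            energy=factor ** 2 * self.energy,
            avg_power=factor ** 2 * self.avg_power,
            parseval_residual=self.parseval_residual,
            label=f"{self.label}*{factor:g}",
        )


def fourier_spectrum(
    u: Callable[[Array], Array],
    T: float,
    K: int,
    n_quad: int = N_QUAD,
    zero_mean_tol: float = 1e-6,
    label: str = "stimulus",
) -> PeriodicStimulus:
    """Fourier coefficients k = 0..K of a piecewise-smooth ``T``-periodic ``u``.

    The mean ``a_0`` must vanish (the theory requires zero-mean input); a
    violation beyond ``zero_mean_tol`` (relative to the RMS) is an error.
    The Parseval residual ``|E0 - (1/2) sum (a_k^2+b_k^2)|`` is stored — it is
    only small if ``K`` covers the bandwidth of ``u``.
    """
    if T <= 0:
        raise ValueError("period must be positive")
    t = np.arange(n_quad) * (T / n_quad)  # uniform grid; rectangle rule is
    ut = np.asarray(u(t), dtype=float)    # spectrally accurate for periodic u
    mean = float(np.mean(ut))
    rms = float(np.sqrt(np.mean(ut ** 2)))
    if abs(mean) > zero_mean_tol * max(rms, 1e-300):
        raise ValueError(
            f"stimulus mean {mean:.3e} violates the zero-mean requirement"
        )
    ks = np.arange(1, K + 1)
    phase = 2 * np.pi * np.outer(ks, t) / T
    a = 2.0 * np.cos(phase) @ ut / n_quad
    b = 2.0 * np.sin(phase) @ ut / n_quad
    M = float(np.mean(ut ** 2) * T)
    E0 = M / T
    resid = abs(E0 - 0.5 * float(np.sum(a ** 2 + b ** 2)))
    return PeriodicStimulus(
        T=T, sampler=u, K=K, a=a, b=b, mean=mean,
        energy=M, avg_power=E0, parseval_residual=resid, label=label,
    )


# ---------------------------------------------------------------------------
# waveform library (the equal-energy comparison shapes)
# ---------------------------------------------------------------------------

def sine_wave(T: float, amplitude: float = 1.0) -> Callable[[Array], Array]:
    return lambda t: amplitude * np.sin(2 * np.pi * np.asarray(t) / T)


def square_wave(T: float, amplitude: float = 1.0) -> Callable[[Array], Array]:
    """Alternates between +A and -A with period T."""
    def u(t):
        tau = np.mod(np.asarray(t, dtype=float), T)
        return np.where(tau < T / 2, amplitude, -amplitude)
    return u


def triangle_wave(T: float, amplitude: float = 1.0) -> Callable[[Array], Array]:
    """Linearly ramps back and forth between +A and -A with period T."""
    def u(t):
        tau = np.mod(np.asarray(t, dtype=float) / T + 0.25, 1.0)
        return amplitude * (4 * np.abs(tau - 0.5) - 1.0)
    return u


def harmonic_mix(
    T: float,
    a: Sequence[float],
    b: Sequence[float],
) -> Callable[[Array], Array]:
    """Band-limited waveform with prescribed cosine/sine coefficients."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ks = np.arange(1, a.size + 1)

    def u(t):
        t = np.asarray(t, dtype=float)
        ph = 2 * np.pi * np.outer(ks, np.atleast_1d(t)) / T
        out = a @ np.cos(ph) + b @ np.sin(ph)
        return out[0] if t.ndim == 0 else out

    return u


def shape_library(T: float) -> dict:
    """Five zero-mean unit shapes used in the equal-energy comparison:
    pure sine, square, triangle, and two composite harmonic mixes."""
    return {
        "sine": sine_wave(T),
        "square": square_wave(T),
        "triangle": triangle_wave(T),
        "mix2": harmonic_mix(T, a=[0.0, 0.5], b=[1.0, 0.0]),
        "mix3": harmonic_mix(T, a=[0.6, 0.0, 0.3], b=[0.7, 0.4, 0.0]),
    }


def normalize_energy(
    u: Callable[[Array], Array], T: float, energy: float, K: int = 32
) -> PeriodicStimulus:
    """Rescale ``u`` so that ``\\int_0^T u^2 dt`` equals ``energy``."""
    spec = fourier_spectrum(u, T, K)
    if spec.energy <= 0:
        raise ValueError("cannot normalize a null stimulus")
    return spec.scaled(np.sqrt(energy / spec.energy))


def equal_spectrum_family(
    T: float, K: int, seeds: Sequence[int], base_power: Sequence[float] | None = None
) -> list[PeriodicStimulus]:
    """Stimuli sharing the same harmonic power ``a_k^2+b_k^2`` for every k,
    with harmonic phases scrambled per seed.

    The Floquet-shift prediction depends on a stimulus only through its power
    spectrum, so these waveforms — although pointwise different — must yield
    bit-identical predictions.
    """
    if K < 2:
        raise ValueError("need K >= 2 harmonics to scramble phases")
    if base_power is None:
        base_power = 1.0 / np.arange(1, K + 1) ** 2
    base_power = np.asarray(base_power, dtype=float)
    amp = np.sqrt(base_power)
    # quarter-turn phase scrambles: (cos, sin) of the phase offset are
    # exactly representable, so a_k^2 + b_k^2 = amp_k^2 bit-identically
    # across family members while the waveforms differ pointwise.
    quarter = [(0.0, 1.0), (1.0, 0.0), (0.0, -1.0), (-1.0, 0.0)]
    out = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        picks = rng.integers(0, 4, size=K)
        a = np.array([amp[k] * quarter[p][0] for k, p in enumerate(picks)])
        b = np.array([amp[k] * quarter[p][1] for k, p in enumerate(picks)])
        u = harmonic_mix(T, a, b)
        spec = fourier_spectrum(u, T, K, label=f"scramble{seed}")
        # overwrite quadrature coefficients with the exact construction
        spec.a, spec.b = a, b
        out.append(spec)
    return out
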