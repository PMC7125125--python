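"""Small-sample trial statistics."""

from __future__ import annotations

import math


def wilson_interval(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Inverts the score test: with ``p_hat = k/n`` and ``z`` the two-sided
    normal quantile for the given confidence,

        (p_hat + z^2/2n +- z sqrt(p_hat(1-p_hat)/n + z^2/4n^2)) / (1 + z^2/n)

    Endpoints are clipped to [0, 1]; ``k = 0`` gives a lower bound of exactly
    0 and ``k = n`` an upper bound of exactly 1.
    """
    if n < 1:
        raise ValueError("need at least one trial")
    if not 0 <= k <= n:
        raise ValueError(f"successes k={k} outside [0, {n}]")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    # two-sided normal quantile via erf inverse (scipy-free on purpose: this
    # is used by the simulation ledger which must stay dependency-light)
    z = math.sqrt(2.0) * _erfinv(confidence)
    p = k / n
    denom = 1.0 + z * z / n
    centre = p + z * z / (2 * n)
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
    lo = (centre - half) / denom
    hi = (centre + half) / denom
    if k == 0:
        lo = 0.0
    if k == n:
        hi = 1.0
    return (max(0.0, lo), min(1.0, hi))


def _erfinv(y: float) -> float:
    """Inverse error function by Newton refinement of a rational seed."""
    # Winitzki-style initial approximation
    a = 0.147
    ln = math.log(1 - y * y)
    t1 = 2 / (math.pi * a) + ln / 2
    x = math.copysign(math.sqrt(math.sqrt(t1 * t1 - ln / a) - t1), y)
    for _ in range(4):
        err = math.erf(x) - y
        x -= err * math.sqrt(math.pi) / 2 * math.exp(x * x)
    return x
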