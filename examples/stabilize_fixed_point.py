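"""Predict the forcing amplitude that stabilizes an unstable focus.

kappa_1(A) = lambda_1 + alpha_1(T) A^2 for a sinusoid of amplitude A: the
predicted zero crossing is compared against exponents measured from the
monodromy of the actual forced orbits.
"""

import numpy as np

from isoflok import (alpha_curve_resolvent, build_hopf_fixture,
                     find_fixed_point, forced_periodic_orbit,
                     predict_floquet_shift)
from isoflok.models import derivative_tensors
from isoflok.stimulus import fourier_spectrum

model = build_hopf_fixture(mu=0.01, omega0=1.0, c=1.0)
fp = find_fixed_point(model, np.array([0.1, 0.0]))
T = 5.5
curve = alpha_curve_resolvent(fp, derivative_tensors(model, fp.x0), model,
                              0, np.array([T]))
alpha = curve.alpha[0]
A_star = np.sqrt(fp.eigenvalues[0].real / -alpha.real)
print(f"lambda_1 = {fp.eigenvalues[0]:.4f};  alpha_1({T}) = {alpha.real:.4f}")
print(f"predicted stabilizing amplitude A* = {A_star:.4f}\n")

print(f"{'A':>8} {'Re kappa (predicted)':>21} {'Re kappa (measured)':>20}")
for A in A_star * np.array([0.5, 0.8, 1.0, 1.2, 1.5]):
    stim = fourier_spectrum(lambda t: A * np.sin(2 * np.pi * t / T), T, K=1)
    pred = predict_floquet_shift(fp, curve, stim).predicted_kappa
    meas = forced_periodic_orbit(model, stim, fp=fp).kappa[0]
    print(f"{A:8.4f} {pred.real:21.5f} {meas.real:20.5f}")

# Re kappa crosses zero at A ~ A*: below it the fixed point stays unstable,
# above it the weak periodic forcing has stabilized it.
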