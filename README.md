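# isoflok

Isostable phase–amplitude reduction for predicting how weak periodic
forcing shifts the Floquet exponents of weakly unstable fixed points — with
applications to desynchronization of coupled neural populations and
high-frequency conduction block in cardiac cells and tissue.

## The problem

High-frequency electrical stimulation (deep brain stimulation, AC-field
conduction block) often works by *changing the stability of a fixed point*:
a desynchronized neural state, or a depolarized cardiomyocyte state, that
is weakly unstable without stimulation.  For a forced system

```
x' = F(x) + b u(t),      u zero-mean, T-periodic, weak,
```

with fixed point `x0` and eigenvalues `λ₁, …, λₙ` (descending real part),
the induced periodic orbit has Floquet exponents

```
κ_j = λ_j + Σ_k  α_j(T/k) · (a_k² + b_k²),
```

where `a_k, b_k` are the Fourier coefficients of `u` and `α_j(T)` is a
transfer curve computable from the system's derivative tensors.  If
`Re α₁(T) < 0` somewhere, stimulation can stabilize the point — and by
Parseval's theorem the energy-optimal stimulus is a **pure sinusoid** at
the period minimizing `Re α₁`, with

```
Re κ₁ ≥ Re λ₁ + 2 E₀ · min_{T ≤ T_m} Re α₁(T),      E₀ = (1/T)∫u² dt.
```

The package computes `α_j(T)` two independent ways (a frequency-domain
resolvent chain, and brute-force monodromy measurement of forced orbits),
predicts stabilization thresholds, and ships the full application
pipelines: adjoint phase-response reduction of a tonically firing neuron,
the Fokker–Planck density model of a coupled noisy population with its
desynchronization threshold `A_crit(T) = √(−Re λ₁ / Re α₁(T))`, stochastic
population simulation with Kuramoto order-parameter readout, single-cell
high-frequency repolarization block, and a 2-D bidomain tissue simulator
with plaque-generated virtual electrodes and AC-field trials.

## Worked example

Predict and verify the amplitude that stabilizes a weakly unstable focus
(eigenvalues `0.01 ± 1i`, cubic saturation), forcing with a sinusoid at
`T = 5.5` ms:

```
$ python examples/stabilize_fixed_point.py
lambda_1 = 0.0100+1.0000j;  alpha_1(5.5) = -24.6464
predicted stabilizing amplitude A* = 0.0201

       A  Re kappa (predicted)  Re kappa (measured)
  0.0101               0.00750              0.00750
  0.0161               0.00360              0.00358
  0.0201              -0.00000             -0.00004
  0.0242              -0.00440             -0.00447
  0.0302              -0.01250             -0.01261
```

The predicted exponent `λ₁ + α₁(T)A²` tracks the measured one (from the
monodromy of the actual forced orbit) through the stability crossing at
`A ≈ 0.02`.  Other examples under `examples/` run each capability:
`alpha_curve_hopf.py` (two-route α computation), `optimal_waveform.py`
(sinusoid optimality among equal-energy shapes), `cardiac_block.py`
(pacing + block thresholds), `desynchronize_population.py` (density
pipeline and the N = 200 stochastic desynchronization experiment),
`bidomain_field_trial.py` (virtual electrodes and field-strength trends).

A thin CLI mirrors the main operations:

```
isoflok alpha --model hopf --tmin 3 --tmax 11 --npts 17
isoflok predict --model hopf --waveform sine --amplitude 0.02 --period 5.5
isoflok fp-pipeline
isoflok popsim --seed 1 --amplitude 1.9 --period 3.8
isoflok cardiac-scan --waveform sine
isoflok bidomain-trial --strength 6 --freq 33
```

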