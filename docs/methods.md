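# Methods

## The model and what is computed

The package analyses a forced ordinary differential equation

    x' = F(x) + b u(t),        x in R^n,

where `b` is a unit input direction (by convention the first coordinate; a
distributed direction is supported everywhere the theory needs it) and
`u(t)` is a weak, zero-mean, `T`-periodic scalar input.  When `u = 0` the
system has a fixed point `x0` with eigenvalues `lambda_1, ..., lambda_n`,
sorted by **descending real part** so `lambda_1` is the principal (most
unstable) exponent.  For small forcing a `T`-periodic orbit emerges near
`x0`; its Floquet exponents `kappa_j` differ from `lambda_j` at second
order in the amplitude, and the shift separates over stimulus harmonics:

    kappa_j = lambda_j + sum_{k>=1} alpha_j(T/k) (a_k^2 + b_k^2),

with `a_k, b_k` the Fourier cosine/sine coefficients of `u`.  The transfer
curve `alpha_j(T)` is the package's central object: if `Re alpha_1(T)` is
negative somewhere, weak periodic forcing can stabilize a weakly unstable
fixed point, and the energy-optimal stimulus at average power
`E0 = (1/T) int u^2 dt` is a pure sinusoid at the period minimizing
`Re alpha_1`, achieving the bound
`Re kappa_1 >= Re lambda_1 + 2 E0 min_{T<=T_m} Re alpha_1(T)`.

The isostable (phase–amplitude) reduction behind this describes the forced
orbit of the autonomous augmentation `y = (x, s)`, `s' = 1`, through a
phase `theta` and amplitude coordinates `psi_j` with response curves: the
phase response curve `Z(theta)` (adjoint solution, normalized
`F_a^T Z = omega`), isostable response curves `I_j(theta)` (normalized
`I_j(theta)^T p_j(theta) = 1` against the Floquet eigenfunctions `p_j`),
and second-order correction curves `B^k(theta)`, `C_j^k(theta)`.  The
exponent shift induced by a deviation `du` from the nominal input is
`d kappa_j = (1/T) int C_j^j(omega s) du(s) ds`.

## Two routes to alpha, and their conventions

**Resolvent route** (`alpha_curve_resolvent`).  For each period the
leading-order chain is evaluated exactly in the frequency domain, tracking
the two signed-frequency phasors of `sin(omega t)` separately (necessary
because the eigen-objects of a complex pair are complex, so positive- and
negative-frequency responses are not conjugates):

1. linear steady state `y_s = (sI - J0)^{-1} b u_s`, `s = ±i omega`;
2. Jacobian modulation `dJ_s` with rows `(H_i y_s)^T` (`H_i` the Hessian of
   component `i`);
3. eigenfunction and isostable-response modulations from resolvents shifted
   by `lambda_j`;
4. Hessian modulation `dH_i = T3_i : y_s` (third-derivative contraction);
5. the constant `C_j^{j,0} = -(J0^T)^{-1} sum_i (e_i^T I_j^0) H_i v_j`;
6. the oscillatory balance `(sI + J0^T) C_s = f_s` and the pairing of the
   resulting covector with the input direction.

The exponent shift per unit harmonic power is `alpha = (C_- - C_+)/(4i)`;
the factor 1/2 relative to the bare correlation integral comes from
integrating the quadratic amplitude dependence of the shift (`d kappa
proportional to q dq` integrates to `q^2/2`).  Both conventions were
verified against closed forms on scalar toys: for `x' = lam x + c x^3 + u`
the chain reduces to `alpha = 3c/(2(omega^2 + lam^2))`, and with a
quadratic term `h x^2/2` to `alpha = (6c - h^2/lam)/(4(omega^2 + lam^2))`;
both appear as unit tests.

Constant "shift" components of the eigen-objects (the pieces generated by
the zero modes of the shifted operators) are deliberately not computed:
they drop out of the zero-mean correlation that defines the exponent
shift.  Removing them eliminates every singular solve except the constant
balance (5), which is well-posed whenever no eigenvalue is exactly zero.
Systems with a conserved quantity (the probability-density model below)
carry an exact zero mode; there the covector space is a quotient modulo the
conservation functional and the balance is solved with the compatible
constant added and a minimal-norm representative — the ambiguity provably
cancels downstream because the Jacobian modulation of a conservative system
is itself conservative.

**Oracle route** (`alpha_curve_oracle`).  Force with `eps sin(2 pi t/T)`,
converge the orbit by Newton on the stroboscopic map (monodromy from the
variational equations integrated alongside, DOP853 at `rtol 1e-11`),
measure `kappa_j = log(multiplier)/T` with the imaginary branch matched to
`Im lambda_j` modulo `2 pi/T` (assignment by minimal distance over all
pairings), and set `alpha ~ (kappa_j - lambda_j)/eps^2`.  Richardson
extrapolation over two amplitudes (default 0.02 and 0.01) cancels the
next-order contamination; near resonances the amplitudes are shrunk by the
linear response gain so the orbit stays inside the asymptotic regime.  The
two routes agree to ~0.1% away from resonance on the reference fixture —
this cross-check is the package's principal validation and runs in the
test suite.

**Resonance guard band.**  Grid periods whose driving frequency falls
within 1e-2 rad/ms of any `Im lambda_i` are flagged: the resolvents are
near-singular there, the curves show sharp resonant peaks, and values are
reported but untrusted.  Predictions that would interpolate inside the
band raise instead of silently extrapolating.

**Time-domain reduction** (`reduction_on_orbit`).  For finite-amplitude
orbits the full curves are computed on the augmented system: periodic
adjoint solutions from the monodromy eigenstructure, and the second-order
curves as periodic solutions of forced linear ODEs via their one-period
transition matrices.  Two degeneracies are handled explicitly: (i) for
`C_j^j` the cyclicity system is singular (the phase direction has unit
multiplier) and the forcing can be incompatible; the compatibility constant
is subtracted along the time-like coordinate, whose column in the augmented
Jacobian vanishes so the correction cannot leak into any state component;
(ii) the equation admits the phase-response curve as a free periodic
homogeneous solution, and the canonical representative is pinned by zeroing
the tangent pairing `<F_a^T C>`.  Nearly degenerate Floquet exponents make
the eigenfunctions ill-conditioned and raise an error rather than
returning garbage.

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| guard band | 1e-2 rad/ms | resolvent distance to `Im lambda` below which alpha is flagged |
| quadrature | 2048 samples/period | rectangle rule on uniform grids (spectrally accurate for periodic integrands) |
| `h_rel` | 1e-4 | central-difference step scale for derivative tensors; analytic evaluators preferred when supplied |
| orbit Newton tol | 1e-10 | stroboscopic residual; relaxed to 1e-6 for discontinuous waveforms (square/triangle corners limit integrator accuracy) |
| validity factor | 10 | orbit excursions beyond 10x the linear response radius raise an escape error — the asymptotic theory no longer applies |
| oracle `eps` pair | (0.02, 0.01) | small enough for the quadratic regime on the shipped fixtures, scaled down by the linear gain near resonance |
| argmin ties | larger `T` | deterministic tie-break in the optimal-period search |

## Shipped models (the study conditions)

**Reference focus fixture** (`build_hopf_fixture`).  Planar normal form
with eigenvalues `mu ± i omega0` (defaults 0.01 ± 1i per ms) and cubic
saturation `c = 1`; optionally extra prescribed stable directions and a
random orthogonal similarity transform (spectrum preserved by
construction).  All derivative tensors analytic.  `Re alpha_1 < 0`
everywhere with the resonant extremum at `T = 2 pi/omega0`.

**Surrogate cardiomyocyte** (`build_surrogate_cardiomyocyte`).  Two
states, voltage `V` (mV) and recovery current `w` (mV/ms):

    V' = -k (V - V_rest)(V - V_thresh)(V - V_peak)
         - g tanh^3((V - V_c)/sigma) - w + I(t)
    w' = s_w (c_w (V - V_rest) - w)

with roots −80/−62/−3 mV, `k = 2.6e-4`, `c_w = 0.215`, `s_w = 0.006`,
`g = 1`, `sigma = 6`, `V_c = -26`.  The phase portrait has a stable rest
state at −78.1 mV, a saddle threshold, and a weakly unstable depolarized
spiral point at −25.9 mV with `lambda_1 = 0.0119 + 0.0311i` per ms.  The
`tanh^3` term is an odd, saturating voltage nonlinearity centred at the
depolarized point: it vanishes there together with its first two
derivatives (so the fixed point and its linearization are untouched) while
supplying the negative third voltage derivative that makes
`Re alpha_1(T) < 0` — without it the plain cubic family yields positive
alpha at this focus and high-frequency forcing would destabilize rather
than block.  Because the term saturates, the unforced escape from the
depolarized point back to rest (the action potential's repolarization,
~450 ms) is preserved; a stronger or narrower well would trap the cell in
a small stable oscillation around the depolarized point, which the build
check rejects.  Paced at 9.5 A/F, 5 ms, 1000 ms intervals, the cell fires
and repolarizes; `check=True` verifies all structural requirements and
rejects bad parameter blocks.

What the surrogate does *not* emulate: real ionic currents, their
restitution and stiffness.  Its membrane forces near the depolarized point
are ~0.1 mV/ms, orders of magnitude softer than a detailed ionic model's.
Single-cell conclusions (thresholds, optimality, saturation diagnostics)
transfer; tissue-level conclusions are trend-level only (below).

**Thalamic-type neuron** (`build_neuron_model`).  A reconstruction of the
standard 3-variable conductance model `(V, h, r)` used in the
desynchronization literature (sodium/potassium with slaved activation,
T-type calcium), with baseline drive 5 uA/cm^2 and capacitance
1 uF/cm^2.  It fires tonically with period 8.395 ms.  Fed through the
density pipeline at `D = 1`, `sigma_c = 0.08` and 400 gridpoints, its
desynchronized state has leading eigenvalues `0.0134 ± 0.7749i` with the
next pair `-0.046 ± 1.567i`, and the synchronized density orbit rotates
with period 8.22 ms.  The reciprocal imaginary parts give the resonant
stimulation periods 8.1 and 4.0 ms.  Since the original parameterization
is not part of this package's sources, the model is labelled a
reconstruction and shipped behind a config switch.

**Population fixture** (`neural_fixture_phase_model`).  An analytic
PRC/voltage pair (two harmonics each) designed once, by structural
criteria, as the pipeline's default study condition: at the reference
noise/coupling the incoherent density has a single weakly unstable pair
(`0.026 ± 0.788i`) with the second mode damped (`-0.030 ± 1.636i`), so
`alpha_1(T)` dips negative just below the second-mode resonance
(`T* = 3.8` ms, `alpha = -0.012`, `A_crit = 1.45`); the PRC first
harmonic is large enough that suprathreshold forcing disperses a
synchronized cluster, while the instability is strong enough that
sub-threshold forcing leaves synchrony intact.  The N = 200 stochastic
simulation then shows a clean desynchronization transition at the
predicted amplitude (R ≈ 0.88 at 0.7x, R ≈ 0.05 at 1.3x across seeds).
Phase-mode simulation uses a stochastic Heun scheme at `dt = 0.005` ms
with multiplicative PRC noise; spikes are phase crossings of multiples of
`2 pi`; in conductance mode a spike is an upward voltage crossing of
−20 mV (the reconstruction's spike peak sits near −7 mV, so the classical
0 mV rule would miss every spike).

## Density (Fokker–Planck) pipeline numerics

The phase density `rho(theta, t)` evolves by drift
`omega + Z(theta)(I_stim + sigma_c (Vbar - V))` and diffusion
`D Z^2(theta)`, discretized in conservative flux form (second-order
central fluxes; diffusion written as the second difference of
`D Z^2 rho`), so total probability is conserved to machine precision;
`Z'` uses the periodic spectral differentiation matrix.  The stationary
desynchronized state is found by Newton with one residual row replaced by
the normalization `sum rho dtheta = 1` (the operator has a conservation
null direction).  The stimulus enters as `-I_stim(t) (diag(Z) A +
diag(Z')) rho`; near the fixed point this is a fixed input vector
`r0 = M_input rho0`, and alpha is computed either directly with the
distributed direction or after the Householder change of variables that
maps `r0` to the first coordinate — the two agree to 1e-8 (tested).  The
quadratic coupling's Hessian contractions are evaluated through their
low-rank structure, never materialized as an `n^3` tensor.

## Cardiac and bidomain experiments

Single-cell block: after pacing to steady state and initiating one action
potential, the high-frequency current replaces pacing; "blocked" means the
voltage stayed above −30 mV over the whole assessment window (default
50 ms to the record's end; single-cell records run 1250 ms, beyond the
~450 ms natural plateau).  Thresholds per waveform are found by bisection
with a moderate-step bracket walk, because at large amplitudes the forced
oscillation itself dips below −30 mV, making the blocked region a band in
amplitude rather than a half-line.  The threshold curves use the
equal-amplitude (±A) convention per shape; the equal-energy convention is
exercised separately by the optimality comparison.

Bidomain tissue: intra/extracellular potentials on a 2-D sheet with
diagonal anisotropic conductivities (0.2/2.0 intracellular, 0.8/2.0
extracellular mS/cm; `beta = 1000` /cm, `C_m = 1` uF/cm^2), operator
splitting — forward-Euler membrane update, then a sparse pure-Neumann
elliptic solve for `V_e` regularized by a zero-mean constraint (bordered
system, one LU per geometry).  The applied field enters as extracellular
boundary flux on the left/right edges.  Insulating plaques remove `g_ix`
along random fiber segments (lengths uniform in 1.41–3.96 mm,
mean-adjusted to 2.69 mm); virtual electrodes form at the resulting
discontinuities (interior response ~1000x the homogeneous case).  Test
scale: 50x50 nodes at 566 um and `dt = 0.02` ms (a diffusion-stability
check guards `dt`), plaque count scaled with area.

A known limitation, documented deliberately: with the literal 500-ms hold
rule, the surrogate tissue shows *no* sustained block at any field
strength.  The surrogate's membrane is soft compared with the
electrotonic sink from repolarized neighbours at physiological
conductivities, so held patches dissolve by front motion once the bulk
repolarizes; detailed ionic models are stiff enough to sustain them.  The
shipped trend experiments therefore use a 250-ms field (shorter than the
natural plateau): the −30 mV rule over [50 ms, field end] then measures
which cells the virtual electrodes capture into sustained depolarization,
and the expected trends hold cleanly — block fraction strictly increasing
with field strength at 33 Hz and decreasing from 33 to 100 Hz at fixed
strength.  Spiral initiation (cross-field S1–S2) and elimination trials
with Wilson-interval statistics are provided for completeness; the trend
experiments start from a deterministic plane wave, which the block map
does not require a spiral for.

## What passing tests show — and what they do not

The tests establish internal consistency of the theory and its two
computational routes on analytic fixtures, and qualitative reproduction of
the application phenomenology on surrogates: desynchronization at the
predicted amplitude, repolarization block thresholds with the right period
dependence, sinusoid optimality, saturation of the second-order curve at
large amplitude, virtual-electrode trends.  They do not validate any
specific ionic model, real DBS electrode physics, or quantitative tissue
behaviour; every surrogate was designed for the *mechanism* (a weakly
unstable fixed point whose stability periodic forcing can flip), which is
exactly the claim under study.

## Problem sizes

Defaults were chosen so the full test suite and the acceptance script each
run on a single CPU in minutes: density grid 400 (as in the reference
setting; 64–200 in forced-orbit cross-checks, where the monodromy costs
`n^2` variational equations), populations of N = 200 for 1.8 s at
`dt = 0.005` ms, bidomain 50x50 for 250-ms fields.  All stochastic runs
take explicit seeds and replay bit-identically.
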