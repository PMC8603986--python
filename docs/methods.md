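# Methods

## Conventions

Energies are molar (kJ/mol), so Boltzmann's constant is realized as
the gas constant R = 8.314462618e-3 kJ/(mol K) (`hemekin.constants`).
Rates are s^-1, viscosities cP, ligand "pressure" is carried as a unit
label (torr by default) and never converted — the equilibrium models
only ever use the product (affinity x pressure), so any consistent
pressure unit works.

## Equilibrium models

Both partition functions are sums of two terms c (alpha + beta p)^n:
MWC with (L, 1, K_T) and (1, 1, K_R); TTS with
(L/l_T^n, 1 + l_T, K_r + l_T K_t) and (1, 1 + l_R, K_r + l_R K_t),
because each TTS bracket is linear in p. All derived quantities are
evaluated in this representation:

- y = p Σ c beta A^(n-1) / Ξ and 1 − y = Σ c alpha A^(n-1) / Ξ
  (A = alpha + beta p), so neither saturates to floating-point 1 and
  the Hill transform stays accurate to y ~ 1 − 1e-300.
- The pointwise Hill slope has the closed form
  h(p) = 1 + (n−1) p [S(beta², n−2)/S(beta, n−1) − S(alpha beta, n−2)/S(alpha, n−1)],
  S(w, m) = Σ c w A^m, which is exactly 1 for a single conformation at
  every pressure — no finite differences are involved anywhere.
- The Hill coefficient maximizes h on an 801-point log-pressure grid
  spanning ±6 decades around the reciprocal geometric-mean affinity,
  then polishes the first (lowest-pressure) grid maximum by bounded
  scalar minimization (xatol 1e-10 in log10 p). Ties therefore resolve
  to the lowest pressure.

The number of subunits n is a parameter (default 4, the hemoglobin
tetramer) so symmetry properties can be tested at other n.

Species enumeration keys classes by counts — (quaternary, number
liganded) for MWC and (quaternary, number liganded, number of
r-subunits) for TTS — because subunits are treated as equivalent;
distinct alpha/beta-chain affinities are out of scope. This grouping
gives 2(n+1) = 10 and 2(n+1)² = 50 classes at n = 4, and the class
weights sum identically to the closed-form partition function.
`subunit_fractions` additionally resolves, per class, the mean r/t
composition of all subunits and of the unliganded subunits, from the
same multinomially collected weights.

Binding-curve fitting log-transforms all parameters (positivity),
uses trust-region reflective least squares (cost tolerance 1e-10)
inside a generous finite box (1e-18..1e18) that prevents overflow when
a parameter is unidentifiable, and flags degeneracy whenever the
Jacobian condition number exceeds 1e8 or the residual RMS is far above
the noise scale. A TTS model fitted to a single noiseless isotherm is
routinely flagged: a five-parameter TTS curve is not identifiable from
one binding curve, and the flag — not a silent answer — is the
intended behavior.

## Distributed geminate rebinding

The forward model N(t) = Σ g_i exp(−A e^(−H_i/RT) t) is evaluated
directly; the initial rate is the analytic sum Σ g_i k(H_i).

The multi-temperature inverse problem assumes one g(H) and one
prefactor A for all curves — the physical statement that the substate
population is frozen while only the rates shift with temperature. g is
parameterized by a softmax over bin logits (non-negativity and unit
normalization exact by construction, never penalized) on a linear
enthalpy grid, default 32 bins over 0–30 kJ/mol (typical heme
rebinding barriers). A is fitted as log10 A (initial guess 1e9 s^-1)
or held fixed. A second-difference penalty with weight `reg`
(default 1e-3) regularizes the otherwise ill-posed inversion; it is
weak enough that a noiseless single exponential still concentrates
> 99% of the recovered mass in two adjacent bins.

Rate-distribution inversion solves N(t_i) ≈ Σ w_j exp(−k_j t_i),
w ≥ 0, on a log-spaced grid (default 20 points/decade) spanning
0.1/t_max to 2/t_min — rates faster than ~2/t_min decay entirely
before the first sample and would act as unconstrained degrees of
freedom. Two regularizations are provided: non-negative least squares
with a ridge term, and maximum entropy (Skilling entropy
S = Σ[w − m − w log(w/m)] against a flat prior m), where the entropy
weight is bisected in log space until chi² per point reaches 1. With
zero data weight the maximum-entropy solution is the prior, returned
exactly. Every inversion reports the effective rank of the weighted
kernel and warns that the problem is ill-posed; this is intrinsic to
inverse Laplace transforms, not a defect of a particular dataset.

Kinetic schemes are labeled first-order networks; the generator has
columns summing to zero and is propagated by eigendecomposition (with
an `expm` fallback if the eigenbasis is ill-conditioned). The geminate
yield is computed exactly from the transient block:
yield = r_bound^T (−Q_TT)^{-1} p0. The canned two-geminate-state
topology (photodissociated ligand in a primary or secondary internal
site, escape to solvent, and a parallel unrelaxed-to-relaxed protein
conformational branch that slows rebinding) ships with placeholder
rate constants — the topology is the model; quantitative rates must be
supplied by the user. Whether the conformational relaxation edge acts
on both geminate states or only the first is genuinely open, so it is
a constructor flag (`relax_gates`, default "both").

## Substate relaxation

The single-transition-state law
k_ij = k_0 g(E_j) δE exp(−(E‡ − E_i)/k_B T) couples every pair of
substates: departure depends on the departing substate only through
its barrier, arrival is weighted by the target density of states. The
same law is used for within-basin and cross-basin moves; the unrelaxed
photoproduct is modeled as a Gaussian population shifted (and
optionally re-widened) on the same substate grid, since nothing pins
down a more detailed coupling topology. Detailed balance against
pi ∝ g(E) e^(−E/k_B T) holds algebraically.

Defaults: 64 substates spanning mu ± 5 s (> 1 − 1e-6 of the Gaussian
density), E‡ = top grid energy + 2 k_B T (guaranteeing positive
barriers; configurable, validated), observable = population-mean
energy with an optional affine map onto a spectral proxy (band-shift
units), since the actual spectroscopic observable has no specified
functional link to substate energy.

Propagation diagonalizes the detailed-balance-symmetrized generator.
Its off-diagonal entries are formed from the analytic expression
k_0 sqrt(g_i g_j) exp((E_i + E_j)/(2 k_B T) − E‡/k_B T) rather than
from ratios of equilibrium populations, which keeps the matrix exactly
symmetric across the ~e^20 dynamic range a 2 k_BT-wide ensemble spans.
Eigenvalues are clamped to ≤ 0 and eigenvalues below 1e-12 of the
spectral radius are snapped to exactly zero, so the stationary mode
never decays numerically; `slowest_relaxation_rate` exposes the
smallest surviving relaxation rate for choosing horizons (the
stationarity tests use 100x its reciprocal).

Stretched-exponential fitting uses the model
offset + amplitude exp(−(k t)^beta) with k log-parameterized and beta
bounded in (0, 1.5]; initial guesses come from the data (offset from
the tail, k from the ~63% decay point). A beta < 0.5 fitted from
fewer than 8 points or less than 2 decades of time triggers a warning,
and non-decaying inputs are flagged, not rejected. The width-stretching
mechanism is quantitative here: ensembles of width 0.5, 1, 2, 4 k_BT
yield monotonically decreasing beta (≈ 0.83, 0.50, 0.26, 0.23 under
the default generator conditions), approaching 1 in the narrow limit.

## Internal friction

k(η) = C/(σ + η) exp(−E_0/k_B T) is fitted in log space. A
single-temperature dataset cannot separate C from E_0, so E_0 is a
fixed input (default 0) and C absorbs the exponential factor; C
carries units of s^-1 cP by convention. The fractional
viscosity-dependence phenomenology is represented only through this
additive-σ law; a power-law k ∝ η^−κ fitter is deliberately excluded.
σ is reported unidentifiable when the viscosity range spans under a
decade, when the data never approach the plateau (min η > 10 σ̂), or
when its log-scale standard error exceeds 1.

## Synthetic data

Every generator is a pure function of (configuration, seed) with an
explicit `NoiseSpec`; no global RNG state. Noise is additive Gaussian
or multiplicative lognormal and is not clipped, so noisy observables
may stray slightly outside [0, 1] (the fitters tolerate this). Default
time grids are log-spaced because the kinetics span picoseconds to
seconds. Study conditions used by the tests, chosen once:

- Enthalpy-distribution recovery: Gaussian g(H) with mean 12 kJ/mol,
  sd 2 kJ/mol, A = 1e9 s^-1 (the prefactor has no canonical printed
  value; 1e9 s^-1 is a physically reasonable glass-phase scale and is
  documented wherever used), temperatures 140/200/297 K, 0.5%
  additive noise, 80 log-spaced points per curve covering each curve's
  own decay window.
- Kramers recovery: C = 1e9 s^-1 cP, σ = 4 cP, 20 points over
  η = 0.5–500 cP, 5% lognormal noise.
- Binding curves: 50 log-spaced pressures over 6 decades, 1% additive
  noise.

The generators emulate idealized instrument output: homoscedastic
noise, no baseline drift, no photoselection or spectral overlap, no
bimolecular (solvent-phase) rebinding phase. Passing recovery tests
therefore demonstrates correctness and conditioning of the estimators
under the stated noise model, not robustness to every artifact of real
transient-absorption data.

## Known limitations

- Equilibrium models assume equivalent subunits (alpha = beta chains);
  effector linkage is represented as alternative (L, l_T, l_R)
  parameter sets, not explicit effector binding polynomials.
- The bimolecular solvent-phase rebinding channel is out of scope; the
  kinetic schemes treat "solvent" as absorbing.
- Single-temperature rate-vs-viscosity fits cannot determine E_0.
- The maximum-entropy inversion, like any inverse Laplace transform,
  has resolution limited by noise: peak widths grow with noise level
  (verified monotonically in the tests), and closely spaced rate
  components merge.
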