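# hemekin

Equilibrium allostery and kinetics models for heme proteins: the
quaternary two-state (MWC) and tertiary two-state (TTS) partition
functions for cooperative ligand binding, distributed
activation-enthalpy geminate-rebinding kinetics, single-transition-state
conformational-substate relaxation, and the Kramers rate law with
additive internal friction — with fitting, simulation, and seeded
synthetic-data generation so every model can be exercised at desk
scale.

The package is aimed at biophysicists analyzing ligand-binding
isotherms, photolysis survival curves, conformational-relaxation
traces, and rate-vs-viscosity series for myoglobin- and
hemoglobin-like systems, and at anyone who wants clean, tested
reference implementations of these classic models.

## Models

**Equilibrium binding.** For a protein with n equivalent sites at
ligand pressure p, the MWC partition function is

    Ξ(MWC) = L (1 + K_T p)^n + (1 + K_R p)^n

with allosteric constant L = [T0]/[R0] and T/R affinities K_T, K_R.
The TTS extension lets each subunit occupy a low-affinity (t) or
high-affinity (r) tertiary conformation inside either quaternary
structure:

    Ξ(TTS) = (L / l_T^n) [1 + K_r p + l_T (1 + K_t p)]^n
             + [1 + K_r p + l_R (1 + K_t p)]^n

Saturation is y(p) = (1/n) d lnΞ / d ln p; the Hill slope
d log(y/(1−y)) / d log p is computed analytically and its maximum
(the Hill coefficient n_H) is bounded by n. Species enumeration
expands Ξ into its symmetry-distinct Boltzmann-weighted terms
(10 for MWC, 50 for TTS at n = 4).

**Geminate rebinding in a glass.** Frozen conformational substates
each rebind their photodissociated ligand at an Arrhenius rate, giving

    N(t) = Σ_i g(H_i) exp(−A e^(−H_i/k_B T) t),

with one enthalpy distribution g(H) shared across all temperatures.
The package fits g(H) jointly to multi-temperature survival curves,
inverts single curves into rate distributions (maximum-entropy or
ridge), and solves arbitrary first-order kinetic schemes (matrix
exponential; geminate yield by a branching-ratio linear solve).

**Substate relaxation.** Substates with Gaussian energy density g(E)
interconvert through transition states of a single energy E‡ at rates
k_ij = k_0 g(E_j) δE exp(−(E‡ − E_i)/k_B T). This master equation
obeys detailed balance, relaxes to the Boltzmann distribution, and for
wide ensembles produces stretched-exponential (exp[−(kt)^β], β < 1)
observables; a constrained stretched-exponential fitter is included.

**Internal friction.** Conformational rates vs solvent viscosity η
follow k = C/(σ + η) exp(−E_0/k_B T), where σ is the protein's
internal-friction viscosity; the fitter flags σ as unidentifiable when
the data never reach the low-viscosity plateau.

Fit-shaped operations are sklearn-style estimators
(`BindingModelEstimator`, `EnthalpyDistributionEstimator`,
`RateDistributionEstimator`, `StretchedExponentialEstimator`,
`KramersEstimator`) with `fit`/`predict` and trailing-underscore
results; thin module-level functions wrap them.

## Worked example

```python
import numpy as np
import hemekin as hk
from hemekin.constants import Conditions

# cooperative tetramer: maximum Hill slope
model = hk.MWCParams(L=1e5, K_T=1e-3, K_R=1.0)
print(f"max Hill slope n_H = {hk.hill_coefficient(model):.3f}")

# geminate yield when escape is 20x faster than rebinding
scheme = hk.KineticScheme(
    states=["bound", "gem", "solvent"],
    rates={("gem", "bound"): 1.7e5, ("gem", "solvent"): 3.4e6},
    initial={"gem": 1.0},
    absorbing=frozenset({"bound", "solvent"}),
)
print(f"geminate yield = {hk.geminate_yield(scheme):.4f}")

# stretched relaxation of a wide substate ensemble
c = Conditions(297.0)
ens = hk.SubstateEnsemble(mu=0.0, s=2 * c.thermal_energy, k0=1e9, cond=c)
trace = hk.relax(ens.gaussian_population(ens.mu + 2 * c.thermal_energy),
                 ens, np.logspace(-11, 3, 140))
fit = hk.fit_stretched_exponential(trace)
print(f"stretched-exponential fit: beta = {fit.beta:.3f}, k = {fit.k:.3g} s^-1")
```

prints

```
max Hill slope n_H = 3.595
geminate yield = 0.0476
stretched-exponential fit: beta = 0.259, k = 2.15e+03 s^-1
```

The Hill coefficient 3.595 (< 4 subunits) reflects strong but
sub-maximal cooperativity for this parameter set; the 4.76% yield is
the branching ratio 1/21 of rebinding against a 20-fold-faster escape;
β = 0.26 shows how a 2 k_BT-wide substate ensemble stretches an
otherwise exponential relaxation.

A command-line interface mirrors the library:

```sh
hemekin binding simulate --config mwc.yaml --out curve.csv
hemekin binding fit --model mwc --data curve.csv --out fit.json
hemekin gem yield --config scheme.yaml
hemekin gen binding --config mwc.yaml --seed 7 --sd 0.01 --out noisy.csv
```

Exit codes: 0 success, 2 validation error, 3 flagged fit.

## Documentation

`docs/methods.md` describes the models, their assumptions, parameter
conventions (units, defaults), the numerical methods, and known
limitations.
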