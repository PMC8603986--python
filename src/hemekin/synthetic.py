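"""Seeded generators for every input the fitting routines consume.

Each generator is a pure function of (configuration, seed): the same
seed always reproduces the same arrays, and sd = 0 returns the exact
forward-model output. Noise is either additive Gaussian or
multiplicative lognormal; noisy observables are not clipped, so values
can stray slightly outside their ideal range (fitters tolerate this).
Default time grids are log-spaced, since the kinetics of interest span
many decades.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import Conditions
from .equilibrium import BindingCurve, BindingModel, saturation
from .geminate import EnthalpyDistribution, SurvivalCurve, survival_distributed
from .io import Trace
from .kramers import KramersParams, kramers_rate
from .relaxation import RelaxationTrace, SubstateEnsemble, relax


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model: kind, scale and seed.

    kind "gaussian-additive" adds N(0, sd); "lognormal-multiplicative"
    multiplies by exp(N(0, sd)), i.e. sd is the log-scale relative
    noise. sd = 0 disables noise. Identical seeds give identical draws.
    """

    kind: str = "gaussian-additive"
    sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian-additive", "lognormal-multiplicative"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0:
            return np.asarray(values, dtype=float).copy()
        if self.kind == "gaussian-additive":
            return values + rng.normal(0.0, self.sd, size=np.shape(values))
        return values * np.exp(rng.normal(0.0, self.sd, size=np.shape(values)))


def gen_binding_curve(model: BindingModel, p, noise: NoiseSpec) -> BindingCurve:
    """Noisy equilibrium binding curve from an MWC or TTS model."""
    rng = np.random.default_rng(noise.seed)
    clean = saturation(p, model)
    y = noise.apply(clean.y, rng)
    sd = np.full_like(y, noise.sd) if noise.sd > 0 else None
    return BindingCurve(p=clean.p, y=y, sd=sd)


def gen_survival_set(
    dist: EnthalpyDistribution,
    temperatures,
    t_grids,
    noise: NoiseSpec,
) -> list[SurvivalCurve]:
    """Noisy multi-temperature survival curves sharing one distribution.

    ``t_grids`` is either one time array used at every temperature or a
    sequence of arrays, one per temperature.
    """
    temperatures = list(temperatures)
    if isinstance(t_grids, np.ndarray) or np.ndim(t_grids[0]) == 0:
        t_grids = [np.asarray(t_grids, dtype=float)] * len(temperatures)
    if len(t_grids) != len(temperatures):
        raise ValueError("need one time grid per temperature")
    rng = np.random.default_rng(noise.seed)
    out = []
    for T, t in zip(temperatures, t_grids):
        clean = survival_distributed(t, dist, Conditions(T))
        N = noise.apply(clean.N, rng)
        sd = np.full_like(N, noise.sd) if noise.sd > 0 else None
        out.append(SurvivalCurve(t=clean.t, N=N, sd=sd, temperature=T))
    return out


def gen_relaxation(
    ens: SubstateEnsemble,
    t,
    noise: NoiseSpec,
    initial_shift: float = 0.0,
    initial_width: float | None = None,
    observable_map: tuple[float, float] | None = None,
) -> RelaxationTrace:
    """Noisy relaxation trace from a shifted-Gaussian initial population.

    The photoproduct is modeled as a Gaussian of mean mu + initial_shift
    (and optionally different width) on the ensemble's substate grid.
    """
    rng = np.random.default_rng(noise.seed)
    p0 = ens.gaussian_population(ens.mu + initial_shift, initial_width)
    clean = relax(p0, ens, t, observable_map=observable_map)
    obs = noise.apply(clean.observable, rng)
    sd = np.full_like(obs, noise.sd) if noise.sd > 0 else None
    return RelaxationTrace(t=clean.t, observable=obs, sd=sd)


def gen_viscosity_series(params: KramersParams, eta, noise: NoiseSpec) -> Trace:
    """Noisy rate-vs-viscosity series from the internal-friction law."""
    rng = np.random.default_rng(noise.seed)
    eta = np.asarray(eta, dtype=float)
    k = noise.apply(kramers_rate(eta, params), rng)
    return Trace(x=eta, y=k, xlabel="viscosity_cP", ylabel="rate_per_s")


def log_time_grid(t_min: float, t_max: float, n: int = 80) -> np.ndarray:
    """Log-spaced time grid (the package default for kinetic traces)."""
    if not 0 < t_min < t_max:
        raise ValueError("need 0 < t_min < t_max")
    return np.logspace(np.log10(t_min), np.log10(t_max), n)
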