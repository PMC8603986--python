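"""Single-transition-state relaxation over a Gaussian substate ensemble.

After photodissociation the protein finds itself with a non-equilibrium
distribution over conformational substates and relaxes toward the
Boltzmann distribution. The model here connects every pair of
substates through transition states of a single common energy E‡: the
rate for a substate of energy E_i to convert to a substate with energy
in [E_j, E_j + dE] is

    k_ij = k_0 g(E_j) dE exp(-(E‡ - E_i) / k_B T),

i.e. departure depends on the departing substate only through its
barrier E‡ - E_i, and arrival is weighted by the density of target
states g(E_j), taken Gaussian. This master equation satisfies detailed
balance with respect to pi_i ∝ g(E_i) exp(-E_i / k_B T) and, for wide
ensembles (s >> k_B T), produces highly stretched (Kohlrausch)
relaxation of ensemble observables; in the narrow-ensemble limit the
relaxation collapses to a single exponential (beta -> 1).

Stretched-exponential fitting is exposed as
:class:`StretchedExponentialEstimator` / :func:`fit_stretched_exponential`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .constants import Conditions


@dataclass
class SubstateEnsemble:
    """Gaussian ensemble of conformational substates with one E‡.

    Parameters
    ----------
    mu, s : float
        Mean and standard deviation of the Gaussian density of substate
        energies, kJ/mol (s > 0).
    k0 : float
        Rate-scale constant of the single-transition-state law, s^-1.
    cond : Conditions
        Temperature (sets k_B T).
    e_dagger : float or None
        Common transition-state energy, kJ/mol. Defaults to the top of
        the energy grid plus 2 k_B T, guaranteeing non-negative
        barriers. Must not lie below any grid energy.
    n_substates : int
        Grid size (default 64).
    span : float
        Grid half-width in units of s (default 5, capturing > 1 - 1e-6
        of the density).
    """

    mu: float
    s: float
    k0: float
    cond: Conditions
    e_dagger: float | None = None
    n_substates: int = 64
    span: float = 5.0

    def __post_init__(self) -> None:
        if not self.s > 0:
            raise ValueError(f"ensemble width s must be positive, got {self.s}")
        if not self.k0 > 0:
            raise ValueError(f"k0 must be positive, got {self.k0}")
        if self.n_substates < 2:
            raise ValueError("need at least 2 substates")
        if self.e_dagger is None:
            self.e_dagger = self.mu + self.span * self.s + 2.0 * self.cond.thermal_energy
        if self.e_dagger < self.mu + self.span * self.s - 1e-9:
            raise ValueError(
                f"E_dagger={self.e_dagger} lies below the top grid energy "
                f"{self.mu + self.span * self.s} (negative barrier)"
            )

    @property
    def energies(self) -> np.ndarray:
        return np.linspace(self.mu - self.span * self.s, self.mu + self.span * self.s,
                           self.n_substates)

    @property
    def delta_e(self) -> float:
        return 2.0 * self.span * self.s / (self.n_substates - 1)

    @property
    def weights(self) -> np.ndarray:
        """Discretized Gaussian density g(E_i) dE, normalized to sum 1."""
        E = self.energies
        w = np.exp(-0.5 * ((E - self.mu) / self.s) ** 2)
        return w / w.sum()

    def boltzmann(self) -> np.ndarray:
        """Equilibrium distribution pi ∝ g(E) exp(-E / k_B T)."""
        E = self.energies
        logpi = np.log(self.weights) - E / self.cond.thermal_energy
        pi = np.exp(logpi - logpi.max())
        return pi / pi.sum()

    def gaussian_population(self, mu0: float, s0: float | None = None) -> np.ndarray:
        """A (possibly shifted/re-widened) Gaussian population on this grid.

        Models the unrelaxed photoproduct as a Gaussian of mean mu0 and
        width s0 (defaulting to the ensemble width) over the same
        substate grid.
        """
        s0 = self.s if s0 is None else s0
        w = np.exp(-0.5 * ((self.energies - mu0) / s0) ** 2)
        tot = w.sum()
        if tot <= 0:
            raise ValueError("initial population has no support on the grid")
        return w / tot


def build_rate_matrix(ens: SubstateEnsemble) -> np.ndarray:
    """Generator matrix of the single-transition-state master equation.

    Q[j, i] = k_0 g_j exp(-(E‡ - E_i)/k_B T) for j != i; the diagonal
    makes columns sum to zero. Every off-diagonal entry is positive,
    and detailed balance holds exactly against the Boltzmann
    distribution pi ∝ g exp(-E/k_B T).
    """
    E = ens.energies
    g = ens.weights
    kt = ens.cond.thermal_energy
    depart = ens.k0 * np.exp(-(ens.e_dagger - E) / kt)  # per departing state i
    Q = np.outer(g, depart)  # Q[j, i] = k0 g_j exp(-(E‡-E_i)/kT)
    np.fill_diagonal(Q, 0.0)
    Q -= np.diag(Q.sum(axis=0))
    return Q


def _symmetrized_spectrum(ens: SubstateEnsemble):
    """Eigendecomposition of the detailed-balance-symmetrized generator.

    With pi_i ∝ g_i exp(-E_i/k_B T), the similarity transform
    B = D^{-1/2} Q D^{1/2} (D = diag pi) is symmetric; its off-diagonal
    entries reduce analytically to
        B_ij = k_0 sqrt(g_i g_j) exp((E_i + E_j)/(2 k_B T) - E‡/k_B T),
    which is used directly (rather than forming ratios of potentially
    tiny pi) for numerical robustness. Positive eigenvalue noise is
    clamped: the generator is negative semidefinite in this frame.
    Returns (eigenvalues, eigenvectors, sqrt(pi)).
    """
    E = ens.energies
    g = ens.weights
    kt = ens.cond.thermal_energy
    half = E / (2.0 * kt)
    B = ens.k0 * np.outer(np.sqrt(g) * np.exp(half), np.sqrt(g) * np.exp(half)) * np.exp(
        -ens.e_dagger / kt
    )
    np.fill_diagonal(B, 0.0)
    depart = ens.k0 * np.exp(-(ens.e_dagger - E) / kt) * (1.0 - g)
    B -= np.diag(depart)
    lam, U = np.linalg.eigh(B)
    lam = np.minimum(lam, 0.0)
    # the stationary eigenvalue is only numerically zero (error ~ eps*|lam|_max);
    # snap it (and anything below eigh's resolution) to exactly zero so the
    # equilibrium mode never decays
    lam[np.abs(lam) < 1e-12 * np.abs(lam).max()] = 0.0
    pi = ens.boltzmann()
    return lam, U, np.sqrt(pi)


def slowest_relaxation_rate(ens: SubstateEnsemble) -> float:
    """Magnitude of the slowest nonzero relaxation eigenvalue (s^-1).

    The zero (stationary) mode is excluded with a cutoff relative to
    the fastest mode, since it is only numerically zero.
    """
    lam, _, _ = _symmetrized_spectrum(ens)
    mags = np.abs(lam)
    nonzero = mags[mags > 0.0]
    return float(nonzero.min())


@dataclass
class RelaxationTrace:
    """Times and an ensemble observable (default: mean substate energy)."""

    t: np.ndarray
    observable: np.ndarray
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.observable = np.asarray(self.observable, dtype=float)
        if self.t.shape != self.observable.shape:
            raise ValueError("t and observable must have the same shape")


def relax(
    p0: np.ndarray,
    ens: SubstateEnsemble,
    t,
    observable_map: tuple[float, float] | None = None,
    return_populations: bool = False,
):
    """Propagate an initial substate population and record an observable.

    p0 is a normalized population on the ensemble's energy grid (use
    :meth:`SubstateEnsemble.gaussian_population` for a shifted-Gaussian
    photoproduct). Propagation uses the symmetrized eigendecomposition
    of the detailed-balance generator, exact for all t. The observable
    is the population-mean energy, optionally mapped affinely
    (scale, offset) onto a spectral proxy such as a band shift; at long
    times it converges to the Boltzmann-ensemble mean.
    """
    p0 = np.asarray(p0, dtype=float)
    t = np.asarray(t, dtype=float)
    if p0.shape != (ens.n_substates,):
        raise ValueError(
            f"initial population has shape {p0.shape}, grid has {ens.n_substates} states"
        )
    if abs(p0.sum() - 1.0) > 1e-8:
        raise ValueError("initial population must be normalized")
    lam, U, sq = _symmetrized_spectrum(ens)
    c = U.T @ (p0 / sq)
    # populations(t) = diag(sq) U exp(lam t) c
    P = (np.exp(np.outer(t, lam)) * c) @ U.T * sq
    E = ens.energies
    obs = P @ E
    if observable_map is not None:
        scale, offset = observable_map
        obs = scale * obs + offset
    trace = RelaxationTrace(t=t, observable=obs)
    if return_populations:
        return trace, P
    return trace


# --------------------------------------------------------------------------
# stretched-exponential fitting
# --------------------------------------------------------------------------


@dataclass
class StretchedExpFit:
    """Fitted Kohlrausch decay  offset + amplitude * exp(-(k t)^beta)."""

    k: float
    beta: float
    amplitude: float
    offset: float
    rms: float
    converged: bool
    decaying: bool

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.offset + self.amplitude * np.exp(-((self.k * t) ** self.beta))


class StretchedExponentialEstimator(BaseEstimator):
    """Least-squares stretched-exponential fit.

    Model: y(t) = offset + amplitude * exp(-(k t)^beta), with k > 0
    enforced by a log parameterization and beta constrained to
    (0, 1.5]. A warning is issued when the data span fewer than 8
    points or 2 decades of time yet the fitted beta falls below 0.5
    (such fits are poorly constrained); a non-decaying input is
    flagged via ``fit_.decaying`` rather than rejected.

    Attributes: ``fit_`` (a :class:`StretchedExpFit`), plus ``k_``,
    ``beta_``, ``amplitude_``, ``offset_``, ``residuals_``.
    """

    def __init__(self, init=None, max_nfev=10000):
        self.init = init
        self.max_nfev = max_nfev

    def fit(self, t, y=None, sd=None):
        if isinstance(t, RelaxationTrace):
            t, y, sd = t.t, t.observable, t.sd if sd is None else sd
        elif hasattr(t, "t") and hasattr(t, "N"):  # SurvivalCurve duck-type
            t, y, sd = t.t, t.N, getattr(t, "sd", None) if sd is None else sd
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        if t.size < 4:
            raise ValueError("need at least 4 points to fit 4 parameters")
        w = 1.0 / np.asarray(sd, dtype=float) if sd is not None else np.ones_like(y)

        decaying = bool(y[0] > y[-1] + 1e-12 * max(abs(y[0]), 1.0))
        if not decaying:
            warnings.warn("input does not decay; stretched-exponential fit flagged")

        offset0 = float(y[-1])
        amp0 = float(y[0] - y[-1]) or 1.0
        # time at which the decay has progressed ~63%
        frac = (y - offset0) / amp0 if amp0 != 0 else np.zeros_like(y)
        below = np.nonzero(frac < np.exp(-1.0))[0]
        t63 = t[below[0]] if below.size and t[below[0]] > 0 else (
            t[t > 0][t[t > 0].size // 2] if np.any(t > 0) else 1.0
        )
        defaults = {"k": 1.0 / t63, "beta": 0.7, "amplitude": amp0, "offset": offset0}
        if self.init:
            defaults.update(self.init)
        theta0 = np.array([np.log(defaults["k"]), defaults["beta"],
                           defaults["amplitude"], defaults["offset"]])

        def model(theta, tt):
            k, beta, amp, off = np.exp(theta[0]), theta[1], theta[2], theta[3]
            kt = np.where(tt > 0, k * tt, 0.0)
            return off + amp * np.exp(-np.power(kt, beta, where=kt > 0,
                                                out=np.zeros_like(kt)))

        res = least_squares(
            lambda th: w * (model(th, t) - y), theta0,
            bounds=([-np.inf, 1e-3, -np.inf, -np.inf], [np.inf, 1.5, np.inf, np.inf]),
            method="trf", ftol=1e-14, xtol=1e-14, gtol=1e-14, max_nfev=self.max_nfev,
        )
        k, beta = float(np.exp(res.x[0])), float(res.x[1])
        tpos = t[t > 0]
        decades = np.log10(tpos.max() / tpos.min()) if tpos.size >= 2 else 0.0
        if beta < 0.5 and (t.size < 8 or decades < 2.0):
            warnings.warn(
                f"beta={beta:.3g} < 0.5 fitted from {t.size} points over "
                f"{decades:.2g} decades of time; need >= 8 points over >= 2 decades"
            )
        self.residuals_ = (res.fun / w)
        rms = float(np.sqrt(np.mean(self.residuals_**2)))
        self.fit_ = StretchedExpFit(
            k=k, beta=beta, amplitude=float(res.x[2]), offset=float(res.x[3]),
            rms=rms, converged=bool(res.status > 0), decaying=decaying,
        )
        self.k_, self.beta_ = k, beta
        self.amplitude_, self.offset_ = float(res.x[2]), float(res.x[3])
        return self

    def predict(self, t):
        return self.fit_(t)


def fit_stretched_exponential(trace, init: dict | None = None) -> StretchedExpFit:
    """Fit offset + A exp(-(kt)^beta) to a trace or survival curve."""
    return StretchedExponentialEstimator(init=init).fit(trace).fit_
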