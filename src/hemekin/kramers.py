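"""Kramers high-friction rate law with additive internal friction.

Conformational dynamics of a protein are damped both by the solvent
(viscosity eta) and by internal atom-atom collisions, modeled as an
additive internal-friction viscosity sigma:

    k(eta) = C / (sigma + eta) * exp(-E_0 / k_B T).

At high solvent viscosity the rate falls off as 1/eta (Kramers
high-friction limit); at low viscosity it plateaus at the
internal-friction-dominated value C/sigma * exp(-E_0 / k_B T). C has
units of rate x viscosity (s^-1 cP), a documented convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .constants import Conditions


@dataclass(frozen=True)
class KramersParams:
    """Parameters of the internal-friction Kramers law.

    C : scale constant, s^-1 cP (> 0); sigma : internal-friction
    viscosity, cP (>= 0); E_0 : activation energy, kJ/mol; cond :
    temperature (enters only the fixed exponential factor).
    """

    C: float
    sigma: float
    E_0: float = 0.0
    cond: Conditions = field(default_factory=lambda: Conditions(T=293.15))

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ValueError(f"C must be positive, got {self.C}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


def kramers_rate(eta, params: KramersParams):
    """k = C/(sigma + eta) exp(-E_0/k_B T); strictly decreasing in eta."""
    eta = np.asarray(eta, dtype=float)
    if np.any(eta < 0):
        raise ValueError("viscosity must be >= 0")
    denom = params.sigma + eta
    if np.any(denom == 0):
        raise ValueError("sigma + eta must be positive")
    return params.C / denom * np.exp(-params.E_0 / params.cond.thermal_energy)


class KramersEstimator(BaseEstimator):
    """Log-space least-squares fit of rate-vs-viscosity data.

    Fits log k = log C_eff - log(sigma + eta) with C_eff = C exp(-E_0 /
    k_B T); a single-temperature dataset cannot separate C from E_0, so
    E_0 is a fixed input (default 0, making C = C_eff). Positivity is
    enforced by log parameterization.

    Identifiability of sigma requires data in both the plateau
    (eta <~ sigma) and the 1/eta regimes: a dataset spanning less than
    a decade of viscosity, or whose smallest viscosity exceeds ~10x the
    fitted sigma, is flagged via ``sigma_identifiable_`` and a warning.

    Attributes
    ----------
    params_ : KramersParams
    stderr_ : dict with keys "C", "sigma" (linear scale)
    sigma_identifiable_ : bool
    residuals_ : ndarray (log-space)
    converged_ : bool
    """

    def __init__(self, E_0=0.0, T=293.15, init=None, max_nfev=5000):
        self.E_0 = E_0
        self.T = T
        self.init = init
        self.max_nfev = max_nfev

    def fit(self, eta, k=None, sd=None):
        eta = np.asarray(eta, dtype=float)
        k = np.asarray(k, dtype=float)
        if eta.size < 3:
            raise ValueError("need >= 3 points (plateau and 1/eta regimes)")
        if np.any(eta < 0) or np.any(k <= 0):
            raise ValueError("viscosities must be >= 0 and rates > 0")
        span = eta[eta > 0].max() / eta[eta > 0].min()
        if span < 10:
            warnings.warn(
                f"viscosity range spans only {np.log10(span):.2g} decades; "
                "sigma is unlikely to be identifiable"
            )
        init = {"C_eff": float(np.median(k * (eta + np.median(eta)))),
                "sigma": float(np.median(eta))}
        if self.init:
            init.update(self.init)
        theta0 = np.log([init["C_eff"], max(init["sigma"], 1e-6)])

        logk = np.log(k)

        def resid(theta):
            return theta[0] - np.log(np.exp(theta[1]) + eta) - logk

        res = least_squares(resid, theta0, method="trf", ftol=1e-14, xtol=1e-14,
                            gtol=1e-14, max_nfev=self.max_nfev)
        c_eff, sigma = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
        cond = Conditions(T=self.T)
        C = c_eff * np.exp(self.E_0 / cond.thermal_energy)
        self.params_ = KramersParams(C=C, sigma=sigma, E_0=self.E_0, cond=cond)
        self.residuals_ = res.fun
        dof = max(eta.size - 2, 1)
        s2 = 2.0 * res.cost / dof
        cov = s2 * np.linalg.pinv(res.jac.T @ res.jac)
        se_log = np.sqrt(np.clip(np.diag(cov), 0, None))
        self.stderr_ = {"C": C * se_log[0], "sigma": sigma * se_log[1]}
        self.converged_ = bool(res.status > 0)
        min_eta = float(eta.min())
        self.sigma_identifiable_ = bool(
            span >= 10 and min_eta <= 10.0 * sigma and se_log[1] < 1.0
        )
        if not self.sigma_identifiable_:
            warnings.warn(
                f"sigma={sigma:.3g} cP flagged unidentifiable: data start at "
                f"eta={min_eta:.3g} cP with relative error {se_log[1]:.2g}; the "
                "plateau regime (eta <~ sigma) is not covered"
            )
        return self

    def predict(self, eta):
        return kramers_rate(np.asarray(eta, dtype=float), self.params_)


def fit_kramers(eta, k, fixed_T: float = 293.15, E_0: float = 0.0,
                init: dict | None = None) -> KramersEstimator:
    """Fit the additive internal-friction law to rate-vs-viscosity data.

    Returns the fitted :class:`KramersEstimator` with ``params_``,
    ``stderr_`` and the ``sigma_identifiable_`` flag.
    """
    return KramersEstimator(E_0=E_0, T=fixed_T, init=init).fit(eta, k)
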