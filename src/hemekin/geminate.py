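"""Distributed-rate geminate rebinding kinetics.

In a rigid (glassy) solvent, protein conformational substates cannot
interconvert, so each substate i rebinds its photodissociated ligand
with its own Arrhenius rate k(H_i) = A exp(-H_i / k_B T), and the
ensemble survival probability is the weighted sum

    N(t) = sum_i g(H_i) exp(-k(H_i) t),

where g(H) is the distribution of activation enthalpies over substates.
This module provides that forward model, its initial rate
|dN/dt|_{t->0} = sum_i g_i k_i, joint multi-temperature inference of
g(H) (one distribution shared across all temperatures), regularized /
maximum-entropy inversion of a survival curve into a rate distribution,
and first-order kinetic schemes (matrix-exponential propagation and
geminate-yield branching), including the canonical room-temperature
two-geminate-state topology.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import least_squares, minimize, nnls
from sklearn.base import BaseEstimator

from .constants import Conditions


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass
class EnthalpyDistribution:
    """Discrete activation-enthalpy distribution of conformational substates.

    H is a strictly increasing grid of activation enthalpies (kJ/mol),
    g the corresponding weights (non-negative, summing to 1), and A the
    Arrhenius prefactor (s^-1) shared by all substates.
    """

    H: np.ndarray
    g: np.ndarray
    A: float

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.H.size == 0:
            raise ValueError("empty enthalpy distribution")
        if self.H.shape != self.g.shape:
            raise ValueError("H and g must have the same shape")
        if self.H.size > 1 and np.any(np.diff(self.H) <= 0):
            raise ValueError("H must be strictly increasing")
        if np.any(self.g < 0):
            raise ValueError("weights must be >= 0")
        if abs(float(self.g.sum()) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {self.g.sum()}")
        if not self.A > 0:
            raise ValueError(f"Arrhenius prefactor must be positive, got {self.A}")

    def rates(self, cond: Conditions) -> np.ndarray:
        """Substate rates k(H_i) = A exp(-H_i / k_B T) in s^-1."""
        return self.A * np.exp(-self.H / cond.thermal_energy)

    def mean(self) -> float:
        return float(np.sum(self.g * self.H))

    def std(self) -> float:
        mu = self.mean()
        return float(np.sqrt(np.sum(self.g * (self.H - mu) ** 2)))

    @classmethod
    def gaussian(cls, mean, sd, A, h_min=None, h_max=None, n_bins=32):
        """Discretized Gaussian g(H) on a linear grid (weights renormalized)."""
        if h_min is None:
            h_min = mean - 5.0 * sd
        if h_max is None:
            h_max = mean + 5.0 * sd
        H = np.linspace(h_min, h_max, n_bins)
        w = np.exp(-0.5 * ((H - mean) / sd) ** 2)
        return cls(H=H, g=w / w.sum(), A=A)


@dataclass
class SurvivalCurve:
    """Survival probability N(t) of the unliganded state after photolysis."""

    t: np.ndarray
    N: np.ndarray
    sd: np.ndarray | None = None
    temperature: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.N = np.asarray(self.N, dtype=float)
        if self.t.shape != self.N.shape:
            raise ValueError("t and N must have the same shape")
        if np.any(self.t < 0):
            raise ValueError("times must be >= 0")
        if self.t.size > 1 and np.any(np.diff(self.t) < 0):
            raise ValueError("times must be ascending")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)


@dataclass
class RateDistribution:
    """Weights w_j on a log-spaced rate grid k_j (s^-1)."""

    k: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.k.shape != self.w.shape:
            raise ValueError("k and w must have the same shape")
        if np.any(self.k <= 0):
            raise ValueError("rates must be positive")
        if np.any(self.w < -1e-12):
            raise ValueError("weights must be >= 0")


# --------------------------------------------------------------------------
# forward model
# --------------------------------------------------------------------------


def survival_distributed(t, dist: EnthalpyDistribution, cond: Conditions) -> SurvivalCurve:
    """Multi-exponential survival N(t) = sum_i g_i exp(-k(H_i) t).

    N(0) = 1 and N is non-increasing and completely monotone for any
    normalized non-negative g.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    k = dist.rates(cond)
    N = np.exp(-np.outer(t, k)) @ dist.g
    return SurvivalCurve(t=t, N=N, temperature=cond.T)


def initial_rate(dist: EnthalpyDistribution, cond: Conditions) -> float:
    """Magnitude of the initial slope |dN/dt|_{t->0} = sum_i g_i k(H_i)."""
    return float(np.sum(dist.g * dist.rates(cond)))


# --------------------------------------------------------------------------
# enthalpy-distribution fitting (shared g across temperatures)
# --------------------------------------------------------------------------


class EnthalpyDistributionEstimator(BaseEstimator):
    """Joint fit of one enthalpy distribution to multi-temperature curves.

    A single non-negative normalized g(H) on a fixed linear grid (and a
    single Arrhenius prefactor A) must reproduce the survival curves at
    every temperature simultaneously — the physical constraint that the
    substate distribution is frozen in the glass while the rates shift
    with T. Non-negativity and normalization of g are enforced exactly
    through a softmax parameterization; a second-difference penalty
    (weight ``reg``) regularizes the ill-posed inversion.

    Parameters
    ----------
    h_min, h_max : float
        Bounds of the linear enthalpy grid, kJ/mol.
    n_bins : int
        Number of substate bins (default 32). Must be >= 2.
    A : float or None
        Arrhenius prefactor in s^-1; None lets the fit determine it
        (recommended only with well-separated temperatures).
    log10_A_init : float
        Initial guess for log10 A when A is free.
    reg : float
        Smoothness-penalty weight on second differences of g.

    Attributes
    ----------
    distribution_ : EnthalpyDistribution
    residuals_ : list of ndarray (per input curve)
    converged_ : bool
    message_ : str
    """

    def __init__(self, h_min=0.0, h_max=30.0, n_bins=32, A=None, log10_A_init=9.0, reg=1e-3):
        self.h_min = h_min
        self.h_max = h_max
        self.n_bins = n_bins
        self.A = A
        self.log10_A_init = log10_A_init
        self.reg = reg

    def fit(self, curves, y=None):
        """Fit to a sequence of SurvivalCurve objects carrying temperatures."""
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        curves = list(curves)
        if not curves:
            raise ValueError("need at least one survival curve")
        for c in curves:
            if c.temperature is None:
                raise ValueError("every curve must carry a temperature")
        H = np.linspace(self.h_min, self.h_max, self.n_bins)
        free_A = self.A is None
        n_u = self.n_bins + (1 if free_A else 0)

        def unpack(theta):
            u = theta[: self.n_bins]
            g = np.exp(u - u.max())
            g /= g.sum()
            A = 10.0 ** theta[-1] if free_A else self.A
            return g, A

        d2 = np.diff(np.eye(self.n_bins), n=2, axis=0)  # second-difference operator

        def resid(theta):
            g, A = unpack(theta)
            parts = []
            for c in curves:
                k = A * np.exp(-H / (Conditions(c.temperature).thermal_energy))
                model = np.exp(-np.outer(c.t, k)) @ g
                w = 1.0 / c.sd if c.sd is not None else 1.0
                parts.append(w * (model - c.N))
            parts.append(np.sqrt(self.reg) * (d2 @ g))
            return np.concatenate(parts)

        theta0 = np.zeros(n_u)
        if free_A:
            theta0[-1] = self.log10_A_init
        res = least_squares(resid, theta0, method="trf", ftol=1e-12, xtol=1e-12,
                            gtol=1e-12, max_nfev=20000)
        g, A = unpack(res.x)
        self.distribution_ = EnthalpyDistribution(H=H, g=g, A=A)
        self.residuals_ = []
        i = 0
        for c in curves:
            self.residuals_.append(res.fun[i : i + c.t.size] * (c.sd if c.sd is not None else 1.0))
            i += c.t.size
        self.converged_ = bool(res.status > 0)
        self.message_ = res.message
        if not self.converged_:
            warnings.warn(f"enthalpy-distribution fit did not converge: {res.message}")
        return self

    def predict(self, t, T):
        """Model survival curve at times t and temperature T."""
        return survival_distributed(t, self.distribution_, Conditions(T)).N


def fit_enthalpy_distribution(
    curves, n_bins: int = 32, A: float | None = None,
    h_min: float = 0.0, h_max: float = 30.0, reg: float = 1e-3,
) -> EnthalpyDistributionEstimator:
    """Fit one activation-enthalpy distribution to multi-temperature curves.

    Thin wrapper over :class:`EnthalpyDistributionEstimator`; see its
    docstring. Returns the fitted estimator.
    """
    return EnthalpyDistributionEstimator(
        h_min=h_min, h_max=h_max, n_bins=n_bins, A=A, reg=reg
    ).fit(curves)


# --------------------------------------------------------------------------
# rate-distribution inversion (inverse Laplace transform of the decay)
# --------------------------------------------------------------------------


def default_rate_grid(t: np.ndarray, per_decade: int = 20) -> np.ndarray:
    """Log-spaced rate grid spanning the reciprocals of the time window."""
    t = np.asarray(t, dtype=float)
    tpos = t[t > 0]
    # rates above ~2/t_min decay entirely before the first sample and are
    # unconstrained by the data, so the grid stops there
    k_lo, k_hi = 0.1 / tpos.max(), 2.0 / tpos.min()
    n = max(int(per_decade * math.log10(k_hi / k_lo)) + 1, 10)
    return np.logspace(math.log10(k_lo), math.log10(k_hi), n)


class RateDistributionEstimator(BaseEstimator):
    """Invert a decay curve into a non-negative rate distribution.

    Solves N(t_i) ~ sum_j w_j exp(-k_j t_i) for w >= 0 on a log-spaced
    rate grid, either by ridge-regularized non-negative least squares
    (``method="ridge"``) or by maximum entropy (``method="maxent"``),
    which maximizes the Skilling entropy S(w; m) = sum_j [w_j - m_j -
    w_j log(w_j/m_j)] relative to a flat prior m subject to a
    chi-square target (chi^2 per point = ``chi2_target``); the entropy
    weight is found by bisection. The inversion is ill-posed: an
    effective-rank diagnostic of the kernel is always reported.

    Attributes
    ----------
    distribution_ : RateDistribution
    chi2_per_point_ : float
    effective_rank_ : int
    ill_posed_ : bool  (effective rank < number of grid points; always
        true in practice — exposed so callers cannot miss it)
    """

    def __init__(self, method="maxent", grid=None, per_decade=20, lam=1e-3,
                 chi2_target=1.0, prior=None):
        self.method = method
        self.grid = grid
        self.per_decade = per_decade
        self.lam = lam
        self.chi2_target = chi2_target
        self.prior = prior

    def fit(self, t, N=None, sd=None):
        if isinstance(t, SurvivalCurve):
            curve = t
            t, N, sd = curve.t, curve.N, curve.sd if sd is None else sd
        t = np.asarray(t, dtype=float)
        N = np.asarray(N, dtype=float)
        if np.any(N < -1e-6) or np.any(N > 1 + 1e-6):
            raise ValueError("N must lie in [0, 1]")
        k = np.asarray(self.grid, dtype=float) if self.grid is not None else default_rate_grid(
            t, self.per_decade
        )
        K = np.exp(-np.outer(t, k))
        sd_arr = np.asarray(sd, dtype=float) * np.ones_like(N) if sd is not None else np.full_like(
            N, 1e-2
        )
        m = (np.asarray(self.prior, dtype=float) if self.prior is not None
             else np.full(k.size, 1.0 / k.size))

        sv = np.linalg.svd(K / sd_arr[:, None], compute_uv=False)
        self.effective_rank_ = int(np.sum(sv > sv[0] * 1e-8))
        self.ill_posed_ = self.effective_rank_ < k.size
        if self.ill_posed_:
            warnings.warn(
                f"rate-distribution inversion is ill-posed: effective rank "
                f"{self.effective_rank_} < {k.size} grid points; the result is "
                "regularization-dependent"
            )

        if np.all(~np.isfinite(1.0 / sd_arr)) or np.all(sd_arr == np.inf):
            w = m.copy()  # zero data weight: entropy/ridge optimum is the prior
        elif self.method == "ridge":
            Kw = K / sd_arr[:, None]
            A_aug = np.vstack([Kw, np.sqrt(self.lam) * np.eye(k.size)])
            b_aug = np.concatenate([N / sd_arr, np.zeros(k.size)])
            w, _ = nnls(A_aug, b_aug)
        elif self.method == "maxent":
            w = self._maxent(K, N, sd_arr, m)
        else:
            raise ValueError(f"unknown method {self.method!r}")

        self.distribution_ = RateDistribution(k=k, w=np.clip(w, 0, None))
        r = (K @ w - N) / sd_arr
        self.chi2_per_point_ = float(np.mean(r**2))
        return self

    def _maxent(self, K, N, sd, m):
        Kw = K / sd[:, None]
        Nw = N / sd

        def solve(alpha):
            def fg(u):
                w = np.exp(u)
                r = Kw @ w - Nw
                # objective: 0.5 chi^2 - alpha * S(w; m)
                S = np.sum(w - m - w * (u - np.log(m)))
                f = 0.5 * np.dot(r, r) - alpha * S
                grad_w = Kw.T @ r + alpha * (u - np.log(m))
                return f, grad_w * w  # chain rule d/du

            res = minimize(fg, np.log(m), jac=True, method="L-BFGS-B",
                           options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
            return np.exp(res.x)

        # bisect log(alpha) to hit chi^2 per point ~ chi2_target
        n = N.size

        def chi2(w):
            r = Kw @ w - Nw
            return np.dot(r, r) / n

        lo, hi = -12.0, 12.0
        w_hi = solve(10.0**hi)
        if chi2(w_hi) < self.chi2_target:  # even the prior fits: keep it
            return w_hi
        w_lo = solve(10.0**lo)
        if chi2(w_lo) > self.chi2_target:  # cannot reach target; least-biased best fit
            return w_lo
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            w_mid = solve(10.0**mid)
            if chi2(w_mid) > self.chi2_target:
                hi = mid
            else:
                lo = mid
        return solve(10.0 ** (0.5 * (lo + hi)))


def invert_rate_distribution(
    curve: SurvivalCurve,
    grid: np.ndarray | None = None,
    method: str = "maxent",
    sd=None,
    **kw,
) -> RateDistributionEstimator:
    """Invert a survival curve into a rate distribution (fitted estimator)."""
    return RateDistributionEstimator(method=method, grid=grid, **kw).fit(curve, sd=sd)


# --------------------------------------------------------------------------
# kinetic schemes
# --------------------------------------------------------------------------


@dataclass
class KineticScheme:
    """Labeled first-order state network.

    rates maps (from_state, to_state) -> rate constant (s^-1, >= 0).
    The generator matrix Q has Q[j, i] = rate i->j for i != j and
    diagonal equal to minus the total outflow, so columns sum to zero
    and populations are conserved in closed schemes. States flagged
    absorbing must have no outgoing edges.
    """

    states: list[str]
    rates: dict[tuple[str, str], float]
    initial: dict[str, float]
    absorbing: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        idx = {s: i for i, s in enumerate(self.states)}
        if len(idx) != len(self.states):
            raise ValueError("duplicate state labels")
        for (a, b), r in self.rates.items():
            if a not in idx or b not in idx:
                raise ValueError(f"rate references unknown state: {(a, b)}")
            if a == b:
                raise ValueError(f"self-edge {a}->{a} not allowed")
            if r < 0:
                raise ValueError(f"negative rate {r} on edge {a}->{b}")
            if a in self.absorbing and r > 0:
                raise ValueError(f"absorbing state {a!r} has outgoing rate")
        for s in self.initial:
            if s not in idx:
                raise ValueError(f"initial population on unknown state {s!r}")

    def rate_matrix(self) -> np.ndarray:
        n = len(self.states)
        idx = {s: i for i, s in enumerate(self.states)}
        Q = np.zeros((n, n))
        for (a, b), r in self.rates.items():
            Q[idx[b], idx[a]] += r
        Q -= np.diag(Q.sum(axis=0))
        return Q

    def initial_vector(self) -> np.ndarray:
        p0 = np.zeros(len(self.states))
        idx = {s: i for i, s in enumerate(self.states)}
        for s, v in self.initial.items():
            p0[idx[s]] = v
        return p0


def scheme_solve(scheme: KineticScheme, t) -> pd.DataFrame:
    """Per-state populations p(t) = expm(Q t) p0 at each requested time.

    Populations remain non-negative and, for closed schemes, sum to the
    initial total at every time.
    """
    t = np.asarray(t, dtype=float)
    Q = scheme.rate_matrix()
    p0 = scheme.initial_vector()
    out = np.empty((t.size, len(scheme.states)))
    # eigendecomposition when diagonalizable; expm fallback otherwise
    lam, V = np.linalg.eig(Q)
    try:
        Vinv = np.linalg.inv(V)
        cond_ok = np.linalg.cond(V) < 1e10
    except np.linalg.LinAlgError:
        cond_ok = False
    if cond_ok:
        c = Vinv @ p0
        out[:] = np.real((np.exp(np.outer(t, lam)) * c) @ V.T)
    else:
        for i, ti in enumerate(t):
            out[i] = expm(Q * ti) @ p0
    out = np.clip(out, 0.0, None)
    return pd.DataFrame(out, index=pd.Index(t, name="time_s"), columns=scheme.states)


def geminate_yield(scheme: KineticScheme, bound: str = "bound", escaped: str = "solvent") -> float:
    """Probability of absorbing into the bound state rather than escaping.

    Computed by a linear solve on the transient block of the generator:
    yield = r_bound^T (-Q_TT)^-1 p0_T + p0_bound, where r_bound is the
    row of rates from transient states into the bound state. Requires
    both named states to be absorbing.
    """
    for s in (bound, escaped):
        if s not in scheme.states:
            raise ValueError(f"state {s!r} not in scheme")
        if s not in scheme.absorbing:
            raise ValueError(f"state {s!r} must be absorbing")
    idx = {s: i for i, s in enumerate(scheme.states)}
    Q = scheme.rate_matrix()
    p0 = scheme.initial_vector()
    transient = [i for s, i in idx.items() if s not in scheme.absorbing]
    if not transient:
        return float(p0[idx[bound]])
    Qtt = Q[np.ix_(transient, transient)]
    r_b = Q[idx[bound], transient]
    absorbed = r_b @ np.linalg.solve(-Qtt, p0[transient])
    return float(absorbed + p0[idx[bound]])


def two_geminate_scheme(
    k_bind_fast: float = 5e7,
    k_bind_slow: float = 2e4,
    k_12: float = 1e7,
    k_21: float = 1e7,
    k_escape: float = 1e6,
    k_relax: float = 1e6,
    relax_gates: str = "both",
) -> KineticScheme:
    """Room-temperature CO rebinding topology with two geminate states.

    The photodissociated ligand starts in the primary geminate site of
    the unrelaxed protein (gem1_star); it can rebind (-> bound), hop to
    a secondary internal site (gem1 <-> gem2), or escape to solvent
    from the secondary site. In parallel the protein relaxes from the
    unrelaxed (starred) to the relaxed conformational-substate
    distribution, which rebinds much more slowly (k_bind_slow).
    ``relax_gates`` selects whether the conformational relaxation edge
    acts on both geminate states or only the first (the topology is
    left open).

    The default rate constants are placeholders illustrating the
    topology, not measured values; supply your own for quantitative
    work.
    """
    states = ["bound", "gem1_star", "gem2_star", "gem1", "gem2", "solvent"]
    rates = {
        ("gem1_star", "bound"): k_bind_fast,
        ("gem1", "bound"): k_bind_slow,
        ("gem1_star", "gem2_star"): k_12,
        ("gem2_star", "gem1_star"): k_21,
        ("gem1", "gem2"): k_12,
        ("gem2", "gem1"): k_21,
        ("gem2_star", "solvent"): k_escape,
        ("gem2", "solvent"): k_escape,
        ("gem1_star", "gem1"): k_relax,
    }
    if relax_gates == "both":
        rates[("gem2_star", "gem2")] = k_relax
    elif relax_gates != "first":
        raise ValueError("relax_gates must be 'both' or 'first'")
    return KineticScheme(
        states=states,
        rates=rates,
        initial={"gem1_star": 1.0},
        absorbing=frozenset({"bound", "solvent"}),
    )
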