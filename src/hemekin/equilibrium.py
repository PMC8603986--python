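"""Equilibrium allosteric models for cooperative ligand binding.

Implements the two classical two-state descriptions of hemoglobin
cooperativity:

* the concerted quaternary two-state (MWC) model, with partition
  function  Xi = L (1 + K_T p)^n + (1 + K_R p)^n, and
* the tertiary two-state (TTS) extension, in which each of the n
  subunits of either quaternary structure can occupy a low-affinity (t)
  or high-affinity (r) tertiary conformation:

      Xi = (L / l_T^n) [1 + K_r p + l_T (1 + K_t p)]^n
           + [1 + K_r p + l_R (1 + K_t p)]^n

Both partition functions are sums of two terms of the form
c (alpha + beta p)^n, which this module exploits: the saturation curve
y(p) = (1/n) dlnXi/dlnp, its complement 1 - y, and the pointwise Hill
slope d log(y/(1-y)) / d log p all have closed forms in (c, alpha,
beta) that stay numerically stable from y ~ 0 to y ~ 1.

Fitting binding curves is exposed both as an sklearn-style estimator
(:class:`BindingModelEstimator`) and as the thin :func:`fit_binding`
wrapper.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize_scalar
from sklearn.base import BaseEstimator


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MWCParams:
    """Parameters of the concerted (quaternary two-state) model.

    Parameters
    ----------
    L : float
        Allosteric constant, the unliganded T/R population ratio
        [T0]/[R0]. Dimensionless, >= 0.
    K_T, K_R : float
        Ligand association constants of the T and R quaternary
        structures, per pressure unit (torr^-1 by default). >= 0.
    n_subunits : int
        Number of equivalent binding sites (4 for hemoglobin).
    pressure_unit : str
        Label carried through outputs; never converted.
    """

    L: float
    K_T: float
    K_R: float
    n_subunits: int = 4
    pressure_unit: str = "torr"

    def __post_init__(self) -> None:
        for name in ("L", "K_T", "K_R"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if int(self.n_subunits) != self.n_subunits or self.n_subunits < 1:
            raise ValueError(f"n_subunits must be an integer >= 1, got {self.n_subunits}")

    def _terms(self) -> list[tuple[float, float, float]]:
        """(c, alpha, beta) for each conformational term c*(alpha+beta*p)^n."""
        return [(self.L, 1.0, self.K_T), (1.0, 1.0, self.K_R)]

    def affinities(self) -> tuple[float, ...]:
        return (self.K_T, self.K_R)


@dataclass(frozen=True)
class TTSParams:
    """Parameters of the tertiary two-state model.

    L is the T/R population ratio between the all-t T and all-r R
    reference states; l_T and l_R are the t/r population ratios of
    unliganded subunits within T and R; K_t and K_r are the ligand
    affinities of the t and r tertiary conformations (torr^-1).
    Allosteric effectors are modeled as alternative (L, l_T, l_R)
    parameter sets, not as explicit binding polynomials.
    """

    L: float
    l_T: float
    l_R: float
    K_t: float
    K_r: float
    n_subunits: int = 4
    pressure_unit: str = "torr"

    def __post_init__(self) -> None:
        for name in ("L", "l_T", "l_R", "K_t", "K_r"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.l_T == 0:
            raise ValueError("l_T must be > 0 (appears as divisor L/l_T^n)")
        if int(self.n_subunits) != self.n_subunits or self.n_subunits < 1:
            raise ValueError(f"n_subunits must be an integer >= 1, got {self.n_subunits}")

    def _terms(self) -> list[tuple[float, float, float]]:
        n = self.n_subunits
        c_T = self.L / self.l_T**n
        return [
            (c_T, 1.0 + self.l_T, self.K_r + self.l_T * self.K_t),
            (1.0, 1.0 + self.l_R, self.K_r + self.l_R * self.K_t),
        ]

    def affinities(self) -> tuple[float, ...]:
        return (self.K_t, self.K_r)


BindingModel = MWCParams | TTSParams


@dataclass
class BindingCurve:
    """A ligand binding isotherm: pressures p and fractional saturation y."""

    p: np.ndarray
    y: np.ndarray
    sd: np.ndarray | None = None
    pressure_unit: str = "torr"

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.p.shape != self.y.shape:
            raise ValueError("p and y must have the same shape")
        if np.any(self.p < 0):
            raise ValueError("pressures must be >= 0")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.p.shape:
                raise ValueError("sd must match p in shape")


@dataclass(frozen=True)
class SpeciesClass:
    """One symmetry class of the partition function.

    Classes are keyed by counts (subunits are equivalent):
    (quaternary, number liganded) for MWC, plus the number of r-state
    subunits for TTS. The Boltzmann weight is the multinomial-collected
    coefficient times p^n_liganded; weights over all classes sum to the
    partition function.
    """

    quaternary: Literal["T", "R"]
    n_liganded: int
    n_r_subunits: int | None
    boltzmann_weight: float


# --------------------------------------------------------------------------
# partition functions and saturation
# --------------------------------------------------------------------------


def _check_pressure(p: np.ndarray | float) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p < 0):
        raise ValueError("pressure must be finite and >= 0")
    return p


def mwc_partition(p, params: MWCParams):
    """MWC partition function  L (1 + K_T p)^n + (1 + K_R p)^n."""
    p = _check_pressure(p)
    n = params.n_subunits
    return params.L * (1.0 + params.K_T * p) ** n + (1.0 + params.K_R * p) ** n


def tts_partition(p, params: TTSParams):
    """TTS partition function.

    (L/l_T^n)[1 + K_r p + l_T(1 + K_t p)]^n + [1 + K_r p + l_R(1 + K_t p)]^n
    """
    p = _check_pressure(p)
    n = params.n_subunits
    b_T = 1.0 + params.K_r * p + params.l_T * (1.0 + params.K_t * p)
    b_R = 1.0 + params.K_r * p + params.l_R * (1.0 + params.K_t * p)
    return (params.L / params.l_T**n) * b_T**n + b_R**n


def partition_function(p, model: BindingModel):
    """Dispatch to :func:`mwc_partition` or :func:`tts_partition`."""
    if isinstance(model, MWCParams):
        return mwc_partition(p, model)
    if isinstance(model, TTSParams):
        return tts_partition(p, model)
    raise TypeError(f"unsupported model type {type(model)!r}")


def _y_and_complement(p: np.ndarray, model: BindingModel):
    """Stable (y, 1-y) from the two-term binding polynomial.

    With Xi = sum_q c_q A_q^n, A_q = alpha_q + beta_q p:
        y      = p * sum_q c_q beta_q  A_q^(n-1) / Xi
        1 - y  =     sum_q c_q alpha_q A_q^(n-1) / Xi
    so neither suffers cancellation near saturation.
    """
    n = model.n_subunits
    u = np.zeros_like(p)
    v = np.zeros_like(p)
    xi = np.zeros_like(p)
    for c, alpha, beta in model._terms():
        if c == 0.0:
            continue
        A = alpha + beta * p
        An1 = A ** (n - 1)
        u += c * beta * An1
        v += c * alpha * An1
        xi += c * An1 * A
    return p * u / xi, v / xi


def saturation(p, model: BindingModel) -> BindingCurve:
    """Fractional saturation y(p) = (1/n) dlnXi/dlnp as a BindingCurve.

    Evaluated from the analytic derivative of the closed-form partition
    function; y(0) = 0 and y -> 1 as p -> infinity whenever a positive
    affinity is present.
    """
    p = _check_pressure(np.atleast_1d(p))
    y, _ = _y_and_complement(p, model)
    return BindingCurve(p=p, y=y, pressure_unit=getattr(model, "pressure_unit", "torr"))


def hill_slope(p, model: BindingModel):
    """Analytic pointwise Hill slope  d log(y/(1-y)) / d log p.

    For Xi = sum_q c_q A_q^n the logit of saturation is
    log p + log(sum c beta A^(n-1)) - log(sum c alpha A^(n-1)), giving

        h(p) = 1 + (n-1) p [ S(beta^2, n-2)/S(beta, n-1)
                             - S(alpha beta, n-2)/S(alpha, n-1) ]

    with S(w, m) = sum_q c_q w_q A_q^m. Exactly 1 for a single
    conformation (no cooperativity), independent of p.
    """
    p = _check_pressure(np.asarray(p, dtype=float))
    n = model.n_subunits
    if n == 1:
        return np.ones_like(p)
    sb = np.zeros_like(p)   # sum c beta A^(n-1)
    sa = np.zeros_like(p)   # sum c alpha A^(n-1)
    sbb = np.zeros_like(p)  # sum c beta^2 A^(n-2)
    sab = np.zeros_like(p)  # sum c alpha beta A^(n-2)
    for c, alpha, beta in model._terms():
        if c == 0.0:
            continue
        A = alpha + beta * p
        An2 = A ** (n - 2)
        An1 = An2 * A
        sb += c * beta * An1
        sa += c * alpha * An1
        sbb += c * beta * beta * An2
        sab += c * alpha * beta * An2
    return 1.0 + (n - 1) * p * (sbb / sb - sab / sa)


@dataclass
class HillTransform:
    """Result of the Hill transformation of a binding curve.

    log10_p and logit are log10(p) and log10(y/(1-y)) for the retained
    points; slope is the pointwise Hill slope (analytic if a model was
    attached, otherwise finite differences); n_dropped counts points
    excluded because p <= 0 or y outside (0, 1).
    """

    log10_p: np.ndarray
    logit: np.ndarray
    slope: np.ndarray
    n_dropped: int


def hill_transform(curve: BindingCurve, model: BindingModel | None = None) -> HillTransform:
    """Hill plot coordinates log10(y/(1-y)) vs log10 p.

    Points with p <= 0 or y outside the open interval (0, 1) are
    outside the domain of the logit and are dropped; the count of
    dropped points is reported. With fewer than 2 transformable points
    a ValueError is raised.
    """
    keep = (curve.p > 0) & (curve.y > 0) & (curve.y < 1)
    n_dropped = int(np.sum(~keep))
    p, y = curve.p[keep], curve.y[keep]
    if p.size < 2:
        raise ValueError(
            f"need at least 2 points with p > 0 and 0 < y < 1; got {p.size} "
            f"({n_dropped} dropped)"
        )
    log10_p = np.log10(p)
    logit = np.log10(y / (1.0 - y))
    if model is not None:
        slope = hill_slope(p, model)
    else:
        slope = np.gradient(logit, log10_p)
    return HillTransform(log10_p=log10_p, logit=logit, slope=slope, n_dropped=n_dropped)


def hill_coefficient(
    model: BindingModel,
    grid_points: int = 801,
    span_decades: float = 6.0,
    polish: bool = True,
) -> float:
    """Maximum Hill slope n_H = max_p d log(y/(1-y)) / d log p.

    The analytic slope is scanned on a log-spaced pressure grid
    spanning +/- `span_decades` decades around the reciprocal geometric
    mean of the model's (positive) affinities; the first grid maximum
    (lowest pressure on ties) is then polished by bounded scalar
    minimization. Bounded above by the subunit count.
    """
    ks = np.array([k for k in model.affinities() if k > 0], dtype=float)
    if ks.size == 0:
        raise ValueError("degenerate model: all ligand affinities are zero")
    p_mid = 1.0 / math.exp(np.mean(np.log(ks)))
    logp = np.linspace(
        math.log10(p_mid) - span_decades, math.log10(p_mid) + span_decades, grid_points
    )
    h = hill_slope(10.0**logp, model)
    i = int(np.argmax(h))  # argmax returns the first (lowest-p) maximum
    best = float(h[i])
    if polish and 0 < i < grid_points - 1:
        res = minimize_scalar(
            lambda x: -float(hill_slope(np.array([10.0**x]), model)[0]),
            bounds=(logp[i - 1], logp[i + 1]),
            method="bounded",
            options={"xatol": 1e-10},
        )
        best = max(best, -float(res.fun))
    return best


# --------------------------------------------------------------------------
# species enumeration
# --------------------------------------------------------------------------


def _tts_microclass_weights(model: TTSParams, p: float):
    """Weights of TTS classes keyed by (quaternary, n_lig, n_r, n_r_liganded).

    Per-subunit statistical factors: unliganded r -> 1, liganded r ->
    K_r p, unliganded t -> l_Q, liganded t -> l_Q K_t p, with the
    quaternary prefactor L/l_T^n for T and 1 for R.
    """
    n = model.n_subunits
    out: dict[tuple[str, int, int, int], float] = {}
    for quaternary, c, l_q in (
        ("T", model.L / model.l_T**n, model.l_T),
        ("R", 1.0, model.l_R),
    ):
        for n_r in range(n + 1):
            n_t = n - n_r
            for m in range(n + 1):
                for j in range(max(0, m - n_t), min(n_r, m) + 1):
                    count = math.comb(n, n_r) * math.comb(n_r, j) * math.comb(n_t, m - j)
                    w = (
                        c
                        * count
                        * model.K_r**j
                        * model.K_t ** (m - j)
                        * l_q**n_t
                        * p**m
                    )
                    out[(quaternary, m, n_r, j)] = w
    return out


def enumerate_species(model: BindingModel, p: float) -> list[SpeciesClass]:
    """Boltzmann weights of the symmetry-distinct terms of Xi at pressure p.

    MWC classes are keyed by (quaternary, n_liganded): 2*(n+1) = 10
    classes for n = 4. TTS classes are keyed by (quaternary,
    n_liganded, n_r_subunits): 2*(n+1)^2 = 50 classes for n = 4. The
    weights sum to the closed-form partition function at the same p.
    """
    p = float(_check_pressure(p))
    n = model.n_subunits
    classes: list[SpeciesClass] = []
    if isinstance(model, MWCParams):
        for quaternary, c, K in (("T", model.L, model.K_T), ("R", 1.0, model.K_R)):
            for m in range(n + 1):
                w = c * math.comb(n, m) * (K * p) ** m
                classes.append(SpeciesClass(quaternary, m, None, w))
        return classes
    if not isinstance(model, TTSParams):
        raise TypeError(f"unsupported model type {type(model)!r}")
    micro = _tts_microclass_weights(model, p)
    agg: dict[tuple[str, int, int], float] = {}
    for (quaternary, m, n_r, _j), w in micro.items():
        agg[(quaternary, m, n_r)] = agg.get((quaternary, m, n_r), 0.0) + w
    for quaternary in ("T", "R"):
        for m in range(n + 1):
            for n_r in range(n + 1):
                classes.append(SpeciesClass(quaternary, m, n_r, agg[(quaternary, m, n_r)]))
    return classes


def subunit_fractions(model: TTSParams, p: float):
    """Tertiary-conformation composition per (quaternary, ligation) class.

    Returns a DataFrame with, for each quaternary structure and
    ligation count: the class Boltzmann weight, the mean fraction of
    subunits in the r (and t) tertiary conformation, and the same
    fractions restricted to unliganded subunits (NaN for the fully
    liganded class). At p = 0 the t/r odds of (necessarily unliganded)
    subunits in T equal l_T, and in R equal l_R.
    """
    import pandas as pd

    p = float(_check_pressure(p))
    n = model.n_subunits
    micro = _tts_microclass_weights(model, p)
    rows = []
    for quaternary in ("T", "R"):
        for m in range(n + 1):
            w_tot = r_sub = r_unlig = 0.0
            for n_r in range(n + 1):
                for j in range(max(0, m - (n - n_r)), min(n_r, m) + 1):
                    w = micro[(quaternary, m, n_r, j)]
                    w_tot += w
                    r_sub += w * n_r
                    r_unlig += w * (n_r - j)
            if w_tot == 0.0:  # class unpopulated at this pressure (e.g. m > 0 at p = 0)
                frac_r = frac_r_unlig = float("nan")
            else:
                frac_r = r_sub / (n * w_tot)
                frac_r_unlig = r_unlig / ((n - m) * w_tot) if m < n else float("nan")
            rows.append(
                {
                    "quaternary": quaternary,
                    "n_liganded": m,
                    "weight": w_tot,
                    "frac_r": frac_r,
                    "frac_t": 1.0 - frac_r,
                    "frac_r_unliganded": frac_r_unlig,
                    "frac_t_unliganded": 1.0 - frac_r_unlig if m < n else float("nan"),
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

_PARAM_NAMES = {"mwc": ("L", "K_T", "K_R"), "tts": ("L", "l_T", "l_R", "K_t", "K_r")}


class BindingModelEstimator(BaseEstimator):
    """Weighted least-squares fit of an MWC or TTS model to a binding curve.

    Parameters are log-transformed to enforce positivity and optimized
    with trust-region reflective least squares. sklearn conventions:
    hyper-parameters in ``__init__``, data in :meth:`fit`, fitted
    results in trailing-underscore attributes.

    Parameters
    ----------
    model_kind : {"mwc", "tts"}
    n_subunits : int
    init : dict or None
        Initial parameter values by name (e.g. ``{"L": 100, "K_R": 1}``);
        unspecified parameters use data-driven heuristics.
    bounds : dict or None
        Optional (low, high) bounds per parameter, in linear space.
    max_nfev : int

    Attributes
    ----------
    params_ : MWCParams or TTSParams
    stderr_ : dict
        Approximate standard errors (linear scale, delta method).
    cov_ : ndarray
        Covariance of the log-parameters.
    residuals_ : ndarray
    converged_ : bool
    degenerate_ : bool
        True when the Jacobian at the solution is numerically rank
        deficient (unidentifiable parameters) or the fit fails to
        describe the data.
    message_ : str
    """

    def __init__(self, model_kind="mwc", n_subunits=4, init=None, bounds=None, max_nfev=5000):
        self.model_kind = model_kind
        self.n_subunits = n_subunits
        self.init = init
        self.bounds = bounds
        self.max_nfev = max_nfev

    # -- helpers -----------------------------------------------------------
    def _make_params(self, theta: np.ndarray) -> BindingModel:
        vals = dict(zip(_PARAM_NAMES[self.model_kind], np.exp(theta)))
        cls = MWCParams if self.model_kind == "mwc" else TTSParams
        return cls(n_subunits=self.n_subunits, **vals)

    def _default_init(self, p: np.ndarray, y: np.ndarray) -> dict:
        # rough half-saturation pressure for affinity scales
        order = np.argsort(p)
        p_half = float(np.interp(0.5, np.clip(y[order], 0, 1), p[order]))
        if not np.isfinite(p_half) or p_half <= 0:
            p_half = float(np.median(p[p > 0])) if np.any(p > 0) else 1.0
        if self.model_kind == "mwc":
            return {"L": 100.0, "K_T": 0.2 / p_half, "K_R": 5.0 / p_half}
        return {
            "L": 100.0,
            "l_T": 100.0,
            "l_R": 0.01,
            "K_t": 0.2 / p_half,
            "K_r": 5.0 / p_half,
        }

    # -- sklearn API -------------------------------------------------------
    def fit(self, p, y=None, sd=None):
        """Fit to pressures p and saturations y (or a BindingCurve)."""
        if isinstance(p, BindingCurve):
            curve = p
            p, y, sd = curve.p, curve.y, curve.sd if sd is None else sd
        p = np.asarray(p, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.model_kind not in _PARAM_NAMES:
            raise ValueError(f"model_kind must be 'mwc' or 'tts', got {self.model_kind!r}")
        names = _PARAM_NAMES[self.model_kind]
        if p.size < len(names):
            raise ValueError(f"need >= {len(names)} data points, got {p.size}")
        if np.any(p < 0):
            raise ValueError("pressures must be >= 0")
        if np.any(y < -0.2) or np.any(y > 1.2):
            raise ValueError("saturation values far outside [0, 1]")
        w = 1.0 / np.asarray(sd, dtype=float) if sd is not None else np.ones_like(y)

        init = self._default_init(p, y)
        if self.init:
            init.update(self.init)
        theta0 = np.log([max(init[k], 1e-12) for k in names])
        # generous but finite default box keeps exp() from overflowing when
        # the data cannot identify a parameter
        lo = np.full(len(names), np.log(1e-18))
        hi = np.full(len(names), np.log(1e18))
        if self.bounds:
            for i, k in enumerate(names):
                if k in self.bounds:
                    b_lo, b_hi = self.bounds[k]
                    lo[i] = np.log(b_lo) if b_lo > 0 else -np.inf
                    hi[i] = np.log(b_hi) if np.isfinite(b_hi) else np.inf

        def resid(theta):
            model = self._make_params(theta)
            yy, _ = _y_and_complement(p, model)
            return w * (yy - y)

        res = least_squares(
            resid, theta0, bounds=(lo, hi), method="trf",
            ftol=1e-10, xtol=1e-12, gtol=1e-12, max_nfev=self.max_nfev,
        )
        self.params_ = self._make_params(res.x)
        self.residuals_ = res.fun / w
        m, k = res.fun.size, len(names)
        sv = np.linalg.svd(res.jac, compute_uv=False)
        cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
        rms = float(np.sqrt(np.mean(self.residuals_**2)))
        noise_scale = float(np.median(1.0 / w)) if sd is not None else 0.02
        self.degenerate_ = bool(cond > 1e8 or rms > max(10 * noise_scale, 0.05))
        dof = max(m - k, 1)
        s2 = 2.0 * res.cost / dof
        jtj_inv = np.linalg.pinv(res.jac.T @ res.jac)
        self.cov_ = s2 * jtj_inv
        se_log = np.sqrt(np.clip(np.diag(self.cov_), 0, None))
        vals = np.exp(res.x)
        self.stderr_ = {k_: float(v * s) for k_, v, s in zip(names, vals, se_log)}
        self.converged_ = bool(res.status > 0 and not self.degenerate_)
        self.message_ = res.message if not self.degenerate_ else (
            res.message + "; flagged degenerate (ill-conditioned or poor fit)"
        )
        self.n_features_in_ = 1
        return self

    def predict(self, p):
        """Model saturation at pressures p."""
        p = np.asarray(p, dtype=float)
        yy, _ = _y_and_complement(p, self.params_)
        return yy


def fit_binding(
    model_kind: str,
    curve: BindingCurve,
    init: dict | None = None,
    bounds: dict | None = None,
) -> BindingModelEstimator:
    """Fit an MWC or TTS model to a binding curve.

    Returns the fitted :class:`BindingModelEstimator`, whose ``params_``,
    ``cov_``, ``stderr_``, ``residuals_`` and ``converged_`` attributes
    carry the results. Non-convergence and parameter degeneracy are
    flagged, never silent.
    """
    return BindingModelEstimator(model_kind=model_kind, init=init, bounds=bounds).fit(curve)
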