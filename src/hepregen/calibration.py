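"""Fitting the model to mass-recovery data; cross-species and disease tools.

The calibration surface is deliberately small: published regeneration
profiles are fractional-mass-recovery time series, and the model is fitted
by minimizing the sum of squared errors between the simulated mass fraction
(interpolated to the data times) and the data.  Species translation uses
two physiological parameters (metabolic demand M and cell growth rate G)
plus a proportional rescaling of the apoptosis threshold; disease scenarios
free documented subsets of the non-parenchymal or hepatocyte-response
parameters.  Model comparison uses a Gaussian likelihood-ratio test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import SimulationError, simulate
from .parameters import ModelParameters

__all__ = [
    "MassRecoverySeries",
    "FitResult",
    "HypothesisSpec",
    "HYPOTHESES",
    "NONPARENCHYMAL_SET",
    "HEPATOCYTE_RESPONSE_SET",
    "fit",
    "disease_fit",
    "scale_theta_ap",
    "demand_from_mass",
    "fit_power_law",
    "gaussian_loglikelihood",
    "llr_test",
    "simulate_hypothesis",
]

#: demand--body-mass allometric law (demand = a * mass^b)
ALLOMETRIC_COEFFICIENT = 47.315
ALLOMETRIC_EXPONENT = -0.1825

#: printed hepatocyte mass growth rates [doublings/min]
G_RAT = 3.5e-4
G_MOUSE = 9.7e-4
#: human growth rate constrained to the rat/mouse mean
G_HUMAN = 0.5 * (G_RAT + G_MOUSE)

#: free-parameter subsets for disease fitting
NONPARENCHYMAL_SET = (
    "M", "G_rate", "k_IL6", "kappa_IL6", "k_GF", "kappa_GF",
    "k_up", "kappa_deg", "kappa_ECM",
)
HEPATOCYTE_RESPONSE_SET = (
    "k_QP", "k_PR", "k_RQ", "k_prol", "k_req", "k_ap",
    "V_JAK", "Km_JAK", "kappa_JAK", "V_STAT3", "Km_STAT3",
    "V_IE", "Km_IE", "kappa_IE",
)


@dataclass
class MassRecoverySeries:
    """Fractional mass-recovery data (times in hours, recovery of pre-PHx mass)."""

    times: np.ndarray
    recovery: np.ndarray
    sd: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.recovery = np.asarray(self.recovery, float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, float)
        if self.times.ndim != 1 or self.times.size == 0:
            raise ValueError("times must be a non-empty 1-d array")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be ascending")
        if self.recovery.shape != self.times.shape:
            raise ValueError("recovery and times must have equal length")
        if np.any(self.recovery <= 0):
            raise ValueError("recovery values must be positive")

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        d = {"time_h": self.times, "recovery_fraction": self.recovery}
        if self.sd is not None:
            d["sd"] = self.sd
        return pd.DataFrame(d)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label: str = "") -> "MassRecoverySeries":
        df = pd.read_csv(path)
        return cls(times=df["time_h"].to_numpy(),
                   recovery=df["recovery_fraction"].to_numpy(),
                   sd=df["sd"].to_numpy() if "sd" in df else None,
                   label=label or str(path))


@dataclass
class FitResult:
    """Outcome of an SSE minimization over a free-parameter subset."""

    estimates: dict[str, float]
    fixed: ModelParameters
    sse: float
    residuals: np.ndarray
    log_likelihood: float
    converged: bool
    n_starts: int = 1
    start_sses: tuple[float, ...] = ()

    @property
    def params(self) -> ModelParameters:
        """Fitted parameter object (fixed set with estimates applied)."""
        p = self.fixed.replace(**self.estimates)
        if "M" in self.estimates:
            p = p.replace(theta_ap=scale_theta_ap(
                self.fixed.theta_ap, self.estimates["M"], self.fixed.M))
        return p


def scale_theta_ap(theta_ap_ref: float, M_target: float, M_ref: float) -> float:
    """Rescale the apoptosis threshold proportionally to metabolic demand.

    Used when translating the model across species: the threshold moves
    with the demand scale so the apoptosis sigmoid keeps the same relative
    operating point.
    """
    if theta_ap_ref <= 0 or M_target <= 0 or M_ref <= 0:
        raise ValueError("all arguments must be positive")
    return theta_ap_ref * (M_target / M_ref)


def demand_from_mass(body_mass_kg: float) -> float:
    """Metabolic demand from organism body mass via the allometric law."""
    if body_mass_kg <= 0:
        raise ValueError("body mass must be positive")
    return ALLOMETRIC_COEFFICIENT * body_mass_kg ** ALLOMETRIC_EXPONENT


def fit_power_law(pairs: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Least-squares power law demand = a * mass^b on log-log axes.

    Round-trips :func:`demand_from_mass` exactly on noise-free data.
    """
    arr = np.asarray(pairs, float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (mass, demand) pairs")
    if np.any(arr <= 0):
        raise ValueError("masses and demands must be positive")
    masses, demands = arr[:, 0], arr[:, 1]
    if np.unique(masses).size < 2:
        raise ValueError("need at least two distinct masses")
    slope, intercept = np.polyfit(np.log(masses), np.log(demands), 1)
    return float(np.exp(intercept)), float(slope)


def gaussian_loglikelihood(residuals: Sequence[float]) -> float:
    """Gaussian log-likelihood of residuals at their ML mean and variance.

    l = -n/2 ln(2*pi) - n/2 ln(sigma^2) - (1/(2 sigma^2)) * sum (x - mu)^2
    with mu and sigma^2 the maximum-likelihood (divide-by-n) estimates.
    """
    x = np.asarray(residuals, float)
    n = x.size
    if n < 2:
        raise ValueError("need at least two residuals")
    mu = x.mean()
    sigma2 = np.mean((x - mu) ** 2)
    if sigma2 <= 0:
        raise ValueError("degenerate (zero-variance) residuals")
    return float(-0.5 * n * math.log(2.0 * math.pi)
                 - 0.5 * n * math.log(sigma2)
                 - 0.5 * np.sum((x - mu) ** 2) / sigma2)


def llr_test(l_restricted: float, l_unrestricted: float,
             df: int = 1) -> tuple[float, float]:
    """Likelihood-ratio statistic G^2 = 2(l_u - l_r) and chi-square p-value."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if l_unrestricted < l_restricted:
        import warnings
        warnings.warn("unrestricted log-likelihood below restricted; "
                      "check fit convergence", stacklevel=2)
    g2 = 2.0 * (l_unrestricted - l_restricted)
    p = float(stats.chi2.sf(max(g2, 0.0), df))
    return float(g2), p


# ---------------------------------------------------------------------------
# SSE fitting


def _objective(series: MassRecoverySeries, params0: ModelParameters,
               free_names: Sequence[str], horizon: float,
               rescale_theta_ap: bool, sim_kw: dict) -> callable:
    base = {name: getattr(params0, name) for name in free_names}

    def sse(values: np.ndarray) -> float:
        changes = dict(zip(free_names, values))
        if rescale_theta_ap and "M" in changes:
            changes["theta_ap"] = scale_theta_ap(
                params0.theta_ap, changes["M"], params0.M)
        try:
            p = params0.replace(**changes)
            tr = simulate(p, horizon=horizon, **sim_kw)
        except (SimulationError, ValueError):
            return 1e6
        sim = np.interp(series.times, tr.times, tr.mass_fraction)
        return float(np.sum((sim - series.recovery) ** 2))

    sse.base = base  # type: ignore[attr-defined]
    return sse


def fit(series: MassRecoverySeries,
        free_names: Sequence[str] = ("M", "G_rate"),
        bounds: Mapping[str, tuple[float, float]] | None = None,
        params0: ModelParameters | None = None,
        n_starts: int = 5,
        seed: int = 0,
        horizon: float | None = None,
        rescale_theta_ap: bool = True,
        rtol: float = 1e-6,
        atol: float = 1e-8,
        maxiter: int | None = None,
        xatol: float = 1e-4,
        fatol: float = 1e-10) -> FitResult:
    """Least-squares calibration of a free-parameter subset.

    A bounded derivative-free simplex search (log-parameterized) is run
    from the nominal start plus ``n_starts - 1`` seeded random starts
    within bounds; the best optimum is returned.  When M is free the
    apoptosis threshold is rescaled in proportion (cross-species
    convention), unless disabled.

    Residuals are simulated-minus-observed at the data times.
    """
    if params0 is None:
        params0 = ModelParameters()
    free_names = list(free_names)
    if not free_names:
        raise ValueError("free_names must not be empty")
    if len(series) < len(free_names):
        raise ValueError(
            f"need at least {len(free_names)} data points for "
            f"{len(free_names)} free parameters, got {len(series)}")
    if horizon is None:
        horizon = float(series.times[-1]) * 1.02 + 1.0
    bounds = dict(bounds or {})
    for name in free_names:
        if name not in bounds:
            base = getattr(params0, name)
            bounds[name] = (base / 10.0, base * 10.0)
        lo, hi = bounds[name]
        if lo <= 0 or hi <= lo:
            raise ValueError(f"bounds for {name} must be positive and ordered")

    sim_kw = dict(output_grid=np.unique(np.concatenate(
        [[0.0], series.times])), rtol=rtol, atol=atol)
    sse = _objective(series, params0, free_names, horizon, rescale_theta_ap,
                     sim_kw)
    lo = np.log([bounds[n][0] for n in free_names])
    hi = np.log([bounds[n][1] for n in free_names])

    def penalized(z: np.ndarray) -> float:
        zc = np.clip(z, lo, hi)
        pen = float(np.sum((z - zc) ** 2)) * 1e3
        return sse(np.exp(zc)) + pen

    rng = np.random.default_rng(seed)
    starts = [np.log([getattr(params0, n) for n in free_names])]
    starts[0] = np.clip(starts[0], lo, hi)
    for _ in range(max(n_starts - 1, 0)):
        starts.append(rng.uniform(lo, hi))

    best = None
    start_sses = []
    for z0 in starts:
        res = optimize.minimize(
            penalized, z0, method="Nelder-Mead",
            options=dict(xatol=xatol, fatol=fatol,
                         maxiter=maxiter or 300 * len(free_names)))
        start_sses.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    z = np.clip(best.x, lo, hi)
    values = np.exp(z)
    estimates = dict(zip(free_names, map(float, values)))

    changes = dict(estimates)
    if rescale_theta_ap and "M" in changes:
        changes["theta_ap"] = scale_theta_ap(params0.theta_ap, changes["M"],
                                             params0.M)
    tr = simulate(params0.replace(**changes), horizon=horizon, **sim_kw)
    sim = np.interp(series.times, tr.times, tr.mass_fraction)
    residuals = sim - series.recovery
    sse_val = float(np.sum(residuals ** 2))
    try:
        ll = gaussian_loglikelihood(residuals)
    except ValueError:
        ll = float("inf")  # perfect (zero-variance) fit
    return FitResult(estimates=estimates, fixed=params0, sse=sse_val,
                     residuals=residuals, log_likelihood=ll,
                     converged=bool(best.success), n_starts=len(starts),
                     start_sses=tuple(start_sses))


def disease_fit(series: MassRecoverySeries,
                free_name_set: str | Sequence[str] = "nonparenchymal",
                **fit_kw) -> FitResult:
    """Multistart SSE fit over a documented disease free-parameter subset.

    ``free_name_set`` may be 'nonparenchymal' (metabolic load, growth rate
    and Kupffer/stellate production-degradation rates), 'hepatocyte'
    (transition, JAK-STAT and requiescence/apoptosis parameters) or an
    explicit sequence of parameter names.
    """
    if isinstance(free_name_set, str):
        try:
            names = {"nonparenchymal": NONPARENCHYMAL_SET,
                     "hepatocyte": HEPATOCYTE_RESPONSE_SET}[free_name_set]
        except KeyError:
            raise ValueError(f"unknown free-parameter set {free_name_set!r}")
    else:
        names = tuple(free_name_set)
    if not names:
        raise ValueError("free-parameter set must not be empty")
    return fit(series, free_names=names, **fit_kw)


# ---------------------------------------------------------------------------
# alternative hypotheses for human regeneration


@dataclass(frozen=True)
class HypothesisSpec:
    """One alternative hypothesis: a named set of parameter overrides."""

    hypothesis_id: int
    description: str
    overrides: Mapping[str, float]

    def __post_init__(self) -> None:
        if not 1 <= self.hypothesis_id <= 5:
            raise ValueError("hypothesis_id must be 1..5")
        bad = [k for k in self.overrides
               if not hasattr(ModelParameters(), k)]
        if bad:
            raise ValueError(f"unknown parameter name(s) in overrides: {bad}")

    def apply(self, base: ModelParameters) -> ModelParameters:
        return base.replace(**dict(self.overrides))


#: published override sets for the five human-regeneration hypotheses
HYPOTHESES: dict[int, HypothesisSpec] = {
    1: HypothesisSpec(1, "altered cytokine response", {
        "k_IL6": 0.1435, "kappa_IL6": 0.4942,
        "V_JAK": 1.364e3, "Km_JAK": 7.565e3, "kappa_JAK": 0.0398,
        "pro_STAT3": 2.031, "V_STAT3": 1.109e3, "Km_STAT3": 0.5178,
        "kappa_SOCS3": 0.1682, "KI_SOCS3": 0.0569,
        "V_IE": 18.60, "Km_IE": 88.13, "kappa_IE": 1.148,
    }),
    2: HypothesisSpec(2, "altered GF storage and ECM balance", {
        "kappa_deg": 4.955, "kappa_ECM": 56.30,
        "k_GF": 3.288e-3, "kappa_GF": 2.139e-3, "k_up": 0.1008,
    }),
    3: HypothesisSpec(3, "altered state-transition rates", {
        "k_QP": 1.4e-3, "k_PR": 1.5e-3, "k_RQ": 70.9e-3,
    }),
    4: HypothesisSpec(4, "slower cell cycle, apoptosis and requiescence "
                         "with altered transitions", {
        "k_QP": 1.1e-3, "k_PR": 2.6e-3, "k_RQ": 135e-3,
        "k_req": 4.17e-3, "k_ap": 4.17e-3, "k_prol": 8.33e-3,
    }),
    5: HypothesisSpec(5, "reduced metabolic demand", {
        "M": 20.8217, "G_rate": 3.474e-4,
    }),
}


def simulate_hypothesis(spec: HypothesisSpec,
                        horizon: float = 2400.0,
                        base: ModelParameters | None = None,
                        output_grid: float = 1.0,
                        **sim_kw):
    """Simulate one hypothesis and report the discriminating readouts.

    Returns (trajectory, readouts) where the readouts give the mass
    recovery at day 14 and the molecular levels plus replicating fraction
    at day 30 — the quantities proposed for differentiating hypotheses
    from clinical measurements.
    """
    base = base or ModelParameters()
    tr = simulate(spec.apply(base), horizon=horizon, output_grid=output_grid,
                  **sim_kw)
    day14, day30 = 14 * 24.0, 30 * 24.0
    readouts = {
        "mass_fraction_day14": tr.at(day14, "mass_fraction"),
        "IL6_day30": tr.at(day30, "IL6"),
        "GF_day30": tr.at(day30, "GF"),
        "ECM_day30": tr.at(day30, "ECM"),
        "replicating_fraction_day30": tr.at(day30, "replicating_fraction"),
    }
    return tr, readouts
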