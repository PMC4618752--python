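"""Core ODE system and trajectory integration.

The dynamic state comprises three hepatocyte pools (Q, P, R, relative to the
post-PHx remnant), the relative mass of responding cells (G_cell), seven
fold-change molecular levels (IL6, JAK, pSTAT3, SOCS3, IE, GF, ECM) and the
two matrix-bound-factor pools (MBF_ECM, MBF_free).  An auxiliary state
(growth_act) carries the first-order activation of the hypertrophy gate.

Structure of the system
-----------------------
* Quiescent cells are primed by immediate-early gene signal (and, when the
  matrix-bound-factor extension is enabled, by liberated MBF), primed cells
  enter replication under growth-factor drive, and replicating cells return
  to quiescence through ECM contact and through requiescence when GF support
  is withdrawn.
* Apoptosis follows a sigmoid of metabolic overload: when the surviving cell
  pool is small relative to the demand it must carry, the apoptotic rate is
  high; it vanishes as the pool recovers.
* Cell growth (hypertrophy of P and R cells) is gated by unmet demand per
  cell and shuts off as the recovering mass meets the pre-PHx demand.
* Growth-factor levels are floored at their baseline of 1 inside the flux
  evaluation (numerical guard used by the original study).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .parameters import ModelParameters, basal_production_constants

__all__ = [
    "STATE_NAMES",
    "ModelState",
    "Trajectory",
    "PeakStats",
    "SimulationError",
    "initial_state",
    "basal_state",
    "rhs",
    "growth_rate_rhs",
    "mbf_release_flux",
    "simulate",
    "peak_stats",
]

#: integration state vector layout
STATE_NAMES = (
    "Q", "P", "R", "G_cell", "growth_act",
    "IL6", "JAK", "pSTAT3", "SOCS3", "IE", "GF", "ECM",
    "MBF_ECM", "MBF_free",
)
_IDX = {name: i for i, name in enumerate(STATE_NAMES)}
#: molecular fold-change levels (baseline 1)
MOLECULAR = ("IL6", "JAK", "pSTAT3", "SOCS3", "IE", "GF", "ECM")

#: columns written to trajectory CSV files
CSV_COLUMNS = (
    "time_h", "Q", "P", "R", "G_cell",
    "IL6", "JAK", "pSTAT3", "SOCS3", "IE", "GF", "ECM",
    "MBF_ECM", "MBF_free", "mass_fraction", "replicating_fraction",
)

LN2 = math.log(2.0)

#: relaxation time [h] of the floor-restoring terms inside the rhs
FLOOR_TAU = 1e-2

#: smallest effective cell pool entering the demand-per-cell ratio; below
#: this the tissue is extinct and the demand signal saturates instead of
#: diverging (numerical regularization of a non-viable regime)
POOL_FLOOR = 1e-3


class SimulationError(RuntimeError):
    """Raised when the stiff integrator fails or states go non-finite."""


@dataclass
class ModelState:
    """A single point of the dynamic state (convenience container)."""

    Q: float
    P: float
    R: float
    G_cell: float
    IL6: float
    JAK: float
    pSTAT3: float
    SOCS3: float
    IE: float
    GF: float
    ECM: float
    MBF_ECM: float = 50.0
    MBF_free: float = 0.0
    growth_act: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in STATE_NAMES])

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "ModelState":
        return cls(**{name: float(y[i]) for i, name in enumerate(STATE_NAMES)})


def initial_state(params: ModelParameters) -> np.ndarray:
    """Post-PHx initial condition: Q=1, P=R=0, molecular levels 1."""
    y0 = np.ones(len(STATE_NAMES))
    y0[_IDX["P"]] = 0.0
    y0[_IDX["R"]] = 0.0
    y0[_IDX["growth_act"]] = 0.0
    y0[_IDX["MBF_ECM"]] = params.MBF_ECM0
    y0[_IDX["MBF_free"]] = 0.0
    return y0


def basal_state(params: ModelParameters) -> np.ndarray:
    """Pre-PHx configuration: the full quiescent pool at basal demand."""
    y0 = initial_state(params)
    y0[_IDX["Q"]] = 1.0 / (1.0 - params.phx_fraction)
    return y0


def _demand_scale(params: ModelParameters) -> float:
    # demand per cell D = M / (scale * N) with N in remnant units
    if params.demand_convention == "whole_liver":
        return 1.0 - params.phx_fraction
    return 1.0


def _apoptosis_sigmoid(params: ModelParameters, Q: float, P: float, R: float,
                       demand_per_cell: float) -> float:
    if params.apoptosis_convention == "as_printed":
        arg = (params.theta_ap - demand_per_cell) / params.beta_ap
    else:
        # inverse-demand: load measure is the surviving cell count (fraction
        # of the pre-PHx pool) per unit demand; apoptosis is high when the
        # pool is too small for the load it carries.
        x = _demand_scale(params) * (Q + P + R) / (
            params.apoptosis_load_scale * params.M)
        arg = (params.theta_ap - x) / params.beta_ap
    return 0.5 * (1.0 + math.tanh(arg))


def make_rhs(params: ModelParameters) -> Callable[[float, np.ndarray], np.ndarray]:
    """Build the time-derivative function with basal constants closed over."""
    params.validate()
    p = params
    k = basal_production_constants(p)
    Db = p.basal_demand_per_cell
    scale = _demand_scale(p)
    pro2 = p.pro_STAT3 ** 2
    gate_width = p.growth_gate_width * Db
    g_rate_h = p.growth_rate_per_h
    mbf = p.include_mbf
    growth = p.include_growth
    tanh = math.tanh

    def f(t: float, y: np.ndarray) -> np.ndarray:
        (Q, P, R, G, A, IL6, JAK, ST3, SOC, IE, GF, ECM, MBe, MBf) = y
        GFe = GF if GF > 1.0 else 1.0
        n_mass = Q + G * (P + R)
        D = p.M / (scale * (n_mass if n_mass > POOL_FLOOR else POOL_FLOOR))

        sig_ap = _apoptosis_sigmoid(p, Q, P, R, D)
        sig_req = 0.5 * (1.0 + tanh((p.theta_req - GFe) / p.beta_req))

        prime_signal = max(IE - p.IE0, 0.0)
        if mbf:
            prime_signal += max(MBf, 0.0)
        prime = p.k_QP * prime_signal * Q
        advance = p.k_PR * max(GFe - p.GF0, 0.0) * P
        ecm_return = p.k_RQ * ECM * R
        requiesce_P = p.k_req * sig_req * P
        requiesce_R = p.k_req * sig_req * R if p.requiescence_on_replicating else 0.0
        ap = p.k_ap * sig_ap
        ap_P = ap * (Q if p.apoptosis_p_convention == "Q_as_printed" else P)

        dQ = -prime + ecm_return + requiesce_P + requiesce_R - ap * Q
        dP = prime - advance - requiesce_P - ap_P
        dR = advance - ecm_return + p.k_prol * R - requiesce_R - ap * R

        if growth:
            gate = 0.5 * (1.0 + tanh((D - Db) / gate_width))
            # hypertrophy saturates well above physiological fold-changes
            cap = 1.0 - (G / p.growth_cap) ** 8
            if cap < 0.0:
                cap = 0.0
            if p.growth_lag_h > 0.0:
                dA = (gate - A) / p.growth_lag_h
                dG = LN2 * g_rate_h * G * A * cap
            else:
                dA = 0.0
                dG = LN2 * g_rate_h * G * gate * cap
        else:
            dA = 0.0
            dG = 0.0

        # substrate levels are clamped at 0 inside the saturating fluxes so
        # transient negative excursions cannot hit a Michaelis singularity
        IL6c = IL6 if IL6 > 0.0 else 0.0
        ST3c = ST3 if ST3 > 0.0 else 0.0
        SOCc = SOC if SOC > 0.0 else 0.0
        jak_flux = p.V_JAK * IL6c / (IL6c + p.Km_JAK)
        dIL6 = p.k_IL6 * D - jak_flux - p.kappa_IL6 * IL6 + k.k1
        dJAK = jak_flux - p.kappa_JAK * JAK + k.k2

        stat_prod = p.V_STAT3 * JAK * pro2 / (
            pro2 + p.Km_STAT3 * (1.0 + SOCc / p.KI_SOCS3))
        ie_flux = p.V_IE * ST3c / (ST3c + p.Km_IE)
        socs_flux = p.V_SOCS3 * ST3c / (ST3c + p.Km_SOCS3)
        dST3 = stat_prod - ie_flux - socs_flux - p.kappa_STAT3 * ST3 + k.k3
        dSOC = socs_flux - p.kappa_SOCS3 * SOC + k.k4
        dIE = ie_flux - p.kappa_IE * IE + k.k5

        dGF = p.k_GF * D - p.k_up * GFe * ECM - p.kappa_GF * GFe + k.k7
        # baseline floor (numerical guard of the original study): a stiff
        # continuous restoring term instead of a hard derivative switch,
        # which would make the implicit integrator chatter at the boundary
        if GF < 1.0:
            dGF += (1.0 - GF) / FLOOR_TAU
        dECM = -p.kappa_deg * IL6c * ECM - p.kappa_ECM * ECM + k.k6

        # nonnegativity guards for the remaining molecular levels
        if IL6 < 0.0:
            dIL6 -= IL6 / FLOOR_TAU
        if ST3 < 0.0:
            dST3 -= ST3 / FLOOR_TAU
        if IE < 0.0:
            dIE -= IE / FLOOR_TAU

        if mbf:
            u = _release_rate(p, ECM, MBe, MBf)
            dMBe = -u + p.k_up * GFe * ECM
            dMBf = u - p.kappa_MBF * MBf
        else:
            dMBe = 0.0
            dMBf = 0.0

        return np.array([dQ, dP, dR, dG, dA, dIL6, dJAK, dST3, dSOC,
                         dIE, dGF, dECM, dMBe, dMBf])

    return f


def _release_rate(p: ModelParameters, ECM: float, MBe: float, MBf: float) -> float:
    # mass-action unbinding of matrix-bound factors during ECM remodeling:
    # degraded matrix (ECM below its reference) liberates bound factors in
    # proportion to the remaining bound pool; when ECM exceeds baseline, the
    # free pool can re-bind.
    if ECM <= 0.0:
        raise SimulationError(f"ECM must be positive, got {ECM}")
    u = p.k_MBF * (1.0 / ECM - p.ECM0)
    if u >= 0.0:
        return u * max(MBe, 0.0)
    return u * max(MBf, 0.0)


def rhs(state: ModelState | np.ndarray, params: ModelParameters) -> np.ndarray:
    """Time derivative of the full state (public, validated entry point)."""
    y = state.to_array() if isinstance(state, ModelState) else np.asarray(state, float)
    if y.shape != (len(STATE_NAMES),):
        raise ValueError(f"state must have {len(STATE_NAMES)} entries")
    if not np.all(np.isfinite(y)):
        raise SimulationError("non-finite state entries")
    return make_rhs(params)(0.0, y)


def growth_rate_rhs(state: ModelState | np.ndarray, params: ModelParameters) -> float:
    """dG_cell/dt for a given state (0 when the growth extension is off)."""
    if not params.include_growth:
        return 0.0
    d = rhs(state, params)
    return float(d[_IDX["G_cell"]])


def mbf_release_flux(state: ModelState | np.ndarray, params: ModelParameters) -> float:
    """Instantaneous unbinding flux of matrix-bound factors.

    Positive when ECM has been degraded below its reference level; zero once
    the bound pool is exhausted.
    """
    if not params.include_mbf:
        raise ValueError("mbf_release_flux requires include_mbf=True")
    y = state.to_array() if isinstance(state, ModelState) else np.asarray(state, float)
    return _release_rate(params, y[_IDX["ECM"]], y[_IDX["MBF_ECM"]],
                         y[_IDX["MBF_free"]])


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class Trajectory:
    """Integrated model output on a fixed time grid.

    ``data`` holds one row per output time with the state columns plus the
    derived series used throughout the analyses (mass fraction of the
    pre-PHx liver, demand per cell, phenotype fractions, priming and MBF
    release fluxes).
    """

    data: pd.DataFrame
    params: ModelParameters

    @property
    def times(self) -> np.ndarray:
        return self.data["time_h"].to_numpy()

    @property
    def mass_fraction(self) -> np.ndarray:
        return self.data["mass_fraction"].to_numpy()

    @property
    def replicating_fraction(self) -> np.ndarray:
        return self.data["replicating_fraction"].to_numpy()

    @property
    def primed_fraction(self) -> np.ndarray:
        return self.data["primed_fraction"].to_numpy()

    @property
    def demand_per_cell(self) -> np.ndarray:
        return self.data["demand_per_cell"].to_numpy()

    def series(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def at(self, time_h: float, column: str = "mass_fraction") -> float:
        """Linear interpolation of a column at an arbitrary time."""
        return float(np.interp(time_h, self.times, self.data[column].to_numpy()))

    def to_csv(self, path: str | Path) -> None:
        self.data[list(CSV_COLUMNS)].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path,
                 params: ModelParameters | None = None) -> "Trajectory":
        df = pd.read_csv(path)
        params = params or ModelParameters()
        return cls(data=_derive(df, params), params=params)


def _derive(df: pd.DataFrame, params: ModelParameters) -> pd.DataFrame:
    """Attach derived series to a raw state table."""
    df = df.copy()
    f = params.phx_fraction
    n_mass = df["Q"] + df["G_cell"] * (df["P"] + df["R"])
    total = df["Q"] + df["P"] + df["R"]
    df["mass_fraction"] = (1.0 - f) * n_mass
    df["demand_per_cell"] = params.M / (_demand_scale(params) * n_mass)
    df["replicating_fraction"] = df["R"] / total
    df["primed_fraction"] = df["P"] / total
    ie_sig = np.maximum(df["IE"] - params.IE0, 0.0)
    if params.include_mbf:
        ie_sig = ie_sig + np.maximum(df["MBF_free"], 0.0)
    df["priming_flux"] = params.k_QP * ie_sig * df["Q"]
    rel = params.k_MBF * (1.0 / df["ECM"] - params.ECM0)
    pool = np.where(rel >= 0, np.maximum(df["MBF_ECM"], 0.0),
                    np.maximum(df["MBF_free"], 0.0))
    df["mbf_release_flux"] = np.where(params.include_mbf, rel * pool, 0.0)
    return df


def simulate(params: ModelParameters,
             horizon: float = 300.0,
             output_grid: np.ndarray | float | None = None,
             y0: np.ndarray | None = None,
             rtol: float = 1e-8,
             atol: float = 1e-10,
             method: str = "LSODA",
             max_nfev: int = 2_000_000) -> Trajectory:
    """Integrate the stiff system from the post-PHx initial condition.

    Parameters
    ----------
    params:
        Validated model parameters (basal constants are recomputed here).
    horizon:
        Final time in hours (> 0).
    output_grid:
        Either an explicit array of output times, a scalar grid spacing in
        hours, or None for the default 0.05 h spacing.
    y0:
        Optional custom initial state (defaults to the post-PHx state).

    Returns
    -------
    Trajectory
        Dense output on the requested grid with derived series.  The GF
        baseline floor is enforced on the reported series.
    """
    if horizon <= 0.0:
        raise ValueError("horizon must be positive")
    if output_grid is None:
        t_eval = np.arange(0.0, horizon + 1e-9, 0.05)
    elif np.isscalar(output_grid):
        t_eval = np.arange(0.0, horizon + 1e-9, float(output_grid))
    else:
        t_eval = np.asarray(output_grid, float)
        if t_eval[0] < 0 or t_eval[-1] > horizon + 1e-9:
            raise ValueError("output_grid must lie within [0, horizon]")
    f = make_rhs(params)
    if y0 is None:
        y0 = initial_state(params)
    nfev = [0]

    def guarded(t, y):
        nfev[0] += 1
        if nfev[0] > max_nfev:
            raise SimulationError(
                f"step-size collapse near t = {t:.3f} h "
                f"(> {max_nfev} rhs evaluations)")
        return f(t, y)

    sol = solve_ivp(guarded, (0.0, float(horizon)), y0, method=method,
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise SimulationError(
            f"integration failed at t = {sol.t[-1] if len(sol.t) else 0.0:.3f} h: "
            f"{sol.message}")
    if not np.all(np.isfinite(sol.y)):
        raise SimulationError("non-finite states in solution")
    df = pd.DataFrame(sol.y.T, columns=list(STATE_NAMES))
    df.insert(0, "time_h", sol.t)
    # report GF with the baseline floor applied (guard used inside the rhs)
    df["GF"] = np.maximum(df["GF"], 1.0)
    # integration noise can leave tiny negative excursions; clamp pools
    for name in ("Q", "P", "R") + MOLECULAR:
        df[name] = np.maximum(df[name], 0.0)
    return Trajectory(data=_derive(df, params), params=params)


# ---------------------------------------------------------------------------
# peak reporting


@dataclass(frozen=True)
class PeakStats:
    """Location and height of a series maximum (quadratically refined)."""

    time: float
    value: float
    flat: bool = False


def peak_stats(times: Sequence[float], values: Sequence[float]) -> PeakStats:
    """Global maximum of a sampled series with sub-grid refinement.

    A parabola through the maximal sample and its neighbours refines the
    peak location; ties are broken toward the earliest time.  An all-equal
    series returns its first point flagged as flat.
    """
    t = np.asarray(times, float)
    v = np.asarray(values, float)
    if t.size == 0:
        raise ValueError("empty series")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
        raise ValueError("series contains non-finite entries")
    if np.all(v == v[0]):
        return PeakStats(time=float(t[0]), value=float(v[0]), flat=True)
    i = int(np.argmax(v))
    if 0 < i < len(v) - 1:
        y0, y1, y2 = v[i - 1], v[i], v[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0.0:  # strictly concave triple: refine
            delta = 0.5 * (y0 - y2) / denom
            h = t[i + 1] - t[i]
            return PeakStats(time=float(t[i] + delta * h),
                             value=float(y1 - 0.25 * (y0 - y2) * delta))
    return PeakStats(time=float(t[i]), value=float(v[i]))
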