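"""Model parameters for the liver-regeneration ODE system.

The model describes the response of the remnant liver to partial hepatectomy
(PHx).  Hepatocytes occupy one of three phenotypes — quiescent (Q), primed
(P) or replicating (R) — and are driven between them by a cytokine cascade
(IL-6 → JAK → pSTAT3 → immediate-early genes, with SOCS3 feedback), growth
factor (GF) bioavailability and extracellular-matrix (ECM) accumulation.
The lumped metabolic demand per cell, M/N, is the initiating signal.

All nominal values are the published rat parameterization.  Rates are
interpreted on an hourly time base, with one exception: the hepatocyte mass
growth rate ``G_rate`` is given in mass-equivalent doublings per *minute*
and is converted internally (see :data:`MINUTES_PER_HOUR`).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator, Mapping

import yaml

__all__ = [
    "ModelParameters",
    "ParameterError",
    "BasalConstants",
    "basal_production_constants",
    "rat_nominal",
    "load_parameters",
    "MINUTES_PER_HOUR",
]

MINUTES_PER_HOUR = 60.0

#: parameters that are sampled / perturbed by default in parameter-space
#: studies (all Table rate/threshold constants; initial conditions and the
#: resected fraction are excluded).
RATE_PARAMETERS = (
    "M", "G_rate",
    "k_IL6", "kappa_IL6",
    "V_JAK", "Km_JAK", "kappa_JAK",
    "pro_STAT3", "V_STAT3", "Km_STAT3", "kappa_STAT3",
    "V_SOCS3", "Km_SOCS3", "kappa_SOCS3", "KI_SOCS3",
    "V_IE", "Km_IE", "kappa_IE",
    "kappa_deg", "kappa_ECM",
    "k_GF", "kappa_GF", "k_up",
    "k_QP", "k_PR", "k_RQ",
    "k_prol", "k_req", "theta_req", "beta_req",
    "k_ap", "theta_ap", "beta_ap",
    "k_MBF", "kappa_MBF",
)


class ParameterError(ValueError):
    """Raised for invalid or inconsistent model parameters."""


@dataclass
class ModelParameters:
    """Full parameter set of the regeneration model.

    Defaults are the nominal rat values.  Molecular variables are
    fold-changes over their pre-PHx baseline of 1; cell pools are relative
    to the post-PHx remnant (Q starts at 1).

    Attributes
    ----------
    M:
        Lumped metabolic demand (relative nutrient/toxin flux per unit of
        pre-PHx liver mass).  Demand per cell is ``M / N`` with N the
        responding cell mass measured against the pre-PHx pool.
    G_rate:
        Hepatocyte mass growth rate, mass-equivalent doublings per minute.
    phx_fraction:
        Resected mass fraction f; the simulation starts from the remnant,
        so the reported mass fraction starts at ``1 - f``.
    """

    # physiological drivers
    M: float = 20.8
    G_rate: float = 3.5e-4            # mass-equivalent doublings / min

    # cytokine (IL-6) production & turnover — Kupffer-cell compartment
    k_IL6: float = 1.5
    kappa_IL6: float = 0.9

    # JAK activation
    V_JAK: float = 2.0e4
    Km_JAK: float = 1.0e4
    kappa_JAK: float = 0.4

    # STAT3 phosphorylation, SOCS3 feedback
    pro_STAT3: float = 2.0            # monomeric STAT3 level (constant)
    V_STAT3: float = 7.5e2
    Km_STAT3: float = 0.4
    kappa_STAT3: float = 0.1
    V_SOCS3: float = 2.4e4
    Km_SOCS3: float = 7.0e-4
    kappa_SOCS3: float = 0.4
    KI_SOCS3: float = 1.5e-2

    # immediate-early genes
    V_IE: float = 2.5e2
    Km_IE: float = 18.0
    kappa_IE: float = 5.0

    # ECM turnover (MMP-driven and constitutive)
    kappa_deg: float = 7.0
    kappa_ECM: float = 33.0

    # growth factors — stellate-cell compartment
    k_GF: float = 0.113
    kappa_GF: float = 0.23
    k_up: float = 6.0e-2

    # phenotype transitions
    k_QP: float = 7.0e-3
    k_PR: float = 4.4e-3
    k_RQ: float = 5.4e-3
    k_prol: float = 2.0e-2

    # requiescence and apoptosis sigmoids
    k_req: float = 0.1
    theta_req: float = 8.0
    beta_req: float = 3.0
    k_ap: float = 0.1
    theta_ap: float = 9.0e-3
    beta_ap: float = 4.5e-3

    # matrix-bound factors
    k_MBF: float = 1.0
    kappa_MBF: float = 1.0

    # surgery / reference levels
    phx_fraction: float = 0.7
    IE0: float = 1.0
    GF0: float = 1.0
    ECM0: float = 1.0
    MBF_ECM0: float = 50.0

    # model-variant flags -------------------------------------------------
    include_growth: bool = True
    include_mbf: bool = False
    #: 'inverse_demand' — apoptosis increases as the recovered cell pool per
    #: unit demand falls below theta_ap (active immediately post-PHx, high
    #: at high metabolic load); 'as_printed' — sigmoid on theta_ap - M/N,
    #: which is identically ~0 at physiological demand.
    apoptosis_convention: str = "inverse_demand"
    #: load normalization inside the apoptosis sigmoid (dimensionless);
    #: calibrated once against the dynamic-sensitivity anchors.
    apoptosis_load_scale: float = 0.84
    #: 'whole_liver' — basal demand per cell equals M (pre-PHx pool carries
    #: demand M per unit mass); 'remnant' — basal demand M*(1-f).
    demand_convention: str = "whole_liver"
    #: requiescence flux k_req*sigma_req also returns replicating cells to
    #: quiescence (termination of regeneration).
    requiescence_on_replicating: bool = True
    #: which pool the apoptosis term of the primed-cell equation drains:
    #: 'P' (typo-corrected) or 'Q_as_printed'.
    apoptosis_p_convention: str = "P"
    #: first-order activation lag of the hypertrophy gate [h].
    growth_lag_h: float = 10.0
    #: gate width as a fraction of the basal demand per cell.
    growth_gate_width: float = 0.1
    #: saturation bound on the relative cell mass G_cell; set well above the
    #: fold-changes the nominal trajectory reaches, it only tames the
    #: runaway growth of non-viable (extinct-pool) regimes.
    growth_cap: float = 100.0

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Check positivity and structural invariants; raise ParameterError."""
        for name in RATE_PARAMETERS:
            v = getattr(self, name)
            if not (v >= 0.0):
                raise ParameterError(f"parameter {name} must be >= 0, got {v}")
        for name in ("Km_JAK", "Km_STAT3", "Km_SOCS3", "Km_IE",
                     "beta_req", "beta_ap", "KI_SOCS3"):
            if getattr(self, name) <= 0.0:
                raise ParameterError(f"parameter {name} must be > 0")
        if not 0.0 < self.phx_fraction < 1.0:
            raise ParameterError(
                f"phx_fraction must lie in (0, 1), got {self.phx_fraction}")
        if self.apoptosis_convention not in ("inverse_demand", "as_printed"):
            raise ParameterError(
                f"unknown apoptosis_convention {self.apoptosis_convention!r}")
        if self.demand_convention not in ("whole_liver", "remnant"):
            raise ParameterError(
                f"unknown demand_convention {self.demand_convention!r}")
        if self.apoptosis_p_convention not in ("P", "Q_as_printed"):
            raise ParameterError(
                f"unknown apoptosis_p_convention {self.apoptosis_p_convention!r}")
        if self.apoptosis_load_scale <= 0.0:
            raise ParameterError("apoptosis_load_scale must be > 0")
        if self.growth_cap <= 1.0:
            raise ParameterError("growth_cap must exceed 1")

    # convenience ------------------------------------------------------
    @property
    def growth_rate_per_h(self) -> float:
        """Mass growth rate converted to doublings per hour."""
        return self.G_rate * MINUTES_PER_HOUR

    @property
    def basal_demand_per_cell(self) -> float:
        """Demand per unit cell mass at the pre-PHx steady state."""
        if self.demand_convention == "whole_liver":
            return self.M
        return self.M * (1.0 - self.phx_fraction)

    def replace(self, **changes: Any) -> "ModelParameters":
        """Return a copy with the given fields replaced (validated)."""
        unknown = set(changes) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, doc: Mapping[str, Any]) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ParameterError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def __iter__(self) -> Iterator[tuple[str, Any]]:
        return iter(self.to_dict().items())


@dataclass(frozen=True)
class BasalConstants:
    """Closed-form basal production constants k1..k7.

    Chosen so that with every molecular level at its baseline of 1 and
    demand per cell at its basal value, each molecular equation has a right
    hand side of exactly zero (the pre-PHx steady state).  k1 belongs to the
    cytokine equation, k2 JAK, k3 pSTAT3, k4 SOCS3, k5 immediate-early
    genes, k6 ECM and k7 growth factor.
    """

    k1: float
    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    k7: float

    def as_tuple(self) -> tuple[float, ...]:
        return (self.k1, self.k2, self.k3, self.k4, self.k5, self.k6, self.k7)


def basal_production_constants(params: ModelParameters) -> BasalConstants:
    """Solve the pre-PHx steady-state condition for k1..k7.

    Each constant is the algebraic closure of one molecular balance at the
    baseline state (all fold-changes 1, ECM 1, demand per cell basal).

    Raises
    ------
    ParameterError
        for non-positive Michaelis constants or other invalid inputs.
    """
    params.validate()
    p = params
    Db = p.basal_demand_per_cell
    jak_flux0 = p.V_JAK * 1.0 / (1.0 + p.Km_JAK)
    pro2 = p.pro_STAT3 ** 2
    stat_prod0 = p.V_STAT3 * 1.0 * pro2 / (
        pro2 + p.Km_STAT3 * (1.0 + 1.0 / p.KI_SOCS3))
    ie_flux0 = p.V_IE * 1.0 / (1.0 + p.Km_IE)
    socs_flux0 = p.V_SOCS3 * 1.0 / (1.0 + p.Km_SOCS3)

    k1 = jak_flux0 + p.kappa_IL6 - p.k_IL6 * Db
    k2 = p.kappa_JAK - jak_flux0
    k3 = ie_flux0 + socs_flux0 + p.kappa_STAT3 - stat_prod0
    k4 = p.kappa_SOCS3 - socs_flux0
    k5 = p.kappa_IE - ie_flux0
    k6 = p.kappa_deg * 1.0 * 1.0 + p.kappa_ECM * 1.0
    k7 = p.k_up * 1.0 * 1.0 + p.kappa_GF * 1.0 - p.k_GF * Db
    return BasalConstants(k1, k2, k3, k4, k5, k6, k7)


def rat_nominal(**overrides: Any) -> ModelParameters:
    """The nominal rat parameter set (optionally with overrides)."""
    return ModelParameters().replace(**overrides) if overrides else ModelParameters()


def load_parameters(path: str | Path) -> ModelParameters:
    """Load a parameter document (YAML or JSON) keyed by parameter names."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise ParameterError(f"parameter document {path} is not a mapping")
    return ModelParameters.from_dict(doc)
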