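"""Model constants and the rules used to derive them.

All densities and concentrations are in g/cm^3, lengths in cm, time in
days.  The default :class:`ParameterSet` is the published table of
constants for the mouse model; the human variant differs only in the
cancer-cell growth rate.  Several rate constants can alternatively be
re-derived from steady-state closures (:func:`derive_closure_rates`),
from molecular weight (:func:`young_diffusion`) or from a half-life
(:func:`rate_from_half_life`); where a derived value disagrees with the
tabulated one the discrepancy is reported, never silently "corrected".
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "InvalidParameterError",
    "ClosureInfeasibleError",
    "ParameterSet",
    "ClosureTargets",
    "ClosureRate",
    "young_diffusion",
    "rate_from_half_life",
    "rate_to_half_life",
    "derive_closure_rates",
    "load_parameters",
]

log = logging.getLogger(__name__)

# Reference protein for the cube-root molecular-weight diffusion scaling:
# VEGF, 24 kDa, 8.64e-2 cm^2/day.
_MW_REF_KDA = 24.0
_DIFF_REF = 8.64e-2


class InvalidParameterError(ValueError):
    """A parameter value violates its domain (sign, range or unknown key)."""


class ClosureInfeasibleError(ValueError):
    """A steady-state closure produced a non-positive rate constant."""


def young_diffusion(molecular_weight: float,
                    mw_ref: float = _MW_REF_KDA,
                    diff_ref: float = _DIFF_REF) -> float:
    """Diffusion coefficient (cm^2/day) of a protein of given weight (kDa).

    Uses the cube-root molecular-weight scaling anchored at VEGF:
    ``D_p = D_ref * (M_ref / M_p)**(1/3)``.
    """
    if molecular_weight <= 0:
        raise InvalidParameterError(
            f"molecular weight must be positive, got {molecular_weight}")
    if mw_ref <= 0 or diff_ref <= 0:
        raise InvalidParameterError("reference weight/diffusivity must be positive")
    return diff_ref * (mw_ref / molecular_weight) ** (1.0 / 3.0)


def rate_from_half_life(half_life: float) -> float:
    """First-order rate constant (1/day) from a half-life (days)."""
    if half_life <= 0:
        raise InvalidParameterError(f"half-life must be positive, got {half_life}")
    return math.log(2.0) / half_life


def rate_to_half_life(rate: float) -> float:
    """Half-life (days) from a first-order rate constant (1/day)."""
    if rate <= 0:
        raise InvalidParameterError(f"rate must be positive, got {rate}")
    return math.log(2.0) / rate


# Provenance of each default value: tabulated, stated in running text,
# derived from a closure, or a package default for an unconstrained constant.
_PROVENANCE: dict[str, str] = {}


def _p(default, provenance: str):
    """Dataclass field with a provenance tag."""
    return field(default=default, metadata={"provenance": provenance})


@dataclass
class ParameterSet:
    """Every constant of the PDE model (g/cm^3, cm, day unit system).

    ``species`` selects the cancer growth rate: ``"mouse"`` or ``"human"``.
    ``lambda_TalphaT_variant`` selects among the three published values of
    the T-cell TNF-a production rate (``"closure"``, ``"text"``,
    ``"table"``); the closure-derived value is the default because it is
    the only one consistent with the half-saturation rule K_X = X0.
    """

    # diffusion coefficients, cm^2/day
    delta_D: float = _p(8.64e-7, "table")
    delta_T: float = _p(8.64e-7, "table")
    delta_C: float = _p(8.64e-7, "table")
    delta_I12: float = _p(7.17e-2, "table")
    delta_Talpha: float = _p(8.46e-2, "table")
    delta_A: float = _p(4.76e-2, "table")
    delta_B: float = _p(4.75e-2, "table")
    # boundary flux rate, 1/cm
    sigma_0: float = _p(1.0, "table")
    # kill / blocking rates, cm^3/(g day)
    eta: float = _p(328.55, "table")
    mu_PA: float = _p(1.03e7, "table")
    mu_TalphaB: float = _p(2.56e8, "table")
    # expression ratios, dimensionless
    rho_P: float = _p(2.49e-7, "table")
    rho_L: float = _p(3.25e-7, "table")
    rho_M: float = _p(1.5e-7, "table")
    rho_G: float = _p(2.0e-8, "table")
    eps_C: float = _p(0.1, "table")
    # upregulation factors, dimensionless
    alpha_L: float = _p(1.0, "table")
    alpha_T: float = _p(1.0, "table")
    alpha_MA: float = _p(2.0, "table")
    # lumped activation rates, g/(cm^3 day)
    lambda_DC_D0: float = _p(8.0e-5, "table")
    lambda_TI12_T0: float = _p(6.48e-4, "table")
    # growth / production rates, 1/day
    lambda_C_mouse: float = _p(1.295, "table")
    lambda_C_human: float = _p(0.895, "table")
    lambda_I12D: float = _p(2.76e-6, "table")
    lambda_TalphaT: float = _p(5.36e-6, "derived")
    # background TNF-a source (macrophages), g/(cm^3 day)
    A_Talpha: float = _p(1.12e-9, "text")
    # death / degradation rates, 1/day
    d_D: float = _p(0.1, "table")
    d_T: float = _p(0.197, "table")
    d_T_closure: float = _p(0.18, "text")
    d_C: float = _p(0.17, "table")
    d_I12: float = _p(1.38, "table")
    d_Talpha: float = _p(216.0, "table")
    d_A: float = _p(0.046, "table")
    d_B: float = _p(0.069, "table")
    # half-saturations, g/cm^3
    K_D: float = _p(4.0e-4, "table")
    K_T: float = _p(1.0e-3, "table")
    K_C: float = _p(0.4, "table")
    K_I12: float = _p(8.0e-10, "table")
    K_Talpha: float = _p(3.0e-11, "table")
    # half-saturation of the drug-enhanced TIM-3 upregulation.  Not
    # tabulated anywhere: order-of-magnitude default (quasi-steady drug
    # level under the mouse dose), deliberately configurable.
    K_A: float = _p(1.0e-10, "default")
    # checkpoint-complex inhibition constants, g^2/cm^6 (the complex
    # association constants are absorbed: only the products sigma*K enter)
    K_TQ1: float = _p(1.36e-18, "table")
    K_TQ2: float = _p(1.365e-18, "table")
    # carrying capacity and boundary T-cell density, g/cm^3
    C_M: float = _p(0.8, "table")
    T_hat: float = _p(2.0e-3, "table")
    # dose pulse decay, 1/day (tabulated unit is a misprint; the constant
    # sits in an exponential over time)
    beta: float = _p(1.55, "table")
    # constant total cell density D + T + C, g/cm^3
    rho_tot: float = _p(0.4014, "text")
    # eta value used in the growth-rate closure reproduction
    eta_closure: float = _p(328.0, "text")

    species: str = "mouse"
    lambda_TalphaT_variant: str = "closure"

    # Alternative published values of lambda_TalphaT, selectable by variant.
    _LAMBDA_TALPHAT = {"closure": 5.36e-6, "text": 1.08e-6, "table": 6.48e-4}

    def __post_init__(self) -> None:
        if self.species not in ("mouse", "human"):
            raise InvalidParameterError(f"unknown species {self.species!r}")
        if self.lambda_TalphaT_variant not in self._LAMBDA_TALPHAT:
            raise InvalidParameterError(
                f"unknown lambda_TalphaT variant {self.lambda_TalphaT_variant!r}")
        self.validate()

    @property
    def lambda_C(self) -> float:
        """Cancer growth rate for the selected species (1/day)."""
        return self.lambda_C_mouse if self.species == "mouse" else self.lambda_C_human

    @property
    def delta_cell(self) -> float:
        """Common cell diffusivity (the three cell values are equal)."""
        return self.delta_D

    @property
    def delta_max(self) -> float:
        """Largest diffusivity over all fields; controls the CFL bound."""
        return max(self.delta_D, self.delta_T, self.delta_C, self.delta_I12,
                   self.delta_Talpha, self.delta_A, self.delta_B)

    def numeric_items(self):
        for f in fields(self):
            if f.type == "float":
                yield f.name, getattr(self, f.name)

    def validate(self) -> None:
        for name, value in self.numeric_items():
            if not (isinstance(value, (int, float)) and math.isfinite(value)):
                raise InvalidParameterError(f"{name} must be finite, got {value!r}")
            if value <= 0:
                raise InvalidParameterError(f"{name} must be positive, got {value}")
        if self.lambda_C_mouse < self.lambda_C_human:
            raise InvalidParameterError(
                "mouse growth rate must be >= human growth rate")
        if not (0 < self.eps_C <= 1):
            raise InvalidParameterError("eps_C must lie in (0, 1]")

    def with_overrides(self, **overrides) -> "ParameterSet":
        return dataclasses.replace(self, **overrides)

    def provenance(self) -> dict[str, str]:
        out = {}
        for f in fields(self):
            if f.type == "float":
                out[f.name] = f.metadata.get("provenance", "default")
        return out

    def to_dict(self) -> dict:
        d = {name: value for name, value in self.numeric_items()}
        d["species"] = self.species
        d["lambda_TalphaT_variant"] = self.lambda_TalphaT_variant
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        """JSON export of the validated set with provenance tags."""
        doc = {
            "values": self.to_dict(),
            "provenance": self.provenance(),
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass(frozen=True)
class ClosureTargets:
    """Steady-state levels the rate closures are anchored to.

    The half-saturation rule sets each K_X equal to the corresponding
    steady state X0, so the defaults mirror the half-saturations.
    """

    D0: float = 4.0e-4
    T0: float = 1.0e-3
    C0: float = 0.4
    I12_0: float = 8.0e-10
    Talpha0: float = 3.0e-11
    P0: float = 2.49e-10
    inhibition: float = 1.0 / 1.8   # combined checkpoint factor at steady state
    depletion_fraction: float = 0.1  # fraction of drug consumed by blocking

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v <= 0:
                raise InvalidParameterError(f"{f.name} must be positive, got {v}")
        if not (0 < self.depletion_fraction < 1):
            raise InvalidParameterError("depletion_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class ClosureRate:
    """A closure-derived rate next to its tabulated counterpart."""

    name: str
    derived: float
    printed: float
    units: str

    @property
    def rel_discrepancy(self) -> float:
        return abs(self.derived - self.printed) / abs(self.printed)


def derive_closure_rates(targets: ClosureTargets | None = None,
                         fixed: ParameterSet | None = None,
                         ) -> dict[str, ClosureRate]:
    """Re-derive the lumped production/blocking rates from steady states.

    Each evolution equation is closed by setting its right-hand side to
    zero with every species at its target level and every half-saturation
    at that same level (so each Michaelis factor equals 1/2), and solved
    for the production rate.  The drug blocking rates come from the
    assumption that a fixed fraction of each drug is consumed by blocking
    while the rest degrades.
    """
    tg = targets or ClosureTargets()
    p = fixed or ParameterSet()

    inv_f = 1.0 / tg.inhibition  # = 1.8

    lam_DC = 2.0 * p.d_D * p.K_D
    lam_T = 2.0 * inv_f * p.d_T_closure * tg.T0
    lam_C = 2.0 * (p.eta_closure * p.K_T + p.d_C)
    lam_I12 = p.d_I12 * p.K_I12 / p.K_D
    lam_Ta_num = p.d_Talpha * p.K_Talpha - p.A_Talpha
    if lam_Ta_num <= 0:
        raise ClosureInfeasibleError(
            "TNF-a closure infeasible: background source A_Talpha "
            f"({p.A_Talpha}) exceeds degradation d_Talpha*K_Talpha "
            f"({p.d_Talpha * p.K_Talpha})")
    lam_Ta = lam_Ta_num / p.K_T
    # fraction q blocked, 1-q degraded:  mu * X * drug = (q/(1-q)) * d * drug
    q = tg.depletion_fraction
    blocked_over_degraded = q / (1.0 - q)
    mu_TaB = blocked_over_degraded * p.d_B / tg.Talpha0
    mu_PA = blocked_over_degraded * p.d_A / tg.P0

    rates = {
        "lambda_DC_D0": ClosureRate("lambda_DC_D0", lam_DC, p.lambda_DC_D0,
                                    "g/cm^3/day"),
        "lambda_TI12_T0": ClosureRate("lambda_TI12_T0", lam_T, p.lambda_TI12_T0,
                                      "g/cm^3/day"),
        "lambda_C": ClosureRate("lambda_C", lam_C, p.lambda_C_mouse, "1/day"),
        "lambda_I12D": ClosureRate("lambda_I12D", lam_I12, p.lambda_I12D, "1/day"),
        "lambda_TalphaT": ClosureRate("lambda_TalphaT", lam_Ta, p.lambda_TalphaT,
                                      "1/day"),
        "mu_TalphaB": ClosureRate("mu_TalphaB", mu_TaB, p.mu_TalphaB,
                                  "cm^3/g/day"),
        "mu_PA": ClosureRate("mu_PA", mu_PA, p.mu_PA, "cm^3/g/day"),
    }
    for r in rates.values():
        if r.derived <= 0:
            raise ClosureInfeasibleError(f"closure for {r.name} is non-positive")
    return rates


_VALID_KEYS = None


def _valid_keys() -> set[str]:
    global _VALID_KEYS
    if _VALID_KEYS is None:
        _VALID_KEYS = {f.name for f in fields(ParameterSet)
                       if not f.name.startswith("_")}
    return _VALID_KEYS


def load_parameters(source: str | Path | Mapping | None = None,
                    discrepancy_threshold: float = 0.05) -> ParameterSet:
    """Build a validated :class:`ParameterSet` from a flat config.

    ``source`` may be a mapping, a path to a YAML file of flat key/value
    pairs, or ``None`` for the defaults.  Unknown keys are rejected.  Any
    loaded value deviating from its closure-derived counterpart by more
    than ``discrepancy_threshold`` is logged (the tabulated value wins).
    """
    if source is None:
        overrides: dict = {}
    elif isinstance(source, Mapping):
        overrides = dict(source)
    else:
        text = Path(source).read_text()
        overrides = yaml.safe_load(text) or {}
        if not isinstance(overrides, dict):
            raise InvalidParameterError(
                f"config {source} must be a flat mapping")

    unknown = set(overrides) - _valid_keys()
    if unknown:
        raise InvalidParameterError(
            f"unknown parameter keys: {sorted(unknown)}")
    for key, value in overrides.items():
        if key in ("species", "lambda_TalphaT_variant"):
            continue
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise InvalidParameterError(
                f"{key} must be numeric, got {value!r}")

    variant = overrides.get("lambda_TalphaT_variant")
    if variant is not None and "lambda_TalphaT" not in overrides:
        try:
            overrides["lambda_TalphaT"] = ParameterSet._LAMBDA_TALPHAT[variant]
        except KeyError:
            raise InvalidParameterError(
                f"unknown lambda_TalphaT variant {variant!r}") from None

    params = ParameterSet(**overrides)

    try:
        for rate in derive_closure_rates(fixed=params).values():
            if rate.rel_discrepancy > discrepancy_threshold:
                log.info(
                    "parameter %s deviates from its closure-derived value: "
                    "using %.4g, closure gives %.4g (%.0f%% apart)",
                    rate.name, rate.printed, rate.derived,
                    100 * rate.rel_discrepancy)
    except ClosureInfeasibleError as exc:  # diagnostics only
        log.warning("closure check skipped: %s", exc)
    return params
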