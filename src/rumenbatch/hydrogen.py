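"""Metabolic hydrogen balance from VFA and methane amounts.

Fermentation of hexose to the individual volatile fatty acids releases or
consumes reducing equivalents ([2H]) in fixed stoichiometric ratios, and
methanogenesis consumes 4 [2H] per CH4.  The classic balance over net molar
production is:

    H2 produced = 2*acetate + propionate + 4*butyrate
                  + 2*isovalerate + 2*valerate
    H2 utilized = 4*CH4 + 2*propionate + 3*butyrate + valerate
    H2 recovery (%) = utilized / produced * 100

Isobutyrate carries no net hydrogen term; lactate, formate, and succinate
are outside the balance.  All amounts are handled in mmol: concentrations
(mmol/L) are converted with the incubation liquid volume (0.06 L by default,
i.e. 20 mL inoculum + 40 mL buffer), and CH4 gas volume is converted with a
configurable molar volume (22.4 L/mol STP default; 25.6 L/mol at 39 degC is
the incubation-temperature alternative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .errors import InvalidInputError, MissingDataError, UndefinedValueError
from .presets import LIQUID_VOLUME_L

__all__ = [
    "VFAProfile", "HydrogenBalance",
    "vfa_to_mmol", "ch4_ml_to_mmol",
    "h2_produced", "h2_utilized", "h2_recovery", "hydrogen_balance",
    "MOLAR_VOLUME_STP_L", "MOLAR_VOLUME_39C_L",
]

MOLAR_VOLUME_STP_L = 22.4
MOLAR_VOLUME_39C_L = 25.6

#: Weights of each acid in the produced / utilized sums.
PRODUCED_WEIGHTS = {"acetate": 2.0, "propionate": 1.0, "butyrate": 4.0,
                    "isovalerate": 2.0, "valerate": 2.0}
UTILIZED_WEIGHTS = {"propionate": 2.0, "butyrate": 3.0, "valerate": 1.0}
CH4_WEIGHT = 4.0


@dataclass(frozen=True)
class VFAProfile:
    """Six-acid VFA profile in mmol/L."""

    acetate: float
    propionate: float
    butyrate: float
    isobutyrate: float
    valerate: float
    isovalerate: float

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if value < 0:
                raise InvalidInputError(f"{name} concentration must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return {
            "acetate": self.acetate,
            "propionate": self.propionate,
            "butyrate": self.butyrate,
            "isobutyrate": self.isobutyrate,
            "valerate": self.valerate,
            "isovalerate": self.isovalerate,
        }


@dataclass(frozen=True)
class HydrogenBalance:
    """Produced / utilized / recovery triple (mmol, mmol, %)."""

    h2_produced: float
    h2_utilized: float
    h2_recovery: float


def vfa_to_mmol(profile: VFAProfile | Mapping[str, float],
                liquid_volume_l: float = LIQUID_VOLUME_L) -> dict[str, float]:
    """Convert concentrations (mmol/L) to amounts (mmol) in the bottle."""
    if liquid_volume_l <= 0:
        raise InvalidInputError("liquid volume must be positive")
    conc = profile.as_dict() if isinstance(profile, VFAProfile) else dict(profile)
    return {acid: c * liquid_volume_l for acid, c in conc.items()}


def ch4_ml_to_mmol(volume_ml: float,
                   molar_volume_l_per_mol: float = MOLAR_VOLUME_STP_L) -> float:
    """CH4 gas volume (mL) to amount (mmol) at the given molar volume."""
    if molar_volume_l_per_mol <= 0:
        raise InvalidInputError("molar volume must be positive")
    if volume_ml < 0:
        raise InvalidInputError("volume must be >= 0")
    return volume_ml / molar_volume_l_per_mol


def _require(amounts: Mapping[str, float], acids: Mapping[str, float]) -> None:
    missing = [a for a in acids if a not in amounts]
    if missing:
        raise MissingDataError(f"missing VFA amounts: {missing}")


def h2_produced(amounts: Mapping[str, float]) -> float:
    """Hydrogen released by VFA synthesis, mmol (isobutyrate excluded)."""
    _require(amounts, PRODUCED_WEIGHTS)
    return sum(w * amounts[a] for a, w in PRODUCED_WEIGHTS.items())


def h2_utilized(ch4_mmol: float, amounts: Mapping[str, float]) -> float:
    """Hydrogen consumed by methanogenesis and VFA synthesis, mmol."""
    if ch4_mmol < 0:
        raise InvalidInputError("CH4 amount must be >= 0")
    _require(amounts, UTILIZED_WEIGHTS)
    return CH4_WEIGHT * ch4_mmol + sum(
        w * amounts[a] for a, w in UTILIZED_WEIGHTS.items())


def h2_recovery(produced_mmol: float, utilized_mmol: float) -> float:
    """Utilized as a percentage of produced hydrogen."""
    if produced_mmol <= 0:
        raise UndefinedValueError(
            "hydrogen recovery is undefined when production is zero")
    return utilized_mmol / produced_mmol * 100.0


def hydrogen_balance(
    profile: VFAProfile | Mapping[str, float],
    ch4_mmol: float,
    liquid_volume_l: float = LIQUID_VOLUME_L,
) -> HydrogenBalance:
    """Full balance from a VFA concentration profile and CH4 amount."""
    amounts = vfa_to_mmol(profile, liquid_volume_l)
    produced = h2_produced(amounts)
    utilized = h2_utilized(ch4_mmol, amounts)
    return HydrogenBalance(produced, utilized, h2_recovery(produced, utilized))
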