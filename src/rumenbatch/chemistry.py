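"""End-point fermentation chemistry: VFA summaries, DMD, colorimetry, AA panel.

Covers the arithmetic behind the end-point tables of a batch-culture run:
total VFA and molar proportions, the acetate-to-propionate ratio, dry-matter
digestibility from residue weights, linear standard-curve conversion for the
colorimetric assays (microbial protein, ammonia nitrogen), and the grouping
of the 20-analyte hydrolysed amino-acid panel into essential/non-essential
totals.  Histidine is grouped as non-essential here, following the source
panel's convention rather than the textbook assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import (DegenerateCurveError, InvalidInputError,
                     MissingDataError, UndefinedValueError)
from .hydrogen import VFAProfile
from .presets import ESSENTIAL_AA, NONESSENTIAL_AA

__all__ = [
    "VFASummary", "AminoAcidPanel", "LinearStandardCurve",
    "summarize_vfa", "dmd", "fit_standard_curve", "colorimetric_quantity",
    "classify_amino_acids",
]

logger = logging.getLogger(__name__)

ALL_AA = ESSENTIAL_AA + NONESSENTIAL_AA


@dataclass(frozen=True)
class VFASummary:
    """TVFA, A/P ratio, and molar proportions of a six-acid profile."""

    tvfa: float
    ap_ratio: float
    molar_proportions: Mapping[str, float]


@dataclass(frozen=True)
class AminoAcidPanel:
    """The 20 amino-acid concentrations with the derived group totals."""

    concentrations: Mapping[str, float]
    eaa_total: float
    neaa_total: float
    total: float


@dataclass(frozen=True)
class LinearStandardCurve:
    """response = slope * quantity + intercept, fitted by least squares."""

    slope: float
    intercept: float
    r_squared: float
    response_unit: str = "absorbance"
    quantity_unit: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise InvalidInputError("r_squared must lie in [0, 1]")


def summarize_vfa(profile: VFAProfile | Mapping[str, float]) -> VFASummary:
    """TVFA (sum of the six acids), A/P ratio, and molar proportions."""
    conc = profile.as_dict() if isinstance(profile, VFAProfile) else dict(profile)
    required = ("acetate", "propionate", "butyrate",
                "isobutyrate", "valerate", "isovalerate")
    missing = [a for a in required if a not in conc]
    if missing:
        raise MissingDataError(f"missing VFA fractions: {missing}")
    tvfa = sum(conc[a] for a in required)
    if conc["propionate"] <= 0:
        raise UndefinedValueError("A/P ratio undefined at zero propionate")
    if tvfa <= 0:
        raise UndefinedValueError("molar proportions undefined at zero TVFA")
    return VFASummary(
        tvfa=tvfa,
        ap_ratio=conc["acetate"] / conc["propionate"],
        molar_proportions={a: conc[a] / tvfa for a in required},
    )


def dmd(residue_g: float, substrate_g: float) -> float:
    """Dry-matter digestibility: (1 - residue/substrate) * 100 (%)."""
    if substrate_g <= 0:
        raise InvalidInputError("substrate mass must be positive")
    if residue_g < 0:
        raise InvalidInputError("residue mass must be >= 0")
    value = (1.0 - residue_g / substrate_g) * 100.0
    if value < 0:
        logger.warning("DMD %.1f%% < 0: residue exceeds substrate", value)
    return value


def fit_standard_curve(
    quantities: Sequence[float],
    responses: Sequence[float],
    response_unit: str = "absorbance",
    quantity_unit: str = "",
) -> LinearStandardCurve:
    """Least-squares linear standard curve from calibration points."""
    q = np.asarray(quantities, dtype=float)
    r = np.asarray(responses, dtype=float)
    if q.size != r.size or q.size < 2 or np.unique(q).size < 2:
        raise DegenerateCurveError(
            "need at least two distinct standards to fit a curve")
    fit = sps.linregress(q, r)
    return LinearStandardCurve(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(min(fit.rvalue ** 2, 1.0)),
        response_unit=response_unit, quantity_unit=quantity_unit)


def colorimetric_quantity(absorbance: float,
                          curve: LinearStandardCurve) -> float:
    """Invert the standard curve: (response - intercept) / slope."""
    if curve.slope == 0:
        raise DegenerateCurveError("cannot invert a zero-slope curve")
    return (absorbance - curve.intercept) / curve.slope


def classify_amino_acids(values: Mapping[str, float]) -> AminoAcidPanel:
    """Group a 20-analyte panel into EAA / NEAA / total sums.

    Unknown analyte names are rejected; missing ones raise
    :class:`MissingDataError` listing the absent names.
    """
    unknown = sorted(set(values) - set(ALL_AA))
    if unknown:
        raise InvalidInputError(f"unknown amino-acid analytes: {unknown}")
    missing = sorted(set(ALL_AA) - set(values))
    if missing:
        raise MissingDataError(f"missing amino acids: {missing}")
    eaa = sum(values[a] for a in ESSENTIAL_AA)
    neaa = sum(values[a] for a in NONESSENTIAL_AA)
    return AminoAcidPanel(
        concentrations=dict(values),
        eaa_total=eaa, neaa_total=neaa, total=eaa + neaa)
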