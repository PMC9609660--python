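"""Absolute qPCR quantification of microbial groups.

Standards are tenfold serial dilutions of template with known copy number;
fitting Ct against log10(copies) gives the standard curve

    Ct = slope * log10(copies) + intercept,

whose slope determines the amplification efficiency
``E = 10^(-1/slope) - 1`` (slope -3.32 <=> 100%).  Unknowns are quantified by
inverting the curve, scaled from copies/reaction to copies/mL of sample by a
single dilution factor, and reported as log10 copies/mL.

Standard copy numbers themselves come from the amplicon mass:
``copies/uL = conc(ng/uL) * N_A / (length_bp * 660 g/mol/bp * 1e9)`` with the
usual 660 g/mol per double-stranded base pair.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateCurveError, InvalidInputError

__all__ = [
    "QpcrStandard", "QpcrCurve", "MicrobialCount",
    "copies_from_concentration", "fit_standard_curve", "quantify_unknown",
    "quantify_plate",
]

logger = logging.getLogger(__name__)

AVOGADRO = 6.022e23
DS_DNA_G_PER_MOL_PER_BP = 660.0


@dataclass(frozen=True)
class QpcrStandard:
    """One standard well: known copies per reaction and its Ct."""

    known_copies: float
    ct: float

    def __post_init__(self) -> None:
        if self.known_copies <= 0:
            raise InvalidInputError("known_copies must be positive")
        if self.ct <= 0:
            raise InvalidInputError("ct must be positive")


@dataclass(frozen=True)
class QpcrCurve:
    """Fitted standard curve with efficiency derived from the slope."""

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency as a fraction (1.0 == perfect doubling)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


@dataclass(frozen=True)
class MicrobialCount:
    """Quantified abundance of one microbial group in one sample."""

    group: str
    copies_per_ml: float

    @property
    def log10_copies(self) -> float:
        return math.log10(self.copies_per_ml)


def copies_from_concentration(conc_ng_per_ul: float,
                              amplicon_length_bp: float) -> float:
    """Copies per uL of a double-stranded amplicon solution."""
    if conc_ng_per_ul <= 0 or amplicon_length_bp <= 0:
        raise InvalidInputError("concentration and length must be positive")
    grams_per_ul = conc_ng_per_ul * 1e-9
    grams_per_copy = amplicon_length_bp * DS_DNA_G_PER_MOL_PER_BP / AVOGADRO
    return grams_per_ul / grams_per_copy


def fit_standard_curve(standards: Sequence[QpcrStandard],
                       r2_warn: float = 0.999) -> QpcrCurve:
    """Least-squares Ct ~ log10(copies) fit over the dilution series.

    Requires at least three standards with non-degenerate copy numbers; a
    span below two decades or an r-squared below *r2_warn* only logs a
    warning (the QC threshold is advisory, not enforced).
    """
    if len(standards) < 3:
        raise DegenerateCurveError("need at least three standards")
    logs = np.array([math.log10(s.known_copies) for s in standards])
    cts = np.array([s.ct for s in standards])
    if np.unique(logs).size < 2:
        raise DegenerateCurveError("standards have zero copy-number variance")
    if logs.max() - logs.min() < 2.0:
        logger.warning("standards span only %.2f decades (< 2)",
                       logs.max() - logs.min())
    fit = sps.linregress(logs, cts)
    curve = QpcrCurve(slope=float(fit.slope), intercept=float(fit.intercept),
                      r_squared=float(min(fit.rvalue ** 2, 1.0)))
    if curve.slope < 0 and not 0.0 < curve.efficiency <= 1.1:
        logger.warning("implausible amplification efficiency %.2f",
                       curve.efficiency)
    if curve.r_squared < r2_warn:
        logger.warning("standard-curve r^2 %.4f below %.3f",
                       curve.r_squared, r2_warn)
    return curve


def quantify_unknown(ct: float, curve: QpcrCurve, group: str = "",
                     dilution_to_per_ml: float = 1.0) -> MicrobialCount:
    """Invert the curve: copies/reaction = 10^((ct - intercept)/slope)."""
    if curve.slope >= 0:
        raise InvalidInputError("a valid assay has a negative slope")
    if dilution_to_per_ml <= 0:
        raise InvalidInputError("dilution factor must be positive")
    copies_rxn = 10.0 ** ((ct - curve.intercept) / curve.slope)
    return MicrobialCount(group=group,
                          copies_per_ml=copies_rxn * dilution_to_per_ml)


def quantify_plate(plate: pd.DataFrame) -> dict[str, object]:
    """Process a whole plate table into curves and per-sample counts.

    Expects columns ``well, target_group, role, known_copies, ct, sample_id,
    dilution_factor`` with ``role`` in {standard, unknown}.  Returns
    ``{"curves": {group: QpcrCurve}, "counts": DataFrame}`` where counts
    holds ``sample_id, target_group, copies_per_ml, log10_copies_per_ml``.
    """
    curves: dict[str, QpcrCurve] = {}
    for group, sub in plate[plate["role"] == "standard"].groupby("target_group"):
        standards = [QpcrStandard(known_copies=row.known_copies, ct=row.ct)
                     for row in sub.itertuples()]
        curves[group] = fit_standard_curve(standards)

    rows = []
    for row in plate[plate["role"] == "unknown"].itertuples():
        curve = curves.get(row.target_group)
        if curve is None:
            raise DegenerateCurveError(
                f"no standard curve for group {row.target_group!r}")
        count = quantify_unknown(row.ct, curve, group=row.target_group,
                                 dilution_to_per_ml=row.dilution_factor)
        rows.append({
            "sample_id": row.sample_id,
            "target_group": row.target_group,
            "copies_per_ml": count.copies_per_ml,
            "log10_copies_per_ml": count.log10_copies,
        })
    return {"curves": curves, "counts": pd.DataFrame(rows)}
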