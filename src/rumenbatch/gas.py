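"""Gas and methane production: blank correction, cumulation, QC rejection.

Each incubation bottle is read with a glass syringe at fixed timepoints; the
reading is the *gross* gas evolved over the interval ending at that
timepoint.  Substrate-free blank bottles measure the inoculum's own gas, and

    net interval volume = gross interval volume - mean blank interval volume.

The 72-h cumulative net volume, divided by the substrate dry mass, is the
``mL/gDM`` total reported per bottle.  CH4 volumes are obtained by scaling
each interval's gas volume by the measured CH4 fraction of that interval
(net basis by default; gross basis available since the convention used for
published CH4 volumes is ambiguous).

Bottles whose 72-h cumulative net total deviates more than a threshold
percentage from their replicate-group mean are rejected in a single pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import math

import numpy as np
import pandas as pd

from .errors import (DegenerateGroupError, InvalidInputError,
                     MissingDataError)

__all__ = [
    "GasReading", "BottleSeries", "CumulativeCurve",
    "blank_mean", "net_gas", "cumulate", "reject_deviant_bottles",
    "series_from_frame", "analyze_gas",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GasReading:
    """One syringe reading: gross volume over the interval ending at time_h."""

    time_h: float
    volume_ml: float
    ch4_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.time_h <= 0:
            raise InvalidInputError("time_h must be positive")
        if self.volume_ml < 0:
            raise InvalidInputError("volume_mL must be >= 0")
        f = self.ch4_fraction
        if f is not None and not math.isnan(f) and not 0.0 <= f <= 1.0:
            raise InvalidInputError("ch4_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class BottleSeries:
    """All readings of one bottle, sorted by time with no duplicates."""

    bottle_id: str
    treatment: str
    substrate_g: float
    readings: tuple[GasReading, ...]
    is_blank: bool = False
    run: int = 1

    def __post_init__(self) -> None:
        times = [r.time_h for r in self.readings]
        if sorted(set(times)) != times:
            raise InvalidInputError(
                f"bottle {self.bottle_id!r}: readings must be sorted by "
                "time_h without duplicates")
        if self.is_blank and self.substrate_g != 0:
            raise InvalidInputError(
                f"blank bottle {self.bottle_id!r} must have substrate_g = 0")
        if not self.is_blank and self.substrate_g < 0:
            raise InvalidInputError("substrate_g must be >= 0")

    def reading_at(self, time_h: float) -> GasReading:
        for r in self.readings:
            if r.time_h == time_h:
                return r
        raise MissingDataError(
            f"bottle {self.bottle_id!r} has no reading at {time_h} h")

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(r.time_h for r in self.readings)


@dataclass(frozen=True)
class CumulativeCurve:
    """Blank-corrected cumulative gas and CH4 series for one bottle."""

    bottle_id: str
    treatment: str
    run: int
    times_h: tuple[float, ...]
    cumulative_net_ml: tuple[float, ...]
    cumulative_ch4_ml: tuple[float, ...]
    total_gas_per_g: float
    total_ch4_per_g: float

    @property
    def total_net_ml(self) -> float:
        return self.cumulative_net_ml[-1]

    @property
    def total_ch4_ml(self) -> float:
        return self.cumulative_ch4_ml[-1]


def blank_mean(blanks: Sequence[BottleSeries], time_h: float) -> float:
    """Arithmetic mean of blank gross volumes at one timepoint."""
    vols = []
    for b in blanks:
        try:
            vols.append(b.reading_at(time_h).volume_ml)
        except MissingDataError:
            continue
    if not vols:
        raise MissingDataError(f"no blank reading available at {time_h} h")
    return float(np.mean(vols))


def net_gas(reading: GasReading, blank_mean_ml: float) -> float:
    """Gross minus mean blank volume; negatives are kept (and logged)."""
    if blank_mean_ml < 0:
        raise InvalidInputError("blank mean must be >= 0")
    net = reading.volume_ml - blank_mean_ml
    if net < 0:
        logger.warning("negative net gas (%.3f mL) at %.1f h retained",
                       net, reading.time_h)
    return net


def cumulate(
    series: BottleSeries,
    blanks: Sequence[BottleSeries] | None = None,
    timepoints_h: Sequence[float] | None = None,
    ch4_basis: Literal["net", "gross"] = "net",
) -> CumulativeCurve:
    """Blank-correct and cumulate one bottle's readings.

    ``timepoints_h`` defaults to the bottle's own reading times; when given,
    a missing reading raises :class:`MissingDataError`.  CH4 interval volume
    is the interval's net (or gross) gas times the measured CH4 fraction;
    missing fractions contribute zero CH4.
    """
    if series.is_blank:
        raise InvalidInputError("cumulate() expects a non-blank bottle")
    if series.substrate_g <= 0:
        raise InvalidInputError(
            f"bottle {series.bottle_id!r}: substrate_g must be positive on a "
            "non-blank series")
    times = tuple(timepoints_h) if timepoints_h is not None else series.times
    cum_net: list[float] = []
    cum_ch4: list[float] = []
    net_acc = ch4_acc = 0.0
    for t in times:
        reading = series.reading_at(t)
        blank = blank_mean(blanks, t) if blanks else 0.0
        net = net_gas(reading, blank)
        net_acc += net
        frac = reading.ch4_fraction
        if frac is not None and not math.isnan(frac):
            ch4_acc += (net if ch4_basis == "net" else reading.volume_ml) * frac
        cum_net.append(net_acc)
        cum_ch4.append(ch4_acc)
    return CumulativeCurve(
        bottle_id=series.bottle_id,
        treatment=series.treatment,
        run=series.run,
        times_h=times,
        cumulative_net_ml=tuple(cum_net),
        cumulative_ch4_ml=tuple(cum_ch4),
        total_gas_per_g=net_acc / series.substrate_g,
        total_ch4_per_g=ch4_acc / series.substrate_g,
    )


def reject_deviant_bottles(
    group: Sequence[CumulativeCurve],
    threshold_pct: float = 10.0,
) -> tuple[list[CumulativeCurve], pd.DataFrame]:
    """Single-pass rejection of bottles deviating from their group mean.

    A bottle is rejected when ``|total - mean| / mean * 100`` exceeds
    *threshold_pct*, where the total is the 72-h (final) cumulative net gas
    and the mean is over the whole replicate group.  Returns the retained
    curves and a per-bottle report.
    """
    if len(group) < 2:
        raise InvalidInputError("need at least two bottles to screen deviants")
    totals = np.array([c.total_net_ml for c in group])
    mean = totals.mean()
    if mean == 0:
        deviation = np.zeros_like(totals)
    else:
        deviation = np.abs(totals - mean) / abs(mean) * 100.0
    rejected = deviation > threshold_pct
    report = pd.DataFrame({
        "bottle_id": [c.bottle_id for c in group],
        "treatment": [c.treatment for c in group],
        "run": [c.run for c in group],
        "total_net_mL": totals,
        "deviation_pct": deviation,
        "rejected": rejected,
    })
    retained = [c for c, r in zip(group, rejected) if not r]
    if not retained:
        raise DegenerateGroupError(
            "every bottle in the group exceeded the rejection threshold")
    for c, d in zip(group, deviation):
        if d > threshold_pct:
            logger.warning("bottle %s rejected: %.1f%% from group mean",
                           c.bottle_id, d)
    return retained, report


# ---------------------------------------------------------------------------
# DataFrame-level front end used by the pipeline

_REQUIRED_GAS_COLUMNS = ("bottle_id", "treatment", "run", "is_blank",
                         "substrate_g", "time_h", "volume_mL")


def series_from_frame(df: pd.DataFrame) -> list[BottleSeries]:
    """Build :class:`BottleSeries` objects from a long readings table."""
    missing = [c for c in _REQUIRED_GAS_COLUMNS if c not in df.columns]
    if missing:
        raise MissingDataError(f"gas table lacks columns: {missing}")
    out = []
    for bid, sub in df.groupby("bottle_id", sort=False):
        sub = sub.sort_values("time_h")
        readings = tuple(
            GasReading(time_h=row.time_h, volume_ml=row.volume_mL,
                       ch4_fraction=getattr(row, "ch4_fraction", None))
            for row in sub.itertuples())
        out.append(BottleSeries(
            bottle_id=str(bid),
            treatment=str(sub["treatment"].iloc[0]),
            substrate_g=float(sub["substrate_g"].iloc[0]),
            readings=readings,
            is_blank=bool(sub["is_blank"].iloc[0]),
            run=int(sub["run"].iloc[0]),
        ))
    return out


def analyze_gas(
    readings: pd.DataFrame,
    threshold_pct: float = 10.0,
    ch4_basis: Literal["net", "gross"] = "net",
) -> dict[str, pd.DataFrame]:
    """Full gas stage on a long readings table.

    Blanks are pooled within each run.  Returns per-bottle totals
    (``bottles``), the rejection report (``rejections``), the per-run bottle
    averages that serve as experimental units (``units``), and the cumulative
    curves in long form (``curves``).
    """
    all_series = series_from_frame(readings)
    blanks_by_run: dict[int, list[BottleSeries]] = {}
    for s in all_series:
        if s.is_blank:
            blanks_by_run.setdefault(s.run, []).append(s)

    curves_by_group: dict[tuple[str, int], list[CumulativeCurve]] = {}
    for s in all_series:
        if s.is_blank:
            continue
        curve = cumulate(s, blanks_by_run.get(s.run), ch4_basis=ch4_basis)
        curves_by_group.setdefault((s.treatment, s.run), []).append(curve)

    retained: list[CumulativeCurve] = []
    reports = []
    for key, curves in curves_by_group.items():
        if len(curves) >= 2 and np.isfinite(threshold_pct):
            kept, report = reject_deviant_bottles(curves, threshold_pct)
        else:
            kept, report = curves, pd.DataFrame()
        retained.extend(kept)
        if not report.empty:
            reports.append(report)

    bottles = pd.DataFrame({
        "bottle_id": [c.bottle_id for c in retained],
        "treatment": [c.treatment for c in retained],
        "run": [c.run for c in retained],
        "total_gas_per_g": [c.total_gas_per_g for c in retained],
        "total_ch4_per_g": [c.total_ch4_per_g for c in retained],
        "total_net_mL": [c.total_net_ml for c in retained],
        "total_ch4_mL": [c.total_ch4_ml for c in retained],
    })
    units = (bottles
             .groupby(["treatment", "run"], as_index=False)
             [["total_gas_per_g", "total_ch4_per_g",
               "total_net_mL", "total_ch4_mL"]]
             .mean())
    curves_long = pd.concat(
        [pd.DataFrame({
            "bottle_id": c.bottle_id, "treatment": c.treatment, "run": c.run,
            "time_h": c.times_h,
            "cumulative_net_mL": c.cumulative_net_ml,
            "cumulative_ch4_mL": c.cumulative_ch4_ml,
        }) for c in retained],
        ignore_index=True) if retained else pd.DataFrame()
    rejections = (pd.concat(reports, ignore_index=True)
                  if reports else pd.DataFrame())
    return {"bottles": bottles, "units": units,
            "curves": curves_long, "rejections": rejections}
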