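"""Synthetic in vitro batch-culture experiments with known ground truth.

Every downstream stage of the pipeline (gas cumulation, hydrogen balance,
fermentation chemistry, qPCR, diversity, group statistics) consumes tabular
measurements.  This module fabricates those tables with the statistical
structure the analysis assumes:

* per-bottle interval gas readings follow a single-pool saturating curve
  ``V(t) = A * (1 - exp(-k t))`` with multiplicative lognormal noise, and
  blank bottles contribute an additive inoculum-gas drift that the analysis
  must subtract back out;
* end-point chemistry, amino-acid, and qPCR measurements are Normal around
  the treatment means, truncated at zero;
* OTU count tables are Dirichlet-multinomial around per-treatment
  compositions with a common sequencing depth.

A single global seed feeds one independent substream per table (gas,
chemistry, amino acids, qPCR, OTU), so regenerating one table never perturbs
the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import presets
from .errors import InvalidInputError

__all__ = [
    "TreatmentSpec",
    "SyntheticConfig",
    "default_treatment_specs",
    "generate_gas_timecourse",
    "generate_endpoint_tables",
    "generate_otu_table",
    "generate_experiment",
]

# Substream indices: one per generated table.
_STREAM_GAS, _STREAM_CHEM, _STREAM_AA, _STREAM_QPCR, _STREAM_OTU = range(5)

#: Default true standard curve used to emit synthetic qPCR plates:
#: Ct = slope * log10(copies/reaction) + intercept. The slope corresponds to
#: 100% amplification efficiency (-1/log10(2)).
QPCR_TRUE_SLOPE = -1.0 / np.log10(2.0)
QPCR_TRUE_INTERCEPT = 38.0
#: Copies per reaction of the tenfold standard-dilution series.
QPCR_STANDARD_COPIES = tuple(10.0 ** e for e in range(8, 2, -1))
#: Multiplicative factor from copies/reaction to copies/mL of culture fluid
#: (template dilution through extraction and plate setup).
QPCR_DILUTION_TO_PER_ML = 1.0e5


@dataclass(frozen=True)
class TreatmentSpec:
    """Ground-truth parameters for one treatment group.

    Parameters
    ----------
    label:
        Treatment name (``Control``/``SN``/``CS``/``CSN`` or user-defined).
    endpoint_means, endpoint_sds:
        Population mean and per-bottle SD for every end-point quantity
        (each VFA, pH, NH3-N, MCP, DMD, each amino acid, each microbial
        group's log10 count, measured CH4 mmol).
    gas_asymptote_ml:
        Final cumulative net gas per bottle (mL), i.e. ``A`` of the
        saturating curve.
    gas_rate_per_h:
        First-order rate constant ``k`` (1/h); must be positive.
    ch4_fraction_curve:
        CH4 volume fraction of net gas, either one value applied to every
        interval or one value per interval.
    """

    label: str
    endpoint_means: Mapping[str, float]
    endpoint_sds: Mapping[str, float]
    gas_asymptote_ml: float
    gas_rate_per_h: float
    ch4_fraction_curve: float | Sequence[float] = 0.12

    def __post_init__(self) -> None:
        if self.gas_asymptote_ml < 0:
            raise InvalidInputError("gas_asymptote_ml must be >= 0")
        if self.gas_rate_per_h <= 0:
            raise InvalidInputError("gas_rate_per_h must be positive")
        missing = set(self.endpoint_means) - set(self.endpoint_sds)
        if missing:
            raise InvalidInputError(
                f"endpoint quantities without an sd: {sorted(missing)}")
        for name, sd in self.endpoint_sds.items():
            if sd < 0:
                raise InvalidInputError(f"negative sd for {name!r}")
        fracs = np.atleast_1d(np.asarray(self.ch4_fraction_curve, dtype=float))
        if np.any((fracs < 0) | (fracs > 1)):
            raise InvalidInputError("CH4 fractions must lie in [0, 1]")

    def ch4_fractions(self, n_intervals: int) -> np.ndarray:
        fracs = np.atleast_1d(np.asarray(self.ch4_fraction_curve, dtype=float))
        if fracs.size == 1:
            return np.full(n_intervals, fracs[0])
        if fracs.size != n_intervals:
            raise InvalidInputError(
                f"ch4_fraction_curve has {fracs.size} entries for "
                f"{n_intervals} intervals")
        return fracs


@dataclass(frozen=True)
class SyntheticConfig:
    """Design of the synthetic experiment (bottles, runs, timepoints, seed)."""

    n_bottles_per_treatment: int = 5
    n_runs: int = 2
    n_blanks: int = 3
    timepoints_h: Sequence[float] = presets.TIMEPOINTS_H
    substrate_g: float = presets.SUBSTRATE_G
    liquid_volume_ml: float = presets.LIQUID_VOLUME_L * 1000.0
    seed: int = 0
    #: coefficient of variation of the multiplicative lognormal noise on each
    #: gas interval (0 disables gas noise entirely)
    gas_noise_cv: float = 0.05
    #: asymptote of the blank (inoculum-only) gas curve, mL
    blank_asymptote_ml: float = 8.0
    blank_rate_per_h: float = 0.15
    #: additive Normal noise on emitted Ct values
    ct_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints_h, dtype=float)
        if t.size == 0 or np.any(np.diff(t) <= 0) or t[0] <= 0:
            raise InvalidInputError("timepoints must be positive and strictly increasing")
        if self.substrate_g <= 0:
            raise InvalidInputError("substrate_g must be positive")
        if self.liquid_volume_ml <= 0:
            raise InvalidInputError("liquid_volume_ml must be positive")
        for name in ("n_bottles_per_treatment", "n_runs"):
            if getattr(self, name) < 1:
                raise InvalidInputError(f"{name} must be >= 1")
        if self.n_blanks < 0 or self.gas_noise_cv < 0 or self.ct_noise_sd < 0:
            raise InvalidInputError("noise/blank parameters must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one output table."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,)))


def default_treatment_specs(noise_scale: float = 1.0) -> list[TreatmentSpec]:
    """The four study treatments parameterized from the published tables.

    ``noise_scale=0`` yields a noise-free experiment whose every measurement
    equals its configured ground truth.
    """
    sds = presets.endpoint_sds(noise_scale)
    specs = []
    for trt in presets.TREATMENTS:
        gas_total = presets.GAS_TOTAL_ML_PER_G[0][trt]
        ch4_total = presets.CH4_TOTAL_ML_PER_G[0][trt]
        specs.append(TreatmentSpec(
            label=trt,
            endpoint_means=presets.endpoint_means(trt),
            endpoint_sds=sds,
            gas_asymptote_ml=gas_total * presets.SUBSTRATE_G,
            gas_rate_per_h=presets.GAS_RATE_PER_H[trt],
            ch4_fraction_curve=ch4_total / gas_total,
        ))
    return specs


def _saturating_intervals(asymptote: float, rate: float,
                          times: np.ndarray) -> np.ndarray:
    """Interval volumes of V(t) = A(1 - exp(-k t)) at the given timepoints."""
    cum = asymptote * (1.0 - np.exp(-rate * times))
    return np.diff(np.concatenate(([0.0], cum)))


def _lognormal_factors(rng: np.random.Generator, cv: float,
                       size: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise; exactly 1 when cv == 0."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def generate_gas_timecourse(
    config: SyntheticConfig,
    specs: Sequence[TreatmentSpec] | TreatmentSpec,
) -> pd.DataFrame:
    """Per-bottle interval gas readings plus matching blank bottles.

    Returns a long table with columns ``bottle_id, treatment, run, is_blank,
    substrate_g, time_h, volume_mL, ch4_fraction``.  ``volume_mL`` is the
    gross syringe reading: the bottle's own (noisy) net interval volume plus
    the true inoculum drift.  Blank rows carry the noisy drift itself and an
    empty CH4 fraction.  Deterministic under a fixed config seed.
    """
    if isinstance(specs, TreatmentSpec):
        specs = [specs]
    rng = config.rng(_STREAM_GAS)
    times = np.asarray(config.timepoints_h, dtype=float)
    n_t = times.size
    blank_true = _saturating_intervals(
        config.blank_asymptote_ml, config.blank_rate_per_h, times)

    rows: list[pd.DataFrame] = []
    for run in range(1, config.n_runs + 1):
        for spec in specs:
            fracs = spec.ch4_fractions(n_t)
            net_true = _saturating_intervals(
                spec.gas_asymptote_ml, spec.gas_rate_per_h, times)
            for b in range(1, config.n_bottles_per_treatment + 1):
                net = net_true * _lognormal_factors(rng, config.gas_noise_cv, n_t)
                rows.append(pd.DataFrame({
                    "bottle_id": f"{spec.label}-r{run}-b{b}",
                    "treatment": spec.label,
                    "run": run,
                    "is_blank": False,
                    "substrate_g": config.substrate_g,
                    "time_h": times,
                    "volume_mL": net + blank_true,
                    "ch4_fraction": fracs,
                }))
        for b in range(1, config.n_blanks + 1):
            drift = blank_true * _lognormal_factors(rng, config.gas_noise_cv, n_t)
            rows.append(pd.DataFrame({
                "bottle_id": f"BLANK-r{run}-b{b}",
                "treatment": "BLANK",
                "run": run,
                "is_blank": True,
                "substrate_g": 0.0,
                "time_h": times,
                "volume_mL": drift,
                "ch4_fraction": np.nan,
            }))
    return pd.concat(rows, ignore_index=True)


def _truncated_normal(rng: np.random.Generator, mean: np.ndarray,
                      sd: np.ndarray, size: int) -> np.ndarray:
    """Normal(mean, sd) truncated at zero; degenerates to the mean at sd=0."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (size,))
    sd = np.broadcast_to(np.asarray(sd, dtype=float), (size,))
    out = mean.copy()
    active = sd > 0
    if np.any(active):
        a = (0.0 - mean[active]) / sd[active]
        out = out.astype(float)
        out[active] = sps.truncnorm.rvs(
            a=a, b=np.inf, loc=mean[active], scale=sd[active],
            size=int(active.sum()), random_state=rng)
    return out


def _check_quantity_sets(specs: Sequence[TreatmentSpec]) -> list[str]:
    names = sorted(specs[0].endpoint_means)
    for spec in specs[1:]:
        if sorted(spec.endpoint_means) != names:
            raise InvalidInputError(
                "all treatment specs must define the same quantity set; "
                f"{spec.label!r} differs from {specs[0].label!r}")
    return names


def generate_endpoint_tables(
    config: SyntheticConfig,
    specs: Sequence[TreatmentSpec],
) -> dict[str, pd.DataFrame]:
    """End-point chemistry, amino-acid, and qPCR plate tables.

    Returns ``{"chemistry": ..., "amino_acids": ..., "qpcr": ...}``.
    Chemistry and amino-acid tables hold one row per bottle with one column
    per quantity, drawn Normal(mean, sd) truncated at 0; the chemistry table
    additionally carries ``residue_g`` back-computed from the drawn DMD.
    The qPCR table is a plate: one tenfold standard-dilution series per
    microbial group plus one unknown well per bottle x group with Ct emitted
    from the configured true curve plus Normal Ct noise.
    """
    specs = list(specs)
    if not specs:
        raise InvalidInputError("at least one treatment spec is required")
    names = _check_quantity_sets(specs)
    aa_names = [n for n in names if n in presets.AMINO_ACIDS]
    microbe_names = [n for n in names if n in presets.MICROBIAL_GROUPS]
    chem_names = [n for n in names if n not in presets.AMINO_ACIDS
                  and n not in presets.MICROBIAL_GROUPS]

    chem_rng = config.rng(_STREAM_CHEM)
    aa_rng = config.rng(_STREAM_AA)
    qpcr_rng = config.rng(_STREAM_QPCR)

    bottles = [(spec, run, b)
               for run in range(1, config.n_runs + 1)
               for spec in specs
               for b in range(1, config.n_bottles_per_treatment + 1)]
    ids = [f"{s.label}-r{r}-b{b}" for s, r, b in bottles]
    base = pd.DataFrame({
        "bottle_id": ids,
        "treatment": [s.label for s, _, _ in bottles],
        "run": [r for _, r, _ in bottles],
    })
    n = len(bottles)

    def draw(rng: np.random.Generator, quantity: str) -> np.ndarray:
        means = np.array([s.endpoint_means[quantity] for s, _, _ in bottles])
        sds = np.array([s.endpoint_sds[quantity] for s, _, _ in bottles])
        return _truncated_normal(rng, means, sds, n)

    chemistry = base.copy()
    for q in chem_names:
        chemistry[q] = draw(chem_rng, q)
    if "dmd" in chemistry:
        chemistry["substrate_g"] = config.substrate_g
        chemistry["residue_g"] = config.substrate_g * (1.0 - chemistry["dmd"] / 100.0)

    amino = base.copy()
    for q in aa_names:
        amino[q] = draw(aa_rng, q)

    qpcr_rows: list[dict] = []
    well = 1
    for group in microbe_names:
        for copies in QPCR_STANDARD_COPIES:
            ct = (QPCR_TRUE_SLOPE * np.log10(copies) + QPCR_TRUE_INTERCEPT
                  + (qpcr_rng.normal(0.0, config.ct_noise_sd)
                     if config.ct_noise_sd > 0 else 0.0))
            qpcr_rows.append({
                "well": f"W{well:03d}", "target_group": group,
                "role": "standard", "known_copies": copies, "ct": ct,
                "sample_id": "", "dilution_factor": np.nan,
            })
            well += 1
    for group in microbe_names:
        log10_per_ml = draw(qpcr_rng, group)
        for (spec, run, b), bid, lg in zip(bottles, ids, log10_per_ml):
            copies_rxn = 10.0 ** lg / QPCR_DILUTION_TO_PER_ML
            ct = (QPCR_TRUE_SLOPE * np.log10(copies_rxn) + QPCR_TRUE_INTERCEPT
                  + (qpcr_rng.normal(0.0, config.ct_noise_sd)
                     if config.ct_noise_sd > 0 else 0.0))
            qpcr_rows.append({
                "well": f"W{well:03d}", "target_group": group,
                "role": "unknown", "known_copies": np.nan, "ct": ct,
                "sample_id": bid, "dilution_factor": QPCR_DILUTION_TO_PER_ML,
            })
            well += 1
    qpcr = pd.DataFrame(qpcr_rows)
    return {"chemistry": chemistry, "amino_acids": amino, "qpcr": qpcr}


def generate_otu_table(
    config: SyntheticConfig,
    group_compositions: Mapping[str, Mapping[str, float] | Sequence[float]],
    depth: int = 10_000,
    overdispersion: float = 200.0,
    n_samples_per_group: int | None = None,
) -> pd.DataFrame:
    """Dirichlet-multinomial OTU counts with group-structured compositions.

    Parameters
    ----------
    group_compositions:
        ``{group: {taxon: probability}}`` (or plain probability sequences);
        each vector must be non-negative and sum to 1 within tolerance.
    depth:
        Reads per sample; every row sums to exactly this value.
    overdispersion:
        Dirichlet concentration. ``np.inf`` removes between-sample
        compositional variation (pure multinomial sampling).
    n_samples_per_group:
        Defaults to bottles x runs from the config.

    Returns a table with ``sample_id`` and ``group`` columns followed by one
    integer count column per taxon.
    """
    if depth <= 0:
        raise InvalidInputError("depth must be positive")
    if overdispersion <= 0:
        raise InvalidInputError("overdispersion must be positive (may be inf)")
    if n_samples_per_group is None:
        n_samples_per_group = config.n_bottles_per_treatment * config.n_runs

    groups = list(group_compositions)
    first = group_compositions[groups[0]]
    if isinstance(first, Mapping):
        taxa = list(first)
        probs = {g: np.array([group_compositions[g][t] for t in taxa], dtype=float)
                 for g in groups}
    else:
        taxa = [f"OTU{i + 1}" for i in range(len(first))]
        probs = {g: np.asarray(group_compositions[g], dtype=float) for g in groups}

    for g, p in probs.items():
        if np.any(p < 0):
            raise InvalidInputError(f"negative probabilities in group {g!r}")
        if abs(p.sum() - 1.0) > 1e-6:
            raise InvalidInputError(
                f"composition of group {g!r} sums to {p.sum():.6f}, not 1")

    rng = config.rng(_STREAM_OTU)
    rows, sample_ids, labels = [], [], []
    for g in groups:
        p = probs[g] / probs[g].sum()
        for i in range(n_samples_per_group):
            if np.isinf(overdispersion):
                theta = p
            else:
                alpha = p * overdispersion
                theta = np.zeros_like(p)
                pos = alpha > 0
                theta[pos] = rng.dirichlet(alpha[pos])
            rows.append(rng.multinomial(depth, theta))
            sample_ids.append(f"{g}-s{i + 1}")
            labels.append(g)
    counts = pd.DataFrame(np.vstack(rows), columns=taxa)
    counts.insert(0, "group", labels)
    counts.insert(0, "sample_id", sample_ids)
    return counts


def generate_experiment(
    config: SyntheticConfig,
    specs: Sequence[TreatmentSpec] | None = None,
    depth: int = 10_000,
    overdispersion: float = 200.0,
) -> dict[str, pd.DataFrame]:
    """Full synthetic experiment: gas, chemistry, amino acids, qPCR, OTU."""
    if specs is None:
        specs = default_treatment_specs()
    tables = generate_endpoint_tables(config, specs)
    tables["gas"] = generate_gas_timecourse(config, specs)
    comps = presets.group_compositions() if set(
        s.label for s in specs) == set(presets.TREATMENTS) else None
    if comps is not None:
        otu = generate_otu_table(
            config, comps, depth=depth, overdispersion=overdispersion)
        # Align community samples with incubation bottles so abundance can be
        # joined against chemistry in the correlation stage.
        n_b = config.n_bottles_per_treatment
        otu["sample_id"] = [
            f"{g}-r{i // n_b + 1}-b{i % n_b + 1}"
            for g in comps
            for i in range(n_b * config.n_runs)
        ]
        tables["otu"] = otu
    return tables
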