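"""Named parameter presets for the four-treatment nitrate/cysteamine study.

The study design: a low-protein substrate (0.5 g) incubated in buffalo rumen
fluid (20 mL) plus buffer (40 mL) for 72 h, under four treatments —

* ``Control`` — no additive
* ``SN``      — 1 mg/mL sodium nitrate
* ``CS``      — 100 ppm cysteamine hydrochloride
* ``CSN``     — both additives combined

Each treatment ran as 5 bottles x 2 runs with substrate-free blank bottles.
The dictionaries below carry the published treatment means and pooled SEMs
for gas/CH4 production, end-point fermentation chemistry, the hydrolysed
amino-acid panel (ng/mL), qPCR microbial counts (log10 copies), and the
genus-level community compositions (%), and are used to parameterize the
synthetic-data generator so that every downstream stage can be exercised
against known ground truth.

Per-bottle standard deviations are back-derived from the pooled SEMs as
``SEM * sqrt(n_runs)`` with n_runs = 2 run-averages as the experimental
unit; see docs/methods.md for the caveats of that convention.
"""

from __future__ import annotations

import math

TREATMENTS = ("Control", "SN", "CS", "CSN")

#: Essential amino acids as grouped in the study's panel (note: histidine is
#: counted as non-essential there, diverging from the textbook assignment).
ESSENTIAL_AA = (
    "isoleucine", "leucine", "lysine", "methionine",
    "phenylalanine", "threonine", "tryptophan", "valine",
)

NONESSENTIAL_AA = (
    "histidine", "alanine", "arginine", "glycine", "glutamine", "glutamate",
    "proline", "tyrosine", "serine", "aspartic_acid", "asparagine", "cysteine",
)

VFA_ACIDS = ("acetate", "propionate", "butyrate",
             "isobutyrate", "valerate", "isovalerate")

MICROBIAL_GROUPS = ("bacteria", "fungi", "protozoa", "methanogens")

#: 72-h cumulative production, mL per g substrate DM: (per-treatment means, SEM)
GAS_TOTAL_ML_PER_G = ({"Control": 117.0, "SN": 69.9, "CS": 120.0, "CSN": 71.5}, 1.85)
CH4_TOTAL_ML_PER_G = ({"Control": 14.3, "SN": 6.05, "CS": 13.8, "CSN": 5.84}, 0.23)

#: First-order rate constants (1/h) for the saturating gas curves. The source
#: study fits no kinetic model; these reproduce its qualitative time course
#: (near-plateau by 48 h, slower early rise under nitrate).
GAS_RATE_PER_H = {"Control": 0.15, "SN": 0.10, "CS": 0.15, "CSN": 0.10}

#: End-point fermentation chemistry: quantity -> ({treatment: mean}, pooled SEM).
#: VFA in mmol/L, NH3-N in mg/100 mL, MCP in mg/mL, DMD in %.
CHEMISTRY = {
    "ph":          ({"Control": 6.83, "SN": 6.90, "CS": 6.81, "CSN": 6.89}, 0.01),
    "acetate":     ({"Control": 38.3, "SN": 42.0, "CS": 39.2, "CSN": 42.9}, 0.46),
    "propionate":  ({"Control": 21.4, "SN": 19.1, "CS": 21.1, "CSN": 18.6}, 0.24),
    "butyrate":    ({"Control": 13.4, "SN": 6.94, "CS": 13.45, "CSN": 6.75}, 0.13),
    "isobutyrate": ({"Control": 2.05, "SN": 1.60, "CS": 1.99, "CSN": 1.53}, 0.03),
    "valerate":    ({"Control": 2.13, "SN": 1.61, "CS": 2.16, "CSN": 1.62}, 0.03),
    "isovalerate": ({"Control": 4.47, "SN": 3.54, "CS": 4.36, "CSN": 3.43}, 0.06),
    "nh3_n":       ({"Control": 18.7, "SN": 18.1, "CS": 18.8, "CSN": 18.5}, 0.19),
    "mcp":         ({"Control": 4.01, "SN": 4.82, "CS": 4.06, "CSN": 5.65}, 0.15),
    "dmd":         ({"Control": 43.0, "SN": 39.8, "CS": 42.0, "CSN": 37.0}, 1.92),
}

#: Measured per-bottle CH4 amount (mmol) used by the hydrogen-balance stage.
#: Back-solved from the published "H2 utilized" block, because the printed
#: CH4 volumes (mL/gDM) do not reproduce the printed utilized hydrogen under
#: any standard molar volume: M = (utilized - 2P - 3B - V) / 4 with VFA in
#: mmol at 0.06 L.
CH4_MMOL = ({"Control": 0.74805, "SN": 0.46805, "CS": 0.74435, "CSN": 0.45895},
            0.02)

#: Hydrolysed amino-acid panel (ng/mL): analyte -> ({treatment: mean}, SEM).
AMINO_ACIDS = {
    "alanine":       ({"Control": 131.0, "SN": 486.0, "CS": 321.0, "CSN": 149.0}, 38.3),
    "valine":        ({"Control": 236.0, "SN": 384.0, "CS": 286.0, "CSN": 460.0}, 23.2),
    "histidine":     ({"Control": 1119.0, "SN": 759.0, "CS": 639.0, "CSN": 378.0}, 69.3),
    "arginine":      ({"Control": 289.0, "SN": 197.0, "CS": 126.0, "CSN": 223.0}, 16.2),
    "glycine":       ({"Control": 102.0, "SN": 226.0, "CS": 161.0, "CSN": 98.2}, 14.2),
    "glutamine":     ({"Control": 57.4, "SN": 16.7, "CS": 18.9, "CSN": 10.1}, 4.84),
    "glutamate":     ({"Control": 1690.0, "SN": 3851.0, "CS": 3160.0, "CSN": 1849.0}, 233.0),
    "proline":       ({"Control": 95.7, "SN": 29.4, "CS": 44.6, "CSN": 49.2}, 6.55),
    "leucine":       ({"Control": 45.7, "SN": 214.0, "CS": 145.0, "CSN": 60.2}, 18.2),
    "lysine":        ({"Control": 40.9, "SN": 28.4, "CS": 13.4, "CSN": 11.6}, 3.83),
    "methionine":    ({"Control": 22.5, "SN": 148.0, "CS": 101.0, "CSN": 44.2}, 13.0),
    "tryptophan":    ({"Control": 26.9, "SN": 105.0, "CS": 60.6, "CSN": 25.4}, 8.56),
    "phenylalanine": ({"Control": 68.3, "SN": 314.0, "CS": 195.0, "CSN": 69.5}, 27.0),
    "threonine":     ({"Control": 125.0, "SN": 281.0, "CS": 205.0, "CSN": 107.0}, 19.1),
    "isoleucine":    ({"Control": 40.7, "SN": 209.0, "CS": 140.0, "CSN": 55.2}, 18.2),
    "tyrosine":      ({"Control": 35.0, "SN": 36.1, "CS": 36.2, "CSN": 40.9}, 1.51),
    "serine":        ({"Control": 291.0, "SN": 436.0, "CS": 295.0, "CSN": 204.0}, 24.2),
    "asparagine":    ({"Control": 44.0, "SN": 204.0, "CS": 141.0, "CSN": 59.7}, 7.05),
    "aspartic_acid": ({"Control": 20.9, "SN": 11.8, "CS": 8.91, "CSN": 12.5}, 1.44),
    "cysteine":      ({"Control": 4.00, "SN": 4.38, "CS": 4.96, "CSN": 5.40}, 0.47),
}

#: qPCR absolute counts, log10 copies per mL: group -> ({treatment: mean}, SEM).
MICROBES_LOG10 = {
    "bacteria":    ({"Control": 11.9, "SN": 12.1, "CS": 12.0, "CSN": 12.3}, 0.03),
    "fungi":       ({"Control": 9.97, "SN": 10.2, "CS": 10.1, "CSN": 10.4}, 0.04),
    "protozoa":    ({"Control": 8.13, "SN": 8.55, "CS": 8.54, "CSN": 8.52}, 0.08),
    "methanogens": ({"Control": 10.0, "SN": 10.1, "CS": 10.1, "CSN": 10.3}, 0.03),
}

#: Genus-level relative abundance (%) of the dominant rumen taxa per
#: treatment; the unlisted remainder is pooled into "Other" so each
#: composition sums to 100%.
GENUS_ABUNDANCE_PCT = {
    "Rikenellaceae_RC9_gut_group":   {"Control": 13.4, "SN": 11.3, "CS": 12.6, "CSN": 11.2},
    "Christensenellaceae_R-7_group": {"Control": 6.94, "SN": 7.61, "CS": 7.18, "CSN": 10.57},
    "norank_f__Muribaculaceae":      {"Control": 4.75, "SN": 7.71, "CS": 7.18, "CSN": 9.04},
    "NK4A214_group":                 {"Control": 6.21, "SN": 5.94, "CS": 6.61, "CSN": 7.44},
    "norank_f__F082":                {"Control": 7.54, "SN": 6.07, "CS": 6.51, "CSN": 4.15},
    "Prevotella":                    {"Control": 2.62, "SN": 6.63, "CS": 3.31, "CSN": 4.40},
    "norank_f__UCG-011":             {"Control": 4.04, "SN": 4.16, "CS": 4.41, "CSN": 4.34},
    "Succiniclasticum":              {"Control": 4.65, "SN": 3.00, "CS": 3.16, "CSN": 3.40},
    "norank_f__UCG-010":             {"Control": 2.84, "SN": 1.98, "CS": 2.75, "CSN": 1.93},
    "Campylobacter":                 {"Control": 0.01, "SN": 4.32, "CS": 0.01, "CSN": 3.15},
    "UCG-005":                       {"Control": 1.68, "SN": 1.63, "CS": 1.75, "CSN": 2.12},
    "norank_f__norank_o__WCHB1-41":  {"Control": 3.21, "SN": 1.46, "CS": 1.40, "CSN": 0.61},
    "Butyrivibrio":                  {"Control": 1.24, "SN": 1.99, "CS": 1.45, "CSN": 1.73},
    "norank_f__Eubacterium_coprostanoligenes_group":
                                     {"Control": 1.68, "SN": 1.08, "CS": 1.89, "CSN": 1.21},
    "Lachnospiraceae_NK3A20_group":  {"Control": 1.23, "SN": 1.37, "CS": 1.56, "CSN": 1.20},
}

#: Experimental-unit count behind the pooled SEMs: the mean of the five
#: bottles in each run is the unit, and there were two runs.
N_UNITS = 2

#: Incubation liquid volume in litres (20 mL rumen fluid + 40 mL buffer).
LIQUID_VOLUME_L = 0.06

SUBSTRATE_G = 0.5
TIMEPOINTS_H = (3.0, 6.0, 9.0, 12.0, 24.0, 48.0, 72.0)


def sd_from_sem(sem: float, n_units: int = N_UNITS) -> float:
    """Back-derive a per-bottle SD from a pooled SEM over *n_units* units."""
    return sem * math.sqrt(n_units)


def group_compositions() -> dict[str, dict[str, float]]:
    """Per-treatment taxon probability vectors (fractions summing to 1).

    The named genera take their tabulated percentages; everything else is
    pooled into an ``Other`` pseudo-taxon.
    """
    out: dict[str, dict[str, float]] = {}
    for trt in TREATMENTS:
        comp = {taxon: vals[trt] / 100.0
                for taxon, vals in GENUS_ABUNDANCE_PCT.items()}
        comp["Other"] = 1.0 - sum(comp.values())
        out[trt] = comp
    return out


def endpoint_means(treatment: str) -> dict[str, float]:
    """All end-point quantity means for one treatment (chemistry + CH4 mmol
    + amino acids + microbial log10 counts)."""
    means: dict[str, float] = {}
    for name, (by_trt, _) in CHEMISTRY.items():
        means[name] = by_trt[treatment]
    means["ch4_mmol"] = CH4_MMOL[0][treatment]
    for name, (by_trt, _) in AMINO_ACIDS.items():
        means[name] = by_trt[treatment]
    for name, (by_trt, _) in MICROBES_LOG10.items():
        means[name] = by_trt[treatment]
    return means


def endpoint_sds(noise_scale: float = 1.0) -> dict[str, float]:
    """Per-bottle SDs for every end-point quantity (same set for all
    treatments, derived from the pooled SEMs), scaled by *noise_scale*."""
    sds: dict[str, float] = {}
    for name, (_, sem) in CHEMISTRY.items():
        sds[name] = sd_from_sem(sem) * noise_scale
    sds["ch4_mmol"] = sd_from_sem(CH4_MMOL[1]) * noise_scale
    for name, (_, sem) in AMINO_ACIDS.items():
        sds[name] = sd_from_sem(sem) * noise_scale
    for name, (_, sem) in MICROBES_LOG10.items():
        sds[name] = sd_from_sem(sem) * noise_scale
    return sds
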