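"""End-to-end orchestration: schemas, validation, stage chaining, manifest.

The pipeline consumes up to five tabular inputs (gas readings, end-point
chemistry, amino-acid panels, a qPCR plate, an OTU table), runs the stages

    gas -> hydrogen balance -> chemistry -> amino acids -> qPCR -> diversity

and emits publication-shaped summary tables (treatment means with
significance letters, pooled SEM, ANOVA p), a Bray-Curtis matrix with a
PERMANOVA, a Venn partition, correlation screens, and a JSON run manifest
sufficient to reproduce the run.  Identical config + seed produces identical
output tables.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import chemistry as chem
from . import diversity as dv
from . import gas as gasmod
from . import hydrogen as h2mod
from . import presets, qpcr as qpcrmod, stats as statsmod, synthetic
from .errors import MissingDataError, SchemaError

__all__ = ["PipelineConfig", "validate_inputs", "run_full_pipeline",
           "simulate_experiment", "SCHEMAS"]

logger = logging.getLogger(__name__)

VFA_COLUMNS = list(presets.VFA_ACIDS)


def _bounds(lo=None, hi=None):
    return {"lo": lo, "hi": hi}


#: Per-file schemas: required columns and optional numeric bounds.
SCHEMAS: dict[str, dict] = {
    "gas": {
        "required": ["bottle_id", "treatment", "run", "is_blank",
                     "substrate_g", "time_h", "volume_mL"],
        "bounds": {"volume_mL": _bounds(lo=0.0), "time_h": _bounds(lo=1e-9),
                   "substrate_g": _bounds(lo=0.0),
                   "ch4_fraction": _bounds(lo=0.0, hi=1.0)},
    },
    "chemistry": {
        "required": ["bottle_id", "treatment", "run"] + VFA_COLUMNS,
        "bounds": {c: _bounds(lo=0.0) for c in VFA_COLUMNS},
    },
    "amino_acids": {
        "required": ["bottle_id", "treatment", "run"],
        "bounds": {a: _bounds(lo=0.0) for a in chem.ALL_AA},
    },
    "qpcr": {
        "required": ["well", "target_group", "role", "known_copies", "ct",
                     "sample_id", "dilution_factor"],
        "bounds": {"ct": _bounds(lo=1e-9)},
    },
    "otu": {
        "required": ["sample_id", "group"],
        "bounds": {},
    },
}


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run."""

    gas_path: str | None = None
    chemistry_path: str | None = None
    amino_acids_path: str | None = None
    qpcr_path: str | None = None
    otu_path: str | None = None
    out_dir: str = "results"
    liquid_volume_l: float = presets.LIQUID_VOLUME_L
    molar_volume_l_per_mol: float = h2mod.MOLAR_VOLUME_STP_L
    rejection_threshold_pct: float = 10.0
    ch4_basis: str = "net"
    n_permutations: int = 999
    posthoc: str = "tukey"
    alpha: float = 0.05
    seed: int = 1
    delimiter: str = ","

    def __post_init__(self) -> None:
        for name in ("liquid_volume_l", "molar_volume_l_per_mol",
                     "rejection_threshold_pct", "n_permutations", "alpha"):
            if getattr(self, name) <= 0:
                raise SchemaError(f"config field {name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _check_table(df: pd.DataFrame, kind: str) -> list[str]:
    schema = SCHEMAS[kind]
    problems = []
    for col in schema["required"]:
        if col not in df.columns:
            problems.append(f"missing column {col!r}")
    for col, b in schema["bounds"].items():
        if col not in df.columns:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = pd.Series(False, index=df.index)
        if b["lo"] is not None:
            bad |= vals < b["lo"]
        if b["hi"] is not None:
            bad |= vals > b["hi"]
        if bad.any():
            row = int(bad.idxmax())
            problems.append(
                f"column {col!r}, row {row}: value {df[col].iloc[row]!r} "
                "outside allowed bounds")
    if kind == "otu":
        taxa = [c for c in df.columns if c not in ("sample_id", "group")]
        for col in taxa:
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any() or (vals < 0).any() or \
                    not np.allclose(vals, vals.round()):
                problems.append(f"column {col!r}: counts must be "
                                "non-negative integers")
                break
    return problems


def validate_inputs(paths: Mapping[str, str | Path],
                    delimiter: str = ",") -> pd.DataFrame:
    """Schema-check each input file; returns a per-file pass/fail report."""
    records = []
    for kind, path in paths.items():
        if kind not in SCHEMAS:
            records.append({"kind": kind, "path": str(path), "ok": False,
                            "message": f"unknown input kind {kind!r}"})
            continue
        try:
            sep = "\t" if kind == "otu" else delimiter
            df = pd.read_csv(path, sep=sep)
        except OSError as exc:
            raise OSError(f"cannot read {kind} table at {path}: {exc}") from exc
        problems = _check_table(df, kind)
        records.append({"kind": kind, "path": str(path),
                        "ok": not problems,
                        "message": "; ".join(problems) if problems else "ok"})
    return pd.DataFrame(records)


def simulate_experiment(
    out_dir: str | Path,
    seed: int = 0,
    noise_scale: float = 1.0,
    config: synthetic.SyntheticConfig | None = None,
    depth: int = 10_000,
    overdispersion: float = 200.0,
) -> dict[str, Path]:
    """Generate a full synthetic experiment and write the input tables.

    ``noise_scale=0`` silences every noise source (end-point SDs, gas CV,
    Ct noise), producing an experiment whose measurements equal their
    configured ground truth.  A manifest records the generator parameters.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = synthetic.SyntheticConfig(
            seed=seed,
            gas_noise_cv=0.05 * noise_scale,
            ct_noise_sd=0.1 * noise_scale,
        )
    specs = synthetic.default_treatment_specs(noise_scale)
    tables = synthetic.generate_experiment(
        config, specs, depth=depth, overdispersion=overdispersion)
    paths: dict[str, Path] = {}
    for kind, name, sep in (("gas", "gas_readings.csv", ","),
                            ("chemistry", "chemistry.csv", ","),
                            ("amino_acids", "amino_acids.csv", ","),
                            ("qpcr", "qpcr_plate.csv", ","),
                            ("otu", "otu_table.tsv", "\t")):
        if kind in tables:
            path = out / name
            tables[kind].to_csv(path, sep=sep, index=False)
            paths[kind] = path
    manifest = {
        "generator": "rumenbatch.synthetic",
        "version": __version__,
        "seed": config.seed,
        "noise_scale": noise_scale,
        "config": asdict(config),
        "treatments": [s.label for s in specs],
        "ground_truth": {
            s.label: {
                "gas_asymptote_ml": s.gas_asymptote_ml,
                "gas_rate_per_h": s.gas_rate_per_h,
                "ch4_fraction": float(np.atleast_1d(
                    np.asarray(s.ch4_fraction_curve, dtype=float))[0]),
                "endpoint_means": dict(s.endpoint_means),
            } for s in specs
        },
    }
    (out / "simulation_manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    return paths


def _unit_means(per_bottle: pd.DataFrame,
                value_cols: Sequence[str]) -> pd.DataFrame:
    """Average bottles into one experimental unit per (treatment, run)."""
    return (per_bottle.groupby(["treatment", "run"], as_index=False)
            [list(value_cols)].mean())


def _h2_per_bottle(chem_df: pd.DataFrame, gas_bottles: pd.DataFrame | None,
                   cfg: PipelineConfig) -> pd.DataFrame:
    """Per-bottle hydrogen balance from VFA plus measured or derived CH4."""
    df = chem_df.copy()
    if "ch4_mmol" in df.columns:
        ch4 = df["ch4_mmol"]
    elif gas_bottles is not None and not gas_bottles.empty:
        merged = df.merge(gas_bottles[["bottle_id", "total_ch4_mL"]],
                          on="bottle_id", how="left")
        ch4 = merged["total_ch4_mL"].apply(
            lambda v: h2mod.ch4_ml_to_mmol(v, cfg.molar_volume_l_per_mol))
    else:
        raise MissingDataError(
            "hydrogen balance needs a ch4_mmol column or gas-stage CH4 totals")
    produced, utilized, recovery = [], [], []
    for i, row in df.iterrows():
        profile = {a: row[a] for a in VFA_COLUMNS}
        bal = h2mod.hydrogen_balance(profile, float(ch4.loc[i]),
                                     cfg.liquid_volume_l)
        produced.append(bal.h2_produced)
        utilized.append(bal.h2_utilized)
        recovery.append(bal.h2_recovery)
    df["h2_produced_mmol"] = produced
    df["h2_utilized_mmol"] = utilized
    df["h2_recovery_pct"] = recovery
    return df


def _chem_summaries(chem_df: pd.DataFrame) -> pd.DataFrame:
    df = chem_df.copy()
    summaries = [chem.summarize_vfa({a: row[a] for a in VFA_COLUMNS})
                 for _, row in df.iterrows()]
    df["tvfa"] = [s.tvfa for s in summaries]
    df["ap_ratio"] = [s.ap_ratio for s in summaries]
    if "dmd" not in df.columns and {"residue_g", "substrate_g"} <= set(df.columns):
        df["dmd"] = [chem.dmd(r, s)
                     for r, s in zip(df["residue_g"], df["substrate_g"])]
    return df


def run_full_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Execute every configured stage and write the result bundle.

    Returns the in-memory results keyed by output name; every table is also
    written under ``config.out_dir`` along with ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sep = config.delimiter
    results: dict[str, object] = {}
    manifest: dict[str, object] = {
        "version": __version__,
        "config": asdict(config),
        "seed": config.seed,
        "stages": {},
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }

    group_order = None
    gas_bottles = None
    if config.gas_path:
        readings = pd.read_csv(config.gas_path, sep=sep)
        gas_res = gasmod.analyze_gas(
            readings, threshold_pct=config.rejection_threshold_pct,
            ch4_basis=config.ch4_basis)  # type: ignore[arg-type]
        gas_bottles = gas_res["bottles"]
        group_order = list(dict.fromkeys(gas_bottles["treatment"]))
        results["gas_curves"] = gas_res["curves"]
        results["gas_rejections"] = gas_res["rejections"]
        gas_table = statsmod.group_summary_table(
            gas_res["units"], ["total_gas_per_g", "total_ch4_per_g"],
            alpha=config.alpha, method=config.posthoc,  # type: ignore[arg-type]
            group_order=group_order)
        results["table_gas"] = gas_table
        manifest["stages"]["gas"] = {
            "bottles_in": int(readings["bottle_id"].nunique()),
            "bottles_retained": int(len(gas_bottles)),
            "rejected": (gas_res["rejections"]["rejected"].sum()
                         if not gas_res["rejections"].empty else 0),
        }

    chem_units = None
    if config.chemistry_path:
        chem_df = pd.read_csv(config.chemistry_path, sep=sep)
        chem_df = _chem_summaries(chem_df)
        chem_df = _h2_per_bottle(chem_df, gas_bottles, config)
        value_cols = [c for c in chem_df.columns
                      if c not in ("bottle_id", "treatment", "run",
                                   "substrate_g", "residue_g", "ch4_mmol")]
        chem_units = _unit_means(chem_df, value_cols)
        if group_order is None:
            group_order = list(dict.fromkeys(chem_units["treatment"]))
        results["table_hydrogen"] = statsmod.group_summary_table(
            chem_units,
            ["h2_produced_mmol", "h2_utilized_mmol", "h2_recovery_pct"],
            alpha=config.alpha, method=config.posthoc,  # type: ignore[arg-type]
            group_order=group_order)
        ferment_cols = [c for c in value_cols if not c.startswith("h2_")]
        results["table_fermentation"] = statsmod.group_summary_table(
            chem_units, ferment_cols, alpha=config.alpha,
            method=config.posthoc,  # type: ignore[arg-type]
            group_order=group_order)
        results["chemistry_bottles"] = chem_df
        manifest["stages"]["chemistry"] = {"bottles": int(len(chem_df))}

    if config.amino_acids_path:
        aa_df = pd.read_csv(config.amino_acids_path, sep=sep)
        aa_cols = [c for c in aa_df.columns if c in chem.ALL_AA]
        panels = [chem.classify_amino_acids(
            {a: row[a] for a in aa_cols}) for _, row in aa_df.iterrows()]
        aa_df["eaa_total"] = [p.eaa_total for p in panels]
        aa_df["neaa_total"] = [p.neaa_total for p in panels]
        aa_df["total_aa"] = [p.total for p in panels]
        aa_units = _unit_means(aa_df, aa_cols + ["eaa_total", "neaa_total",
                                                 "total_aa"])
        if group_order is None:
            group_order = list(dict.fromkeys(aa_units["treatment"]))
        results["table_amino_acids"] = statsmod.group_summary_table(
            aa_units, aa_cols + ["eaa_total", "neaa_total", "total_aa"],
            alpha=config.alpha, method=config.posthoc,  # type: ignore[arg-type]
            group_order=group_order)
        manifest["stages"]["amino_acids"] = {"bottles": int(len(aa_df))}

    if config.qpcr_path:
        plate = pd.read_csv(config.qpcr_path, sep=sep)
        q = qpcrmod.quantify_plate(plate)
        counts = q["counts"]
        wide = counts.pivot(index="sample_id", columns="target_group",
                            values="log10_copies_per_ml").reset_index()
        meta = wide["sample_id"].str.extract(
            r"^(?P<treatment>.+)-r(?P<run>\d+)-b\d+$")
        wide["treatment"] = meta["treatment"]
        wide["run"] = meta["run"].astype("Int64")
        wide = wide.dropna(subset=["treatment", "run"])
        microbe_cols = [c for c in wide.columns
                        if c not in ("sample_id", "treatment", "run")]
        micro_units = _unit_means(wide, microbe_cols)
        if group_order is None:
            group_order = list(dict.fromkeys(micro_units["treatment"]))
        results["table_microbes"] = statsmod.group_summary_table(
            micro_units, microbe_cols, alpha=config.alpha,
            method=config.posthoc,  # type: ignore[arg-type]
            group_order=group_order)
        results["qpcr_curves"] = pd.DataFrame([
            {"target_group": g, "slope": c.slope, "intercept": c.intercept,
             "r_squared": c.r_squared, "efficiency": c.efficiency}
            for g, c in q["curves"].items()])
        results["qpcr_counts"] = counts
        manifest["stages"]["qpcr"] = {
            "standards": int((plate["role"] == "standard").sum()),
            "unknowns": int((plate["role"] == "unknown").sum())}

    if config.otu_path:
        otu = pd.read_csv(config.otu_path, sep="\t")
        counts = otu.drop(columns=["sample_id", "group"])
        counts.index = otu["sample_id"]
        groups = pd.Series(otu["group"].to_numpy(), index=otu["sample_id"])
        alpha_df = dv.alpha_table(counts)
        alpha_df["treatment"] = groups
        meta = alpha_df.index.to_series().str.extract(r"-r(?P<run>\d+)-b\d+$")
        alpha_df["run"] = meta["run"].fillna("1").astype(int).to_numpy()
        alpha_units = _unit_means(alpha_df.reset_index(drop=True),
                                  ["observed_otus", "shannon", "simpson",
                                   "chao1", "ace", "goods_coverage"])
        results["table_alpha"] = statsmod.group_summary_table(
            alpha_units, ["observed_otus", "shannon", "simpson", "chao1",
                          "ace", "goods_coverage"],
            alpha=config.alpha, method=config.posthoc,  # type: ignore[arg-type]
            group_order=list(dict.fromkeys(alpha_units["treatment"])))
        dm = dv.bray_curtis(counts)
        perm = dv.permanova(dm, groups.to_numpy(),
                            n_permutations=config.n_permutations,
                            seed=config.seed)
        results["bray_curtis"] = pd.DataFrame(dm.data, index=dm.ids,
                                              columns=dm.ids)
        results["permanova"] = perm
        venn = dv.otu_venn(counts, groups)
        results["venn"] = pd.DataFrame(
            [{"groups": "&".join(k), "n_otus": v} for k, v in venn.items()])
        manifest["stages"]["diversity"] = {
            "samples": int(counts.shape[0]), "otus": int(counts.shape[1]),
            "permanova_p": perm.p_value, "permanova_F": perm.pseudo_f}

        # correlation screen: genus relative abundance vs fermentation traits
        if "chemistry_bottles" in results:
            rel = counts.div(counts.sum(axis=1), axis=0)
            chem_df = results["chemistry_bottles"]  # type: ignore[assignment]
            traits = chem_df.set_index("bottle_id")[
                [c for c in ("acetate", "propionate", "butyrate", "tvfa",
                             "ap_ratio", "mcp", "h2_produced_mmol",
                             "h2_utilized_mmol", "h2_recovery_pct")
                 if c in chem_df.columns]]
            shared = rel.index.intersection(traits.index)
            if shared.size >= 4:
                corr = statsmod.spearman_matrix(rel.loc[shared],
                                                traits.loc[shared])
                results["spearman_rho"] = corr["rho"]
                results["spearman_p"] = corr["p"]
                results["spearman_stars"] = corr["stars"]

    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(out / f"{name}.csv", sep=sep,
                       index=not obj.index.equals(pd.RangeIndex(len(obj))))
    if "permanova" in results:
        perm = results["permanova"]  # type: ignore[assignment]
        (out / "permanova.json").write_text(json.dumps({
            "pseudo_F": perm.pseudo_f, "r_squared": perm.r_squared,
            "p_value": perm.p_value,
            "n_permutations": perm.n_permutations}, indent=2))
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    return results
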