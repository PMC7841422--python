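"""End-to-end orchestration: per-method predictions, evaluation, manifest.

A run reads a compound table, applies each selected prediction method to
every eligible compound (compounds missing a method's inputs are skipped
*per method* with a recorded reason, so per-method n may differ), evaluates
against observed values when present, and writes a reproducible manifest
(config, seed, package version, warning counts) next to the outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .allometry import TwoSpeciesCoefficients, single_species_scale, two_species_scale
from .cells import STRATEGIES, plasma_referenced_kp, strategy_vdss
from .errors import ConfigError, InputError, VdistWarning
from .ionization import CompoundProperties
from .kp import kp_all_tissues
from .metrics import evaluate_methods
from .physiology import BodyPhysiology, load_physiology
from .tables import CompoundTable, read_compound_table
from .vdss import VdssPrediction, erythrocyte_plasma_ratio, vdss_from_kp

__all__ = ["RunConfig", "RunResult", "predict_mechanistic", "run"]

ALLOMETRY_METHODS = ("allometry_rat", "allometry_dog", "allometry_two_species")
ALL_METHODS = ("mechanistic",) + ALLOMETRY_METHODS + STRATEGIES


@dataclass
class RunConfig:
    physiology: str = "human_70kg"
    methods: tuple[str, ...] = ("mechanistic",)
    fup_correction: bool = True
    two_species: TwoSpeciesCoefficients = field(
        default_factory=TwoSpeciesCoefficients
    )
    bpr_default: float = 1.0
    cell_kp_convention: str = "multiply"
    r2_scale: str = "log"
    seed: int = 0

    def validate(self) -> None:
        if not self.methods:
            raise ConfigError("at least one method must be selected")
        unknown = [m for m in self.methods if m not in ALL_METHODS]
        if unknown:
            raise ConfigError(f"unknown method(s): {unknown}")
        if "separate" in self.methods and "mechanistic" not in self.methods:
            raise ConfigError(
                "strategy 'separate' requires the mechanistic method to be enabled"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        if "two_species" in raw and isinstance(raw["two_species"], dict):
            raw["two_species"] = TwoSpeciesCoefficients(**raw["two_species"])
        return cls(**raw)


@dataclass
class RunResult:
    predictions: pd.DataFrame
    report: pd.DataFrame | None
    rejects: pd.DataFrame
    manifest: dict


def predict_mechanistic(
    compound: CompoundProperties,
    physiology: BodyPhysiology,
    bpr_default: float = 1.0,
    method_label: str = "mechanistic",
) -> VdssPrediction:
    """Mechanistic Kp for every tissue assembled into V_D,ss (L/kg)."""
    bpr = compound.BPR if compound.BPR is not None else bpr_default
    vec = kp_all_tissues(compound, physiology)
    ep = erythrocyte_plasma_ratio(bpr, physiology.Hct)
    return vdss_from_kp(vec, physiology, ep, method_label=method_label)


def _extra(table: CompoundTable, cid: str, column: str):
    if column not in table.extras.columns:
        return None
    value = table.extras.at[cid, column]
    return None if pd.isna(value) else float(value)


def _predict_one(
    method: str,
    comp: CompoundProperties,
    table: CompoundTable,
    phys: BodyPhysiology,
    config: RunConfig,
) -> VdssPrediction:
    cid = comp.compound_id
    if method == "mechanistic":
        return predict_mechanistic(comp, phys, config.bpr_default)
    if method in ("allometry_rat", "allometry_dog"):
        species = method.split("_")[1]
        v = _extra(table, cid, f"v_{species}")
        if v is None:
            raise InputError(f"missing v_{species}")
        fup_a = _extra(table, cid, f"fup_{species}")
        vh = single_species_scale(
            v, fup_a, comp.fup, fup_correction=config.fup_correction
        )
        return VdssPrediction(cid, method, vh, EP_ratio=0.0)
    if method == "allometry_two_species":
        v_rat, v_dog = _extra(table, cid, "v_rat"), _extra(table, cid, "v_dog")
        if v_rat is None or v_dog is None:
            raise InputError("missing v_rat or v_dog")
        vh = two_species_scale(v_rat, v_dog, config.two_species)
        return VdssPrediction(cid, method, vh, EP_ratio=0.0)
    # cell-partition strategies
    kp_fat = kp_muscle = None
    kc_a = _extra(table, cid, "kp_cell_adipocyte")
    kc_m = _extra(table, cid, "kp_cell_myocyte")
    if kc_a is not None:
        kp_fat = plasma_referenced_kp(kc_a, comp.fup, config.cell_kp_convention)
    if kc_m is not None:
        kp_muscle = plasma_referenced_kp(kc_m, comp.fup, config.cell_kp_convention)
    mech = kp_all_tissues(comp, phys) if method == "separate" else None
    return strategy_vdss(
        method, comp, phys, Kp_fat=kp_fat, Kp_muscle=kp_muscle, mechanistic_kp=mech
    )


def run(
    config: RunConfig,
    table: CompoundTable | str | Path,
    out_dir: str | Path | None = None,
) -> RunResult:
    """Execute every selected method over the table; optionally write outputs."""
    config.validate()
    if not isinstance(table, CompoundTable):
        table = read_compound_table(table)
    phys = load_physiology(config.physiology)

    predictions: list[VdssPrediction] = []
    reject_rows: list[dict] = list(table.rejects.to_dict("records"))
    warning_counts: dict[str, int] = {}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", VdistWarning)
        for method in config.methods:
            for comp in table:
                try:
                    predictions.append(
                        _predict_one(method, comp, table, phys, config)
                    )
                except InputError as exc:
                    reject_rows.append({
                        "compound_id": comp.compound_id,
                        "method_label": method,
                        "reason": str(exc),
                    })
        for w in caught:
            name = w.category.__name__
            warning_counts[name] = warning_counts.get(name, 0) + 1
    if not predictions:
        raise InputError("no method produced a prediction for any compound")

    pred_df = pd.DataFrame([
        {
            "compound_id": p.compound_id,
            "method_label": p.method_label,
            "vdss_L_per_kg": p.vdss,
        }
        for p in predictions
    ])

    observed = {}
    if "observed_vdss" in table.extras.columns:
        obs_series = table.extras["observed_vdss"].dropna()
        observed = {str(k): float(v) for k, v in obs_series.items() if v > 0}
    report = (
        evaluate_methods(pred_df, observed, r2_scale=config.r2_scale)
        if observed
        else None
    )
    rejects = pd.DataFrame(
        reject_rows, columns=["compound_id", "method_label", "reason"]
    )

    manifest = {
        "package": "vdist",
        "version": __version__,
        "seed": config.seed,
        "physiology": phys.name,
        "methods": list(config.methods),
        "config": {
            "fup_correction": config.fup_correction,
            "two_species": asdict(config.two_species),
            "bpr_default": config.bpr_default,
            "cell_kp_convention": config.cell_kp_convention,
            "r2_scale": config.r2_scale,
        },
        "n_compounds": len(table),
        "n_predictions": len(pred_df),
        "n_rejects": len(rejects),
        "warning_counts": warning_counts,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pred_df.to_csv(out / "predictions.csv", index=False)
        rejects.to_csv(out / "rejects.csv", index=False)
        if report is not None:
            report.to_csv(out / "report.csv", index=False)
            (out / "report.json").write_text(
                report.to_json(orient="records", indent=2)
            )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return RunResult(
        predictions=pred_df, report=report, rejects=rejects, manifest=manifest
    )
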