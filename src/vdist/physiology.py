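"""Reference body composition used by every partition and V_D,ss computation.

The packaged ``human_70kg`` physiology carries, per tissue, the fractional
water/lipid/phospholipid composition, acidic-phospholipid concentration,
tissue:plasma protein concentration ratios and intracellular pH of the
Rodgers–Rowland family of tissue-composition tables, together with per-kg
tissue volumes for a 70-kg reference human.  Volumes are stored in L per kg
body weight so assembled V_D,ss comes out directly in L/kg.

Users can supply their own physiology as a delimited tissue table plus a
blood-side YAML file in the documented format (see ``write_physiology`` for
a round-trippable template).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd
import yaml

from .errors import FormatError, ValidationError

_TISSUE_COLUMNS = [
    "tissue_name", "V_T", "f_EW", "f_IW", "f_NL", "f_NP",
    "AP", "RA_alb", "RA_lip", "pH_IW",
]

#: tissues every physiology must provide
REQUIRED_TISSUES = frozenset({
    "adipose", "bone", "brain", "gut", "heart", "kidney",
    "liver", "lung", "muscle", "skin", "spleen",
})


@dataclass(frozen=True)
class TissueComposition:
    """Composition of one tissue.

    Fractions are of total tissue volume; ``AP`` is the acidic-phospholipid
    concentration in mg per g tissue; ``RA_alb``/``RA_lip`` are the
    tissue:plasma concentration ratios of albumin and lipoprotein.
    """

    tissue_name: str
    f_EW: float
    f_IW: float
    f_NL: float
    f_NP: float
    AP: float
    RA_alb: float
    RA_lip: float
    pH_IW: float

    def validate(self) -> None:
        t = self.tissue_name
        for name in ("f_EW", "f_IW", "f_NL", "f_NP"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{t}: {name} = {getattr(self, name)} < 0")
        if self.f_EW + self.f_IW + self.f_NL + self.f_NP > 1 + 1e-9:
            raise ValidationError(
                f"{t}: composition fractions sum to "
                f"{self.f_EW + self.f_IW + self.f_NL + self.f_NP:.4f} > 1"
            )
        if self.AP < 0:
            raise ValidationError(f"{t}: AP = {self.AP} < 0")
        if self.RA_alb < 0 or self.RA_lip < 0:
            raise ValidationError(f"{t}: negative protein ratio")
        if not 6.0 <= self.pH_IW <= 7.6:
            raise ValidationError(f"{t}: pH_IW = {self.pH_IW} outside [6.0, 7.6]")


@dataclass(frozen=True)
class PlasmaComposition:
    """Neutral-lipid and neutral-phospholipid volume fractions of plasma."""

    f_NL: float
    f_NP: float


@dataclass(frozen=True)
class BloodCellComposition:
    """Erythrocyte composition used to calibrate acidic-phospholipid affinity."""

    f_IW: float
    f_NL: float
    f_NP: float
    AP: float
    pH: float


@dataclass(frozen=True)
class BodyPhysiology:
    """Tissue compositions + volumes and the blood-side reference values."""

    tissues: dict[str, TissueComposition]
    volumes: dict[str, float]          # L per kg body weight, keyed like tissues
    V_P: float                         # plasma volume, L/kg
    V_E: float                         # erythrocyte volume, L/kg
    Hct: float
    pH_P: float
    plasma: PlasmaComposition
    blood_cell: BloodCellComposition
    name: str = "custom"

    @property
    def total_tissue_volume(self) -> float:
        return float(sum(self.volumes.values()))

    @property
    def total_body_volume(self) -> float:
        """Sum of tissue, plasma and erythrocyte volumes (L/kg)."""
        return self.total_tissue_volume + self.V_P + self.V_E

    def validate(self) -> None:
        for t in self.tissues.values():
            t.validate()
        if set(self.tissues) != set(self.volumes):
            raise ValidationError("tissue composition and volume keys differ")
        missing = REQUIRED_TISSUES - set(self.tissues)
        if missing:
            raise ValidationError(f"missing required tissues: {sorted(missing)}")
        if not 0 < self.Hct < 1:
            raise ValidationError(f"Hct = {self.Hct} outside (0, 1)")
        expected_VE = self.Hct / (1 - self.Hct) * self.V_P
        if abs(self.V_E - expected_VE) > 1e-3 * expected_VE:
            raise ValidationError(
                f"V_E = {self.V_E} inconsistent with Hct/(1-Hct)*V_P = {expected_VE:.6f}"
            )
        if not 0.9 <= self.total_body_volume <= 1.1:
            raise ValidationError(
                f"total body volume {self.total_body_volume:.3f} L/kg not within "
                "10% of 1.0"
            )
        for tissue, v in self.volumes.items():
            if v < 0:
                raise ValidationError(f"{tissue}: V_T = {v} < 0")


def _packaged(filename: str) -> Path:
    return Path(str(importlib.resources.files("vdist").joinpath("data", filename)))


def load_physiology(
    source: str | Path = "human_70kg",
    blood: str | Path | None = None,
) -> BodyPhysiology:
    """Load and validate a physiology.

    Parameters
    ----------
    source
        Either the packaged table name ``"human_70kg"`` or a path to a tissue
        CSV in the documented format.
    blood
        Path to the blood-side YAML; defaults to the packaged human values
        when ``source`` is a packaged name, and is required alongside a
        custom tissue table unless the packaged blood values are wanted.
    """
    if isinstance(source, str) and source == "human_70kg":
        tissue_path = _packaged("human_70kg_tissues.csv")
        blood_path = _packaged("human_70kg_blood.yaml") if blood is None else Path(blood)
        name = "human_70kg"
    else:
        tissue_path = Path(source)
        blood_path = _packaged("human_70kg_blood.yaml") if blood is None else Path(blood)
        name = tissue_path.stem

    try:
        df = pd.read_csv(tissue_path)
    except FileNotFoundError:
        raise FormatError(f"physiology table not found: {tissue_path}") from None
    missing = [c for c in _TISSUE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"physiology table missing column(s): {missing}")

    with open(blood_path) as fh:
        bl = yaml.safe_load(fh)

    tissues: dict[str, TissueComposition] = {}
    volumes: dict[str, float] = {}
    for row in df.itertuples(index=False):
        comp = TissueComposition(
            tissue_name=str(row.tissue_name),
            f_EW=float(row.f_EW), f_IW=float(row.f_IW),
            f_NL=float(row.f_NL), f_NP=float(row.f_NP),
            AP=float(row.AP), RA_alb=float(row.RA_alb),
            RA_lip=float(row.RA_lip), pH_IW=float(row.pH_IW),
        )
        tissues[comp.tissue_name] = comp
        volumes[comp.tissue_name] = float(row.V_T)

    phys = BodyPhysiology(
        tissues=tissues,
        volumes=volumes,
        V_P=float(bl["V_P"]),
        V_E=float(bl["V_E"]),
        Hct=float(bl["Hct"]),
        pH_P=float(bl["pH_P"]),
        plasma=PlasmaComposition(
            f_NL=float(bl["plasma"]["f_NL"]), f_NP=float(bl["plasma"]["f_NP"])
        ),
        blood_cell=BloodCellComposition(
            f_IW=float(bl["blood_cell"]["f_IW"]),
            f_NL=float(bl["blood_cell"]["f_NL"]),
            f_NP=float(bl["blood_cell"]["f_NP"]),
            AP=float(bl["blood_cell"]["AP"]),
            pH=float(bl["blood_cell"]["pH"]),
        ),
        name=name,
    )
    phys.validate()
    return phys


def write_physiology(
    phys: BodyPhysiology, tissue_path: str | Path, blood_path: str | Path
) -> None:
    """Write a physiology back to the documented two-file format."""
    rows = []
    for name, comp in phys.tissues.items():
        d = asdict(comp)
        d["V_T"] = phys.volumes[name]
        rows.append(d)
    pd.DataFrame(rows)[_TISSUE_COLUMNS].to_csv(tissue_path, index=False)
    blood = {
        "version": 1,
        "V_P": phys.V_P, "V_E": phys.V_E, "Hct": phys.Hct, "pH_P": phys.pH_P,
        "plasma": asdict(phys.plasma),
        "blood_cell": {
            "f_IW": phys.blood_cell.f_IW, "f_NL": phys.blood_cell.f_NL,
            "f_NP": phys.blood_cell.f_NP, "AP": phys.blood_cell.AP,
            "pH": phys.blood_cell.pH,
        },
    }
    with open(blood_path, "w") as fh:
        yaml.safe_dump(blood, fh, sort_keys=False)
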