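"""Adipocyte/myocyte cell-partition arithmetic and tissue-level strategies.

Cultured-cell uptake assays report analyte/internal-standard peak-area
ratios in the cell lysate and in the (corrected) medium, plus the protein
content of the well.  The intracellular partition is

    Kp_cell = (AR_cells * V_lysate / V_cell) / AR_medium,
    V_cell  = 6.5 µl per mg protein.

Plasma-referenced tissue Kp assumes the medium is protein-free, so the
cell-to-unbound partition converts with the plasma unbound fraction:
``Kp_tissue = Kp_cell * fup`` (the inverse convention, division, is
selectable for labs that reference the other way).

Five strategies turn measured fat/muscle cell partitioning into whole-body
V_D,ss: use the adipocyte value for fat only, the myocyte value for muscle
only, both (others fixed at 1), both with their average for the remaining
tissues, or both on top of mechanistic Kp for every other tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean
from typing import Iterable

from .errors import AnalyticalFailureError, DomainError, InputError
from .ionization import CompoundProperties
from .kp import KpVector
from .physiology import BodyPhysiology
from .vdss import VdssPrediction, erythrocyte_plasma_ratio, vdss_from_kp

__all__ = [
    "AssayReadout",
    "CellKp",
    "STRATEGIES",
    "cell_volume",
    "intracellular_kp",
    "plasma_referenced_kp",
    "strategy_vdss",
]

MICROLITRE_PER_MG_PROTEIN = 6.5
DEFAULT_LYSATE_UL = 150.0

STRATEGIES = ("adipocyte_only", "myocyte_only", "combined", "average", "separate")


@dataclass(frozen=True)
class AssayReadout:
    """One replicate well of a cell-uptake assay."""

    compound_id: str
    cell_type: str                      # "adipocyte" or "myocyte"
    area_ratio_cells: float
    area_ratio_medium: float
    protein_mg: float
    V_lysate: float = DEFAULT_LYSATE_UL  # µl
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.cell_type not in ("adipocyte", "myocyte"):
            raise DomainError(f"unknown cell_type {self.cell_type!r}")
        if self.area_ratio_cells < 0 or self.area_ratio_medium < 0:
            raise DomainError("peak-area ratios must be >= 0")
        if self.protein_mg <= 0:
            raise DomainError(f"protein_mg = {self.protein_mg} must be > 0")


@dataclass(frozen=True)
class CellKp:
    compound_id: str
    Kp_cell_adipocyte: float | None = None
    Kp_cell_myocyte: float | None = None
    Kp_fat: float | None = None
    Kp_muscle: float | None = None


def cell_volume(protein_mg: float) -> float:
    """Cell volume in µl, assuming 6.5 µl per mg protein."""
    if protein_mg <= 0:
        raise DomainError(f"protein_mg = {protein_mg} must be > 0")
    return MICROLITRE_PER_MG_PROTEIN * protein_mg


def intracellular_kp(readouts: AssayReadout | Iterable[AssayReadout]) -> float:
    """Cell-to-medium partition; replicates averaged after per-well Kp."""
    if isinstance(readouts, AssayReadout):
        readouts = [readouts]
    kps = []
    for r in readouts:
        if r.area_ratio_medium <= 0:
            raise AnalyticalFailureError(
                f"{r.compound_id} ({r.cell_type}, replicate {r.replicate}): "
                "zero medium signal; compound flagged for exclusion"
            )
        amount_in_cells = r.area_ratio_cells * r.V_lysate
        c_cell = amount_in_cells / cell_volume(r.protein_mg)
        kps.append(c_cell / r.area_ratio_medium)
    if not kps:
        raise InputError("no readouts supplied")
    return fmean(kps)


def plasma_referenced_kp(
    Kp_cell: float, fup: float, convention: str = "multiply"
) -> float:
    """Convert a cell-to-medium partition to a plasma-referenced tissue Kp.

    ``convention="multiply"`` (default) assumes a protein-free medium, so
    the measured partition is cell-to-unbound and ``Kp_tissue = Kp_cell*fup``;
    ``"divide"`` applies the inverse referencing.
    """
    if not 0.0 < fup <= 1.0:
        raise InputError(f"fup = {fup} required in (0, 1] for plasma referencing")
    if convention == "multiply":
        return Kp_cell * fup
    if convention == "divide":
        return Kp_cell / fup
    raise InputError(f"unknown plasma-referencing convention {convention!r}")


def strategy_vdss(
    strategy: str,
    compound: CompoundProperties,
    physiology: BodyPhysiology,
    Kp_fat: float | None = None,
    Kp_muscle: float | None = None,
    mechanistic_kp: KpVector | None = None,
) -> VdssPrediction:
    """Whole-body V_D,ss from measured fat/muscle Kp under one strategy."""
    if strategy not in STRATEGIES:
        raise InputError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    if strategy in ("adipocyte_only", "combined", "average", "separate") and Kp_fat is None:
        raise InputError(f"strategy {strategy!r} requires Kp_fat")
    if strategy in ("myocyte_only", "combined", "average", "separate") and Kp_muscle is None:
        raise InputError(f"strategy {strategy!r} requires Kp_muscle")
    if strategy == "separate" and mechanistic_kp is None:
        raise InputError("strategy 'separate' requires a mechanistic Kp vector")

    def others_default() -> float:
        if strategy == "average":
            return 0.5 * (Kp_fat + Kp_muscle)
        return 1.0

    kp: dict[str, float] = {}
    for tissue in physiology.tissues:
        if tissue == "adipose" and strategy != "myocyte_only":
            kp[tissue] = Kp_fat
        elif tissue == "muscle" and strategy != "adipocyte_only":
            kp[tissue] = Kp_muscle
        elif strategy == "separate":
            kp[tissue] = mechanistic_kp[tissue]
        else:
            kp[tissue] = others_default()

    bpr = compound.BPR if compound.BPR is not None else 1.0
    ep = erythrocyte_plasma_ratio(bpr, physiology.Hct)
    vector = KpVector(
        compound_id=compound.compound_id,
        kp=kp,
        Ka_AP=mechanistic_kp.Ka_AP if mechanistic_kp is not None else 0.0,
        Ka_PR=mechanistic_kp.Ka_PR if mechanistic_kp is not None else 0.0,
    )
    return vdss_from_kp(vector, physiology, ep, method_label=strategy)
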