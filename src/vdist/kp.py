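"""Mechanistic tissue:plasma partition coefficients (unified continuous form).

Tissue-to-plasma-water partitioning is modelled as a sum of five terms that
are present for every compound regardless of its pKa — extracellular water,
pH-partitioned intracellular water, neutral lipid + neutral phospholipid,
acidic-phospholipid binding of the cationic species, and extracellular
protein binding:

    Kpu_T = f_EW
          + ((1 + X_T + Z_T) / (1 + X_P + Z_P)) * f_IW
          + (P * f_NL + (0.3 P + 0.7) * f_NP) / (1 + X_P + Z_P)
          + Ka_AP * AP * X_T / (1 + X_P + Z_P)
          + Ka_PR * RA

with ``P = 10^logP`` (the adipose neutral-lipid term uses ``10^logD74``),
``X``/``Z`` the cationic/anionic Henderson–Hasselbalch ratios at the
relevant pH, ``RA`` the lipoprotein ratio for bases and the albumin ratio
otherwise.  Terms whose driver is zero vanish naturally, so a single
equation covers acids, bases, neutrals and zwitterions continuously — there
is no pKa-7 switch between equation sets.

The two affinity constants are calibrated per compound from routinely
measured quantities: ``Ka_PR`` from the plasma unbound fraction fup, and
``Ka_AP`` from the blood-to-plasma concentration ratio via the erythrocyte
partition (erythrocytes are the one cell whose drug content is measurable
from whole blood).  Plasma-referenced coefficients follow as
``Kp_T = fup * Kpu_T``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import DomainError, FloorWarning
from .ionization import BASE, CompoundProperties, species_ratios
from .physiology import BodyPhysiology, PlasmaComposition, TissueComposition

__all__ = [
    "KpVector",
    "calibrate_ka_pr",
    "calibrate_ka_ap",
    "kpu_tissue",
    "kp_all_tissues",
]


@dataclass(frozen=True)
class KpVector:
    """Plasma-referenced Kp per tissue plus the calibrated affinity constants."""

    compound_id: str
    kp: dict[str, float]
    Ka_AP: float
    Ka_PR: float

    def __getitem__(self, tissue: str) -> float:
        return self.kp[tissue]

    def scaled(self, factor: float) -> "KpVector":
        return KpVector(
            compound_id=self.compound_id,
            kp={t: v * factor for t, v in self.kp.items()},
            Ka_AP=self.Ka_AP,
            Ka_PR=self.Ka_PR,
        )


def _neutral_lipid_term(P: float, f_NL: float, f_NP: float, P_nl: float | None = None) -> float:
    """Neutral lipid + neutral phospholipid binding (numerator only).

    ``P_nl`` overrides the partition coefficient used for the neutral-lipid
    term (the adipose convention substitutes 10^logD74 there).
    """
    if P_nl is None:
        P_nl = P
    return P_nl * f_NL + (0.3 * P + 0.7) * f_NP


def calibrate_ka_pr(fup: float, logP: float, plasma: PlasmaComposition) -> float:
    """Protein-affinity constant from the plasma mass balance.

    In plasma the protein ratio is 1 by definition, so
    ``1/fup = 1 + lipid binding + Ka_PR`` and

        Ka_PR = max(0, 1/fup − 1 − (P f_NL,P + (0.3 P + 0.7) f_NP,P))
    """
    if not 0.0 < fup <= 1.0:
        raise DomainError(f"fup = {fup} outside (0, 1]")
    P = 10.0 ** logP
    ka = 1.0 / fup - 1.0 - _neutral_lipid_term(P, plasma.f_NL, plasma.f_NP)
    if ka < 0.0:
        warnings.warn(
            f"Ka_PR calibration negative ({ka:.3g}); floored at 0 "
            "(plasma lipid binding already accounts for 1/fup - 1)",
            FloorWarning,
            stacklevel=2,
        )
        ka = 0.0
    return ka


def kpu_blood_cells(BPR: float, fup: float, Hct: float) -> float:
    """Blood-cell-to-plasma-water partition from BPR:
    ``Kpu_BC = (BPR − (1 − Hct)) / (Hct · fup)``."""
    if not 0.0 < Hct < 1.0:
        raise DomainError(f"Hct = {Hct} outside (0, 1)")
    if BPR < 0:
        raise DomainError(f"BPR = {BPR} < 0")
    if not 0.0 < fup <= 1.0:
        raise DomainError(f"fup = {fup} outside (0, 1]")
    return (BPR - (1.0 - Hct)) / (Hct * fup)


def calibrate_ka_ap(
    compound: CompoundProperties, physiology: BodyPhysiology
) -> float:
    """Acidic-phospholipid affinity calibrated from erythrocyte partitioning.

    The measured BPR fixes the blood-cell partition ``Kpu_BC``; subtracting
    the water and neutral-lipid contributions of the erythrocyte and
    attributing the remainder to binding of the cationic species on the
    cell's acidic phospholipids gives Ka_AP.  Compounds with no cationic
    species at erythrocyte pH carry no information about this affinity and
    return 0.
    """
    bc = physiology.blood_cell
    BPR = compound.BPR if compound.BPR is not None else 1.0
    X_BC, Z_BC = compound.species_ratios(bc.pH)
    if X_BC == 0.0:
        return 0.0
    kpu_bc = kpu_blood_cells(BPR, compound.fup, physiology.Hct)
    if kpu_bc <= 0.0:
        warnings.warn(
            f"{compound.compound_id}: BPR = {BPR} at or below the physical "
            f"floor 1 - Hct = {1 - physiology.Hct:.2f}; Ka_AP set to 0",
            FloorWarning,
            stacklevel=2,
        )
        return 0.0
    X_P, Z_P = compound.species_ratios(physiology.pH_P)
    D_P = 1.0 + X_P + Z_P
    P = 10.0 ** compound.logP
    residual = (
        kpu_bc
        - ((1.0 + X_BC + Z_BC) / D_P) * bc.f_IW
        - _neutral_lipid_term(P, bc.f_NL, bc.f_NP) / D_P
    )
    ka = residual * D_P / (bc.AP * X_BC)
    if ka < 0.0:
        warnings.warn(
            f"{compound.compound_id}: Ka_AP calibration negative ({ka:.3g}); "
            "floored at 0",
            FloorWarning,
            stacklevel=2,
        )
        ka = 0.0
    return ka


def kpu_tissue(
    compound: CompoundProperties,
    tissue: TissueComposition,
    Ka_AP: float,
    Ka_PR: float,
    plasma_pH: float = 7.4,
) -> float:
    """Tissue-to-plasma-water partition coefficient (five-term sum above)."""
    X_T, Z_T = compound.species_ratios(tissue.pH_IW)
    X_P, Z_P = compound.species_ratios(plasma_pH)
    D_P = 1.0 + X_P + Z_P
    P = 10.0 ** compound.logP
    # adipose neutral-lipid binding follows the distribution coefficient
    P_nl = 10.0 ** compound.logD74 if tissue.tissue_name == "adipose" else P
    RA = tissue.RA_lip if compound.ionization_class == BASE else tissue.RA_alb
    return (
        tissue.f_EW
        + ((1.0 + X_T + Z_T) / D_P) * tissue.f_IW
        + _neutral_lipid_term(P, tissue.f_NL, tissue.f_NP, P_nl=P_nl) / D_P
        + Ka_AP * tissue.AP * X_T / D_P
        + Ka_PR * RA
    )


def kp_all_tissues(
    compound: CompoundProperties, physiology: BodyPhysiology
) -> KpVector:
    """Calibrate both affinity constants and evaluate Kp for every tissue."""
    ka_pr = calibrate_ka_pr(compound.fup, compound.logP, physiology.plasma)
    ka_ap = calibrate_ka_ap(compound, physiology)
    kp = {
        name: compound.fup
        * kpu_tissue(compound, tissue, ka_ap, ka_pr, physiology.pH_P)
        for name, tissue in physiology.tissues.items()
    }
    return KpVector(compound_id=compound.compound_id, kp=kp, Ka_AP=ka_ap, Ka_PR=ka_pr)
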