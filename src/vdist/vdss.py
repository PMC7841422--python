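"""Whole-body steady-state volume of distribution from a Kp vector.

Plasma-referenced assembly:

    V_D,ss = V_P + V_E * (E/P) + sum_T Kp_T * V_T        [L/kg]

where ``E/P = (BPR + Hct − 1)/Hct`` converts the erythrocyte compartment to
plasma reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import ConsistencyError, DomainError, FloorWarning
from .kp import KpVector
from .physiology import BodyPhysiology

__all__ = ["VdssPrediction", "erythrocyte_plasma_ratio", "vdss_from_kp"]


@dataclass(frozen=True)
class VdssPrediction:
    compound_id: str
    method_label: str
    vdss: float          # L/kg
    EP_ratio: float


def erythrocyte_plasma_ratio(BPR: float, Hct: float) -> float:
    """``E/P = (BPR + Hct − 1)/Hct``, floored at 0 when BPR < 1 − Hct."""
    if not 0.0 < Hct < 1.0:
        raise DomainError(f"Hct = {Hct} outside (0, 1)")
    if BPR < 0:
        raise DomainError(f"BPR = {BPR} < 0")
    # association ((BPR - 1) + Hct)/Hct keeps the BPR = 1 reference point
    # exactly at E/P = 1 in floating point
    ep = ((BPR - 1.0) + Hct) / Hct
    if ep < 0.0:
        warnings.warn(
            f"E/P = {ep:.3g} < 0 for BPR = {BPR} (below the physical floor "
            f"1 - Hct = {1 - Hct:.2f}); floored at 0",
            FloorWarning,
            stacklevel=2,
        )
        ep = 0.0
    return ep


def vdss_from_kp(
    kp: KpVector,
    physiology: BodyPhysiology,
    EP_ratio: float,
    method_label: str = "mechanistic",
) -> VdssPrediction:
    """Assemble V_D,ss (L/kg) from per-tissue Kp and the E/P ratio."""
    missing = set(physiology.tissues) - set(kp.kp)
    if missing:
        raise ConsistencyError(
            f"Kp vector for {kp.compound_id} missing tissue(s): {sorted(missing)}"
        )
    if EP_ratio < 0:
        raise DomainError(f"E/P = {EP_ratio} < 0")
    vdss = (
        physiology.V_P
        + physiology.V_E * EP_ratio
        + sum(kp.kp[t] * physiology.volumes[t] for t in physiology.tissues)
    )
    return VdssPrediction(
        compound_id=kp.compound_id,
        method_label=method_label,
        vdss=float(vdss),
        EP_ratio=float(EP_ratio),
    )
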