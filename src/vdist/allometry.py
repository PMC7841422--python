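"""Interspecies scaling of V_D,ss to human.

Single-species scaling optionally corrects for the species difference in
plasma protein binding via the fup ratio (distribution of the unbound drug
is assumed conserved across species):

    V_human = V_animal * (fup_human / fup_animal)

Two-species scaling combines rat and dog volumes log-linearly:

    V_human = 10 ** (a0 + a_r * log10 V_rat + a_d * log10 V_dog)

The default coefficients (a0 = 0, a_r = a_d = 0.5) take the unweighted
geometric mean; published regression coefficients can be supplied instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError, InputError

__all__ = [
    "AllometryInputs",
    "TwoSpeciesCoefficients",
    "single_species_scale",
    "two_species_scale",
]


@dataclass(frozen=True)
class AllometryInputs:
    V_rat: float | None = None
    fup_rat: float | None = None
    V_dog: float | None = None
    fup_dog: float | None = None
    fup_human: float | None = None

    def __post_init__(self) -> None:
        for name in ("V_rat", "V_dog", "fup_rat", "fup_dog", "fup_human"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise DomainError(f"{name} = {v} must be > 0")
        for name in ("fup_rat", "fup_dog", "fup_human"):
            v = getattr(self, name)
            if v is not None and v > 1:
                raise DomainError(f"{name} = {v} > 1")


@dataclass(frozen=True)
class TwoSpeciesCoefficients:
    """Log10-space combination weights; defaults give the geometric mean."""

    a0: float = 0.0
    a_r: float = 0.5
    a_d: float = 0.5

    def __post_init__(self) -> None:
        if self.a_r + self.a_d <= 0:
            raise DomainError("two-species weights must satisfy a_r + a_d > 0")


def single_species_scale(
    V_animal: float,
    fup_animal: float | None = None,
    fup_human: float | None = None,
    fup_correction: bool = True,
) -> float:
    """Scale one species' V_D,ss to human, optionally fup-corrected."""
    if V_animal <= 0:
        raise DomainError(f"V_animal = {V_animal} must be > 0")
    if not fup_correction:
        return float(V_animal)
    if fup_animal is None or fup_human is None:
        raise InputError("fup correction requested but fup values are missing")
    if not 0 < fup_animal <= 1 or not 0 < fup_human <= 1:
        raise DomainError("fup values must lie in (0, 1]")
    return float(V_animal * fup_human / fup_animal)


def two_species_scale(
    V_rat: float,
    V_dog: float,
    coeffs: TwoSpeciesCoefficients | None = None,
) -> float:
    """Combine rat and dog V_D,ss log-linearly into a human prediction."""
    if V_rat <= 0 or V_dog <= 0:
        raise DomainError("animal volumes must be > 0")
    c = coeffs if coeffs is not None else TwoSpeciesCoefficients()
    return float(
        10.0 ** (c.a0 + c.a_r * math.log10(V_rat) + c.a_d * math.log10(V_dog))
    )
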