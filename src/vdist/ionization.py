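"""Henderson–Hasselbalch species ratios, ionization classes and log D.

The partition model treats every compound with one optional acidic and one
optional basic pKa.  At a given pH the cationic/neutral ratio is
``X = 10^(pKa_basic − pH)`` and the anionic/neutral ratio is
``Z = 10^(pH − pKa_acidic)``; the un-ionized fraction is ``1/(1 + X + Z)``.
All logarithms are base 10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import DomainError

#: ionization class labels
ACID, BASE, NEUTRAL, ZWITTERION = "acid", "base", "neutral", "zwitterion"

# classification thresholds: an acidic pKa below plasma pH 7.4 makes the
# anion relevant; a basic pKa above 6.0 makes the cation relevant
_ACID_PKA_MAX = 7.4
_BASE_PKA_MIN = 6.0


def species_ratios(
    pKa_acidic: float | None, pKa_basic: float | None, pH: float
) -> tuple[float, float]:
    """Return ``(X, Z)``: cationic and anionic to neutral species ratios."""
    if not 0.0 <= pH <= 14.0:
        raise DomainError(f"pH = {pH} outside [0, 14]")
    X = 10.0 ** (pKa_basic - pH) if pKa_basic is not None else 0.0
    Z = 10.0 ** (pH - pKa_acidic) if pKa_acidic is not None else 0.0
    return X, Z


def classify_ionization(
    pKa_acidic: float | None, pKa_basic: float | None
) -> str:
    """Assign acid / base / neutral / zwitterion from the pKa values.

    A compound counts as acidic when its acidic pKa lies below plasma pH
    (7.4) and as basic when its basic pKa exceeds 6.0; both together give a
    zwitterion, neither gives neutral.
    """
    acidic = pKa_acidic is not None and pKa_acidic < _ACID_PKA_MAX
    basic = pKa_basic is not None and pKa_basic > _BASE_PKA_MIN
    if acidic and basic:
        return ZWITTERION
    if acidic:
        return ACID
    if basic:
        return BASE
    return NEUTRAL


def logd_from_logp(
    logP: float,
    pKa_acidic: float | None,
    pKa_basic: float | None,
    pH: float = 7.4,
) -> float:
    """Distribution coefficient ``logD = logP − log10(1 + X + Z)`` at ``pH``."""
    if not math.isfinite(logP):
        raise DomainError(f"logP = {logP} is not finite")
    X, Z = species_ratios(pKa_acidic, pKa_basic, pH)
    return logP - math.log10(1.0 + X + Z)


@dataclass
class CompoundProperties:
    """Physicochemical inputs for one compound.

    ``logD74`` is derived from ``logP`` and the pKa values when not supplied.
    ``provenance`` records, per field, whether the value was measured,
    supplied as a prediction, or defaulted; assay-limit clipping only touches
    predicted fields.
    """

    compound_id: str
    logP: float
    fup: float
    BPR: float | None = None
    logD74: float | None = None
    pKa_acidic: float | None = None
    pKa_basic: float | None = None
    ionization_class: str | None = None
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ionization_class is None:
            self.ionization_class = classify_ionization(
                self.pKa_acidic, self.pKa_basic
            )
        if self.logD74 is None:
            self.logD74 = logd_from_logp(self.logP, self.pKa_acidic, self.pKa_basic)
            self.provenance.setdefault("logD74", "derived")

    def species_ratios(self, pH: float) -> tuple[float, float]:
        return species_ratios(self.pKa_acidic, self.pKa_basic, pH)
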