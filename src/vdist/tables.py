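"""Compound-table I/O, assay-limit clipping and the CHI -> ChromlogD transform.

The compound table is delimited text (comma by default, tab accepted) with a
header row.  Recognised columns (case-insensitive):

    compound_id, logp, logd74, pka_acidic, pka_basic, fup, bpr,
    observed_vdss, chi_ph74, kp_cell_adipocyte, kp_cell_myocyte,
    v_rat, fup_rat, v_dog, fup_dog, smiles

Missing values are empty cells.  Rows that fail validation are collected
into a rejects list instead of aborting the batch.  ``fup`` supplied as a
percentage (> 1) is auto-detected and divided by 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ClipWarning, FormatError, InputError, ValidationError
from .ionization import CompoundProperties

__all__ = [
    "ASSAY_LIMITS",
    "CompoundTable",
    "chromlogd_from_chi",
    "clip_to_assay_limits",
    "read_compound_table",
    "write_predictions",
]

#: typical assay limits predicted inputs are clipped to
ASSAY_LIMITS = {
    "fup": (0.001, 1.0),
    "BPR": (0.0, 200.0),
    "logP": (-3.0, 10.0),
    "logD74": (-3.0, 10.0),
}

_OPTIONAL_COLUMNS = (
    "observed_vdss", "chi_ph74", "kp_cell_adipocyte", "kp_cell_myocyte",
    "v_rat", "fup_rat", "v_dog", "fup_dog", "smiles",
)


def chromlogd_from_chi(chi: float) -> float:
    """ChromlogD at pH 7.4 from the chromatographic hydrophobicity index:
    ``ChromlogD = 0.0857 * CHI − 2.00``."""
    if not np.isfinite(chi):
        raise InputError(f"CHI = {chi} is not finite")
    return 0.0857 * chi - 2.00


def clip_to_assay_limits(
    props: CompoundProperties,
    predicted_fields: set[str] | None = None,
) -> CompoundProperties:
    """Clip predicted inputs to assay limits; measured fields are untouched.

    ``predicted_fields`` names the fields to treat as model predictions;
    ``None`` clips every limited field.  Idempotent; each clip event is
    warned with the compound id and field.
    """
    updates: dict[str, float] = {}
    for fname, (lo, hi) in ASSAY_LIMITS.items():
        if predicted_fields is not None and fname not in predicted_fields:
            continue
        value = getattr(props, fname)
        if value is None:
            continue
        clipped = min(max(value, lo), hi)
        if clipped != value:
            warnings.warn(
                f"{props.compound_id}: {fname} = {value} clipped to {clipped}",
                ClipWarning,
                stacklevel=2,
            )
            updates[fname] = clipped
    if not updates:
        return props
    new = replace(props, **updates)
    for fname in updates:
        new.provenance[fname] = "predicted-clipped"
    return new


@dataclass
class CompoundTable:
    """Validated compounds plus carried-through optional columns."""

    compounds: list[CompoundProperties]
    extras: pd.DataFrame                  # indexed by compound_id
    rejects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["compound_id", "reason"])
    )

    def __len__(self) -> int:
        return len(self.compounds)

    def __iter__(self):
        return iter(self.compounds)

    def get(self, compound_id: str) -> CompoundProperties:
        for c in self.compounds:
            if c.compound_id == compound_id:
                return c
        raise KeyError(compound_id)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.compounds:
            rows.append({
                "compound_id": c.compound_id,
                "logp": c.logP,
                "logd74": c.logD74,
                "pka_acidic": c.pKa_acidic,
                "pka_basic": c.pKa_basic,
                "fup": c.fup,
                "bpr": c.BPR,
                "ionization_class": c.ionization_class,
            })
        df = pd.DataFrame(rows)
        if len(self.extras):
            df = df.merge(
                self.extras.reset_index(), on="compound_id", how="left"
            )
        return df


def _float_or_none(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return float(value)


def _row_to_compound(row: dict) -> CompoundProperties:
    cid = str(row["compound_id"])
    logp = _float_or_none(row.get("logp"))
    if logp is None:
        raise ValidationError(f"{cid}: logp is required")
    fup = _float_or_none(row.get("fup"))
    if fup is None:
        raise ValidationError(f"{cid}: fup is required")
    provenance: dict[str, str] = {}
    if fup > 1.0:
        # percent-style fup (e.g. 35 meaning 35%)
        provenance["fup"] = "measured (auto-converted from %)"
        fup = fup / 100.0
    if not 0.0 < fup <= 1.0:
        raise ValidationError(f"{cid}: fup = {fup} outside (0, 1]")
    bpr = _float_or_none(row.get("bpr"))
    if bpr is not None and bpr < 0:
        raise ValidationError(f"{cid}: bpr = {bpr} < 0")
    obs = _float_or_none(row.get("observed_vdss"))
    if obs is not None and obs <= 0:
        raise ValidationError(f"{cid}: observed_vdss = {obs} must be > 0")
    return CompoundProperties(
        compound_id=cid,
        logP=logp,
        logD74=_float_or_none(row.get("logd74")),
        pKa_acidic=_float_or_none(row.get("pka_acidic")),
        pKa_basic=_float_or_none(row.get("pka_basic")),
        fup=fup,
        BPR=bpr,
        provenance=provenance,
    )


def read_compound_table(path: str | Path, sep: str | None = None) -> CompoundTable:
    """Read and validate a compound table; invalid rows go to ``rejects``."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"compound table not found: {path}")
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip().lower() for c in df.columns]
    if "compound_id" not in df.columns:
        raise FormatError("compound table missing required column: compound_id")

    compounds: list[CompoundProperties] = []
    rejects: list[dict] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        record = row.to_dict()
        cid = str(record.get("compound_id"))
        if cid in seen:
            rejects.append({"compound_id": cid, "reason": "duplicate compound_id"})
            continue
        try:
            compounds.append(_row_to_compound(record))
            seen.add(cid)
        except (ValidationError, ValueError) as exc:
            rejects.append({"compound_id": cid, "reason": str(exc)})
    if not compounds:
        raise InputError(f"no valid rows in {path}")

    extra_cols = [c for c in _OPTIONAL_COLUMNS if c in df.columns]
    extras = (
        df[df["compound_id"].astype(str).isin(seen)]
        .set_index(df[df["compound_id"].astype(str).isin(seen)]["compound_id"].astype(str))
        [extra_cols]
        if extra_cols
        else pd.DataFrame(index=pd.Index(sorted(seen), name="compound_id"))
    )
    extras.index.name = "compound_id"
    return CompoundTable(
        compounds=compounds,
        extras=extras,
        rejects=pd.DataFrame(rejects, columns=["compound_id", "reason"]),
    )


def write_predictions(
    path: str | Path,
    predictions,                       # iterable of VdssPrediction
    report: pd.DataFrame | None = None,
    report_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write the prediction table (and optional metrics report) to disk."""
    df = pd.DataFrame(
        [
            {
                "compound_id": p.compound_id,
                "method_label": p.method_label,
                "vdss_L_per_kg": p.vdss,
            }
            for p in predictions
        ]
    )
    df.to_csv(path, index=False)
    if report is not None and report_path is not None:
        report.to_csv(report_path, index=False)
    return df
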