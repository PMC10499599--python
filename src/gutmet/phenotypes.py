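"""Clinical phenotype derivation: HOMA-IR, insulin-resistance class, MetS class.

The rules follow the Japanese clinical criteria: insulin resistance (IR) is
HOMA-IR >= 2.5, normal insulin sensitivity (IS) is HOMA-IR <= 1.6, and the
metabolic-syndrome call is gated on abdominal circumference (>=85 cm for men,
>=90 cm for women) plus counting three clinical abnormality groups
(dyslipidaemia, elevated blood pressure, impaired fasting glucose).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

#: Sentinel label for rows where a required measurement is absent.
MISSING = "missing"


class InvalidMeasurementError(ValueError):
    """A clinical measurement is negative or non-finite."""


@dataclass(frozen=True)
class PhenotypeRules:
    """Thresholds of the phenotype-derivation rules.

    All concentrations are in conventional clinical units: insulin in uU/ml,
    glucose/TG/HDL-C/FBG in mg/dl, blood pressure in mmHg, waist in cm.
    """

    homa_denominator: float = 405.0
    ir_threshold: float = 2.5
    is_threshold: float = 1.6
    waist_male_cm: float = 85.0
    waist_female_cm: float = 90.0
    tg_mgdl: float = 150.0
    hdl_mgdl: float = 40.0
    sbp_mmhg: float = 130.0
    dbp_mmhg: float = 85.0
    fbg_mgdl: float = 110.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be strictly positive")
        if self.is_threshold >= self.ir_threshold:
            raise ValueError("is_threshold must be below ir_threshold")


DEFAULT_RULES = PhenotypeRules()


def compute_homa_ir(
    insulin_uU_ml: float, glucose_mg_dl: float, rules: PhenotypeRules = DEFAULT_RULES
) -> float:
    """HOMA-IR = fasting insulin (uU/ml) x fasting glucose (mg/dl) / 405."""
    for v, name in ((insulin_uU_ml, "insulin"), (glucose_mg_dl, "glucose")):
        if not math.isfinite(v) or v < 0:
            raise InvalidMeasurementError(f"{name} must be finite and non-negative, got {v!r}")
    return insulin_uU_ml * glucose_mg_dl / rules.homa_denominator


def classify_ir(homa_ir: float, rules: PhenotypeRules = DEFAULT_RULES) -> str:
    """Classify a HOMA-IR value as ``IS`` (<=1.6), ``IR`` (>=2.5) or ``intermediate``.

    Both boundaries are inclusive; a missing value yields the ``missing``
    sentinel rather than silently defaulting to IS.
    """
    if homa_ir is None or (isinstance(homa_ir, float) and math.isnan(homa_ir)):
        return MISSING
    if not math.isfinite(homa_ir) or homa_ir < 0:
        raise InvalidMeasurementError(f"HOMA-IR must be finite and non-negative, got {homa_ir!r}")
    if homa_ir >= rules.ir_threshold:
        return "IR"
    if homa_ir <= rules.is_threshold:
        return "IS"
    return "intermediate"


_MET_S_FIELDS = ("sex", "waist_cm", "tg_mgdl", "hdl_mgdl", "sbp_mmhg", "dbp_mmhg", "fbg_mgdl")


def classify_mets(row, rules: PhenotypeRules = DEFAULT_RULES) -> str:
    """Metabolic-syndrome call for one participant.

    ``row`` is a mapping (or pandas Series) with keys ``sex`` (0 = male,
    1 = female), ``waist_cm``, ``tg_mgdl``, ``hdl_mgdl``, ``sbp_mmhg``,
    ``dbp_mmhg``, ``fbg_mgdl``.  The waist criterion is a mandatory gate;
    each abnormality group counts once even when both of its sub-criteria
    hold.  Two or more groups -> ``MetS``; exactly one -> ``preMetS``;
    waist gate failed or zero groups -> ``none``.
    """
    vals = {}
    for key in _MET_S_FIELDS:
        try:
            v = row[key]
        except (KeyError, IndexError):
            return MISSING
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return MISSING
        vals[key] = v

    waist_cut = rules.waist_male_cm if int(vals["sex"]) == 0 else rules.waist_female_cm
    if vals["waist_cm"] < waist_cut:
        return "none"

    abnormalities = 0
    if vals["tg_mgdl"] >= rules.tg_mgdl or vals["hdl_mgdl"] < rules.hdl_mgdl:
        abnormalities += 1
    if vals["sbp_mmhg"] >= rules.sbp_mmhg or vals["dbp_mmhg"] >= rules.dbp_mmhg:
        abnormalities += 1
    if vals["fbg_mgdl"] >= rules.fbg_mgdl:
        abnormalities += 1

    if abnormalities >= 2:
        return "MetS"
    if abnormalities == 1:
        return "preMetS"
    return "none"


def derive_phenotypes(frame: pd.DataFrame, rules: PhenotypeRules = DEFAULT_RULES) -> pd.DataFrame:
    """Add ``homa_ir``, ``ir_class`` and ``mets_class`` columns to a metadata frame.

    Expects ``insulin_uU_ml`` and ``glucose_mg_dl`` columns plus the MetS
    component columns; rows with missing components get the sentinel label.
    """
    out = frame.copy()
    homa = []
    for _, r in frame.iterrows():
        ins, glc = r.get("insulin_uU_ml"), r.get("glucose_mg_dl")
        if pd.isna(ins) or pd.isna(glc):
            homa.append(float("nan"))
        else:
            homa.append(compute_homa_ir(float(ins), float(glc), rules))
    out["homa_ir"] = homa
    out["ir_class"] = [classify_ir(h, rules) for h in out["homa_ir"]]
    out["mets_class"] = [classify_mets(r, rules) for _, r in out.iterrows()]
    return out
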