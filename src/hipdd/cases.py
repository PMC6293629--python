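"""Registry case definition and incidence-panel construction.

A hospital admission counts as a hip fracture when it carries a femoral
fracture diagnosis in the hip range (ICD-10 S72.0, S72.1 or S72.2) *and*
a NOMESCO surgical procedure code for femoral fracture treatment
(NFJxy, x = 0-9, y = 0-2) or hip-joint replacement (NFBxy, x = 0-4,
y = 0-2; plus NFB62).  The conjunction of diagnosis and procedure is the
validated definition for Nordic discharge registries: it excludes
conservative femoral-shaft admissions and coding noise on either axis.

Codes are normalised (uppercased, periods and whitespace stripped)
before matching, so registry dialects like ``"S72.0"`` and ``"S720"``
are equivalent.  Diagnoses match on the three-character-plus-digit stem,
admitting national subdivision characters (``S7201``); procedure codes
must match the stated five-character patterns exactly.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synth import ANALYSIS_STRATA

__all__ = [
    "AdmissionRecord",
    "PanelError",
    "normalize_code",
    "match_diagnosis",
    "match_procedure",
    "is_hip_fracture",
    "classify_admissions",
    "build_panel",
    "completeness_filter",
]

_DIAGNOSIS_STEMS = ("S720", "S721", "S722")
_PROCEDURE_RE = re.compile(r"NFJ[0-9][0-2]|NFB[0-4][0-2]|NFB62")


class PanelError(ValueError):
    """Panel construction failed (typically a missing population cell)."""


@dataclass(frozen=True)
class AdmissionRecord:
    """One hospital stay, the unit the case definition filters."""

    record_id: int
    municipality_id: int
    year: int
    age: int
    sex: str
    diagnosis_codes: tuple[str, ...] = field(default_factory=tuple)
    procedure_codes: tuple[str, ...] = field(default_factory=tuple)


def normalize_code(code: str) -> str:
    return code.replace(".", "").replace(" ", "").strip().upper()


def match_diagnosis(code: str) -> bool:
    """True iff the ICD-10 code denotes a hip fracture (S72.0-S72.2)."""
    return normalize_code(code).startswith(_DIAGNOSIS_STEMS)


def match_procedure(code: str) -> bool:
    """True iff the NOMESCO code denotes femoral-fracture surgery or hip
    replacement (NFJ x0-9 y0-2, NFB x0-4 y0-2, NFB62)."""
    return _PROCEDURE_RE.fullmatch(normalize_code(code)) is not None


def is_hip_fracture(record: AdmissionRecord) -> bool:
    """Conjunction rule: a qualifying diagnosis AND a qualifying procedure."""
    return any(match_diagnosis(c) for c in record.diagnosis_codes) and any(
        match_procedure(c) for c in record.procedure_codes
    )


def _split(codes: str) -> list[str]:
    return [c for c in str(codes).split(";") if c and c.lower() != "nan"]


def classify_admissions(records: pd.DataFrame) -> pd.Series:
    """Vectorised case definition over an admission table.

    ``records`` needs ``icd10_codes`` and ``procedure_codes`` columns of
    ';'-separated code strings; returns a boolean Series aligned to it.
    """
    diag_ok = records["icd10_codes"].fillna("").map(
        lambda s: any(match_diagnosis(c) for c in _split(s))
    )
    proc_ok = records["procedure_codes"].fillna("").map(
        lambda s: any(match_procedure(c) for c in _split(s))
    )
    return diag_ok & proc_ok


def build_panel(
    records: pd.DataFrame,
    populations: pd.DataFrame,
    treated_ids: Iterable[int],
    dedup: bool = False,
) -> pd.DataFrame:
    """Count qualifying admissions into the six analysis strata.

    Strata are (65+, 80+) x (both, male, female); a record aged 80+
    contributes to both age groups, one aged 65-79 to 65+ only, younger
    records are outside the study population.  The year grid is taken
    from the population table, so cells without cases appear with zero
    counts.  ``dedup`` keeps at most one qualifying admission per
    patient-year (off by default: the registry definition counts
    admissions).

    Raises :class:`PanelError` when a qualifying record falls in a
    municipality-year absent from the population table.
    """
    qualifying = records.loc[classify_admissions(records)].copy()
    qualifying = qualifying[qualifying["age"] >= 65]
    if dedup and "patient_id" in qualifying.columns:
        qualifying = qualifying.drop_duplicates(subset=["patient_id", "year"])

    pop_grid = set(zip(populations["municipality_id"], populations["year"]))
    missing = [
        cell
        for cell in set(zip(qualifying["municipality_id"], qualifying["year"]))
        if cell not in pop_grid
    ]
    if missing:
        mid, year = sorted(missing)[0]
        raise PanelError(
            f"no population for municipality {mid}, year {year} "
            f"({len(missing)} cell(s) missing)"
        )

    treated_set = set(treated_ids)
    # population aggregated to the six strata
    pop = populations.copy()
    frames = []
    for age_group, sex in ANALYSIS_STRATA:
        pop_mask = pd.Series(True, index=pop.index)
        if age_group == "80+":
            pop_mask &= pop["age_group"] == "80+"
        if sex != "both":
            pop_mask &= pop["sex"] == sex
        pop_cell = (
            pop.loc[pop_mask]
            .groupby(["municipality_id", "year"], as_index=False)["population"]
            .sum()
        )

        rec_mask = pd.Series(True, index=qualifying.index)
        if age_group == "80+":
            rec_mask &= qualifying["age"] >= 80
        if sex != "both":
            rec_mask &= qualifying["sex"] == sex
        counts = (
            qualifying.loc[rec_mask]
            .groupby(["municipality_id", "year"])
            .size()
            .rename("cases")
            .reset_index()
        )
        cell = pop_cell.merge(counts, on=["municipality_id", "year"], how="left")
        cell["cases"] = cell["cases"].fillna(0).astype(np.int64)
        cell["age_group"] = age_group
        cell["sex"] = sex
        frames.append(cell)

    panel = pd.concat(frames, ignore_index=True)
    panel["rate"] = panel["cases"] / panel["population"] * 1e5
    panel["treated"] = panel["municipality_id"].isin(treated_set)
    cols = ["municipality_id", "year", "age_group", "sex",
            "cases", "population", "rate", "treated"]
    return (
        panel[cols]
        .sort_values(["age_group", "sex", "municipality_id", "year"], kind="stable")
        .reset_index(drop=True)
    )


def completeness_filter(
    panel: pd.DataFrame, required_years: Sequence[int]
) -> tuple[pd.DataFrame, list[int]]:
    """Drop municipalities lacking any required year.

    The estimators need a complete annual series per municipality (units
    involved in administrative mergers typically break it), so a
    municipality is retained only when every year in ``required_years``
    is present.  Returns the filtered panel and the sorted list of
    dropped municipality ids.
    """
    required = set(int(y) for y in required_years)
    years_by_muni = panel.groupby("municipality_id")["year"].agg(lambda y: set(y))
    keep = [m for m, ys in years_by_muni.items() if required <= ys]
    dropped = sorted(set(years_by_muni.index) - set(keep))
    if not keep:
        warnings.warn("completeness_filter removed every municipality")
    filtered = panel[panel["municipality_id"].isin(set(keep))].reset_index(drop=True)
    return filtered, dropped
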