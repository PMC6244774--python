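"""Patient-cohort table: packaged fixture, validated I/O and confounder encodings.

The package ships a transcription of a published 24-patient diffuse-glioma
cohort (``data/glioma_cohort.csv``): newly diagnosed WHO 2007 grade II-IV
glioma patients who underwent preoperative resting-state MEG and subsequent
resection.  Each row carries the clinical covariates, progression-free
survival in weeks (``event`` marks observed progression; censored patients
carry time of last contact), the cohort-based z-score of global broadband
(0.5-48 Hz) oscillatory power, and the immunohistochemical NLGN3 expression
tier (low / moderate / high) where tumor tissue was available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "SchemaError",
    "FixtureIntegrityWarning",
    "fixture_path",
    "load_patient_table",
    "write_patient_table",
    "records",
    "derive_codeletion",
    "encode_covariates",
]

SEX_LEVELS = {"M", "F"}
HISTOLOGY_LEVELS = {"oligodendroglioma", "oligoastrocytoma", "astrocytoma", "GBM"}
GRADE_LEVELS = {"II", "III", "IV"}
IDH1_LEVELS = {"mutant", "wildtype", "unavailable"}
CODELETION_LEVELS = {"codeleted", "non_codeleted", "unavailable"}
TREATMENT_LEVELS = {"rt_plus_chemo", "rt_alone", "none"}
NLGN3_LEVELS = {"low", "moderate", "high", "unavailable"}

#: canonical column order of the fixture dialect
COLUMNS = [
    "patient_id", "sex", "age_years", "histology", "who_grade",
    "idh1_status", "codeletion_assessed", "tumor_location", "aed",
    "tumor_volume_cm3", "eor_percent", "adjuvant_treatment", "kps",
    "time_weeks", "event", "oba_global_z", "nlgn3_tier",
]

#: columns any user-supplied table must provide at minimum
REQUIRED_USER_COLUMNS = ["patient_id", "time_weeks", "event", "oba_global_z"]


class SchemaError(ValueError):
    """Raised when a patient table violates the column schema or a cell fails to parse."""


class FixtureIntegrityWarning(UserWarning):
    """A table claimed to be the packaged cohort does not match its known checksums."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient of the clinical/survival/biomarker table."""

    patient_id: str
    sex: str
    age_years: int
    histology: str
    who_grade: str
    idh1_status: str
    codeletion_assessed: str
    tumor_location: str
    aed: str
    tumor_volume_cm3: float
    eor_percent: float
    adjuvant_treatment: str
    kps: int
    time_weeks: float
    event: bool
    oba_global_z: float
    nlgn3_tier: str


def fixture_path() -> Path:
    """Location of the packaged cohort CSV."""
    return Path(str(resources.files("oscillomark").joinpath("data/glioma_cohort.csv")))


def _check_levels(df: pd.DataFrame, column: str, levels: set[str]) -> None:
    bad = set(df[column].astype(str)) - levels
    if bad:
        ids = df.loc[~df[column].astype(str).isin(levels), "patient_id"].tolist()
        raise SchemaError(
            f"column {column!r}: invalid value(s) {sorted(bad)} for patient(s) {ids}"
        )


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    for col, levels in [
        ("sex", SEX_LEVELS), ("histology", HISTOLOGY_LEVELS),
        ("who_grade", GRADE_LEVELS), ("idh1_status", IDH1_LEVELS),
        ("codeletion_assessed", CODELETION_LEVELS),
        ("adjuvant_treatment", TREATMENT_LEVELS), ("nlgn3_tier", NLGN3_LEVELS),
    ]:
        if col in df.columns:
            _check_levels(df, col, levels)
    for col, caster in [
        ("age_years", int), ("tumor_volume_cm3", float), ("eor_percent", float),
        ("kps", int), ("time_weeks", float), ("oba_global_z", float),
    ]:
        if col not in df.columns:
            continue
        try:
            df[col] = df[col].map(caster)
        except (TypeError, ValueError):
            for pid, cell in zip(df["patient_id"], df[col]):
                try:
                    caster(cell)
                except (TypeError, ValueError):
                    raise SchemaError(
                        f"column {col!r}: unparseable cell {cell!r} for patient {pid!r}"
                    ) from None
    df["event"] = df["event"].astype(int).astype(bool)
    if (df.get("time_weeks", pd.Series(dtype=float)) <= 0).any():
        bad = df.loc[df["time_weeks"] <= 0, "patient_id"].tolist()
        raise SchemaError(f"time_weeks must be positive; violated by {bad}")
    return df


def _check_fixture_invariants(df: pd.DataFrame) -> None:
    """Checksums of the packaged cohort; mismatches warn, they do not abort."""
    n, n_events = len(df), int(df["event"].sum())
    if (n, n_events) != (24, 17):
        warnings.warn(
            f"expected the packaged 24-patient cohort with 17 progression events, "
            f"got n={n} with {n_events} events",
            FixtureIntegrityWarning,
            stacklevel=3,
        )
        return
    tiers = df["nlgn3_tier"].value_counts()
    expected = {"low": 12, "moderate": 6, "high": 3, "unavailable": 3}
    checks = [
        all(tiers.get(k, 0) == v for k, v in expected.items()),
        int((df["histology"] == "GBM").sum()) == 2,
        float(df.loc[df["event"], "time_weeks"].median()) == 87.0,
        abs(df["oba_global_z"].mean()) <= 0.02,
        abs(df["oba_global_z"].std(ddof=1) - 1.0) <= 0.05,
    ]
    if not all(checks):
        warnings.warn(
            "cohort table has n=24/17 events but fails a content checksum "
            "(NLGN3 tier counts, GBM count, median event time, or z-score scaling)",
            FixtureIntegrityWarning,
            stacklevel=3,
        )


def load_patient_table(path: str | Path | None = None, dialect: str = "fixture") -> pd.DataFrame:
    """Read and validate a patient table.

    Parameters
    ----------
    path:
        CSV to read; ``None`` loads the packaged cohort.
    dialect:
        ``"fixture"`` requires the full packaged column set and checks the
        cohort checksums (warning on mismatch); ``"user"`` requires only the
        survival/biomarker core columns.
    """
    if dialect not in {"fixture", "user"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    path = fixture_path() if path is None else Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype={"patient_id": str})
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file, no header") from None
    required = COLUMNS if dialect == "fixture" else REQUIRED_USER_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise SchemaError(f"{path}: table has a header but no rows")
    df = _validate(df)
    if dialect == "fixture":
        _check_fixture_invariants(df)
    return df.reset_index(drop=True)


def write_patient_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a patient table in the fixture dialect (read/write round-trips)."""
    out = df.copy()
    out["event"] = out["event"].astype(int)
    out.to_csv(path, index=False)


def records(df: pd.DataFrame) -> list[PatientRecord]:
    """View the table as typed records (fixture dialect only)."""
    names = [f.name for f in fields(PatientRecord)]
    return [PatientRecord(**{k: row[k] for k in names}) for _, row in df.iterrows()]


def derive_codeletion(df: pd.DataFrame) -> pd.Series:
    """1p/19q codeletion status with the retrospective labeling rule applied.

    Assessed status (loss-of-heterozygosity, available for 9 patients) is kept
    as is; IDH1-mutant astrocytomas without an assessment are labeled
    non-codeleted, the convention under which such tumors are grouped in the
    2016 WHO molecular classification.  Everything else stays unavailable.
    """
    out = df["codeletion_assessed"].copy()
    retro = (
        (out == "unavailable")
        & (df["idh1_status"] == "mutant")
        & (df["histology"] == "astrocytoma")
    )
    out[retro] = "non_codeleted"
    return out.rename("codeletion_status")


def encode_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Model-ready confounder encodings, one row per patient.

    Cut-points follow the source cohort's confounder definitions: age
    dichotomized at 40 years (<=40 coded 1), KPS at 80 (<=80 coded 1), WHO
    grade II as reference against III-IV.  Histology is ordinal
    (oligodendroglioma 1, oligoastrocytoma 2, astrocytoma/GBM 3), adjuvant
    treatment ordinal by intensity (none 0, radiotherapy 1, radiotherapy plus
    chemotherapy 2), and ``molecular_3group`` follows the 2016 WHO prognostic
    groups (1 IDH-mutant codeleted, 2 IDH-mutant non-codeleted,
    3 IDH-wildtype).  Missing inputs propagate to NaN; model drivers drop
    incomplete rows listwise per model.
    """
    codel = derive_codeletion(df)
    idh = df["idh1_status"]
    molecular = pd.Series(np.nan, index=df.index, name="molecular_3group")
    molecular[(idh == "mutant") & (codel == "codeleted")] = 1.0
    molecular[(idh == "mutant") & (codel == "non_codeleted")] = 2.0
    molecular[idh == "wildtype"] = 3.0
    histology_code = df["histology"].map(
        {"oligodendroglioma": 1, "oligoastrocytoma": 2, "astrocytoma": 3, "GBM": 3}
    )
    return pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "age_le40": (df["age_years"] <= 40).astype(float),
            "age_continuous": df["age_years"].astype(float),
            "sex_code": (df["sex"] == "F").astype(float),
            "kps_le80": (df["kps"] <= 80).astype(float),
            "grade_ii_vs_higher": (df["who_grade"] != "II").astype(float),
            "histology_code": histology_code.astype(float),
            "idh1_code": idh.map({"mutant": 1.0, "wildtype": 0.0}),
            "molecular_3group": molecular,
            "treatment_code": df["adjuvant_treatment"].map(
                {"none": 0.0, "rt_alone": 1.0, "rt_plus_chemo": 2.0}
            ),
            "volume_cm3": df["tumor_volume_cm3"].astype(float),
        }
    )
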