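"""Subject records, derived bioimpedance measures, and cohort CSV I/O.

A cohort is represented as a :class:`pandas.DataFrame` with one row per
subject and the column schema in :data:`COHORT_COLUMNS`.  Anthropometry is
stored in field units (weight kg, stature cm), bioimpedance in ohms at
50 kHz, and the dual-energy X-ray absorptiometry (DXA) reference components
in kg.  The DXA fat-free mass is defined as bone mineral content plus lean
soft tissue (FFM = BMC + LST).

Scalar helpers (:func:`impedance_magnitude`, :func:`body_mass_index`,
:func:`ffm_reference`) accept scalars or array-likes and broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from ._errors import InputValidationError

#: Canonical cohort CSV column order.  The three DXA columns may be absent
#: (prediction-only mode).
COHORT_COLUMNS = [
    "subject_id",
    "age",
    "sex",
    "weight_kg",
    "stature_cm",
    "resistance_ohm",
    "reactance_ohm",
    "fm_kg",
    "bmc_kg",
    "lst_kg",
]

DXA_COLUMNS = ["fm_kg", "bmc_kg", "lst_kg"]

#: Default tolerance (kg) for the |FM + BMC + LST - scale weight| check.
#: DXA-derived total mass routinely disagrees with scale weight by a couple
#: of kilograms, so the default is permissive.
MASS_CLOSURE_TOLERANCE_KG = 5.0


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's anthropometry, bioimpedance, and DXA components.

    ``sex`` follows the convention of the published equations: 1 = male,
    0 = female.  The DXA fields (``fm``, ``bmc``, ``lst``) are ``None`` when
    only predictions are required.
    """

    subject_id: str
    age: float
    sex: int
    weight: float          # kg
    stature: float         # cm
    resistance: float      # ohm
    reactance: float       # ohm
    fm: float | None = None    # kg, DXA fat mass
    bmc: float | None = None   # kg, DXA bone mineral content
    lst: float | None = None   # kg, DXA lean soft tissue

    def __post_init__(self) -> None:
        if self.weight <= 0 or self.stature <= 0:
            raise InputValidationError(
                f"subject {self.subject_id}: weight and stature must be positive"
            )
        if self.resistance <= 0 or self.reactance < 0:
            raise InputValidationError(
                f"subject {self.subject_id}: resistance must be positive and "
                "reactance non-negative"
            )
        for name in ("fm", "bmc", "lst"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise InputValidationError(
                    f"subject {self.subject_id}: {name} must be non-negative"
                )

    @property
    def has_dxa(self) -> bool:
        return None not in (self.fm, self.bmc, self.lst)

    @classmethod
    def from_row(cls, row: pd.Series | dict) -> "SubjectRecord":
        def _opt(key: str) -> float | None:
            value = row.get(key)
            if value is None or (isinstance(value, float) and np.isnan(value)):
                return None
            return float(value)

        return cls(
            subject_id=str(row["subject_id"]),
            age=float(row["age"]),
            sex=int(row["sex"]),
            weight=float(row["weight_kg"]),
            stature=float(row["stature_cm"]),
            resistance=float(row["resistance_ohm"]),
            reactance=float(row["reactance_ohm"]),
            fm=_opt("fm_kg"),
            bmc=_opt("bmc_kg"),
            lst=_opt("lst_kg"),
        )


@dataclass(frozen=True)
class DerivedMeasures:
    """Quantities derived from a subject's primary measurements."""

    bmi: float                    # kg/m^2
    impedance: float              # ohm, |Z| = sqrt(R^2 + Xc^2)
    ffm_dxa: float | None         # kg, BMC + LST
    impedance_index: float        # cm^2/ohm, stature^2 / R
    log_impedance_index: float    # log10(stature^2 / R)


def impedance_magnitude(resistance, reactance, *, method: str = "magnitude"):
    """Impedance Z (ohm) from resistance R and reactance Xc.

    The default is the vector magnitude sqrt(R^2 + Xc^2), the physically
    meaningful combination of the resistive and capacitive components of
    bioimpedance.  ``method="arithmetic_sum"`` returns R + Xc instead; it is
    provided only so the occasional legacy convention can be reproduced and
    is never used by the equation catalogue.
    """
    r = np.asarray(resistance, dtype=float)
    xc = np.asarray(reactance, dtype=float)
    if np.any(r <= 0):
        raise InputValidationError("resistance must be positive")
    if np.any(xc < 0):
        raise InputValidationError("reactance must be non-negative")
    if method == "magnitude":
        z = np.hypot(r, xc)
    elif method == "arithmetic_sum":
        z = r + xc
    else:
        raise InputValidationError(f"unknown impedance method: {method!r}")
    return z if z.ndim else float(z)


def body_mass_index(weight, stature):
    """Body mass index (kg/m^2) from weight in kg and stature in cm."""
    w = np.asarray(weight, dtype=float)
    s = np.asarray(stature, dtype=float)
    if np.any(w <= 0) or np.any(s <= 0):
        raise InputValidationError("weight and stature must be positive")
    bmi = w / (s / 100.0) ** 2
    return bmi if bmi.ndim else float(bmi)


def ffm_reference(bmc, lst):
    """Reference fat-free mass (kg): bone mineral content + lean soft tissue."""
    b = np.asarray(bmc, dtype=float)
    l = np.asarray(lst, dtype=float)
    if np.any(b < 0) or np.any(l < 0):
        raise InputValidationError("bmc and lst must be non-negative")
    out = b + l
    return out if out.ndim else float(out)


def impedance_index(stature, resistance):
    """Impedance index stature^2/R (cm^2/ohm), the dominant FFM predictor."""
    s = np.asarray(stature, dtype=float)
    r = np.asarray(resistance, dtype=float)
    if np.any(s <= 0) or np.any(r <= 0):
        raise InputValidationError("stature and resistance must be positive")
    out = s**2 / r
    return out if out.ndim else float(out)


def derive_measures(subject: SubjectRecord) -> DerivedMeasures:
    """Compute all derived measures for a single subject."""
    idx = impedance_index(subject.stature, subject.resistance)
    return DerivedMeasures(
        bmi=body_mass_index(subject.weight, subject.stature),
        impedance=impedance_magnitude(subject.resistance, subject.reactance),
        ffm_dxa=(
            ffm_reference(subject.bmc, subject.lst) if subject.has_dxa else None
        ),
        impedance_index=idx,
        log_impedance_index=float(np.log10(idx)),
    )


def add_derived(frame: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a cohort frame with derived-measure columns appended.

    Adds ``bmi``, ``impedance_ohm``, ``impedance_index``,
    ``log_impedance_index`` and, when the DXA columns are present,
    ``ffm_dxa_kg``.
    """
    out = frame.copy()
    out["bmi"] = body_mass_index(out["weight_kg"], out["stature_cm"])
    out["impedance_ohm"] = impedance_magnitude(
        out["resistance_ohm"], out["reactance_ohm"]
    )
    out["impedance_index"] = impedance_index(
        out["stature_cm"], out["resistance_ohm"]
    )
    out["log_impedance_index"] = np.log10(out["impedance_index"])
    if has_dxa_columns(frame):
        out["ffm_dxa_kg"] = ffm_reference(out["bmc_kg"], out["lst_kg"])
    return out


def has_dxa_columns(frame: pd.DataFrame) -> bool:
    return all(c in frame.columns for c in DXA_COLUMNS) and not (
        frame[DXA_COLUMNS].isna().any().any()
    )


def validate_cohort(
    frame: pd.DataFrame,
    *,
    require_dxa: bool = False,
    mass_tolerance_kg: float = MASS_CLOSURE_TOLERANCE_KG,
) -> None:
    """Check cohort invariants; raise :class:`InputValidationError` on failure.

    Verifies positivity of the physical measurements, uniqueness of subject
    ids, and — when DXA columns are present — that the DXA components sum to
    the scale weight within ``mass_tolerance_kg``.
    """
    required = [c for c in COHORT_COLUMNS if c not in DXA_COLUMNS]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise InputValidationError(f"cohort is missing columns: {missing}")
    if require_dxa and not has_dxa_columns(frame):
        raise InputValidationError(
            "cohort lacks complete DXA columns (fm_kg, bmc_kg, lst_kg) "
            "required for validation against the reference method"
        )
    if frame["subject_id"].duplicated().any():
        raise InputValidationError("duplicate subject_id values")
    for col in ("weight_kg", "stature_cm", "resistance_ohm"):
        if (frame[col] <= 0).any():
            raise InputValidationError(f"non-positive values in {col}")
    if (frame["reactance_ohm"] < 0).any():
        raise InputValidationError("negative values in reactance_ohm")
    if has_dxa_columns(frame):
        for col in DXA_COLUMNS:
            if (frame[col] < 0).any():
                raise InputValidationError(f"negative values in {col}")
        closure = (
            frame["fm_kg"] + frame["bmc_kg"] + frame["lst_kg"]
            - frame["weight_kg"]
        ).abs()
        if (closure > mass_tolerance_kg).any():
            worst = float(closure.max())
            raise InputValidationError(
                "DXA components disagree with scale weight by up to "
                f"{worst:.2f} kg (tolerance {mass_tolerance_kg} kg)"
            )


def read_cohort(
    path,
    *,
    require_dxa: bool = False,
    mass_tolerance_kg: float = MASS_CLOSURE_TOLERANCE_KG,
) -> pd.DataFrame:
    """Read and validate a cohort CSV."""
    frame = pd.read_csv(path)
    validate_cohort(
        frame, require_dxa=require_dxa, mass_tolerance_kg=mass_tolerance_kg
    )
    return frame


def write_cohort(frame: pd.DataFrame, path) -> None:
    """Write a cohort frame to CSV in the canonical column order."""
    cols = [c for c in COHORT_COLUMNS if c in frame.columns]
    frame.loc[:, cols].to_csv(path, index=False)


def records_to_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Build a cohort frame from :class:`SubjectRecord` objects."""
    rows = [
        {
            "subject_id": r.subject_id,
            "age": r.age,
            "sex": r.sex,
            "weight_kg": r.weight,
            "stature_cm": r.stature,
            "resistance_ohm": r.resistance,
            "reactance_ohm": r.reactance,
            "fm_kg": r.fm,
            "bmc_kg": r.bmc,
            "lst_kg": r.lst,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[SubjectRecord]:
    return [SubjectRecord.from_row(row) for _, row in frame.iterrows()]
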