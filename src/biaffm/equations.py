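"""Catalogue of fat-free-mass (FFM) prediction equations for 50 kHz BIA.

Eight equations from the body-composition literature plus the
population-specific equation for young, physically active adult males
developed with this package's pipeline.  Each equation is described by an
:class:`EquationSpec` carrying its named coefficients and unit conventions,
and evaluated by :func:`predict_ffm` on a subject record or cohort frame.

Unit conventions
----------------
Stature enters the impedance indices (S^2/R, S^2/Z) in centimetres.  The
Deurenberg equations (eq4, eq5) additionally contain a standalone stature
term in metres; only this mixed convention yields estimates on the scale of
adult FFM.  Impedance Z is the vector magnitude sqrt(R^2 + Xc^2).  Sex is
coded 1 for male, 0 for female.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import InputValidationError
from .cohort import SubjectRecord, impedance_magnitude

__all__ = [
    "EquationSpec",
    "PredictionSet",
    "equation_catalogue",
    "get_equation",
    "predict_ffm",
    "predict_all",
    "predict_specific",
    "catalogue_to_json",
]


@dataclass(frozen=True)
class EquationSpec:
    """A named, unit-aware FFM prediction formula.

    ``reference_r2`` and ``reference_see`` are the fit statistics reported
    by the source publication (``None`` where not reported).  ``see_unit``
    is "kg" except for Kotler's equation, whose published SEE is a
    percentage and is stored as printed.
    """

    equation_id: str
    source: str
    criterion: str                     # reference method of the source study
    required_inputs: tuple[str, ...]
    coefficients: Mapping[str, float]
    reference_r2: float | None = None
    reference_see: float | None = None
    see_unit: str = "kg"
    notes: str = ""

    def to_dict(self) -> dict:
        return {
            "equation_id": self.equation_id,
            "source": self.source,
            "criterion": self.criterion,
            "required_inputs": list(self.required_inputs),
            "coefficients": dict(self.coefficients),
            "reference_r2": self.reference_r2,
            "reference_see": self.reference_see,
            "see_unit": self.see_unit,
            "notes": self.notes,
        }


@dataclass(frozen=True)
class PredictionSet:
    """FFM estimates (kg) for one equation, aligned with a cohort's rows."""

    equation_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise InputValidationError(
                f"{self.equation_id}: non-finite prediction"
            )
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)


# --- formula evaluators -----------------------------------------------------
# Each evaluator receives the spec's coefficient mapping and a dict of input
# arrays in field units (stature cm, weight kg, ohms) and returns FFM in kg.

def _eval_lukaski(c, v):
    s2_r = v["stature"] ** 2 / v["resistance"]
    return (
        c["impedance_index"] * s2_r
        + c["weight"] * v["weight"]
        + c["reactance"] * v["reactance"]
        + c["sex"] * v["sex"]
        + c["intercept"]
    )


def _eval_chumlea(c, v):
    z = impedance_magnitude(v["resistance"], v["reactance"])
    return c["impedance_index_z"] * v["stature"] ** 2 / z + c["intercept"]


def _eval_segal(c, v):
    return (
        c["stature_sq"] * v["stature"] ** 2
        + c["resistance"] * v["resistance"]
        + c["weight"] * v["weight"]
        + c["age"] * v["age"]
        + c["intercept"]
    )


def _eval_deurenberg_1989(c, v):
    z = impedance_magnitude(v["resistance"], v["reactance"])
    return (
        c["impedance_index_z"] * v["stature"] ** 2 / z
        + c["weight"] * v["weight"]
        + c["sex"] * v["sex"]
        + c["stature_m"] * v["stature"] / 100.0
        + c["intercept"]
    )


def _eval_deurenberg_1991(c, v):
    z = impedance_magnitude(v["resistance"], v["reactance"])
    return (
        c["impedance_index_z"] * v["stature"] ** 2 / z
        + c["age"] * v["age"]
        + c["weight"] * v["weight"]
        + c["sex"] * v["sex"]
        + c["stature_m"] * v["stature"] / 100.0
        + c["intercept"]
    )


def _eval_lohman(c, v):
    s2_r = v["stature"] ** 2 / v["resistance"]
    return c["impedance_index"] * s2_r + c["weight"] * v["weight"] + c["intercept"]


def _eval_kotler(c, v):
    # Power-law impedance term; the published 1/1.21 calibration factor is
    # kept as an explicit coefficient rather than folded into the slope.
    z = impedance_magnitude(v["resistance"], v["reactance"])
    term = v["stature"] ** c["stature_exp"] / z ** c["impedance_exp"]
    return (
        c["index_slope"] * term * c["calibration_factor"]
        + c["weight"] * v["weight"]
        + c["intercept"]
    )


def _eval_sun(c, v):
    s2_r = v["stature"] ** 2 / v["resistance"]
    return (
        c["impedance_index"] * s2_r
        + c["weight"] * v["weight"]
        + c["resistance"] * v["resistance"]
        + c["intercept"]
    )


def _eval_specific(c, v):
    log_index = np.log10(v["stature"] ** 2 / v["resistance"])
    return c["weight"] * v["weight"] + c["log_impedance_index"] * log_index + c["intercept"]


_EVALUATORS: dict[str, Callable] = {
    "eq1": _eval_lukaski,
    "eq2": _eval_chumlea,
    "eq3": _eval_segal,
    "eq4": _eval_deurenberg_1989,
    "eq5": _eval_deurenberg_1991,
    "eq6": _eval_lohman,
    "eq7": _eval_kotler,
    "eq8": _eval_sun,
    "specific": _eval_specific,
}


_CATALOGUE: tuple[EquationSpec, ...] = (
    EquationSpec(
        equation_id="eq1",
        source="Lukaski et al. 1986",
        criterion="UW",
        required_inputs=("stature", "resistance", "weight", "reactance", "sex"),
        coefficients={
            "impedance_index": 0.734,
            "weight": 0.116,
            "reactance": 0.096,
            "sex": 0.878,
            "intercept": -4.03,
        },
        reference_r2=0.99,
        reference_see=2.2,
    ),
    EquationSpec(
        equation_id="eq2",
        source="Chumlea et al. 1988",
        criterion="UW",
        required_inputs=("stature", "resistance", "reactance"),
        coefficients={"impedance_index_z": 0.87, "intercept": 3.50},
        reference_r2=0.81,
        reference_see=3.0,
    ),
    EquationSpec(
        equation_id="eq3",
        source="Segal et al. 1988",
        criterion="UW",
        required_inputs=("stature", "resistance", "weight", "age"),
        coefficients={
            "stature_sq": 0.00132,
            "resistance": -0.04394,
            "weight": 0.3052,
            "age": -0.1676,
            "intercept": 22.66827,
        },
        reference_r2=0.90,
        reference_see=3.6,
        notes="source reports r, not R^2",
    ),
    EquationSpec(
        equation_id="eq4",
        source="Deurenberg et al. 1989",
        criterion="UW",
        required_inputs=("stature", "resistance", "reactance", "weight", "sex"),
        coefficients={
            "impedance_index_z": 0.438,
            "weight": 0.308,
            "sex": 1.6,
            "stature_m": 7.04,
            "intercept": -8.50,
        },
        reference_r2=0.99,
        reference_see=2.4,
        notes="standalone stature term in metres; index term in cm^2/ohm",
    ),
    EquationSpec(
        equation_id="eq5",
        source="Deurenberg et al. 1991",
        criterion="UW",
        required_inputs=("stature", "resistance", "reactance", "weight", "age", "sex"),
        coefficients={
            "impedance_index_z": 0.34,
            "age": -0.127,
            "weight": 0.273,
            "sex": 4.56,
            "stature_m": 15.34,
            "intercept": -12.44,
        },
        reference_r2=0.93,
        reference_see=2.6,
        notes="standalone stature term in metres; index term in cm^2/ohm",
    ),
    EquationSpec(
        equation_id="eq6",
        source="Lohman 1992",
        criterion="UW",
        required_inputs=("stature", "resistance", "weight"),
        coefficients={
            "impedance_index": 0.485,
            "weight": 0.338,
            "intercept": 5.32,
        },
        reference_r2=None,
        reference_see=2.9,
    ),
    EquationSpec(
        equation_id="eq7",
        source="Kotler et al. 1996",
        criterion="DXA",
        required_inputs=("stature", "resistance", "reactance", "weight"),
        coefficients={
            "index_slope": 0.50,
            "stature_exp": 1.48,
            "impedance_exp": 0.55,
            "calibration_factor": 1.0 / 1.21,
            "weight": 0.42,
            "intercept": 0.49,
        },
        reference_r2=0.90,
        reference_see=5.0,
        see_unit="%",
        notes="source reports r, not R^2; SEE published as a percentage",
    ),
    EquationSpec(
        equation_id="eq8",
        source="Sun et al. 2003",
        criterion="4C",
        required_inputs=("stature", "resistance", "weight"),
        coefficients={
            "impedance_index": 0.65,
            "weight": 0.26,
            "resistance": 0.02,
            "intercept": -10.68,
        },
        reference_r2=0.90,
        reference_see=3.9,
    ),
    EquationSpec(
        equation_id="specific",
        source="this package's development pipeline (army-cadet population)",
        criterion="DXA",
        required_inputs=("weight", "stature", "resistance"),
        coefficients={
            "weight": 0.508,
            "log_impedance_index": 39.234,
            "intercept": -48.263,
        },
        reference_r2=0.88,
        reference_see=2.2,
        notes="development-group fit statistics",
    ),
)


def equation_catalogue() -> list[EquationSpec]:
    """Return the nine catalogued equation specs (eq1..eq8 + specific)."""
    return list(_CATALOGUE)


def get_equation(equation_id: str) -> EquationSpec:
    for spec in _CATALOGUE:
        if spec.equation_id == equation_id:
            return spec
    raise InputValidationError(f"unknown equation_id: {equation_id!r}")


_FIELD_MAP = {
    "age": "age",
    "sex": "sex",
    "weight": "weight_kg",
    "stature": "stature_cm",
    "resistance": "resistance_ohm",
    "reactance": "reactance_ohm",
}


def _inputs_from(subject, required: Sequence[str]) -> dict:
    """Collect required input arrays/scalars, naming any missing field."""
    values = {}
    if isinstance(subject, SubjectRecord):
        for name in required:
            value = getattr(subject, name, None)
            if value is None:
                raise InputValidationError(
                    f"subject {subject.subject_id} is missing required "
                    f"input {name!r}"
                )
            values[name] = value
    elif isinstance(subject, (pd.DataFrame, Mapping)):
        for name in required:
            col = _FIELD_MAP.get(name, name)
            if isinstance(subject, pd.DataFrame):
                if col not in subject.columns:
                    raise InputValidationError(
                        f"cohort is missing required input column {col!r}"
                    )
                values[name] = subject[col].to_numpy(dtype=float)
            else:
                if col not in subject and name not in subject:
                    raise InputValidationError(
                        f"missing required input {name!r}"
                    )
                values[name] = subject.get(col, subject.get(name))
    else:
        raise InputValidationError(
            f"cannot evaluate equation on {type(subject).__name__}"
        )
    return values


def predict_ffm(spec: EquationSpec | str, subject):
    """Evaluate one catalogued equation on a subject or cohort frame.

    Returns a float for a single :class:`SubjectRecord` (or mapping of
    scalars) and an ndarray for a cohort :class:`~pandas.DataFrame`.
    """
    if isinstance(spec, str):
        spec = get_equation(spec)
    evaluator = _EVALUATORS.get(spec.equation_id)
    if evaluator is None:
        raise InputValidationError(
            f"no evaluator for equation_id {spec.equation_id!r}"
        )
    values = _inputs_from(subject, spec.required_inputs)
    out = evaluator(spec.coefficients, values)
    out = np.asarray(out, dtype=float)
    if not np.all(np.isfinite(out)):
        raise InputValidationError(
            f"{spec.equation_id}: evaluation produced non-finite values"
        )
    return out if out.ndim else float(out)


def predict_all(
    frame: pd.DataFrame, equations: Sequence[str] | None = None
) -> list[PredictionSet]:
    """Evaluate a selection of equations (default: whole catalogue)."""
    specs = (
        equation_catalogue()
        if equations is None
        else [get_equation(e) for e in equations]
    )
    return [
        PredictionSet(spec.equation_id, predict_ffm(spec, frame))
        for spec in specs
    ]


def predict_specific(weight, stature, resistance):
    """FFM (kg) from the population-specific equation.

    FFM = 0.508*Wt + 39.234*log10(stature^2/R) - 48.263, with weight in kg,
    stature in cm and resistance in ohm.  Strictly increasing in weight and
    stature, strictly decreasing in resistance.
    """
    w = np.asarray(weight, dtype=float)
    s = np.asarray(stature, dtype=float)
    r = np.asarray(resistance, dtype=float)
    if np.any(w <= 0) or np.any(s <= 0) or np.any(r <= 0):
        raise InputValidationError("all inputs must be positive")
    c = get_equation("specific").coefficients
    out = c["weight"] * w + c["log_impedance_index"] * np.log10(s**2 / r) + c["intercept"]
    return out if out.ndim else float(out)


def catalogue_to_json(path=None) -> str:
    """Serialize the catalogue (ids, citations, coefficients, units) to JSON."""
    payload = json.dumps([s.to_dict() for s in _CATALOGUE], indent=2)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(payload)
    return payload
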