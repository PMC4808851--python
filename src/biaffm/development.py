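"""Development and cross-validation of population-specific FFM equations.

Follows the standard prediction-equation workflow for body-composition
research: the cohort is randomly split 2:1 into a development group (DG)
and a cross-validation group (CVG); a new model is fitted on the DG by
bidirectional stepwise ordinary least squares over a fixed candidate pool
(age, stature, BMI, resistance, reactance, impedance, weight, and the
log10 impedance index); residual normality is checked with Shapiro–Wilk;
and the fitted model is evaluated with the full agreement suite on the DG,
the CVG, and the total sample.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import InputValidationError, StatisticalError
from .agreement import AgreementReport, build_report
from .cohort import add_derived, has_dxa_columns, validate_cohort

__all__ = [
    "SplitResult",
    "FittedModel",
    "DevelopmentResult",
    "split_cohort",
    "candidate_predictors",
    "stepwise_fit",
    "develop_and_validate",
    "CANDIDATE_NAMES",
    "DEFAULT_ALPHA_ENTER",
    "DEFAULT_ALPHA_REMOVE",
]

#: Fixed candidate-predictor pool, in a stable order.
CANDIDATE_NAMES = (
    "age",
    "stature",
    "bmi",
    "resistance",
    "reactance",
    "impedance",
    "weight",
    "log10_impedance_index",
)

# Conventional stepwise thresholds of the SPSS family of packages.
DEFAULT_ALPHA_ENTER = 0.05
DEFAULT_ALPHA_REMOVE = 0.10


@dataclass(frozen=True)
class SplitResult:
    """A reproducible random partition into development/validation groups."""

    development_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    seed: int

    @property
    def sizes(self) -> tuple[int, int]:
        return len(self.development_ids), len(self.validation_ids)


@dataclass(frozen=True)
class FittedModel:
    """A stepwise-selected OLS model for fat-free mass.

    ``coefficients`` maps each selected predictor (plus ``"intercept"``)
    to its estimate; ``standard_errors`` holds the matching OLS standard
    errors.  ``see`` is the residual standard deviation (kg, n-p-1
    divisor) and ``residual_normality_p`` the Shapiro–Wilk p-value of the
    fit residuals.
    """

    selected_predictors: tuple[str, ...]
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    r2_adj: float
    see: float
    residual_normality_p: float
    n_fit: int

    def predict(self, candidates: pd.DataFrame) -> np.ndarray:
        """Evaluate the model on a candidate-predictor frame."""
        out = np.full(len(candidates), self.coefficients["intercept"])
        for name in self.selected_predictors:
            out = out + self.coefficients[name] * candidates[name].to_numpy(dtype=float)
        return out

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class DevelopmentResult:
    """Fitted model plus agreement reports on DG, CVG, and the total sample."""

    model: FittedModel
    split: SplitResult
    dg_report: AgreementReport
    cvg_report: AgreementReport
    total_report: AgreementReport

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "split": {
                "seed": self.split.seed,
                "n_development": self.split.sizes[0],
                "n_validation": self.split.sizes[1],
                "development_ids": list(self.split.development_ids),
                "validation_ids": list(self.split.validation_ids),
            },
            "dg_report": self.dg_report.to_dict(),
            "cvg_report": self.cvg_report.to_dict(),
            "total_report": self.total_report.to_dict(),
        }

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(payload)
        return payload


def split_cohort(
    frame: pd.DataFrame, dev_fraction: float = 2.0 / 3.0, seed: int = 0
) -> SplitResult:
    """Randomly split a cohort into development and validation groups.

    The development-group size is round-half-up of ``n * dev_fraction``
    (396 at 2/3 gives the conventional 264/132 partition).  Assignment is
    a uniformly random permutation, reproducible from ``seed``.
    """
    n = len(frame)
    if n < 6:
        raise InputValidationError("cohort too small to split (need n >= 6)")
    if not 0 < dev_fraction < 1:
        raise InputValidationError("dev_fraction must be in (0, 1)")
    n_dev = int(np.floor(n * dev_fraction + 0.5))
    if n_dev == 0 or n_dev == n:
        raise InputValidationError("degenerate split: one group would be empty")
    ids = frame["subject_id"].astype(str).to_numpy()
    order = np.random.default_rng(seed).permutation(n)
    return SplitResult(
        development_ids=tuple(ids[order[:n_dev]]),
        validation_ids=tuple(ids[order[n_dev:]]),
        seed=seed,
    )


def candidate_predictors(frame: pd.DataFrame) -> pd.DataFrame:
    """Build the fixed candidate-predictor frame from a cohort frame.

    Columns: age, stature (cm), BMI, resistance, reactance, impedance
    (ohm), weight (kg), and log10(stature^2/resistance).
    """
    derived = add_derived(frame)
    out = pd.DataFrame(
        {
            "age": derived["age"].astype(float),
            "stature": derived["stature_cm"].astype(float),
            "bmi": derived["bmi"].astype(float),
            "resistance": derived["resistance_ohm"].astype(float),
            "reactance": derived["reactance_ohm"].astype(float),
            "impedance": derived["impedance_ohm"].astype(float),
            "weight": derived["weight_kg"].astype(float),
            "log10_impedance_index": derived["log_impedance_index"].astype(float),
        },
        index=frame.index,
    )
    if out.isna().any().any():
        missing = out.columns[out.isna().any()].tolist()
        raise InputValidationError(f"missing values in candidate predictors: {missing}")
    return out[list(CANDIDATE_NAMES)]


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _partial_f_p(
    rss_reduced: float, rss_full: float, df_resid_full: int, tiny: float
) -> float:
    """p-value of the partial F test for one added regressor.

    ``tiny`` is the numerical floor for a residual sum of squares; below it
    the fit counts as perfect, so a term is decisive only if the reduced
    model is imperfect.
    """
    if df_resid_full <= 0:
        return 1.0
    if rss_full < tiny:
        return 1.0 if rss_reduced < tiny else 0.0
    f = (rss_reduced - rss_full) / (rss_full / df_resid_full)
    return float(stats.f.sf(max(f, 0.0), 1, df_resid_full))


def stepwise_fit(
    candidates: pd.DataFrame,
    response,
    alpha_enter: float = DEFAULT_ALPHA_ENTER,
    alpha_remove: float = DEFAULT_ALPHA_REMOVE,
) -> FittedModel:
    """Bidirectional stepwise OLS over the candidate pool.

    Repeatedly adds the candidate with the smallest partial-F p-value while
    it is below ``alpha_enter``, then removes any included predictor whose
    partial-F p-value exceeds ``alpha_remove``, until the selection is
    stable.  The final model is refitted by ordinary least squares.

    A candidate whose entry would make the design matrix rank-deficient is
    skipped with a warning (the later-entering collinear variable loses).
    """
    if not 0 < alpha_enter < 1 or not 0 < alpha_remove < 1:
        raise InputValidationError("alpha levels must be in (0, 1)")
    y = np.asarray(response, dtype=float).ravel()
    n = len(y)
    if len(candidates) != n:
        raise InputValidationError("response length does not match candidates")
    if n <= len(candidates.columns) + 2:
        raise StatisticalError(
            "too few observations for stepwise selection over "
            f"{len(candidates.columns)} candidates (n={n})"
        )
    cols = {c: candidates[c].to_numpy(dtype=float) for c in candidates.columns}
    ones = np.ones(n)
    tss = float(np.sum((y - y.mean()) ** 2))
    tiny = 1e-12 * max(tss, 1.0)

    def design(names):
        return np.column_stack([ones] + [cols[c] for c in names])

    selected: list[str] = []
    while True:
        changed = False
        # entry scan
        rss0 = _rss(design(selected), y)
        best_p, best_name = 1.0, None
        for name in candidates.columns:
            if name in selected:
                continue
            X1 = design(selected + [name])
            if np.linalg.matrix_rank(X1) < X1.shape[1]:
                warnings.warn(
                    f"candidate {name!r} is collinear with the current model; skipped",
                    stacklevel=2,
                )
                continue
            pval = _partial_f_p(rss0, _rss(X1, y), n - X1.shape[1], tiny)
            if pval < best_p:
                best_p, best_name = pval, name
        if best_name is not None and best_p < alpha_enter:
            selected.append(best_name)
            changed = True
        # removal scan
        while selected:
            rss_full = _rss(design(selected), y)
            df_full = n - len(selected) - 1
            worst_p, worst_name = 0.0, None
            for name in selected:
                reduced = [c for c in selected if c != name]
                pval = _partial_f_p(_rss(design(reduced), y), rss_full, df_full, tiny)
                if pval > worst_p:
                    worst_p, worst_name = pval, name
            if worst_name is not None and worst_p > alpha_remove:
                selected.remove(worst_name)
                changed = True
            else:
                break
        if not changed:
            break

    # final OLS fit on the selected set
    X = design(selected)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    k = len(selected)
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    see = float(np.sqrt(rss / (n - k - 1)))
    if np.ptp(resid) == 0:
        normality_p = 1.0
    else:
        normality_p = float(stats.shapiro(resid).pvalue)
    cov = np.linalg.inv(X.T @ X) * (rss / (n - k - 1))
    ses = np.sqrt(np.diag(cov))
    names = ["intercept"] + selected
    return FittedModel(
        selected_predictors=tuple(selected),
        coefficients={name: float(b) for name, b in zip(names, beta)},
        standard_errors={name: float(s) for name, s in zip(names, ses)},
        r2_adj=float(r2_adj),
        see=see,
        residual_normality_p=normality_p,
        n_fit=n,
    )


def develop_and_validate(
    frame: pd.DataFrame,
    dev_fraction: float = 2.0 / 3.0,
    seed: int = 0,
    alpha_enter: float = DEFAULT_ALPHA_ENTER,
    alpha_remove: float = DEFAULT_ALPHA_REMOVE,
    normality_alpha: float = 0.05,
) -> DevelopmentResult:
    """Full development/cross-validation pipeline on a DXA-referenced cohort.

    Splits the cohort, fits the stepwise model on the development group
    only, and evaluates its agreement with the DXA reference on the
    development group, the cross-validation group, and the total sample.
    """
    validate_cohort(frame, require_dxa=True)
    if not has_dxa_columns(frame):
        raise InputValidationError("cohort lacks complete DXA reference columns")
    split = split_cohort(frame, dev_fraction=dev_fraction, seed=seed)
    indexed = frame.set_index(frame["subject_id"].astype(str))
    dg = indexed.loc[list(split.development_ids)]
    cvg = indexed.loc[list(split.validation_ids)]

    derived_all = add_derived(frame)
    ref_all = derived_all["ffm_dxa_kg"].to_numpy(dtype=float)
    dg_ref = add_derived(dg)["ffm_dxa_kg"].to_numpy(dtype=float)
    cvg_ref = add_derived(cvg)["ffm_dxa_kg"].to_numpy(dtype=float)

    model = stepwise_fit(
        candidate_predictors(dg), dg_ref, alpha_enter, alpha_remove
    )
    dg_pred = model.predict(candidate_predictors(dg))
    cvg_pred = model.predict(candidate_predictors(cvg))
    total_pred = model.predict(candidate_predictors(frame))
    return DevelopmentResult(
        model=model,
        split=split,
        dg_report=build_report("specific_dg", dg_pred, dg_ref, normality_alpha),
        cvg_report=build_report("specific_cvg", cvg_pred, cvg_ref, normality_alpha),
        total_report=build_report("specific_total", total_pred, ref_all, normality_alpha),
    )
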