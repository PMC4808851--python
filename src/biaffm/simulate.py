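"""Synthetic cohorts of young, physically active adult males.

The generator emulates the joint structure of an army-cadet sample:
stature and fat-free mass (FFM) are drawn jointly normal at a configurable
correlation, fat-mass percentage is drawn independently, body weight
follows from FFM / (1 - FM%/100), and resistance is obtained by inverting
the population-specific prediction model

    FFM = c_w * weight + c_log * log10(stature^2 / R) + intercept + eps

so that the two-predictor equation is, by construction, the data-generating
truth.  Reactance is an independent truncated normal.  The DXA components
close exactly: BMC is a fixed fraction of FFM, LST = FFM - BMC, and
FM = weight - FFM, so weight = FM + BMC + LST for every record (real DXA
does not close exactly; see the methods note).

All truncation is by rejection sampling against the configured min/max,
and generated resistance is constrained to a physiologic guard band by
redrawing the whole subject.  A single integer seed drives one named
random stream per channel, so adding a channel never perturbs the draws
of existing ones.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import InputValidationError
from .cohort import COHORT_COLUMNS

__all__ = [
    "CohortConfig",
    "RetestConfig",
    "default_config",
    "default_retest_config",
    "generate",
    "generate_retest",
    "synthesize_response",
    "config_to_json",
    "config_from_json",
    "RESISTANCE_GUARD_BAND",
]

log = logging.getLogger(__name__)

#: Physiologic guard band for whole-body resistance at 50 kHz (ohm).
RESISTANCE_GUARD_BAND = (250.0, 900.0)

_RETEST_CHANNELS = {
    "resistance": ("resistance_ohm", "tem_resistance"),
    "reactance": ("reactance_ohm", "tem_reactance"),
    "fm": ("fm_kg", "tem_fm"),
    "bmc": ("bmc_kg", "tem_bmc"),
    "lst": ("lst_kg", "tem_lst"),
}


@dataclass(frozen=True)
class CohortConfig:
    """Distributional parameters and true-model coefficients of the generator."""

    n: int = 396
    stature_mean: float = 175.8   # cm
    stature_sd: float = 6.4
    stature_min: float = 159.6
    stature_max: float = 192.7
    age_mean: float = 19.2        # years
    age_sd: float = 1.8
    age_min: float = 17.0
    age_max: float = 24.0
    fmpct_mean: float = 17.2      # % of body weight
    fmpct_sd: float = 3.9
    fmpct_min: float = 9.0
    fmpct_max: float = 27.8
    reactance_mean: float = 62.4  # ohm
    reactance_sd: float = 7.0
    reactance_min: float = 27.0
    reactance_max: float = 86.0
    ffm_mean: float = 58.2        # kg (latent, before coupling to stature)
    ffm_sd: float = 6.5
    ffm_min: float = 40.6
    ffm_max: float = 79.5
    stature_ffm_corr: float = 0.6
    true_coef_weight: float = 0.508
    true_coef_logindex: float = 39.234
    true_intercept: float = -48.263
    model_noise_sd: float = 2.2   # kg
    bmc_fraction: float = 3.0 / 58.2
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise InputValidationError("n must be positive")
        for stem in ("stature", "age", "fmpct", "reactance", "ffm"):
            mean = getattr(self, f"{stem}_mean")
            sd = getattr(self, f"{stem}_sd")
            lo = getattr(self, f"{stem}_min")
            hi = getattr(self, f"{stem}_max")
            if sd <= 0:
                raise InputValidationError(f"{stem}_sd must be positive")
            if not lo < mean < hi:
                raise InputValidationError(
                    f"{stem}: require min < mean < max, got {lo}, {mean}, {hi}"
                )
        if not abs(self.stature_ffm_corr) < 1:
            raise InputValidationError("|stature_ffm_corr| must be < 1")
        if self.fmpct_max >= 100:
            raise InputValidationError("fmpct_max >= 100 is non-physical")
        if self.model_noise_sd < 0:
            raise InputValidationError("model_noise_sd must be non-negative")
        if not 0 < self.bmc_fraction < 1:
            raise InputValidationError("bmc_fraction must be in (0, 1)")
        if self.true_coef_logindex == 0:
            raise InputValidationError("true_coef_logindex must be non-zero")


@dataclass(frozen=True)
class RetestConfig:
    """Test-retest noise model: one technical error per measurement channel."""

    tem_resistance: float = 3.54  # ohm
    tem_reactance: float = 0.49   # ohm
    tem_fm: float = 0.25          # kg
    tem_bmc: float = 0.02         # kg
    tem_lst: float = 0.25         # kg
    n_pairs: int = 23

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            if f.name.startswith("tem_") and getattr(self, f.name) < 0:
                raise InputValidationError(f"{f.name} must be non-negative")
        if self.n_pairs < 1:
            raise InputValidationError("n_pairs must be positive")


def default_config() -> CohortConfig:
    """The default study conditions: a 396-subject cadet-like sample."""
    return CohortConfig()


def default_retest_config() -> RetestConfig:
    """Default 23-pair test-retest noise model."""
    return RetestConfig()


def _channel_rng(seed: int, name: str) -> np.random.Generator:
    """One independent, named random stream per channel."""
    return np.random.default_rng([int(seed), zlib.crc32(name.encode()) & 0x7FFFFFFF])


def _truncated_normal(rng, mean, sd, lo, hi, size, max_tries=1000):
    """Rejection-sampled truncated normal (normal in the interior)."""
    out = np.empty(size)
    filled = 0
    for _ in range(max_tries):
        need = size - filled
        draw = rng.normal(mean, sd, need)
        ok = draw[(draw >= lo) & (draw <= hi)]
        out[filled:filled + len(ok)] = ok
        filled += len(ok)
        if filled == size:
            return out
    raise InputValidationError(
        f"truncated-normal rejection did not converge for mean={mean}, "
        f"sd={sd}, bounds=({lo}, {hi})"
    )


def generate(config: CohortConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Generate a synthetic cohort frame in the canonical CSV schema.

    ``seed`` overrides ``config.seed`` when given.  Subjects whose derived
    resistance falls outside :data:`RESISTANCE_GUARD_BAND` are redrawn in
    full; the redraw count is logged at DEBUG level.
    """
    config = default_config() if config is None else config
    config.validate()
    seed = config.seed if seed is None else int(seed)

    rng_sf = _channel_rng(seed, "stature_ffm")
    rng_age = _channel_rng(seed, "age")
    rng_fm = _channel_rng(seed, "fmpct")
    rng_xc = _channel_rng(seed, "reactance")
    rng_eps = _channel_rng(seed, "model_noise")

    n = config.n
    rho = config.stature_ffm_corr
    lo_r, hi_r = RESISTANCE_GUARD_BAND

    def draw_block(m: int):
        # stature-FFM joint truncated normal, joint rejection on both margins
        stature = np.empty(m)
        ffm = np.empty(m)
        filled = 0
        while filled < m:
            need = m - filled
            z1 = rng_sf.standard_normal(need)
            z2 = rng_sf.standard_normal(need)
            s = config.stature_mean + config.stature_sd * z1
            f = config.ffm_mean + config.ffm_sd * (
                rho * z1 + np.sqrt(1 - rho**2) * z2
            )
            ok = (
                (s >= config.stature_min) & (s <= config.stature_max)
                & (f >= config.ffm_min) & (f <= config.ffm_max)
            )
            k = int(ok.sum())
            stature[filled:filled + k] = s[ok]
            ffm[filled:filled + k] = f[ok]
            filled += k
        age = _truncated_normal(
            rng_age, config.age_mean, config.age_sd, config.age_min, config.age_max, m
        )
        fmpct = _truncated_normal(
            rng_fm, config.fmpct_mean, config.fmpct_sd, config.fmpct_min, config.fmpct_max, m
        )
        reactance = _truncated_normal(
            rng_xc, config.reactance_mean, config.reactance_sd,
            config.reactance_min, config.reactance_max, m,
        )
        eps = rng_eps.normal(0.0, config.model_noise_sd, m)
        weight = ffm / (1.0 - fmpct / 100.0)
        # invert the true model for resistance
        log_index = (
            ffm - config.true_coef_weight * weight - config.true_intercept - eps
        ) / config.true_coef_logindex
        resistance = stature**2 / 10.0**log_index
        return stature, ffm, age, fmpct, reactance, weight, resistance

    parts = {k: [] for k in ("stature", "ffm", "age", "fmpct", "reactance", "weight", "resistance")}
    kept = 0
    redraws = 0
    while kept < n:
        block = draw_block(n - kept)
        mask = (block[6] >= lo_r) & (block[6] <= hi_r)
        redraws += int((~mask).sum())
        for key, arr in zip(parts, block):
            parts[key].append(arr[mask])
        kept += int(mask.sum())
    if redraws:
        log.debug("resistance guard band: %d subject redraw(s)", redraws)

    stature = np.concatenate(parts["stature"])
    ffm = np.concatenate(parts["ffm"])
    weight = np.concatenate(parts["weight"])
    bmc = config.bmc_fraction * ffm
    frame = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:04d}" for i in range(n)],
            "age": np.concatenate(parts["age"]),
            "sex": np.ones(n, dtype=int),
            "weight_kg": weight,
            "stature_cm": stature,
            "resistance_ohm": np.concatenate(parts["resistance"]),
            "reactance_ohm": np.concatenate(parts["reactance"]),
            "fm_kg": weight - ffm,
            "bmc_kg": bmc,
            "lst_kg": ffm - bmc,
        },
        columns=COHORT_COLUMNS,
    )
    return frame


def generate_retest(
    cohort: pd.DataFrame,
    retest_config: RetestConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate duplicate measurements on a subsample of the cohort.

    For each sampled subject and each channel, two replicates are drawn as
    the subject's value plus independent N(0, TEM) noise, so the
    within-pair difference has SD TEM*sqrt(2) and the standard TEM
    estimator sqrt(sum(d^2)/(2n)) targets the configured TEM.  Returns a
    long-format frame (subject_id, channel, replicate, value).
    """
    retest_config = default_retest_config() if retest_config is None else retest_config
    retest_config.validate()
    if retest_config.n_pairs > len(cohort):
        raise InputValidationError(
            f"n_pairs={retest_config.n_pairs} exceeds cohort size {len(cohort)}"
        )
    pick = _channel_rng(seed, "retest_sample").choice(
        len(cohort), size=retest_config.n_pairs, replace=False
    )
    sample = cohort.iloc[np.sort(pick)]
    rows = []
    for channel, (column, tem_field) in _RETEST_CHANNELS.items():
        tem = getattr(retest_config, tem_field)
        rng = _channel_rng(seed, f"retest_{channel}")
        truth = sample[column].to_numpy(dtype=float)
        for replicate in (1, 2):
            noisy = truth + rng.normal(0.0, tem, len(truth))
            rows.extend(
                {
                    "subject_id": sid,
                    "channel": channel,
                    "replicate": replicate,
                    "value": val,
                }
                for sid, val in zip(sample["subject_id"], noisy)
            )
    return pd.DataFrame(rows, columns=["subject_id", "channel", "replicate", "value"])


def synthesize_response(
    cohort: pd.DataFrame,
    coef_weight: float = 0.508,
    coef_logindex: float = 39.234,
    intercept: float = -48.263,
    noise_sd: float = 2.2,
    seed: int = 0,
) -> np.ndarray:
    """Synthesize an FFM response from a cohort's predictor columns.

    Returns ``coef_weight*weight + coef_logindex*log10(stature^2/R) +
    intercept + N(0, noise_sd)``.  Because the noise is added to the
    response (not embedded in the predictors), refitting this response by
    OLS is an unbiased parameter-recovery experiment — unlike refitting
    the generator's own FFM, where the model inversion places the noise
    inside the observed resistance (an errors-in-variables design that
    attenuates the log-index slope; see the methods note).
    """
    rng = _channel_rng(seed, "response_noise")
    weight = cohort["weight_kg"].to_numpy(dtype=float)
    log_index = np.log10(
        cohort["stature_cm"].to_numpy(dtype=float) ** 2
        / cohort["resistance_ohm"].to_numpy(dtype=float)
    )
    return (
        coef_weight * weight
        + coef_logindex * log_index
        + intercept
        + rng.normal(0.0, noise_sd, len(cohort))
    )


def config_to_json(config: CohortConfig, path=None) -> str:
    payload = json.dumps(dataclasses.asdict(config), indent=2)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(payload)
    return payload


def config_from_json(source) -> CohortConfig:
    """Load a :class:`CohortConfig` from a JSON string or file path."""
    if isinstance(source, str) and source.lstrip().startswith("{"):
        data = json.loads(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            data = json.load(fh)
    known = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(data) - known
    if unknown:
        raise InputValidationError(f"unknown config fields: {sorted(unknown)}")
    config = CohortConfig(**data)
    config.validate()
    return config
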