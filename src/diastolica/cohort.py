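"""Synthetic patient cohorts with a known proportional-hazards survival truth.

The generator emulates a single-center population evaluated invasively for
diastolic dysfunction: right-skewed serum biomarkers (natriuretic peptides,
sST2, galectin-3, MR-proADM) drawn log-normal from (median, IQR) anchors,
echocardiographic and catheterization parameters, Bernoulli comorbidities, and
an all-cause-death process following a Weibull proportional-hazards model whose
linear predictor acts on median-dichotomized covariates.  Administrative
censoring arises from a uniform enrollment window, giving a median follow-up
of about 1.66 years and an observed mortality of about 14.5% at the default
configuration.

Invasive columns can either be sampled directly from anchored distributions
("sampled" mode) or obtained by simulating one pressure waveform per patient
and running the full hemodynamics extraction ("waveform" mode), which
exercises the analysis chain end to end.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .errors import ParameterError
from .hemodynamics import classify_diastolic_dysfunction, compute_hemodynamic_params
from .waveform import WaveformParams, simulate_waveform

__all__ = [
    "LogNormalSpec",
    "NormalSpec",
    "BernoulliSpec",
    "CohortConfig",
    "Cohort",
    "simulate_cohort",
    "derive_invasive_covariates",
    "INVASIVE_COLUMNS",
]

# z(0.75) - z(0.25): the IQR of a standard normal
_IQR_Z = 1.3489795003921634


@dataclass(frozen=True)
class LogNormalSpec:
    """Log-normal anchored by its median and quartiles.

    ``sigma = ln(q3/q1) / (z75 - z25)``; ``negate=True`` samples the magnitude
    and flips the sign (used for minimum dP/dt, anchored by the magnitude
    quartiles but stored as a negative quantity).
    """

    median: float
    q1: float
    q3: float
    negate: bool = False

    def __post_init__(self) -> None:
        if min(self.median, self.q1, self.q3) <= 0:
            raise ParameterError(
                f"log-normal anchors must be positive, got {self.median}, {self.q1}, {self.q3}"
            )
        if self.q3 < self.q1:
            raise ParameterError("q3 must be >= q1")

    @property
    def mu(self) -> float:
        return math.log(self.median)

    @property
    def sigma(self) -> float:
        return math.log(self.q3 / self.q1) / _IQR_Z

    @property
    def population_median(self) -> float:
        return -self.median if self.negate else self.median

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        x = rng.lognormal(self.mu, self.sigma, size=n)
        return -x if self.negate else x


@dataclass(frozen=True)
class NormalSpec:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ParameterError("sd must be non-negative")

    @property
    def population_median(self) -> float:
        return self.mean

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.normal(self.mean, self.sd, size=n)


@dataclass(frozen=True)
class BernoulliSpec:
    p: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ParameterError("p must be in [0, 1]")

    @property
    def population_median(self) -> float:
        # dichotomized effects use the indicator itself for binary covariates
        return 0.5

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return (rng.random(n) < self.p).astype(float)


CovariateSpec = Union[LogNormalSpec, NormalSpec, BernoulliSpec]


def _default_covariate_specs() -> dict[str, CovariateSpec]:
    """Anchors for the default study population.

    Log-normal medians use the whole-cohort medians where the source summaries
    print them (the Kaplan-Meier cut-offs); quartile ratios come from the
    survivor-group IQRs.  The LVEDP spec is pinned by the printed cohort mean
    (14.0 mmHg) and median (13.5 mmHg), which under a log-normal fixes
    sigma = sqrt(2 ln(mean/median)) ~ 0.27.
    """
    return {
        # clinical
        "male_sex": BernoulliSpec(0.75),
        "age_years": NormalSpec(62.6, 12.6),
        "bmi_kg_m2": NormalSpec(28.9, 4.5),
        "hypertension": BernoulliSpec(0.70),
        "diabetes_mellitus": BernoulliSpec(0.31),
        "chronic_kidney_disease": BernoulliSpec(0.05),
        "atrial_fibrillation": BernoulliSpec(0.18),
        "coronary_artery_disease": BernoulliSpec(0.68),
        "valvular_heart_disease": BernoulliSpec(0.12),
        # serum biomarkers
        "mr_proanp_pg_ml": LogNormalSpec(138.0, 98.0, 193.0),
        "bnp_pg_ml": LogNormalSpec(110.0, 57.0, 249.0),
        "nt_probnp_pg_ml": LogNormalSpec(123.6, 36.0, 424.0),
        "sst2_ng_ml": LogNormalSpec(17.0, 13.2, 22.3),
        "galectin3_ng_ml": LogNormalSpec(9.0, 7.1, 11.1),
        "mr_proadm_pg_ml": LogNormalSpec(216.0, 126.0, 575.0),
        # echocardiography
        "lvef_percent": NormalSpec(48.0, 11.0),
        "gls_percent": NormalSpec(-15.5, 4.5),
        "e_over_eprime": LogNormalSpec(9.8, 7.4, 13.0),
        "lvesv_ml_m2": LogNormalSpec(41.0, 28.8, 58.3),
        "la_volume_ml_m2": LogNormalSpec(36.8, 30.0, 45.0),
    }


def _default_invasive_specs() -> dict[str, CovariateSpec]:
    return {
        "lvedp_mmhg": LogNormalSpec(13.5, 11.24, 16.22),
        "min_dpdt_mmhg_s": LogNormalSpec(1915.0, 1556.0, 2357.0, negate=True),
        "max_dpdt_mmhg_s": LogNormalSpec(1841.0, 1373.0, 2179.0),
        "contraction_integral_mmhg": NormalSpec(158.0, 33.9),
        "relaxation_integral_mmhg": NormalSpec(140.1, 27.8),
        "diastolic_integral_mmhg_s": LogNormalSpec(22.0, 16.0, 32.4),
    }


def _default_log_hazards() -> dict[str, float]:
    """True effects on the dichotomized (> population median) scale.

    Magnitudes follow the multivariable hazard ratios of the study the
    generator emulates: E/E' 2.02, NT-proBNP 2.25, sST2 1.58, LVESV 1.15 and
    minimum dP/dt 2.13 (less-negative dP/dt, i.e. above the median, is the
    high-risk stratum).
    """
    return {
        "nt_probnp_pg_ml": math.log(2.25),
        "sst2_ng_ml": math.log(1.58),
        "e_over_eprime": math.log(2.02),
        "lvesv_ml_m2": math.log(1.15),
        "min_dpdt_mmhg_s": math.log(2.13),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration; defaults reproduce the study conditions.

    The Weibull baseline scale and the enrollment/censoring window are
    calibrated so that the default cohort shows ~14.5% observed mortality
    (about 9% within the first year) over a median follow-up of ~1.66 years.
    """

    n: int = 110
    covariate_specs: Mapping[str, CovariateSpec] = field(
        default_factory=_default_covariate_specs
    )
    invasive_specs: Mapping[str, CovariateSpec] = field(
        default_factory=_default_invasive_specs
    )
    log_hazards: Mapping[str, float] = field(default_factory=_default_log_hazards)
    continuous_effects: Mapping[str, float] = field(default_factory=dict)
    weibull_shape: float = 1.2
    weibull_scale: float = 34.0       # years; calibrated, see docs/methods.md
    censor_min: float = 0.85          # years: horizon minus enrollment window
    censor_max: float = 2.78          # years: full administrative horizon
    invasive_mode: str = "sampled"    # "sampled" | "waveform"
    seed: int = 0

    def validate(self) -> None:
        if self.n < 2:
            raise ParameterError("n must be at least 2")
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ParameterError("Weibull shape and scale must be positive")
        if not (0 <= self.censor_min < self.censor_max):
            raise ParameterError("require 0 <= censor_min < censor_max")
        if self.invasive_mode not in ("sampled", "waveform"):
            raise ParameterError(f"unknown invasive_mode {self.invasive_mode!r}")
        unknown = set(self.log_hazards) - set(self.covariate_specs) - set(self.invasive_specs)
        if unknown:
            raise ParameterError(f"log_hazards name unknown covariates: {sorted(unknown)}")


INVASIVE_COLUMNS = tuple(_default_invasive_specs())


@dataclass
class Cohort:
    """Patient table plus the hidden generating truth."""

    data: pd.DataFrame
    truth: CohortConfig | None = None

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path: str | Path, truth_sidecar: bool = True) -> None:
        path = Path(path)
        self.data.to_csv(path, index=False)
        if truth_sidecar and self.truth is not None:
            sidecar = path.with_suffix(path.suffix + ".truth.json")
            sidecar.write_text(json.dumps(_config_to_jsonable(self.truth), indent=2))


def _config_to_jsonable(config: CohortConfig) -> dict:
    def enc(value):
        if dataclasses.is_dataclass(value) and not isinstance(value, type):
            d = dataclasses.asdict(value)
            d["__spec__"] = type(value).__name__
            return d
        if isinstance(value, Mapping):
            return {k: enc(v) for k, v in value.items()}
        return value

    return {f.name: enc(getattr(config, f.name)) for f in dataclasses.fields(config)}


def _linear_predictor(df: pd.DataFrame, config: CohortConfig) -> np.ndarray:
    specs = {**config.covariate_specs, **config.invasive_specs}
    lp = np.zeros(len(df))
    for name, beta in config.log_hazards.items():
        spec = specs[name]
        if isinstance(spec, BernoulliSpec):
            indicator = df[name].to_numpy() > 0.5
        else:
            indicator = df[name].to_numpy() > spec.population_median
        lp += beta * indicator
    for name, beta in config.continuous_effects.items():
        lp += beta * df[name].to_numpy()
    return lp


def simulate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Draw one cohort: covariates, invasive parameters, survival outcome.

    Event times follow a Weibull proportional-hazards model,
    ``S(t | x) = exp(-(t/scale)^shape * exp(lp(x)))`` with the linear predictor
    built from median-dichotomized covariates; follow-up is the minimum of the
    event time and a Uniform(censor_min, censor_max) administrative censoring
    time.  Fully reproducible from ``config.seed``.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    data = {
        name: spec.sample(rng, config.n) for name, spec in config.covariate_specs.items()
    }
    df = pd.DataFrame(data)
    df.insert(0, "patient_id", np.arange(1, config.n + 1))

    cohort = Cohort(data=df, truth=config)
    cohort = derive_invasive_covariates(cohort, mode=config.invasive_mode, _rng=rng)
    df = cohort.data

    lp = _linear_predictor(df, config)
    # inverse-transform sampling of the Weibull PH event time
    u = rng.exponential(1.0, size=config.n)
    event_time = config.weibull_scale * (u / np.exp(lp)) ** (1.0 / config.weibull_shape)
    censor_time = rng.uniform(config.censor_min, config.censor_max, size=config.n)

    event = (event_time <= censor_time).astype(int)
    follow_up = np.minimum(event_time, censor_time)
    df["follow_up_years"] = follow_up
    df["event"] = event
    return Cohort(data=df, truth=config)


def derive_invasive_covariates(
    cohort: Cohort,
    mode: str = "sampled",
    _rng: np.random.Generator | None = None,
) -> Cohort:
    """Attach catheterization-derived columns to a cohort.

    ``sampled``: draw each invasive parameter from its anchored distribution.
    ``waveform``: simulate one pressure recording per patient — with the
    patient's true end-diastolic pressure and relaxation/contraction timing
    solved from the sampled dP/dt targets — then run the full hemodynamics
    extraction, so the invasive columns are *measured*, not copied, values.
    Survival columns, if present, are left untouched.
    """
    config = cohort.truth or CohortConfig(n=len(cohort))
    if mode not in ("sampled", "waveform"):
        raise ParameterError(f"unknown invasive mode {mode!r}")
    rng = _rng or np.random.default_rng(config.seed + 104729)
    df = cohort.data.copy()
    n = len(df)

    sampled = {name: spec.sample(rng, n) for name, spec in config.invasive_specs.items()}

    if mode == "sampled":
        for name, values in sampled.items():
            df[name] = values
        if "lvedp_mmhg" in df.columns:
            df["diastolic_dysfunction"] = (df["lvedp_mmhg"] > 15.0).astype(int)
        return Cohort(data=df, truth=cohort.truth)

    base = WaveformParams(noise_sd=0.5, resp_amplitude=3.0)
    rows = []
    seeds = rng.integers(0, 2**31 - 1, size=n)
    for i in range(n):
        p_ed = float(sampled["lvedp_mmhg"][i])
        min_target = abs(float(sampled["min_dpdt_mmhg_s"][i]))
        max_target = abs(float(sampled["max_dpdt_mmhg_s"][i]))
        # solve phase durations from the closed-form extrema, clipped to keep
        # both phases inside the cycle
        t_fall = float(np.clip((base.p_peak - base.p_es) * math.pi / (2 * min_target), 0.06, 0.30))
        t_up = float(np.clip((base.p_peak - p_ed) * math.pi / (2 * max_target), 0.06, 0.30))
        params = replace(
            base,
            p_ed=p_ed,
            t_upstroke=t_up,
            t_fall=t_fall,
            seed=int(seeds[i]),
        )
        try:
            waveform, _ = simulate_waveform(params)
            hp = compute_hemodynamic_params(waveform, k=5)
        except Exception as exc:  # pragma: no cover - surfaced with patient id
            raise ParameterError(
                f"hemodynamics extraction failed for patient_id="
                f"{df['patient_id'].iloc[i] if 'patient_id' in df else i}: {exc}"
            ) from exc
        rows.append(hp)

    df["lvedp_mmhg"] = [h.lvedp for h in rows]
    df["min_dpdt_mmhg_s"] = [h.min_dpdt for h in rows]
    df["max_dpdt_mmhg_s"] = [h.max_dpdt for h in rows]
    df["contraction_integral_mmhg"] = [h.contraction_integral for h in rows]
    df["relaxation_integral_mmhg"] = [h.relaxation_integral for h in rows]
    df["diastolic_integral_mmhg_s"] = [h.diastolic_integral for h in rows]
    df["diastolic_dysfunction"] = [
        int(classify_diastolic_dysfunction(h.lvedp)) for h in rows
    ]
    return Cohort(data=df, truth=cohort.truth)
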