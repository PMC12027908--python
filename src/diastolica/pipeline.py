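"""End-to-end orchestration of the two clinical-scenario survival analyses.

The non-invasive scenario models long-term survival from clinical covariates,
serum biomarkers and echocardiographic parameters; the invasive scenario adds
the catheterization-derived pressure-curve parameters.  For each scenario the
pipeline produces a descriptive comparison (by 1-year mortality), univariate
Cox regressions, Kaplan-Meier curves for median-dichotomized predictors, a
forward-stepwise-BIC multivariable Cox model with bootstrap confidence
intervals, and Harrell's C for the final model.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort
from .errors import ParameterError, ValidationError
from .survival import (
    KMCurve,
    SelectedModel,
    compare_descriptives,
    fit_cox,
    kaplan_meier,
    median_dichotomize,
    stepwise_bic,
)
from .waveform import PressureWaveform

__all__ = [
    "ScenarioConfig",
    "ModelReport",
    "run_analysis",
    "read_waveform_csv",
    "write_waveform_csv",
    "read_cohort_csv",
    "summarize_cohort",
    "NON_INVASIVE_CANDIDATES",
    "INVASIVE_CANDIDATES",
    "write_report",
]

logger = logging.getLogger(__name__)

WAVEFORM_COLUMNS = ("time_s", "pressure_mmHg")

NON_INVASIVE_CANDIDATES: tuple[str, ...] = (
    "e_over_eprime",
    "nt_probnp_pg_ml",
    "sst2_ng_ml",
    "lvesv_ml_m2",
    "bnp_pg_ml",
    "mr_proanp_pg_ml",
    "galectin3_ng_ml",
    "mr_proadm_pg_ml",
    "lvef_percent",
    "gls_percent",
    "la_volume_ml_m2",
)
INVASIVE_CANDIDATES: tuple[str, ...] = NON_INVASIVE_CANDIDATES + (
    "min_dpdt_mmhg_s",
    "lvedp_mmhg",
    "contraction_integral_mmhg",
    "relaxation_integral_mmhg",
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Which candidate covariates enter the multivariable selection."""

    scenario: str = "non_invasive"     # "non_invasive" | "invasive"
    candidates: tuple[str, ...] = ()
    dichotomize: bool = True
    seed: int = 0
    bootstrap_B: int = 1000

    def __post_init__(self) -> None:
        if self.scenario not in ("non_invasive", "invasive"):
            raise ParameterError(f"unknown scenario {self.scenario!r}")
        if not self.candidates:
            default = (
                NON_INVASIVE_CANDIDATES
                if self.scenario == "non_invasive"
                else INVASIVE_CANDIDATES
            )
            object.__setattr__(self, "candidates", default)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "candidates" in raw and raw["candidates"] is not None:
            raw["candidates"] = tuple(raw["candidates"])
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ModelReport:
    """All scenario outputs, traceable to the seed and config hash."""

    scenario: str
    summary: dict
    descriptives: pd.DataFrame
    univariate: pd.DataFrame
    km_curves: dict[str, dict[str, KMCurve]]  # variable -> {"above"/"below": curve}
    cutoffs: dict[str, float]
    selected_model: SelectedModel
    provenance: dict


def read_waveform_csv(path: str | Path) -> PressureWaveform:
    """Read a two-column ``time_s,pressure_mmHg`` trace."""
    df = pd.read_csv(path)
    missing = [c for c in WAVEFORM_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    p = df["pressure_mmHg"].to_numpy(dtype=float)
    if not np.all(np.isfinite(t)) or not np.all(np.isfinite(p)):
        bad = np.flatnonzero(~(np.isfinite(t) & np.isfinite(p)))
        raise ValidationError(f"{path}: non-numeric/non-finite rows {bad[:5].tolist()}")
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.flatnonzero(dt <= 0)[0]) + 1
        raise ValidationError(f"{path}: time not strictly increasing at row {row}")
    fs = 1.0 / float(np.median(dt))
    return PressureWaveform(time=t, pressure=p, sampling_rate=fs)


def write_waveform_csv(waveform: PressureWaveform, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": waveform.time, "pressure_mmHg": waveform.pressure}
    ).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> Cohort:
    """Read and validate a patient table.

    Requires ``follow_up_years`` (positive) and ``event`` in {0, 1}; every
    other column must be numeric.  Errors name the offending columns/rows.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("follow_up_years", "event") if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValidationError(
                f"{path}: non-numeric values in {col!r} at rows {list(bad[:5])}"
            )
        df[col] = coerced
    if (df["follow_up_years"] <= 0).any():
        rows = list(df.index[df["follow_up_years"] <= 0][:5])
        raise ValidationError(f"{path}: non-positive follow_up_years at rows {rows}")
    bad_event = df.index[~df["event"].isin((0, 1))]
    if len(bad_event):
        raise ValidationError(
            f"{path}: event values outside {{0,1}} at rows {list(bad_event[:5])}"
        )
    return Cohort(data=df, truth=None)


def _pct(count: int, n: int) -> float:
    """Percentage truncated to one decimal (16/110 -> 14.5, 10/110 -> 9.0,
    50/110 -> 45.4), the convention of the clinical tables this mirrors."""
    return math.floor(1000.0 * count / n + 1e-9) / 10.0


def summarize_cohort(cohort: Cohort | pd.DataFrame) -> dict:
    """Headline cohort counts and rates (percentages to 1 decimal)."""
    df = cohort.data if isinstance(cohort, Cohort) else cohort
    if len(df) == 0:
        raise ParameterError("cohort is empty")
    n = len(df)
    deaths = int(df["event"].sum())
    one_year = int(((df["event"] == 1) & (df["follow_up_years"] <= 1.0)).sum())
    fu = df["follow_up_years"].to_numpy(dtype=float)
    q1, med, q3 = np.percentile(fu, [25, 50, 75])
    out = {
        "n": n,
        "deaths": deaths,
        "death_pct": _pct(deaths, n),
        "one_year_deaths": one_year,
        "one_year_death_pct": _pct(one_year, n),
        "median_follow_up_years": float(med),
        "follow_up_iqr_years": (float(q1), float(q3)),
    }
    if "lvedp_mmhg" in df.columns:
        dd = int((df["lvedp_mmhg"] > 15.0).sum())
        out["diastolic_dysfunction_n"] = dd
        out["diastolic_dysfunction_pct"] = _pct(dd, n)
    return out


def _one_year_death_group(df: pd.DataFrame) -> np.ndarray:
    return ((df["event"] == 1) & (df["follow_up_years"] <= 1.0)).to_numpy()


def run_analysis(
    cohort: Cohort | pd.DataFrame | str | Path,
    config: ScenarioConfig | None = None,
) -> ModelReport:
    """Run one clinical scenario end to end on a cohort table."""
    config = config or ScenarioConfig()
    if isinstance(cohort, (str, Path)):
        cohort = read_cohort_csv(cohort)
    df = (cohort.data if isinstance(cohort, Cohort) else cohort).copy()

    missing = [c for c in config.candidates if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort lacks candidate column(s): {missing}")
    times = df["follow_up_years"].to_numpy(dtype=float)
    events = df["event"].to_numpy(dtype=int)

    logger.info(
        "run_analysis scenario=%s seed=%d config=%s n=%d",
        config.scenario, config.seed, config.hash(), len(df),
    )

    descriptives = compare_descriptives(
        df,
        _one_year_death_group(df),
        variables=[c for c in df.columns if c not in ("patient_id", "follow_up_years", "event")],
    )

    uni_rows = []
    for name in config.candidates:
        try:
            fit = fit_cox(df[[name]], times, events)
        except Exception as exc:
            logger.warning("univariate Cox failed for %r: %s", name, exc)
            continue
        uni_rows.append(
            {
                "variable": name,
                "HR": float(fit.hazard_ratios[0]),
                "ci_lower": float(fit.ci_lower[0]),
                "ci_upper": float(fit.ci_upper[0]),
                "p": float(fit.p_values[0]),
            }
        )
    univariate = pd.DataFrame(uni_rows)

    cutoffs: dict[str, float] = {}
    km_curves: dict[str, dict[str, KMCurve]] = {}
    design = pd.DataFrame(index=df.index)
    for name in config.candidates:
        values = df[name].to_numpy(dtype=float)
        if config.dichotomize and len(np.unique(values)) > 2:
            cutoff, indicator = median_dichotomize(values)
            cutoffs[name] = cutoff
            design[f"{name}_gt_median"] = indicator
        else:
            indicator = (values > 0.5).astype(int)
            design[name] = values
        above, below = indicator == 1, indicator == 0
        if events[above].sum() + events[below].sum() > 0 and above.any() and below.any():
            km_curves[name] = {
                "above": kaplan_meier(times[above], events[above]),
                "below": kaplan_meier(times[below], events[below]),
            }

    selected = stepwise_bic(design, times, events)
    if selected.final_fit is not None and config.bootstrap_B:
        final = fit_cox(
            design[list(selected.selected)],
            times,
            events,
            bootstrap_B=config.bootstrap_B,
            bootstrap_seed=config.seed,
        )
        selected = SelectedModel(
            selected=selected.selected,
            bic_trajectory=selected.bic_trajectory,
            final_fit=final,
            c_statistic=selected.c_statistic,
        )

    summary = summarize_cohort(df)
    return ModelReport(
        scenario=config.scenario,
        summary=summary,
        descriptives=descriptives,
        univariate=univariate,
        km_curves=km_curves,
        cutoffs=cutoffs,
        selected_model=selected,
        provenance={
            "seed": config.seed,
            "config_hash": config.hash(),
            "version": __version__,
        },
    )


def write_report(report: ModelReport, outdir: str | Path) -> None:
    """Serialize a report: JSON blocks, CSV tables, per-stratum KM CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.descriptives.to_csv(outdir / "descriptives.csv", index=False)
    report.univariate.to_csv(outdir / "univariate_cox.csv", index=False)

    model = report.selected_model
    model_block: dict = {
        "selected": list(model.selected),
        "bic_trajectory": list(model.bic_trajectory),
        "c_statistic": model.c_statistic,
    }
    if model.final_fit is not None:
        model_block["fit"] = {
            name: {
                "HR": float(hr),
                "ci_lower": float(lo),
                "ci_upper": float(hi),
                "p": float(p),
                "ci_method": model.final_fit.ci_method,
            }
            for name, hr, lo, hi, p in zip(
                model.final_fit.names,
                model.final_fit.hazard_ratios,
                model.final_fit.ci_lower,
                model.final_fit.ci_upper,
                model.final_fit.p_values,
            )
        }
    payload = {
        "scenario": report.scenario,
        "summary": report.summary,
        "cutoffs": report.cutoffs,
        "model": model_block,
        "provenance": report.provenance,
    }
    (outdir / "report.json").write_text(json.dumps(payload, indent=2, default=str))

    km_dir = outdir / "km"
    km_dir.mkdir(exist_ok=True)
    for name, strata in report.km_curves.items():
        for stratum, curve in strata.items():
            curve.to_frame().to_csv(km_dir / f"{name}_{stratum}.csv", index=False)
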