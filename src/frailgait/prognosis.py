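"""Mortality risk scoring and frailty-adjusted survival models.

The MAGGIC risk score is the published integer heart-failure mortality
score: points accrue over 13 clinical covariates (age banded per decade
with an ejection-fraction interaction, BMI, systolic blood pressure
banded per 10 mmHg with an EF interaction, EF banded per 5% up to 40,
creatinine banded per 10 up to 350 umol/L, NYHA class, and binary points
for male sex, current smoking, diabetes, COPD, heart-failure duration
over 18 months, and absence of ACE-inhibitor/ARB or beta-blocker
therapy), to a maximum total of 57.  The full point table is embedded as
a versioned constant.

Cox proportional-hazards models relate the predicted frailty rating
(integer CFS or continuous FL) to all-cause death with increasing
adjustment: unadjusted; + age and sex; + MAGGIC total; + MAGGIC and
log NT-pro BNP; + MAGGIC, log NT-pro BNP and serum albumin.  The
proportional-hazards assumption is checked on scaled Schoenfeld
residuals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test

__all__ = [
    "MAGGIC_TABLE_VERSION",
    "MaggicScore",
    "maggic_score",
    "maggic_worst_profile",
    "maggic_extreme_total",
    "fit_cox_models",
    "CoxModelResult",
]

MAGGIC_TABLE_VERSION = "1.0"

# --- embedded integer point table ------------------------------------------

# ejection fraction (%): band lower edges and points
_EF_BANDS = ((0, 7), (20, 6), (25, 5), (30, 3), (35, 2), (40, 0))

# age points depend on the EF band group: EF <30 / 30-39 / >=40
_AGE_BANDS = (
    (0, (0, 0, 0)),
    (55, (1, 2, 3)),
    (60, (2, 4, 5)),
    (65, (4, 6, 7)),
    (70, (6, 8, 9)),
    (75, (8, 10, 12)),
    (80, (10, 13, 15)),
)

# systolic blood pressure (mmHg), same EF grouping
_SBP_BANDS = (
    (0, (5, 3, 2)),
    (110, (4, 2, 1)),
    (120, (3, 1, 1)),
    (130, (2, 1, 0)),
    (140, (1, 0, 0)),
    (150, (0, 0, 0)),
)

_BMI_BANDS = ((0, 6), (15, 5), (20, 3), (25, 2), (30, 0))

# creatinine (umol/L); values above 350 are scored as the top band
_CREAT_BANDS = (
    (0, 0), (90, 1), (100, 2), (110, 2), (120, 3),
    (140, 3), (150, 4), (170, 5), (210, 6), (250, 8),
)

_NYHA_POINTS = {1: 0, 2: 2, 3: 6, 4: 8}

_BINARY_POINTS = {
    "male": 1,
    "current_smoker": 1,
    "diabetes": 3,
    "copd": 2,
    "hf_duration_gt18mo": 2,
    "no_acei_arb": 1,
    "no_beta_blocker": 3,
}

_REQUIRED_COVARIATES = (
    "age_y", "sex", "bmi_kgm2", "sbp_mmHg", "lvef_pct", "nyha_class",
    "current_smoker", "diabetes", "copd", "hf_duration_gt18mo",
    "creatinine_umolL", "acei_arb_use", "beta_blocker_use",
)

_PHYSIOLOGICAL_RANGES = {
    "age_y": (18.0, 110.0),
    "bmi_kgm2": (8.0, 80.0),
    "sbp_mmHg": (50.0, 260.0),
    "lvef_pct": (5.0, 85.0),
    "creatinine_umolL": (20.0, 350.0),
}


def _band_points(value: float, bands) -> int | tuple:
    pts = bands[0][1]
    for lower, p in bands:
        if value >= lower:
            pts = p
    return pts


def _ef_group(lvef: float) -> int:
    if lvef < 30:
        return 0
    if lvef < 40:
        return 1
    return 2


@dataclass(frozen=True)
class MaggicScore:
    total_points: int
    components: dict[str, int]

    def __post_init__(self) -> None:
        assert self.total_points == sum(self.components.values())


def maggic_score(record: Mapping[str, float]) -> MaggicScore:
    """Integer MAGGIC risk score of one subject.

    ``record`` must provide the 13 covariates (see the cohort column
    schema); ``sex`` is 1 for male.  A covariate outside its
    physiological range is clamped to the table bounds with a warning.
    """
    missing = [k for k in _REQUIRED_COVARIATES if k not in record]
    if missing:
        raise KeyError(f"missing MAGGIC covariates: {missing}")
    vals = {k: float(record[k]) for k in _REQUIRED_COVARIATES}
    for key, (lo, hi) in _PHYSIOLOGICAL_RANGES.items():
        if not lo <= vals[key] <= hi:
            warnings.warn(
                f"{key}={vals[key]:g} outside [{lo:g}, {hi:g}]; clamped",
                stacklevel=2,
            )
            vals[key] = min(max(vals[key], lo), hi)
    nyha = int(vals["nyha_class"])
    if nyha not in _NYHA_POINTS:
        raise ValueError(f"nyha_class must be 1-4, got {nyha}")
    grp = _ef_group(vals["lvef_pct"])
    comp = {
        "lvef": _band_points(vals["lvef_pct"], _EF_BANDS),
        "age": _band_points(vals["age_y"], _AGE_BANDS)[grp],
        "sbp": _band_points(vals["sbp_mmHg"], _SBP_BANDS)[grp],
        "bmi": _band_points(vals["bmi_kgm2"], _BMI_BANDS),
        "creatinine": _band_points(vals["creatinine_umolL"], _CREAT_BANDS),
        "nyha": _NYHA_POINTS[nyha],
        "male": _BINARY_POINTS["male"] * int(vals["sex"] > 0),
        "current_smoker": _BINARY_POINTS["current_smoker"] * int(vals["current_smoker"] > 0),
        "diabetes": _BINARY_POINTS["diabetes"] * int(vals["diabetes"] > 0),
        "copd": _BINARY_POINTS["copd"] * int(vals["copd"] > 0),
        "hf_duration_gt18mo": _BINARY_POINTS["hf_duration_gt18mo"]
        * int(vals["hf_duration_gt18mo"] > 0),
        "no_acei_arb": _BINARY_POINTS["no_acei_arb"] * int(vals["acei_arb_use"] <= 0),
        "no_beta_blocker": _BINARY_POINTS["no_beta_blocker"]
        * int(vals["beta_blocker_use"] <= 0),
    }
    return MaggicScore(total_points=sum(comp.values()), components=comp)


def maggic_extreme_total(which: str = "max") -> tuple[int, dict[str, float]]:
    """Exhaustively enumerate every point-table band for the extreme total.

    The interactions (age and SBP points depend on the EF band) make a
    per-component greedy choice unsafe, so the banded covariates are
    enumerated jointly over all their band combinations; each binary
    covariate is additive and enumerated over both settings.  Returns
    the extreme total together with a profile that achieves it.
    """
    sign = 1 if which == "max" else -1
    if which not in ("max", "min"):
        raise ValueError("which must be 'max' or 'min'")
    best = None
    for ef_lo, ef_pts in _EF_BANDS:
        ef_val = ef_lo + 1.0
        grp = _ef_group(ef_val)
        for age_lo, age_pts in _AGE_BANDS:
            for sbp_lo, sbp_pts in _SBP_BANDS:
                for bmi_lo, bmi_pts in _BMI_BANDS:
                    for cr_lo, cr_pts in _CREAT_BANDS:
                        for nyha, nyha_pts in _NYHA_POINTS.items():
                            banded = (
                                ef_pts + age_pts[grp] + sbp_pts[grp]
                                + bmi_pts + cr_pts + nyha_pts
                            )
                            if best is None or sign * banded > sign * best[0]:
                                best = (banded, ef_val, age_lo, sbp_lo,
                                        bmi_lo, cr_lo, nyha)
    assert best is not None
    banded_total, ef_val, age_lo, sbp_lo, bmi_lo, cr_lo, nyha = best
    # binaries: additive, both settings enumerated per covariate
    binary_choice = {
        name: (1 if sign * pts > 0 else 0)
        for name, pts in _BINARY_POINTS.items()
    }
    binary_total = sum(
        pts * binary_choice[name] for name, pts in _BINARY_POINTS.items()
    )
    profile = {
        "lvef_pct": max(ef_val, _PHYSIOLOGICAL_RANGES["lvef_pct"][0]),
        "age_y": max(age_lo + 1.0, _PHYSIOLOGICAL_RANGES["age_y"][0]),
        "sbp_mmHg": max(sbp_lo + 1.0, _PHYSIOLOGICAL_RANGES["sbp_mmHg"][0]),
        "bmi_kgm2": max(bmi_lo + 1.0, _PHYSIOLOGICAL_RANGES["bmi_kgm2"][0]),
        "creatinine_umolL": max(
            cr_lo + 1.0, _PHYSIOLOGICAL_RANGES["creatinine_umolL"][0]
        ),
        "nyha_class": float(nyha),
        "sex": float(binary_choice["male"]),
        "current_smoker": float(binary_choice["current_smoker"]),
        "diabetes": float(binary_choice["diabetes"]),
        "copd": float(binary_choice["copd"]),
        "hf_duration_gt18mo": float(binary_choice["hf_duration_gt18mo"]),
        "acei_arb_use": float(1 - binary_choice["no_acei_arb"]),
        "beta_blocker_use": float(1 - binary_choice["no_beta_blocker"]),
    }
    total = banded_total + binary_total
    check = maggic_score(profile).total_points
    if check != total:
        raise AssertionError(
            f"enumeration total {total} disagrees with scorer total {check}"
        )
    return total, profile


def maggic_worst_profile() -> dict[str, float]:
    return maggic_extreme_total("max")[1]


# --- Cox models -------------------------------------------------------------

MODEL_ADJUSTMENTS: dict[str, tuple[str, ...]] = {
    "unadjusted": (),
    "model1_age_sex": ("age_y", "sex"),
    "model2_maggic": ("maggic_total",),
    "model3_maggic_bnp": ("maggic_total", "log_ntprobnp"),
    "model4_maggic_bnp_alb": ("maggic_total", "log_ntprobnp", "albumin_gdl"),
}


@dataclass(frozen=True)
class CoxModelResult:
    model: str
    exposure: str
    hr_per_unit: float
    ci_low: float
    ci_high: float
    p_value: float
    ph_test_p: float
    n: int
    n_events: int


class CoxModelError(RuntimeError):
    pass


def fit_cox_models(
    cohort: pd.DataFrame,
    exposure: str = "predicted_cfs",
    log_ntprobnp: bool = True,
    models: tuple[str, ...] | None = None,
) -> dict[str, CoxModelResult]:
    """Fit the five increasingly adjusted Cox models for all-cause death.

    ``cohort`` needs ``time_days``, ``event``, the exposure column, and
    the adjusters (MAGGIC covariates for models 2-4; ``ntprobnp_pgml``
    and ``albumin_gdl`` for models 3-4).  NT-pro BNP enters
    log-transformed by default (it is heavily right-skewed).  Ties are
    handled by Efron's method (lifelines' default).
    """
    df = cohort.copy()
    if df["event"].sum() < 1:
        raise CoxModelError("no events in the cohort")
    if df[exposure].isna().any():
        raise CoxModelError(f"exposure {exposure!r} missing for some subjects")
    if "maggic_total" not in df.columns:
        df["maggic_total"] = [
            maggic_score(row).total_points for _, row in df.iterrows()
        ]
    if "ntprobnp_pgml" in df.columns:
        df["log_ntprobnp"] = (
            np.log(df["ntprobnp_pgml"]) if log_ntprobnp else df["ntprobnp_pgml"]
        )
    wanted = MODEL_ADJUSTMENTS if models is None else {
        m: MODEL_ADJUSTMENTS[m] for m in models
    }
    results: dict[str, CoxModelResult] = {}
    for model_name, adjusters in wanted.items():
        cols = [exposure, *adjusters, "time_days", "event"]
        sub = df[cols].dropna()
        cph = CoxPHFitter()
        try:
            cph.fit(sub, duration_col="time_days", event_col="event")
        except Exception as exc:  # convergence failures carry the model id
            raise CoxModelError(f"Cox model {model_name!r} failed: {exc}") from exc
        summ = cph.summary.loc[exposure]
        ph = proportional_hazard_test(cph, sub, time_transform="rank")
        ph_p = float(ph.summary.loc[exposure, "p"])
        results[model_name] = CoxModelResult(
            model=model_name,
            exposure=exposure,
            hr_per_unit=float(summ["exp(coef)"]),
            ci_low=float(summ["exp(coef) lower 95%"]),
            ci_high=float(summ["exp(coef) upper 95%"]),
            p_value=float(summ["p"]),
            ph_test_p=ph_p,
            n=len(sub),
            n_events=int(sub["event"].sum()),
        )
    return results


def cox_report(results: Mapping[str, CoxModelResult]) -> pd.DataFrame:
    """Table-style report: one row per model."""
    return pd.DataFrame(
        [
            {
                "model": r.model,
                "exposure": r.exposure,
                "HR": r.hr_per_unit,
                "CI_low": r.ci_low,
                "CI_high": r.ci_high,
                "p": r.p_value,
                "PH_p": r.ph_test_p,
                "n": r.n,
                "events": r.n_events,
            }
            for r in results.values()
        ]
    ).set_index("model")
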