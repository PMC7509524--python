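"""The PREDICT-PD risk algorithm.

Baseline odds of Parkinson's disease at a given age:

    odds(age) = 1 / (1 + c0 + c1 * exp(-k * (age - 60)))

with c0 = 28.53049, c1 = 73.67057 and k = 0.165308 per year — strictly
increasing in age and bounded above by 1/(1 + c0).  The baseline odds are then
multiplied by fixed trait odds multipliers (female sex divides by 1.5; current
smoking x0.44, previous smoking x0.78, family history of PD x4.45, >1 cup of
coffee/day x0.67, >1 alcoholic drink/week x0.9, constipation x2.34, anxiety or
depression x1.86, erectile dysfunction x3.8 in males).  Missing traits are
treated as absent (multiplier 1); the erectile-dysfunction multiplier is
skipped, not imputed, for females.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd


class Smoking(str, Enum):
    NEVER = "never"
    PREVIOUS = "previous"
    CURRENT = "current"


@dataclass(frozen=True)
class PredictPDBaseline:
    c0: float = 28.53049
    c1: float = 73.67057
    k: float = 0.165308  # per year
    age_ref: float = 60.0


@dataclass(frozen=True)
class MultiplierTable:
    female_divisor: float = 1.5
    smoking_current: float = 0.44
    smoking_previous: float = 0.78
    family_history_pd: float = 4.45
    coffee_gt1cup: float = 0.67
    alcohol_gt1wk: float = 0.9
    constipation: float = 2.34
    anxiety_or_depression: float = 1.86
    erectile_dysfunction: float = 3.8

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"multiplier {name} must be positive")


@dataclass
class PredictPDProfile:
    age: float
    female: bool = False
    smoking: Smoking = Smoking.NEVER
    family_history_pd: bool = False
    coffee_gt1cup: bool = False
    alcohol_gt1wk: bool = False
    constipation: bool = False
    anxiety_or_depression: bool = False
    erectile_dysfunction: bool = False

    def __post_init__(self) -> None:
        self.smoking = Smoking(self.smoking)
        if self.female:
            self.erectile_dysfunction = False


def baseline_odds(age, baseline: PredictPDBaseline = PredictPDBaseline()):
    """Age-based baseline odds of PD; accepts scalars or arrays."""
    age_arr = np.asarray(age, dtype=float)
    if not np.all(np.isfinite(age_arr)):
        raise ValueError("age must be finite")
    odds = 1.0 / (
        1.0 + baseline.c0 + baseline.c1 * np.exp(-baseline.k * (age_arr - baseline.age_ref))
    )
    return float(odds) if np.isscalar(age) or age_arr.ndim == 0 else odds


def apply_profile(
    odds: float,
    profile: PredictPDProfile,
    table: MultiplierTable = MultiplierTable(),
) -> float:
    """Multiply the baseline odds by each applicable trait factor."""
    if odds <= 0:
        raise ValueError("odds must be positive")
    out = odds
    if profile.female:
        out /= table.female_divisor
    if profile.smoking is Smoking.CURRENT:
        out *= table.smoking_current
    elif profile.smoking is Smoking.PREVIOUS:
        out *= table.smoking_previous
    if profile.family_history_pd:
        out *= table.family_history_pd
    if profile.coffee_gt1cup:
        out *= table.coffee_gt1cup
    if profile.alcohol_gt1wk:
        out *= table.alcohol_gt1wk
    if profile.constipation:
        out *= table.constipation
    if profile.anxiety_or_depression:
        out *= table.anxiety_or_depression
    if profile.erectile_dysfunction and not profile.female:
        out *= table.erectile_dysfunction
    return out


def odds_to_probability(odds):
    odds = np.asarray(odds, dtype=float)
    if np.any(odds < 0):
        raise ValueError("odds must be non-negative")
    out = odds / (1.0 + odds)
    return float(out) if out.ndim == 0 else out


def probability_to_odds(p):
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p >= 1)):
        raise ValueError("probability must lie in [0, 1)")
    out = p / (1.0 - p)
    return float(out) if out.ndim == 0 else out


def log_odds(odds):
    odds = np.asarray(odds, dtype=float)
    if np.any(odds <= 0):
        raise ValueError("odds must be positive for the log-odds scale")
    out = np.log(odds)
    return float(out) if out.ndim == 0 else out


def odds_from_log_odds(lo):
    out = np.exp(np.asarray(lo, dtype=float))
    return float(out) if out.ndim == 0 else out


def profile_from_row(row: pd.Series) -> PredictPDProfile:
    """Map a cohort phenotype row to a PREDICT-PD trait profile.

    ``anxiety_or_depression`` is the logical OR of separate anxiety and
    depression columns; ``alcohol_gt1wk`` is the complement of a
    ``low_alcohol`` (<1 drink/week) indicator; absent columns count as the
    trait being absent.
    """
    def flag(name: str) -> bool:
        return bool(row.get(name, 0) == 1)

    if flag("smoking_current"):
        smoking = Smoking.CURRENT
    elif flag("smoking_previous"):
        smoking = Smoking.PREVIOUS
    else:
        smoking = Smoking.NEVER
    alcohol = not flag("low_alcohol") if "low_alcohol" in row.index else flag("alcohol_gt1wk")
    return PredictPDProfile(
        age=float(row["age"]),
        female=row.get("sex") == "female",
        smoking=smoking,
        family_history_pd=flag("family_history_pd"),
        coffee_gt1cup=flag("coffee_gt1cup"),
        alcohol_gt1wk=alcohol,
        constipation=flag("constipation"),
        anxiety_or_depression=flag("anxiety") or flag("depression"),
        erectile_dysfunction=flag("erectile_dysfunction"),
    )


def predict_cohort(
    cohort: pd.DataFrame,
    baseline: PredictPDBaseline = PredictPDBaseline(),
    table: MultiplierTable = MultiplierTable(),
) -> pd.DataFrame:
    """Batch PREDICT-PD: per-individual odds, probability and log-odds.

    Vectorised equivalent of applying :func:`profile_from_row` +
    :func:`apply_profile` row by row (asserted in the test suite).
    """
    n = len(cohort)
    odds = baseline_odds(cohort["age"].to_numpy(dtype=float), baseline)

    def flags(name: str) -> np.ndarray:
        if name in cohort.columns:
            return (cohort[name].to_numpy() == 1).astype(bool)
        return np.zeros(n, dtype=bool)

    female = (cohort["sex"] == "female").to_numpy() if "sex" in cohort.columns else np.zeros(n, bool)
    odds = np.where(female, odds / table.female_divisor, odds)
    current = flags("smoking_current")
    previous = flags("smoking_previous") & ~current
    odds = np.where(current, odds * table.smoking_current, odds)
    odds = np.where(previous, odds * table.smoking_previous, odds)
    odds = np.where(flags("family_history_pd"), odds * table.family_history_pd, odds)
    odds = np.where(flags("coffee_gt1cup"), odds * table.coffee_gt1cup, odds)
    if "low_alcohol" in cohort.columns:
        alcohol = ~flags("low_alcohol")
    else:
        alcohol = flags("alcohol_gt1wk")
    odds = np.where(alcohol, odds * table.alcohol_gt1wk, odds)
    odds = np.where(flags("constipation"), odds * table.constipation, odds)
    odds = np.where(flags("anxiety") | flags("depression"), odds * table.anxiety_or_depression, odds)
    odds = np.where(
        flags("erectile_dysfunction") & ~female, odds * table.erectile_dysfunction, odds
    )
    return pd.DataFrame(
        {
            "ID": cohort["id"].to_numpy(),
            "ODDS": odds,
            "PROB": odds_to_probability(odds),
            "LOG_ODDS": np.log(odds),
        }
    )


def multiplier_table_from_yaml(path) -> MultiplierTable:
    import yaml

    with open(path) as fh:
        overrides = yaml.safe_load(fh) or {}
    return MultiplierTable(**overrides)
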