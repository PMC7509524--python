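"""Incident case-control association analyses.

Per-risk-factor multivariable logistic regressions of the form
``PD status ~ age + sex + ethnicity + deprivation + risk factor``, fitted on
incident cases plus all non-PD controls (prevalent cases excluded), with Wald
ORs/CIs, likelihood-ratio tests against the covariates-only null,
Benjamini-Hochberg FDR across the exposure family, a combined multivariable
model for the robustly associated exposures, and a matched 4:1 case-control
sensitivity design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from ._design import complete_cases, design_matrix, rank_deficient

DEFAULT_COVARIATES = ("age", "sex", "ethnicity", "townsend")


@dataclass(frozen=True)
class ModelSpec:
    outcome: str = "pd_status"
    exposure: str = ""
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    drop_sex_for_sex_specific: bool = False

    def __post_init__(self) -> None:
        if self.exposure in self.covariates:
            raise ValueError("exposure cannot also be a covariate")

    def effective_covariates(self) -> tuple[str, ...]:
        if self.drop_sex_for_sex_specific:
            return tuple(c for c in self.covariates if c != "sex")
        return self.covariates


@dataclass
class AssociationResult:
    exposure: str
    level: str | None
    or_: float
    ci_low: float
    ci_high: float
    p_wald: float
    lrt_p: float
    lrt_q: float | None = None
    n: int = 0
    flagged: bool = False
    flag_reason: str = ""

    def to_dict(self) -> dict:
        return {
            "exposure": self.exposure,
            "level": self.level,
            "OR": self.or_,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_wald": self.p_wald,
            "lrt_p": self.lrt_p,
            "lrt_q": self.lrt_q,
            "n": self.n,
            "flagged": self.flagged,
        }


def incident_case_control(cohort: pd.DataFrame) -> pd.DataFrame:
    """Incident cases plus all non-PD controls; prevalent cases excluded."""
    prevalent = (cohort["pd_status"] == 1) & (cohort["incident"] == 0)
    return cohort.loc[~prevalent].copy()


def _flagged(spec: ModelSpec, reason: str, level: str | None = None, n: int = 0):
    return AssociationResult(
        spec.exposure, level, np.nan, np.nan, np.nan, np.nan, np.nan,
        n=n, flagged=True, flag_reason=reason,
    )


def fit_exposure_model(
    cohort: pd.DataFrame, spec: ModelSpec
) -> list[AssociationResult]:
    """Adjusted logistic model for one exposure; one result per exposure level.

    Complete-case on the model's columns.  Degenerate exposures (constant) and
    non-converged or separated fits return flagged results rather than raising.
    """
    covs = spec.effective_covariates()
    df = complete_cases(incident_case_control(cohort), [spec.outcome, spec.exposure, *covs])
    y = df[spec.outcome].to_numpy(dtype=float)
    exp_design = design_matrix(df, (spec.exposure,), add_const=False)
    if exp_design.shape[1] == 0 or any(exp_design.nunique() < 2):
        return [_flagged(spec, "degenerate exposure (constant)", n=len(df))]
    X_null = design_matrix(df, covs)
    X = pd.concat([X_null, exp_design], axis=1)
    if rank_deficient(X.to_numpy(dtype=float)):
        return [_flagged(spec, "collinear design", n=len(df))]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            null_fit = sm.Logit(y, X_null.to_numpy(dtype=float)).fit(disp=0)
            full_fit = sm.Logit(y, X.to_numpy(dtype=float)).fit(disp=0)
    except Exception as exc:  # separation, numerical failure
        return [_flagged(spec, f"fit failed: {exc}", n=len(df))]
    if not (null_fit.mle_retvals["converged"] and full_fit.mle_retvals["converged"]):
        return [_flagged(spec, "non-converged", n=len(df))]
    lrt_p, _ = lrt(full_fit, null_fit)
    names = list(X.columns)
    results = []
    for col in exp_design.columns:
        k = names.index(col)
        beta, se = full_fit.params[k], full_fit.bse[k]
        level = col[len(spec.exposure) + 1 :] if col != spec.exposure else None
        if not np.isfinite(se) or se > 100:
            results.append(_flagged(spec, "unstable coefficient", level=level, n=len(df)))
            continue
        results.append(
            AssociationResult(
                exposure=spec.exposure,
                level=level,
                or_=float(np.exp(beta)),
                ci_low=float(np.exp(beta - 1.96 * se)),
                ci_high=float(np.exp(beta + 1.96 * se)),
                p_wald=float(full_fit.pvalues[k]),
                lrt_p=lrt_p,
                n=len(df),
            )
        )
    return results


def lrt(full_fit, null_fit) -> tuple[float, float]:
    """Likelihood-ratio test p-value and statistic for nested logistic fits."""
    df_diff = int(full_fit.df_model - null_fit.df_model)
    if df_diff < 0:
        raise ValueError("models are not nested (null has more parameters)")
    stat = 2.0 * (full_fit.llf - null_fit.llf)
    if stat < -1e-6:
        raise ValueError("full model fits worse than null: not nested or failed fit")
    stat = max(0.0, stat)
    if df_diff == 0:
        return (1.0 if stat < 1e-8 else np.nan), stat
    return float(sps.chi2.sf(stat, df_diff)), stat


def fdr_adjust(pvals, q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and discovery flags at ``q_level``."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, q, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return q, reject


def run_association_family(
    cohort: pd.DataFrame,
    exposures: list[str],
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    sex_specific: set[str] = frozenset(),
    q_level: float = 0.05,
) -> pd.DataFrame:
    """Fit every exposure model and BH-adjust the LRT p-values across the family."""
    all_results: list[AssociationResult] = []
    for exp in exposures:
        spec = ModelSpec(
            exposure=exp,
            covariates=covariates,
            drop_sex_for_sex_specific=exp in sex_specific,
        )
        all_results.extend(fit_exposure_model(cohort, spec))
    # one LRT p per exposure (levels share the model); adjust at exposure level
    by_exposure: dict[str, float] = {}
    for r in all_results:
        if not r.flagged and r.exposure not in by_exposure:
            by_exposure[r.exposure] = r.lrt_p
    if by_exposure:
        q, _ = fdr_adjust(list(by_exposure.values()), q_level)
        q_map = dict(zip(by_exposure.keys(), q))
        for r in all_results:
            r.lrt_q = q_map.get(r.exposure)
    return pd.DataFrame([r.to_dict() for r in all_results])


def fit_combined_model(
    cohort: pd.DataFrame,
    exposures: list[str],
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> list[AssociationResult]:
    """Joint logistic model over all robustly associated exposures.

    Collinear exposure columns are reported flagged; otherwise per-exposure
    OR, Wald CI and p from the single joint fit.
    """
    df = complete_cases(incident_case_control(cohort), ["pd_status", *exposures, *covariates])
    y = df["pd_status"].to_numpy(dtype=float)
    X_cov = design_matrix(df, covariates)
    exp_design = design_matrix(df, tuple(exposures), add_const=False)
    X = pd.concat([X_cov, exp_design], axis=1)
    collinear = rank_deficient(X.to_numpy(dtype=float))
    if collinear:
        return [
            _flagged(ModelSpec(exposure=exp), "collinear design", n=len(df))
            for exp in exposures
        ]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, X.to_numpy(dtype=float)).fit(disp=0, maxiter=100)
    names = list(X.columns)
    results = []
    for exp in exposures:
        cols = [c for c in exp_design.columns if c == exp or c.startswith(exp + "_")]
        for col in cols:
            k = names.index(col)
            beta, se = fit.params[k], fit.bse[k]
            level = col[len(exp) + 1 :] if col != exp else None
            flagged = collinear or not np.isfinite(se) or se > 100
            results.append(
                AssociationResult(
                    exposure=exp,
                    level=level,
                    or_=float(np.exp(beta)),
                    ci_low=float(np.exp(beta - 1.96 * se)),
                    ci_high=float(np.exp(beta + 1.96 * se)),
                    p_wald=float(fit.pvalues[k]),
                    lrt_p=np.nan,
                    n=len(df),
                    flagged=flagged,
                    flag_reason="collinear design" if collinear else "",
                )
            )
    return results


def matched_design(
    cohort: pd.DataFrame,
    ratio: int = 4,
    age_tolerance: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Matched case-control sub-cohort: each incident case with exactly
    ``ratio`` controls of identical sex and ethnicity and age within
    ±``age_tolerance`` years, sampled without replacement.  Cases with too few
    eligible controls are dropped with a warning."""
    rng = np.random.default_rng(seed)
    df = incident_case_control(cohort)
    cases = df[df["pd_status"] == 1].sort_values("id")
    controls = df[df["pd_status"] == 0]
    used: set[str] = set()
    rows: list[pd.DataFrame] = []
    n_dropped = 0
    for _, case in cases.iterrows():
        eligible = controls[
            (controls["sex"] == case["sex"])
            & (controls["ethnicity"] == case["ethnicity"])
            & (np.abs(controls["age"] - case["age"]) <= age_tolerance)
            & (~controls["id"].isin(used))
        ]
        if len(eligible) < ratio:
            n_dropped += 1
            continue
        pick = eligible.iloc[np.sort(rng.choice(len(eligible), size=ratio, replace=False))]
        used.update(pick["id"])
        rows.append(pd.concat([case.to_frame().T, pick]))
    if n_dropped:
        warnings.warn(f"{n_dropped} cases dropped (fewer than {ratio} eligible controls)",
                      stacklevel=2)
    if not rows:
        return df.iloc[0:0]
    return pd.concat(rows, ignore_index=True).infer_objects()
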