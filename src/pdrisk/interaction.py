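"""Gene-environment interaction on additive and multiplicative scales.

For a logistic model ``logit p = b0 + b1 x + b2 y + b3 x*y + covariates`` the
Relative Excess Risk due to Interaction and the Attributable Proportion are

    RERI = exp(b1 + b2 + b3) - exp(b1) - exp(b2) + 1
    AP   = RERI / exp(b1 + b2 + b3)

AP is the share of disease in the doubly exposed group attributable to the
interaction; negative values indicate sub-additivity.  Continuous factors
(e.g. the polygenic score) are inverse-normal transformed first, and the AP
contrast is then per 1 SD of the transformed variable.  Confidence intervals
for AP come from percentile bootstrap over individuals (default 5000
replicates); the multiplicative scale is tested by the likelihood-ratio test
of the interaction term, FDR-adjusted across the exposure family.
"""

from __future__ import annotations

from dataclasses import dataclass

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationWarning

warnings.filterwarnings("ignore", category=ConvergenceWarning)
warnings.filterwarnings("ignore", category=PerfectSeparationWarning)
from scipy import stats as sps

from ._design import complete_cases, design_matrix
from ._logit import fit_logistic
from .association import fdr_adjust
from .transforms import inverse_normal_transform

DEFAULT_GXE_COVARIATES = ("age", "sex", "townsend", "pc1", "pc2", "pc3", "pc4")


@dataclass
class InteractionFit:
    """Coefficients of the interaction logistic model."""

    beta0: float
    beta_rf1: float
    beta_rf2: float
    beta_int: float
    covariate_betas: dict[str, float]
    llf: float
    n: int
    converged: bool


def reri_from_fit(fit: InteractionFit) -> float:
    """RERI = exp(b1+b2+b3) - exp(b1) - exp(b2) + 1."""
    return reri_from_betas(fit.beta_rf1, fit.beta_rf2, fit.beta_int)


def reri_from_betas(b1: float, b2: float, b3: float) -> float:
    if not (np.isfinite(b1) and np.isfinite(b2) and np.isfinite(b3)):
        return np.nan
    return float(np.exp(b1 + b2 + b3) - np.exp(b1) - np.exp(b2) + 1.0)


def ap_from_fit(fit: InteractionFit) -> float:
    """AP = RERI / exp(b1 + b2 + b3)."""
    return ap_from_betas(fit.beta_rf1, fit.beta_rf2, fit.beta_int)


def ap_from_betas(b1: float, b2: float, b3: float) -> float:
    reri = reri_from_betas(b1, b2, b3)
    if not np.isfinite(reri):
        return np.nan
    return float(reri / np.exp(b1 + b2 + b3))


def _interaction_design(
    df: pd.DataFrame, factor1: str, factor2: str, covariates: tuple[str, ...]
) -> tuple[np.ndarray, list[str], np.ndarray, np.ndarray]:
    """(X, column names, x1, x2); continuous factors inverse-normal transformed."""
    def prepared(col: str) -> np.ndarray:
        v = df[col].to_numpy(dtype=float)
        if np.unique(v[~np.isnan(v)]).size > 2:
            v = inverse_normal_transform(v)
        return v

    x1 = prepared(factor1)
    x2 = prepared(factor2)
    covs = design_matrix(df, covariates, add_const=False)
    X = np.column_stack([np.ones(len(df)), x1, x2, x1 * x2, covs.to_numpy(dtype=float)])
    names = ["const", factor1, factor2, f"{factor1}:{factor2}", *covs.columns]
    return X, names, x1, x2


def fit_interaction(
    cohort: pd.DataFrame,
    factor1: str,
    factor2: str,
    covariates: tuple[str, ...] = DEFAULT_GXE_COVARIATES,
    outcome: str = "pd_status",
) -> InteractionFit:
    """Fit the interaction logistic model by maximum likelihood (statsmodels)."""
    df = complete_cases(cohort, [outcome, factor1, factor2, *covariates])
    X, names, _, _ = _interaction_design(df, factor1, factor2, covariates)
    y = df[outcome].to_numpy(dtype=float)
    fit = sm.Logit(y, X).fit(disp=0)
    return InteractionFit(
        beta0=float(fit.params[0]),
        beta_rf1=float(fit.params[1]),
        beta_rf2=float(fit.params[2]),
        beta_int=float(fit.params[3]),
        covariate_betas=dict(zip(names[4:], map(float, fit.params[4:]))),
        llf=float(fit.llf),
        n=len(df),
        converged=bool(fit.mle_retvals["converged"]),
    )


@dataclass
class BootstrapAPResult:
    ap: float
    ci_low: float
    ci_high: float
    reri: float
    n_boot: int
    n_failed: int
    flagged: bool


def bootstrap_ap(
    cohort: pd.DataFrame,
    factor1: str,
    factor2: str,
    covariates: tuple[str, ...] = DEFAULT_GXE_COVARIATES,
    n_boot: int = 5000,
    seed: int | None = None,
    outcome: str = "pd_status",
) -> BootstrapAPResult:
    """Point AP from the full-data fit plus a percentile bootstrap CI.

    Individuals are resampled with replacement (no case/control
    stratification); each replicate refits the model (warm-started Newton)
    and recomputes AP; the CI is the empirical 2.5th/97.5th percentile over
    converged replicates.  More than 10% failed replicates flags the result.
    """
    df = complete_cases(cohort, [outcome, factor1, factor2, *covariates]).reset_index(drop=True)
    X, _, _, _ = _interaction_design(df, factor1, factor2, covariates)
    y = df[outcome].to_numpy(dtype=float)
    full = sm.Logit(y, X).fit(disp=0)
    ap_point = ap_from_betas(full.params[1], full.params[2], full.params[3])
    reri_point = reri_from_betas(full.params[1], full.params[2], full.params[3])

    rng = np.random.default_rng(seed)
    n = len(y)
    start = np.asarray(full.params, dtype=float)
    aps = np.full(n_boot, np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        refit = fit_logistic(X[idx], y[idx], start=start)
        if refit.converged:
            val = ap_from_betas(refit.params[1], refit.params[2], refit.params[3])
            if np.isfinite(val):
                aps[b] = val
    ok = np.isfinite(aps)
    n_failed = int(n_boot - ok.sum())
    if ok.any():
        lo, hi = np.percentile(aps[ok], [2.5, 97.5])
    else:
        lo = hi = np.nan
    return BootstrapAPResult(
        ap=ap_point,
        ci_low=float(lo),
        ci_high=float(hi),
        reri=reri_point,
        n_boot=n_boot,
        n_failed=n_failed,
        flagged=n_failed > 0.1 * n_boot,
    )


@dataclass
class MultiplicativeResult:
    beta: float
    se: float
    ci_low: float
    ci_high: float
    lrt_p: float
    flagged: bool


def multiplicative_test(
    cohort: pd.DataFrame,
    factor1: str,
    factor2: str,
    covariates: tuple[str, ...] = DEFAULT_GXE_COVARIATES,
    outcome: str = "pd_status",
) -> MultiplicativeResult:
    """LRT of the interaction-term model against the nested main-effects model."""
    df = complete_cases(cohort, [outcome, factor1, factor2, *covariates])
    X_full, _, x1, x2 = _interaction_design(df, factor1, factor2, covariates)
    if np.nanstd(x1) == 0 or np.nanstd(x2) == 0:
        return MultiplicativeResult(np.nan, np.nan, np.nan, np.nan, np.nan, True)
    X_null = np.delete(X_full, 3, axis=1)
    y = df[outcome].to_numpy(dtype=float)
    try:
        full = sm.Logit(y, X_full).fit(disp=0)
        null = sm.Logit(y, X_null).fit(disp=0)
    except Exception:
        return MultiplicativeResult(np.nan, np.nan, np.nan, np.nan, np.nan, True)
    converged = full.mle_retvals["converged"] and null.mle_retvals["converged"]
    stat = max(0.0, 2.0 * (full.llf - null.llf))
    beta, se = float(full.params[3]), float(full.bse[3])
    return MultiplicativeResult(
        beta=beta,
        se=se,
        ci_low=beta - 1.96 * se,
        ci_high=beta + 1.96 * se,
        lrt_p=float(sps.chi2.sf(stat, 1)),
        flagged=not converged or not np.isfinite(se),
    )


def interaction_family(
    cohort: pd.DataFrame,
    exposures: list[str],
    prs_col: str,
    covariates: tuple[str, ...] = DEFAULT_GXE_COVARIATES,
    n_boot: int = 5000,
    seed: int | None = None,
    outcome: str = "pd_status",
) -> pd.DataFrame:
    """AP (with bootstrap CI) and multiplicative interaction for each exposure
    against the PRS, with BH FDR over the multiplicative LRT p-values."""
    rows = []
    ss = np.random.SeedSequence(seed).spawn(len(exposures))
    for exp, child in zip(exposures, ss):
        boot = bootstrap_ap(
            cohort, exp, prs_col, covariates, n_boot=n_boot,
            seed=int(child.generate_state(1)[0] % (2**31)), outcome=outcome,
        )
        mult = multiplicative_test(cohort, exp, prs_col, covariates, outcome=outcome)
        rows.append(
            {
                "exposure": exp,
                "RERI": boot.reri,
                "AP": boot.ap,
                "AP_CI_LOW": boot.ci_low,
                "AP_CI_HIGH": boot.ci_high,
                "MULT_BETA": mult.beta,
                "LRT_P": mult.lrt_p,
                "N_BOOT": boot.n_boot,
                "N_FAILED": boot.n_failed,
                "FLAGGED": boot.flagged or mult.flagged,
            }
        )
    out = pd.DataFrame(rows)
    valid = out["LRT_P"].notna()
    out["Q"] = np.nan
    if valid.any():
        q, _ = fdr_adjust(out.loc[valid, "LRT_P"].to_numpy())
        out.loc[valid, "Q"] = q
    return out
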