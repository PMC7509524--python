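"""Train/test splitting and model-performance metrics.

The cohort is split 30/70 (stratified by case status) into a training set used
only for PRS selection and standardisation, and a testing set on which all
performance metrics, interactions and risk-model comparisons are computed.
Metrics: Nagelkerke's pseudo-R² (Cox-Snell rescaled to a maximum of 1), AUC
(rank statistic with tie correction), and calibration slope/intercept on the
log-odds scale.  Bootstrap CIs use the normal approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationWarning

warnings.filterwarnings("ignore", category=ConvergenceWarning)
warnings.filterwarnings("ignore", category=PerfectSeparationWarning)
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

from ._logit import fit_logistic


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.30
    seed: int = 0
    stratify_on: str = "pd_status"

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class EvalMetrics:
    nagelkerke_r2: float
    r2_ci: tuple[float, float]
    auc: float
    calibration_slope: float
    calibration_intercept: float
    lrt_p_vs_null: float


def split(cohort: pd.DataFrame, spec: SplitSpec) -> tuple[list[str], list[str]]:
    """Disjoint, exhaustive random split stratified by case status."""
    rng = np.random.default_rng(spec.seed)
    train: list[str] = []
    test: list[str] = []
    for _, group in cohort.groupby(spec.stratify_on, sort=True):
        ids = group["id"].to_numpy()
        perm = rng.permutation(len(ids))
        n_train = int(round(spec.train_fraction * len(ids)))
        train.extend(ids[perm[:n_train]])
        test.extend(ids[perm[n_train:]])
    n_cases_train = cohort.set_index("id").loc[train, spec.stratify_on].sum()
    n_cases_test = cohort.set_index("id").loc[test, spec.stratify_on].sum()
    if min(n_cases_train, n_cases_test) < 10:
        warnings.warn("fewer than 10 cases in one split", stacklevel=2)
    return train, test


def nagelkerke(ll_null: float, ll_full: float, n: int) -> float:
    """Nagelkerke pseudo-R²: Cox-Snell R² rescaled to a maximum of 1.

    ``CS = 1 - exp(2 (ll_null - ll_full) / n)``, ``max = 1 - exp(2 ll_null / n)``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if ll_full < ll_null - 1e-8:
        raise ValueError("full-model log-likelihood below the null (non-nested or failed fit)")
    cox_snell = 1.0 - np.exp(2.0 * (ll_null - min(ll_full, 0.0)) / n)
    max_cs = 1.0 - np.exp(2.0 * ll_null / n)
    if max_cs <= 0:
        return 0.0
    return float(cox_snell / max_cs)


def bootstrap_metric(
    metric_fn,
    data: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
) -> dict:
    """Normal-approximation bootstrap CI for any row-resamplable metric.

    ``metric_fn(df) -> float``; replicates raising or returning NaN count as
    failures, and >10% failures flags the result.
    """
    estimate = float(metric_fn(data))
    rng = np.random.default_rng(seed)
    n = len(data)
    reps = np.full(n_boot, np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            reps[b] = metric_fn(data.iloc[idx])
        except Exception:
            pass
    ok = np.isfinite(reps)
    n_failed = int(n_boot - ok.sum())
    sd = float(np.std(reps[ok])) if ok.any() else np.nan
    return {
        "estimate": estimate,
        "ci_low": estimate - 1.96 * sd,
        "ci_high": estimate + 1.96 * sd,
        "sd": sd,
        "n_boot": n_boot,
        "n_failed": n_failed,
        "flagged": n_failed > 0.1 * n_boot,
    }


def auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney with tie correction)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both outcome classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def calibration(predicted_probs, labels) -> tuple[float, float]:
    """Calibration slope and intercept on the log-odds scale.

    Logistic regression of outcomes on the log-odds of the predictions;
    slope 1, intercept 0 indicates perfect calibration.
    """
    p = np.clip(np.asarray(predicted_probs, dtype=float), 1e-12, 1 - 1e-12)
    lo = np.log(p / (1.0 - p))
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    X = np.column_stack([np.ones_like(lo), lo])
    fit = sm.Logit(y, X).fit(disp=0)
    return float(fit.params[1]), float(fit.params[0])


def _metrics_for_design(
    X: np.ndarray, y: np.ndarray, n_boot: int, rng: np.random.Generator
) -> EvalMetrics:
    n = len(y)
    null = sm.Logit(y, np.ones((n, 1))).fit(disp=0)
    full = sm.Logit(y, X).fit(disp=0)
    r2 = nagelkerke(null.llf, max(full.llf, null.llf), n)
    pred = np.asarray(full.predict(X), dtype=float)
    slope, intercept = calibration(pred, y)
    stat = max(0.0, 2.0 * (full.llf - null.llf))
    df = X.shape[1] - 1
    lrt_p = float(sps.chi2.sf(stat, df)) if df > 0 else 1.0
    ci = (np.nan, np.nan)
    if n_boot > 0:
        warm_n = fit_logistic(np.ones((n, 1)), y)
        warm_f = fit_logistic(X, y)
        reps = np.full(n_boot, np.nan)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            fn = fit_logistic(np.ones((n, 1)), y[idx], start=warm_n.params)
            ff = fit_logistic(X[idx], y[idx], start=warm_f.params)
            if fn.converged and ff.converged:
                reps[b] = nagelkerke(fn.llf, max(ff.llf, fn.llf), n)
        sd = np.nanstd(reps)
        ci = (r2 - 1.96 * sd, r2 + 1.96 * sd)
    return EvalMetrics(r2, ci, auc(pred, y), slope, intercept, lrt_p)


def compare_models(
    test_cohort: pd.DataFrame,
    predictpd_log_odds: np.ndarray,
    prs_scores: np.ndarray,
    prs_restricted_scores: np.ndarray | None = None,
    outcome: str = "incident",
    pc_cols: tuple[str, ...] = ("pc1", "pc2", "pc3", "pc4"),
    n_boot: int = 0,
    seed: int | None = None,
) -> dict:
    """Compare risk models on the testing set.

    (a) PREDICT-PD log-odds + PCs 1-4; (b) = (a) + PRS; (c) = (a) + PRS with
    known risk loci excluded.  Reports each model's metrics plus the
    incremental Nagelkerke R² and LRT p of (b) and (c) over (a).
    """
    for name, arr in (("predictpd_log_odds", predictpd_log_odds), ("prs", prs_scores)):
        if arr is None:
            raise ValueError(f"missing model component: {name}")
    rng = np.random.default_rng(seed)
    y = test_cohort[outcome].to_numpy(dtype=float)
    pcs = test_cohort[list(pc_cols)].to_numpy(dtype=float)
    ones = np.ones((len(y), 1))
    X_a = np.column_stack([ones, predictpd_log_odds, pcs])
    X_b = np.column_stack([X_a, prs_scores])
    out: dict = {}
    fit_a = sm.Logit(y, X_a).fit(disp=0)
    out["predictpd"] = _metrics_for_design(X_a, y, n_boot, rng)
    fit_b = sm.Logit(y, X_b).fit(disp=0)
    out["predictpd_plus_prs"] = _metrics_for_design(X_b, y, n_boot, rng)
    out["incremental_r2_prs"] = nagelkerke(fit_a.llf, max(fit_b.llf, fit_a.llf), len(y))
    out["incremental_lrt_p_prs"] = float(
        sps.chi2.sf(max(0.0, 2.0 * (fit_b.llf - fit_a.llf)), 1)
    )
    if prs_restricted_scores is not None:
        X_c = np.column_stack([X_a, prs_restricted_scores])
        fit_c = sm.Logit(y, X_c).fit(disp=0)
        out["predictpd_plus_prs_noloci"] = _metrics_for_design(X_c, y, n_boot, rng)
        out["incremental_r2_prs_noloci"] = nagelkerke(
            fit_a.llf, max(fit_c.llf, fit_a.llf), len(y)
        )
        out["incremental_lrt_p_prs_noloci"] = float(
            sps.chi2.sf(max(0.0, 2.0 * (fit_c.llf - fit_a.llf)), 1)
        )
    return out
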