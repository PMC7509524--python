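"""Clumping-and-thresholding polygenic risk scores.

Candidate scores are built over a grid of GWAS p-value thresholds
(5e-5 ... 1) and LD r² clumping thresholds (0.1 ... 0.8, 250 kb window),
scored as the sum of per-locus standardised (dosage × beta) terms with
missing genotypes contributing the per-locus mean, and the candidate with the
highest Nagelkerke pseudo-R² on the training split is selected (ties broken
by fewer SNPs).  The selected score is characterised by decile odds ratios
and an age-at-diagnosis linear model, and can be re-derived with all variants
within 1 Mb of known risk-locus lead SNPs removed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationWarning

warnings.filterwarnings("ignore", category=ConvergenceWarning)
warnings.filterwarnings("ignore", category=PerfectSeparationWarning)

from ._design import DEFAULT_PRS_COVARIATES, complete_cases, design_matrix
from ._logit import fit_logistic
from .genotypes import GenotypeMatrix
from .evaluate import nagelkerke
from .transforms import inverse_normal_transform

__all__ = [
    "CTGrid",
    "PRSModel",
    "PRSResult",
    "clump",
    "build_candidates",
    "score",
    "select_best",
    "decile_analysis",
    "onset_model",
    "exclude_known_loci",
]


@dataclass(frozen=True)
class CTGrid:
    """The clumping-and-thresholding hyperparameter grid."""

    p_thresholds: tuple[float, ...] = (
        0.00005, 0.0005, 0.005, 0.05, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0,
    )
    r2_thresholds: tuple[float, ...] = (0.1, 0.2, 0.4, 0.6, 0.8)
    clump_window_kb: float = 250.0

    def __post_init__(self) -> None:
        if any(not 0 < p <= 1 for p in self.p_thresholds):
            raise ValueError("p thresholds must lie in (0, 1]")
        if self.clump_window_kb <= 0:
            raise ValueError("clump window must be positive")


@dataclass
class PRSModel:
    """A fitted score definition: variants, weights, standardisation constants.

    ``locus_mean``/``locus_sd`` are the training-set mean and SD of the
    per-locus score (dosage × beta); per-locus terms are standardised with
    them before summing, so a missing genotype contributes exactly 0.
    """

    rsids: np.ndarray
    chroms: np.ndarray
    positions: np.ndarray
    effect_alleles: np.ndarray
    other_alleles: np.ndarray
    weights: np.ndarray
    locus_mean: np.ndarray
    locus_sd: np.ndarray
    p_threshold: float
    r2_threshold: float
    empty: bool = False

    @property
    def n_snps(self) -> int:
        return len(self.rsids)

    def to_files(self, tsv_path: str | Path, json_path: str | Path) -> None:
        pd.DataFrame(
            {
                "SNP": self.rsids,
                "CHR": self.chroms,
                "BP": self.positions,
                "A1": self.effect_alleles,
                "A2": self.other_alleles,
                "BETA": self.weights,
                "MEAN": self.locus_mean,
                "SD": self.locus_sd,
            }
        ).to_csv(tsv_path, sep="\t", index=False)
        Path(json_path).write_text(
            json.dumps(
                {
                    "p_threshold": self.p_threshold,
                    "r2_threshold": self.r2_threshold,
                    "n_snps": self.n_snps,
                    "standardisation": "per-locus score (dosage x beta), training set",
                }
            )
        )

    @classmethod
    def from_files(cls, tsv_path: str | Path, json_path: str | Path) -> "PRSModel":
        df = pd.read_csv(tsv_path, sep="\t")
        meta = json.loads(Path(json_path).read_text())
        return cls(
            rsids=df["SNP"].to_numpy(),
            chroms=df["CHR"].to_numpy(),
            positions=df["BP"].to_numpy(),
            effect_alleles=df["A1"].to_numpy(),
            other_alleles=df["A2"].to_numpy(),
            weights=df["BETA"].to_numpy(dtype=float),
            locus_mean=df["MEAN"].to_numpy(dtype=float),
            locus_sd=df["SD"].to_numpy(dtype=float),
            p_threshold=meta["p_threshold"],
            r2_threshold=meta["r2_threshold"],
            empty=len(df) == 0,
        )


@dataclass
class PRSResult:
    """Per-individual scores: raw standardised sum, inverse-normal transform, decile."""

    ids: list[str]
    raw: np.ndarray
    transformed: np.ndarray
    decile: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ID": self.ids,
                "SCORE": self.raw,
                "SCORE_INT": self.transformed,
                "DECILE": self.decile,
            }
        )


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return 0.0
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def clump(
    stats: pd.DataFrame,
    reference: GenotypeMatrix,
    r2_threshold: float,
    window_kb: float = 250.0,
) -> list[str]:
    """Greedy LD clumping against a reference panel.

    Variants are visited by ascending p (ties by position then rsid); each
    unclaimed variant becomes an index SNP and claims all unclaimed variants
    on the same chromosome within ``window_kb`` whose dosage r² with it
    (pairwise-complete on the reference) reaches ``r2_threshold``.  Returns
    the index-SNP rsids.  Variants absent from the reference are dropped with
    a warning.
    """
    ref_idx = reference.variant_index()
    present = stats["SNP"].isin(ref_idx)
    if not present.all():
        warnings.warn(
            f"{int((~present).sum())} variants absent from the reference panel; excluded",
            stacklevel=2,
        )
    work = stats.loc[present].sort_values(["P", "BP", "SNP"], kind="mergesort")
    snps = work["SNP"].to_numpy()
    chrom = work["CHR"].to_numpy()
    pos = work["BP"].to_numpy(dtype=float)
    cols = np.array([ref_idx[s] for s in snps])
    dos = reference.dosages
    window = window_kb * 1000.0

    claimed = np.zeros(len(work), dtype=bool)
    retained: list[str] = []
    for i in range(len(work)):
        if claimed[i]:
            continue
        claimed[i] = True
        retained.append(snps[i])
        near = np.flatnonzero(
            (~claimed) & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window)
        )
        if near.size == 0:
            continue
        xi = dos[:, cols[i]].astype(float)
        for j in near:
            if _pairwise_r2(xi, dos[:, cols[j]].astype(float)) >= r2_threshold:
                claimed[j] = True
    return retained


def _fit_standardisation(
    train_genotypes: GenotypeMatrix, rsids: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    idx = train_genotypes.variant_index()
    cols = np.array([idx[s] for s in rsids], dtype=int)
    s = train_genotypes.dosages[:, cols].astype(float) * weights
    mean = np.nanmean(s, axis=0)
    sd = np.nanstd(s, axis=0)
    mean = np.where(np.isnan(mean), 0.0, mean)
    sd = np.where((sd == 0) | np.isnan(sd), 1.0, sd)
    return mean, sd


def build_candidates(
    stats: pd.DataFrame,
    reference: GenotypeMatrix,
    grid: CTGrid,
    train_genotypes: GenotypeMatrix,
) -> list[PRSModel]:
    """One candidate PRS per (p threshold, r² threshold) grid cell.

    Clumping runs on the reference panel; standardisation constants are fitted
    on the training genotypes and frozen into each model.
    """
    stats_by_snp = stats.set_index("SNP")
    models: list[PRSModel] = []
    for p_thr in grid.p_thresholds:
        subset = stats[stats["P"] < p_thr] if p_thr < 1.0 else stats[stats["P"] <= 1.0]
        for r2_thr in grid.r2_thresholds:
            if len(subset) == 0:
                models.append(_empty_model(p_thr, r2_thr))
                continue
            kept = clump(subset, reference, r2_thr, grid.clump_window_kb)
            if len(kept) == 0:
                models.append(_empty_model(p_thr, r2_thr))
                continue
            rows = stats_by_snp.loc[kept]
            rsids = np.asarray(kept)
            weights = rows["BETA"].to_numpy(dtype=float)
            mean, sd = _fit_standardisation(train_genotypes, rsids, weights)
            models.append(
                PRSModel(
                    rsids=rsids,
                    chroms=rows["CHR"].to_numpy(),
                    positions=rows["BP"].to_numpy(),
                    effect_alleles=rows["A1"].to_numpy(),
                    other_alleles=rows["A2"].to_numpy(),
                    weights=weights,
                    locus_mean=mean,
                    locus_sd=sd,
                    p_threshold=p_thr,
                    r2_threshold=r2_thr,
                )
            )
    return models


def _empty_model(p_thr: float, r2_thr: float) -> PRSModel:
    z = np.array([])
    return PRSModel(z, z, z, z, z, z, z, z, p_thr, r2_thr, empty=True)


def score(genotypes: GenotypeMatrix, model: PRSModel) -> PRSResult:
    """Score individuals under a PRS model.

    Per locus: effect-allele dosage × beta, standardised by the model's
    stored mean/SD; missing or absent loci contribute the per-locus mean
    (exactly 0 after standardisation); the total is the sum over loci.  If
    the genotype file counts the other allele, the dosage is flipped to
    ``2 - dosage``.  More than 50% of model variants absent is an error.
    """
    if model.empty or model.n_snps == 0:
        raise ValueError("cannot score with an empty PRS model")
    idx = genotypes.variant_index()
    v = genotypes.variants
    n = genotypes.n_samples
    z_total = np.zeros(n)
    n_absent = 0
    for k in range(model.n_snps):
        col = idx.get(model.rsids[k])
        if col is None:
            n_absent += 1
            continue
        g_a1, g_a2 = v.at[col, "a1"], v.at[col, "a2"]
        d = genotypes.dosages[:, col].astype(float)
        if g_a1 == model.effect_alleles[k]:
            pass
        elif g_a2 == model.effect_alleles[k]:
            d = 2.0 - d
        else:
            n_absent += 1  # allele mismatch: treat as absent
            continue
        s = d * model.weights[k]
        z = (s - model.locus_mean[k]) / model.locus_sd[k]
        z_total += np.where(np.isnan(z), 0.0, z)
    if n_absent > 0.5 * model.n_snps:
        raise ValueError(
            f"{n_absent}/{model.n_snps} model variants absent from genotypes"
        )
    if np.unique(z_total).size < 2:
        transformed = np.zeros(n)
    else:
        transformed = inverse_normal_transform(z_total)
    ranks = pd.Series(z_total).rank(method="first")
    decile = np.ceil(ranks * 10.0 / n).astype(int).clip(1, 10).to_numpy()
    return PRSResult(list(genotypes.sample_ids), z_total, transformed, decile)


def _nagelkerke_for_scores(
    X_null: np.ndarray, y: np.ndarray, scores: np.ndarray
) -> tuple[float, bool, float, float]:
    """(R², converged, ll_null, ll_full) for status ~ covariates [+ PRS]."""
    X_full = np.column_stack([X_null, scores])
    try:
        null = sm.Logit(y, X_null).fit(disp=0)
        full = sm.Logit(y, X_full).fit(disp=0)
    except Exception:
        return np.nan, False, np.nan, np.nan
    ok = bool(null.mle_retvals["converged"] and full.mle_retvals["converged"])
    r2 = nagelkerke(null.llf, max(full.llf, null.llf), len(y))
    return r2, ok, null.llf, full.llf


@dataclass
class SelectionRow:
    p_threshold: float
    r2_threshold: float
    n_snps: int
    r2: float
    r2_ci_low: float
    r2_ci_high: float
    converged: bool


def select_best(
    candidates: list[PRSModel],
    train_cohort: pd.DataFrame,
    train_scores: list[PRSResult | None],
    outcome: str = "pd_status",
    covariates: tuple[str, ...] = DEFAULT_PRS_COVARIATES,
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[PRSModel, pd.DataFrame]:
    """Pick the candidate with the highest Nagelkerke pseudo-R² on training data.

    Each candidate's logistic model (status ~ covariates + PRS) is compared
    with the covariates-only null; a normal-approximation bootstrap CI on R²
    is attached when ``n_boot`` > 0.  Empty or non-converged candidates are
    excluded from selection; ties are broken by fewer SNPs.
    """
    df = complete_cases(train_cohort, [outcome, *covariates]).reset_index(drop=True)
    id_pos = {s: i for i, s in enumerate(df["id"])}
    y = df[outcome].to_numpy(dtype=float)
    X_null = design_matrix(df, covariates).to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    rows: list[SelectionRow] = []
    best: tuple[float, int, int] | None = None  # (-r2, n_snps, index)
    for i, (model, result) in enumerate(zip(candidates, train_scores)):
        if model.empty or result is None:
            rows.append(
                SelectionRow(model.p_threshold, model.r2_threshold, 0, np.nan, np.nan, np.nan, False)
            )
            continue
        if result.ids == list(df["id"]):
            aligned = result.raw
        else:
            pos = {s: k for k, s in enumerate(result.ids)}
            aligned = np.array([result.raw[pos[s]] for s in df["id"]])
        r2, ok, _, _ = _nagelkerke_for_scores(X_null, y, aligned)
        lo = hi = np.nan
        if ok and n_boot > 0:
            reps = _bootstrap_r2(X_null, y, aligned, n_boot, rng)
            sd = np.nanstd(reps)
            lo, hi = r2 - 1.96 * sd, r2 + 1.96 * sd
        rows.append(
            SelectionRow(model.p_threshold, model.r2_threshold, model.n_snps, r2, lo, hi, ok)
        )
        if ok and np.isfinite(r2):
            key = (-r2, model.n_snps, i)
            if best is None or key < best:
                best = key
    if best is None:
        raise ValueError("no candidate PRS model converged")
    table = pd.DataFrame([r.__dict__ for r in rows])
    return candidates[best[2]], table


def _bootstrap_r2(
    X_null: np.ndarray, y: np.ndarray, scores: np.ndarray,
    n_boot: int, rng: np.random.Generator,
) -> np.ndarray:
    n = len(y)
    X_full = np.column_stack([X_null, scores])
    warm_null = fit_logistic(X_null, y)
    warm_full = fit_logistic(X_full, y)
    reps = np.full(n_boot, np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        fn = fit_logistic(X_null[idx], y[idx], start=warm_null.params)
        ff = fit_logistic(X_full[idx], y[idx], start=warm_full.params)
        if fn.converged and ff.converged:
            reps[b] = nagelkerke(fn.llf, max(ff.llf, fn.llf), n)
    return reps


def decile_analysis(
    result: PRSResult,
    cohort: pd.DataFrame,
    outcome: str = "pd_status",
    covariates: tuple[str, ...] = DEFAULT_PRS_COVARIATES,
) -> pd.DataFrame:
    """Odds ratio (and Wald 95% CI) per PRS decile relative to decile 1.

    Logistic model of status on decile indicators plus covariates.  A decile
    with an empty status cell is flagged and its CI reported unbounded.
    """
    df = complete_cases(cohort, [outcome, *covariates]).copy()
    scores = result.to_frame().set_index("ID").reindex(df["id"])
    df["decile"] = scores["DECILE"].to_numpy()
    df = df.dropna(subset=["decile"])
    y = df[outcome].to_numpy(dtype=float)
    dummies = pd.get_dummies(df["decile"].astype(int), prefix="decile", dtype=float)
    dummies = dummies.drop(columns="decile_1")
    X = pd.concat(
        [design_matrix(df, covariates).reset_index(drop=True), dummies.reset_index(drop=True)],
        axis=1,
    )
    fit = sm.Logit(y, X.to_numpy(dtype=float)).fit(disp=0)
    names = list(X.columns)
    out = []
    counts = df.groupby(df["decile"].astype(int))[outcome].agg(["sum", "count"])
    for d in range(1, 11):
        n_case = int(counts.loc[d, "sum"]) if d in counts.index else 0
        n_tot = int(counts.loc[d, "count"]) if d in counts.index else 0
        flagged = n_case == 0 or n_case == n_tot
        if d == 1:
            out.append((d, 1.0, 1.0, 1.0, n_case, n_tot, flagged))
            continue
        if f"decile_{d}" not in names:
            out.append((d, np.nan, np.nan, np.nan, n_case, n_tot, True))
            continue
        k = names.index(f"decile_{d}")
        beta, se = fit.params[k], fit.bse[k]
        if flagged or not np.isfinite(se):
            out.append((d, np.exp(beta), 0.0, np.inf, n_case, n_tot, True))
        else:
            out.append(
                (d, np.exp(beta), np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se),
                 n_case, n_tot, False)
            )
    return pd.DataFrame(
        out, columns=["decile", "or_", "ci_low", "ci_high", "n_cases", "n_total", "flagged"]
    )


def onset_model(
    result: PRSResult,
    case_cohort: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex", "pc1", "pc2", "pc3", "pc4"),
) -> dict[str, float]:
    """Linear model of age at diagnosis on the transformed PRS (cases only)."""
    df = complete_cases(case_cohort, ["age_at_diagnosis", *covariates]).copy()
    if len(df) < 30:
        raise ValueError("insufficient cases for the age-at-diagnosis model (<30)")
    scores = result.to_frame().set_index("ID").reindex(df["id"])
    df["prs_int"] = scores["SCORE_INT"].to_numpy()
    df = df.dropna(subset=["prs_int"])
    X = design_matrix(df, covariates)
    X["prs_int"] = df["prs_int"].to_numpy()
    fit = sm.OLS(df["age_at_diagnosis"].to_numpy(), X.to_numpy(dtype=float)).fit()
    k = list(X.columns).index("prs_int")
    return {
        "slope": float(fit.params[k]),
        "se": float(fit.bse[k]),
        "p": float(fit.pvalues[k]),
        "ci_low": float(fit.params[k] - 1.96 * fit.bse[k]),
        "ci_high": float(fit.params[k] + 1.96 * fit.bse[k]),
        "n": int(len(df)),
    }


def exclude_known_loci(
    model: PRSModel,
    lead_snps: list[tuple[int, int]],
    train_genotypes: GenotypeMatrix,
    window_bp: int = 1_000_000,
) -> PRSModel:
    """Remove model variants within 1 Mb (inclusive) of any lead SNP and refit
    the standardisation constants on the training genotypes."""
    if model.empty or not lead_snps:
        return model
    keep = np.ones(model.n_snps, dtype=bool)
    for chrom, pos in lead_snps:
        hit = (model.chroms.astype(int) == int(chrom)) & (
            np.abs(model.positions.astype(int) - int(pos)) <= window_bp
        )
        keep &= ~hit
    if not keep.any():
        return _empty_model(model.p_threshold, model.r2_threshold)
    rsids = model.rsids[keep]
    weights = model.weights[keep]
    mean, sd = _fit_standardisation(train_genotypes, rsids, weights)
    return PRSModel(
        rsids=rsids,
        chroms=model.chroms[keep],
        positions=model.positions[keep],
        effect_alleles=model.effect_alleles[keep],
        other_alleles=model.other_alleles[keep],
        weights=weights,
        locus_mean=mean,
        locus_sd=sd,
        p_threshold=model.p_threshold,
        r2_threshold=model.r2_threshold,
    )
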