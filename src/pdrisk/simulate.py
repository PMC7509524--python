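"""Synthetic incident case-control cohort generator.

Everything downstream of data access in the pipeline — QC, clumping and
thresholding, PREDICT-PD, association, interaction — is exercised on cohorts
produced here with *known* generative parameters, so each stage's estimates can
be compared against the truth that generated them.

The generator emulates:

* biallelic SNP genotypes in autoregressive LD blocks, with configurable
  missingness, a palindromic (A/T, C/G) subset and low-imputation-quality /
  Hardy-Weinberg-violating subsets to give the QC filters something to remove;
* external GWAS summary statistics whose effect estimates are the true causal
  effects plus Wald-scale noise (se = 1/sqrt(2 N maf (1-maf)));
* an incident-disease phenotype from a logistic model with age, sex, a
  standardised latent genetic score, binary exposures with stated prevalences
  and optional exposure x score interaction terms;
* age at diagnosis for cases with a negative dependence on the genetic score;
* related sample pairs (kinship coefficients) and ancestry-linked principal
  components.

One integer seed governs a splittable per-component RNG: identical config and
seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .genotypes import GenotypeMatrix

__all__ = [
    "ConfigurationError",
    "ExposureSpec",
    "InteractionSpec",
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_genotypes",
    "simulate_summary_stats",
    "simulate_phenotypes",
    "simulate_kinship",
    "simulate_cohort",
]


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class ExposureSpec:
    """A binary exposure: name, population prevalence, log-odds disease effect."""

    name: str
    prevalence: float
    effect: float


@dataclass(frozen=True)
class InteractionSpec:
    """Log-odds interaction between an exposure and the standardised genetic score."""

    name: str
    effect: float


# Prevalences and log-odds effects mirror well-replicated incident-PD risk
# factor estimates (family history OR ~2.2, depression ~1.8, epilepsy ~2.9,
# low alcohol ~1.4, daytime sleepiness ~1.3, current smoking ~0.65 ...).
DEFAULT_EXPOSURES: tuple[ExposureSpec, ...] = (
    ExposureSpec("family_history_pd", 0.05, float(np.log(2.19))),
    ExposureSpec("smoking_current", 0.10, float(np.log(0.65))),
    ExposureSpec("smoking_previous", 0.35, float(np.log(0.88))),
    ExposureSpec("low_alcohol", 0.30, float(np.log(1.39))),
    ExposureSpec("depression", 0.07, float(np.log(1.76))),
    ExposureSpec("daytime_sleepiness", 0.22, float(np.log(1.33))),
    ExposureSpec("epilepsy", 0.011, float(np.log(2.87))),
    ExposureSpec("diabetes", 0.05, float(np.log(1.27))),
    ExposureSpec("gastric_ulcer", 0.02, float(np.log(1.69))),
    ExposureSpec("constipation", 0.02, float(np.log(1.28))),
    ExposureSpec("anxiety", 0.015, float(np.log(1.30))),
    ExposureSpec("coffee_gt1cup", 0.55, 0.0),
)


@dataclass
class SimulationConfig:
    """Generative parameters for one synthetic cohort.

    The logistic disease model is
    ``logit P(PD) = baseline + age_coef*(age-60) + sex_coef*male
    + prs_coef*g + sum_e beta_e x_e + sum_e gamma_e x_e*g``
    with ``g`` the standardised latent genetic score.
    """

    n_individuals: int = 5000
    n_variants: int = 500
    n_causal: int = 20
    ld_block_size: int = 10
    ld_decay: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_beta_range: tuple[float, float] = (0.08, 0.25)
    exposure_specs: tuple[ExposureSpec, ...] = DEFAULT_EXPOSURES
    baseline_log_odds: float = -3.4
    age_coefficient: float = 0.07
    sex_coefficient: float = 0.45
    prs_coefficient: float = float(np.log(1.5))
    interaction_specs: tuple[InteractionSpec, ...] = ()
    incident_fraction: float = 0.6
    missing_genotype_rate: float = 0.02
    n_related_pairs: int = 25
    gwas_n: int = 100_000
    # age-at-diagnosis model for cases: onset_base - onset_slope*g + N(0, onset_sd)
    onset_base: float = 65.0
    onset_slope: float = 0.5
    onset_sd: float = 5.0
    white_british_fraction: float = 0.94
    n_pcs: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        self.exposure_specs = tuple(
            e if isinstance(e, ExposureSpec) else ExposureSpec(*e)
            for e in self.exposure_specs
        )
        self.interaction_specs = tuple(
            s if isinstance(s, InteractionSpec) else InteractionSpec(*s)
            for s in self.interaction_specs
        )
        self.maf_range = tuple(self.maf_range)  # type: ignore[assignment]
        self.causal_beta_range = tuple(self.causal_beta_range)  # type: ignore[assignment]
        self.validate()

    def validate(self) -> None:
        if self.n_individuals <= 0 or self.n_variants <= 0 or self.ld_block_size <= 0:
            raise ConfigurationError("dimensions must be positive")
        if not 0 <= self.n_causal <= self.n_variants:
            raise ConfigurationError("n_causal must lie in [0, n_variants]")
        if not 0.0 <= self.ld_decay < 1.0:
            raise ConfigurationError("ld_decay must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError("maf_range must lie within (0, 1)")
        for e in self.exposure_specs:
            if not 0.0 < e.prevalence < 1.0:
                raise ConfigurationError(f"prevalence of {e.name!r} outside (0, 1)")
        names = [e.name for e in self.exposure_specs]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate exposure names")
        for s in self.interaction_specs:
            if s.name not in names:
                raise ConfigurationError(
                    f"interaction names unknown exposure {s.name!r}"
                )
        if not 0.0 < self.incident_fraction <= 1.0:
            raise ConfigurationError("incident_fraction must lie in (0, 1]")
        if not 0.0 <= self.missing_genotype_rate < 1.0:
            raise ConfigurationError("missing_genotype_rate must lie in [0, 1)")
        if self.gwas_n <= 0:
            raise ConfigurationError("gwas_n must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["exposure_specs"] = [list(dataclasses.astuple(e)) for e in self.exposure_specs]
        d["interaction_specs"] = [
            list(dataclasses.astuple(s)) for s in self.interaction_specs
        ]
        d["maf_range"] = list(self.maf_range)
        d["causal_beta_range"] = list(self.causal_beta_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "exposure_specs" in d:
            d["exposure_specs"] = tuple(ExposureSpec(*e) for e in d["exposure_specs"])
        if "interaction_specs" in d:
            d["interaction_specs"] = tuple(
                InteractionSpec(*s) for s in d["interaction_specs"]
            )
        return cls(**d)


# per-component RNG streams derived from the single config seed
_COMPONENT = {"genotypes": 0, "sumstats": 1, "phenotypes": 2, "kinship": 3}


def component_rng(seed: int, component: str) -> np.random.Generator:
    ss = np.random.SeedSequence(seed).spawn(len(_COMPONENT))
    return np.random.default_rng(ss[_COMPONENT[component]])


_NONPAL_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PAL_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


def simulate_genotypes(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Generate the dosage matrix and the per-variant true causal effects.

    Haplotypes are built block-wise from a latent AR(1) Gaussian process
    (lag-1 correlation ``ld_decay``) thresholded at each variant's allele
    frequency, so within-block dosage correlation decays with distance and
    blocks are independent — enough LD structure to make clumping non-trivial.
    A ~4% subset of variants is made palindromic and ~2%/~1% subsets get low
    ``info`` / extreme ``hwe_p`` metadata to exercise the QC filters; causal
    variants are drawn from the remaining clean variants.
    """
    rng = component_rng(config.seed, "genotypes")
    n, m = config.n_individuals, config.n_variants
    block = config.ld_block_size

    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    thresholds = stats.norm.ppf(mafs)

    dosages = np.empty((n, m), dtype=np.float32)
    starts = list(range(0, m, block))
    for start in starts:
        b = min(block, m - start)
        eps = rng.standard_normal((2 * n, b))
        z = np.empty_like(eps)
        z[:, 0] = eps[:, 0]
        rho = config.ld_decay
        scale = np.sqrt(1.0 - rho**2)
        for j in range(1, b):
            z[:, j] = rho * z[:, j - 1] + scale * eps[:, j]
        alleles = (z < thresholds[start : start + b]).astype(np.float32)
        dosages[:, start : start + b] = alleles[:n] + alleles[n:]

    if config.missing_genotype_rate > 0:
        mask = rng.random((n, m), dtype=np.float32) < config.missing_genotype_rate
        dosages[mask] = np.nan

    # variant metadata ------------------------------------------------------
    n_pal = max(1, int(round(0.04 * m)))
    n_lowinfo = max(1, int(round(0.02 * m)))
    n_badhwe = max(1, int(round(0.01 * m)))
    special = rng.choice(m, size=min(m, n_pal + n_lowinfo + n_badhwe), replace=False)
    pal_idx = special[:n_pal]
    lowinfo_idx = special[n_pal : n_pal + n_lowinfo]
    badhwe_idx = special[n_pal + n_lowinfo :]

    pair_choice = rng.integers(0, len(_NONPAL_PAIRS), size=m)
    a1 = np.array([_NONPAL_PAIRS[k][0] for k in pair_choice], dtype=object)
    a2 = np.array([_NONPAL_PAIRS[k][1] for k in pair_choice], dtype=object)
    pal_choice = rng.integers(0, len(_PAL_PAIRS), size=len(pal_idx))
    for i, k in zip(pal_idx, pal_choice):
        a1[i], a2[i] = _PAL_PAIRS[k]

    info = rng.uniform(0.75, 1.0, size=m)
    info[lowinfo_idx] = rng.uniform(0.05, 0.29, size=len(lowinfo_idx))
    hwe_p = rng.uniform(0.05, 1.0, size=m)
    hwe_p[badhwe_idx] = 10.0 ** rng.uniform(-9.0, -6.5, size=len(badhwe_idx))

    # positions: blocks spread over chromosomes in genome order (so the
    # variant order is already chrom/pos sorted), 10 kb spacing within a
    # block and a 600 kb gap between blocks on the same chromosome
    chrom = np.empty(m, dtype=int)
    pos = np.empty(m, dtype=int)
    next_pos = {c: 1_000_000 for c in range(1, 23)}
    n_blocks = len(starts)
    for bi, start in enumerate(starts):
        b = min(block, m - start)
        c = 1 + (bi * min(22, n_blocks)) // n_blocks
        p0 = next_pos[c]
        for j in range(b):
            chrom[start + j] = c
            pos[start + j] = p0 + 10_000 * j
        next_pos[c] = p0 + 10_000 * b + 600_000

    variants = pd.DataFrame(
        {
            "rsid": [f"rs{100000 + i}" for i in range(m)],
            "chrom": chrom,
            "pos": pos,
            "a1": a1.astype(str),
            "a2": a2.astype(str),
            "maf": mafs,
            "info": info,
            "hwe_p": hwe_p,
        }
    )

    beta_true = np.zeros(m)
    if config.n_causal > 0:
        clean = np.setdiff1d(np.arange(m), special)
        pool = clean if len(clean) >= config.n_causal else np.arange(m)
        causal = rng.choice(pool, size=config.n_causal, replace=False)
        mag = rng.uniform(*config.causal_beta_range, size=config.n_causal)
        sign = rng.choice([-1.0, 1.0], size=config.n_causal)
        beta_true[causal] = mag * sign

    sample_ids = [f"S{i:06d}" for i in range(n)]
    return GenotypeMatrix(sample_ids, variants, dosages), beta_true


def simulate_summary_stats(
    genotypes: GenotypeMatrix,
    beta_true: np.ndarray,
    gwas_n: int,
    seed: int,
) -> pd.DataFrame:
    """Emulate an external GWAS: noisy effect estimates and Wald p-values.

    ``beta_hat = beta_true + N(0, se^2)`` with ``se = 1/sqrt(2 N maf (1-maf))``;
    non-causal variants have true effect zero.  Columns: SNP, CHR, BP, A1, A2,
    BETA, P, FREQ.
    """
    if gwas_n <= 0:
        raise ConfigurationError("gwas_n must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    v = genotypes.variants
    maf = np.clip(v["maf"].to_numpy(dtype=float), 1e-6, 1 - 1e-6)
    se = 1.0 / np.sqrt(2.0 * gwas_n * maf * (1.0 - maf))
    beta_hat = np.asarray(beta_true, dtype=float) + rng.normal(0.0, se)
    z = beta_hat / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "SNP": v["rsid"].to_numpy(),
            "CHR": v["chrom"].to_numpy(),
            "BP": v["pos"].to_numpy(),
            "A1": v["a1"].to_numpy(),
            "A2": v["a2"].to_numpy(),
            "BETA": beta_hat,
            "P": p,
            "FREQ": v["maf"].to_numpy(dtype=float),
        }
    )


def true_genetic_score(genotypes: GenotypeMatrix, beta_true: np.ndarray) -> np.ndarray:
    """Standardised latent genetic score: sum of dosage x causal effect.

    Missing dosages are mean-imputed per variant before weighting; the score is
    standardised to mean 0, SD 1 across the cohort (all-zero if no causal
    variants).
    """
    d = genotypes.dosages
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-NaN columns
        col_mean = np.nanmean(d, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean).astype(d.dtype)
    filled = np.where(np.isnan(d), col_mean, d)
    raw = (filled @ np.asarray(beta_true, dtype=d.dtype)).astype(float)
    sd = raw.std()
    if sd == 0:
        return np.zeros(len(raw))
    return (raw - raw.mean()) / sd


_PC_OFFSETS = (0.30, 0.20, 0.10, 0.05)


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    beta_true: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw exposures, covariates and disease status from the logistic model.

    Returns the cohort table: id, age, sex, ethnicity, townsend, exposures,
    pd_status, incident, age_at_diagnosis (cases only), pc1..pc_k and the
    latent ``true_genetic_score`` (simulation-only column).
    """
    rng = component_rng(config.seed, "phenotypes")
    n = genotypes.n_samples
    if beta_true is None:
        beta_true = np.zeros(genotypes.n_variants)
    g = true_genetic_score(genotypes, beta_true)

    age = rng.integers(40, 70, size=n).astype(float)
    male = rng.random(n) < 0.5
    white = rng.random(n) < config.white_british_fraction
    townsend = rng.normal(0.0, 3.0, size=n)

    exposures: dict[str, np.ndarray] = {}
    spec_by_name = {e.name: e for e in config.exposure_specs}
    smoking = {"smoking_current", "smoking_previous"} <= set(spec_by_name)
    if smoking:
        p_cur = spec_by_name["smoking_current"].prevalence
        p_prev = spec_by_name["smoking_previous"].prevalence
        if p_cur + p_prev >= 1.0:
            raise ConfigurationError("smoking prevalences sum to >= 1")
        u = rng.random(n)
        exposures["smoking_current"] = (u < p_cur).astype(float)
        exposures["smoking_previous"] = ((u >= p_cur) & (u < p_cur + p_prev)).astype(float)
    for e in config.exposure_specs:
        if smoking and e.name in ("smoking_current", "smoking_previous"):
            continue
        exposures[e.name] = (rng.random(n) < e.prevalence).astype(float)

    lp = (
        config.baseline_log_odds
        + config.age_coefficient * (age - 60.0)
        + config.sex_coefficient * male
        + config.prs_coefficient * g
    )
    for e in config.exposure_specs:
        lp = lp + e.effect * exposures[e.name]
    for s in config.interaction_specs:
        lp = lp + s.effect * exposures[s.name] * g

    pd_status = (rng.random(n) < expit(lp)).astype(int)
    incident = np.zeros(n, dtype=int)
    cases = pd_status == 1
    incident[cases] = (rng.random(cases.sum()) < config.incident_fraction).astype(int)

    age_dx = np.full(n, np.nan)
    age_dx[cases] = (
        config.onset_base
        - config.onset_slope * g[cases]
        + rng.normal(0.0, config.onset_sd, size=cases.sum())
    )

    pcs = {}
    for k in range(config.n_pcs):
        offset = _PC_OFFSETS[k] if k < len(_PC_OFFSETS) else 0.02
        pcs[f"pc{k + 1}"] = rng.normal(0.0, 0.05, size=n) + offset * (~white)

    out = pd.DataFrame(
        {
            "id": genotypes.sample_ids,
            "age": age,
            "sex": np.where(male, "male", "female"),
            "ethnicity": np.where(white, "white_british", "other"),
            "townsend": townsend,
            **exposures,
            "pd_status": pd_status,
            "incident": incident,
            "age_at_diagnosis": age_dx,
            **pcs,
            "true_genetic_score": g,
        }
    )
    return out


def simulate_kinship(
    sample_ids: list[str], config: SimulationConfig
) -> pd.DataFrame:
    """Related pairs with kinship coefficients (first- to beyond-third-degree)."""
    rng = component_rng(config.seed, "kinship")
    n_pairs = min(config.n_related_pairs, len(sample_ids) // 2)
    chosen = rng.choice(len(sample_ids), size=2 * n_pairs, replace=False)
    kin = rng.choice([0.25, 0.125, 0.0625, 0.03], size=n_pairs, p=[0.1, 0.2, 0.5, 0.2])
    return pd.DataFrame(
        {
            "id1": [sample_ids[i] for i in chosen[:n_pairs]],
            "id2": [sample_ids[i] for i in chosen[n_pairs:]],
            "kinship": kin,
        }
    )


@dataclass
class SyntheticCohort:
    """Bundle of all generated components for one cohort."""

    config: SimulationConfig
    genotypes: GenotypeMatrix
    beta_true: np.ndarray
    summary_stats: pd.DataFrame
    cohort: pd.DataFrame
    kinship: pd.DataFrame


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Run all generators under the config's single seed."""
    genotypes, beta_true = simulate_genotypes(config)
    # the summary-stats stream gets its own child seed so the external GWAS is
    # independent of the cohort draw
    ss_seed = int(
        np.random.SeedSequence(config.seed).spawn(len(_COMPONENT))[
            _COMPONENT["sumstats"]
        ].generate_state(1)[0]
        % (2**31)
    )
    stats_df = simulate_summary_stats(genotypes, beta_true, config.gwas_n, ss_seed)
    cohort = simulate_phenotypes(genotypes, config, beta_true)
    kinship = simulate_kinship(genotypes.sample_ids, config)
    return SyntheticCohort(config, genotypes, beta_true, stats_df, cohort, kinship)
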