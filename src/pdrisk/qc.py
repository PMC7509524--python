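"""Variant- and sample-level quality control and relatedness pruning.

Variant filters (applied in a fixed order, each on the survivors of the
previous step): presence in both the target genotypes and the external summary
statistics, duplicate rsIDs, duplicate positions, palindromic (A/T, C/G)
variants, variants without an rsID, then minor allele frequency < 0.01,
genotype missingness > 10%, Hardy-Weinberg p < 1e-6 and imputation quality
< 0.3 (defaults; all configurable).  Boundary conventions follow the stated
thresholds strictly: MAF exactly at the minimum is retained, missingness
exactly at the maximum is retained.

Sample filters: genotype missingness > 10% (strict), then an ancestry label
restriction.  Relatedness pruning removes one member of each related pair at
kinship >= 0.0442 (third-degree) by greedy maximum-degree elimination, which
retains more individuals than naive pairwise removal in multi-relative
clusters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, is_palindromic


class NoOverlapError(ValueError):
    """Raised when genotypes and summary statistics share no variants."""


@dataclass(frozen=True)
class QCThresholds:
    maf_min: float = 0.01
    geno_missing_max: float = 0.10
    hwe_p_min: float = 1e-6
    info_min: float = 0.3
    sample_missing_max: float = 0.10
    kinship_cutoff: float = 0.0442

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass
class QCReport:
    """Per-criterion removal counts plus the retained identifiers."""

    axis: str
    n_input: int
    removed: dict[str, int] = field(default_factory=dict)
    retained_ids: list[str] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    def check(self) -> None:
        if self.n_removed + len(self.retained_ids) != self.n_input:
            raise AssertionError("QC bookkeeping does not sum to input total")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "axis": self.axis,
                "n_input": self.n_input,
                "removed": self.removed,
                "n_retained": len(self.retained_ids),
                "retained_ids": list(self.retained_ids),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def hwe_exact_p(n_het: int, n_hom_rare: int, n_hom_common: int) -> float:
    """Exact Hardy-Weinberg test p-value for a biallelic genotype count triple.

    Sums the probabilities of all heterozygote counts (given the observed
    allele counts) no more likely than the observed one.  Used only when a
    variant carries no precomputed ``hwe_p`` attribute.
    """
    n_het, n_hom_rare, n_hom_common = int(n_het), int(n_hom_rare), int(n_hom_common)
    rare = 2 * n_hom_rare + n_het
    n = n_het + n_hom_rare + n_hom_common
    if n == 0:
        return 1.0
    # probabilities over all het counts with the same parity as `rare`
    het_values = np.arange(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    if len(het_values) == 0:
        return 1.0
    probs = np.zeros(len(het_values))
    # start from the midpoint and recurse outwards for numerical stability
    mid_idx = int(np.argmin(np.abs(het_values - rare / 2.0)))
    probs[mid_idx] = 1.0
    for i in range(mid_idx, len(het_values) - 1):
        h = het_values[i]
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        # P(h+2)/P(h) = 4*hom_r*hom_c / ((h+2)*(h+1))
        probs[i + 1] = probs[i] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
    for i in range(mid_idx, 0, -1):
        h = het_values[i]
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        # P(h-2)/P(h) = h*(h-1) / (4*(hom_r+1)*(hom_c+1))
        probs[i - 1] = probs[i] * h * (h - 1.0) / (4.0 * (hom_r + 1.0) * (hom_c + 1.0))
    probs /= probs.sum()
    p_obs = probs[int(np.searchsorted(het_values, n_het))]
    return float(min(1.0, probs[probs <= p_obs + 1e-12].sum()))


def _hwe_from_dosages(dosages: np.ndarray) -> np.ndarray:
    out = np.empty(dosages.shape[1])
    for j in range(dosages.shape[1]):
        col = dosages[:, j]
        col = col[~np.isnan(col)]
        n_het = int((col == 1).sum())
        n_alt = int((col == 2).sum())
        n_ref = int((col == 0).sum())
        n_hom_rare, n_hom_common = min(n_alt, n_ref), max(n_alt, n_ref)
        out[j] = hwe_exact_p(n_het, n_hom_rare, n_hom_common)
    return out


def filter_variants(
    genotypes: GenotypeMatrix,
    stats: pd.DataFrame,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the variant QC cascade; returns filtered genotypes and the report."""
    v = genotypes.variants
    report = QCReport(axis="variant", n_input=len(v))
    keep = np.ones(len(v), dtype=bool)

    def drop(mask_fail: np.ndarray, label: str) -> None:
        fail = keep & np.asarray(mask_fail, dtype=bool)
        report.removed[label] = int(fail.sum())
        keep[fail] = False

    rsids = v["rsid"].astype(str)
    in_stats = rsids.isin(set(stats["SNP"].astype(str)))
    if not in_stats.any():
        raise NoOverlapError("no overlapping variants between genotypes and summary stats")
    drop(~in_stats.to_numpy(), "absent_from_summary_stats")
    drop(rsids.duplicated(keep="first").to_numpy(), "duplicate_rsid")
    drop(v.duplicated(subset=["chrom", "pos"], keep="first").to_numpy(), "duplicate_position")
    pal = np.array([is_palindromic(a, b) for a, b in zip(v["a1"], v["a2"])])
    drop(pal, "palindromic")
    no_rsid = rsids.isna() | (rsids == "") | (rsids == ".")
    drop(no_rsid.to_numpy(), "missing_rsid")

    if "maf" in v.columns and v["maf"].notna().all():
        maf = v["maf"].to_numpy(dtype=float)
    else:
        maf = genotypes.empirical_maf()
    drop(maf < thresholds.maf_min, "maf_below_min")
    drop(genotypes.variant_missingness() > thresholds.geno_missing_max, "missingness_above_max")
    if "hwe_p" in v.columns and v["hwe_p"].notna().all():
        hwe = v["hwe_p"].to_numpy(dtype=float)
    else:
        hwe = _hwe_from_dosages(genotypes.dosages)
    drop(hwe < thresholds.hwe_p_min, "hwe_below_min")
    if "info" in v.columns and v["info"].notna().any():
        info = v["info"].to_numpy(dtype=float)
        drop(np.nan_to_num(info, nan=1.0) < thresholds.info_min, "info_below_min")
    else:
        report.removed["info_below_min"] = 0

    report.retained_ids = list(v.loc[keep, "rsid"])
    report.check()
    return genotypes.subset_variants(keep), report


def filter_samples(
    genotypes: GenotypeMatrix,
    cohort: pd.DataFrame,
    thresholds: QCThresholds = QCThresholds(),
    ethnicity_label: str = "white_british",
) -> tuple[list[str], QCReport]:
    """Drop samples with high genotype missingness, then off-label ancestry.

    The ancestry restriction is a label filter on the cohort's ethnicity
    column (PC-based ancestry assignment is out of scope; PCs are carried as
    covariates only).
    """
    ids = np.array(genotypes.sample_ids)
    report = QCReport(axis="sample", n_input=len(ids))
    keep = np.ones(len(ids), dtype=bool)

    miss = genotypes.sample_missingness()
    fail = miss > thresholds.sample_missing_max
    report.removed["missingness_above_max"] = int(fail.sum())
    keep[fail] = False

    eth = cohort.set_index("id")["ethnicity"].reindex(ids)
    fail_eth = keep & (eth != ethnicity_label).to_numpy()
    report.removed["ethnicity"] = int(fail_eth.sum())
    keep[fail_eth] = False

    report.retained_ids = list(ids[keep])
    report.check()
    return report.retained_ids, report


def prune_related(
    sample_ids: list[str],
    pairs: pd.DataFrame,
    cutoff: float = 0.0442,
) -> list[str]:
    """Greedy relatedness pruning: repeatedly remove the highest-degree sample.

    Builds the graph of pairs with kinship >= cutoff and removes the node of
    maximum degree (ties broken by lexicographically smallest id) until no
    edges remain.  Returns survivors in the input order.
    """
    known = set(sample_ids)
    for col in ("id1", "id2"):
        unknown = set(pairs[col].astype(str)) - known
        if unknown:
            raise ValueError(f"kinship pairs reference unknown ids: {sorted(unknown)[:5]}")
    adj: dict[str, set[str]] = {}
    for id1, id2, kin in zip(pairs["id1"], pairs["id2"], pairs["kinship"]):
        if id1 == id2:
            raise ValueError(f"self-pair in kinship table: {id1}")
        if kin >= cutoff:
            adj.setdefault(id1, set()).add(id2)
            adj.setdefault(id2, set()).add(id1)
    removed: set[str] = set()
    while True:
        degrees = {s: len(nb) for s, nb in adj.items() if nb}
        if not degrees:
            break
        max_deg = max(degrees.values())
        victim = min(s for s, d in degrees.items() if d == max_deg)
        removed.add(victim)
        for nb in adj.pop(victim):
            adj[nb].discard(victim)
    return [s for s in sample_ids if s not in removed]
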