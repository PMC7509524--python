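"""Dosage-matrix container for biallelic SNP genotypes.

The matrix holds additive effect-allele dosages (0/1/2, NaN = missing) for
``n_samples`` individuals by ``n_variants`` variants, together with per-variant
metadata (rsid, chromosome, 1-based position, effect allele ``a1``, other
allele ``a2``, and optional ``maf``/``info``/``hwe_p`` attributes).  It is the
substrate for variant/sample QC, LD computation and polygenic scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ("rsid", "chrom", "pos", "a1", "a2")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage data with variant metadata."""

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table lacks columns: {missing}")
        self.dosages = np.asarray(self.dosages, dtype=np.float32)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        d = self.dosages
        if d.size:
            valid = np.isnan(d) | (d == 0.0) | (d == 1.0) | (d == 2.0)
            if not valid.all():
                raise ValueError("dosages must be 0, 1, 2 or NaN")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    # ---- per-axis summaries -------------------------------------------------

    def variant_missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def sample_missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    def empirical_maf(self) -> np.ndarray:
        """Minor-allele frequency from the observed dosages (folded to <=0.5)."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.dosages, axis=0) / 2.0
        freq = np.where(np.isnan(freq), 0.0, freq)
        return np.minimum(freq, 1.0 - freq)

    # ---- subsetting ---------------------------------------------------------

    def subset_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset by positional index (bool mask or integer positions)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=self.variants.iloc[index].reset_index(drop=True),
            dosages=self.dosages[:, index],
        )

    def subset_samples(self, ids: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            rows = [pos[s] for s in ids]
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None
        return GenotypeMatrix(
            sample_ids=list(ids),
            variants=self.variants.copy(),
            dosages=self.dosages[rows, :],
        )

    def variant_index(self) -> dict[str, int]:
        return {rsid: i for i, rsid in enumerate(self.variants["rsid"])}


def is_palindromic(a1: str, a2: str) -> bool:
    """True for strand-ambiguous allele pairs (A/T or C/G)."""
    return _COMPLEMENT.get(str(a1).upper()) == str(a2).upper()
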