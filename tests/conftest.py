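import numpy as np
import pandas as pd
import pytest

from pdrisk.genotypes import GenotypeMatrix
from pdrisk.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def bundle():
    """Mid-sized synthetic cohort shared by read-only tests."""
    cfg = SimulationConfig(n_individuals=2000, n_variants=200, n_causal=10, seed=42)
    return simulate_cohort(cfg)


def make_genotypes(
    rsids,
    dosages,
    chrom=None,
    pos=None,
    a1=None,
    a2=None,
    maf=None,
    info=None,
    hwe_p=None,
    sample_ids=None,
):
    """Hand-construct a GenotypeMatrix for toy QC/PRS fixtures."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    assert m == len(rsids)
    variants = pd.DataFrame(
        {
            "rsid": rsids,
            "chrom": chrom if chrom is not None else [1] * m,
            "pos": pos if pos is not None else [1000 * (i + 1) for i in range(m)],
            "a1": a1 if a1 is not None else ["A"] * m,
            "a2": a2 if a2 is not None else ["G"] * m,
        }
    )
    if maf is not None:
        variants["maf"] = maf
    if info is not None:
        variants["info"] = info
    if hwe_p is not None:
        variants["hwe_p"] = hwe_p
    ids = sample_ids if sample_ids is not None else [f"S{i:04d}" for i in range(n)]
    return GenotypeMatrix(ids, variants, dosages)


def stats_for(genotypes, beta=0.1, p=0.01):
    """Summary-stats table matching a toy genotype matrix."""
    v = genotypes.variants
    m = len(v)
    return pd.DataFrame(
        {
            "SNP": v["rsid"],
            "CHR": v["chrom"],
            "BP": v["pos"],
            "A1": v["a1"],
            "A2": v["a2"],
            "BETA": np.full(m, beta) if np.isscalar(beta) else np.asarray(beta),
            "P": np.full(m, p) if np.isscalar(p) else np.asarray(p),
            "FREQ": v["maf"] if "maf" in v.columns else np.full(m, 0.3),
        }
    )
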