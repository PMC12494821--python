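import numpy as np
import pytest

from statewise_burden.io_formats import GenotypeMatrix, VariantRecord
from statewise_burden.synthetic_cohort import CohortConfig, generate_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_variants(positions, chrom="chr1", maf=None, **ann):
    """Minimal variant records at the given positions."""
    out = []
    for i, pos in enumerate(positions):
        v = VariantRecord(chrom=chrom, pos=int(pos), ref="A", alt="G")
        if maf is not None:
            v.maf = float(maf[i])
        out.append(v)
    return out


def hwe_genotypes(rng, n_samples, freqs):
    """HWE genotype matrix for given per-variant allele frequencies."""
    freqs = np.asarray(freqs)
    g = rng.binomial(2, freqs[None, :].repeat(n_samples, axis=0)).astype(np.int8)
    return GenotypeMatrix(g, [f"S{i}" for i in range(n_samples)])


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic cohort shared across read-only tests."""
    cfg = CohortConfig(
        n_bd=80,
        n_sz=120,
        n_internal_control=150,
        n_external_control=250,
        genome=(("chr1", 20_000_000),),
        n_variants=4000,
        seed=7,
    )
    return cfg, generate_cohort(cfg)
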