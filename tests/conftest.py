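import numpy as np
import pandas as pd
import pytest

from admixpipe.io import GenotypeMatrix, IndividualRecord, SNPRecord


def make_genotypes(dosage, populations=None, chromosomes=None, positions=None,
                   alleles=("A", "G")):
    """Build a GenotypeMatrix from a dosage array with generated metadata."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if populations is None:
        populations = ["pop1"] * n
    if chromosomes is None:
        chromosomes = [1] * m
    if positions is None:
        positions = [(j + 1) * 1000 for j in range(m)]
    snps = [
        SNPRecord(f"rs{j}", int(chromosomes[j]), int(positions[j]), alleles[0], alleles[1])
        for j in range(m)
    ]
    inds = [IndividualRecord(f"ind{i}", populations[i]) for i in range(n)]
    return GenotypeMatrix(individuals=inds, snps=snps, dosage=dosage)


def balding_nichols(rng, p, F):
    """Independent drifted frequencies around ancestral p with variance F p(1-p)."""
    r = (1 - F) / F
    return np.clip(rng.beta(np.maximum(p * r, 1e-12), np.maximum((1 - p) * r, 1e-12)),
                   1e-9, 1 - 1e-9)


def two_population_panel(rng, n_per_pop, n_snps, F, populations=("A", "B")):
    """Genotypes for two populations drifted F each from a shared root."""
    root = rng.uniform(0.05, 0.95, n_snps)
    fa = balding_nichols(rng, root, F)
    fb = balding_nichols(rng, root, F)
    da = rng.binomial(2, fa, size=(n_per_pop, n_snps)).astype(np.int8)
    db = rng.binomial(2, fb, size=(n_per_pop, n_snps)).astype(np.int8)
    g = make_genotypes(np.vstack([da, db]),
                       populations=[populations[0]] * n_per_pop + [populations[1]] * n_per_pop)
    return g, fa, fb


@pytest.fixture(scope="session")
def study_fixture():
    """Small study-like synthetic dataset shared across tests."""
    import admixpipe as ap

    cfg = ap.default_config(seed=42, n_snps=400)
    return ap.make_study_fixture(cfg)
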