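"""Shared fixtures: small simulated cohorts reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import popsel


@pytest.fixture(scope="session")
def sweep_cohort():
    """One completed hard sweep (s=0.05) in a two-population phased cohort."""
    spec = popsel.SimSpec(n_pops=2, samples_per_pop=100, n_variants=10_000,
                          fst_target=0.0, seed=42, chrom_length_bp=5_000_000)
    sw = popsel.SweepSpec(target_pop="sweep", s=0.05, sweep_pos=2_500_000,
                          generations=200)
    return popsel.simulate_sweep_cohort(spec, sw)


@pytest.fixture(scope="session")
def neutral_cohort():
    """Same demography as the sweep cohort but with s = 0 (neutral null)."""
    spec = popsel.SimSpec(n_pops=2, samples_per_pop=100, n_variants=10_000,
                          fst_target=0.0, seed=43, chrom_length_bp=5_000_000)
    sw = popsel.SweepSpec(target_pop="sweep", s=0.0, sweep_pos=2_500_000,
                          generations=200)
    return popsel.simulate_sweep_cohort(spec, sw)


@pytest.fixture(scope="session")
def structured_gm():
    """Two Balding-Nichols populations at F_ST 0.05, 60+60 samples."""
    spec = popsel.SimSpec(n_pops=2, samples_per_pop=60, n_variants=2000,
                          fst_target=0.05, seed=7)
    gm, _ = popsel.simulate_structured_genotypes(spec)
    return gm


def make_genotype_matrix(dosage, positions=None, chrom="1", pops=None):
    """Build a GenotypeMatrix from a plain dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    if pops is None:
        pops = ["pop1"] * n
    variants = pd.DataFrame({"chrom": chrom, "pos": positions,
                             "id": [f"v{j}" for j in range(m)],
                             "ref": "A", "alt": "G"})
    samples = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                            "population": pops})
    return popsel.GenotypeMatrix(dosage, variants, samples)


def make_haplotype_matrix(alleles, positions=None, chrom="1", pops=None):
    """Build a HaplotypeMatrix from a plain 0/1 allele array."""
    alleles = np.asarray(alleles, dtype=np.uint8)
    nh, m = alleles.shape
    assert nh % 2 == 0
    n = nh // 2
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    if pops is None:
        pops = ["pop1"] * n
    variants = pd.DataFrame({"chrom": chrom, "pos": positions,
                             "id": [f"v{j}" for j in range(m)],
                             "ref": "A", "alt": "G"})
    samples = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                            "population": pops})
    return popsel.HaplotypeMatrix(alleles, variants, samples)
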