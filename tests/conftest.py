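import numpy as np
import pandas as pd
import pytest

from herdsweep.genotype_io import (
    GenotypeMatrix,
    HaplotypePanel,
    MarkerMap,
    PedigreeTable,
)
from herdsweep.synthetic_data import QTL, SimConfig, simulate_breeding


def make_map(n_snps, chrom=1, spacing=50_000, start=50_000):
    pos = start + spacing * np.arange(n_snps)
    return MarkerMap(
        snp_id=np.array([f"snp{chrom}_{i}" for i in range(n_snps)], dtype=object),
        chromosome=np.full(n_snps, chrom),
        position_bp=pos,
        allele_a=np.repeat("A", n_snps).astype(object),
        allele_b=np.repeat("B", n_snps).astype(object),
    )


def make_multi_map(snps_per_chrom, chroms=(1, 2), spacing=50_000):
    parts = [make_map(snps_per_chrom, chrom=c, spacing=spacing) for c in chroms]
    return MarkerMap(
        snp_id=np.concatenate([p.snp_id for p in parts]),
        chromosome=np.concatenate([p.chromosome for p in parts]),
        position_bp=np.concatenate([p.position_bp for p in parts]),
        allele_a=np.concatenate([p.allele_a for p in parts]),
        allele_b=np.concatenate([p.allele_b for p in parts]),
    )


def make_genotypes(codes, spacing=50_000):
    codes = np.asarray(codes, dtype=np.int8)
    markers = make_map(codes.shape[1], spacing=spacing)
    animals = [f"an{i}" for i in range(codes.shape[0])]
    return GenotypeMatrix(animals, markers, codes)


def make_panel(haps, spacing=50_000, markers=None):
    """haps: (n_animals, 2, n_snps) array-like of 0/1 alleles."""
    haps = np.asarray(haps, dtype=np.int8)
    if markers is None:
        markers = make_map(haps.shape[2], spacing=spacing)
    animals = [f"an{i}" for i in range(haps.shape[0])]
    return HaplotypePanel(animals, markers, haps)


def make_pedigree(rows):
    """rows: (animal, sire-or-None, dam-or-None, birth_year) tuples."""
    return PedigreeTable(
        pd.DataFrame(
            rows, columns=["animal_id", "sire_id", "dam_id", "birth_year"]
        )
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small neutral population reused by IO / property tests."""
    cfg = SimConfig(
        n_chromosomes=2,
        snps_per_chromosome=120,
        chromosome_length_bp=12_000_000,
        n_ancestral_haplotypes=8,
        year_start=1990,
        year_end=2005,
        animals_per_year=12,
        n_founders=24,
        n_sires_per_year=2,
        sire_selection_fraction=0.5,
        rng_seed=7,
    )
    return simulate_breeding(cfg)


@pytest.fixture(scope="session")
def sweep_sim():
    """A small population with one strongly selected QTL (chromosome 1, SNP 60)."""
    cfg = SimConfig(
        n_chromosomes=2,
        snps_per_chromosome=120,
        chromosome_length_bp=12_000_000,
        n_ancestral_haplotypes=8,
        year_start=1980,
        year_end=2007,
        animals_per_year=20,
        n_founders=40,
        n_sires_per_year=2,
        sire_selection_fraction=0.3,
        qtls=[QTL(1, 60, 4.0, origin_templates=1)],
        trait_noise_sd=1.0,
        rng_seed=11,
    )
    return simulate_breeding(cfg)
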