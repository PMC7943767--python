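"""Shared fixtures: small genomes and deterministic random sequence builders."""

from __future__ import annotations

import numpy as np
import pytest

from paleodup.genome_io import Gene, Genome
from paleodup.synthetic_data import SimConfig, depth_to_mya, simulate

SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    return "".join(rng.choice(SENSE_CODONS) for _ in range(n_codons))


def toy_genome(spec: list[tuple[str, str, int, int]], species: str = "sp") -> Genome:
    """Build a genome from (gene_id, chromosome, start, end) tuples."""
    return Genome.from_genes(
        species, [Gene(gene_id=g, chromosome=c, start=s, end=e) for g, c, s, e in spec]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def wgd_sim():
    """Small single-species dataset with one clean WGD at depth 0.5."""
    cfg = SimConfig(
        seed=11,
        n_genes=120,
        n_chromosomes=3,
        codons_per_gene=300,
        wgd_events=[(depth_to_mya(0.5), 1.0)],
    )
    return cfg, simulate(cfg)
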