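"""Shared fixtures: small simulated clades and toy genomes."""

from __future__ import annotations

import logging

import pytest

from amkarya.genome import GeneModel, Genome
from amkarya.sim import (
    Fission,
    Fusion,
    Inversion,
    LineageSpec,
    SimConfig,
    WGD,
    simulate_clade,
)

logging.getLogger("amkarya").setLevel(logging.ERROR)


def toy_genome(species: str, chrom_sizes: dict[str, int], gene_len: int = 1200,
               spacer: int = 800) -> Genome:
    """Deterministic genome: consecutive genes, alternating strands."""
    records = []
    counter = 0
    for chrom, n in chrom_sizes.items():
        for i in range(n):
            start = i * (gene_len + spacer)
            records.append(
                GeneModel(
                    id=f"{species}_g{counter:05d}",
                    species=species,
                    chrom=chrom,
                    start=start,
                    end=start + gene_len,
                    strand="+" if i % 2 == 0 else "-",
                    order=0,
                )
            )
            counter += 1
    return Genome.from_records(species, records)


@pytest.fixture(scope="session")
def small_clade():
    """One ancestor, four lineages covering WGD, fusion, fission, inversion."""
    cfg = SimConfig(
        seed=17,
        n_ancestral_chromosomes=5,
        genes_per_chromosome=120,
        lineages=[
            LineageSpec("wgd_sp", 0.05, [WGD(retention_bias=0.3)]),
            LineageSpec("fus_sp", 0.06, [Fusion(), Fusion()]),
            LineageSpec("fis_sp", 0.07, [Fission()]),
            LineageSpec("inv_sp", 0.05, [Inversion()]),
        ],
    )
    return simulate_clade(cfg)
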