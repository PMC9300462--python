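"""Gene models and genomes as ordered, stranded gene lists.

All synteny logic in this package works at gene resolution: every gene
carries both a base-pair interval (0-based, half-open) and an integer
order index (its rank along the chromosome).  The order index is the
coordinate system for anchors, blocks and breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List


@dataclass(frozen=True)
class GeneModel:
    """A single gene: id, location and rank along its chromosome."""

    id: str
    species: str
    chrom: str
    start: int
    end: int
    strand: str
    order: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.id}: start must be < end ({self.start} >= {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def aa_length(self) -> int:
        """Protein length implied by the genomic span (span // 3, >= 1)."""
        return max(1, self.length // 3)


@dataclass
class Genome:
    """A species' chromosomes as ordered lists of :class:`GeneModel`.

    Chromosome dictionaries preserve insertion order; gene lists are kept
    sorted by start coordinate with order indices 0..n-1.
    """

    species: str
    chromosomes: Dict[str, List[GeneModel]] = field(default_factory=dict)
    genome_size: int | None = None

    @classmethod
    def from_records(cls, species: str, records: List[GeneModel]) -> "Genome":
        """Build a genome from unordered gene records, recomputing ranks."""
        by_chrom: Dict[str, List[GeneModel]] = {}
        for rec in records:
            by_chrom.setdefault(rec.chrom, []).append(rec)
        genome = cls(species=species)
        for chrom in by_chrom:
            genome.chromosomes[chrom] = by_chrom[chrom]
        genome.recompute_orders()
        return genome

    def recompute_orders(self) -> None:
        """Sort each chromosome by start and reassign order indices."""
        seen: set[str] = set()
        for chrom, genes in self.chromosomes.items():
            genes.sort(key=lambda g: (g.start, g.id))
            self.chromosomes[chrom] = [
                replace(g, order=i) for i, g in enumerate(genes)
            ]
            for g in self.chromosomes[chrom]:
                if g.id in seen:
                    raise ValueError(
                        f"duplicate gene id {g.id!r} in genome {self.species!r}"
                    )
                seen.add(g.id)

    # -- look-ups ---------------------------------------------------------

    def genes(self) -> Iterator[GeneModel]:
        for genes in self.chromosomes.values():
            yield from genes

    def gene_index(self) -> Dict[str, GeneModel]:
        return {g.id: g for g in self.genes()}

    @property
    def n_genes(self) -> int:
        return sum(len(v) for v in self.chromosomes.values())

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Genome({self.species!r}, {self.n_chromosomes} chromosomes, "
            f"{self.n_genes} genes)"
        )
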