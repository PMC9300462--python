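"""Conserved-gene detection and one-to-one ortholog extraction.

Step 1 of the karyotype-reconstruction method scores each query-subject
gene pair over all of its BLAST high-scoring pairs (HSPs):

* ``CIP`` (cumulative identity percentage) = 100 * (sum of identical
  residues over all retained HSPs) / (sum of retained HSP aligned
  lengths);
* ``CALP`` (cumulative alignment length percentage) = (sum of retained
  HSP aligned lengths) / query length.

Pairs with CIP >= 50 and CALP >= 0.5 are "conserved genes".  Step 2
removes species-specific and local (tandem) duplicates and reduces the
remaining relations to one-to-one orthologs by mutual best scoring.

Overlapping HSPs would inflate CALP above 1; they are resolved greedily:
HSPs are consumed by descending bitscore, later HSPs are clipped to the
query intervals not yet claimed and their aligned length and identity
counts prorated by the clipped fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import pandas as pd

from amkarya.genome import Genome


@dataclass(frozen=True)
class HSP:
    """One local alignment segment of a query-subject pair.

    ``aligned_length`` is the alignment length AL (including gap
    columns); ``n_identical`` the number of identical residues; the
    query interval is 0-based half-open.
    """

    aligned_length: int
    n_identical: float
    qstart: int
    qend: int
    bitscore: float

    def __post_init__(self) -> None:
        if not (self.aligned_length >= self.n_identical >= 0):
            raise ValueError(
                f"HSP requires AL >= ID >= 0, got AL={self.aligned_length}, "
                f"ID={self.n_identical}"
            )


@dataclass
class HitSet:
    """All HSPs for one query-subject gene pair."""

    query: str
    subject: str
    query_length: int
    hsps: List[HSP] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.query_length <= 0:
            raise ValueError(f"query length must be > 0 for {self.query}")


@dataclass(frozen=True)
class HitSummary:
    """CIP/CALP summary of a hit set.  CIP is a percent, CALP a fraction."""

    query: str
    subject: str
    cip: float
    calp: float
    bitscore_sum: float

    def passes(self, cip_min: float = 50.0, calp_min: float = 0.5) -> bool:
        return self.cip >= cip_min and self.calp >= calp_min


@dataclass(frozen=True)
class OrthologPair:
    """A one-to-one ortholog pair between two species."""

    gene_a: str
    gene_b: str
    species_a: str
    species_b: str
    cip: float
    calp: float
    bitscore_sum: float


# ---------------------------------------------------------------------------
# CIP / CALP
# ---------------------------------------------------------------------------


def _resolve_overlaps(hsps: Sequence[HSP]) -> List[Tuple[float, float]]:
    """Greedy overlap resolution on the query axis.

    Returns (effective AL, effective ID) per retained HSP.  HSPs are
    taken by descending bitscore (ties: longer first, then left-most);
    each is clipped to the unclaimed part of its query interval and its
    AL/ID prorated by the unclipped fraction.  Fully claimed HSPs are
    dropped.
    """
    claimed: List[Tuple[int, int]] = []
    out: List[Tuple[float, float]] = []
    order = sorted(
        hsps, key=lambda h: (-h.bitscore, -(h.qend - h.qstart), h.qstart)
    )
    for hsp in order:
        span = hsp.qend - hsp.qstart
        if span <= 0:
            continue
        free = span
        for cs, ce in claimed:
            lo, hi = max(hsp.qstart, cs), min(hsp.qend, ce)
            if hi > lo:
                free -= hi - lo
        if free <= 0:
            continue
        frac = free / span
        out.append((hsp.aligned_length * frac, hsp.n_identical * frac))
        claimed.append((hsp.qstart, hsp.qend))
    return out


def compute_cip_calp(hitset: HitSet) -> HitSummary:
    """Score a hit set: CIP = 100 * sum(ID) / sum(AL), CALP = sum(AL) / qlen."""
    if not hitset.hsps:
        raise ValueError(f"hit set {hitset.query}-{hitset.subject} has no HSPs")
    contrib = _resolve_overlaps(hitset.hsps)
    al_sum = sum(al for al, _ in contrib)
    id_sum = sum(i for _, i in contrib)
    if al_sum <= 0:
        raise ValueError(
            f"hit set {hitset.query}-{hitset.subject}: zero cumulative length"
        )
    return HitSummary(
        query=hitset.query,
        subject=hitset.subject,
        cip=100.0 * id_sum / al_sum,
        calp=al_sum / hitset.query_length,
        bitscore_sum=sum(h.bitscore for h in hitset.hsps),
    )


def group_hitsets(
    hits: pd.DataFrame, query_lengths: Mapping[str, int]
) -> List[HitSet]:
    """Group raw BLAST tabular rows into :class:`HitSet` objects.

    ``query_lengths`` maps gene id to protein length (aa).  The number
    of identical residues per HSP is recovered from ``pident * length``.
    """
    sets: Dict[Tuple[str, str], HitSet] = {}
    for row in hits.itertuples(index=False):
        key = (row.qseqid, row.sseqid)
        if key not in sets:
            if row.qseqid not in query_lengths:
                raise KeyError(f"no query length for gene {row.qseqid!r}")
            sets[key] = HitSet(
                query=row.qseqid,
                subject=row.sseqid,
                query_length=int(query_lengths[row.qseqid]),
            )
        qstart, qend = (row.qstart, row.qend) if row.qstart <= row.qend else (
            row.qend,
            row.qstart,
        )
        sets[key].hsps.append(
            HSP(
                aligned_length=int(row.length),
                n_identical=row.pident * row.length / 100.0,
                qstart=int(qstart) - 1,
                qend=int(qend),
                bitscore=float(row.bitscore),
            )
        )
    return list(sets.values())


def filter_conserved(
    summaries: Iterable[HitSummary],
    cip_min: float = 50.0,
    calp_min: float = 0.5,
) -> Dict[Tuple[str, str], HitSummary]:
    """Keep conserved gene pairs: CIP/CALP pass in either direction.

    Returns an unordered-pair dict keyed by the sorted gene-id pair,
    carrying the best-scoring passing direction (by CIP, then CALP,
    then bitscore).
    """
    kept: Dict[Tuple[str, str], HitSummary] = {}
    for s in summaries:
        if not s.passes(cip_min, calp_min):
            continue
        key = (s.query, s.subject) if s.query <= s.subject else (s.subject, s.query)
        prev = kept.get(key)
        if prev is None or (s.cip, s.calp, s.bitscore_sum) > (
            prev.cip,
            prev.calp,
            prev.bitscore_sum,
        ):
            kept[key] = s
    return kept


# ---------------------------------------------------------------------------
# step 2: tandem collapse + one-to-one reduction
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self) -> None:
        self.parent: Dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def _tandem_clusters(
    pairs: Dict[Tuple[str, str], HitSummary],
    genome: Genome,
    tandem_window: int,
) -> Dict[str, str]:
    """Map each gene to its tandem-cluster representative (lowest order)."""
    idx = genome.gene_index()
    uf = _UnionFind()
    for (a, b) in pairs:
        ga, gb = idx.get(a), idx.get(b)
        if ga is None or gb is None:
            continue
        if ga.chrom == gb.chrom and abs(ga.order - gb.order) <= tandem_window:
            uf.union(a, b)
    members: Dict[str, List[str]] = {}
    for gid in uf.parent:
        members.setdefault(uf.find(gid), []).append(gid)
    rep: Dict[str, str] = {}
    for group in members.values():
        group.sort(key=lambda g: (idx[g].order, g))
        head = group[0]
        for g in group:
            rep[g] = head
    return rep


def remove_local_and_specific(
    conserved: Dict[Tuple[str, str], HitSummary],
    genomes: Mapping[str, Genome],
    tandem_window: int = 5,
) -> List[OrthologPair]:
    """Reduce conserved pairs to one-to-one orthologs.

    Within each species, genes linked by a conserved same-species hit at
    most ``tandem_window`` order ranks apart are collapsed to one
    representative (the lowest-order member).  Genes hitting only their
    own species drop out.  Remaining many-to-many relations between each
    species pair are reduced to mutual-best pairs scored by (CIP, CALP,
    bitscore sum) with lexicographic gene-id tie-break.
    """
    species_of: Dict[str, str] = {}
    for sp, genome in genomes.items():
        for g in genome.genes():
            species_of[g.id] = sp
    for (a, b) in conserved:
        for gid in (a, b):
            if gid not in species_of:
                raise ValueError(f"gene {gid!r} in hit pairs but absent from genomes")

    # same-species conserved pairs drive tandem collapsing
    within: Dict[str, Dict[Tuple[str, str], HitSummary]] = {sp: {} for sp in genomes}
    between: Dict[Tuple[str, str], HitSummary] = {}
    for (a, b), s in conserved.items():
        if species_of[a] == species_of[b]:
            within[species_of[a]][(a, b)] = s
        else:
            between[(a, b)] = s

    rep: Dict[str, str] = {}
    for sp, genome in genomes.items():
        rep.update(_tandem_clusters(within[sp], genome, tandem_window))

    # project cross-species pairs onto representatives, keep best summary
    projected: Dict[Tuple[str, str], HitSummary] = {}
    for (a, b), s in between.items():
        ra, rb = rep.get(a, a), rep.get(b, b)
        key = (ra, rb) if ra <= rb else (rb, ra)
        prev = projected.get(key)
        if prev is None or (s.cip, s.calp, s.bitscore_sum) > (
            prev.cip,
            prev.calp,
            prev.bitscore_sum,
        ):
            projected[key] = s

    # mutual best per species pair
    def sort_key(item: Tuple[Tuple[str, str], HitSummary]):
        (a, b), s = item
        return (-s.cip, -s.calp, -s.bitscore_sum, a, b)

    best: Dict[Tuple[str, str, str], Tuple[str, HitSummary]] = {}
    for (a, b), s in sorted(projected.items(), key=sort_key):
        spa, spb = species_of[a], species_of[b]
        # best partner of `a` within species pair (spa, spb), and vice versa;
        # first occurrence in sorted order is the best (ties broken by id)
        best.setdefault((a, spa, spb), (b, s))
        best.setdefault((b, spb, spa), (a, s))

    out: List[OrthologPair] = []
    for (a, b), s in sorted(projected.items()):
        spa, spb = species_of[a], species_of[b]
        if best[(a, spa, spb)][0] == b and best[(b, spb, spa)][0] == a:
            out.append(
                OrthologPair(
                    gene_a=a,
                    gene_b=b,
                    species_a=spa,
                    species_b=spb,
                    cip=s.cip,
                    calp=s.calp,
                    bitscore_sum=s.bitscore_sum,
                )
            )
    return out


def best_per_query(
    conserved: Dict[Tuple[str, str], HitSummary],
    genomes: Mapping[str, Genome],
    query_species: str,
    subject_species: str,
) -> List[OrthologPair]:
    """One best subject partner per query gene (one-to-many allowed on
    the subject side).

    Used for dotplot and WGD-multiplicity analyses where each modern
    gene should map to its single best ancestral position while an
    ancestral gene may retain several post-WGD copies.
    """
    species_of: Dict[str, str] = {}
    for sp, genome in genomes.items():
        for g in genome.genes():
            species_of[g.id] = sp
    best: Dict[str, Tuple[str, HitSummary]] = {}
    for (a, b), s in conserved.items():
        if species_of.get(a) == subject_species and species_of.get(b) == query_species:
            a, b = b, a
        if species_of.get(a) != query_species or species_of.get(b) != subject_species:
            continue
        prev = best.get(a)
        if prev is None or (s.cip, s.calp, s.bitscore_sum, prev[0]) > (
            prev[1].cip,
            prev[1].calp,
            prev[1].bitscore_sum,
            b,
        ):
            best[a] = (b, s)
    return [
        OrthologPair(
            gene_a=a,
            gene_b=b,
            species_a=query_species,
            species_b=subject_species,
            cip=s.cip,
            calp=s.calp,
            bitscore_sum=s.bitscore_sum,
        )
        for a, (b, s) in sorted(best.items())
    ]
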