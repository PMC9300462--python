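"""Ancestral karyotype construction and rearrangement scenarios.

Steps 4-6 of the reconstruction method:

* **CARs** (conserved ancestral regions, i.e. ancestral chromosomes):
  synteny blocks between a pivot genome and at least two other species
  are merged into independent groups.  Pivot genes spanned by a common
  block are glued together; the connected components of this gluing,
  per pivot chromosome, are the CARs.  A junction on a pivot chromosome
  splits into two CARs only when *no* species retains a block spanning
  it, so shared ancestral contiguity is preserved while lineage-specific
  fusions in the pivot fall apart.
* **WGD multiplicity**: the modal number of syntenic blocks stacked
  over windows of the reference genome (1 = no duplication, 2 = one
  whole-genome duplication, 3 = triplication).
* **Scenario inference**: each modern chromosome is decomposed into
  CAR-copy-labelled segments; fusions are junctions between distinct
  origins on one chromosome, fissions are extra chromosomes touched by
  one origin, and the chromosome-number bookkeeping identity
  ``n_modern = m * n_CARs + fissions - fusions`` is checked.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import pandas as pd

from amkarya.genome import Genome
from amkarya.synteny import SyntenyBlock

logger = logging.getLogger("amkarya")


@dataclass
class CAR:
    """A conserved ancestral region: an ordered run of protogenes."""

    id: str
    pivot_chrom: str
    protogenes: List[str]
    support: List[str]  # species whose blocks support this CAR

    @property
    def length(self) -> int:
        return len(self.protogenes)


@dataclass
class AncestralKaryotype:
    """Ordered CARs of protogenes reconstructed on a pivot genome."""

    pivot: str
    cars: List[CAR]
    unsupported_components: int = 0

    @property
    def n_cars(self) -> int:
        return len(self.cars)

    @property
    def n_protogenes(self) -> int:
        return sum(c.length for c in self.cars)

    def protogene_positions(self) -> Dict[str, Tuple[str, int]]:
        """Map protogene id -> (CAR id, position within CAR)."""
        pos: Dict[str, Tuple[str, int]] = {}
        for car in self.cars:
            for i, g in enumerate(car.protogenes):
                if g in pos:
                    raise ValueError(f"protogene {g!r} appears in two CARs")
                pos[g] = (car.id, i)
        return pos

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, car.id, i, car.pivot_chrom)
            for car in self.cars
            for i, g in enumerate(car.protogenes)
        ]
        return pd.DataFrame(rows, columns=["protogene", "car", "position", "pivot_chrom"])


def karyotype_from_genome(genome: Genome) -> AncestralKaryotype:
    """Treat a (known or previously inferred) genome as a karyotype.

    Each chromosome becomes one CAR and every gene a protogene.  Used
    when a trusted ancestral reconstruction serves as the pivot.
    """
    cars = [
        CAR(
            id=f"CAR{i + 1:02d}",
            pivot_chrom=chrom,
            protogenes=[g.id for g in genes],
            support=[genome.species],
        )
        for i, (chrom, genes) in enumerate(genome.chromosomes.items())
    ]
    return AncestralKaryotype(pivot=genome.species, cars=cars)


# ---------------------------------------------------------------------------
# CAR construction
# ---------------------------------------------------------------------------


def _pivot_side(block: SyntenyBlock, pivot: str) -> Tuple[str, List[Tuple[int, str]]]:
    """Return (pivot chromosome, [(pivot order, pivot gene id), ...])."""
    if block.species_a == pivot:
        return block.chrom_a, [(a.order_a, a.gene_a) for a in block.anchors]
    if block.species_b == pivot:
        return block.chrom_b, [(a.order_b, a.gene_b) for a in block.anchors]
    raise ValueError(
        f"block {block.species_a}-{block.species_b} does not involve pivot {pivot!r}"
    )


def build_cars(
    blocks_by_species: Mapping[str, Sequence[SyntenyBlock]],
    pivot_genome: Genome,
    min_support: int = 2,
) -> AncestralKaryotype:
    """Merge synteny blocks into CARs on the pivot gene order.

    ``blocks_by_species`` maps each non-pivot species to its blocks
    against the pivot.  Pivot genes covered by one block are glued
    (they were contiguous in that species, hence ancestrally);
    connected components define candidate CARs.  Components supported
    by blocks from fewer than ``min_support`` species are dropped and
    counted.  Protogenes are the pivot genes with an anchor in at least
    ``min_support`` species, ordered by pivot coordinates.
    """
    if len(blocks_by_species) < 2:
        raise ValueError(
            "CAR construction needs blocks from at least 2 non-pivot species, "
            f"got {len(blocks_by_species)}"
        )
    pivot = pivot_genome.species

    # union-find over gene ranks, per pivot chromosome
    parents: Dict[str, List[int]] = {
        chrom: list(range(len(genes))) for chrom, genes in pivot_genome.chromosomes.items()
    }

    def find(chrom: str, r: int) -> int:
        p = parents[chrom]
        while p[r] != r:
            p[r] = p[p[r]]
            r = p[r]
        return r

    def union(chrom: str, a: int, b: int) -> None:
        ra, rb = find(chrom, a), find(chrom, b)
        if ra != rb:
            parents[chrom][max(ra, rb)] = min(ra, rb)

    anchor_species: Dict[str, set] = {}
    cover_species: Dict[Tuple[str, int], set] = {}
    for sp, blocks in blocks_by_species.items():
        for block in blocks:
            chrom, pivot_anchors = _pivot_side(block, pivot)
            if chrom not in parents:
                raise ValueError(f"block chromosome {chrom!r} not in pivot genome")
            lo = min(o for o, _ in pivot_anchors)
            hi = max(o for o, _ in pivot_anchors)
            for r in range(lo, hi):
                union(chrom, r, r + 1)
            for r in range(lo, hi + 1):
                cover_species.setdefault((chrom, r), set()).add(sp)
            for _, gid in pivot_anchors:
                anchor_species.setdefault(gid, set()).add(sp)

    cars: List[CAR] = []
    unsupported = 0
    for chrom, genes in pivot_genome.chromosomes.items():
        comps: Dict[int, List[int]] = {}
        for r in range(len(genes)):
            comps.setdefault(find(chrom, r), []).append(r)
        for root in sorted(comps):
            ranks = comps[root]
            support = set()
            for r in ranks:
                support |= cover_species.get((chrom, r), set())
            if len(support) < min_support:
                if any((chrom, r) in cover_species for r in ranks):
                    unsupported += 1
                # runs never touched by any block are unplaced genes, not CARs
                elif len(ranks) > 0 and len(support) > 0:
                    unsupported += 1
                continue
            protogenes = [
                genes[r].id
                for r in ranks
                if len(anchor_species.get(genes[r].id, ())) >= min_support
            ]
            cars.append(
                CAR(
                    id="",
                    pivot_chrom=chrom,
                    protogenes=protogenes,
                    support=sorted(support),
                )
            )
    cars.sort(key=lambda c: (c.pivot_chrom, c.protogenes[0] if c.protogenes else ""))
    for i, car in enumerate(cars):
        car.id = f"CAR{i + 1:02d}"
    return AncestralKaryotype(pivot=pivot, cars=cars, unsupported_components=unsupported)


# ---------------------------------------------------------------------------
# WGD multiplicity
# ---------------------------------------------------------------------------


def wgd_multiplicity(
    blocks: Sequence[SyntenyBlock],
    reference: Genome,
    window: int = 20,
) -> Tuple[int, List[List[int]]]:
    """Syntenic coverage depth of a genome over a reference.

    Depth is measured over non-overlapping windows of ``window``
    reference genes: the number of blocks overlapping at least half of
    the window.  The multiplicity m is the mode of the depth over
    covered windows.  The second return value groups block indices that
    stack over common reference regions (the duplicated-block pairing).
    """
    if not blocks:
        raise ValueError("wgd_multiplicity requires at least one block")
    ref = reference.species
    spans: List[Tuple[str, int, int]] = []
    for block in blocks:
        chrom, pivot_anchors = _pivot_side(block, ref)
        orders = [o for o, _ in pivot_anchors]
        spans.append((chrom, min(orders), max(orders)))

    depths: List[int] = []
    window_blocks: List[List[int]] = []
    for chrom, genes in reference.chromosomes.items():
        n = len(genes)
        for w0 in range(0, n, window):
            w1 = min(w0 + window, n)
            need = (w1 - w0 + 1) // 2
            here = [
                i
                for i, (c, lo, hi) in enumerate(spans)
                if c == chrom and min(hi + 1, w1) - max(lo, w0) >= need
            ]
            if here:
                depths.append(len(here))
                window_blocks.append(here)
    if not depths:
        raise ValueError("no reference window is covered by any block")
    m = Counter(depths).most_common(1)[0][0]

    # group blocks that co-occur over windows (connected components)
    parent = list(range(len(blocks)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for group in window_blocks:
        for i in group[1:]:
            ri, r0 = find(i), find(group[0])
            if ri != r0:
                parent[max(ri, r0)] = min(ri, r0)
    comps: Dict[int, List[int]] = {}
    covered = {i for grp in window_blocks for i in grp}
    for i in sorted(covered):
        comps.setdefault(find(i), []).append(i)
    return m, [comps[r] for r in sorted(comps)]


# ---------------------------------------------------------------------------
# scenario inference
# ---------------------------------------------------------------------------


@dataclass
class Scenario:
    """Parsimonious rearrangement counts from a karyotype to a genome."""

    lineage: str
    m: int
    fusions: int
    fissions: int
    translocations: int
    inversions: int
    n_cars: int
    n_modern: int
    n_assigned: int
    segments: pd.DataFrame = field(repr=False)

    @property
    def identity_ok(self) -> bool:
        """Bookkeeping: n = m * n_CARs + fissions - fusions.

        Evaluated over the chromosomes the scenario explains
        (``n_assigned``); chromosomes too small to carry a synteny
        block are reported via ``n_modern - n_assigned`` and the
        coverage warning rather than silently breaking the identity.
        """
        return self.n_assigned == self.m * self.n_cars + self.fissions - self.fusions


def _block_car_segments(
    ak: AncestralKaryotype,
    modern: Genome,
    blocks: Sequence[SyntenyBlock],
) -> List[dict]:
    """Label each block with its CAR and CAR-coordinate interval."""
    positions = ak.protogene_positions()
    segments = []
    for bi, block in enumerate(blocks):
        if block.species_a == modern.species:
            mo = [(a.order_a, a.chrom_a) for a in block.anchors]
            pg = [a.gene_b for a in block.anchors]
        else:
            mo = [(a.order_b, a.chrom_b) for a in block.anchors]
            pg = [a.gene_a for a in block.anchors]
        hits = [positions[g] for g in pg if g in positions]
        if not hits:
            continue
        car = Counter(c for c, _ in hits).most_common(1)[0][0]
        car_pos = [p for c, p in hits if c == car]
        segments.append(
            {
                "block": bi,
                "modern_chrom": mo[0][1],
                "modern_lo": min(o for o, _ in mo),
                "modern_hi": max(o for o, _ in mo),
                "car": car,
                "car_lo": min(car_pos),
                "car_hi": max(car_pos),
                "orientation": block.orientation,
                "n_anchors": len(hits),
            }
        )
    return segments


def _assign_copies(segments: List[dict], m: int, overlap_tol: int = 2) -> None:
    """First-fit interval partitioning of each CAR's segments into copies.

    Segments of the same copy must occupy disjoint CAR intervals;
    homeologous (post-WGD) segments overlap and are forced onto
    different copies.  Sorting by CAR start and filling the first copy
    with room keeps each copy's segments contiguous.  A duplication of
    multiplicity m leaves at most m copies, so overflow segments
    (chain wobble around inversion breakpoints can nick a few anchors
    off a neighbouring run) are folded back onto the established copy
    they overlap least.
    """
    by_car: Dict[str, List[dict]] = {}
    for seg in segments:
        by_car.setdefault(seg["car"], []).append(seg)
    for car in sorted(by_car):
        segs = sorted(
            by_car[car], key=lambda s: (s["car_lo"], s["modern_chrom"], s["modern_lo"])
        )
        ends: List[int] = []  # last claimed car_hi per copy
        for seg in segs:
            placed = False
            for ci, end in enumerate(ends):
                if seg["car_lo"] >= end - overlap_tol:
                    seg["copy"] = ci
                    ends[ci] = max(end, seg["car_hi"])
                    placed = True
                    break
            if not placed:
                seg["copy"] = len(ends)
                ends.append(seg["car_hi"])
        if len(ends) > m:
            intervals: Dict[int, List[Tuple[int, int]]] = {}
            for seg in segs:
                intervals.setdefault(seg["copy"], []).append(
                    (seg["car_lo"], seg["car_hi"])
                )
            # fold extra copies (fewest anchors first) onto 0..m-1
            extra = sorted(
                (c for c in intervals if c >= m),
                key=lambda c: sum(s["n_anchors"] for s in segs if s["copy"] == c),
            )
            for c in extra:
                for seg in segs:
                    if seg["copy"] != c:
                        continue

                    def overlap(ci: int) -> int:
                        return sum(
                            max(0, min(hi, seg["car_hi"]) - max(lo, seg["car_lo"]) + 1)
                            for lo, hi in intervals.get(ci, [])
                        )

                    target = min(range(m), key=lambda ci: (overlap(ci), ci))
                    seg["copy"] = target
                    intervals.setdefault(target, []).append(
                        (seg["car_lo"], seg["car_hi"])
                    )


def infer_scenario(
    ak: AncestralKaryotype,
    modern: Genome,
    blocks: Sequence[SyntenyBlock],
    m: int,
    lineage: str | None = None,
    translocation_frac: float = 0.25,
    merge_gap: int = 20,
) -> Scenario:
    """Infer the smallest fusion/fission counts explaining a modern genome.

    Every modern chromosome is decomposed into CAR-copy segments from
    the given blocks.  After merging adjacent segments with the same
    (CAR, copy) origin:

    * fusions = sum over modern chromosomes of (distinct origins - 1);
    * fissions = sum over origins of (modern chromosomes touched - 1);
    * inversions = orientation flips between adjacent same-origin
      segments (reported, excluded from the chromosome-count identity);
    * translocations = origin incidences contributing less than
      ``translocation_frac`` of the origin's anchors to a chromosome
      dominated by other origins (a classification of junctions, also
      outside the identity).
    """
    lineage = lineage or modern.species
    segments = _block_car_segments(ak, modern, blocks)
    _assign_copies(segments, m)
    n_copies_seen = len({(s["car"], s["copy"]) for s in segments})

    # merge adjacent same-origin segments per modern chromosome, but only
    # when their CAR intervals continue one ancestral run (orientation-
    # aware): a fission piece re-fused in swapped order must stay two
    # segments - that junction costs a fission + fusion, not nothing.
    def _continuous(cur: dict, seg: dict, tol: int) -> bool:
        if cur["orientation"] == seg["orientation"] == "+":
            return -tol <= seg["car_lo"] - cur["car_hi"] <= tol
        if cur["orientation"] == seg["orientation"] == "-":
            return -tol <= cur["car_lo"] - seg["car_hi"] <= tol
        # orientation flip (local inversion): intervals must tile
        gap = max(cur["car_lo"], seg["car_lo"]) - min(cur["car_hi"], seg["car_hi"])
        return -tol <= gap <= tol

    inversions = 0
    merged: List[dict] = []
    by_chrom: Dict[str, List[dict]] = {}
    for seg in segments:
        by_chrom.setdefault(seg["modern_chrom"], []).append(seg)
    for chrom in sorted(by_chrom):
        run = sorted(by_chrom[chrom], key=lambda s: s["modern_lo"])
        cur = None
        for seg in run:
            if (
                cur is not None
                and (seg["car"], seg["copy"]) == (cur["car"], cur["copy"])
                and _continuous(cur, seg, merge_gap)
            ):
                if seg["orientation"] != cur["orientation"]:
                    inversions += 1
                    cur["orientation"] = seg["orientation"]
                cur["modern_hi"] = seg["modern_hi"]
                cur["car_lo"] = min(cur["car_lo"], seg["car_lo"])
                cur["car_hi"] = max(cur["car_hi"], seg["car_hi"])
                cur["n_anchors"] += seg["n_anchors"]
            else:
                if cur is not None:
                    merged.append(cur)
                cur = dict(seg)
        if cur is not None:
            merged.append(cur)

    # junction bookkeeping: fusions join segments of distinct runs on one
    # chromosome; fissions scatter one origin over several runs
    origins = {(s["car"], s["copy"]) for s in merged}
    per_origin: Dict[Tuple[str, int], int] = {}
    for s in merged:
        key = (s["car"], s["copy"])
        per_origin[key] = per_origin.get(key, 0) + 1
    chroms_assigned = {s["modern_chrom"] for s in merged}
    n_modern = modern.n_chromosomes
    n_assigned = len(chroms_assigned)
    if n_assigned < n_modern:
        logger.warning(
            "infer_scenario(%s): %d/%d modern chromosomes carry no CAR segment",
            lineage,
            n_modern - n_assigned,
            n_modern,
        )
    fusions = len(merged) - n_assigned
    fissions = len(merged) - len(origins)

    # translocation classification
    origin_anchors: Dict[Tuple[str, int], int] = {}
    for s in merged:
        key = (s["car"], s["copy"])
        origin_anchors[key] = origin_anchors.get(key, 0) + s["n_anchors"]
    chrom_anchors: Dict[str, int] = {}
    for s in merged:
        chrom_anchors[s["modern_chrom"]] = (
            chrom_anchors.get(s["modern_chrom"], 0) + s["n_anchors"]
        )
    translocations = 0
    for s in merged:
        key = (s["car"], s["copy"])
        own = s["n_anchors"]
        if (
            own < translocation_frac * origin_anchors[key]
            and own < 0.5 * chrom_anchors[s["modern_chrom"]]
        ):
            translocations += 1

    seg_frame = pd.DataFrame(
        merged,
        columns=[
            "modern_chrom",
            "modern_lo",
            "modern_hi",
            "car",
            "copy",
            "car_lo",
            "car_hi",
            "orientation",
            "n_anchors",
        ],
    )
    if n_copies_seen < m * ak.n_cars:
        logger.info(
            "infer_scenario(%s): %d of %d expected CAR copies observed",
            lineage,
            n_copies_seen,
            m * ak.n_cars,
        )
    return Scenario(
        lineage=lineage,
        m=m,
        fusions=fusions,
        fissions=fissions,
        translocations=translocations,
        inversions=inversions,
        n_cars=ak.n_cars,
        n_modern=n_modern,
        n_assigned=n_assigned,
        segments=seg_frame,
    )


# ---------------------------------------------------------------------------
# dotplots
# ---------------------------------------------------------------------------


def dotplot_table(blocks: Sequence[SyntenyBlock]) -> pd.DataFrame:
    """Anchor coordinate table with diagonal-run labels.

    One row per anchor: gene ids, chromosomes, gene-order coordinates,
    the run (block) label and its orientation.  CARs appear as
    uninterrupted diagonals (+) or antidiagonals (-).
    """
    rows = []
    for bi, block in enumerate(blocks):
        for a in block.anchors:
            rows.append(
                (
                    a.gene_a,
                    a.gene_b,
                    a.chrom_a,
                    a.chrom_b,
                    a.order_a,
                    a.order_b,
                    f"run{bi:04d}",
                    block.orientation,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_a",
            "gene_b",
            "chrom_a",
            "chrom_b",
            "order_a",
            "order_b",
            "run",
            "orientation",
        ],
    )
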