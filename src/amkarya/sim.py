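"""Multi-lineage genome-evolution simulator with recorded ground truth.

The simulator evolves an ancestral genome of ordered, stranded genes
through lineage-specific event lists - whole-genome duplication (with
biased post-WGD gene loss), triplication, fusion, fission, inversion,
translocation, tandem duplication and background gene loss - and
fabricates the downstream pipeline inputs: BLAST-tabular hit tables
whose identities scale with divergence, per-gene trait tables with
planted retention couplings, expression matrices with subgenome
dominance, TE interval tracks and orthogroup copy-number matrices.

Ground truth is a replayable event log: every record carries the fully
realized outcome (chromosomes affected, breakpoints, genes deleted,
subgenome labels), so replaying the log on the ancestor reproduces each
descendant exactly, and after any event sequence the chromosome count
obeys ``n = m * n_ancestral + fissions - fusions`` with m the product
of ploidy multipliers.

Randomness: one global integer seed; per-lineage streams are derived by
hashing (seed, lineage name), so adding a lineage leaves the others'
genomes unchanged.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from amkarya.genome import GeneModel, Genome
from amkarya.io import HIT_COLUMNS


class SimulationError(RuntimeError):
    pass


def derive_seed(seed: int, name: str) -> int:
    """Stable per-stream seed below 2**31 from (seed, name)."""
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


# ---------------------------------------------------------------------------
# events and configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WGD:
    """Whole-genome duplication with biased fractionation.

    Both copies of every chromosome are kept; genes are then deleted
    per copy with geometric (independent per-gene) loss.  The
    less-fractionated (LF) copy loses genes at ``loss_rate``; the
    more-fractionated (MF) copy at loss_rate * (1 + bias) / (1 - bias),
    clipped to [0, 0.95].
    """

    retention_bias: float = 0.0  # delta in [0, 1)
    loss_rate: float = 0.2

    multiplier = 2


@dataclass(frozen=True)
class Triplication:
    retention_bias: float = 0.0
    loss_rate: float = 0.2

    multiplier = 3


@dataclass(frozen=True)
class Fusion:
    """Join two chromosomes end-to-end; unset fields are drawn uniformly."""

    chrom_a: str | None = None
    chrom_b: str | None = None
    invert_b: bool | None = None


@dataclass(frozen=True)
class Fission:
    """Split one chromosome at an internal gene boundary."""

    chrom: str | None = None
    breakpoint: int | None = None  # genes [0, k) | [k, n)


@dataclass(frozen=True)
class Inversion:
    chrom: str | None = None
    start: int | None = None
    end: int | None = None  # half-open gene-index range


@dataclass(frozen=True)
class Translocation:
    """Move a gene run from one chromosome into another."""

    source: str | None = None
    dest: str | None = None
    start: int | None = None
    length: int | None = None


@dataclass(frozen=True)
class TandemDup:
    rate: float = 0.01


@dataclass(frozen=True)
class GeneLoss:
    rate: float = 0.02


Event = Union[WGD, Triplication, Fusion, Fission, Inversion, Translocation, TandemDup, GeneLoss]


@dataclass
class LineageSpec:
    """One descendant lineage: name, divergence scalar d and its events."""

    name: str
    divergence: float
    events: List[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.divergence < 1:
            raise ValueError(f"divergence must be in [0, 1), got {self.divergence}")


@dataclass
class TraitModel:
    """Marginal trait distributions and retention couplings.

    Couplings are latent-Gaussian correlation coefficients between the
    (standardized) retention count and each trait, realized through a
    Gaussian copula; mild marginals keep the achieved Pearson r close
    to the planted coefficient.
    """

    expression_mu: float = 1.0
    expression_sigma: float = 0.4
    methylation_a: float = 2.0
    methylation_b: float = 20.0
    te_a: float = 2.0
    te_b: float = 5.0
    pi_scale: float = 0.001
    couplings: Dict[str, float] = field(
        default_factory=lambda: {
            "expression": 0.0,
            "methylation": 0.0,
            "te_fraction": 0.0,
            "pi": 0.0,
        }
    )
    n_tissues: int = 5
    tissue_sigma: float = 0.6
    dominance_shift: float = 0.0  # log2 LF-over-MF expression shift


@dataclass
class SimConfig:
    seed: int = 0
    n_ancestral_chromosomes: int = 6
    genes_per_chromosome: int = 100
    ancestor_name: str = "ANC"
    lineages: List[LineageSpec] = field(default_factory=list)
    trait_model: TraitModel = field(default_factory=TraitModel)
    gene_length_range: Tuple[int, int] = (900, 3000)
    intergenic_spacer: int = 2000
    spurious_hit_rate: float = 0.0
    paralog_extra_divergence: float = 0.15
    tandem_divergence: float = 0.02
    identity_noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.n_ancestral_chromosomes < 1 or self.genes_per_chromosome < 1:
            raise ValueError("need >= 1 chromosome and >= 1 gene per chromosome")
        names = [l.name for l in self.lineages]
        if len(names) != len(set(names)):
            raise ValueError("lineage names must be unique")


# ---------------------------------------------------------------------------
# internal genome state
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimGene:
    protogene: int
    strand: int  # +1 / -1
    subgenome: str  # "anc", "LF", "MF", "MF2"
    length: int
    tandem: bool = False


State = Dict[str, List[SimGene]]


@dataclass
class GenomeBundle:
    """A materialized genome plus its ground-truth gene maps."""

    genome: Genome
    protogene: Dict[str, int]
    subgenome: Dict[str, str]
    tandem: Dict[str, bool]
    divergence: float = 0.0

    @property
    def species(self) -> str:
        return self.genome.species


def _materialize(state: State, species: str, spacer: int, divergence: float) -> GenomeBundle:
    records: List[GeneModel] = []
    protogene: Dict[str, int] = {}
    subgenome: Dict[str, str] = {}
    tandem: Dict[str, bool] = {}
    counter = 0
    for chrom, genes in state.items():
        pos = 0
        for g in genes:
            gid = f"{species}_g{counter:05d}"
            counter += 1
            records.append(
                GeneModel(
                    id=gid,
                    species=species,
                    chrom=chrom,
                    start=pos,
                    end=pos + g.length,
                    strand="+" if g.strand > 0 else "-",
                    order=0,
                )
            )
            protogene[gid] = g.protogene
            subgenome[gid] = g.subgenome
            tandem[gid] = g.tandem
            pos += g.length + spacer
    genome = Genome(species=species)
    for chrom in state:
        genome.chromosomes[chrom] = []
    genome_tmp = Genome.from_records(species, records)
    # keep the simulator's chromosome insertion order
    for chrom in state:
        genome.chromosomes[chrom] = genome_tmp.chromosomes.get(chrom, [])
    genome.genome_size = sum(
        (genes[-1].end if genes else 0) for genes in genome.chromosomes.values()
    )
    return GenomeBundle(
        genome=genome,
        protogene=protogene,
        subgenome=subgenome,
        tandem=tandem,
        divergence=divergence,
    )


def simulate_ancestor(config: SimConfig) -> GenomeBundle:
    """Create the ancestral genome: consecutive protogenes, random strands."""
    rng = np.random.default_rng(derive_seed(config.seed, config.ancestor_name))
    lo, hi = config.gene_length_range
    state: State = {}
    pg = 0
    for c in range(config.n_ancestral_chromosomes):
        chrom = f"chr{c + 1:02d}"
        genes = []
        for _ in range(config.genes_per_chromosome):
            length = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
            strand = 1 if rng.random() < 0.5 else -1
            genes.append(SimGene(pg, strand, "anc", length))
            pg += 1
        state[chrom] = genes
    return _materialize(state, config.ancestor_name, config.intergenic_spacer, 0.0)


def _state_from_bundle(bundle: GenomeBundle) -> State:
    state: State = {}
    for chrom, genes in bundle.genome.chromosomes.items():
        state[chrom] = [
            SimGene(
                protogene=bundle.protogene[g.id],
                strand=1 if g.strand == "+" else -1,
                subgenome=bundle.subgenome[g.id],
                length=g.length,
                tandem=bundle.tandem[g.id],
            )
            for g in genes
        ]
    return state


# ---------------------------------------------------------------------------
# event realization and application
# ---------------------------------------------------------------------------


def _draw_record(
    state: State, event: Event, index: int, lineage: str, rng: np.random.Generator
) -> dict:
    """Realize an abstract event into a fully determined log record."""
    chroms = sorted(state)

    def pick(candidates: List[str]) -> str:
        return candidates[int(rng.integers(len(candidates)))]

    rec: dict = {"lineage": lineage, "index": index}
    if isinstance(event, (WGD, Triplication)):
        mult = event.multiplier
        p_lf = event.loss_rate
        delta = event.retention_bias
        if not 0 <= delta < 1:
            raise SimulationError(f"event {index}: retention bias must be in [0,1)")
        p_mf = min(0.95, p_lf * (1 + delta) / (1 - delta))
        copies = {}
        deleted = {}
        suffixes = "abc"[:mult]
        labels = ["LF"] + ["MF" if i == 1 else "MF2" for i in range(1, mult)]
        for chrom in chroms:
            lf_first = bool(rng.random() < 0.5)
            order = list(range(mult)) if lf_first else [1, 0] + list(range(2, mult))
            copy_ids = [f"{chrom}{s}" for s in suffixes]
            copies[chrom] = [
                {"id": copy_ids[i], "label": labels[order.index(i)]} for i in range(mult)
            ]
            for i in range(mult):
                label = copies[chrom][i]["label"]
                p = p_lf if label == "LF" else p_mf
                n = len(state[chrom])
                lost = sorted(np.nonzero(rng.random(n) < p)[0].tolist())
                if len(lost) == n:  # never delete a whole chromosome copy
                    lost = lost[:-1]
                deleted[copy_ids[i]] = lost
        rec.update(
            type="wgd" if isinstance(event, WGD) else "triplication",
            multiplier=mult,
            copies=copies,
            deleted_positions=deleted,
        )
    elif isinstance(event, Fusion):
        if len(chroms) < 2:
            raise SimulationError(f"event {index} (fusion): need >= 2 chromosomes")
        a = event.chrom_a or pick(chroms)
        b = event.chrom_b or pick([c for c in chroms if c != a])
        if a == b or a not in state or b not in state:
            raise SimulationError(f"event {index} (fusion): bad chromosomes {a}, {b}")
        invert_b = (
            bool(rng.random() < 0.5) if event.invert_b is None else event.invert_b
        )
        rec.update(type="fusion", chrom_a=a, chrom_b=b, invert_b=invert_b,
                   new_chrom=f"{a}|{b}")
    elif isinstance(event, Fission):
        candidates = [c for c in chroms if len(state[c]) >= 2]
        if not candidates:
            raise SimulationError(
                f"event {index} (fission): no chromosome with >= 2 genes"
            )
        chrom = event.chrom or pick(candidates)
        if chrom not in state or len(state[chrom]) < 2:
            raise SimulationError(f"event {index} (fission): bad chromosome {chrom}")
        k = (
            int(rng.integers(1, len(state[chrom])))
            if event.breakpoint is None
            else event.breakpoint
        )
        if not 1 <= k <= len(state[chrom]) - 1:
            raise SimulationError(f"event {index} (fission): bad breakpoint {k}")
        rec.update(type="fission", chrom=chrom, breakpoint=k,
                   new_chroms=[f"{chrom}.1", f"{chrom}.2"])
    elif isinstance(event, Inversion):
        candidates = [c for c in chroms if len(state[c]) >= 2]
        if not candidates:
            raise SimulationError(
                f"event {index} (inversion): no chromosome with >= 2 genes"
            )
        chrom = event.chrom or pick(candidates)
        n = len(state[chrom])
        if event.start is None:
            start = int(rng.integers(0, n - 1))
            end = int(rng.integers(start + 2, n + 1))
        else:
            start, end = event.start, event.end if event.end is not None else n
        if not (0 <= start < end <= n):
            raise SimulationError(f"event {index} (inversion): bad range {start}:{end}")
        rec.update(type="inversion", chrom=chrom, start=start, end=end)
    elif isinstance(event, Translocation):
        if len(chroms) < 2:
            raise SimulationError(f"event {index} (translocation): need >= 2 chromosomes")
        source = event.source or pick([c for c in chroms if len(state[c]) >= 2])
        dest = event.dest or pick([c for c in chroms if c != source])
        if source == dest:
            raise SimulationError(f"event {index} (translocation): source == dest")
        n = len(state[source])
        length = event.length or int(rng.integers(1, max(2, n // 4 + 1)))
        length = min(length, n - 1)  # leave the source non-empty
        start = (
            int(rng.integers(0, n - length + 1)) if event.start is None else event.start
        )
        if not (0 <= start and start + length <= n and length >= 1):
            raise SimulationError(f"event {index} (translocation): bad segment")
        insert_at = int(rng.integers(0, len(state[dest]) + 1))
        rec.update(type="translocation", source=source, dest=dest,
                   start=start, length=length, insert_at=insert_at)
    elif isinstance(event, TandemDup):
        positions = []
        for chrom in chroms:
            for i in range(len(state[chrom])):
                if rng.random() < event.rate:
                    positions.append([chrom, i])
        rec.update(type="tandem_dup", positions=positions)
    elif isinstance(event, GeneLoss):
        positions = []
        for chrom in chroms:
            n = len(state[chrom])
            lost = np.nonzero(rng.random(n) < event.rate)[0].tolist()
            if len(lost) == n:
                lost = lost[:-1]
            positions.extend([chrom, int(i)] for i in lost)
        rec.update(type="gene_loss", positions=positions)
    else:  # pragma: no cover - exhaustive
        raise SimulationError(f"event {index}: unknown event {event!r}")
    return rec


def apply_record(state: State, rec: dict) -> State:
    """Apply one fully realized log record; deterministic, no RNG."""
    kind = rec["type"]
    if kind in ("wgd", "triplication"):
        new_state: State = {}
        for chrom, genes in state.items():
            for copy in rec["copies"][chrom]:
                label = copy["label"]
                lost = set(rec["deleted_positions"][copy["id"]])
                new_state[copy["id"]] = [
                    replace(g, subgenome=label)
                    for i, g in enumerate(genes)
                    if i not in lost
                ]
        return new_state
    if kind == "fusion":
        a, b = rec["chrom_a"], rec["chrom_b"]
        gb = state[b]
        if rec["invert_b"]:
            gb = [replace(g, strand=-g.strand) for g in reversed(gb)]
        new_state = {}
        for chrom, genes in state.items():
            if chrom == a:
                new_state[rec["new_chrom"]] = state[a] + gb
            elif chrom != b:
                new_state[chrom] = genes
        return new_state
    if kind == "fission":
        chrom, k = rec["chrom"], rec["breakpoint"]
        n1, n2 = rec["new_chroms"]
        new_state = {}
        for c, genes in state.items():
            if c == chrom:
                new_state[n1] = genes[:k]
                new_state[n2] = genes[k:]
            else:
                new_state[c] = genes
        return new_state
    if kind == "inversion":
        chrom, s, e = rec["chrom"], rec["start"], rec["end"]
        genes = state[chrom]
        seg = [replace(g, strand=-g.strand) for g in reversed(genes[s:e])]
        return {**state, chrom: genes[:s] + seg + genes[e:]}
    if kind == "translocation":
        src, dst = rec["source"], rec["dest"]
        s, ln, at = rec["start"], rec["length"], rec["insert_at"]
        seg = state[src][s : s + ln]
        new_state = {}
        for c, genes in state.items():
            if c == src:
                new_state[c] = genes[:s] + genes[s + ln :]
            elif c == dst:
                new_state[c] = genes[:at] + seg + genes[at:]
            else:
                new_state[c] = genes
        return new_state
    if kind == "tandem_dup":
        new_state = {c: list(g) for c, g in state.items()}
        by_chrom: Dict[str, List[int]] = {}
        for chrom, i in rec["positions"]:
            by_chrom.setdefault(chrom, []).append(i)
        for chrom, idxs in by_chrom.items():
            genes = new_state[chrom]
            for i in sorted(idxs, reverse=True):
                genes.insert(i + 1, replace(genes[i], tandem=True))
        return new_state
    if kind == "gene_loss":
        new_state = {c: list(g) for c, g in state.items()}
        by_chrom = {}
        for chrom, i in rec["positions"]:
            by_chrom.setdefault(chrom, []).append(i)
        for chrom, idxs in by_chrom.items():
            genes = new_state[chrom]
            for i in sorted(set(idxs), reverse=True):
                del genes[i]
        return new_state
    raise SimulationError(f"unknown record type {kind!r}")


def evolve_lineage(
    ancestor: GenomeBundle, spec: LineageSpec, seed: int, spacer: int = 2000
) -> Tuple[GenomeBundle, List[dict]]:
    """Evolve the ancestor along one lineage; returns genome + event log."""
    rng = np.random.default_rng(derive_seed(seed, spec.name))
    state = _state_from_bundle(ancestor)
    log: List[dict] = []
    for i, event in enumerate(spec.events):
        rec = _draw_record(state, event, i, spec.name, rng)
        state = apply_record(state, rec)
        log.append(rec)
    bundle = _materialize(state, spec.name, spacer, spec.divergence)
    return bundle, log


def replay(ancestor: GenomeBundle, log: Sequence[dict], species: str,
           spacer: int = 2000, divergence: float = 0.0) -> GenomeBundle:
    """Reproduce a descendant exactly by re-applying its event log."""
    state = _state_from_bundle(ancestor)
    for rec in log:
        state = apply_record(state, rec)
    return _materialize(state, species, spacer, divergence)


def expected_chromosomes(log: Sequence[dict], n_ancestral: int) -> int:
    """Chromosome count implied by the event log, applied in order.

    When every fusion/fission postdates the duplications this equals
    m * n_ancestral + fissions - fusions (the identity scenario
    inference checks against a karyotype); a fusion *before* a WGD is
    doubled by it and shows up as two coordinated post-WGD fusions.
    """
    n = n_ancestral
    for rec in log:
        if rec["type"] in ("wgd", "triplication"):
            n *= rec["multiplier"]
        elif rec["type"] == "fission":
            n += 1
        elif rec["type"] == "fusion":
            n -= 1
    return n


def count_events(log: Sequence[dict]) -> Dict[str, int]:
    out: Dict[str, int] = {}
    for rec in log:
        out[rec["type"]] = out.get(rec["type"], 0) + 1
    return out


# ---------------------------------------------------------------------------
# hit-table fabrication
# ---------------------------------------------------------------------------


def _pair_divergence(
    a: GenomeBundle, b: GenomeBundle, ga: str, gb: str, config: SimConfig
) -> float:
    if a.species != b.species:
        return a.divergence + b.divergence
    if a.tandem.get(ga) or a.tandem.get(gb):
        return config.tandem_divergence
    return 2 * a.divergence + config.paralog_extra_divergence


def emit_hit_table(
    bundles: Mapping[str, GenomeBundle],
    config: SimConfig,
    pairs: Sequence[Tuple[str, str]] | None = None,
    include_within: bool = True,
) -> pd.DataFrame:
    """Fabricate a BLAST-tabular hit table for the given genomes.

    Every pair of genes sharing a protogene yields full-length hits in
    both query directions with identity drawn around 100 * (1 - d),
    where d sums the two lineages' divergence scalars (plus a paralog
    penalty within a species).  Spurious short low-identity hits are
    added at ``config.spurious_hit_rate`` per true row.
    """
    rng = np.random.default_rng(derive_seed(config.seed, "hits"))
    names = sorted(bundles)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i:]
                 if include_within or a != b]
    rows: List[tuple] = []

    def add_row(qb: GenomeBundle, q: GeneModel, sb: GenomeBundle, s: GeneModel,
                identity: float, al: int | None = None, qstart: int = 1) -> None:
        qlen = q.aa_length
        al = qlen if al is None else min(al, qlen)
        ident_n = int(round(identity / 100.0 * al))
        pident = 100.0 * ident_n / al if al else 0.0
        bitscore = round(2.0 * al * identity / 100.0, 1)
        evalue = 10.0 ** -min(180.0, bitscore / 3.0)
        rows.append(
            (q.id, s.id, round(pident, 2), al, al - ident_n, 0,
             qstart, qstart + al - 1, 1, al, evalue, bitscore)
        )

    for a, b in pairs:
        ba, bb = bundles[a], bundles[b]
        by_pg_a: Dict[int, List[GeneModel]] = {}
        for g in ba.genome.genes():
            by_pg_a.setdefault(ba.protogene[g.id], []).append(g)
        by_pg_b: Dict[int, List[GeneModel]] = {}
        for g in bb.genome.genes():
            by_pg_b.setdefault(bb.protogene[g.id], []).append(g)
        n_true = 0
        for pg in sorted(set(by_pg_a) & set(by_pg_b)):
            for qa in by_pg_a[pg]:
                for sbg in by_pg_b[pg]:
                    if a == b and qa.id >= sbg.id:
                        continue  # emit each unordered same-species pair once per direction below
                    d = _pair_divergence(ba, bb, qa.id, sbg.id, config)
                    base = 100.0 * max(0.05, 1.0 - d)
                    noise = 1.0 + config.identity_noise_sd * rng.standard_normal()
                    identity = float(np.clip(base * noise, 5.0, 100.0))
                    add_row(ba, qa, bb, sbg, identity)
                    add_row(bb, sbg, ba, qa, identity)
                    n_true += 2
        n_spurious = int(round(config.spurious_hit_rate * n_true))
        if n_spurious:
            genes_a = list(ba.genome.genes())
            genes_b = list(bb.genome.genes())
            for _ in range(n_spurious):
                q = genes_a[int(rng.integers(len(genes_a)))]
                s = genes_b[int(rng.integers(len(genes_b)))]
                if q.id == s.id:
                    continue
                al = int(rng.integers(10, max(11, q.aa_length // 3)))
                identity = float(rng.uniform(25.0, 45.0))
                qstart = int(rng.integers(1, max(2, q.aa_length - al + 2)))
                add_row(ba, q, bb, s, identity, al=al, qstart=qstart)
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def registry_anchor_pairs(
    query: GenomeBundle, subject: GenomeBundle, one_to_one: bool = False
):
    """Ground-truth homolog pairs straight from the protogene registry.

    Every (query gene, subject gene) pair sharing a protogene becomes an
    anchor pair; with ``one_to_one`` only the lexicographically first
    copy on each side is kept per protogene.  Bypasses hit fabrication
    and CIP/CALP scoring for tests that target the downstream stages.
    """
    from amkarya.homology import OrthologPair

    by_pg_q: Dict[int, List[str]] = {}
    for g in query.genome.genes():
        by_pg_q.setdefault(query.protogene[g.id], []).append(g.id)
    by_pg_s: Dict[int, List[str]] = {}
    for g in subject.genome.genes():
        by_pg_s.setdefault(subject.protogene[g.id], []).append(g.id)
    pairs = []
    for pg in sorted(set(by_pg_q) & set(by_pg_s)):
        qs = sorted(by_pg_q[pg])
        ss = sorted(by_pg_s[pg])
        if one_to_one:
            qs, ss = qs[:1], ss[:1]
        for q in qs:
            for s in ss:
                pairs.append(
                    OrthologPair(
                        gene_a=q,
                        gene_b=s,
                        species_a=query.species,
                        species_b=subject.species,
                        cip=100.0,
                        calp=1.0,
                        bitscore_sum=0.0,
                    )
                )
    return pairs


# ---------------------------------------------------------------------------
# traits, expression, TE tracks, orthogroup matrices
# ---------------------------------------------------------------------------


def emit_4dtv_table(
    query: GenomeBundle,
    subject: GenomeBundle,
    config: SimConfig,
    n_sites_range: Tuple[int, int] = (200, 600),
) -> pd.DataFrame:
    """Fabricated fourfold-degenerate-site counts for homolog pairs.

    For each gene pair sharing a protogene, the number of observed
    transversions is binomial with success probability
    p = 0.5 * (1 - exp(-2d)) - the saturation curve whose multiple-hit
    correction recovers d - so corrected 4dTv estimates scatter around
    the pair's true divergence.
    """
    rng = np.random.default_rng(
        derive_seed(config.seed, f"4dtv:{query.species}:{subject.species}")
    )
    by_pg_q: Dict[int, List[str]] = {}
    for g in query.genome.genes():
        by_pg_q.setdefault(query.protogene[g.id], []).append(g.id)
    by_pg_s: Dict[int, List[str]] = {}
    for g in subject.genome.genes():
        by_pg_s.setdefault(subject.protogene[g.id], []).append(g.id)
    rows = []
    for pg in sorted(set(by_pg_q) & set(by_pg_s)):
        for q in sorted(by_pg_q[pg]):
            for s in sorted(by_pg_s[pg]):
                if query.species == subject.species and q >= s:
                    continue
                d = _pair_divergence(query, subject, q, s, config)
                p = 0.5 * (1.0 - np.exp(-2.0 * d))
                n_sites = int(rng.integers(*n_sites_range))
                tv = int(rng.binomial(n_sites, p))
                rows.append((q, s, n_sites, tv))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "n_sites", "n_transversions"])


def emit_traits(
    bundle: GenomeBundle,
    trait_model: TraitModel,
    retention: pd.Series,
    seed: int,
) -> pd.DataFrame:
    """Per-gene trait table with planted retention couplings.

    ``retention`` maps gene ids to retention counts (species with a
    syntenic anchor); traits are generated through a Gaussian copula so
    that the Pearson correlation between retention and each trait
    approximates the planted coupling coefficient.
    """
    rng = np.random.default_rng(derive_seed(seed, f"traits:{bundle.species}"))
    genes = [g.id for g in bundle.genome.genes()]
    ret = retention.reindex(genes).fillna(0).to_numpy(dtype=float)
    sd = ret.std()
    z_ret = (ret - ret.mean()) / sd if sd > 0 else np.zeros_like(ret)

    def latent(rho: float) -> np.ndarray:
        eps = rng.standard_normal(len(genes))
        return rho * z_ret + np.sqrt(max(0.0, 1.0 - rho**2)) * eps

    c = trait_model.couplings
    u = {
        name: stats.norm.cdf(latent(c.get(name, 0.0)))
        for name in ("expression", "methylation", "te_fraction", "pi")
    }
    df = pd.DataFrame(
        {
            "expression": np.exp(
                trait_model.expression_mu
                + trait_model.expression_sigma * stats.norm.ppf(u["expression"])
            ),
            "methylation": stats.beta.ppf(
                u["methylation"], trait_model.methylation_a, trait_model.methylation_b
            ),
            "te_fraction": stats.beta.ppf(u["te_fraction"], trait_model.te_a, trait_model.te_b),
            "pi": stats.expon.ppf(u["pi"], scale=trait_model.pi_scale),
            "retention": ret.astype(int),
        },
        index=pd.Index(genes, name="gene"),
    )
    return df


def emit_expression(
    bundle: GenomeBundle,
    trait_model: TraitModel,
    seed: int,
    base_expression: pd.Series | None = None,
) -> pd.DataFrame:
    """Genes x tissues FPKM matrix with optional subgenome dominance.

    Per-gene mean expression is log-normal (or taken from a trait
    table); tissue values scatter log-normally around it, and genes on
    MF subgenome copies are shifted down by ``dominance_shift`` doublings.
    """
    rng = np.random.default_rng(derive_seed(seed, f"expr:{bundle.species}"))
    genes = [g.id for g in bundle.genome.genes()]
    if base_expression is None:
        base = np.exp(
            trait_model.expression_mu
            + trait_model.expression_sigma * rng.standard_normal(len(genes))
        )
    else:
        base = base_expression.reindex(genes).fillna(1.0).to_numpy(dtype=float)
    tissues = [f"tissue{t + 1}" for t in range(trait_model.n_tissues)]
    vals = base[:, None] * np.exp(
        trait_model.tissue_sigma * rng.standard_normal((len(genes), len(tissues)))
    )
    if trait_model.dominance_shift:
        mf = np.array(
            [bundle.subgenome.get(g, "anc").startswith("MF") for g in genes]
        )
        vals[mf] *= 2.0 ** -trait_model.dominance_shift
    return pd.DataFrame(vals, index=pd.Index(genes, name="gene"), columns=tissues)


def emit_te_track(
    bundle: GenomeBundle,
    seed: int,
    density: float = 0.15,
    mf_flank_boost: float = 0.0,
    te_length: int = 400,
) -> pd.DataFrame:
    """Random TE intervals per chromosome (BED-style frame).

    Baseline intervals cover about ``density`` of each chromosome;
    ``mf_flank_boost`` adds extra TE insertions in the 5-kb flanks of
    MF-subgenome genes to plant the LF/MF TE-density contrast.
    """
    rng = np.random.default_rng(derive_seed(seed, f"te:{bundle.species}"))
    rows: List[tuple] = []
    for chrom, genes in bundle.genome.chromosomes.items():
        if not genes:
            continue
        span = genes[-1].end
        n = int(density * span / te_length)
        for start in sorted(rng.integers(0, max(1, span - te_length), size=n).tolist()):
            rows.append((chrom, int(start), int(start) + te_length))
        if mf_flank_boost > 0:
            for g in genes:
                if not bundle.subgenome.get(g.id, "").startswith("MF"):
                    continue
                k = rng.poisson(mf_flank_boost)
                for _ in range(k):
                    off = int(rng.integers(50, 5000 - te_length))
                    side = g.start - off - te_length if rng.random() < 0.5 else g.end + off
                    if side >= 0:
                        rows.append((chrom, side, side + te_length))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def emit_og_matrix(
    species: Sequence[str],
    clade: Sequence[str],
    n_ogs: int,
    n_loss: int,
    n_expansion: int,
    seed: int,
    base_lambda: float = 1.0,
    expansion_fold: float = 2.5,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Orthogroup copy-number matrix with planted clade shifts.

    ``n_loss`` OGs are absent from every ``clade`` species but present
    outside it; ``n_expansion`` OGs have ``expansion_fold`` higher mean
    copy number inside the clade.  Returns the matrix and a per-OG
    ground-truth label series ("background", "loss", "expansion").
    """
    if n_loss + n_expansion > n_ogs:
        raise ValueError("planted OGs exceed total OGs")
    rng = np.random.default_rng(derive_seed(seed, "og_matrix"))
    species = list(species)
    clade_set = set(clade)
    if not clade_set <= set(species):
        raise ValueError("clade must be a subset of species")
    counts = rng.poisson(base_lambda, size=(n_ogs, len(species)))
    counts = np.maximum(counts, 0)
    labels = np.array(["background"] * n_ogs, dtype=object)
    in_clade = np.array([sp in clade_set for sp in species])
    for i in range(n_loss):
        counts[i, in_clade] = 0
        counts[i, ~in_clade] = np.maximum(1, rng.poisson(base_lambda, (~in_clade).sum()))
        labels[i] = "loss"
    for i in range(n_loss, n_loss + n_expansion):
        outside = np.maximum(1, rng.poisson(base_lambda, (~in_clade).sum()))
        counts[i, ~in_clade] = outside
        # plant the fold against the realized outside mean
        counts[i, in_clade] = rng.poisson(
            expansion_fold * outside.mean(), in_clade.sum()
        )
        labels[i] = "expansion"
    index = pd.Index([f"OG{i:05d}" for i in range(n_ogs)], name="og")
    matrix = pd.DataFrame(counts, index=index, columns=species)
    truth = pd.Series(labels, index=index, name="truth")
    return matrix, truth


def lineage_tree_newick(config: SimConfig) -> str:
    """Star newick of the simulated lineages with divergence branch lengths."""
    parts = ",".join(f"{l.name}:{l.divergence}" for l in config.lineages)
    return f"({parts}){config.ancestor_name};"


# ---------------------------------------------------------------------------
# one-call clade simulation
# ---------------------------------------------------------------------------


@dataclass
class SimResult:
    config: SimConfig
    ancestor: GenomeBundle
    lineages: Dict[str, GenomeBundle]
    logs: Dict[str, List[dict]]

    def all_bundles(self) -> Dict[str, GenomeBundle]:
        return {self.ancestor.species: self.ancestor, **self.lineages}


def simulate_clade(config: SimConfig) -> SimResult:
    """Simulate the ancestor and every lineage in the configuration."""
    ancestor = simulate_ancestor(config)
    lineages: Dict[str, GenomeBundle] = {}
    logs: Dict[str, List[dict]] = {}
    for spec in config.lineages:
        bundle, log = evolve_lineage(
            ancestor, spec, config.seed, spacer=config.intergenic_spacer
        )
        lineages[spec.name] = bundle
        logs[spec.name] = log
    return SimResult(config=config, ancestor=ancestor, lineages=lineages, logs=logs)
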