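"""Synteny blocks and gene-order conservation statistics.

Step 3 of the reconstruction method chains one-to-one orthologs
("anchors") into synteny blocks per chromosome pair; a block's size is
its anchor count and blocks with fewer than ``min_anchors`` (default 6,
reading "more than five orthologous genes" strictly) are discarded.

On top of blocks the module implements:

* the synteny-decay curve F(s) = fraction of anchors lying in blocks of
  size >= s, with an exponential-survival decay rate fitted on
  log F(s) = -lambda * s + c (the decay-rate notion borrowed from
  linkage-disequilibrium decay);
* per-gene retention profiles (number of surveyed species with a
  syntenic anchor for each outgroup gene) and per-species totals;
* least-squares trait regressions, Pearson retention correlates,
  quartile grouping with Kruskal-Wallis and pairwise Mann-Whitney
  tests (Benjamini-Hochberg adjusted);
* per-tip substitution rates as branch-length sums from a clade MRCA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from amkarya.genome import Genome
from amkarya.homology import OrthologPair


class DegenerateInputError(ValueError):
    """Raised when a statistic is undefined for the given input."""


@dataclass(frozen=True)
class Anchor:
    """An ortholog pair placed on both genomes' gene-order axes."""

    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    order_a: int
    order_b: int


@dataclass
class SyntenyBlock:
    """A chained run of anchors on one chromosome pair."""

    species_a: str
    species_b: str
    chrom_a: str
    chrom_b: str
    anchors: List[Anchor]
    orientation: str  # "+" or "-"

    @property
    def size(self) -> int:
        return len(self.anchors)

    @property
    def span_a(self) -> Tuple[int, int]:
        """Inclusive gene-order interval covered on genome A."""
        orders = [a.order_a for a in self.anchors]
        return min(orders), max(orders)

    @property
    def span_b(self) -> Tuple[int, int]:
        orders = [a.order_b for a in self.anchors]
        return min(orders), max(orders)


# ---------------------------------------------------------------------------
# chaining
# ---------------------------------------------------------------------------


def _place_anchors(
    pairs: Sequence[OrthologPair], genome_a: Genome, genome_b: Genome
) -> List[Anchor]:
    idx_a = genome_a.gene_index()
    idx_b = genome_b.gene_index()
    anchors = []
    for p in pairs:
        a, b = p.gene_a, p.gene_b
        if a in idx_b and b in idx_a:  # pair given in the opposite orientation
            a, b = b, a
        ga, gb = idx_a.get(a), idx_b.get(b)
        if ga is None or gb is None:
            raise ValueError(f"ortholog pair ({p.gene_a}, {p.gene_b}) not in genomes")
        anchors.append(
            Anchor(
                gene_a=a,
                gene_b=b,
                chrom_a=ga.chrom,
                chrom_b=gb.chrom,
                order_a=ga.order,
                order_b=gb.order,
            )
        )
    return anchors


def chain_blocks(
    pairs: Sequence[OrthologPair],
    genome_a: Genome,
    genome_b: Genome,
    min_anchors: int = 6,
    max_gap: int = 20,
) -> List[SyntenyBlock]:
    """Chain anchors into synteny blocks.

    Within each chromosome pair anchors are taken in genome-A order and
    chained greedily while the order gap on both genomes stays at most
    ``max_gap`` and the genome-B order stays strictly monotone in one
    direction (block orientation).  Chains shorter than ``min_anchors``
    are dropped; every anchor belongs to at most one block.  The result
    is invariant to the input row order.
    """
    anchors = _place_anchors(pairs, genome_a, genome_b)
    by_pair: Dict[Tuple[str, str], List[Anchor]] = {}
    for a in anchors:
        by_pair.setdefault((a.chrom_a, a.chrom_b), []).append(a)

    blocks: List[SyntenyBlock] = []
    for (ca, cb) in sorted(by_pair):
        run = sorted(by_pair[(ca, cb)], key=lambda x: (x.order_a, x.order_b))
        chain: List[Anchor] = []
        direction = 0  # 0 unknown, +1 increasing in B, -1 decreasing

        def close() -> None:
            nonlocal chain, direction
            if len(chain) >= min_anchors:
                blocks.append(
                    SyntenyBlock(
                        species_a=genome_a.species,
                        species_b=genome_b.species,
                        chrom_a=ca,
                        chrom_b=cb,
                        anchors=list(chain),
                        orientation="+" if direction >= 0 else "-",
                    )
                )
            chain = []
            direction = 0

        for anchor in run:
            if not chain:
                chain.append(anchor)
                continue
            prev = chain[-1]
            gap_a = anchor.order_a - prev.order_a
            delta_b = anchor.order_b - prev.order_b
            step = 0 if delta_b == 0 else (1 if delta_b > 0 else -1)
            ok = (
                0 < gap_a <= max_gap
                and step != 0
                and abs(delta_b) <= max_gap
                and (direction == 0 or step == direction)
            )
            if ok:
                if direction == 0:
                    direction = step
                chain.append(anchor)
            else:
                close()
                chain.append(anchor)
        close()
    return blocks


# ---------------------------------------------------------------------------
# synteny decay
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DecayFit:
    """Exponential-survival fit of the block-size distribution."""

    rate: float  # lambda >= 0
    intercept: float
    fit_range: Tuple[int, int]
    degenerate: bool


def decay_curve(blocks: Sequence[SyntenyBlock], s_min: int | None = None) -> pd.DataFrame:
    """Survival function F(s) = fraction of anchors in blocks of size >= s.

    Tabulated at integer s from ``s_min`` (default: the smallest block
    size) to the largest block size.  F is non-increasing and equals 1
    at the smallest observed size.
    """
    if not blocks:
        raise DegenerateInputError("decay_curve requires at least one block")
    sizes = np.array([b.size for b in blocks])
    total = sizes.sum()
    lo = int(sizes.min()) if s_min is None else int(s_min)
    hi = int(sizes.max())
    rows = [(s, sizes[sizes >= s].sum() / total) for s in range(lo, hi + 1)]
    return pd.DataFrame(rows, columns=["size", "fraction"])


def decay_rate(blocks: Sequence[SyntenyBlock], min_anchors: int = 6) -> DecayFit:
    """Fit log F(s) = -lambda * s + c over s in [min_anchors, q95 of sizes].

    If F is constant over the fit range (e.g. a single block, or all
    blocks the same size) the rate is 0 and the fit is flagged
    degenerate.
    """
    sizes = np.array([b.size for b in blocks])
    hi = int(min(np.percentile(sizes, 95), sizes.max()))
    lo = min(min_anchors, int(sizes.min()))
    curve = decay_curve(blocks, s_min=lo)
    seg = curve[(curve["size"] >= lo) & (curve["size"] <= hi)]
    s = seg["size"].to_numpy(dtype=float)
    logf = np.log(seg["fraction"].to_numpy(dtype=float))
    if len(s) < 2 or np.allclose(logf, logf[0]):
        return DecayFit(rate=0.0, intercept=float(logf[0]) if len(s) else 0.0,
                        fit_range=(lo, hi), degenerate=True)
    slope, intercept = np.polyfit(s, logf, 1)
    return DecayFit(
        rate=max(0.0, -float(slope)),
        intercept=float(intercept),
        fit_range=(lo, hi),
        degenerate=False,
    )


# ---------------------------------------------------------------------------
# retention profiles
# ---------------------------------------------------------------------------


@dataclass
class RetentionProfile:
    """Synteny retention of outgroup genes across a species panel.

    ``indicator`` is a genes x species boolean frame: True when the
    outgroup gene has a syntenic anchor in that species.
    """

    outgroup: str
    indicator: pd.DataFrame = field(repr=False)

    @property
    def per_gene(self) -> pd.Series:
        """Number of surveyed species with a syntenic anchor, per gene."""
        return self.indicator.sum(axis=1)

    @property
    def per_species(self) -> pd.Series:
        """Total syntenic outgroup genes per species."""
        return self.indicator.sum(axis=0)


def retention_profile(
    outgroup: Genome,
    blocks_by_species: Mapping[str, Sequence[SyntenyBlock]],
) -> RetentionProfile:
    """Count, for every outgroup gene, the species with a syntenic anchor.

    ``blocks_by_species`` maps each surveyed species to the synteny
    blocks between the outgroup and that species.  Genes in no block are
    reported with count 0.
    """
    gene_ids = [g.id for g in outgroup.genes()]
    indicator = pd.DataFrame(
        False, index=gene_ids, columns=list(blocks_by_species.keys())
    )
    own = set(gene_ids)
    for sp, blocks in blocks_by_species.items():
        anchored = set()
        for b in blocks:
            for a in b.anchors:
                anchored.add(a.gene_a if a.gene_a in own else a.gene_b)
        indicator.loc[sorted(anchored & own), sp] = True
    return RetentionProfile(outgroup=outgroup.species, indicator=indicator)


# ---------------------------------------------------------------------------
# regressions and group tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    r2: float
    p: float
    n: int


def trait_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Least-squares line of a gene trait (y) on retention count (x).

    Pairs with a missing value in either variable are dropped pairwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise DegenerateInputError(f"regression needs n >= 3 finite pairs, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("regression undefined: zero variance")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        r2=float(fit.rvalue) ** 2,
        p=float(fit.pvalue),
        n=len(x),
    )


def correlate_retention(
    totals: Sequence[float], factor: Sequence[float]
) -> Tuple[float, float]:
    """Pearson correlation between per-species retention totals and a factor."""
    x = np.asarray(totals, dtype=float)
    y = np.asarray(factor, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise DegenerateInputError("correlation needs n >= 3 finite pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("correlation undefined: zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class GroupTestResult:
    groups: pd.Series  # gene -> group index 1..k (1 = highest retention)
    kw_statistic: float
    kw_p: float
    pairwise: pd.DataFrame  # group_a, group_b, u, p, p_adj


def assign_retention_groups(counts: pd.Series, k: int = 4) -> pd.Series:
    """Split genes into k groups by descending retention count.

    Rank quartiles with ties kept together: a run of equal counts goes
    entirely to the group that was open when the run began (the lower
    group index, i.e. the higher-retention group), which reproduces
    unequal group sizes.
    """
    if k < 2:
        raise ValueError("need k >= 2 groups")
    counts = counts.sort_values(ascending=False, kind="mergesort")
    n = len(counts)
    if n < k:
        raise DegenerateInputError(f"cannot split {n} genes into {k} groups")
    out = pd.Series(0, index=counts.index, dtype=int)
    group = 1
    assigned = 0
    for value, run in counts.groupby(counts, sort=False):
        out.loc[run.index] = group
        assigned += len(run)
        while group < k and assigned >= group * n / k:
            group += 1
    return out


def group_and_test(
    counts: pd.Series, trait: pd.Series, k: int = 4
) -> GroupTestResult:
    """Quartile-group genes by retention and test a trait across groups.

    Only genes with retention >= 1 enter the grouping.  The trait is
    compared across groups with a Kruskal-Wallis test plus all pairwise
    two-sided Mann-Whitney tests, Benjamini-Hochberg adjusted.
    """
    counts = counts[counts >= 1]
    common = counts.index.intersection(trait.dropna().index)
    groups = assign_retention_groups(counts.loc[common], k=k)
    samples = [
        trait.loc[groups.index[groups == g]].to_numpy(dtype=float)
        for g in range(1, k + 1)
    ]
    if any(len(s) == 0 for s in samples):
        raise DegenerateInputError("empty retention group; reduce k")
    kw = stats.kruskal(*samples)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            mwu = stats.mannwhitneyu(samples[i], samples[j], alternative="two-sided")
            rows.append((i + 1, j + 1, float(mwu.statistic), float(mwu.pvalue)))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "u", "p"])
    pairwise["p_adj"] = stats.false_discovery_control(pairwise["p"], method="bh")
    return GroupTestResult(
        groups=groups,
        kw_statistic=float(kw.statistic),
        kw_p=float(kw.pvalue),
        pairwise=pairwise,
    )


# ---------------------------------------------------------------------------
# substitution rate
# ---------------------------------------------------------------------------


def substitution_rate(
    tree: dendropy.Tree, clade_tips: Sequence[str]
) -> pd.Series:
    """Per-tip branch-length sums from the MRCA of ``clade_tips``.

    Returns the sum of branch lengths from every tip below the MRCA up
    to the MRCA node - the relative substitution rate of that tip.
    """
    labels = set(clade_tips)
    present = {t.label for t in tree.taxon_namespace}
    missing = labels - present
    if missing:
        raise ValueError(f"tips not in tree: {sorted(missing)}")
    mrca = tree.mrca(taxon_labels=list(labels))
    rates: Dict[str, float] = {}
    for leaf in mrca.leaf_iter():
        dist = 0.0
        node = leaf
        while node is not mrca:
            dist += node.edge.length or 0.0
            node = node.parent_node
        rates[leaf.taxon.label] = dist
    return pd.Series(rates).sort_index()
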