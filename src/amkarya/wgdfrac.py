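"""WGD dating and subgenome fractionation statistics.

* **4dTv**: the transversion proportion p at fourfold-degenerate codon
  sites, corrected for multiple transversions at the same site with
  d = -0.5 * ln(1 - 2p) (the transversion analogue of a Jukes-Cantor
  style multiple-hit correction; p >= 0.5 is saturated and flagged
  infinite).  Histograms use a 0.01 bin by convention.
* **LF/MF classification**: for a pair of homeologous blocks mapped to
  the same ancestral interval, ancestral ("collinear") genes retained
  vs lost in each copy form a 2x2 table tested with a Pearson
  chi-square (df=1, no continuity correction); the copy retaining more
  ancestral genes is the less-fractionated (LF) copy, the other the
  more-fractionated (MF) copy.
* **TE profiles**: averaged TE-coverage fraction over 100-bp windows
  stepped by 10 bp across +-5 kb gene flanks (491 windows per flank)
  and 40 evenly divided gene-body bins; flank positions overlapping any
  annotated gene are discarded.
* **Dominance**: per-tissue one-sided paired t tests on log2(FPKM+1) of
  LF vs MF anchor duplicates (LF > MF).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from amkarya.genome import GeneModel


class DegenerateInputError(ValueError):
    pass


# ---------------------------------------------------------------------------
# 4dTv
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FourDTV:
    """4dTv summary for one gene pair."""

    pair: str
    n_sites: int
    n_transversions: int
    raw: float
    corrected: float

    @property
    def saturated(self) -> bool:
        return not np.isfinite(self.corrected)


def correct_4dtv(p: float | np.ndarray) -> float | np.ndarray:
    """Multiple-hit correction d = -0.5 * ln(1 - 2p); inf for p >= 0.5."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.inf)
    ok = p < 0.5
    out[ok] = -0.5 * np.log1p(-2.0 * p[ok])
    if out.ndim == 0:
        return float(out)
    return out


def four_dtv(pair: str, n_sites: int, n_transversions: int) -> FourDTV:
    """Raw and corrected 4dTv from fourfold-degenerate site counts."""
    if n_sites < 1:
        raise ValueError("four_dtv requires at least one 4-fold degenerate site")
    if not 0 <= n_transversions <= n_sites:
        raise ValueError("transversion count must be within [0, n_sites]")
    p = n_transversions / n_sites
    return FourDTV(
        pair=pair,
        n_sites=n_sites,
        n_transversions=n_transversions,
        raw=p,
        corrected=correct_4dtv(p),
    )


def histogram(values: Iterable[float], bin_width: float = 0.01) -> pd.DataFrame:
    """Histogram of finite 4dTv values with a fixed bin width."""
    vals = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if vals.size == 0:
        raise DegenerateInputError("no finite values to histogram")
    hi = np.ceil(vals.max() / bin_width) * bin_width
    edges = np.arange(0.0, hi + bin_width, bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    return pd.DataFrame({"bin_left": edges[:-1], "count": counts})


# ---------------------------------------------------------------------------
# LF / MF fractionation
# ---------------------------------------------------------------------------


def chi2_2x2(a: int, b: int, c: int, d: int) -> Tuple[float, float]:
    """Pearson chi-square for a 2x2 table, df=1, no continuity correction.

    Closed form: N * (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)).
    """
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        raise DegenerateInputError("chi-square undefined: a zero margin")
    chi2 = n * (a * d - b * c) ** 2 / denom
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass(frozen=True)
class FractionationCall:
    """LF/MF call for one homeologous block pair."""

    pair_id: str
    retained_lf: int
    lost_lf: int
    retained_mf: int
    lost_mf: int
    lf_copy: str
    mf_copy: str
    chi2: float
    p: float
    low_power: bool

    @property
    def biased(self) -> bool:
        return self.p < 0.05


def classify_fractionation(
    pair_id: str,
    copy_a: str,
    retained_a: int,
    lost_a: int,
    copy_b: str,
    retained_b: int,
    lost_b: int,
    min_genes: int = 10,
) -> FractionationCall:
    """Label the copies of a homeologous block pair LF/MF and test bias.

    ``retained`` counts ancestral (collinear) genes still present in a
    copy, ``lost`` those deleted; the copy retaining more is LF (tie:
    the lexicographically smaller copy id).  Ancestral intervals with
    fewer than ``min_genes`` genes yield a low-power warning flag but a
    call is still emitted.
    """
    for v in (retained_a, lost_a, retained_b, lost_b):
        if v < 0:
            raise ValueError("retained/lost counts must be non-negative")
    chi2, p = chi2_2x2(retained_a, lost_a, retained_b, lost_b)
    if (retained_a, copy_b) > (retained_b, copy_a):
        lf, mf = (copy_a, copy_b)
        r_lf, l_lf, r_mf, l_mf = retained_a, lost_a, retained_b, lost_b
    else:
        lf, mf = (copy_b, copy_a)
        r_lf, l_lf, r_mf, l_mf = retained_b, lost_b, retained_a, lost_a
    total = retained_a + lost_a + retained_b + lost_b
    return FractionationCall(
        pair_id=pair_id,
        retained_lf=r_lf,
        lost_lf=l_lf,
        retained_mf=r_mf,
        lost_mf=l_mf,
        lf_copy=lf,
        mf_copy=mf,
        chi2=chi2,
        p=p,
        low_power=total < 2 * min_genes,
    )


def classify_block_pair(
    pair_id: str,
    block_a,
    block_b,
    reference,
    panel_anchored: set | None = None,
    min_genes: int = 10,
) -> FractionationCall:
    """LF/MF call for two homeologous blocks over one ancestral interval.

    Both blocks must map to the same chromosome of the reference
    (ancestral) genome; the ancestral interval is the union of their
    reference spans.  A reference gene counts as ancestral when it lies
    in the interval (and, if ``panel_anchored`` is given, has a
    syntenic anchor in at least one panel species); it is retained in a
    copy when that copy's block anchors it.
    """
    ref = reference.species

    def ref_side(block):
        if block.species_a == ref:
            return block.chrom_a, {(a.order_a, a.gene_a) for a in block.anchors}
        if block.species_b == ref:
            return block.chrom_b, {(a.order_b, a.gene_b) for a in block.anchors}
        raise ValueError(f"block does not involve reference {ref!r}")

    chrom_a, anch_a = ref_side(block_a)
    chrom_b, anch_b = ref_side(block_b)
    if chrom_a != chrom_b:
        raise ValueError("homeologous blocks must share a reference chromosome")
    orders = [o for o, _ in anch_a] + [o for o, _ in anch_b]
    lo, hi = min(orders), max(orders)
    interval = [
        g for g in reference.chromosomes[chrom_a] if lo <= g.order <= hi
    ]
    if panel_anchored is not None:
        interval = [g for g in interval if g.id in panel_anchored]
    ids = {g.id for g in interval}
    retained_a = sum(1 for _, gid in anch_a if gid in ids)
    retained_b = sum(1 for _, gid in anch_b if gid in ids)
    n = len(interval)

    def copy_name(block):
        return block.chrom_a if block.species_a != ref else block.chrom_b

    return classify_fractionation(
        pair_id,
        copy_name(block_a),
        retained_a,
        n - retained_a,
        copy_name(block_b),
        retained_b,
        n - retained_b,
        min_genes=min_genes,
    )


def retention_validation(
    retained_genes_lf: Mapping[str, set],
    retained_genes_mf: Mapping[str, set],
    panel_anchors: Mapping[str, set],
) -> pd.DataFrame:
    """Per-outgroup validation of an LF/MF call.

    For each outgroup in ``panel_anchors`` (mapping species to the set
    of genes with a syntenic anchor in it), count LF- and MF-copy genes
    retained; a consistent call has LF >= MF in most outgroups.
    """
    rows = []
    for sp, anchored in panel_anchors.items():
        lf = sum(1 for genes in retained_genes_lf.values() for g in genes if g in anchored)
        mf = sum(1 for genes in retained_genes_mf.values() for g in genes if g in anchored)
        rows.append((sp, lf, mf, lf >= mf))
    return pd.DataFrame(rows, columns=["outgroup", "lf_retained", "mf_retained", "consistent"])


# ---------------------------------------------------------------------------
# TE window profiles
# ---------------------------------------------------------------------------


def _merge_intervals(intervals: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    merged: List[Tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _coverage(merged: Sequence[Tuple[int, int]], lo: int, hi: int) -> int:
    """Total bases of merged intervals inside [lo, hi)."""
    cov = 0
    for s, e in merged:
        if e <= lo:
            continue
        if s >= hi:
            break
        cov += min(e, hi) - max(s, lo)
    return cov


def flank_window_starts(flank: int = 5000, window: int = 100, step: int = 10) -> np.ndarray:
    """Window offsets within one flank: (flank - window) / step + 1 windows."""
    return np.arange(0, flank - window + 1, step)


def te_profile(
    genes: Sequence[GeneModel],
    te_intervals: pd.DataFrame,
    mask_genes: Sequence[GeneModel] | None = None,
    flank: int = 5000,
    window: int = 100,
    step: int = 10,
    body_bins: int = 40,
) -> Dict[str, np.ndarray]:
    """Average TE-coverage profile over gene flanks and bodies.

    Returns arrays ``upstream`` and ``downstream`` (one value per
    sliding window, 491 for the defaults) and ``body`` (``body_bins``
    values).  Flank windows overlapping any gene in ``mask_genes``
    (default: the profiled genes themselves) are discarded from the
    average; upstream/downstream are oriented by strand.
    """
    te_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for row in te_intervals.itertuples(index=False):
        te_by_chrom.setdefault(row.chrom, []).append((int(row.start), int(row.end)))
    te_by_chrom = {c: _merge_intervals(v) for c, v in te_by_chrom.items()}

    mask_src = genes if mask_genes is None else mask_genes
    gene_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for g in mask_src:
        gene_by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
    gene_by_chrom = {c: _merge_intervals(v) for c, v in gene_by_chrom.items()}

    starts = flank_window_starts(flank, window, step)
    nwin = len(starts)
    up_sum = np.zeros(nwin)
    up_n = np.zeros(nwin)
    down_sum = np.zeros(nwin)
    down_n = np.zeros(nwin)
    body_sum = np.zeros(body_bins)
    body_n = np.zeros(body_bins)

    for g in genes:
        te = te_by_chrom.get(g.chrom, [])
        others = gene_by_chrom.get(g.chrom, [])

        def flank_values(edge: int, direction: int) -> np.ndarray:
            # direction -1: windows walk away from the gene start;
            # +1: away from the gene end.  Values indexed by distance.
            vals = np.full(nwin, np.nan)
            for i, off in enumerate(starts):
                if direction < 0:
                    lo = edge - off - window
                    hi = edge - off
                else:
                    lo = edge + off
                    hi = edge + off + window
                if lo < 0:
                    continue
                if _coverage(others, lo, hi) > 0:
                    continue  # flank position overlaps a gene: discarded
                vals[i] = _coverage(te, lo, hi) / window
            return vals

        left = flank_values(g.start, -1)
        right = flank_values(g.end, +1)
        up, down = (left, right) if g.strand == "+" else (right, left)
        for arr, s_, n_ in ((up, up_sum, up_n), (down, down_sum, down_n)):
            ok = np.isfinite(arr)
            s_[ok] += arr[ok]
            n_[ok] += 1

        edges = np.linspace(g.start, g.end, body_bins + 1)
        if g.strand == "-":
            edges = edges[::-1]
        for b in range(body_bins):
            lo, hi = sorted((edges[b], edges[b + 1]))
            lo_i, hi_i = int(np.floor(lo)), int(np.ceil(hi))
            if hi_i > lo_i:
                body_sum[b] += _coverage(te, lo_i, hi_i) / (hi_i - lo_i)
                body_n[b] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        return {
            "upstream": up_sum / np.where(up_n > 0, up_n, np.nan),
            "body": body_sum / np.where(body_n > 0, body_n, np.nan),
            "downstream": down_sum / np.where(down_n > 0, down_n, np.nan),
        }


# ---------------------------------------------------------------------------
# subgenome expression dominance
# ---------------------------------------------------------------------------


def dominance_test(
    lf_expr: pd.DataFrame, mf_expr: pd.DataFrame, offset: float = 1.0
) -> pd.DataFrame:
    """One-sided paired t tests of LF > MF expression per tissue.

    Inputs are FPKM matrices (anchor duplicate pairs x tissues) with
    matched rows: row i of ``lf_expr`` is the LF copy of the pair whose
    MF copy is row i of ``mf_expr``.  Values are log2(FPKM + offset)
    transformed.  Raises on fewer than 3 pairs or zero-variance
    differences.
    """
    if lf_expr.shape != mf_expr.shape:
        raise ValueError("LF and MF matrices must have identical shape")
    if list(lf_expr.columns) != list(mf_expr.columns):
        raise ValueError("LF and MF matrices must share tissue columns")
    if len(lf_expr) < 3:
        raise DegenerateInputError("dominance test needs >= 3 anchor pairs")
    if (lf_expr.to_numpy() < 0).any() or (mf_expr.to_numpy() < 0).any():
        raise ValueError("FPKM values must be non-negative")
    lf = np.log2(lf_expr.to_numpy(dtype=float) + offset)
    mf = np.log2(mf_expr.to_numpy(dtype=float) + offset)
    rows = []
    for j, tissue in enumerate(lf_expr.columns):
        diff = lf[:, j] - mf[:, j]
        if np.allclose(diff.std(ddof=1), 0.0):
            raise DegenerateInputError(
                f"tissue {tissue!r}: zero-variance paired differences"
            )
        t, p = stats.ttest_rel(lf[:, j], mf[:, j], alternative="greater")
        rows.append((tissue, float(t), float(p), len(diff)))
    return pd.DataFrame(rows, columns=["tissue", "t", "p", "n_pairs"])
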