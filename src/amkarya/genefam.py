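"""Orthogroup evolution on a rooted species tree.

* **Dollo parsimony**: a gene family (orthogroup, OG) is gained exactly
  once - on the branch to the MRCA of all species carrying it - and may
  be lost any number of times.  The minimal loss set consists of the
  maximal subtrees below the gain node whose tips all lack the family.
* **Copy-number shift test**: a two-sided rank-sum comparison of copy
  counts between two clades (exact enumeration for combined n <= 20,
  tie-corrected normal approximation otherwise), flagged when P < 0.01
  and the fold change of the average copy number is >= 2.
* **tau**: the tissue-specificity index
  tau = sum_i (1 - x_i / x_max) / (n - 1), 0 for uniform expression and
  1 for single-tissue expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import dendropy
import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DolloResult:
    """Dollo-parsimony reconstruction of OG gains and losses."""

    gain_branch: Dict[str, str]  # OG -> node label of the gain
    loss_branches: Dict[str, List[str]]  # OG -> node labels of losses
    branch_gains: pd.Series
    branch_losses: pd.Series
    skipped: List[str] = field(default_factory=list)


def _node_label(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return node.label
    # stable internal label: MRCA of the two extreme leaf labels
    leaves = sorted(l.taxon.label for l in node.leaf_iter())
    return f"mrca({leaves[0]},{leaves[-1]})"


def dollo(presence: pd.DataFrame, tree: dendropy.Tree) -> DolloResult:
    """Single-gain / multiple-loss reconstruction for each orthogroup.

    ``presence`` is a binary OG x species matrix (anything > 0 counts
    as present; the presence threshold is copy >= 1).  Species names
    must match the tree's tip labels.  OGs absent everywhere are
    skipped with a warning entry.
    """
    tips = {t.label for t in tree.taxon_namespace}
    missing = set(presence.columns) - tips
    if missing:
        raise ValueError(f"species not in tree: {sorted(missing)}")

    gain_branch: Dict[str, str] = {}
    loss_branches: Dict[str, List[str]] = {}
    gains: Dict[str, int] = {}
    losses: Dict[str, int] = {}
    skipped: List[str] = []

    for og, row in presence.iterrows():
        present = {sp for sp, v in row.items() if v >= 1}
        if not present:
            skipped.append(str(og))
            continue
        if len(present) == 1:
            gain = tree.find_node_with_taxon_label(next(iter(present)))
        else:
            gain = tree.mrca(taxon_labels=list(present))
        glabel = _node_label(gain)
        gain_branch[str(og)] = glabel
        gains[glabel] = gains.get(glabel, 0) + 1

        # maximal all-absent subtrees below the gain node
        og_losses: List[str] = []

        def walk(node: dendropy.Node) -> bool:
            """True when every tip below ``node`` lacks the OG."""
            if node.is_leaf():
                return node.taxon.label not in present
            child_absent = [walk(c) for c in node.child_nodes()]
            return all(child_absent)

        def collect(node: dendropy.Node) -> None:
            for child in node.child_nodes():
                if walk(child):
                    og_losses.append(_node_label(child))
                else:
                    collect(child)

        collect(gain)
        loss_branches[str(og)] = sorted(og_losses)
        for label in og_losses:
            losses[label] = losses.get(label, 0) + 1

    return DolloResult(
        gain_branch=gain_branch,
        loss_branches=loss_branches,
        branch_gains=pd.Series(gains, dtype=int).sort_index(),
        branch_losses=pd.Series(losses, dtype=int).sort_index(),
        skipped=skipped,
    )


# ---------------------------------------------------------------------------
# clade copy-number shift
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CopyShiftResult:
    p: float
    fold_change: float
    direction: str  # "up" when clade A mean > clade B mean
    significant: bool
    complete_loss: bool
    method: str


def _u_statistic(x: np.ndarray, y: np.ndarray, axis: int = -1) -> np.ndarray:
    """Mann-Whitney U of the first sample, vectorized over leading axes."""
    nx = x.shape[axis]
    ranks = stats.rankdata(np.concatenate([x, y], axis=axis), axis=axis)
    rx = np.take(ranks, np.arange(nx), axis=axis)
    return rx.sum(axis=axis) - nx * (nx + 1) / 2


def copy_shift_test(
    clade_a: Sequence[float],
    clade_b: Sequence[float],
    p_threshold: float = 0.01,
    fc_threshold: float = 2.0,
    eps: float = 0.1,
    exact_max_n: int = 20,
) -> CopyShiftResult:
    """Two-sided rank-sum test of copy counts between two clades.

    For combined n <= ``exact_max_n`` the null distribution of the
    Mann-Whitney U statistic is enumerated exactly over all group
    reassignments (valid under ties); larger samples use the
    tie-corrected normal approximation.  The fold change is
    (mean_A + eps) / (mean_B + eps), reported as ``direction`` "up"/
    "down"; a complete loss (one clade all zero, the other non-zero)
    always satisfies the fold-change condition by construction and is
    reported in its own category.
    """
    x = np.asarray(clade_a, dtype=float)
    y = np.asarray(clade_b, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("both clades need >= 3 species")
    if np.ptp(np.concatenate([x, y])) == 0:
        fc = 1.0
        return CopyShiftResult(1.0, fc, "up", False, False, "degenerate")

    if len(x) + len(y) <= exact_max_n:
        res = stats.permutation_test(
            (x, y),
            _u_statistic,
            permutation_type="independent",
            alternative="two-sided",
            n_resamples=np.inf,
            vectorized=True,
        )
        p = float(res.pvalue)
        method = "exact"
    else:
        p = float(
            stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic",
                use_continuity=False,
            ).pvalue
        )
        method = "asymptotic"

    mean_a, mean_b = float(x.mean()), float(y.mean())
    if mean_a >= mean_b:
        fc = (mean_a + eps) / (mean_b + eps)
        direction = "up"
    else:
        fc = (mean_b + eps) / (mean_a + eps)
        direction = "down"
    complete_loss = (mean_a == 0) != (mean_b == 0)
    significant = p < p_threshold and fc >= fc_threshold
    return CopyShiftResult(p, fc, direction, significant, complete_loss, method)


def copy_shift_table(
    og_matrix: pd.DataFrame,
    clade_a: Sequence[str],
    clade_b: Sequence[str],
    **kwargs,
) -> pd.DataFrame:
    """Apply :func:`copy_shift_test` to every row of an OG copy matrix."""
    a_cols = list(clade_a)
    b_cols = list(clade_b)
    rows = []
    for og, row in og_matrix.iterrows():
        res = copy_shift_test(row[a_cols].to_numpy(), row[b_cols].to_numpy(), **kwargs)
        rows.append(
            (og, res.p, res.fold_change, res.direction, res.significant, res.complete_loss)
        )
    return pd.DataFrame(
        rows, columns=["og", "p", "fold_change", "direction", "significant", "complete_loss"]
    ).set_index("og")


# ---------------------------------------------------------------------------
# tau
# ---------------------------------------------------------------------------


def tau(expression: Sequence[float]) -> float:
    """Tissue-specificity index over >= 2 tissues.

    tau = sum_i (1 - x_i / x_max) / (n - 1); invariant to positive
    scaling; undefined (error) for an all-zero vector.
    """
    x = np.asarray(expression, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("tau needs a vector of >= 2 tissues")
    if (x < 0).any():
        raise ValueError("expression values must be >= 0")
    xmax = x.max()
    if xmax == 0:
        raise ValueError("tau undefined for an all-zero expression vector")
    return float((1.0 - x / xmax).sum() / (len(x) - 1))


def tau_matrix(expression: pd.DataFrame) -> pd.Series:
    """Per-gene tau over a genes x tissues FPKM matrix (all-zero rows -> NaN)."""
    vals = expression.to_numpy(dtype=float)
    xmax = vals.max(axis=1)
    n = vals.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (1.0 - vals / xmax[:, None]).sum(axis=1) / (n - 1)
    t[xmax == 0] = np.nan
    return pd.Series(t, index=expression.index, name="tau")
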