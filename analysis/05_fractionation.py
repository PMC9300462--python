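"""Post-WGD fractionation of the palaeotetraploid lineage.

For the single-WGD lineage: corrected 4dTv age distributions of
paralogs vs orthologs, LF/MF classification of homeologous block pairs
with chi-square bias tests (validated against the logged subgenome
labels), TE window profiles around LF vs MF genes, and the
subgenome expression-dominance test.
"""

import sys
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import RESULTS, STUDY, load  # noqa: E402

from amkarya import io  # noqa: E402
from amkarya.karyotype import wgd_multiplicity  # noqa: E402
from amkarya.sim import emit_4dtv_table, registry_anchor_pairs  # noqa: E402
from amkarya.synteny import chain_blocks  # noqa: E402
from amkarya.wgdfrac import (  # noqa: E402
    classify_block_pair,
    dominance_test,
    four_dtv,
    histogram,
    te_profile,
)

LINEAGE = "slowpoke"


def main() -> None:
    sim = RESULTS / "sim"
    out = RESULTS / "fractionation"
    out.mkdir(parents=True, exist_ok=True)
    res = load()
    poly = res.lineages[LINEAGE]
    anc = res.ancestor

    # 4dTv: within-lineage paralogs age older than lineage-vs-ancestor
    medians = {}
    for label, (qa, qb) in {
        "paralogs": (poly, poly),
        "orthologs": (poly, anc),
    }.items():
        table = emit_4dtv_table(qa, qb, STUDY)
        vals = np.array(
            [
                four_dtv(f"{r.gene_a}:{r.gene_b}", r.n_sites, r.n_transversions).corrected
                for r in table.itertuples()
            ]
        )
        finite = vals[np.isfinite(vals)]
        medians[label] = float(np.median(finite))
        histogram(finite, bin_width=0.01).to_csv(
            out / f"4dtv_hist.{label}.tsv", sep="\t", index=False
        )
    print(f"median corrected 4dTv: paralogs {medians['paralogs']:.3f}, "
          f"{LINEAGE}-ancestor orthologs {medians['orthologs']:.3f}")

    # homeologous block pairs and LF/MF calls
    blocks = chain_blocks(registry_anchor_pairs(poly, anc), poly.genome, anc.genome)
    m, groups = wgd_multiplicity(blocks, anc.genome)
    print(f"syntenic coverage depth over the ancestor: m = {m}")

    def copy_name(block):
        return block.chrom_a if block.species_a == LINEAGE else block.chrom_b

    def true_label(block):
        genes = [
            a.gene_a if a.gene_a.startswith(LINEAGE) else a.gene_b
            for a in block.anchors
        ]
        return Counter(poly.subgenome[g] for g in genes).most_common(1)[0][0]

    rows = []
    correct = total = 0
    for gi, grp in enumerate(groups):
        if len(grp) != 2:
            continue
        ba, bb = blocks[grp[0]], blocks[grp[1]]
        call = classify_block_pair(f"pair{gi:02d}", ba, bb, anc.genome)
        lf_block = ba if call.lf_copy == copy_name(ba) else bb
        ok = true_label(lf_block) == "LF"
        correct += ok
        total += 1
        rows.append(
            (call.pair_id, call.lf_copy, call.mf_copy, call.retained_lf,
             call.lost_lf, call.retained_mf, call.lost_mf, call.chi2, call.p, ok)
        )
    calls = pd.DataFrame(
        rows, columns=["pair", "lf_copy", "mf_copy", "retained_lf", "lost_lf",
                       "retained_mf", "lost_mf", "chi2", "p", "matches_truth"]
    )
    calls.to_csv(out / "lf_mf_calls.tsv", sep="\t", index=False)
    print(f"LF/MF calls: {total} homeologous pairs, "
          f"{(calls['p'] < 0.05).sum()} significantly biased, "
          f"true LF labelled correctly in {correct}/{total}")

    # TE window profiles for LF vs MF gene groups
    te = io.read_intervals_bed(sim / f"{LINEAGE}.te.bed")
    all_genes = list(poly.genome.genes())
    lf_genes = [g for g in all_genes if poly.subgenome[g.id] == "LF"]
    mf_genes = [g for g in all_genes if poly.subgenome[g.id] == "MF"]
    prof_rows = []
    means = {}
    for label, genes in (("LF", lf_genes), ("MF", mf_genes)):
        prof = te_profile(genes, te, mask_genes=all_genes)
        means[label] = float(np.nanmean(prof["upstream"]))
        for part in ("upstream", "body", "downstream"):
            for i, v in enumerate(prof[part]):
                prof_rows.append((label, part, i, v))
    pd.DataFrame(prof_rows, columns=["group", "region", "window", "te_fraction"]).to_csv(
        out / "te_profile.tsv", sep="\t", index=False
    )
    print(f"mean upstream TE fraction: LF {means['LF']:.3f} < MF {means['MF']:.3f}")

    # subgenome expression dominance on anchor duplicate pairs
    expr = io.read_matrix(sim / f"{LINEAGE}.fpkm.tsv")
    by_pg = {}
    for g in all_genes:
        by_pg.setdefault(poly.protogene[g.id], []).append(g.id)
    lf_rows, mf_rows = [], []
    for pg, gs in sorted(by_pg.items()):
        labels = {poly.subgenome[g]: g for g in gs}
        if set(labels) >= {"LF", "MF"}:
            lf_rows.append(labels["LF"])
            mf_rows.append(labels["MF"])
    dom = dominance_test(
        expr.loc[lf_rows].reset_index(drop=True),
        expr.loc[mf_rows].reset_index(drop=True),
    )
    dom.to_csv(out / "dominance.tsv", sep="\t", index=False)
    print(f"expression dominance (LF > MF), {len(lf_rows)} duplicate pairs:")
    print(dom.round(6).to_string(index=False))


if __name__ == "__main__":
    main()
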