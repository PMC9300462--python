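"""Synteny blocks, decay rates, retention profiles and trait regressions.

Chains the one-to-one orthologs from 02 into blocks per lineage,
fits the synteny-decay rate of each lineage, builds the ancestor-side
retention profile, then (with trait tables planted against the
realized retention) reproduces the retention-trait regression table
and the quartile-group Kruskal-Wallis comparisons.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import RESULTS, STUDY, load  # noqa: E402

from amkarya import io  # noqa: E402
from amkarya.homology import OrthologPair  # noqa: E402
from amkarya.sim import count_events, emit_traits  # noqa: E402
from amkarya.synteny import (  # noqa: E402
    chain_blocks,
    correlate_retention,
    decay_rate,
    group_and_test,
    retention_profile,
    trait_regression,
)


def read_orthologs(path, species_a, species_b):
    df = pd.read_csv(path, sep="\t")
    return [
        OrthologPair(r.gene_a, r.gene_b, species_a, species_b, r.cip, r.calp, r.bitscore)
        for r in df.itertuples()
    ]


def main() -> None:
    sim, hom = RESULTS / "sim", RESULTS / "homology"
    out = RESULTS / "synteny"
    out.mkdir(parents=True, exist_ok=True)
    res = load()
    genomes = {
        p.stem: io.read_gff3(p, species=p.stem) for p in sorted(sim.glob("*.gff3"))
    }

    blocks_by = {}
    block_rows, decay_rows = [], []
    for spec in STUDY.lineages:
        name = spec.name
        pairs = read_orthologs(hom / f"orthologs.{name}.tsv", "AMK", name)
        blocks = chain_blocks(pairs, genomes["AMK"], genomes[name])
        blocks_by[name] = blocks
        fit = decay_rate(blocks)
        n_events = sum(
            v for k, v in count_events(res.logs[name]).items() if k != "tandem_dup"
        )
        decay_rows.append(
            (name, len(blocks), sum(b.size for b in blocks), fit.rate,
             spec.divergence, n_events)
        )
        for i, b in enumerate(blocks):
            block_rows.append(
                (name, f"{name}.b{i:03d}", b.chrom_a, b.chrom_b, b.orientation, b.size)
            )

    pd.DataFrame(
        block_rows, columns=["lineage", "block", "chrom_amk", "chrom_modern",
                             "orientation", "size"]
    ).to_csv(out / "blocks.tsv", sep="\t", index=False)
    decay = pd.DataFrame(
        decay_rows,
        columns=["lineage", "n_blocks", "anchors", "decay_rate", "divergence",
                 "n_events"],
    )
    decay.to_csv(out / "decay.tsv", sep="\t", index=False)
    print("synteny decay per lineage (rate rises with rearrangement load):")
    print(decay.to_string(index=False))

    profile = retention_profile(genomes["AMK"], blocks_by)
    profile.per_gene.rename("n_lineages").to_csv(out / "retention_per_gene.tsv",
                                                 sep="\t")
    totals = profile.per_species
    print("\nper-lineage syntenic ancestor genes:", dict(totals))
    r_div, p_div = correlate_retention(
        totals.to_numpy(), [s.divergence for s in STUDY.lineages]
    )
    print(f"retention vs divergence: r = {r_div:.2f} (P = {p_div:.3g})")

    # trait table planted against the realized retention counts
    traits = emit_traits(res.ancestor, STUDY.trait_model, profile.per_gene, STUDY.seed)
    traits.to_csv(out / "amk_traits.tsv", sep="\t")
    reg_rows = []
    for trait in ("methylation", "expression", "te_fraction", "pi"):
        fit = trait_regression(traits["retention"], traits[trait])
        reg_rows.append((trait, fit.slope, fit.intercept, fit.r, fit.r2, fit.p, fit.n))
    table = pd.DataFrame(
        reg_rows, columns=["trait", "slope", "intercept", "r", "r2", "p", "n"]
    )
    table.to_csv(out / "trait_regressions.tsv", sep="\t", index=False)
    print("\nretention-trait regressions (planted couplings "
          f"{STUDY.trait_model.couplings}):")
    print(table.round(4).to_string(index=False))

    # with only five lineages the count distribution is concentrated at
    # the top; fall back to coarser groupings until every group is filled
    from amkarya.synteny import DegenerateInputError

    counts = profile.per_gene[profile.per_gene >= 1]
    for k in (4, 3, 2):
        try:
            gt = group_and_test(counts, traits["methylation"], k=k)
            break
        except DegenerateInputError as exc:
            print(f"grouping with k={k} degenerate ({exc}); coarsening")
    sizes = gt.groups.value_counts().sort_index()
    print(f"\nretention groups (k={k}) sizes: {list(sizes)}; "
          f"methylation KW P = {gt.kw_p:.3g}")
    gt.pairwise.to_csv(out / "group_pairwise.tsv", sep="\t", index=False)
    gt.groups.rename("group").to_csv(out / "retention_groups.tsv", sep="\t")


if __name__ == "__main__":
    main()
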