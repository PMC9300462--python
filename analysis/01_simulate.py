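"""Simulate the study clade and write every interchange file.

Outputs under results/sim/: one GFF3 per genome, the BLAST-tabular hit
table for ancestor-vs-lineage and within-lineage comparisons, the true
lineage tree, per-species protogene/subgenome registries, the TE track
and expression matrix of the palaeotetraploid lineage, an orthogroup
copy matrix with planted clade shifts, and the complete event logs.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import RESULTS, STUDY, load  # noqa: E402

from amkarya import io  # noqa: E402
from amkarya.sim import (  # noqa: E402
    count_events,
    emit_expression,
    emit_hit_table,
    emit_og_matrix,
    emit_te_track,
    expected_chromosomes,
    lineage_tree_newick,
)


def main() -> None:
    out = RESULTS / "sim"
    out.mkdir(parents=True, exist_ok=True)
    res = load()

    print(f"ancestor: {res.ancestor.genome}")
    for name, bundle in res.lineages.items():
        log = res.logs[name]
        n_expect = expected_chromosomes(log, STUDY.n_ancestral_chromosomes)
        assert bundle.genome.n_chromosomes == n_expect, name
        print(
            f"  {name:>10}: {bundle.genome.n_chromosomes:>2} chromosomes, "
            f"{bundle.genome.n_genes:>5} genes, events {count_events(log)}"
        )

    for name, bundle in res.all_bundles().items():
        io.write_gff3(bundle.genome, out / f"{name}.gff3")
        pd.DataFrame(
            {
                "gene": list(bundle.protogene),
                "protogene": list(bundle.protogene.values()),
                "subgenome": [bundle.subgenome[g] for g in bundle.protogene],
            }
        ).to_csv(out / f"{name}.registry.tsv", sep="\t", index=False)
        io.write_event_log(res.logs.get(name, []), out / f"{name}.events.json")

    pairs = [("AMK", n) for n in res.lineages] + [
        (n, n) for n, b in res.lineages.items()
        if any(r["type"] in ("wgd", "triplication") for r in res.logs[n])
    ]
    hits = emit_hit_table(res.all_bundles(), STUDY, pairs=pairs)
    io.write_hits(hits, out / "hits.tsv")
    print(f"hit table: {len(hits)} rows for {len(pairs)} genome pairs")

    (out / "lineages.nwk").write_text(lineage_tree_newick(STUDY) + "\n")

    slow = res.lineages["slowpoke"]
    io.write_intervals_bed(
        emit_te_track(slow, STUDY.seed, mf_flank_boost=1.5), out / "slowpoke.te.bed"
    )
    io.write_matrix(
        emit_expression(slow, STUDY.trait_model, STUDY.seed), out / "slowpoke.fpkm.tsv"
    )

    species = [f"tax{i:02d}" for i in range(24)]
    og, truth = emit_og_matrix(
        species, clade=species[:12], n_ogs=800, n_loss=20, n_expansion=20,
        seed=STUDY.seed,
    )
    io.write_matrix(og, out / "og_matrix.tsv")
    truth.to_csv(out / "og_truth.tsv", sep="\t")
    print(f"orthogroup matrix: {og.shape[0]} OGs x {og.shape[1]} taxa "
          "(20 planted losses, 20 planted expansions)")
    print(f"wrote {len(list(out.iterdir()))} files to {out}")


if __name__ == "__main__":
    main()
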