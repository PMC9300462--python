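"""Conserved genes (CIP/CALP >= 50/50) and one-to-one orthologs.

Reads the hit table and genomes written by 01, scores every gene pair,
applies the conservation filter, collapses tandem/species-specific
duplicates and reduces to one-to-one orthologs per ancestor-lineage
pair.  Writes results/homology/orthologs.<lineage>.tsv and a summary.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import RESULTS, STUDY  # noqa: E402

from amkarya import io  # noqa: E402
from amkarya.homology import (  # noqa: E402
    compute_cip_calp,
    filter_conserved,
    group_hitsets,
    remove_local_and_specific,
)


def main() -> None:
    sim = RESULTS / "sim"
    out = RESULTS / "homology"
    out.mkdir(parents=True, exist_ok=True)

    genomes = {
        p.stem: io.read_gff3(p, species=p.stem) for p in sorted(sim.glob("*.gff3"))
    }
    qlen = {g.id: g.aa_length for gm in genomes.values() for g in gm.genes()}
    hits = io.read_hits(sim / "hits.tsv")

    summary_rows = []
    for spec in STUDY.lineages:
        name = spec.name
        mask = (
            hits.qseqid.str.startswith(("AMK_", f"{name}_"))
            & hits.sseqid.str.startswith(("AMK_", f"{name}_"))
        )
        summaries = [compute_cip_calp(h) for h in group_hitsets(hits[mask], qlen)]
        conserved = filter_conserved(summaries)
        orthologs = remove_local_and_specific(
            conserved, {"AMK": genomes["AMK"], name: genomes[name]}
        )
        frame = pd.DataFrame(
            [
                (p.gene_a, p.gene_b, round(p.cip, 2), round(p.calp, 4), p.bitscore_sum)
                for p in orthologs
            ],
            columns=["gene_a", "gene_b", "cip", "calp", "bitscore"],
        )
        frame.to_csv(out / f"orthologs.{name}.tsv", sep="\t", index=False)
        summary_rows.append(
            (name, len(summaries), len(conserved), len(orthologs))
        )
        print(
            f"{name:>10}: {len(summaries):>6} scored pairs -> "
            f"{len(conserved):>5} conserved -> {len(orthologs):>5} one-to-one"
        )

    pd.DataFrame(
        summary_rows, columns=["lineage", "scored", "conserved", "one_to_one"]
    ).to_csv(out / "summary.tsv", sep="\t", index=False)
    total = sum(r[3] for r in summary_rows)
    print(f"total one-to-one orthologs across lineage pairs: {total}")


if __name__ == "__main__":
    main()
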