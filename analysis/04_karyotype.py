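"""CAR reconstruction, dotplots and parsimonious scenarios per lineage.

Merges the lineage blocks into conserved ancestral regions with the
simulated ancestor as pivot, validates the CAR count against the known
karyotype, infers each lineage's WGD multiplicity and fusion/fission
scenario, and checks both the chromosome-count identity and the true
event log.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from study import RESULTS, STUDY, load  # noqa: E402

from amkarya import io  # noqa: E402
from amkarya.homology import (  # noqa: E402
    best_per_query,
    compute_cip_calp,
    filter_conserved,
    group_hitsets,
)
from amkarya.karyotype import (  # noqa: E402
    build_cars,
    dotplot_table,
    infer_scenario,
    wgd_multiplicity,
)
from amkarya.synteny import chain_blocks  # noqa: E402


def main() -> None:
    sim, hom = RESULTS / "sim", RESULTS / "homology"
    out = RESULTS / "karyotype"
    out.mkdir(parents=True, exist_ok=True)
    res = load()
    genomes = {
        p.stem: io.read_gff3(p, species=p.stem) for p in sorted(sim.glob("*.gff3"))
    }
    qlen = {g.id: g.aa_length for gm in genomes.values() for g in gm.genes()}
    hits = io.read_hits(sim / "hits.tsv")

    # pivot-side blocks from the one-to-one orthologs of 02
    from amkarya.homology import OrthologPair

    blocks_by = {}
    for spec in STUDY.lineages:
        df = pd.read_csv(hom / f"orthologs.{spec.name}.tsv", sep="\t")
        pairs = [
            OrthologPair(r.gene_a, r.gene_b, "AMK", spec.name, r.cip, r.calp,
                         r.bitscore)
            for r in df.itertuples()
        ]
        blocks_by[spec.name] = chain_blocks(pairs, genomes["AMK"], genomes[spec.name])

    ak = build_cars(blocks_by, genomes["AMK"])
    ak.to_frame().to_csv(out / "cars.tsv", sep="\t", index=False)
    print(
        f"reconstructed {ak.n_cars} CARs with {ak.n_protogenes} protogenes "
        f"(simulated ancestor: {STUDY.n_ancestral_chromosomes} chromosomes, "
        f"{STUDY.n_ancestral_chromosomes * STUDY.genes_per_chromosome} genes)"
    )
    assert ak.n_cars == STUDY.n_ancestral_chromosomes

    rows = []
    for spec in STUDY.lineages:
        name = spec.name
        mask = hits.qseqid.str.startswith(f"{name}_") & hits.sseqid.str.startswith(
            "AMK_"
        )
        conserved = filter_conserved(
            [compute_cip_calp(h) for h in group_hitsets(hits[mask], qlen)]
        )
        anchors = best_per_query(
            conserved, {"AMK": genomes["AMK"], name: genomes[name]}, name, "AMK"
        )
        blocks = chain_blocks(anchors, genomes[name], genomes["AMK"])
        dotplot_table(blocks).to_csv(out / f"dotplot.{name}.tsv", sep="\t",
                                     index=False)
        m, _ = wgd_multiplicity(blocks, genomes["AMK"])
        sc = infer_scenario(ak, genomes[name], blocks, m, lineage=name)
        truth = {}
        for rec in res.logs[name]:
            truth[rec["type"]] = truth.get(rec["type"], 0) + 1
        true_m = 1
        for rec in res.logs[name]:
            if rec["type"] in ("wgd", "triplication"):
                true_m *= rec["multiplier"]
        rows.append(
            (name, m, true_m, sc.fusions, truth.get("fusion", 0), sc.fissions,
             truth.get("fission", 0), sc.inversions, sc.translocations,
             sc.n_modern, sc.identity_ok)
        )
        sc.segments.to_csv(out / f"segments.{name}.tsv", sep="\t", index=False)

    table = pd.DataFrame(
        rows,
        columns=["lineage", "m", "m_true", "fusions", "fusions_true", "fissions",
                 "fissions_true", "inversions", "translocations", "n_modern",
                 "identity_ok"],
    )
    table.to_csv(out / "scenarios.tsv", sep="\t", index=False)
    print("\ninferred scenarios vs ground truth:")
    print(table.to_string(index=False))
    assert table["identity_ok"].all(), "chromosome-count identity violated"
    exact = (
        (table["fusions"] == table["fusions_true"])
        & (table["fissions"] == table["fissions_true"])
        & (table["m"] == table["m_true"])
    ).sum()
    print(f"\nscenario exactly matches the event log for {exact}/{len(table)} lineages")


if __name__ == "__main__":
    main()
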