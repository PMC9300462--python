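"""The synthetic study: one ancestral karyotype, five descendant lineages.

The clade emulates the shape of an early-branching monocot comparison
at desk scale: a slowly evolving palaeotetraploid (one WGD, few
rearrangements, short branch), two double-WGD lineages with many
fusions, a diploid lineage reshaped by fissions/fusions, and a fast,
heavily shuffled lineage.  The ancestor has n = 6 protochromosomes of
400 genes each; every event is recorded, so each downstream analysis
can be checked against ground truth.

All analysis scripts import ``STUDY`` and the deterministic
``load()``; script 01 additionally writes the interchange files under
``results/sim/`` for inspection and for the io-layer demonstration.
"""

from pathlib import Path

from amkarya.sim import (
    Fission,
    Fusion,
    Inversion,
    LineageSpec,
    SimConfig,
    TraitModel,
    WGD,
    simulate_clade,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"

STUDY = SimConfig(
    seed=42,
    n_ancestral_chromosomes=6,
    genes_per_chromosome=400,
    ancestor_name="AMK",
    trait_model=TraitModel(
        couplings={
            "expression": 0.15,
            "methylation": -0.22,
            "te_fraction": -0.12,
            "pi": -0.11,
        },
        dominance_shift=0.5,
    ),
    lineages=[
        # one WGD, no further reshuffling, shortest branch
        LineageSpec("slowpoke", 0.03, [WGD(retention_bias=0.35, loss_rate=0.2)]),
        # two WGDs then extensive fusion (24 -> 20)
        LineageSpec(
            "reedling",
            0.08,
            [WGD(retention_bias=0.25), WGD(retention_bias=0.25)] + [Fusion()] * 4,
        ),
        # two WGDs then heavier fusion (24 -> 14)
        LineageSpec(
            "taroid",
            0.07,
            [WGD(retention_bias=0.25), WGD(retention_bias=0.25)] + [Fusion()] * 10,
        ),
        # diploid, reshaped by fissions and fusions (6 -> 7)
        LineageSpec(
            "yamvine",
            0.09,
            [Fission(), Fission(), Fusion(), Inversion(), Inversion()],
        ),
        # fastest branch, heavily shuffled
        LineageSpec(
            "speargrass",
            0.12,
            [Fusion(), WGD(retention_bias=0.3), Fission(), Fusion(), Fusion()]
            + [Inversion()] * 4,
        ),
    ],
)


def load():
    """Deterministically regenerate the study clade."""
    return simulate_clade(STUDY)
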