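"""CAR construction, WGD multiplicity and scenario inference."""

import numpy as np
import pytest

from amkarya import karyotype as K
from amkarya.synteny import chain_blocks
from amkarya.sim import (
    Fission,
    Fusion,
    Inversion,
    LineageSpec,
    SimConfig,
    Triplication,
    WGD,
    registry_anchor_pairs,
    simulate_clade,
)


def blocks_vs_ancestor(res, name, one_to_one=True):
    bundle = res.lineages[name]
    pairs = registry_anchor_pairs(res.ancestor, bundle, one_to_one=one_to_one)
    return chain_blocks(pairs, res.ancestor.genome, bundle.genome)


def blocks_of_modern(res, name):
    """Modern-vs-ancestor blocks, one best ancestor position per modern gene."""
    bundle = res.lineages[name]
    pairs = registry_anchor_pairs(bundle, res.ancestor)
    return chain_blocks(pairs, bundle.genome, res.ancestor.genome)


class TestBuildCars:
    def test_unmodified_descendants_reproduce_ancestor_chromosomes(self):
        cfg = SimConfig(
            seed=2,
            n_ancestral_chromosomes=4,
            genes_per_chromosome=60,
            lineages=[LineageSpec("d1", 0.02, []), LineageSpec("d2", 0.03, [])],
        )
        res = simulate_clade(cfg)
        blocks_by = {n: blocks_vs_ancestor(res, n) for n in res.lineages}
        ak = K.build_cars(blocks_by, res.ancestor.genome)
        assert ak.n_cars == 4
        chroms = {car.pivot_chrom for car in ak.cars}
        assert chroms == set(res.ancestor.genome.chromosomes)
        assert ak.n_protogenes == res.ancestor.genome.n_genes

    def test_fewer_than_two_species_is_an_error(self):
        cfg = SimConfig(seed=2, n_ancestral_chromosomes=2, genes_per_chromosome=30,
                        lineages=[LineageSpec("only", 0.02, [])])
        res = simulate_clade(cfg)
        with pytest.raises(ValueError, match="at least 2"):
            K.build_cars({"only": blocks_vs_ancestor(res, "only")}, res.ancestor.genome)

    def test_shared_fusion_in_all_descendants_merges_cars(self):
        """Two ancestral chromosomes fused in every lineage cannot be split.

        Using a fused descendant as pivot, the other lineages' blocks
        span the junction, so the two ancestral chromosomes come back
        as a single CAR - the information-theoretic limit.
        """
        shared = [Fusion(chrom_a="chr01", chrom_b="chr02", invert_b=False)]
        cfg = SimConfig(
            seed=6,
            n_ancestral_chromosomes=3,
            genes_per_chromosome=50,
            lineages=[
                LineageSpec("p", 0.02, shared),
                LineageSpec("q", 0.03, shared),
                LineageSpec("r", 0.04, shared),
            ],
        )
        res = simulate_clade(cfg)
        pivot = res.lineages["p"]
        blocks_by = {}
        for other in ("q", "r"):
            pairs = registry_anchor_pairs(pivot, res.lineages[other], one_to_one=True)
            blocks_by[other] = chain_blocks(
                pairs, pivot.genome, res.lineages[other].genome
            )
        ak = K.build_cars(blocks_by, pivot.genome)
        assert ak.n_cars == 2  # chr01+chr02 merged, chr03 separate

    def test_protogenes_unique_across_cars(self):
        cfg = SimConfig(
            seed=8,
            n_ancestral_chromosomes=3,
            genes_per_chromosome=50,
            lineages=[
                LineageSpec("a", 0.02, [Fusion()]),
                LineageSpec("b", 0.03, [Fission()]),
            ],
        )
        res = simulate_clade(cfg)
        blocks_by = {n: blocks_vs_ancestor(res, n) for n in res.lineages}
        ak = K.build_cars(blocks_by, res.ancestor.genome)
        ak.protogene_positions()  # raises on duplicates


class TestMultiplicity:
    @pytest.mark.parametrize(
        "events,expected_m",
        [([], 1), ([WGD(retention_bias=0.2)], 2), ([Triplication(retention_bias=0.2)], 3)],
    )
    def test_ploidy_recovered_from_coverage_depth(self, events, expected_m):
        cfg = SimConfig(
            seed=9,
            n_ancestral_chromosomes=3,
            genes_per_chromosome=100,
            lineages=[LineageSpec("x", 0.03, events)],
        )
        res = simulate_clade(cfg)
        m, groups = K.wgd_multiplicity(blocks_of_modern(res, "x"), res.ancestor.genome)
        assert m == expected_m
        if expected_m == 2:
            assert all(len(g) >= 2 for g in groups)


class TestScenario:
    def test_wgd_twelve_fusions_fixture(self):
        """12 CARs, WGD, 12 pairwise fusions of distinct CAR copies -> 12
        fusions, 0 fissions; identity 2*12 + 0 - 12 = 12."""
        fusions = [
            Fusion(chrom_a=f"chr{2*i+1:02d}{sa}", chrom_b=f"chr{2*i+2:02d}{sb}",
                   invert_b=False)
            for i in range(6)
            for sa, sb in (("a", "a"), ("b", "b"))
        ]
        cfg = SimConfig(
            seed=12,
            n_ancestral_chromosomes=12,
            genes_per_chromosome=40,
            lineages=[
                LineageSpec("doubled_lineage", 0.02, [WGD(loss_rate=0.0)] + fusions)
            ],
        )
        res = simulate_clade(cfg)
        assert res.lineages["doubled_lineage"].genome.n_chromosomes == 12
        ak = K.karyotype_from_genome(res.ancestor.genome)
        blocks = blocks_of_modern(res, "doubled_lineage")
        m, _ = K.wgd_multiplicity(blocks, res.ancestor.genome)
        sc = K.infer_scenario(ak, res.lineages["doubled_lineage"].genome, blocks, m)
        assert m == 2
        assert (sc.fusions, sc.fissions) == (12, 0)
        assert sc.identity_ok
        assert sc.m * sc.n_cars + sc.fissions - sc.fusions == 12

    def test_fission_two_fusions_fixture(self):
        """6 CARs + 1 fission + 2 fusions -> n=5: inferred exactly (1, 2)."""
        events = [
            Fission(chrom="chr06", breakpoint=20),
            Fusion(chrom_a="chr06.1", chrom_b="chr01", invert_b=False),
            Fusion(chrom_a="chr06.2", chrom_b="chr02", invert_b=False),
        ]
        cfg = SimConfig(
            seed=12,
            n_ancestral_chromosomes=6,
            genes_per_chromosome=40,
            lineages=[LineageSpec("reduced_lineage", 0.02, events)],
        )
        res = simulate_clade(cfg)
        assert res.lineages["reduced_lineage"].genome.n_chromosomes == 5
        ak = K.karyotype_from_genome(res.ancestor.genome)
        blocks = blocks_of_modern(res, "reduced_lineage")
        m, _ = K.wgd_multiplicity(blocks, res.ancestor.genome)
        sc = K.infer_scenario(ak, res.lineages["reduced_lineage"].genome, blocks, m)
        assert m == 1
        assert (sc.fissions, sc.fusions) == (1, 2)
        assert sc.identity_ok

    def test_identity_comparison_has_all_zero_counts(self):
        cfg = SimConfig(
            seed=3,
            n_ancestral_chromosomes=4,
            genes_per_chromosome=50,
            lineages=[LineageSpec("same", 0.0, [])],
        )
        res = simulate_clade(cfg)
        ak = K.karyotype_from_genome(res.ancestor.genome)
        blocks = blocks_of_modern(res, "same")
        sc = K.infer_scenario(ak, res.lineages["same"].genome, blocks, 1)
        assert (sc.fusions, sc.fissions, sc.translocations, sc.inversions) == (0, 0, 0, 0)
        assert sc.identity_ok

    def test_scenario_recovery_over_seeded_simulations(self):
        """50 seeded clades: fusion+fission equal the log in >=90% of
        lineages and never exceed it (parsimony is a lower bound);
        the chromosome-count identity holds everywhere."""
        rng = np.random.default_rng(11)
        lin_total = lin_exact = lin_identity = lin_bound = 0
        for rep in range(50):
            n_anc = int(rng.integers(5, 9))
            lineages = []
            for li in range(4):
                events = []
                n_now = n_anc
                if rng.random() < 0.4:
                    events.append(WGD(retention_bias=0.2))
                    n_now *= 2
                for _ in range(int(rng.integers(0, 7))):
                    if rng.random() < 0.5 and n_now >= 3:
                        events.append(Fusion())
                        n_now -= 1
                    else:
                        events.append(Fission())
                        n_now += 1
                lineages.append(
                    LineageSpec(f"sp{li+1}", float(rng.uniform(0.03, 0.12)), events)
                )
            cfg = SimConfig(
                seed=1000 + rep,
                n_ancestral_chromosomes=n_anc,
                genes_per_chromosome=800,
                lineages=lineages,
            )
            res = simulate_clade(cfg)
            blocks_by = {n: blocks_vs_ancestor(res, n) for n in res.lineages}
            ak = K.build_cars(blocks_by, res.ancestor.genome)
            for n in res.lineages:
                blocks = blocks_of_modern(res, n)
                m, _ = K.wgd_multiplicity(blocks, res.ancestor.genome)
                sc = K.infer_scenario(ak, res.lineages[n].genome, blocks, m)
                ev = {}
                for recd in res.logs[n]:
                    ev[recd["type"]] = ev.get(recd["type"], 0) + 1
                true_f, true_fi = ev.get("fusion", 0), ev.get("fission", 0)
                lin_total += 1
                lin_exact += (
                    sc.fusions == true_f
                    and sc.fissions == true_fi
                    and m == (2 if ev.get("wgd") else 1)
                )
                lin_identity += sc.identity_ok
                lin_bound += (sc.fusions + sc.fissions) <= (true_f + true_fi)
        assert lin_identity == lin_total
        assert lin_bound == lin_total
        assert lin_exact >= 0.9 * lin_total

    def test_car_recovery_monotone_under_shared_fusions(self):
        """Fusions shared by all lineages only ever merge CARs."""
        base = dict(seed=14, n_ancestral_chromosomes=5, genes_per_chromosome=60)
        counts = []
        for n_shared in (0, 1, 2):
            shared = [
                Fusion(chrom_a=f"chr{2*i+1:02d}", chrom_b=f"chr{2*i+2:02d}",
                       invert_b=False)
                for i in range(n_shared)
            ]
            cfg = SimConfig(
                **base,
                lineages=[
                    LineageSpec("p", 0.02, list(shared)),
                    LineageSpec("q", 0.03, list(shared)),
                    LineageSpec("r", 0.04, list(shared)),
                ],
            )
            res = simulate_clade(cfg)
            pivot = res.lineages["p"]
            blocks_by = {
                o: chain_blocks(
                    registry_anchor_pairs(pivot, res.lineages[o], one_to_one=True),
                    pivot.genome,
                    res.lineages[o].genome,
                )
                for o in ("q", "r")
            }
            counts.append(K.build_cars(blocks_by, pivot.genome).n_cars)
        assert counts[0] >= counts[1] >= counts[2]
        assert counts == [5, 4, 3]


class TestDotplot:
    def test_identity_comparison_is_one_diagonal_per_chromosome(self):
        cfg = SimConfig(
            seed=4,
            n_ancestral_chromosomes=3,
            genes_per_chromosome=40,
            lineages=[LineageSpec("same", 0.0, [])],
        )
        res = simulate_clade(cfg)
        blocks = blocks_of_modern(res, "same")
        table = K.dotplot_table(blocks)
        assert table["run"].nunique() == 3
        assert (table.groupby("run")["orientation"].nunique() == 1).all()

    def test_inversion_shows_an_antidiagonal_at_logged_breakpoints(self):
        cfg = SimConfig(
            seed=4,
            n_ancestral_chromosomes=1,
            genes_per_chromosome=60,
            lineages=[LineageSpec("inv", 0.0, [Inversion(chrom="chr01", start=20, end=40)])],
        )
        res = simulate_clade(cfg)
        blocks = blocks_of_modern(res, "inv")
        table = K.dotplot_table(blocks)
        minus = table[table["orientation"] == "-"]
        assert minus["run"].nunique() == 1
        # greedy chaining may absorb one boundary anchor into the
        # neighbouring forward run; the antidiagonal still sits at the
        # logged breakpoints to within one anchor
        assert 20 <= minus["order_a"].min() <= 21
        assert 38 <= minus["order_a"].max() <= 39

    def test_row_count_equals_anchor_count(self):
        cfg = SimConfig(
            seed=4,
            n_ancestral_chromosomes=2,
            genes_per_chromosome=30,
            lineages=[LineageSpec("x", 0.02, [Fusion()])],
        )
        res = simulate_clade(cfg)
        blocks = blocks_of_modern(res, "x")
        assert len(K.dotplot_table(blocks)) == sum(b.size for b in blocks)
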