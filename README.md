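# amkarya

Ancestral karyotype reconstruction from gene order, with the companion
statistics of comparative plant genomics: synteny decay, retention–trait
regression, post-WGD fractionation bias and subgenome dominance,
corrected 4dTv dating, Dollo gain/loss and clade copy-number-shift
tests — validated end-to-end by a genome-evolution simulator with a
replayable event log.

## The problem

The gene order of a modern genome is a palimpsest of its ancestor's
chromosomes, overwritten by whole-genome duplications (WGD), fusions,
fissions, inversions and gene loss. Given several modern genomes and
their all-vs-all protein hits, one can invert this process: find the
genes that are still recognizably the same (conserved genes), keep one
copy per species (one-to-one orthologs), chain them into collinear runs
(synteny blocks, SBs), merge blocks that share ancestry across species
into conserved ancestral regions (CARs ≈ ancestral chromosomes), and
explain each modern genome as the ancestral set transformed by the
fewest rearrangements. Slowly evolving genomes anchor the comparison;
the statistics around it ask *which* genes hold their ancestral
positions (methylation, expression breadth τ, TE context, π), and how
duplicated subgenomes diverge after a WGD (less- vs more-fractionated
copies, LF/MF).

## The method

Conserved genes are defined over all HSPs of a gene pair by

    CIP  = 100 · Σ ID / Σ AL      (cumulative identity percentage)
    CALP = Σ AL / L_query         (cumulative alignment length percentage)

with thresholds CIP ≥ 50 %, CALP ≥ 0.5. Blocks need more than five
anchors. CARs are connected components of pivot-genome segments glued
by blocks from ≥ 2 species. WGD multiplicity m is the modal syntenic
coverage depth over 20-gene reference windows. A lineage scenario
counts fusions as same-chromosome junctions between distinct CAR-copy
origins and fissions as extra chromosomes per origin, satisfying

    n_modern = m · n_CARs + fissions − fusions.

Around it: exponential-survival fit of the block-size distribution
(synteny decay rate λ), least-squares retention–trait regressions with
R² = r², Kruskal–Wallis over retention quartile groups, χ² (df = 1, no
continuity correction) on retained/lost counts of homeologous copies,
4dTv corrected as d = −½ ln(1 − 2p), one-sided paired t on log2 FPKM
for LF > MF dominance, Dollo parsimony (one gain, minimal losses),
exact/asymptotic Mann–Whitney copy-shift tests (P < 0.01, FC ≥ 2), and
τ = Σ(1 − x_i/x_max)/(n − 1). Details and design rationale:
[docs/methods.md](docs/methods.md).

## Worked example

The numbered scripts under `analysis/` run a complete synthetic study:
a six-chromosome ancestor (2,400 genes) evolved into five lineages with
recorded ground truth, then every pipeline stage applied to the written
interchange files (GFF3, 12-column BLAST tabular, BED, TSV, newick).

    python analysis/01_simulate.py
    python analysis/02_homology.py
    python analysis/03_synteny.py
    python analysis/04_karyotype.py
    python analysis/05_fractionation.py
    python analysis/06_genefamilies.py

Step 04 prints:

    reconstructed 6 CARs with 2400 protogenes (simulated ancestor: 6 chromosomes, 2400 genes)

    inferred scenarios vs ground truth:
       lineage  m  m_true  fusions  fusions_true  fissions  fissions_true  inversions  translocations  n_modern  identity_ok
      slowpoke  2       2        0             0         0              0           0               0        12         True
      reedling  4       4        4             4         0              0           0               0        20         True
        taroid  4       4       10            10         0              0           0               0        14         True
       yamvine  1       1        1             1         2              2           2               0         7         True
    speargrass  2       2        7             3         4              1           3               2         9         True

Every CAR of the simulated ancestor is recovered; each lineage's WGD
multiplicity, fusion and fission counts match its event log except
`speargrass`, whose fusions *preceded* its WGD — the duplication doubles
them, and the parsimonious post-WGD reading (7 fusions, 4 fissions)
still satisfies the chromosome-count identity, 2·6 + 4 − 7 = 9.
Step 05 prints, for the palaeotetraploid lineage:

    median corrected 4dTv: paralogs 0.212, slowpoke-ancestor orthologs 0.030
    LF/MF calls: 6 homeologous pairs, 6 significantly biased, true LF labelled correctly in 6/6
    mean upstream TE fraction: LF 0.115 < MF 0.217

i.e. the duplication is correctly dated older than the speciation
(divergence 0.03 planted; paralog age ≈ 0.2 planted through the WGD
paralog penalty), fractionation bias recovers the logged subgenome
labels, TE density is higher around the more-fractionated copies, and
the one-sided paired t tests find LF > MF expression in all five
tissues. Step 06 recovers all 20 planted clade losses as Dollo losses
on the focal clade's stem branch and flags 32 of the 40 planted
copy-number shifts at P < 0.01 and FC ≥ 2 with a 0.8 % false-flag rate.

Outputs land under `results/` as TSV tables (blocks, CARs, dotplots,
scenarios, LF/MF calls, TE profiles, regressions, Dollo branch counts).

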