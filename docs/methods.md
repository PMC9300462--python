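# Methods

`amkarya` reconstructs ancestral karyotypes from gene order and tests
what shapes gene-order survival. This note records the models, the
parameter choices that matter, what the simulator does and does not
emulate, and the numerical decisions a maintainer would want to know.

## The reconstruction method

All comparisons work at gene resolution: a genome is its chromosomes as
ordered, stranded gene lists, and every gene carries an integer order
index alongside its base-pair interval. Synteny logic uses only the
order indices.

**Step 1 — conserved genes.** Each query-subject protein pair is scored
over all of its BLAST HSPs:

    CIP  = 100 * Σ ID_i / Σ AL_i        (cumulative identity percentage)
    CALP = Σ AL_i / query length        (cumulative alignment length
                                         percentage, stored as a fraction)

Pairs passing CIP ≥ 50 and CALP ≥ 0.5 in *either* query direction are
conserved genes. Overlapping HSPs would let CALP exceed 1, so HSPs are
consumed by descending bitscore and later HSPs are clipped to the query
intervals not yet claimed, their AL and identity counts prorated by the
clipped fraction. On disjoint HSPs the score reduces to the plain ratio
of sums, which is what the brute-force oracle in the test suite checks.

**Step 2 — one-to-one orthologs.** Genes linked by a conserved
same-species hit within `tandem_window` (default 5) order ranks collapse
to the lowest-order representative; genes hitting only their own species
drop out; the remaining relations reduce to mutual-best pairs ranked by
(CIP, CALP, bitscore sum) with a lexicographic gene-id tie-break, so the
matching is deterministic.

**Step 3 — synteny blocks.** Within each chromosome pair, anchors are
chained greedily in genome-A order while the order gap on both genomes
stays ≤ `max_gap` (default 20) and the genome-B order stays strictly
monotone in one direction. Chains with fewer than `min_anchors`
(default 6 — "more than five" anchors read strictly; the flag is exposed
because related tools use 5) are discarded. A block's size is its anchor
count. Greedy chaining can absorb one boundary anchor across an
inversion breakpoint (a diagonal jump within the gap tolerance); the
downstream scenario logic tolerates this.

**Step 4 — CARs.** Blocks between a pivot genome and ≥ 2 other species
are merged on the pivot gene order: genes spanned by one block were
contiguous in that species, hence ancestrally, and are glued; connected
components per pivot chromosome are the conserved ancestral regions.
A junction splits two CARs only when *no* species retains a block across
it, so lineage-specific rearrangements in any one genome — including
the pivot — cannot fabricate or destroy ancestral chromosomes, while a
fusion shared by every compared genome is genuinely unresolvable and
yields a merged CAR (this limit is tested). Components supported by
fewer than 2 species are dropped and counted. Protogenes are pivot genes
anchored in ≥ 2 species, in pivot order. The natural pivot is the most
conserved genome available or a previously inferred karyotype.

**Step 5 — dotplot validation and WGD multiplicity.** The dotplot table
lists every anchor with its diagonal-run label; CARs appear as clean
diagonals/antidiagonals. Duplication multiplicity m is the mode of the
syntenic coverage depth: over non-overlapping windows of 20 reference
genes, the number of blocks overlapping at least half the window
(1 = none, 2 = one WGD, 3 = triplication). Blocks stacking over common
windows are grouped into homeologous sets.

**Step 6 — parsimonious scenario.** Each modern chromosome is
decomposed into segments labelled by (CAR, copy). Copy assignment is a
first-fit interval partition in CAR coordinates (homeologous segments
overlap and must take different copies), capped at m, with overflow
slivers folded onto the least-overlapping copy. Adjacent same-origin
segments merge only when their CAR intervals continue one run,
orientation-aware: forward–forward requires the next interval to start
where the previous ended (± `merge_gap` = 20), reverse–reverse the
mirror image, and an orientation flip requires the intervals to tile —
and counts one inversion. Then

    fusions  = Σ_chromosome (segments − 1)
    fissions = Σ_origin     (segments − 1)

and the chromosome-count identity n = m · n_CARs + fissions − fusions
holds by construction whenever every CAR copy is observed. A fission
piece re-fused in swapped order is two segments, costing one fission
plus one fusion, as it should. Translocations are reported separately —
an origin contributing < 25 % of its anchors to a chromosome dominated
by other origins — and, like inversions, stay outside the
chromosome-count identity. The identity is evaluated over chromosomes
the blocks can assign: a fragment with fewer genes than `min_anchors`
is invisible to synteny, is reported through the coverage warning, and
cannot be booked. A fusion that *precedes* a WGD is doubled by it and
is correctly inferred as two coordinated post-WGD fusions; the event
log applies events in order, so its chromosome arithmetic is
sequential.

## Companion statistics

**Synteny decay.** F(s) = fraction of anchors in blocks of size ≥ s,
non-increasing with F = 1 at the smallest size. The decay rate λ comes
from least squares on log F(s) = −λs + c over s ∈ [min_anchors, 95th
percentile of block sizes] (the upper cut avoids tail noise). F constant
over the fit range gives λ = 0 with a degenerate flag — covering both
the single-giant-block case and the all-equal-sizes case.

**Retention.** For each outgroup gene, the number of surveyed species
with a syntenic anchor; per-species totals are the column sums of the
gene × species indicator. Trait regressions are ordinary least squares
with pairwise deletion of missing values, R² = r² by construction, and
zero-variance inputs are errors, not NaNs. Quartile grouping sorts genes
by descending retention; a run of tied counts goes wholly to the group
open when the run began (the higher-retention group), which reproduces
unequal group sizes and, with few surveyed species and strong ties, can
legitimately leave a group empty — that raises a degenerate-input error
for the caller to coarsen k. Group differences use Kruskal–Wallis plus
pairwise two-sided Mann–Whitney with Benjamini–Hochberg adjustment over
the C(k,2) comparisons.

**Substitution rate.** The branch-length sum from a tip to the clade's
MRCA, for every tip below it.

**4dTv.** The transversion proportion p at fourfold-degenerate sites,
corrected for multiple hits as d = −½ ln(1 − 2p). This correction is
the largest single modelling assumption in the package: it is the
transversion analogue of a single-parameter multiple-hit correction,
strictly increasing and convex on [0, ½), undefined (flagged infinite)
at saturation p ≥ ½. Histograms use a 0.01 bin.

**Fractionation.** For two homeologous blocks over one ancestral
interval, the 2×2 table copy × (retained, lost) is tested with a
Pearson chi-square, df = 1, *without* continuity correction — intended
use has large per-block counts; tables from intervals under 10 genes
are flagged low-power but still called. The copy retaining more
ancestral genes is LF (less fractionated), ties broken by copy id.
Labels are per block pair, not chromosome-wide, because homeologous
fragments differ individually in retention.

**TE profiles.** 100-bp windows stepped by 10 bp across ±5-kb flanks
(491 windows per flank) and 40 equal gene-body bins; each window's
value is its TE-covered fraction; flank windows overlapping any
annotated gene are discarded from the group average; flanks are
oriented by strand.

**Dominance.** Per-tissue one-sided paired t tests on log2(FPKM + 1)
of LF vs MF anchor duplicates (LF > MF). The +1 offset keeps the
statistic finite for any non-negative FPKM.

**Dollo parsimony.** One gain at the MRCA of the species carrying the
orthogroup (presence threshold: copy ≥ 1), losses at the maximal
all-absent subtrees below it. This placement achieves the minimum loss
count over all single-gain placements (verified exhaustively on 8-tip
trees). Note that absence of a family from an entire clade registers as
a stem-branch loss only if the gain node lies above the clade — with a
monophyletic complement the parsimonious reading is a later gain, so
species trees should reflect the true (paraphyletic) outgroup
structure.

**Copy-number shift.** Two-sided rank-sum between clades: for combined
n ≤ 20 the U-statistic null is enumerated exactly over all group
reassignments (valid under ties, vectorized); above that, the
tie-corrected normal approximation without continuity correction,
which tracks the exact branch within 10 % on tie-free data at the
boundary and holds a 5 % nominal type-I rate on tied counts. An
orthogroup is flagged at P < 0.01 and fold change ≥ 2, with
FC = (mean_A + ε)/(mean_B + ε), ε = 0.1, so complete losses have a
defined, automatically-passing FC and are reported in their own
category. The flag's power is limited by design at small effects: a
twofold Poisson shift at 15 species per clade is flagged in roughly
29 % of replicates (the expected fold change sits exactly on the
threshold), while a fourfold shift is flagged almost always; the test
suite pins both figures.

**τ.** τ = Σ (1 − x_i/x_max)/(n − 1) over n ≥ 2 tissues; 0 uniform,
1 single-tissue; scale-invariant; undefined for an all-zero vector.

## The simulator

The generator evolves an ancestor of `n_ancestral_chromosomes` ×
`genes_per_chromosome` genes (lengths uniform 900–3000 bp in codon
multiples, spacer 2 kb, random strands) through per-lineage event lists:
WGD and triplication (each chromosome copied, copies labelled LF/MF,
then per-gene geometric loss with p_MF = p_LF (1+δ)/(1−δ) clipped to
[0, 0.95] — δ is the fractionation bias, p_LF defaults to 0.2), fusion
(uniform chromosome pair, uniform orientation), fission (uniform
internal boundary), inversion, translocation, tandem duplication and
background gene loss. Every record stores its fully realized outcome
(chromosomes, breakpoints, deleted genes, subgenome labels), so
replaying the log reproduces the descendant byte-for-byte and the
chromosome count follows the log arithmetically. One global seed;
per-lineage streams are derived by hashing (seed, lineage name), so
adding a lineage never perturbs the others.

Hit tables give every gene pair sharing a protogene a full-length hit
in both query directions with identity ≈ 100 (1 − d), d the sum of the
two branches' divergence scalars, plus a paralog penalty (default 0.15)
within a species and a small tandem divergence (0.02) for tandem
copies; optional spurious hits are short (≤ ⅓ of the query) at 25–45 %
identity. Trait tables plant retention couplings through a Gaussian
copula with mild marginals (log-normal expression σ = 0.4, beta
methylation/TE, exponential π), so the realized Pearson r stays within
about 0.03 of the planted coefficient at 5,000 genes. Expression
matrices scatter log-normally around a per-gene mean with an optional
log2 dominance shift applied to MF-subgenome genes. 4dTv site tables
draw transversions binomially at p = ½(1 − e^{−2d}), the saturation
curve whose correction returns d. Orthogroup matrices plant complete
clade losses and fold-change expansions against the realized
out-of-clade mean.

What the simulator does **not** emulate: nucleotide or protein
sequences (identities are drawn, not aligned), realistic TE families or
insertion preferences, gene length or density heterogeneity along
chromosomes, unequal rates within a lineage, gene conversion between
homeologs, and segmental (sub-chromosome-scale) duplication. Passing
tests therefore demonstrate that the pipeline recovers gene-order
history and planted statistical structure from idealized but
noise-bearing inputs — not that it is robust to annotation error or
alignment artefacts in real genomes.

## Problem sizes and verification

The analysis scripts run a clade of five lineages over a 6 × 400-gene
ancestor — large enough that every chromosome carries dozens of blocks,
small enough to run in seconds. Recovery suites use: 20 clades at 250
genes/chromosome through the full hit-table pipeline for CAR-count and
bookkeeping checks; 50 clades at 800 genes/chromosome via
registry-truth anchors for the fusion/fission equality rate, where the
residual inexactness is fission fragments below the 6-anchor block
resolution — an information limit of synteny at any scale, shrinking
with chromosome size (at 800 genes ≈ 93 % of lineages are exact, and
inferred counts never exceed the log, as parsimony requires). Null
calibration uses 2,000 replicates. All randomness in tests and in
`scripts/acceptance.py` derives from explicit seeds.

## Known limitations

- CAR construction assumes blocks are given against a single pivot;
  multi-pivot reconciliation (median-genome style) is out of scope.
- Scenario inference reports inversions and translocations but does not
  attempt a minimal inversion (reversal-distance) decomposition.
- The exact copy-shift branch enumerates C(n, n_A) reassignments; it is
  capped at combined n = 20 by default.
- The 4dTv correction assumes a uniform transversion rate across sites;
  saturated pairs are flagged rather than modelled.
- With few surveyed species, retention counts concentrate and quartile
  grouping degenerates by design; callers coarsen k.
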