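# Methods

This note documents the models and procedures implemented in `symbiomet`,
the defaults chosen where the underlying protocols leave latitude, and what
the synthetic-data validation does and does not establish.

## Coordinate and data-model conventions

All coordinates are converted to 0-based half-open intervals on load and
restored to each format's native convention on write (GFF3 and the BGC
table are 1-based inclusive externally).  Loaders reject structural
violations (duplicate ids, bad strands, non-DNA characters, incomplete
orthology tables) rather than repairing them, and errors name the file,
line, and offending identifier.  Missing Newick branch lengths default to
1.0 with a warning: the Mk likelihood needs lengths, and a constant
preserves topology-only analyses.  BGC input is a documented tabular
dialect (one row per gene) rather than GenBank regions; region products are
normalised onto a six-way class vocabulary (NRPS, PKS, terpene, hybrid,
betalactone, other), with multi-product regions mapped to `hybrid`.

## Synthetic data generator

The generator exists so that every downstream stage has an input whose
correct answer is known.

* **Species tree** — forward birth–death simulation (birth 1.0, death 0.2
  per lineage per unit time by default) conditioned on the requested tip
  count, delegated to DendroPy's sampler.  The sampler stops at the n-th
  speciation, which leaves the two newest branches at length zero; all tip
  branches are therefore extended by one exponential waiting-time draw,
  keeping the tree ultrametric with strictly positive branch lengths.
* **Binary pathway traits** — each pathway evolves independently down the
  tree as a two-state continuous-time Markov chain with gain rate g (0→1)
  and loss rate l (1→0), using the exact closed-form transition
  probabilities per branch (no event-time discretisation).  Defaults
  g = 0.02, l = 0.05 per unit branch length give the sparse, loss-biased
  presence patterns typical of secondary-metabolite clusters; the root
  state is drawn from the stationary distribution g/(g+l) unless
  overridden.  Gains and losses are recorded as parent→child state changes
  and stored as ground truth.
* **BGC emission** — each (strain, present pathway) pair emits one BGC with
  a pathway-specific gene-label architecture and protein set shared by all
  carriers, so family clustering must reproduce the trait matrix exactly;
  class frequencies follow the observed symbiont class mix (28.7% NRPS,
  25.6% PKS, 21.3% terpene, 16.3% hybrid, 2.4% betalactone, 3.6% other,
  renormalised to sum to one).
* **Assemblies** — i.i.d. uniform A/C/G/T background (50% GC, so dinucleotide
  ratio indices are ~1 under the null), with `(TTAGGG)n` / `(CCCTAA)n`
  planted at planned contig ends, genes planted at known coordinates, and
  RIP-mutated spans created by the canonical strand-symmetric signature
  (C→T at CpA, G→A at TpG).
* **Orthology tables** — per-genome totals drawn uniformly from the
  observed symbiont range 6 477–7 693; shared counts are chosen so the
  realised conserved-protein percentage matches a per-pair target within
  integer rounding (≤ 0.1 point).  Targets may be supplied directly or
  derived from patristic distance as `100·exp(−d/5)`.

Everything is driven by one integer seed through `SeedSequence` spawning;
identical configurations give byte-identical outputs.

What the generator does **not** emulate: real gene content or homology
families, codon structure, genuine sequence divergence between orthologues
(emitted same-pathway proteins are identical), compositional biases such as
the TpA suppression of real genomes, or assembly artefacts.  Passing the
validation therefore shows the algorithms are implemented correctly, not
that real data meet their assumptions.

## Telomere screen

A contig end is telomeric when a maximal tandem run of the motif (default
`TTAGGG`, reverse complement allowed) with at least `min_copies = 3` copies
starts (left end) or ends (right end) within `end_window = 500` bp of the
terminus.  Interstitial runs do not count.  Three tandem copies make a
chance hit at a genome end vanishingly unlikely (an 18-mer match within
500 bp) while tolerating degraded telomere tails; both knobs are exposed.
`complete` requires both ends, `one_end` exactly one.

## Windowed statistics

Windows tile each contig (default non-overlapping); a gene is counted in
the window containing its start coordinate, the unambiguous single
assignment.  The final partial window is kept and flagged.  GC fraction is
(G+C)/(A+C+G+T), ignoring N; all-N windows report a missing value.  Either
`gene` or `mRNA` features can be counted via the loader's `feature_type`.

## RIP indices

Per window the screen computes product = TpA/ApT, substrate =
(CpA+TpG)/(ApC+GpT), composite = product − substrate, counting overlapping
dinucleotides on the given strand.  A window is flagged only when all of
product ≥ 1.1, substrate ≤ 0.9, composite > 0 hold and both denominators
are non-zero; the genome statistic is the merged flagged span over genome
length.  The thresholds are the published defaults of the standard RIP
screening tool.  The window default here is **5 000 bp (step 2 500)**: the
sampling noise of the two ratios scales as ~1/√window, and at 1 kb the
1.1/0.9 thresholds sit well inside the null distribution of random
sequence — a uniform-random genome would have >10% of its length flagged,
swamping any biological signal of the size reported for weakly affected
genomes (~1%).  At 5 kb the random-sequence flagged fraction is ≈ 0.3–0.5%,
while genuinely RIP-mutated spans (product ≈ 3, substrate ≈ 0.2) are flagged
essentially always.  The cost is coarser boundaries: recovered affected
fractions carry an edge uncertainty of roughly one window per span
boundary, which is why planted-recovery validation uses multi-kilobase
spans on megabase contigs.

## POCP

`POCP(i,j) = 100 (C_i + C_j)/(T_i + T_j)` with `C_i` the number of genome-i
proteins in orthogroups containing both genomes — per-protein units, so C
and T are commensurable.  Orthogroup-overlap tables natively count
orthogroups, not proteins; an `orthogroup_units` flag supports that reading
(both directions collapsed to the shared orthogroup count).  Rank calls use
half-open intervals with "below 91" strict: `[0,91)` inter-genus, `[91,95)`
intra-genus/inter-species, `[95,100]` intra-species; an 87–91 band is
additionally reported as the genus-delineation zone.  The heatmap ordering
is average-linkage clustering on `100 − P`.

## Gene cluster families

The pairwise BGC distance is `1 − (J_labels + J_adjacency)/2`, where
`J_labels` is the Jaccard index of gene function-label sets and
`J_adjacency` the Jaccard index of orientation-insensitive adjacent-label
pairs.  This is a deliberate surrogate for full architectural similarity
scoring (no domain-sequence similarity, no glocal alignment mode): the
package's focus is the downstream comparative analysis, and an import path
for externally computed distance matrices is provided for users who want a
heavier metric.  Families are connected components of the graph with edges
`d ≤ 0.5` — single linkage, deterministic, input-order invariant; singleton
BGCs form singleton families.  Family ids are assigned by sorting
components on their smallest member id; the representative is the longest
member.

Fragment curation applies explicit merge/split directives always; the
automatic mode only *suggests* merging two same-genome, different-contig,
contig-edge fragments whose disjoint label sets jointly cover ≥ 80% of some
other genome's single BGC, and applies nothing without a confirmation flag
— mirroring a manual-curation step as a declarative, reviewable directives
file.  Split halves keep the parent's genomic span (per-gene coordinates
are not modelled); the log records the breakpoint.

Rarefaction uses the exact hypergeometric expectation
`E[S(n)] = Σ_f 1 − C(N−N_f, n)/C(N, n)` per group, with the exact variance
from pairwise joint-absence probabilities (union support sizes).  Binomial
coefficients are computed as exact integers.

## Pathway grouping

Two families join one pathway when their representative BGCs (i) share
architecture — same backbone class and adjacency-pair Jaccard ≥ 0.3, the
operationalisation of "genes arranged in similar ways"; (ii) share function
labels for a strict majority (> 50%) of the smaller cluster's genes; and
(iii) a strict majority of the smaller cluster's genes have a local protein
alignment (BLOSUM62, gap open −11 / extend −1, BLAST-like) with identity
> 0.50 over ≥ 0.80 coverage of the shorter protein.  Exactly half does not
qualify.  Pathways are connected components of qualifying pairs; presence
is the union of member-family presence.  Relaxing the identity floor can
only add qualifying edges, so it never splits an existing pathway.

## Mk1 ancestral-state reconstruction

The Mk1 model has a single symmetric rate μ; over a branch of length t,
`P(same) = (1+e^{−2μt})/2`.  The likelihood is computed by Felsenstein
pruning with a uniform (0.5, 0.5) root prior — the conventional default
when nothing is known about the root state; μ is maximised by bounded
search on log μ ∈ [log 1e−6, log 1e3] (tolerance 1e−8).  Constant
characters leave μ unidentifiable: the fit warns and returns the lower
boundary.  Marginal posteriors use the standard two-pass algorithm
(pruning up, conditioning down); both passes are validated against
brute-force enumeration over all internal-state assignments to 1e−10 on
trees of up to 6 tips.  A node is called present when its marginal presence
probability strictly exceeds 0.5 (marginal, not joint, reconstruction).
Acquisitions are present nodes with absent parents (the root counts when
present), losses the converse, and two or more acquisitions for one pathway
flag candidate horizontal transfer.  An asymmetric two-rate variant was
considered and deliberately left out of the default path to match the
one-parameter model the analysis is defined around.

Event recovery on simulated data matches inferred and true events by node
identity; root "acquisitions" (ancestral presence, not a branch event) are
excluded.  On the frozen regression fixture (34 tips, 100 pathways,
g = 0.02, l = 0.05, seed 7) the harness was run once and measured gain
recall 0.94 and loss recall 0.80; the regression test asserts the
pre-stated 0.8 floor.  Recall degrades as μ saturates — with high rates the
marginals flatten toward the prior and late, short-lived gains are missed;
the harness reports this but asserts nothing about saturated regimes.

## Ecology

Jaccard distance operates on family sets; a pair of all-zero profiles has
no defined similarity and is reported as distance 0 with a warning.  NMDS
minimises Kruskal stress-1 with disparities from isotonic
(pool-adjacent-violators) regression of configuration distances on
dissimilarity ranks (Kruskal's primary tie approach) and Guttman-transform
updates; restarts (default 20) start from the classical-scaling solution
plus seeded jitter, and the best restart is returned with coordinates
centred at the origin.  ANOSIM uses midranks for ties and the divisor
M/2 = n(n−1)/4.  PERMANOVA is one-way: `SS_total = Σ_{i<j} d²_ij / N`,
within-group terms analogously per group, pseudo-F with (a−1, N−a) degrees
of freedom, R² = SS_between/SS_total.  Multi-factor designs are expressed
by passing a composite label (e.g. genus × host) as the grouping factor;
sequential multi-term partitioning is out of scope.  Both tests use the
(count+1)/(perms+1) p-value estimator (999 permutations by default) so p is
never zero, with an exhaustive mode that enumerates all distinct label
assignments for small designs.  Calibration: over 2 000 null simulations
(n = 12, two groups) both tests reject at 4.95–5.0% at α = 0.05, and on 1-D
Euclidean distances the pseudo-F equals the classical one-way ANOVA F to
1e−10.

## Cophylogeny

Profile dendrograms support the correlation metric (d = 1 − Pearson r
between binary profiles; zero-variance profiles get distance 1 with a
warning) with complete linkage, and the Jaccard metric with UPGMA; the
Jaccard/UPGMA pair is the default for tanglegram comparisons, the
correlation/complete pair for standalone clustering, since both appear in
common practice and they can disagree.  Entanglement places the shared
leaves at positions 1..n in each tree, scores `Σ|pos_a − pos_b|^L`
(L = 1.5, the conventional exponent) normalised by the fully-reversed
maximum, and minimises over rotations with an iterated two-sided pass over
all internal nodes (≤ 20 rounds).  Plateau moves — rotations that leave the
score unchanged but reach an unvisited leaf-order state — are accepted,
which lets the search cross flat ridges where a root rotation only pays off
after a second rotation in the other tree; the best state visited is
returned.  Against exhaustive enumeration of all rotation states on trees
of ≤ 7 leaves the search attained the global optimum on every seeded
fixture tested (the regression test allows a 0.05 slack).

## Pipeline

Stages communicate only through the files they write.  The run manifest
records the seed, parameters, input hashes, and a SHA-256 per output;
deterministic stages are bit-reproducible from the manifest.  The single
pipeline seed fans out to per-stage sub-seeds via
`SeedSequence(seed, spawn_key=(stage_index,))`, so disabling a stage never
shifts the randomness of the others.  The packaged demo is a 12-strain,
40-pathway bundle (fixed seed) that runs end to end in a few seconds.

## Problem sizes used in validation

The validation suite runs at desk scale by design: enumeration oracles on
trees of ≤ 6 tips (100 random instances), the frozen 34-tip / 100-pathway
recovery fixture, 2 000 null simulations at n = 12 for test calibration,
megabase contigs for the genome screens, and 10⁴-draw Monte-Carlo checks
for rarefaction and trait dynamics.  Counts reported for real surveys
(hundreds of families across dozens of strains) depend on genome number,
annotation pipelines, and external tool versions and are not reproduced
here; the package validates the machinery, not those totals.

## Known limitations

* The family-clustering distance is a label/adjacency surrogate; clusters
  whose homology is visible only at the sequence level will not merge
  without an external distance matrix.
* PERMANOVA is one-way; no sequential (type-I) multi-factor partitioning.
* Marginal (not joint) ancestral reconstruction; no stochastic character
  mapping; horizontal transfer is flagged from repeated acquisitions, not
  from reconciliation.
* The RIP screen's 5 kb windows trade boundary resolution for a clean null;
  affected fractions for genomes whose RIP tracts are much shorter than
  5 kb will be underestimated.
* Real-data idiosyncrasies (fragmented assemblies, unusual base
  composition, paralogy in orthology tables) are outside what the synthetic
  validation exercises.
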