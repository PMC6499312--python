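# Methods

This note documents the models, defaults, and design choices behind
`crisischain`, and what the synthetic data do and do not emulate.

## Coordinate and orientation conventions

All internal coordinates are 0-based half-open. BEDPE and bedGraph files
are 0-based on disk; "tsv" SV tables and SNV tables are 1-based on disk
and converted on read/write. Junction sides carry a head/tail orientation
(`H`/`T`): the end of the joined fragment that faces the junction. BEDPE
strands map `+`→`T`, `-`→`H`. Intrachromosomal records are canonically
ordered (pos1 ≤ pos2, sides swapped together); `svtype` is `TRA` exactly
when the breakends sit on different chromosomes. PSL and LAST-tab readers
normalize minus-strand query intervals to forward-query coordinates.

## Uniform-spacing null and chain detection

The null model treats breakpoints as uniform per chromosome with rate
S_bp = (breakends on the chromosome across samples) / (length × samples).
The proximity p-value for a separation d is 1 − (1 − S_bp)^d, evaluated
as `-expm1(d·log1p(-s))`; naive float exponentiation loses precision at
small rates, and a test pins the log-space form against arbitrary-
precision arithmetic.

Chain detection builds one node per breakend. Gray (proximity) edges are
evaluated only between *consecutive* breakends in sorted genomic order:
because p is monotone in distance, consecutive-pair linking yields the
same connected components as all-pairs linking at O(n log n). Black (SV)
edges optionally merge gray components across chromosomes
(`link_by_sv_edges`, default on, since observed chains span chromosomes);
a component qualifies as a chain when it has ≥ b_min breakends and at
least one gray edge. Interchromosomal breakend pairs never receive gray
edges (d is undefined across chromosomes).

**Calibration.** `calibrate_thresholds` grid-searches
t ∈ {1e-2, 1e-3, 1e-4} × b_min ∈ {4, 6, 8, 10}, measuring the
false-positive rate as the fraction of uniform-null catalogs (counts
matched to the estimated rates) yielding ≥ 1 chain, and sensitivity as
planted-breakend recall. It maximizes sensitivity subject to FPR ≤ 0.05;
sensitivities within one percentage point are treated as equivalent, and
among equivalents the smaller t and then the larger b_min (the more
conservative criterion) win. On the default synthetic genome (500 null
simulations, seed 1) this selects **t = 1e-3, b_min = 10** with FPR 0.000
and sensitivity 1.00; those are the shipped `ChainConfig` defaults.

**Prevalence tests** use the two-sided Fisher exact convention (sum of
all tables with point probability ≤ observed), verified against
hypergeometric enumeration.

## Fold-back inversions and copy number

Candidates are INV calls with span < 50 kb (strict), support ≥ 3,
MAPQ ≥ 2, on ordinary chromosomes (1–22, X, Y). Depth is summarized from
150-bp bins: flanking 20-kb windows use the same bin values as the
inverted spacer (the flank/bin interpretation is a declared choice).
Calls require (i) mean of (b_D, inv_D, a_D) < 75 — an "any window"
alternative is config-exposed; (ii) a strictly monotone step in either
direction, ties rejecting; (iii) both step contrasts significant at
p < 0.02 under Welch's unequal-variance t-test (the unequal-variance
form is a declared choice; the test flavor is config-visible). Direction
(toward telomere/centromere) needs a centromere table; without one it is
"unknown". Missing bins inside a region are tolerated and counted.

CN normalization divides 10-kb window depths by the median of their GC
stratum (10 bins; a binned stand-in for a loess fit), masks
zero-mappability windows, takes log2 against the identically normalized
parental track, and clips to ±1 for reporting. Segmentation is a simple
recursive binary-split changepoint stand-in, not a full CBS/PCF
implementation.

The fold-back/chain association statistics discretize the genome into
10-kb bins for the footprint Fisher test; the edge-position null is
proportional to cluster counts (2 edge clusters per multi-cluster chain),
a declared construction since no standard one exists.

## Block models, modularity, and spacing

Cluster labels come from the same proximity criterion applied within a
chain (a new cluster starts at each non-significant consecutive gap or
chromosome change). Every SV maps to exactly one adjacency cell.
Modularity is Newman–Girvan over SV edges with fixed cluster communities,
Q = Σ_c (e_cc/m − (d_c/2m)²); it is tested against the brute-force
double-sum definition (exhaustive over all graphs on 4 nodes × all
partitions, randomized multigraphs up to 6 nodes — full exhaustion of all
6-node graph × partition pairs is combinatorially excessive for a test
suite, so 6-node coverage is a large random sample) and cross-checked
against networkx on simple graphs.

The randomized null redraws SV pairings as a uniform random perfect
matching of the engaged breakends with positions and labels fixed;
multi-edges are allowed and an SV's two ends may land in the same
cluster. Monte-Carlo enrichment p-values are floored at 1/(n_sims+1)
(add-one rule) so zero p-values are never reported; depletion is
symmetric.

Nearest-neighbor distances within clusters count mutual pairs once. The
"unit interval" for rescaling — needed because absolute spacing depends
on genomic scale — is each cluster's extent divided by (breakend count −
1); λ is the exponential MLE 1/mean of the pooled rescaled distances,
with per-sample rates and their SD reported. Only the recovery of a known
rate is asserted, not any particular absolute value, because the
normalization constant is a declared convention. Database-style inputs
are pre-filtered to 40 < breakpoints < 1500 (strict), the range where
cluster separation is reliable.

## Contig path selection

Candidates sort by query midpoint; an edge u→v exists when v starts and
ends strictly beyond u on the query and the overlap is at most
`max_microhomology` (50 bp). Edge weight is score(v) − 1/bp per query gap
− 0.5/bp per overlap − a jump penalty (15 strand switch, 20 chromosome
switch, 10 for same-chromosome jumps beyond 100 kb). These constants are
config-exposed; path-selection correctness is asserted against exhaustive
enumeration under whatever constants are set, so the defaults only need
to be sane. Paths may start/end anywhere (soft-clipped contig ends are
free). Ties break toward the lower reference coordinate, then input
order, deterministically. Microhomology = max(0, q_end(u) − q_start(v)),
insertion = max(0, q_start(v) − q_end(u)); by construction at most one is
positive per junction. E-values are carried through from input, never
recomputed, and short alignments are reported rather than filtered —
path context is the reason to retain them.

Adjacent-segment similarity aligns the two reference segments locally
(match +1, mismatch −1, gap −2 via Biopython's PairwiseAligner) against a
null of independent single-sequence shuffles (mononucleotide composition
matched); p = fraction of null scores ≥ observed, floored at
1/(n_random+1); segments under 10 bp are flagged rather than tested.

## Mutation context

Breakpoint-proximal rates use 20-kb centered windows (clipped windows are
flagged and use their true length); the background is the mean rate of
all *other* samples over identical windows, and the pooled fold-change is
mean sample rate / mean background rate with a Mann–Whitney U test across
breakpoints. Kataegis uses declared defaults — ≥ 6 consecutive same-sample
SNVs with mean inter-mutation distance ≤ 1 kb — implemented as passing
windows of exactly 6 merged when they share SNVs; the cited upstream
method's constants are external, so both parameters are config-exposed.
Kataegis/chain co-location uses 1-Mb genome bins (declared) in a Fisher
2×2 over bins.

Contig mismatch and indel rates re-align each chosen alignment's contig
segment to its reference segment with edlib and count substitution and
indel operations; a junction's rate is the mean of its two flanking
alignments, and an alignment sandwiched between two junctions contributes
to both (it cannot be uniquely assigned). The baseline is the primary
alignments of contigs built from random 1-kb loci.

The eight SV categories are id = 4·chained + 2·complex +
interchromosomal. Category mean features (microhomology, insertion,
mismatch rate, indel rate) are z-scored (population SD; zero-variance
features pass through) and clustered by average-linkage Euclidean
agglomeration; the tree is cut at the height yielding at most three
groups, so categories merging at zero height are never split. Mutational-
signature deconvolution is deliberately out of scope; a 96-trinucleotide-
context count matrix is emitted for external tools.

## Synthetic data: what it emulates, and what not

The default genome is 4 chromosomes / 180 Mb with a background break rate
of 3×10⁻⁷/bp — ~55 breakends per sample, the scale of a heavily
rearranged post-crisis clone. Background breakends are uniform and paired
uniformly at random (matching the calibration null), with orientations
drawn uniformly and DEL/DUP/INV/TRA derived from them. Planted chains
default to 6 clusters × 12 breakends over 10-kb footprints — sub-kilobase
intra-cluster spacing, the density observed in real chained
rearrangements — linked with a homophilic bias (diagonal weight 3).
Fold-back plants use 60/40/20 coverage levels around a 5-kb spacer
(matching reported spacer scales). Contigs default to 14 fragments of
60–400 bp (13 junctions) with 2–12-bp microhomologies or 2–15-bp
insertions; microhomology is physically realized by rewriting the
(synthetic, i.i.d. uniform ACGT) reference so adjacent alignments truly
overlap on the query, and the rewritten reference is returned with the
contig. Decoy candidates are short sub-fragments re-assigned to random
loci with degraded scores, mimicking ambiguous short BLAT/LAST hits.

What passing tests do **not** show about real data: no read-level error
model, mappability structure, repeat content, GC bias (unless set), or
caller-specific artifacts; background SV pairing is distance-unbiased;
kataegis plants are not strand-coordinated unless a reference is given.
The suite demonstrates correctness of the statistics under their stated
assumptions, not robustness to every artifact of real WGS.

## Numerical choices and degenerate inputs

Monte-Carlo p-values are floored (add-one rule). Welch tests on
zero-variance inputs return 1 when means agree, 0 otherwise. Fold-changes
over a zero background report infinity rather than raising. Zero-length
intervals are rejected in reciprocal overlap; span exactly 2.5 kb uses
the large-event uniqueness rule (the boundary is open in the defining
inequalities); crisis duration uses the population SD and interpolates
threshold crossings linearly. Seeds are explicit everywhere; derived
seeds stay below 2³¹.

## Known limitations

Chain detection assumes a single per-chromosome rate; regional rate
variation (e.g. fragile sites) would inflate local significance. The
block-model clusters come from genomic clustering, not community
optimization, by design. The uniqueness crosscheck operates on calls, not
raw discordant reads. Segmentation is a stand-in, adequate for boundary
recovery on clean steps only.
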