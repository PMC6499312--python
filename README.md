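# crisischain

Analysis of the catastrophic genome rearrangements that arise when cells
escape a telomere-driven crisis. Clones that survive crisis carry dense,
chained structural variants (SVs) resembling chromothripsis; `crisischain`
provides the statistical machinery to detect those chains, characterize
their repair topology, and test whether the joining process is random —
together with a synthetic-data generator so every stage is exercisable and
testable without sequencing data.

It is intended for genomics researchers working on genome instability,
chromothripsis, breakage–fusion–bridge (BFB) cycles and telomere biology
who have SV call tables (BEDPE-like), binned read-depth tracks, contig
alignment candidates, and SNV tables, and want the downstream statistics
rather than another variant caller.

## What it computes

**Chained SVs.** Under a null of uniform breakpoint spacing with
per-chromosome break rate *S*<sub>bp</sub> (breaks/bp, averaged across
samples), the probability of one or more breaks within a separation *d* is

> *P* = 1 − Binomial(0; *d*, *S*<sub>bp</sub>) = 1 − (1 − *S*<sub>bp</sub>)<sup>*d*</sup>,

computed in log space. Breakends form graph nodes; SVs contribute black
edges and significantly proximal pairs (*P* < *t*) gray edges; connected
subgraphs with ≥ *b*<sub>min</sub> breakends are chains. (*t*,
*b*<sub>min</sub>) are calibrated by simulation against randomized
catalogs; prevalence differences between sample groups use two-sided
Fisher exact tests.

**Fold-back inversions.** Short inversions (< 50 kb, ≥ 3 supporting reads,
MAPQ ≥ 2) are screened for the stepped depth profile of a sister-chromatid
fusion: mean depth over a 20-kb window before the inversion
(*b*<sub>D</sub>), over 150-bp bins across the inverted spacer
(*inv*<sub>D</sub>), and over a 20-kb window after (*a*<sub>D</sub>) must
be strictly monotone with both Welch *t*-tests at *p* < 0.02, and mean
depth < 75.

**Repair topology.** Each chain's breakends are partitioned into genomic
clusters and collapsed to a block model (diagonal = intracluster SV
counts, off-diagonal = intercluster). Newman–Girvan modularity
*Q* = Σ<sub>c</sub>(*e*<sub>cc</sub>/*m* − (*d*<sub>c</sub>/2*m*)²) is
compared against edge-randomized nulls (uniform random perfect matchings
of the engaged breakends with cluster labels fixed); Monte-Carlo
simulation gives per-cluster-pair enrichment probabilities
*P*(X ≥ *n*) = 1 − *s*, with *s* the proportion of randomized graphs with
fewer than *n* edges. Intracluster nearest-neighbor spacing is summarized
by an exponential rate λ (mutual nearest-neighbor pairs counted once).

**Contig paths.** Candidate alignments of an assembled contig become
nodes of a DAG ordered along the query; the optimal alignment set is the
highest-scoring path (dynamic programming, O(V²)). Junction microhomology
is the overlap of adjacent alignments on the query, insertions are the
gaps, and adjacent-segment sequence similarity is tested against a
shuffled-sequence null.

**Mutation context.** SNV rates in 20-kb windows centered on breakpoints
versus the mean rate of all other samples over identical intervals;
kataegis clusters (≥ 6 consecutive SNVs, mean inter-mutation distance
≤ 1 kb); contig mismatch/indel rates versus random 1-kb-locus baseline
contigs; and agglomerative (average-linkage) clustering of the eight SV
categories defined by chained × complex × interchromosomal.

## Worked example

```sh
python examples/01_chain_detection.py
```

```
per-chromosome break rates (breaks/bp):
  chr1: 2.88e-07
  ...
1 chain(s) detected in 60 SVs
  chain: 72 breakends, 36 SVs, footprint [('chr1', 36799415), ...]
planted-breakend recall: 100.00%
```

The break rate (~3×10⁻⁷/bp, about 55 breakends per 180-Mb synthetic
genome) sets the uniform null; all 72 breakends of the planted
six-cluster chain are recovered in a single chain while the
megabase-spaced background stays unchained. `examples/03_network_topology.py`
then prints the chain's block-model adjacency matrix and

```
modularity: observed 0.361 vs randomized -0.010
```

— the positive observed coefficient against a near-zero randomized mean
is the signature of preferentially intracluster (homophilic) repair.
The remaining examples cover fold-back calling (exact recovery of a
planted 5-kb spacer), contig path selection (13/13 junctions with exact
microhomology/insertion lengths), and mutation context (an ~8-fold
breakpoint-proximal SNV excess and ~3.85-fold contig mismatch excess
recovered from plants).

A thin CLI mirrors the library: `crisischain simulate | unique | chains |
foldbacks | network | contigpath | mutations` (see `crisischain --help`).

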