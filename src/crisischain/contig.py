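"""Optimal alignment-path selection for assembled contigs.

Candidate alignments of one contig become nodes of a directed acyclic
graph ordered along the query; edges link order-compatible alignments
(downstream starts and ends strictly beyond upstream, overlap at most the
microhomology cap) and carry the downstream alignment score minus
penalties for query gaps (insertions), query overlaps (microhomology) and
the class of rearrangement the transition implies.  The chosen set of
alignments is the highest-scoring path, found by dynamic programming in
query order (O(V^2)).  Junctions of the chosen path are annotated with
microhomology (query overlap), insertion (query gap, with the inserted
sequence), the transition class, and a random-sampling similarity p-value
between the adjacent reference segments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from Bio import Align

from .io import AlignmentCandidate


@dataclass(frozen=True)
class ScoringConfig:
    """Edge-cost constants for the alignment DAG.

    Path-selection correctness is independent of the constants (it is
    checked against exhaustive enumeration under whatever is set); the
    defaults merely prefer long confident alignments, mildly discourage
    large unexplained transitions, and cap usable microhomology.
    """

    gap_penalty: float = 1.0          # per bp of query gap (insertion)
    overlap_penalty: float = 0.5      # per bp of query overlap (microhomology)
    jump_strand: float = 15.0         # strand switch on the same chromosome
    jump_chrom: float = 20.0          # chromosome switch
    jump_far: float = 10.0            # same-chromosome jump beyond far_distance
    far_distance: int = 100_000
    max_microhomology: int = 50


@dataclass
class AlignmentGraph:
    nodes: list[AlignmentCandidate]   # sorted by query midpoint
    edges: dict[int, list[tuple[int, float]]]   # u -> [(v, weight)]
    scoring: ScoringConfig


@dataclass
class JunctionAnnotation:
    microhomology: int
    insertion: int
    insertion_seq: str = ""
    transition: str = ""              # intra | intra-far | strand-switch | interchrom
    partner_distance_mb: float | None = None
    direction: str = ""               # up | down along the reference
    similarity_p: float | None = None
    similarity_flagged: bool = False


@dataclass
class ContigPath:
    alignments: list[AlignmentCandidate]
    junctions: list[JunctionAnnotation]
    score: float

    @property
    def n_svs(self) -> int:
        return len(self.alignments) - 1


def _transition(u: AlignmentCandidate, v: AlignmentCandidate,
                cfg: ScoringConfig) -> tuple[str, float]:
    if u.r_chrom != v.r_chrom:
        return "interchrom", cfg.jump_chrom
    if u.strand != v.strand:
        return "strand-switch", cfg.jump_strand
    dist = abs(v.r_start - u.r_end)
    if dist > cfg.far_distance:
        return "intra-far", cfg.jump_far
    return "intra", 0.0


def build_graph(candidates: list[AlignmentCandidate],
                scoring: ScoringConfig | None = None) -> AlignmentGraph:
    """Build the query-ordered alignment DAG.

    An edge (u, v) exists iff v starts after u starts and extends beyond
    u's end on the query, with query overlap at most ``max_microhomology``.
    Nested query intervals never connect.  Edge weight = score(v) minus
    gap/overlap/jump penalties.
    """
    if not candidates:
        raise ValueError("need at least one candidate alignment")
    cfg = scoring or ScoringConfig()
    nodes = sorted(candidates,
                   key=lambda c: (c.q_start + c.q_end, c.q_start, c.r_chrom,
                                  c.r_start))
    edges: dict[int, list[tuple[int, float]]] = {i: [] for i in range(len(nodes))}
    for ui, u in enumerate(nodes):
        for vi, v in enumerate(nodes):
            if vi == ui:
                continue
            if not (v.q_start > u.q_start and v.q_end > u.q_end):
                continue
            overlap = u.q_end - v.q_start
            if overlap > cfg.max_microhomology:
                continue
            gap = max(0, -overlap)
            mh = max(0, overlap)
            _, jump = _transition(u, v, cfg)
            w = v.score - cfg.gap_penalty * gap - cfg.overlap_penalty * mh - jump
            edges[ui].append((vi, w))
    return AlignmentGraph(nodes, edges, cfg)


def best_path(graph: AlignmentGraph) -> ContigPath:
    """Highest-scoring path through the alignment DAG.

    Dynamic programming in query order; a path may start and end at any
    node (unaligned contig ends carry no penalty).  Ties break
    deterministically toward the lower reference coordinate, then graph
    order.
    """
    nodes = graph.nodes
    if not nodes:
        raise ValueError("empty alignment graph")
    n = len(nodes)
    dp = [nodes[i].score for i in range(n)]
    back: list[int | None] = [None] * n

    def tie_key(i: int | None):
        # lower reference coordinate, then graph order; None (path start)
        # sorts first so starting fresh wins exact ties
        if i is None:
            return ("", -1, -1)
        return (nodes[i].r_chrom, nodes[i].r_start, i)

    # nodes are sorted by query midpoint, and edges require strictly larger
    # (q_start, q_end), so predecessors always sort before successors
    for u in range(n):
        for v, w in graph.edges[u]:
            cand = dp[u] + w
            if cand > dp[v] + 1e-12 or \
                    (abs(cand - dp[v]) <= 1e-12 and tie_key(u) < tie_key(back[v])):
                dp[v] = cand
                back[v] = u
    best = min(range(n), key=lambda i: (-dp[i],) + tie_key(i))
    path = []
    cur: int | None = best
    while cur is not None:
        path.append(nodes[cur])
        cur = back[cur]
    path.reverse()
    junctions = [JunctionAnnotation(
        microhomology=max(0, u.q_end - v.q_start),
        insertion=max(0, v.q_start - u.q_end),
        transition=_transition(u, v, graph.scoring)[0])
        for u, v in zip(path, path[1:])]
    return ContigPath(path, junctions, float(dp[best]))


def annotate_junctions(path: ContigPath, contig_seq: str | None = None,
                       reference: dict[str, str] | None = None,
                       n_random: int = 500, seed: int = 1,
                       similarity: bool = False) -> ContigPath:
    """Fill junction annotations of a chosen path.

    Microhomology is the overlap of adjacent alignments on the query;
    an insertion is the query gap between them (sequence extracted from
    the contig when provided); at most one of the two is positive per
    junction.  With ``similarity=True`` and a reference, each junction also
    gets the adjacent-segment similarity p-value.
    """
    rng = np.random.default_rng(seed)
    out = []
    for (u, v), jx in zip(zip(path.alignments, path.alignments[1:]), path.junctions):
        mh = max(0, u.q_end - v.q_start)
        ins = max(0, v.q_start - u.q_end)
        if u.q_end > v.q_end or u.q_start >= v.q_start:
            raise ValueError("chosen alignments are not properly ordered on the query")
        ins_seq = ""
        if ins and contig_seq is not None:
            ins_seq = contig_seq[u.q_end:v.q_start]
        dist_mb = None
        direction = ""
        if u.r_chrom == v.r_chrom:
            delta = v.r_start - u.r_end
            dist_mb = abs(delta) / 1e6
            direction = "down" if delta >= 0 else "up"
        jx = replace(jx, microhomology=mh, insertion=ins, insertion_seq=ins_seq,
                     partner_distance_mb=dist_mb, direction=direction)
        if similarity and reference is not None:
            seed_j = int(rng.integers(0, 2**31 - 1))
            res = adjacent_similarity(u, v, reference, n_random=n_random,
                                      seed=seed_j)
            jx = replace(jx, similarity_p=res[0], similarity_flagged=res[1])
        out.append(jx)
    return ContigPath(path.alignments, out, path.score)


def _aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def adjacent_similarity(u: AlignmentCandidate, v: AlignmentCandidate,
                        reference: dict[str, str], n_random: int = 500,
                        seed: int = 1, match: float = 1.0,
                        mismatch: float = -1.0, gap: float = -2.0,
                        ) -> tuple[float | None, bool]:
    """Similarity p-value between two adjacent reference segments.

    The local alignment score of the two segments is compared against a
    null of composition-matched random sequences (independent shuffles of
    each segment); p = fraction of null scores >= observed, floored at
    1/(n_random + 1).  Segments shorter than 10 bp give (None, True).
    """
    seg_u = reference[u.r_chrom][u.r_start:u.r_end]
    seg_v = reference[v.r_chrom][v.r_start:v.r_end]
    if len(seg_u) < 10 or len(seg_v) < 10:
        return None, True
    rng = np.random.default_rng(seed)
    aligner = _aligner(match, mismatch, gap)
    observed = aligner.score(seg_u, seg_v)
    letters_u, letters_v = list(seg_u), list(seg_v)
    n_ge = 0
    for _ in range(n_random):
        ru = "".join(rng.permutation(letters_u))
        rv = "".join(rng.permutation(letters_v))
        if aligner.score(ru, rv) >= observed:
            n_ge += 1
    p = max(n_ge / n_random, 1.0 / (n_random + 1))
    return float(p), False
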