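"""Block-model topology of chained rearrangements.

Each chain's breakends are partitioned into genomic breakpoint clusters
(reusing the binomial proximity criterion), and the chain collapses to a
block model: one node per cluster, diagonal adjacency cells counting
intracluster SVs and off-diagonal cells counting SVs between cluster
pairs.  Repair randomness is probed three ways: Newman-Girvan modularity of
the SV edges against edge-randomized nulls (uniform random perfect
matchings of the engaged breakends, cluster labels fixed), Monte-Carlo
per-cluster-pair enrichment/depletion p-values, and the nearest-neighbor
spacing rate lambda of intracluster breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .chains import BreakRateModel, Chain, proximity_pvalue


def cluster_breakends(chain: Chain, rates: BreakRateModel, t: float = 1e-3,
                      ) -> list[int]:
    """Partition a chain's breakends into genomic clusters.

    Breakends are scanned in sorted genomic order; a new cluster starts
    whenever the chromosome changes or the separation from the previous
    breakend is not significant under the proximity test at level ``t``.
    Returns one cluster label per chain breakend (chain order).
    """
    if not chain.breakends:
        raise ValueError("empty chain")
    order = sorted(range(len(chain.breakends)),
                   key=lambda i: (chain.breakends[i].chrom, chain.breakends[i].pos))
    labels = [0] * len(order)
    current = 0
    for prev, cur in zip(order, order[1:]):
        a, b = chain.breakends[prev], chain.breakends[cur]
        if a.chrom != b.chrom or \
                proximity_pvalue(b.pos - a.pos, rates.rate(b.chrom)) >= t:
            current += 1
        labels[cur] = current
    return labels


@dataclass
class BlockModel:
    """Cluster-level summary of a chain's SV edges."""

    n_clusters: int
    adjacency: np.ndarray          # symmetric; diagonal = intracluster counts
    degrees: np.ndarray            # intercluster SVs per cluster (row sums, no diagonal)
    edge_labels: list[tuple[int, int]]   # one (ci, cj) per SV, ci <= cj
    node_labels: list[int]         # cluster label per engaged breakend


def build_block_model(chain: Chain, labels: Sequence[int]) -> BlockModel:
    """Collapse a chain to its block model under the given cluster labels.

    Every SV whose two ends lie in the chain contributes exactly once:
    to a diagonal cell when both ends share a cluster, else to one
    unordered off-diagonal pair.
    """
    if len(labels) != len(chain.breakends):
        raise ValueError("labels must cover all breakends of the chain")
    k = max(labels) + 1
    adj = np.zeros((k, k), dtype=int)
    edge_labels = []
    node_labels = []
    for i, j in chain.sv_edges:
        ci, cj = sorted((labels[i], labels[j]))
        adj[ci, cj] += 1
        if ci != cj:
            adj[cj, ci] += 1
        edge_labels.append((ci, cj))
        node_labels.extend((labels[i], labels[j]))
    degrees = adj.sum(axis=1) - np.diag(adj)
    return BlockModel(k, adj, degrees, edge_labels, node_labels)


def modularity(edge_labels: Iterable[tuple[int, int]]) -> float:
    """Newman-Girvan modularity of SV edges under fixed community labels.

    ``edge_labels`` holds one (community_u, community_v) pair per edge.
    Q = sum_c (e_cc / m - (d_c / 2m)^2), where m is the edge count, e_cc
    the number of intra-community edges and d_c the community degree sum
    (each edge endpoint counts once; self-community edges count twice).
    """
    edge_labels = list(edge_labels)
    m = len(edge_labels)
    if m == 0:
        raise ValueError("modularity undefined for a graph with no edges")
    e_cc: dict[int, int] = {}
    d_c: dict[int, int] = {}
    for cu, cv in edge_labels:
        if cu == cv:
            e_cc[cu] = e_cc.get(cu, 0) + 1
        d_c[cu] = d_c.get(cu, 0) + 1
        d_c[cv] = d_c.get(cv, 0) + 1
    return float(sum(e_cc.get(c, 0) / m - (d_c[c] / (2 * m)) ** 2 for c in d_c))


def randomize_edges(node_labels: Sequence[int], rng: np.random.Generator,
                    ) -> list[tuple[int, int]]:
    """One uniform random perfect matching of the engaged breakends.

    Breakend positions and cluster labels stay fixed; only the pairing is
    redrawn, modelling a fully random end-joining process.  Returns edge
    labels (ci, cj) with ci <= cj; the edge count is conserved.
    """
    n = len(node_labels)
    if n % 2:
        raise ValueError("need an even number of engaged breakends")
    perm = rng.permutation(n)
    out = []
    for a in range(0, n, 2):
        ci, cj = node_labels[perm[a]], node_labels[perm[a + 1]]
        out.append((min(ci, cj), max(ci, cj)))
    return out


def modularity_comparison(models: Sequence[BlockModel], n_random: int = 1000,
                          seed: int = 1):
    """Observed vs randomized modularity per chain, with a paired t-test.

    For each chain's block model, Q_obs is compared with the mean Q over
    ``n_random`` random perfect matchings of its engaged breakends.
    Returns (q_obs array, q_rand_mean array, paired-t p-value).
    """
    rng = np.random.default_rng(seed)
    q_obs, q_rand = [], []
    for bm in models:
        q_obs.append(modularity(bm.edge_labels))
        qs = [modularity(randomize_edges(bm.node_labels, rng))
              for _ in range(n_random)]
        q_rand.append(float(np.mean(qs)))
    q_obs, q_rand = np.array(q_obs), np.array(q_rand)
    if len(models) >= 2:
        p = float(stats.ttest_rel(q_obs, q_rand).pvalue)
    else:
        p = float("nan")
    return q_obs, q_rand, p


@dataclass(frozen=True)
class EnrichmentResult:
    cluster_pair: tuple[int, int]
    observed: int
    p_enriched: float   # P(X >= n) = 1 - s, s = fraction of sims with < n edges
    p_depleted: float


def intercluster_enrichment(model: BlockModel, n_sims: int = 1000, seed: int = 1,
                            ) -> list[EnrichmentResult]:
    """Monte-Carlo enrichment/depletion of each cluster pair's SV count.

    ``n_sims`` random perfect matchings give the null distribution of edge
    counts per cluster pair; p_enriched = 1 - (fraction of sims with fewer
    than the observed count), floored at 1/(n_sims + 1) so no zero p-values
    are reported; depletion is symmetric.
    """
    if n_sims < 100:
        raise ValueError("need at least 100 simulations")
    rng = np.random.default_rng(seed)
    k = model.n_clusters
    pairs = [(i, j) for i in range(k) for j in range(i, k)]
    obs = {p: 0 for p in pairs}
    for e in model.edge_labels:
        obs[e] += 1
    below = {p: 0 for p in pairs}
    above = {p: 0 for p in pairs}
    for _ in range(n_sims):
        counts = {p: 0 for p in pairs}
        for e in randomize_edges(model.node_labels, rng):
            counts[e] += 1
        for p in pairs:
            if counts[p] < obs[p]:
                below[p] += 1
            elif counts[p] > obs[p]:
                above[p] += 1
    floor = 1.0 / (n_sims + 1)
    out = []
    for p in pairs:
        p_enr = max(1.0 - below[p] / n_sims, floor)
        p_dep = max(1.0 - above[p] / n_sims, floor)
        out.append(EnrichmentResult(p, obs[p], p_enr, p_dep))
    return out


# ---------------------------------------------------------------------------
# Nearest-neighbor spacing


@dataclass
class SpacingFit:
    distances: np.ndarray        # deduplicated nearest-neighbor distances (bp)
    rescaled: np.ndarray         # distances over the declared unit interval
    lam: float                   # pooled exponential-MLE rate
    per_sample: dict[str, float]
    sd: float                    # SD of per-sample rates


def nn_distances(positions: Sequence[int]) -> list[int]:
    """Nearest-neighbor distance per point on a line, mutual pairs counted
    once (if x and y are each other's nearest neighbor, d_xy enters once)."""
    pos = np.sort(np.asarray(positions))
    n = len(pos)
    if n < 2:
        return []
    gaps = np.diff(pos)
    nn = np.empty(n)
    nn[0], nn[-1] = gaps[0], gaps[-1]
    if n > 2:
        nn[1:-1] = np.minimum(gaps[:-1], gaps[1:])
    out = []
    skip = np.zeros(n, dtype=bool)
    for i in range(n - 1):
        if nn[i] == gaps[i] and nn[i + 1] == gaps[i] and not skip[i]:
            # mutual nearest neighbors: count the shared distance once
            skip[i + 1] = True
            out.append(int(gaps[i]))
        elif not skip[i]:
            out.append(int(nn[i]))
    if not skip[-1]:
        out.append(int(nn[-1]))
    return out


def fit_rate(distances: Sequence[float]) -> float:
    """Exponential MLE: lambda = 1 / mean distance."""
    d = np.asarray(distances, dtype=float)
    if len(d) == 0 or d.mean() <= 0:
        raise ValueError("need at least one positive distance")
    return float(1.0 / d.mean())


def nn_rate(per_sample_clusters: Mapping[str, Sequence[Sequence[int]]],
            ) -> SpacingFit:
    """Breakage rate lambda from intracluster nearest-neighbor spacing.

    Each cluster's distances are rescaled by that cluster's mean spacing
    unit (cluster extent / (breakend count - 1)), the declared "unit
    interval" that makes rates comparable across samples of different
    genomic scale; lambda is the exponential MLE 1/mean of the pooled
    rescaled distances, with per-sample rates and their SD reported.
    """
    all_raw, all_scaled = [], []
    per_sample: dict[str, float] = {}
    for sample, clusters in per_sample_clusters.items():
        scaled = []
        for positions in clusters:
            pos = np.sort(np.asarray(positions))
            if len(pos) < 2 or pos[-1] == pos[0]:
                continue
            unit = (pos[-1] - pos[0]) / (len(pos) - 1)
            d = nn_distances(pos)
            all_raw.extend(d)
            scaled.extend(np.asarray(d) / unit)
        if scaled:
            per_sample[sample] = fit_rate(scaled)
            all_scaled.extend(scaled)
    if not all_scaled:
        raise ValueError("no eligible nearest-neighbor distances")
    rates = np.array(list(per_sample.values()))
    return SpacingFit(np.array(all_raw), np.array(all_scaled),
                      fit_rate(all_scaled), per_sample,
                      float(rates.std(ddof=1)) if len(rates) > 1 else 0.0)


def db_sample_filter(counts: Mapping[str, int]) -> list[str]:
    """Samples suitable for cluster separation: 40 < breakpoints < 1500."""
    for sample, n in counts.items():
        if n < 0:
            raise ValueError(f"negative breakpoint count for {sample}")
    return [s for s, n in counts.items() if 40 < n < 1500]
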