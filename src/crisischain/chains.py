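"""Chained-SV detection by a binomial spatial-proximity test plus graph
clustering, with randomization-based threshold calibration and Fisher tests
of chain prevalence between sample groups.

The null model is uniform breakpoint spacing at a per-chromosome break rate
``s`` (breaks/bp).  The probability of seeing one or more breaks within a
separation ``d`` is ``1 - (1 - s)**d``; breakend pairs whose separation is
significant at level ``t`` are linked by proximity ("gray") edges, SVs
contribute "black" edges, and connected subgraphs with at least ``b_min``
breakends qualify as chains.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import SVRecord
from .simulate import ChainSpec, GenomeModel, plant_chain, simulate_background_breaks


@dataclass(frozen=True)
class BreakRateModel:
    """Mean breaks per bp per chromosome, across samples."""

    s_bp: dict[str, float]

    def __post_init__(self):
        for chrom, s in self.s_bp.items():
            if not np.isfinite(s) or s < 0:
                raise ValueError(f"invalid break rate for {chrom}")

    def rate(self, chrom: str) -> float:
        return self.s_bp[chrom]


@dataclass(frozen=True)
class ChainConfig:
    """Gray-edge significance level and minimum chain size.

    The shipped defaults are the output of ``calibrate_thresholds`` on the
    default synthetic genome (see docs/methods.md).
    """

    t: float = 1e-3
    b_min: int = 10
    link_by_sv_edges: bool = True

    def __post_init__(self):
        if not 0 < self.t < 1:
            raise ValueError("t must lie in (0, 1)")
        if self.b_min < 2:
            raise ValueError("b_min must be >= 2")


@dataclass
class Breakend:
    chrom: str
    pos: int
    orient: str
    record_index: int
    end: int  # 0 or 1 within the record


@dataclass
class Chain:
    """A connected subgraph of breakends linked by proximity/SV edges."""

    sample: str
    breakends: list[Breakend]
    sv_edges: list[tuple[int, int]]      # indices into ``breakends``
    gray_edges: list[tuple[int, int]]
    record_indices: list[int]
    cluster_labels: list[int] | None = None

    def __len__(self) -> int:
        return len(self.breakends)

    def footprint(self) -> list[tuple[str, int, int]]:
        """Per-chromosome (chrom, min, max) genomic intervals of members."""
        by_chrom: dict[str, list[int]] = {}
        for be in self.breakends:
            by_chrom.setdefault(be.chrom, []).append(be.pos)
        return [(c, min(ps), max(ps) + 1) for c, ps in sorted(by_chrom.items())]


def estimate_break_rate(catalogs: list[list[SVRecord]], genome: GenomeModel,
                        ) -> BreakRateModel:
    """S_bp[chrom] = breakends on chrom across samples / (length x n_samples)."""
    if not catalogs:
        raise ValueError("need at least one sample catalog")
    counts: dict[str, int] = {c: 0 for c in genome.chromosomes}
    for records in catalogs:
        for rec in records:
            for chrom, _, _ in rec.breakends():
                if chrom not in counts:
                    raise KeyError(f"chromosome {chrom} absent from genome model")
                counts[chrom] += 1
    n = len(catalogs)
    return BreakRateModel({c: counts[c] / (genome.chromosomes[c] * n)
                           for c in counts})


def proximity_pvalue(d, s):
    """P(one or more breaks within d bp) = 1 - (1 - s)**d, in log space.

    Vectorised over ``d``.  Monotone non-decreasing in both arguments.
    """
    d = np.asarray(d, dtype=float)
    s = float(s)
    if (d < 0).any():
        raise ValueError("separation must be >= 0")
    if not 0 <= s <= 1:
        raise ValueError("break rate must lie in [0, 1]")
    if s == 1.0:
        out = np.where(d > 0, 1.0, 0.0)
    else:
        out = -np.expm1(d * np.log1p(-s))
    return float(out) if out.ndim == 0 else out


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def detect_chains(records: list[SVRecord], rates: BreakRateModel,
                  cfg: ChainConfig | None = None) -> list[Chain]:
    """Chains in a single-sample catalog.

    One node per breakend; gray edges link consecutive same-chromosome
    breakends in sorted order whose proximity p-value is below ``t``
    (consecutive pairs suffice: p is monotone in distance, so the connected
    components match the all-pairs construction).  Components with at least
    ``b_min`` breakends are returned; with ``link_by_sv_edges`` the SV
    (black) edges also merge components, letting chains span chromosomes.
    """
    cfg = cfg or ChainConfig()
    nodes: list[Breakend] = []
    for ri, rec in enumerate(records):
        (c1, p1, o1), (c2, p2, o2) = rec.breakends()
        nodes.append(Breakend(c1, p1, o1, ri, 0))
        nodes.append(Breakend(c2, p2, o2, ri, 1))
    if not nodes:
        return []
    sample = records[0].sample

    uf = _UnionFind(len(nodes))
    gray: list[tuple[int, int]] = []
    by_chrom: dict[str, list[int]] = {}
    for i, be in enumerate(nodes):
        by_chrom.setdefault(be.chrom, []).append(i)
    for chrom, idx in by_chrom.items():
        idx.sort(key=lambda i: nodes[i].pos)
        s = rates.rate(chrom)
        for a, b in zip(idx, idx[1:]):
            d = nodes[b].pos - nodes[a].pos
            if proximity_pvalue(d, s) < cfg.t:
                gray.append((a, b))
                uf.union(a, b)

    # gray edges define cluster connectivity; SV edges optionally merge the
    # gray components into cross-chromosome chains
    if cfg.link_by_sv_edges:
        for ri in range(len(records)):
            uf.union(2 * ri, 2 * ri + 1)

    comps: dict[int, list[int]] = {}
    for i in range(len(nodes)):
        comps.setdefault(uf.find(i), []).append(i)
    gray_endpoints = {a for a, _ in gray}

    chains = []
    for members in comps.values():
        # a chain needs proximity evidence (>= 1 gray edge) and b_min breakends
        if len(members) < cfg.b_min or not gray_endpoints.intersection(members):
            continue
        members = sorted(members, key=lambda i: (nodes[i].chrom, nodes[i].pos))
        index = {node: k for k, node in enumerate(members)}
        mset = set(members)
        sv_edges = [(index[2 * ri], index[2 * ri + 1])
                    for ri in {nodes[i].record_index for i in members}
                    if 2 * ri in mset and 2 * ri + 1 in mset]
        gray_edges = [(index[a], index[b]) for a, b in gray if a in mset and b in mset]
        chains.append(Chain(
            sample=sample,
            breakends=[nodes[i] for i in members],
            sv_edges=sorted(sv_edges),
            gray_edges=sorted(gray_edges),
            record_indices=sorted({nodes[i].record_index for i in members}),
        ))
    chains.sort(key=lambda c: (c.breakends[0].chrom, c.breakends[0].pos))
    return chains


@dataclass
class CalibrationResult:
    t: float
    b_min: int
    table: pd.DataFrame  # columns: t, b_min, fpr, sensitivity


DEFAULT_GRID = tuple(itertools.product((1e-2, 1e-3, 1e-4), (4, 6, 8, 10)))


def calibrate_thresholds(genome: GenomeModel, rates: BreakRateModel,
                         n_sims: int = 500,
                         grid=DEFAULT_GRID,
                         seed: int = 1,
                         chain_spec: ChainSpec | None = None,
                         fpr_bound: float = 0.05,
                         n_plants: int = 25) -> CalibrationResult:
    """Grid-search (t, b_min) by simulation.

    False-positive rate: fraction of ``n_sims`` uniform-null catalogs
    (per-chromosome counts matched to ``rates``) that yield at least one
    chain.  Sensitivity: mean fraction of planted breakends recovered in
    chains over ``n_plants`` planted-chain catalogs.  Returns the grid point
    maximising sensitivity subject to FPR <= ``fpr_bound``; ties prefer the
    smaller t, then the larger b_min (the more conservative setting).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty calibration grid")
    null_model = GenomeModel(genome.chromosomes,
                             {c: rates.rate(c) for c in genome.chromosomes})
    null_catalogs = simulate_background_breaks(null_model, n_sims, seed=seed)
    spec = chain_spec or ChainSpec()
    plants = [plant_chain(genome, spec, seed=seed + 1 + k) for k in range(n_plants)]
    backgrounds = simulate_background_breaks(null_model, n_plants, seed=seed + 10_000)

    rows = []
    for t, b_min in grid:
        cfg = ChainConfig(t=t, b_min=b_min)
        fp = sum(bool(detect_chains(cat, rates, cfg)) for cat in null_catalogs)
        recalls = []
        for (records, labels), bg in zip(plants, backgrounds):
            merged = records + [  # background relabelled into the same sample
                type(r)(records[0].sample, r.chrom1, r.pos1, r.orient1,
                        r.chrom2, r.pos2, r.orient2, r.svtype, r.support, r.mapq)
                for r in bg]
            chains_found = detect_chains(merged, rates, cfg)
            in_chain = {(be.chrom, be.pos) for ch in chains_found for be in ch.breakends}
            hit = sum((c, p) in in_chain for c, p, _ in labels)
            recalls.append(hit / len(labels))
        rows.append({"t": t, "b_min": b_min, "fpr": fp / n_sims,
                     "sensitivity": float(np.mean(recalls))})
    table = pd.DataFrame(rows)
    ok = table[table.fpr <= fpr_bound]
    pool = (ok if len(ok) else table).copy()
    # sensitivities within one percentage point are treated as equivalent;
    # among equivalent settings prefer the smaller t, then the larger b_min
    # (the more conservative gray-edge criterion)
    pool["sens_band"] = pool.sensitivity.round(2)
    best = pool.sort_values(["sens_band", "t", "b_min"],
                            ascending=[False, True, False]).iloc[0]
    return CalibrationResult(float(best.t), int(best.b_min), table)


def chain_prevalence_test(group_a: tuple[int, int], group_b: tuple[int, int]) -> float:
    """Two-sided Fisher exact p for chain prevalence between two groups.

    ``group_a`` and ``group_b`` are (positive samples, total samples); the
    test is on the 2x2 table [[a_pos, a_neg], [b_pos, b_neg]], two-sided by
    the standard sum-of-at-most-as-probable-tables rule.
    """
    (a_pos, a_tot), (b_pos, b_tot) = group_a, group_b
    if min(a_pos, b_pos) < 0 or a_tot < a_pos or b_tot < b_pos:
        raise ValueError("need totals >= positives >= 0")
    table = [[a_pos, a_tot - a_pos], [b_pos, b_tot - b_pos]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
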