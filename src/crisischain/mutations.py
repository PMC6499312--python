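"""Mutation context of rearrangements: SNV rates around breakpoints,
kataegis detection, contig mismatch/indel rates against a random-locus
baseline, and the eight-category SV signature clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .contig import ContigPath
from .io import AlignmentCandidate, SNVRecord
from .simulate import GenomeModel, revcomp


# ---------------------------------------------------------------------------
# SNV rates around breakpoints


@dataclass(frozen=True)
class BreakpointMutationRate:
    sample: str
    chrom: str
    pos: int
    interval: tuple[int, int]
    clipped: bool
    count: int
    rate: float              # SNVs/bp in the sample over the interval
    background_rate: float   # mean rate of all other samples, same interval


@dataclass
class MutationRateSummary:
    records: list[BreakpointMutationRate]
    fold_change: float       # pooled sample rate / pooled background rate
    pvalue: float            # Mann-Whitney over breakpoints


def sv_mutation_rates(breakpoints: list[tuple[str, str, int]],
                      snvs_by_sample: dict[str, list[SNVRecord]],
                      genome: GenomeModel, halfwidth: int = 10_000,
                      ) -> MutationRateSummary:
    """SNV rates in 20-kb intervals centered on each breakpoint.

    ``breakpoints`` holds (sample, chrom, pos) triples.  The background at
    each interval is the mean rate across all *other* samples over the
    identical interval; the pooled fold-change compares mean sample rate to
    mean background rate, with a Mann-Whitney U p-value across breakpoints.
    Intervals clipped at chromosome ends are flagged and use their actual
    length.
    """
    if len(snvs_by_sample) < 2:
        raise ValueError("need at least two samples for a background")
    pos_index = {
        s: {c: np.sort([v.pos for v in lst if v.chrom == c])
            for c in {v.chrom for v in lst}}
        for s, lst in snvs_by_sample.items()}

    def count_in(sample, chrom, lo, hi) -> int:
        pos = pos_index.get(sample, {}).get(chrom)
        if pos is None or not len(pos):
            return 0
        return int(np.searchsorted(pos, hi) - np.searchsorted(pos, lo))

    records = []
    for sample, chrom, pos in breakpoints:
        length = genome.chromosomes[chrom]
        lo, hi = max(0, pos - halfwidth), min(length, pos + halfwidth)
        clipped = (hi - lo) < 2 * halfwidth
        span = hi - lo
        count = count_in(sample, chrom, lo, hi)
        others = [count_in(s, chrom, lo, hi) / span
                  for s in snvs_by_sample if s != sample]
        records.append(BreakpointMutationRate(
            sample, chrom, pos, (lo, hi), clipped, count, count / span,
            float(np.mean(others))))
    sample_rates = np.array([r.rate for r in records])
    bg_rates = np.array([r.background_rate for r in records])
    bg_mean = bg_rates.mean() if len(bg_rates) else 0.0
    fold = float(sample_rates.mean() / bg_mean) if bg_mean > 0 else float("inf")
    if len(records) >= 2 and (sample_rates.var() > 0 or bg_rates.var() > 0
                              or sample_rates.mean() != bg_rates.mean()):
        p = float(stats.mannwhitneyu(sample_rates, bg_rates,
                                     alternative="two-sided").pvalue)
    else:
        p = 1.0
    return MutationRateSummary(records, fold, p)


# ---------------------------------------------------------------------------
# Kataegis


@dataclass(frozen=True)
class KataegisCluster:
    sample: str
    chrom: str
    start: int
    end: int
    count: int
    mean_distance: float


def detect_kataegis(snvs: list[SNVRecord], min_count: int = 6,
                    max_mean_dist: float = 1000.0) -> list[KataegisCluster]:
    """Clusters of >= min_count consecutive same-sample SNVs whose mean
    inter-mutation distance is <= max_mean_dist bp.

    Windows of exactly ``min_count`` consecutive SNVs are tested; passing
    windows are merged into maximal disjoint clusters.
    """
    out = []
    by_key: dict[tuple[str, str], list[int]] = {}
    for v in snvs:
        by_key.setdefault((v.sample, v.chrom), []).append(v.pos)
    for (sample, chrom), positions in sorted(by_key.items()):
        pos = np.sort(np.asarray(positions))
        n = len(pos)
        if n < min_count:
            continue
        w = min_count - 1  # inter-mutation gaps per window
        gaps = np.diff(pos)
        windows = [(i, i + w) for i in range(n - w)
                   if gaps[i:i + w].mean() <= max_mean_dist]
        # merge windows that share SNVs into maximal clusters
        merged: list[list[int]] = []
        for lo, hi in windows:
            if merged and lo <= merged[-1][1]:
                merged[-1][1] = hi
            else:
                merged.append([lo, hi])
        for lo, hi in merged:
            run = pos[lo:hi + 1]
            out.append(KataegisCluster(sample, chrom, int(run[0]), int(run[-1]) + 1,
                                       len(run), float(np.diff(run).mean())))
    return out


def kataegis_sv_overlap(clusters: list[KataegisCluster],
                        chain_intervals: list[tuple[str, int, int]],
                        genome: GenomeModel, bin_size: int = 1_000_000) -> float:
    """Fisher p for co-location of kataegis and chain footprints.

    The genome is cut into ``bin_size`` bins; the 2x2 table classifies bins
    by (contains a kataegis cluster) x (overlaps a chain footprint).
    """
    if not clusters:
        return 1.0
    kat_bins, chain_bins, all_bins = set(), set(), set()
    for chrom, length in genome.chromosomes.items():
        for b in range(0, length, bin_size):
            all_bins.add((chrom, b // bin_size))
    for k in clusters:
        for b in range(k.start // bin_size, k.end // bin_size + 1):
            kat_bins.add((k.chrom, b))
    for chrom, s, e in chain_intervals:
        for b in range(s // bin_size, e // bin_size + 1):
            chain_bins.add((chrom, b))
    kat_bins &= all_bins
    chain_bins &= all_bins
    both = len(kat_bins & chain_bins)
    k_only = len(kat_bins - chain_bins)
    c_only = len(chain_bins - kat_bins)
    neither = len(all_bins) - both - k_only - c_only
    return float(stats.fisher_exact([[both, k_only], [c_only, neither]])[1])


# ---------------------------------------------------------------------------
# Contig mutation rates


def alignment_diff_rates(aln: AlignmentCandidate, contig_seq: str,
                         reference: dict[str, str]) -> tuple[float, float]:
    """(mismatch rate, indel rate) per bp of one alignment.

    The contig segment is re-aligned to its reference segment (global
    edit-distance alignment) and substitutions/indels are counted from the
    operation string.
    """
    query = contig_seq[aln.q_start:aln.q_end]
    ref = reference[aln.r_chrom][aln.r_start:aln.r_end]
    if aln.strand == "-":
        ref = revcomp(ref)
    if not query or not ref:
        return 0.0, 0.0
    res = edlib.align(query, ref, task="path")
    cigar = res["cigar"] or ""
    mism = indel = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num or 1)
            if ch == "X":
                mism += n
            elif ch in "ID":
                indel += n
            num = ""
    span = max(len(query), 1)
    return mism / span, indel / span


@dataclass
class ContigRateSummary:
    per_junction: pd.DataFrame    # columns: contig_id, junction, mismatch_rate, indel_rate
    mismatch_fold: float
    indel_fold: float
    p_mismatch: float
    p_indel: float


def contig_mutation_rates(paths: dict[str, ContigPath],
                          contigs: dict[str, str],
                          reference: dict[str, str],
                          baseline_paths: dict[str, ContigPath] | None = None,
                          baseline_contigs: dict[str, str] | None = None,
                          ) -> ContigRateSummary:
    """Per-junction mismatch/indel rates of SV contigs vs a baseline.

    Each junction's rates are the mean over its two flanking alignments (an
    alignment sandwiched between two junctions contributes to both).  The
    baseline is the set of primary alignments of contigs assembled from
    random loci; fold-changes and Mann-Whitney p-values compare the two.
    """
    rows = []
    for cid, path in paths.items():
        seq = contigs[cid]
        rates = [alignment_diff_rates(a, seq, reference) for a in path.alignments]
        for j in range(len(path.alignments) - 1):
            mm = (rates[j][0] + rates[j + 1][0]) / 2
            ind = (rates[j][1] + rates[j + 1][1]) / 2
            rows.append({"contig_id": cid, "junction": j,
                         "mismatch_rate": mm, "indel_rate": ind})
    table = pd.DataFrame(rows, columns=["contig_id", "junction",
                                        "mismatch_rate", "indel_rate"])

    mismatch_fold = indel_fold = float("nan")
    p_mm = p_ind = float("nan")
    if baseline_paths:
        base_rows = []
        for cid, path in baseline_paths.items():
            seq = (baseline_contigs or contigs)[cid]
            for a in path.alignments:
                mm, ind = alignment_diff_rates(a, seq, reference)
                base_rows.append((mm, ind))
        base = np.array(base_rows) if base_rows else np.zeros((0, 2))
        if len(table) and len(base):
            sv_mm = table.mismatch_rate.to_numpy()
            sv_ind = table.indel_rate.to_numpy()
            base_mm_mean = base[:, 0].mean()
            base_ind_mean = base[:, 1].mean()
            mismatch_fold = float(sv_mm.mean() / base_mm_mean) if base_mm_mean > 0 else float("inf")
            indel_fold = float(sv_ind.mean() / base_ind_mean) if base_ind_mean > 0 else float("inf")

            def mw(a, b):
                if np.ptp(np.concatenate([a, b])) == 0:
                    return 1.0
                return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)

            p_mm = mw(sv_mm, base[:, 0])
            p_ind = mw(sv_ind, base[:, 1])
    return ContigRateSummary(table, mismatch_fold, indel_fold, p_mm, p_ind)


# ---------------------------------------------------------------------------
# Eight-category SV signatures


def category_id(chained: bool, complex_: bool, inter: bool) -> int:
    """Category 0-7 from the three binary splits (bit order: chained,
    complex, interchromosomal)."""
    return 4 * int(chained) + 2 * int(complex_) + int(inter)


@dataclass
class CategoryClustering:
    features: pd.DataFrame        # per-category mean features (populated only)
    standardized: pd.DataFrame
    linkage: np.ndarray
    clusters: dict[int, int]      # category id -> cluster label (1..n)


FEATURE_COLUMNS = ("microhomology", "insertion", "mismatch_rate", "indel_rate")


def categorize_and_cluster(sv_table: pd.DataFrame, n_clusters: int = 3,
                           ) -> CategoryClustering:
    """Bin SVs into 8 categories and cluster the category mean features.

    ``sv_table`` needs boolean columns chained/complex/inter plus the four
    feature columns (mean microhomology and insertion in bp, mismatch and
    indel rates per bp).  Features are z-scored per column and clustered by
    average-linkage Euclidean agglomeration; the tree is cut at the height
    yielding at most ``n_clusters`` groups, so categories merging at zero
    height are never split apart.  Categories with no members are dropped.
    """
    df = sv_table.copy()
    df["category"] = [category_id(c, x, i) for c, x, i in
                      zip(df["chained"], df["complex"], df["inter"])]
    feats = df.groupby("category")[list(FEATURE_COLUMNS)].mean()
    if len(feats) < 2:
        raise ValueError("need at least two populated categories to cluster")
    std = feats.std(ddof=0).replace(0, 1.0)
    z = (feats - feats.mean()) / std
    link = hierarchy.linkage(z.to_numpy(), method="average", metric="euclidean")
    heights = link[:, 2]
    k = min(n_clusters, len(feats))
    # cutting just below the (k-1)-th largest merge height gives k clusters;
    # a non-positive cut (tied zero heights) collapses to a single cluster
    cut = heights[len(heights) - (k - 1)] - 1e-9 * max(heights.max(), 1.0) \
        if k > 1 else heights.max() + 1.0
    if cut <= 0:
        labels = np.ones(len(feats), dtype=int)
    else:
        labels = hierarchy.fcluster(link, t=cut, criterion="distance")
    clusters = dict(zip(feats.index.tolist(), (int(x) for x in labels)))
    return CategoryClustering(feats, z, link, clusters)


# ---------------------------------------------------------------------------
# 96-context matrix


_PYRIMIDINE = {"C", "T"}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def context_matrix(snvs: list[SNVRecord], reference: dict[str, str]) -> pd.Series:
    """Counts over the 96 trinucleotide substitution contexts.

    Substitutions are folded onto the pyrimidine strand, indexed as e.g.
    ``A[C>T]G``; intended for export to external signature-fitting tools.
    """
    subs = []
    for ref in "CT":
        for alt in "ACGT":
            if alt == ref:
                continue
            for left in "ACGT":
                for right in "ACGT":
                    subs.append(f"{left}[{ref}>{alt}]{right}")
    counts = pd.Series(0, index=subs, dtype=int)
    for v in snvs:
        seq = reference.get(v.chrom)
        if seq is None or not 1 <= v.pos < len(seq) - 1:
            continue
        left, ref, right, alt = seq[v.pos - 1], seq[v.pos], seq[v.pos + 1], v.alt_base
        if ref != v.ref_base:
            continue
        if ref not in _PYRIMIDINE:
            left, ref, right, alt = _COMP[right], _COMP[ref], _COMP[left], _COMP[alt]
        counts[f"{left}[{ref}>{alt}]{right}"] += 1
    return counts
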