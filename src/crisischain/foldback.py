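"""Fold-back inversion calling from stepped read-depth profiles, plus
windowed copy-number normalization and fold-back/chain association
statistics.

A fold-back joins a sequence to its own nearby reverse complement, the
footprint of a sister-chromatid fusion in a breakage-fusion-bridge cycle.
Its depth signature is a three-level step: a gained window on one side of
an inverted disomic spacer and a lost window on the other.  Candidates are
short inversions (< 50 kb, support >= 3, MAPQ >= 2 on ordinary
chromosomes); depth is summarised in 150-bp bins over the spacer and 20-kb
flanks, the step must be strictly monotone, and both step contrasts must
pass Welch t-tests at p < 0.02.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .chains import Chain
from .io import DepthBin, SVRecord

log = logging.getLogger(__name__)

_NORMAL_CHROM = re.compile(r"(chr)?(\d{1,2}|X|Y)$")


@dataclass(frozen=True)
class FoldbackConfig:
    max_span: int = 50_000
    min_support: int = 3
    min_mapq: int = 2
    flank: int = 20_000
    bin_size: int = 150
    p_threshold: float = 0.02
    max_mean_depth: float = 75.0
    depth_rule: str = "mean"  # "mean" of (b_D, inv_D, a_D) or "any" window


@dataclass(frozen=True)
class FoldbackDepthProfile:
    b_d: float       # mean depth, 20-kb window before the inversion start
    inv_d: float     # mean depth of 150-bp bins across the inverted segment
    a_d: float       # mean depth, 20-kb window after the inversion end
    p_before_vs_inv: float
    p_inv_vs_after: float
    n_bins: tuple[int, int, int] = (0, 0, 0)


@dataclass(frozen=True)
class FoldbackCall:
    record: SVRecord
    profile: FoldbackDepthProfile
    direction: str   # toward-telomere | toward-centromere | unknown
    spacer: int      # pos2 - pos1 of the inversion


# ---------------------------------------------------------------------------
# Copy-number normalization (10-kb windows)


@dataclass
class CNWindowTrack:
    """Windowed depth with GC and mappability annotations (one chromosome
    set, concatenated)."""

    chrom: np.ndarray       # window chromosome names
    start: np.ndarray       # window starts (non-overlapping, fixed width)
    depth: np.ndarray
    gc: np.ndarray          # GC fraction per window
    mappability: np.ndarray

    def __post_init__(self):
        n = len(self.start)
        for arr in (self.chrom, self.depth, self.gc, self.mappability):
            if len(arr) != n:
                raise ValueError("all track arrays must have equal length")


def normalize_cn(sample: CNWindowTrack, parental: CNWindowTrack,
                 n_gc_bins: int = 10, clip: float = 1.0):
    """Log2 CN ratio of sample vs parental, GC/mappability corrected.

    Each track's window depths are divided by the median of their GC
    stratum (a binned stand-in for a loess fit); windows with mappability 0
    are masked.  The returned ratio is log2(sample/parental), clipped to
    [-clip, +clip] for reporting.
    """
    if len(sample.start) != len(parental.start) or \
            (sample.start != parental.start).any() or \
            (sample.chrom != parental.chrom).any():
        raise ValueError("sample and parental window grids do not match")

    def corrected(track: CNWindowTrack) -> np.ndarray:
        out = np.full(len(track.depth), np.nan)
        ok = track.mappability > 0
        gc_bin = np.clip((track.gc * n_gc_bins).astype(int), 0, n_gc_bins - 1)
        depth = track.depth / np.maximum(track.mappability, 1e-9)
        for b in range(n_gc_bins):
            sel = ok & (gc_bin == b)
            if sel.any():
                med = np.median(depth[sel])
                out[sel] = depth[sel] / med if med > 0 else np.nan
        return out

    s, p = corrected(sample), corrected(parental)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2(s / p)
    ratio = np.clip(ratio, -clip, clip)
    mask = np.isfinite(ratio)
    return ratio, mask


def segment_cn(ratio: np.ndarray, min_size: int = 5, threshold: float = 0.3,
               ) -> list[tuple[int, int, float]]:
    """Simple recursive binary-segmentation changepoint stand-in.

    Splits at the point maximising the absolute mean difference between the
    two sides when that difference exceeds ``threshold``; recurses down to
    ``min_size`` windows.  Returns (start, end, mean) window-index segments.
    """
    ratio = np.asarray(ratio, dtype=float)
    segs: list[tuple[int, int, float]] = []

    def rec(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 2 * min_size:
            segs.append((lo, hi, float(np.nanmean(ratio[lo:hi]))))
            return
        best, best_gap = None, threshold
        for cut in range(lo + min_size, hi - min_size + 1):
            gap = abs(np.nanmean(ratio[lo:cut]) - np.nanmean(ratio[cut:hi]))
            if gap > best_gap:
                best, best_gap = cut, gap
        if best is None:
            segs.append((lo, hi, float(np.nanmean(ratio[lo:hi]))))
        else:
            rec(lo, best)
            rec(best, hi)

    if len(ratio):
        rec(0, len(ratio))
    return segs


# ---------------------------------------------------------------------------
# Fold-back detection


def candidate_inversions(records, cfg: FoldbackConfig | None = None) -> list[SVRecord]:
    """INV records < 50 kb with support >= 3 and MAPQ >= 2 on chr1-22/X/Y."""
    cfg = cfg or FoldbackConfig()
    return [r for r in records
            if r.svtype == "INV"
            and r.span is not None and r.span < cfg.max_span
            and r.support >= cfg.min_support
            and r.mapq >= cfg.min_mapq
            and _NORMAL_CHROM.match(r.chrom1)]


def _bin_depths(track: list[DepthBin], chrom: str, start: int, end: int) -> np.ndarray:
    return np.array([b.depth for b in track
                     if b.chrom == chrom and b.start >= start and b.end <= end])


def foldback_profile(inv: SVRecord, track: list[DepthBin],
                     cfg: FoldbackConfig | None = None) -> FoldbackDepthProfile | None:
    """Depth summaries and step t-tests for one candidate inversion.

    Returns None (with a log entry) when a 20-kb flank falls outside the
    track extent.  Welch (unequal-variance) t-tests compare the 150-bp bin
    depths of each adjacent pair of regions.
    """
    cfg = cfg or FoldbackConfig()
    chrom, start, end = inv.chrom1, inv.pos1, inv.pos2
    on_chrom = [b for b in track if b.chrom == chrom]
    if not on_chrom:
        log.warning("no depth bins for %s; candidate dropped", chrom)
        return None
    lo = min(b.start for b in on_chrom)
    hi = max(b.end for b in on_chrom)
    if start - cfg.flank < lo or end + cfg.flank > hi:
        log.warning("flank outside track extent for %s:%d-%d; candidate dropped",
                    chrom, start, end)
        return None
    before = _bin_depths(on_chrom, chrom, start - cfg.flank, start)
    inside = _bin_depths(on_chrom, chrom, start, end)
    after = _bin_depths(on_chrom, chrom, end, end + cfg.flank)
    if len(before) < 2 or len(inside) < 2 or len(after) < 2:
        log.warning("too few depth bins for %s:%d-%d; candidate dropped",
                    chrom, start, end)
        return None

    def welch(a, b) -> float:
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            return 1.0 if a.mean() == b.mean() else 0.0
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)

    return FoldbackDepthProfile(
        b_d=float(before.mean()), inv_d=float(inside.mean()), a_d=float(after.mean()),
        p_before_vs_inv=welch(before, inside),
        p_inv_vs_after=welch(inside, after),
        n_bins=(len(before), len(inside), len(after)),
    )


def _direction(profile: FoldbackDepthProfile, chrom: str, pos: int,
               centromeres: dict[str, int] | None) -> str:
    """Which way the step decreases, relative to the chromosome arm."""
    if centromeres is None or chrom not in centromeres:
        return "unknown"
    decreasing_right = profile.b_d > profile.a_d
    on_p_arm = pos < centromeres[chrom]
    if decreasing_right:
        return "toward-centromere" if on_p_arm else "toward-telomere"
    return "toward-telomere" if on_p_arm else "toward-centromere"


def call_foldbacks(candidates, track: list[DepthBin],
                   cfg: FoldbackConfig | None = None,
                   centromeres: dict[str, int] | None = None) -> list[FoldbackCall]:
    """Filter candidate inversions down to stepped-profile fold-back calls.

    Keeps candidates whose mean depth across windows is < 75, whose three
    depth levels are strictly monotone (either direction; ties reject), and
    whose two step t-tests both give p < 0.02.
    """
    cfg = cfg or FoldbackConfig()
    calls = []
    for inv in candidates:
        prof = foldback_profile(inv, track, cfg)
        if prof is None:
            continue
        levels = (prof.b_d, prof.inv_d, prof.a_d)
        if cfg.depth_rule == "any":
            too_deep = max(levels) >= cfg.max_mean_depth
        else:
            too_deep = float(np.mean(levels)) >= cfg.max_mean_depth
        if too_deep:
            continue
        stepped = (prof.b_d > prof.inv_d > prof.a_d) or (prof.b_d < prof.inv_d < prof.a_d)
        if not stepped:
            continue
        if prof.p_before_vs_inv >= cfg.p_threshold or prof.p_inv_vs_after >= cfg.p_threshold:
            continue
        calls.append(FoldbackCall(inv, prof,
                                  _direction(prof, inv.chrom1, inv.pos1, centromeres),
                                  spacer=inv.pos2 - inv.pos1))
    return calls


# ---------------------------------------------------------------------------
# Fold-back / chain association


@dataclass
class FoldbackChainStats:
    chains_with_fb: int
    total_chains: int
    fb_in_footprint: int
    fb_outside: int
    footprint_bp: int
    genome_bp: int
    p_footprint: float
    fb_edge: int
    fb_interior: int
    edge_clusters: int
    interior_clusters: int
    p_edge: float


def fb_chain_stats(fbs: list[FoldbackCall], chains: list[Chain],
                   genome_bp: int, cluster_labels: list[list[int]] | None = None,
                   bin_size: int = 10_000) -> FoldbackChainStats:
    """Association statistics between fold-backs and chain footprints.

    Footprint enrichment Fisher test compares fold-back-containing vs empty
    ``bin_size`` genome bins inside vs outside chain footprints.  The
    edge-position test compares fold-backs located in the first or last
    breakpoint cluster of a chain footprint against a null proportional to
    cluster counts (2 edge clusters per multi-cluster chain).
    """
    footprints = [(c, s, e) for ch in chains for (c, s, e) in ch.footprint()]
    fb_pos = [(fb.record.chrom1, fb.record.pos1) for fb in fbs]

    def in_footprint(chrom, pos):
        return any(c == chrom and s - bin_size <= pos <= e + bin_size
                   for c, s, e in footprints)

    fb_in = sum(in_footprint(c, p) for c, p in fb_pos)
    fb_out = len(fb_pos) - fb_in
    fp_bp = sum(e - s for _, s, e in footprints)
    bins_in = max(1, fp_bp // bin_size)
    bins_out = max(1, (genome_bp - fp_bp) // bin_size)
    table = [[fb_in, max(0, bins_in - fb_in)], [fb_out, max(0, bins_out - fb_out)]]
    p_footprint = 1.0 if not fb_pos else float(stats.fisher_exact(table)[1])

    chains_with_fb = sum(
        any(in_footprint(c, p) for c, p in fb_pos
            if any(fc == c and fs - bin_size <= p <= fe + bin_size
                   for fc, fs, fe in ch.footprint()))
        for ch in chains)

    # edge-position analysis over breakpoint clusters
    fb_edge = fb_interior = edge_clusters = interior_clusters = 0
    if cluster_labels is not None:
        for ch, labels in zip(chains, cluster_labels):
            k = max(labels) + 1 if labels else 0
            if k == 0:
                continue
            # clusters ordered along the genome; first/last are "edges"
            edge_ids = {0, k - 1}
            edge_clusters += min(2, k)
            interior_clusters += max(0, k - 2)
            spans: dict[int, tuple[str, int, int]] = {}
            for be, lab in zip(ch.breakends, labels):
                c, s, e = spans.get(lab, (be.chrom, be.pos, be.pos))
                spans[lab] = (be.chrom, min(s, be.pos), max(e, be.pos))
            for c, p in fb_pos:
                for lab, (cc, s, e) in spans.items():
                    if cc == c and s - bin_size <= p <= e + bin_size:
                        if lab in edge_ids:
                            fb_edge += 1
                        else:
                            fb_interior += 1
                        break
    if fb_edge + fb_interior and interior_clusters:
        p_edge = float(stats.fisher_exact(
            [[fb_edge, fb_interior], [edge_clusters, interior_clusters]])[1])
    else:
        p_edge = 1.0

    return FoldbackChainStats(
        chains_with_fb=chains_with_fb, total_chains=len(chains),
        fb_in_footprint=fb_in, fb_outside=fb_out,
        footprint_bp=fp_bp, genome_bp=genome_bp, p_footprint=p_footprint,
        fb_edge=fb_edge, fb_interior=fb_interior,
        edge_clusters=edge_clusters, interior_clusters=interior_clusters,
        p_edge=p_edge)
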