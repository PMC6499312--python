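"""Catalog hygiene: support filtering, cross-sample uniqueness by
reciprocal overlap, head/tail join profiles, and the crisis-duration
utility.

Uniqueness mirrors a call-level crosscheck: a variant is discarded when any
other sample from the same background carries a same-type call whose
breakends both fall within a span-dependent padding and whose interval
(for intrachromosomal events) shares more than a span-dependent reciprocal
overlap.  Events spanning more than 2.5 kb, and translocations, use 1.25-kb
padding with an 0.80 overlap threshold; smaller events use 1-kb padding
with 0.90.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io import SVRecord
from .simulate import GrowthCurve


@dataclass(frozen=True)
class UniquenessConfig:
    span_threshold: int = 2_500
    large_padding: int = 1_250
    small_padding: int = 1_000
    large_overlap: float = 0.80
    small_overlap: float = 0.90
    min_support: int = 3
    match_svtype: bool = True

    def __post_init__(self):
        if not (0 < self.large_overlap <= 1 and 0 < self.small_overlap <= 1):
            raise ValueError("overlap fractions must lie in (0, 1]")
        if self.large_padding <= 0 or self.small_padding <= 0:
            raise ValueError("paddings must be positive")


def filter_support(records: Iterable[SVRecord], min_support: int = 3) -> list[SVRecord]:
    """Keep records with read support >= ``min_support``."""
    return [r for r in records if r.support >= min_support]


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(|a n b|/|a|, |a n b|/|b|) for two half-open intervals; 0 if disjoint."""
    (a0, a1), (b0, b1) = a, b
    if a1 <= a0 or b1 <= b0:
        raise ValueError("zero-length interval")
    inter = min(a1, b1) - max(a0, b0)
    if inter <= 0:
        return 0.0
    return min(inter / (a1 - a0), inter / (b1 - b0))


def _rules(rec: SVRecord, cfg: UniquenessConfig) -> tuple[int, float]:
    """(padding, overlap threshold) for a record: span > 2.5 kb and TRA use
    the large-event rule; span exactly at the threshold counts as large."""
    if rec.svtype == "TRA" or rec.span >= cfg.span_threshold:
        return cfg.large_padding, cfg.large_overlap
    return cfg.small_padding, cfg.small_overlap


def _matches(rec: SVRecord, other: SVRecord, cfg: UniquenessConfig) -> bool:
    if cfg.match_svtype and rec.svtype != other.svtype:
        return False
    if rec.chrom1 != other.chrom1 or rec.chrom2 != other.chrom2:
        return False
    padding, threshold = _rules(rec, cfg)
    if abs(rec.pos1 - other.pos1) > padding or abs(rec.pos2 - other.pos2) > padding:
        return False
    if rec.svtype == "TRA":
        return True  # no span: breakend padding alone decides
    if other.span == 0 or rec.span == 0:
        return False
    return reciprocal_overlap((rec.pos1, rec.pos2), (other.pos1, other.pos2)) > threshold


def unique_svs(sample_records: Sequence[SVRecord],
               others: Mapping[str, Sequence[SVRecord]] | Sequence[Sequence[SVRecord]],
               cfg: UniquenessConfig | None = None,
               return_discards: bool = False):
    """Records of one sample with cross-sample duplicates removed.

    ``others`` holds the raw catalogs of the remaining samples of the same
    background.  A record is discarded when any other-sample record matches
    under the span-appropriate padding/overlap rule.
    """
    cfg = cfg or UniquenessConfig()
    other_lists = list(others.values()) if isinstance(others, Mapping) else list(others)
    pool = [r for lst in other_lists for r in lst]
    kept, discarded = [], []
    for rec in sample_records:
        hit = next((o for o in pool if _matches(rec, o, cfg)), None)
        (discarded if hit is not None else kept).append(rec)
    if return_discards:
        return kept, discarded
    return kept


@dataclass(frozen=True)
class JoinProfile:
    """Counts of the four two-letter head/tail join codes."""

    hh: int
    ht: int
    th: int
    tt: int
    chi2: float
    pvalue: float

    @property
    def total(self) -> int:
        return self.hh + self.ht + self.th + self.tt


def join_profile(records: Sequence[SVRecord]) -> JoinProfile:
    """Tabulate HH/HT/TH/TT join codes and test deviation from uniform 1/4.

    Under random end joining each code is equally likely; the chi-square
    statistic quantifies deviation from that expectation.
    """
    counts = {"HH": 0, "HT": 0, "TH": 0, "TT": 0}
    for r in records:
        counts[r.join_code] += 1
    obs = np.array([counts["HH"], counts["HT"], counts["TH"], counts["TT"]])
    if obs.sum() == 0:
        return JoinProfile(0, 0, 0, 0, 0.0, 1.0)
    chi2, p = stats.chisquare(obs)
    return JoinProfile(*obs.tolist(), float(chi2), float(p))


def crisis_duration(curve: GrowthCurve) -> float:
    """Total days spent below mean(D_f) - SD(D_f).

    The threshold uses the population SD (divisor N).  Durations are
    integrated piecewise-linearly: when D_f crosses the threshold between
    samples, the crossing time is interpolated.
    """
    t, d = curve.times, curve.df
    if len(t) < 2:
        raise ValueError("need at least two time points")
    threshold = d.mean() - d.std()
    total = 0.0
    for i in range(len(t) - 1):
        t0, t1, d0, d1 = t[i], t[i + 1], d[i] - threshold, d[i + 1] - threshold
        dt = t1 - t0
        if d0 < 0 and d1 < 0:
            total += dt
        elif d0 < 0 <= d1:
            total += dt * d0 / (d0 - d1)
        elif d1 < 0 <= d0:
            total += dt * d1 / (d1 - d0)
        # both at or above threshold: contributes nothing
    return float(total)
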