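"""Synthetic multi-sample inputs with the statistical structure the
pipeline assumes.

The generators emulate what a post-crisis whole-genome catalog looks like:
a sparse uniform background of structural variants per sample, planted
chains of densely clustered breakpoints joined with configurable
intra/inter-cluster bias, fold-back inversions as three-level stepped depth
profiles, contigs stitched from short template-switched reference fragments
with microhomology or insertion junctions, and kataegis-like SNV clusters.
Everything is deterministic under an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import AlignmentCandidate, DepthBin, SNVRecord, SVRecord, make_sv

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Genome model


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome names/lengths plus a per-chromosome background break rate.

    ``break_rate`` is breaks per bp; a scalar applies to every chromosome.
    """

    chromosomes: dict[str, int]
    break_rate: float | dict[str, float] = 3e-7

    def __post_init__(self):
        if not self.chromosomes:
            raise ValueError("genome must contain at least one chromosome")
        for chrom, length in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
        for chrom in self.chromosomes:
            if self.rate(chrom) < 0 or not np.isfinite(self.rate(chrom)):
                raise ValueError(f"invalid break rate for {chrom}")

    def rate(self, chrom: str) -> float:
        if isinstance(self.break_rate, dict):
            return self.break_rate[chrom]
        return float(self.break_rate)

    @property
    def total_length(self) -> int:
        return sum(self.chromosomes.values())


def default_genome(break_rate: float = 3e-7) -> GenomeModel:
    """A compact four-chromosome genome used throughout the examples.

    180 Mb total; at the default rate a sample carries ~50-60 background
    breakends, comparable to a heavily rearranged post-crisis clone.
    """
    return GenomeModel(
        {"chr1": 60_000_000, "chr2": 50_000_000, "chr3": 40_000_000,
         "chr4": 30_000_000},
        break_rate,
    )


# ---------------------------------------------------------------------------
# Background SVs


def _svtype_from_orientation(o1: str, o2: str) -> str:
    if (o1, o2) == ("T", "H"):
        return "DEL"
    if (o1, o2) == ("H", "T"):
        return "DUP"
    return "INV"


def _pair_to_record(sample, be1, be2, rng, min_support=3) -> SVRecord:
    (c1, p1), (c2, p2) = sorted([be1, be2])
    o1, o2 = rng.choice(["H", "T"], size=2)
    if c1 != c2:
        svtype = "TRA"
    else:
        if p1 == p2:
            p2 += 1
        svtype = _svtype_from_orientation(o1, o2)
    support = int(min_support + rng.poisson(4))
    return make_sv(sample, c1, p1, o1, c2, p2, o2, svtype, support=support)


def simulate_background_breaks(model: GenomeModel, n_samples: int, seed: int = 1,
                               ) -> list[list[SVRecord]]:
    """Per-sample catalogs under the uniform-spacing null.

    Breakend counts per chromosome are Poisson(rate x length); positions are
    uniform; breakends are paired uniformly at random across the genome (so
    cross-chromosome pairs become translocations) and orientations are drawn
    uniformly, determining DEL/DUP/INV for intrachromosomal pairs.
    """
    if model.total_length <= 0:
        raise ValueError("zero-length genome")
    rng = np.random.default_rng(seed)
    catalogs = []
    for i in range(n_samples):
        sample = f"sim{i}"
        breakends: list[tuple[str, int]] = []
        for chrom, length in model.chromosomes.items():
            n = rng.poisson(model.rate(chrom) * length)
            for pos in rng.integers(0, length, size=n):
                breakends.append((chrom, int(pos)))
        rng.shuffle(breakends)
        if len(breakends) % 2:
            breakends.pop()
        records = [_pair_to_record(sample, breakends[j], breakends[j + 1], rng)
                   for j in range(0, len(breakends), 2)]
        records.sort(key=lambda r: (r.chrom1, r.pos1))
        catalogs.append(records)
    return catalogs


# ---------------------------------------------------------------------------
# Planted chains


@dataclass(frozen=True)
class ChainSpec:
    """Layout of a planted chain: breakpoint clusters plus a linking bias.

    ``bias[i, j]`` is the relative propensity of drawing an SV between
    clusters i and j (diagonal = intracluster).  ``None`` builds a
    homophilic default: ``intra_weight`` on the diagonal, 1 off it.
    """

    n_clusters: int = 6
    footprint: int = 10_000
    breakends_per_cluster: int = 12
    intra_weight: float = 3.0
    bias: np.ndarray | None = None

    def __post_init__(self):
        if self.n_clusters < 1 or self.breakends_per_cluster < 1:
            raise ValueError("counts must be >= 1")
        if self.footprint <= 0:
            raise ValueError("footprint must be positive")
        if self.bias is not None:
            b = np.asarray(self.bias, dtype=float)
            if b.shape != (self.n_clusters, self.n_clusters):
                raise ValueError("bias matrix shape must match cluster count")
            if (b < 0).any() or not b.any():
                raise ValueError("bias propensities must be >= 0 and not all zero")

    def bias_matrix(self) -> np.ndarray:
        if self.bias is not None:
            return np.asarray(self.bias, dtype=float)
        b = np.ones((self.n_clusters, self.n_clusters))
        np.fill_diagonal(b, self.intra_weight)
        return b


def plant_chain(model: GenomeModel, spec: ChainSpec, seed: int = 1,
                sample: str = "planted",
                ) -> tuple[list[SVRecord], list[tuple[str, int, int]]]:
    """Plant one chain; returns (records, truth labels).

    Truth labels are (chrom, pos, cluster_id) per planted breakend and
    partition all planted breakends.  SV edges are drawn between cluster
    pairs with probability proportional to the bias matrix.
    """
    rng = np.random.default_rng(seed)
    margin = 25_000
    eligible = [c for c, ln in model.chromosomes.items()
                if ln > spec.footprint + 2 * margin]
    if not eligible:
        raise ValueError("cluster footprint exceeds every chromosome")
    # anchor clusters on chromosomes, spread out to keep clusters separable
    clusters: list[list[tuple[str, int]]] = []
    labels: list[tuple[str, int, int]] = []
    for ci in range(spec.n_clusters):
        chrom = eligible[ci % len(eligible)]
        length = model.chromosomes[chrom]
        anchor = int(rng.integers(margin, length - spec.footprint - margin))
        positions = np.sort(rng.integers(anchor, anchor + spec.footprint,
                                         size=spec.breakends_per_cluster))
        members = [(chrom, int(p)) for p in positions]
        clusters.append(members)
        labels.extend((chrom, int(p), ci) for p in positions)

    bias = spec.bias_matrix()
    avail = [list(m) for m in clusters]
    for m in avail:
        rng.shuffle(m)
    records: list[SVRecord] = []
    while True:
        counts = np.array([len(m) for m in avail])
        if counts.sum() < 2:
            break
        # feasible cluster pairs weighted by bias
        pairs, weights = [], []
        k = spec.n_clusters
        for i in range(k):
            for j in range(i, k):
                need = 2 if i == j else 1
                if counts[i] >= need and (i == j or counts[j] >= 1) and bias[i, j] > 0:
                    pairs.append((i, j))
                    weights.append(bias[i, j])
        if not pairs:
            break
        w = np.asarray(weights, dtype=float)
        i, j = pairs[rng.choice(len(pairs), p=w / w.sum())]
        be1 = avail[i].pop()
        be2 = avail[j].pop()
        records.append(_pair_to_record(sample, be1, be2, rng))
    return records, labels


# ---------------------------------------------------------------------------
# Fold-back inversions


@dataclass(frozen=True)
class FoldbackSpec:
    """Three-level stepped depth profile around an inverted disomic spacer."""

    spacer: int = 5_000
    level_before: float = 60.0
    level_inside: float = 40.0
    level_after: float = 20.0
    noise_sd: float = 0.0
    flank: int = 20_000

    def __post_init__(self):
        if self.spacer <= 0:
            raise ValueError("spacer must be positive")
        if min(self.level_before, self.level_inside, self.level_after) < 0:
            raise ValueError("depth levels must be >= 0")


def plant_foldback(track: list[DepthBin], spec: FoldbackSpec, at: int,
                   mirrored: bool = False, seed: int = 1, sample: str = "planted",
                   ) -> tuple[list[DepthBin], SVRecord, dict]:
    """Impose a stepped fold-back depth profile on ``track`` at ``at``.

    Bins in the 20-kb window before the inversion are set to the high level,
    bins across the spacer to the middle level, and the 20-kb window after
    to the low level (levels reversed when ``mirrored``), with optional
    Gaussian noise.  Returns the modified track, the INV record, and a truth
    dict.
    """
    if not track:
        raise ValueError("empty depth track")
    rng = np.random.default_rng(seed)
    chrom = track[0].chrom
    lo = min(b.start for b in track if b.chrom == chrom)
    hi = max(b.end for b in track if b.chrom == chrom)
    start, end = at, at + spec.spacer
    if start - spec.flank < lo or end + spec.flank > hi:
        raise ValueError("fold-back position too close to track edge for 20-kb flanks")
    before, after = spec.level_before, spec.level_after
    if mirrored:
        before, after = after, before
    out = []
    for b in track:
        if b.chrom != chrom:
            out.append(b)
            continue
        mid = (b.start + b.end) // 2
        if start - spec.flank <= mid < start:
            level = before
        elif start <= mid < end:
            level = spec.level_inside
        elif end <= mid < end + spec.flank:
            level = after
        else:
            out.append(b)
            continue
        depth = max(0.0, level + (rng.normal(0, spec.noise_sd) if spec.noise_sd else 0.0))
        out.append(DepthBin(b.chrom, b.start, b.end, depth))
    inv = make_sv(sample, chrom, start, "H", chrom, end, "H", "INV", support=5, mapq=60)
    truth = {"chrom": chrom, "start": start, "end": end, "spacer": spec.spacer,
             "mirrored": mirrored}
    return out, inv, truth


def flat_track(chrom: str, length: int, bin_size: int = 150, depth: float = 30.0,
               noise_sd: float = 0.0, seed: int = 1) -> list[DepthBin]:
    """A constant-coverage 150-bp binned track, optionally with noise."""
    rng = np.random.default_rng(seed)
    bins = []
    for s in range(0, length - bin_size + 1, bin_size):
        d = depth + (rng.normal(0, noise_sd) if noise_sd else 0.0)
        bins.append(DepthBin(chrom, s, s + bin_size, max(0.0, d)))
    return bins


# ---------------------------------------------------------------------------
# Synthetic references and contigs


def random_reference(chrom_lengths: dict[str, int], seed: int = 1,
                     gc: float = 0.5) -> dict[str, str]:
    """I.i.d. random sequences; ``gc`` sets the G+C fraction."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.array(list("ACGT"))
    return {name: "".join(alphabet[rng.choice(4, size=ln, p=p)])
            for name, ln in chrom_lengths.items()}


@dataclass(frozen=True)
class ContigSpec:
    """How to stitch a contig from short template-switched fragments."""

    n_fragments: int = 14
    frag_len_range: tuple[int, int] = (60, 400)
    mh_range: tuple[int, int] = (2, 12)
    insertion_range: tuple[int, int] = (2, 15)
    p_microhomology: float = 0.5
    mismatch_rate: float = 0.0
    indel_rate: float = 0.0
    n_decoys: int = 20

    def __post_init__(self):
        if self.n_fragments < 1:
            raise ValueError("need at least one fragment")
        if self.frag_len_range[0] <= 0:
            raise ValueError("fragment lengths must be positive")
        for r in (self.mismatch_rate, self.indel_rate, self.p_microhomology):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class JunctionTruth:
    microhomology: int
    insertion: int
    insertion_seq: str


@dataclass
class SyntheticContig:
    contig_id: str
    sequence: str
    reference: dict[str, str]
    true_alignments: list[AlignmentCandidate]
    junctions: list[JunctionTruth]
    candidates: list[AlignmentCandidate]


def _write_oriented(ref: dict[str, list[str]], chrom: str, start: int, end: int,
                    strand: str, contig_bases: str) -> None:
    """Write contig-oriented bases into the reference interval."""
    seq = contig_bases if strand == "+" else revcomp(contig_bases)
    ref[chrom][start:end] = list(seq)


def make_contig(reference: dict[str, str], spec: ContigSpec, seed: int = 1,
                contig_id: str = "contig0") -> SyntheticContig:
    """Build a contig of reference fragments joined with microhomology or
    insertion junctions, plus a decoyed candidate-alignment list.

    Microhomology is realised physically: the reference around the start of
    the downstream fragment is rewritten so its first m contig-oriented
    bases equal the last m of the upstream fragment, and the contig consumes
    the shared bases once.  The (possibly rewritten) reference is returned
    so alignments remain exact.
    """
    rng = np.random.default_rng(seed)
    ref = {k: list(v) for k, v in reference.items()}
    lo, hi = spec.frag_len_range
    max_mh = spec.mh_range[1]
    if max_mh >= lo:
        raise ValueError("microhomology may not be as long as a fragment")

    # non-overlapping reference intervals so microhomology rewrites are safe
    chroms = list(reference)
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def sample_interval(length: int) -> tuple[str, int]:
        for _ in range(1000):
            chrom = chroms[rng.integers(len(chroms))]
            limit = len(reference[chrom]) - length
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            if all(start + length + 5 <= s or start >= e + 5
                   for s, e in taken[chrom]):
                taken[chrom].append((start, start + length))
                return chrom, start
        raise ValueError("reference too short for the requested fragments")

    frags = []  # (chrom, start, end, strand, length)
    for _ in range(spec.n_fragments):
        length = int(rng.integers(lo, hi + 1))
        chrom, start = sample_interval(length)
        strand = "+" if rng.random() < 0.5 else "-"
        frags.append((chrom, start, start + length, strand, length))

    def frag_seq(i: int) -> str:
        chrom, s, e, strand, _ = frags[i]
        seq = "".join(ref[chrom][s:e])
        return seq if strand == "+" else revcomp(seq)

    contig_parts = [frag_seq(0)]
    q_intervals = [(0, frags[0][4])]
    junctions: list[JunctionTruth] = []
    pos = frags[0][4]
    alphabet = "ACGT"
    for i in range(1, spec.n_fragments):
        chrom, s, e, strand, length = frags[i]
        if rng.random() < spec.p_microhomology:
            m = int(rng.integers(spec.mh_range[0], spec.mh_range[1] + 1))
            prev = contig_parts[-1]
            shared = prev[-m:] if m else ""
            if m:
                # rewrite the first m contig-oriented bases of this fragment
                if strand == "+":
                    _write_oriented(ref, chrom, s, s + m, "+", shared)
                else:
                    _write_oriented(ref, chrom, e - m, e, "-", shared)
            seq = frag_seq(i)
            contig_parts.append(seq[m:])
            q_intervals.append((pos - m, pos - m + length))
            pos += length - m
            junctions.append(JunctionTruth(m, 0, ""))
        else:
            ins_len = int(rng.integers(spec.insertion_range[0],
                                       spec.insertion_range[1] + 1))
            ins = "".join(alphabet[rng.integers(4)] for _ in range(ins_len))
            contig_parts.append(ins)
            pos += ins_len
            contig_parts.append(frag_seq(i))
            q_intervals.append((pos, pos + length))
            pos += length
            junctions.append(JunctionTruth(0, ins_len, ins))
    contig = "".join(contig_parts)

    true_alignments = [
        AlignmentCandidate(contig_id, qs, qe, frags[i][0], frags[i][1],
                           frags[i][2], frags[i][3], score=float(qe - qs),
                           evalue=10.0 ** -min(qe - qs, 60))
        for i, (qs, qe) in enumerate(q_intervals)
    ]

    # mutagenise the contig copy (reference untouched)
    if spec.mismatch_rate > 0 or spec.indel_rate > 0:
        contig, true_alignments, junctions = _mutate_contig(
            contig, true_alignments, junctions, spec, rng)

    # decoys: short re-aligned sub-fragments at random loci, degraded scores
    decoys = []
    for _ in range(spec.n_decoys):
        base = true_alignments[rng.integers(len(true_alignments))]
        span = base.q_end - base.q_start
        sub = int(rng.integers(15, max(16, min(35, span))))
        off = int(rng.integers(0, span - sub + 1))
        chrom = chroms[rng.integers(len(chroms))]
        limit = max(1, len(reference[chrom]) - sub)
        r_start = int(rng.integers(0, limit))
        decoys.append(AlignmentCandidate(
            contig_id, base.q_start + off, base.q_start + off + sub,
            chrom, r_start, r_start + sub,
            "+" if rng.random() < 0.5 else "-",
            score=0.5 * sub, evalue=0.1))
    candidates = list(true_alignments) + decoys
    rng.shuffle(candidates)

    return SyntheticContig(contig_id, contig, {k: "".join(v) for k, v in ref.items()},
                           true_alignments, junctions, candidates)


def _mutate_contig(contig, alignments, junctions, spec, rng):
    """Apply per-base mismatches and 1-bp indels, shifting coordinates."""
    bases = list(contig)
    alphabet = "ACGT"
    for i, b in enumerate(bases):
        if rng.random() < spec.mismatch_rate:
            bases[i] = alphabet[(alphabet.index(b) + 1 + rng.integers(3)) % 4]
    # indels applied right-to-left so earlier coordinates stay valid
    n = len(bases)
    events = [(int(p), rng.random() < 0.5) for p in np.flatnonzero(
        rng.random(n) < spec.indel_rate)]
    new_aln = list(alignments)
    for p, is_ins in sorted(events, reverse=True):
        if is_ins:
            bases.insert(p, alphabet[rng.integers(4)])
            shift = 1
        else:
            del bases[p]
            shift = -1
        new_aln = [
            replace(a,
                    q_start=a.q_start + (shift if a.q_start > p else 0),
                    q_end=a.q_end + (shift if a.q_end > p else 0))
            for a in new_aln
        ]
    return "".join(bases), new_aln, junctions


# ---------------------------------------------------------------------------
# Kataegis


def plant_kataegis(snvs: list[SNVRecord], sample: str, chrom: str, pos: int,
                   count: int, span: int, seed: int = 1,
                   reference: dict[str, str] | None = None) -> list[SNVRecord]:
    """Add ``count`` clustered SNVs within ``span`` bp starting at ``pos``.

    Mutations are C->T (or G->A on the reverse strand) when the reference is
    supplied and the site permits, mimicking APOBEC-style kataegis; else the
    record is written as C->T regardless of true context.
    """
    if span <= 0:
        raise ValueError("span must be positive")
    if count == 0:
        return list(snvs)
    rng = np.random.default_rng(seed)
    positions = set()
    while len(positions) < count:
        positions.add(int(rng.integers(pos, pos + span)))
    out = list(snvs)
    for p in sorted(positions):
        ref_base, alt = "C", "T"
        if reference is not None and chrom in reference and p < len(reference[chrom]):
            base = reference[chrom][p]
            if base == "G":
                ref_base, alt = "G", "A"
            elif base in "AT":
                ref_base, alt = base, ("T" if base == "A" else "C")
        out.append(SNVRecord(sample, chrom, p, ref_base, alt))
    return out


def simulate_snvs(model: GenomeModel, n_samples: int, rate: float = 1e-6,
                  seed: int = 1) -> dict[str, list[SNVRecord]]:
    """Uniform background SNVs per sample at ``rate`` per bp."""
    rng = np.random.default_rng(seed)
    out: dict[str, list[SNVRecord]] = {}
    bases = "ACGT"
    for i in range(n_samples):
        sample = f"sim{i}"
        snvs = []
        for chrom, length in model.chromosomes.items():
            n = rng.poisson(rate * length)
            for pos in np.sort(rng.integers(0, length, size=n)):
                ref = bases[rng.integers(4)]
                alt = bases[(bases.index(ref) + 1 + rng.integers(3)) % 4]
                snvs.append(SNVRecord(sample, chrom, int(pos), ref, alt))
        out[sample] = snvs
    return out


# ---------------------------------------------------------------------------
# Growth curves


@dataclass(frozen=True)
class GrowthCurve:
    """Cell-division frequency D_f (divisions/day) over time (days)."""

    times: np.ndarray
    df: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        d = np.asarray(self.df, dtype=float)
        if t.ndim != 1 or t.shape != d.shape:
            raise ValueError("times and df must be 1-D and equal length")
        if not (np.diff(t) > 0).all():
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "df", d)
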