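"""Readers and writers for the tabular formats the pipeline consumes.

All coordinates are 0-based half-open internally.  BEDPE and bedGraph are
0-based on disk; "tsv" SV tables and SNV tables are 1-based on disk (the
convention of VCF-derived exports) and are converted on read/write.

Junction orientation is encoded per breakend as ``H`` (head, the 5' end of
the joined fragment faces the junction) or ``T`` (tail, the 3' end does).
BEDPE strands map ``+`` -> ``T`` and ``-`` -> ``H``: a ``+`` breakend joins
sequence extending to its left, i.e. the fragment's tail.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

SVTYPES = ("DEL", "INV", "DUP", "TRA")
ORIENTATIONS = ("H", "T")

_STRAND_TO_ORIENT = {"+": "T", "-": "H"}
_ORIENT_TO_STRAND = {"T": "+", "H": "-"}

_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """Raised on malformed input rows; carries the offending line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.lineno = lineno


def _chrom_key(chrom: str):
    """Sort chromosomes naturally: chr2 before chr10, numbers before X/Y."""
    m = re.match(r"(chr)?(\d+)$", chrom)
    if m:
        return (0, int(m.group(2)), "")
    return (1, 0, chrom)


@dataclass(frozen=True, slots=True)
class SVRecord:
    """One structural variant: a pair of oriented breakends.

    Intrachromosomal records are canonicalised so that pos1 <= pos2;
    interchromosomal records (svtype TRA) are ordered by chromosome.
    """

    sample: str
    chrom1: str
    pos1: int
    orient1: str
    chrom2: str
    pos2: int
    orient2: str
    svtype: str
    support: int = 0
    mapq: int = 60

    def __post_init__(self):
        if self.svtype not in SVTYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if self.orient1 not in ORIENTATIONS or self.orient2 not in ORIENTATIONS:
            raise ValueError("orientation must be 'H' or 'T'")
        if self.support < 0 or self.mapq < 0:
            raise ValueError("support and mapq must be non-negative")
        if (self.chrom1 != self.chrom2) != (self.svtype == "TRA"):
            raise ValueError("svtype must be TRA iff breakends are on different chromosomes")
        # canonical ordering of the two sides
        k1 = (_chrom_key(self.chrom1), self.pos1)
        k2 = (_chrom_key(self.chrom2), self.pos2)
        if k1 > k2:
            c1, p1, o1 = self.chrom1, self.pos1, self.orient1
            object.__setattr__(self, "chrom1", self.chrom2)
            object.__setattr__(self, "pos1", self.pos2)
            object.__setattr__(self, "orient1", self.orient2)
            object.__setattr__(self, "chrom2", c1)
            object.__setattr__(self, "pos2", p1)
            object.__setattr__(self, "orient2", o1)

    @property
    def span(self) -> int | None:
        """Breakend separation in bp for intrachromosomal records, else None."""
        if self.svtype == "TRA":
            return None
        return self.pos2 - self.pos1

    def breakends(self):
        """The two (chrom, pos, orient) breakends of the record."""
        return ((self.chrom1, self.pos1, self.orient1), (self.chrom2, self.pos2, self.orient2))

    @property
    def join_code(self) -> str:
        """Two-letter head/tail join code, e.g. 'HT'."""
        return self.orient1 + self.orient2


def make_sv(sample, chrom1, pos1, orient1, chrom2, pos2, orient2, svtype,
            support=0, mapq=60) -> SVRecord:
    """Construct an SVRecord, swapping sides into canonical order if needed."""
    if (_chrom_key(chrom1), pos1) > (_chrom_key(chrom2), pos2):
        chrom1, pos1, orient1, chrom2, pos2, orient2 = chrom2, pos2, orient2, chrom1, pos1, orient1
    return SVRecord(sample, chrom1, int(pos1), orient1, chrom2, int(pos2), orient2,
                    svtype, int(support), int(mapq))


@dataclass(frozen=True, slots=True)
class DepthBin:
    chrom: str
    start: int
    end: int
    depth: float

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("bin start must be < end")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")


@dataclass(frozen=True, slots=True)
class AlignmentCandidate:
    """A candidate alignment of (part of) a contig to the reference.

    Query coordinates are always in forward-query convention regardless of
    strand; reference coordinates are forward-reference.
    """

    contig_id: str
    q_start: int
    q_end: int
    r_chrom: str
    r_start: int
    r_end: int
    strand: str
    score: float
    evalue: float | None = None

    def __post_init__(self):
        if self.q_start >= self.q_end:
            raise ValueError("q_start must be < q_end")
        if self.r_start >= self.r_end:
            raise ValueError("r_start must be < r_end")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True, slots=True)
class SNVRecord:
    sample: str
    chrom: str
    pos: int
    ref_base: str
    alt_base: str

    def __post_init__(self):
        if self.ref_base not in _BASES or self.alt_base not in _BASES:
            raise ValueError("bases must be one of A, C, G, T")
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt base must differ")


# ---------------------------------------------------------------------------
# SV tables


def read_sv_table(path, dialect: str = "bedpe") -> list[SVRecord]:
    """Read an SV table.

    ``bedpe``: chrom1 start1 end1 chrom2 start2 end2 name score strand1
    strand2 svtype [sample [mapq]].  0-based; the score column carries read
    support; the name column carries the sample label unless '.', in which
    case the optional 12th column or 'sample' is used.

    ``tsv``: headered columns sample chrom1 pos1 orient1 chrom2 pos2 orient2
    svtype support mapq, with 1-based positions.
    """
    if dialect not in ("bedpe", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records = []
    with open(path) as fh:
        header_done = dialect != "tsv"
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if not header_done:
                header_done = True
                continue
            try:
                if dialect == "bedpe":
                    if len(fields) < 11:
                        raise ValueError("expected >= 11 BEDPE columns")
                    chrom1, start1 = fields[0], int(fields[1])
                    chrom2, start2 = fields[3], int(fields[4])
                    name, score = fields[6], int(fields[7])
                    o1 = _STRAND_TO_ORIENT[fields[8]]
                    o2 = _STRAND_TO_ORIENT[fields[9]]
                    svtype = fields[10]
                    sample = fields[11] if len(fields) > 11 else (name if name != "." else "sample")
                    mapq = int(fields[12]) if len(fields) > 12 else 60
                    rec = make_sv(sample, chrom1, start1, o1, chrom2, start2, o2,
                                  svtype, support=score, mapq=mapq)
                else:
                    (sample, chrom1, pos1, o1, chrom2, pos2, o2,
                     svtype, support, mapq) = fields[:10]
                    rec = make_sv(sample, chrom1, int(pos1) - 1, o1,
                                  chrom2, int(pos2) - 1, o2, svtype,
                                  support=int(support), mapq=int(mapq))
            except (ValueError, KeyError, IndexError) as exc:
                raise FormatError(path, lineno, f"malformed SV row: {exc}") from exc
            records.append(rec)
    return records


def write_sv_table(records: Iterable[SVRecord], path, dialect: str = "bedpe") -> None:
    if dialect not in ("bedpe", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        if dialect == "tsv":
            fh.write("sample\tchrom1\tpos1\torient1\tchrom2\tpos2\torient2\t"
                     "svtype\tsupport\tmapq\n")
        for r in records:
            if dialect == "bedpe":
                fh.write("\t".join(map(str, (
                    r.chrom1, r.pos1, r.pos1 + 1, r.chrom2, r.pos2, r.pos2 + 1,
                    r.sample, r.support, _ORIENT_TO_STRAND[r.orient1],
                    _ORIENT_TO_STRAND[r.orient2], r.svtype, r.sample, r.mapq))) + "\n")
            else:
                fh.write("\t".join(map(str, (
                    r.sample, r.chrom1, r.pos1 + 1, r.orient1, r.chrom2,
                    r.pos2 + 1, r.orient2, r.svtype, r.support, r.mapq))) + "\n")


# ---------------------------------------------------------------------------
# Depth tracks (bedGraph)


def read_depth_track(path) -> list[DepthBin]:
    """Read a 4-column bedGraph into sorted, non-overlapping DepthBins."""
    bins = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            try:
                if len(fields) < 4:
                    raise ValueError("expected 4 bedGraph columns")
                bins.append(DepthBin(fields[0], int(fields[1]), int(fields[2]),
                                     float(fields[3])))
            except ValueError as exc:
                raise FormatError(path, lineno, f"malformed bedGraph row: {exc}") from exc
    bins.sort(key=lambda b: (_chrom_key(b.chrom), b.start))
    for a, b in zip(bins, bins[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError(f"overlapping bins at {b.chrom}:{b.start}")
    return bins


def write_depth_track(bins: Iterable[DepthBin], path) -> None:
    with open(path, "w") as fh:
        for b in bins:
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.depth:g}\n")


# ---------------------------------------------------------------------------
# Alignment candidates (PSL / LAST tab)


def read_alignments(path, dialect: str = "last_tab") -> list[AlignmentCandidate]:
    """Read candidate contig-to-reference alignments.

    ``psl``: BLAT PSL rows; header lines are skipped; score is taken as
    matches - mismatches.  Minus-strand query intervals are flipped to the
    forward-query convention using the query size column.

    ``last_tab``: LAST tabular output (score, ref name/start/alnSize/strand/
    size, query name/start/alnSize/strand/size, blocks, [EG2=, E=]).
    """
    if dialect not in ("psl", "last_tab"):
        raise ValueError(f"unknown dialect {dialect!r}")
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if dialect == "psl":
                if not fields[0].lstrip("-").isdigit():
                    continue  # header / separator lines
                if len(fields) < 17:
                    raise FormatError(path, lineno, "truncated PSL row")
                matches, mismatches = int(fields[0]), int(fields[1])
                strand = fields[8][-1]  # translated PSL may carry two chars
                q_name, q_size = fields[9], int(fields[10])
                q_start, q_end = int(fields[11]), int(fields[12])
                t_name = fields[13]
                t_start, t_end = int(fields[15]), int(fields[16])
                if strand == "-":
                    q_start, q_end = q_size - q_end, q_size - q_start
                out.append(AlignmentCandidate(
                    q_name, q_start, q_end, t_name, t_start, t_end,
                    strand, float(matches - mismatches)))
            else:
                if len(fields) < 12:
                    raise FormatError(path, lineno, "truncated LAST tab row")
                score = float(fields[0])
                r_name, r_start, r_aln = fields[1], int(fields[2]), int(fields[3])
                q_name, q_start, q_aln = fields[6], int(fields[7]), int(fields[8])
                q_strand, q_size = fields[9], int(fields[10])
                evalue = None
                for f in fields[12:]:
                    if f.startswith("E="):
                        evalue = float(f[2:])
                if q_strand == "-":
                    q_start = q_size - (q_start + q_aln)
                out.append(AlignmentCandidate(
                    q_name, q_start, q_start + q_aln, r_name, r_start,
                    r_start + r_aln, q_strand, score, evalue))
    return out


def write_alignments(cands: Iterable[AlignmentCandidate], path) -> None:
    """Write candidates as LAST-tab rows (query coordinates forward)."""
    with open(path, "w") as fh:
        for c in cands:
            q_aln = c.q_end - c.q_start
            q_size = c.q_end  # a lower bound; forward convention keeps this lossless
            q_start = c.q_start if c.strand == "+" else q_size - c.q_end
            extra = f"\tE={c.evalue:g}" if c.evalue is not None else ""
            fh.write(f"{c.score:g}\t{c.r_chrom}\t{c.r_start}\t{c.r_end - c.r_start}"
                     f"\t+\t{c.r_end}\t{c.contig_id}\t{q_start}\t{q_aln}"
                     f"\t{c.strand}\t{q_size}\t{q_aln}{extra}\n")


# ---------------------------------------------------------------------------
# SNV tables


def read_snv_table(path) -> list[SNVRecord]:
    """Read a headered TSV of sample, chrom, pos (1-based), ref, alt."""
    out = []
    with open(path) as fh:
        header = True
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if header:
                header = False
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                sample, chrom, pos, ref, alt = fields[:5]
                out.append(SNVRecord(sample, chrom, int(pos) - 1, ref, alt))
            except (ValueError, IndexError) as exc:
                raise FormatError(path, lineno, f"malformed SNV row: {exc}") from exc
    return out


def write_snv_table(snvs: Iterable[SNVRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tpos\tref\talt\n")
        for s in snvs:
            fh.write(f"{s.sample}\t{s.chrom}\t{s.pos + 1}\t{s.ref_base}\t{s.alt_base}\n")


# ---------------------------------------------------------------------------
# FASTA (minimal, for synthetic references and contigs)


def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None and line:
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
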