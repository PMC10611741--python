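"""Shared domain types: intervals, genomes, paralog sets and read stores.

Coordinates are 0-based half-open internally; 1-based only in VCF/TSV output.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pysam
from Bio import Align
from Bio.Seq import Seq
from intervaltree import IntervalTree

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start >= self.end:
            raise ValueError(f"start must be < end ({self.start} >= {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def intersect(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return replace(self, start=max(self.start, other.start), end=min(self.end, other.end))

    def expand(self, slop: int, contig_length: int | None = None) -> "GenomicInterval":
        """Widen by ``slop`` on both sides, clipping at [0, contig_length)."""
        start = max(0, self.start - slop)
        end = self.end + slop
        if contig_length is not None:
            end = min(end, contig_length)
        return replace(self, start=start, end=end)

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


def merge_intervals(intervals: Iterable[GenomicInterval], max_gap: int = 0) -> list[GenomicInterval]:
    """Merge intervals on the same chrom separated by at most ``max_gap`` bp."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda i: (i.chrom, i.start, i.end)):
        if out and out[-1].chrom == iv.chrom and iv.start - out[-1].end <= max_gap:
            if iv.end > out[-1].end:
                out[-1] = replace(out[-1], end=iv.end)
        else:
            out.append(iv)
    return out


class IntervalIndex:
    """Position-queryable collection of GenomicIntervals."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._intervals: list[GenomicInterval] = []
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GenomicInterval) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
        self._intervals.append(iv)

    def overlapping(self, iv: GenomicInterval) -> list[GenomicInterval]:
        tree = self._trees.get(iv.chrom)
        if tree is None:
            return []
        return sorted((hit.data for hit in tree.overlap(iv.start, iv.end)),
                      key=lambda i: (i.start, i.end))

    def any_overlap(self, iv: GenomicInterval) -> bool:
        tree = self._trees.get(iv.chrom)
        return bool(tree and tree.overlap(iv.start, iv.end))

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __len__(self) -> int:
        return len(self._intervals)


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

class Genome:
    """A sequence store over named contigs (dict- or FASTA-backed)."""

    def __init__(self, contigs: Mapping[str, str]) -> None:
        self._contigs = {name: str(seq).upper() for name, seq in contigs.items()}

    @classmethod
    def from_fasta(cls, path: str) -> "Genome":
        import pyfaidx

        fa = pyfaidx.Fasta(path)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def fetch(self, chrom: str, start: int | None = None, end: int | None = None) -> str:
        seq = self._contigs[chrom]
        if start is None:
            return seq
        if start < 0 or (end is not None and end > len(seq)):
            raise KeyError(f"{chrom}:{start}-{end} outside contig bounds")
        return seq[start:end]

    def fetch_interval(self, iv: GenomicInterval) -> str:
        seq = self.fetch(iv.chrom, iv.start, iv.end)
        return revcomp(seq) if iv.strand == "-" else seq

    def contig_length(self, chrom: str) -> int:
        return len(self._contigs[chrom])

    @property
    def contigs(self) -> dict[str, str]:
        return self._contigs

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._contigs

    def write_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self._contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Pairwise and progressive alignment
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


def global_align(a: str, b: str) -> tuple[str, str]:
    """Best global alignment of two sequences as a pair of gapped strings."""
    aln = _ALIGNER.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    return ga, gb


def alignment_identity(ga: str, gb: str) -> float:
    """Matching columns over alignment length for two gapped strings."""
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    return matches / len(ga) if ga else 0.0


def identity_score(a: str, b: str, try_revcomp: bool = True) -> tuple[float, str]:
    """Normalized global-alignment identity; best of forward and revcomp.

    Returns (score, strand) where strand is '-' if the reverse complement of
    ``b`` aligned better.
    """
    if not a or not b:
        return 0.0, "+"
    fwd = alignment_identity(*global_align(a, b))
    if not try_revcomp:
        return fwd, "+"
    rev = alignment_identity(*global_align(a, revcomp(b)))
    return (fwd, "+") if fwd >= rev else (rev, "-")


def progressive_msa(seqs: Sequence[str]) -> list[str]:
    """Progressive multiple alignment seeded by the highest-identity pair.

    Remaining sequences are added in decreasing order of identity to the
    growing profile's first member; gaps already in the profile are propagated.
    """
    n = len(seqs)
    if n == 1:
        return [seqs[0]]
    if n == 2:
        return list(global_align(seqs[0], seqs[1]))
    pair_scores = {}
    for i in range(n):
        for j in range(i + 1, n):
            pair_scores[(i, j)] = identity_score(seqs[i], seqs[j], try_revcomp=False)[0]
    (si, sj) = max(pair_scores, key=pair_scores.get)
    order = [si, sj] + sorted(
        (k for k in range(n) if k not in (si, sj)),
        key=lambda k: -pair_scores[tuple(sorted((si, k)))],
    )
    profile = list(global_align(seqs[si], seqs[sj]))
    members = [si, sj]
    for k in order[2:]:
        profile = _merge_into_profile(profile, seqs[k])
        members.append(k)
    # restore input order
    out = [""] * n
    for row, member in zip(profile, members):
        out[member] = row
    return out


def _merge_into_profile(profile: list[str], new_seq: str) -> list[str]:
    rep_ungapped = profile[0].replace("-", "")
    g_rep, g_new = global_align(rep_ungapped, new_seq)
    # walk profile columns and pairwise columns simultaneously, keyed on rep
    merged = [[] for _ in range(len(profile) + 1)]
    pi = 0  # profile column
    for rcol, ncol in zip(g_rep, g_new):
        if rcol == "-":
            # insertion in new seq relative to the whole profile
            for row in merged[:-1]:
                row.append("-")
            merged[-1].append(ncol)
            continue
        # emit profile columns that are gaps in the representative first
        while pi < len(profile[0]) and profile[0][pi] == "-":
            for r, row in enumerate(merged[:-1]):
                row.append(profile[r][pi])
            merged[-1].append("-")
            pi += 1
        for r, row in enumerate(merged[:-1]):
            row.append(profile[r][pi])
        merged[-1].append(ncol)
        pi += 1
    while pi < len(profile[0]):
        for r, row in enumerate(merged[:-1]):
            row.append(profile[r][pi])
        merged[-1].append("-")
        pi += 1
    return ["".join(row) for row in merged]


# ---------------------------------------------------------------------------
# Paralog sets and SUNs
# ---------------------------------------------------------------------------

@dataclass
class ParalogSet:
    """A group of mutually homologous regions with their alignment.

    ``alignment`` holds one gapped string per member over common columns, on
    each member's extracted orientation (``members[i].strand``). Exactly one
    member stays unmasked in the masked reference.
    """

    set_id: str
    members: list[GenomicInterval]
    seqs: list[str]
    alignment: list[str] = field(default_factory=list)
    unmasked_member: int = 0
    origin: str = "set1"

    def __post_init__(self) -> None:
        if self.alignment:
            ncols = {len(row) for row in self.alignment}
            if len(ncols) != 1:
                raise ValueError("alignment rows have unequal column counts")

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def n_columns(self) -> int:
        return len(self.alignment[0]) if self.alignment else 0

    def column_offsets(self, member: int) -> np.ndarray:
        """Per-column offset into the member's (ungapped) sequence; -1 at gaps."""
        row = np.frombuffer(self.alignment[member].encode(), dtype=np.uint8)
        is_base = row != ord("-")
        off = np.cumsum(is_base) - 1
        off[~is_base] = -1
        return off

    def offset_to_column(self, member: int, offset: int) -> int:
        """Alignment column holding the member's ``offset``-th base."""
        off = self.column_offsets(member)
        cols = np.nonzero(off == offset)[0]
        if len(cols) == 0:
            raise IndexError(f"offset {offset} outside member {member}")
        return int(cols[0])

    def member_offset_to_genomic(self, member: int, offset: int) -> tuple[str, int]:
        iv = self.members[member]
        if iv.strand == "+":
            return iv.chrom, iv.start + offset
        return iv.chrom, iv.end - 1 - offset

    def genomic_to_member_offset(self, member: int, chrom: str, pos: int) -> int:
        iv = self.members[member]
        if chrom != iv.chrom or not iv.contains_point(pos):
            raise IndexError(f"{chrom}:{pos} outside member {member}")
        return pos - iv.start if iv.strand == "+" else iv.end - 1 - pos

    def project(self, from_member: int, offset: int, to_member: int) -> int | None:
        """Project a member offset through the alignment; None at gap columns."""
        col = self.offset_to_column(from_member, offset)
        target = int(self.column_offsets(to_member)[col])
        return None if target < 0 else target


@dataclass(frozen=True)
class SunRecord:
    """A singly unique nucleotide: a column where paralogs disagree.

    ``per_member_allele`` holds each member's bases over the SUN's columns
    ('' for a member gapped there); ``member_positions`` the genomic
    coordinate of the first non-gap column per member (None if all-gap).
    """

    set_id: str
    column: int
    n_columns: int
    per_member_allele: tuple[str, ...]
    member_positions: tuple[tuple[str, int] | None, ...]
    kind: str  # 'snv' or 'indel'


@dataclass(frozen=True)
class SubRegion:
    """An exon-resolution unit within a paralog member."""

    set_id: str
    member_index: int
    interval: GenomicInterval
    partner_intervals: tuple[GenomicInterval, ...] = ()

    @property
    def key(self) -> str:
        iv = self.interval
        return f"{self.set_id}:{self.member_index}:{iv.chrom}:{iv.start}-{iv.end}"


# ---------------------------------------------------------------------------
# Reads and alignment stores
# ---------------------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    return [(op, int(n)) for n, op in _CIGAR_RE.findall(cigar)]


def cigar_ref_len(cigar: str | None, seq_len: int) -> int:
    if cigar is None:
        return seq_len
    return sum(n for op, n in parse_cigar(cigar) if op in "M=XDN")


@dataclass
class Read:
    """A placed sequencing read (SAM conventions, 0-based start)."""

    name: str
    chrom: str
    start: int
    seq: str
    mapq: int
    strand: str = "+"
    cigar: str | None = None  # None means gapless full-length match layout
    sample_id: str = ""
    origin_member: int = -1
    is_paired: bool = False
    mate_name: str | None = None

    @property
    def end(self) -> int:
        return self.start + cigar_ref_len(self.cigar, len(self.seq))


class AlignmentStore:
    """Position-queryable store of reads for one or more samples."""

    def __init__(self, reads: Iterable[Read] = ()) -> None:
        self._reads: list[Read] = []
        self._index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] | None = None
        for r in reads:
            self.add(r)

    def add(self, read: Read) -> None:
        self._reads.append(read)
        self._index = None

    def _build_index(self) -> None:
        by_chrom: dict[str, list[tuple[int, int, int, int]]] = {}
        for i, r in enumerate(self._reads):
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end, r.mapq, i))
        self._index = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            starts, ends, mqs, idxs = (np.array(col) for col in zip(*rows))
            self._index[chrom] = (starts, ends, mqs, idxs)

    def fetch(self, chrom: str, start: int, end: int) -> list[Read]:
        if self._index is None:
            self._build_index()
        entry = self._index.get(chrom)
        if entry is None:
            return []
        starts, ends, _, idxs = entry
        k = int(np.searchsorted(starts, end, side="left"))
        hit = idxs[:k][ends[:k] > start]
        return [self._reads[i] for i in np.sort(hit)]

    def count_overlap(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """(MQ>0 count, total count) of reads overlapping [start, end)."""
        if self._index is None:
            self._build_index()
        entry = self._index.get(chrom)
        if entry is None:
            return 0, 0
        starts, ends, mqs, _ = entry
        k = int(np.searchsorted(starts, end, side="left"))
        hit = ends[:k] > start
        return int((hit & (mqs[:k] > 0)).sum()), int(hit.sum())

    def __iter__(self) -> Iterator[Read]:
        return iter(sorted(self._reads, key=lambda r: (r.chrom, r.start, r.name)))

    def __len__(self) -> int:
        return len(self._reads)

    # ---- SAM round-trip -------------------------------------------------
    def to_sam(self, path: str, genome: Genome) -> None:
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": name, "LN": len(seq)} for name, seq in genome.contigs.items()
            ],
        }
        with pysam.AlignmentFile(path, "w", header=header) as out:
            for read in self:
                a = pysam.AlignedSegment(out.header)
                a.query_name = read.name
                a.query_sequence = read.seq
                a.reference_name = read.chrom
                a.reference_start = read.start
                a.mapping_quality = read.mapq
                a.cigarstring = read.cigar or f"{len(read.seq)}M"
                a.flag = 16 if read.strand == "-" else 0
                a.set_tag("SM", read.sample_id)
                a.set_tag("OM", read.origin_member)
                out.write(a)

    @classmethod
    def from_sam(cls, path: str) -> "AlignmentStore":
        store = cls()
        with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
            for a in fh:
                if a.is_unmapped:
                    continue
                store.add(
                    Read(
                        name=a.query_name,
                        chrom=a.reference_name,
                        start=a.reference_start,
                        seq=a.query_sequence or "",
                        mapq=a.mapping_quality,
                        strand="-" if a.is_reverse else "+",
                        cigar=a.cigarstring,
                        sample_id=str(a.get_tag("SM")) if a.has_tag("SM") else "",
                        origin_member=int(a.get_tag("OM")) if a.has_tag("OM") else -1,
                    )
                )
        return store


def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())
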