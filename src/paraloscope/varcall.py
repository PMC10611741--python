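"""Sensitive pileup calling on masked alignments and variant processing.

Variant calls on the masked alignment pool reads from all members of a
paralog set, so allele fractions sit at multiples of 1/(2 x n_members)
rather than 0.5 — the caller therefore applies no allele-ratio prior, only
a minimal read-support threshold. Heterozygous non-SUN calls are expanded
to VAPs (variants with ambiguous positions), one candidate per paralog.
"""
from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .model import (
    AlignmentStore,
    Genome,
    GenomicInterval,
    ParalogSet,
    SubRegion,
    SunRecord,
    parse_cigar,
    translate_codon,
)

logger = logging.getLogger("paraloscope")

MIN_SUPPORT = 2
MIN_DEPTH = 60
MIN_VAF = 0.15
HOM_VAF = 0.85
MAX_CAF = 0.10
HOMOPOLYMER_MIN_RUN = 6
HOMOPOLYMER_PAD = 2
SUN_DENSE_COUNT = 5
SUN_DENSE_SPAN = 10


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class VariantCall:
    """A call in masked coordinates (0-based ``pos``)."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    vaf: float
    set_id: str = ""
    zygosity_class: str = "vap_het"  # vap_het | hom_all_paralogs | sun_site
    in_original_vcf: bool = False

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass(frozen=True)
class VapCandidate:
    member_index: int
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str = "other"
    projectable: bool = True


@dataclass
class VAP:
    parent: VariantCall
    candidates: list[VapCandidate]


@dataclass
class FilterTrace:
    caf_fail: bool = False
    vaf_consistency_fail: bool = False
    homopolymer_fail: bool = False
    sun_dense_fail: bool = False

    @property
    def surviving(self) -> bool:
        return not (self.caf_fail or self.vaf_consistency_fail
                    or self.homopolymer_fail or self.sun_dense_fail)

    @property
    def first_fail(self) -> str | None:
        for name in ("caf_fail", "vaf_consistency_fail",
                     "homopolymer_fail", "sun_dense_fail"):
            if getattr(self, name):
                return name
        return None


# ---------------------------------------------------------------------------
# Pileup engine
# ---------------------------------------------------------------------------

class _Pileup:
    def __init__(self, genome: Genome) -> None:
        self.genome = genome
        self.cov: dict[str, np.ndarray] = {}
        self.bases: Counter = Counter()        # (chrom, pos, base) -> count
        self.ins: Counter = Counter()          # (chrom, anchor, seq) -> count
        self.dels: Counter = Counter()         # (chrom, anchor, len) -> count

    def _cov_diff(self, chrom: str) -> np.ndarray:
        if chrom not in self.cov:
            self.cov[chrom] = np.zeros(self.genome.contig_length(chrom) + 1, dtype=np.int32)
        return self.cov[chrom]

    def add_read(self, read) -> None:
        chrom = read.chrom
        ref = self.genome.contigs[chrom]
        diff = self._cov_diff(chrom)
        ops = parse_cigar(read.cigar) if read.cigar else [("M", len(read.seq))]
        rpos, qpos = read.start, 0
        for op, n in ops:
            if op in "M=X":
                diff[rpos] += 1
                diff[rpos + n] -= 1
                if op == "=":
                    pass
                else:  # M or X: compare against the reference
                    seg = read.seq[qpos : qpos + n]
                    refseg = ref[rpos : rpos + n]
                    if seg != refseg:
                        for i, (a, b) in enumerate(zip(seg, refseg)):
                            if a != b:
                                self.bases[(chrom, rpos + i, a)] += 1
                rpos += n
                qpos += n
            elif op == "I":
                if rpos > read.start:
                    self.ins[(chrom, rpos - 1, read.seq[qpos : qpos + n])] += 1
                qpos += n
            elif op in "DN":
                if op == "D" and rpos > read.start:
                    self.dels[(chrom, rpos - 1, n)] += 1
                diff[rpos] += 1
                diff[rpos + n] -= 1
                rpos += n
            elif op in "SH":
                if op == "S":
                    qpos += n
            else:
                raise ValueError(f"unsupported cigar op {op}")

    def depth_array(self, chrom: str) -> np.ndarray:
        diff = self._cov_diff(chrom)
        return np.cumsum(diff)[:-1]


def pileup_call(
    store: AlignmentStore,
    regions: Sequence[GenomicInterval],
    genome: Genome,
    min_support: int = MIN_SUPPORT,
    min_mq: int = 0,
    sample_id: str = "",
) -> list[VariantCall]:
    """Report every non-reference allele with >= ``min_support`` reads.

    No allele-ratio prior is applied; exact depth and VAF accompany each
    call. ``min_mq`` > 0 gives the MQ-aware behaviour of a conventional
    caller (used on unmasked alignments).
    """
    pile = _Pileup(genome)
    n_added = 0
    for region in regions:
        for read in store.fetch(region.chrom, region.start, region.end):
            if read.mapq < min_mq:
                continue
            pile.add_read(read)
            n_added += 1
    if n_added == 0:
        logger.info("no reads in pileup regions")
        return []

    depth_cache: dict[str, np.ndarray] = {}

    def depth_at(chrom: str, pos: int) -> int:
        if chrom not in depth_cache:
            depth_cache[chrom] = pile.depth_array(chrom)
        arr = depth_cache[chrom]
        return int(arr[pos]) if 0 <= pos < len(arr) else 0

    def in_regions(chrom: str, pos: int) -> bool:
        return any(r.chrom == chrom and r.contains_point(pos) for r in regions)

    calls: list[VariantCall] = []
    for (chrom, pos, base), count in sorted(pile.bases.items()):
        if count < min_support or not in_regions(chrom, pos):
            continue
        depth = depth_at(chrom, pos)
        ref = pile.genome.fetch(chrom, pos, pos + 1)
        calls.append(VariantCall(
            sample_id=sample_id, chrom=chrom, pos=pos, ref=ref, alt=base,
            depth=depth, vaf=count / depth if depth else 0.0,
        ))
    for (chrom, anchor, seq), count in sorted(pile.ins.items()):
        if count < min_support or not in_regions(chrom, anchor):
            continue
        depth = depth_at(chrom, anchor)
        ref = pile.genome.fetch(chrom, anchor, anchor + 1)
        calls.append(VariantCall(
            sample_id=sample_id, chrom=chrom, pos=anchor, ref=ref, alt=ref + seq,
            depth=depth, vaf=count / depth if depth else 0.0,
        ))
    for (chrom, anchor, dlen), count in sorted(pile.dels.items()):
        if count < min_support or not in_regions(chrom, anchor):
            continue
        depth = depth_at(chrom, anchor)
        ref = pile.genome.fetch(chrom, anchor, anchor + 1 + dlen)
        calls.append(VariantCall(
            sample_id=sample_id, chrom=chrom, pos=anchor, ref=ref, alt=ref[0],
            depth=depth, vaf=count / depth if depth else 0.0,
        ))
    calls.sort(key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
    return calls


def call_unmasked(
    store: AlignmentStore,
    regions: Sequence[GenomicInterval],
    genome: Genome,
    min_support: int = MIN_SUPPORT,
    min_vaf: float = 0.20,
    sample_id: str = "",
) -> list[VariantCall]:
    """Conventional MQ-aware calling on the original (unmasked) alignment.

    Only reads with MQ > 0 contribute; in fully ambiguous regions this
    caller is blind by construction. Output serves as each sample's
    "original VCF" for the raw-call-set exclusion.
    """
    calls = pileup_call(store, regions, genome, min_support=min_support,
                        min_mq=1, sample_id=sample_id)
    return [c for c in calls if c.vaf >= min_vaf]


def site_vaf_lookup(
    store: AlignmentStore,
    regions: Sequence[GenomicInterval],
    genome: Genome,
):
    """Depth/VAF lookup at arbitrary (chrom, pos, ref, alt) keys.

    Used for parental genotyping in trio validation: returns a callable
    mapping a variant key to (vaf, depth), or None outside the piled-up
    regions.
    """
    pile = _Pileup(genome)
    for region in regions:
        for read in store.fetch(region.chrom, region.start, region.end):
            pile.add_read(read)
    depth_cache: dict[str, np.ndarray] = {}

    def lookup(key: tuple[str, int, str, str]) -> tuple[float, int] | None:
        chrom, pos, ref, alt = key
        if chrom not in pile.cov:
            return None
        if chrom not in depth_cache:
            depth_cache[chrom] = pile.depth_array(chrom)
        arr = depth_cache[chrom]
        if not (0 <= pos < len(arr)):
            return None
        depth = int(arr[pos])
        if len(ref) == len(alt) == 1:
            count = pile.bases.get((chrom, pos, alt), 0)
        elif len(ref) > len(alt):
            count = pile.dels.get((chrom, pos, len(ref) - len(alt)), 0)
        else:
            count = pile.ins.get((chrom, pos, alt[len(ref):]), 0)
        return (count / depth if depth else 0.0, depth)

    return lookup


# ---------------------------------------------------------------------------
# Normalization and SUN lookup
# ---------------------------------------------------------------------------

def normalize_variant(chrom: str, pos: int, ref: str, alt: str, genome: Genome) -> tuple[str, int, str, str]:
    """Left-aligned minimal representation of a variant."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    # left-shift pure indels while flanking context allows
    while len(ref) != len(alt) and len(ref) >= 1 and len(alt) >= 1 and pos > 0:
        if ref[0] != alt[0]:
            break
        longer = ref if len(ref) > len(alt) else alt
        prev = genome.fetch(chrom, pos - 1, pos)
        if longer[-1] != prev:
            break
        ref = prev + ref[:-1]
        alt = prev + alt[:-1]
        pos -= 1
    return chrom, pos, ref, alt


def sun_alteration_lookup(
    sets_and_suns: Sequence[tuple[ParalogSet, Sequence[SunRecord]]],
) -> set[tuple[str, int, str]]:
    """(chrom, pos, alt) triples on unmasked members that match a SUN allele.

    A masked-alignment call whose alt equals another member's allele at that
    column is an alteration of a singly unique nucleotide, not a variant.
    """
    lookup: set[tuple[str, int, str]] = set()
    for pset, suns in sets_and_suns:
        u = pset.unmasked_member
        for sun in suns:
            if sun.kind != "snv":
                continue
            upos = sun.member_positions[u]
            if upos is None:
                continue
            chrom, pos = upos
            for m, allele in enumerate(sun.per_member_allele):
                if m != u and allele and allele != sun.per_member_allele[u]:
                    lookup.add((chrom, pos, allele))
    return lookup


# ---------------------------------------------------------------------------
# Raw call set
# ---------------------------------------------------------------------------

def build_raw_callset(
    calls: Sequence[VariantCall],
    sun_lookup: set[tuple[str, int, str]],
    original_vcf: set[tuple[str, int, str, str]] | None,
    genome: Genome,
    min_depth: int = MIN_DEPTH,
    min_vaf: float = MIN_VAF,
    hom_vaf: float = HOM_VAF,
) -> list[VariantCall]:
    """Raw call set: non-SUN, depth >= 60, VAF >= 0.15, absent from the
    sample's original (unmasked) VCF after left-aligned normalization.

    Calls with VAF >= ``hom_vaf`` are classed homozygous-in-all-paralogs;
    the rest are VAP-heterozygous.
    """
    if original_vcf is None:
        raise ValueError("original VCF required: criterion unevaluable without it")
    raw: list[VariantCall] = []
    for call in calls:
        if len(call.ref) == 1 and len(call.alt) == 1 and \
                (call.chrom, call.pos, call.alt) in sun_lookup:
            call.zygosity_class = "sun_site"
            continue
        if call.depth < min_depth or call.vaf < min_vaf:
            continue
        norm = normalize_variant(call.chrom, call.pos, call.ref, call.alt, genome)
        if norm in original_vcf:
            call.in_original_vcf = True
            continue
        call.zygosity_class = "hom_all_paralogs" if call.vaf >= hom_vaf else "vap_het"
        raw.append(call)
    return raw


def assign_sets(calls: Iterable[VariantCall], sets: Sequence[ParalogSet]) -> None:
    """Attach set_id by locating each call inside an unmasked member."""
    for call in calls:
        for pset in sets:
            member = pset.members[pset.unmasked_member]
            if member.chrom == call.chrom and member.contains_point(call.pos):
                call.set_id = pset.set_id
                break


# ---------------------------------------------------------------------------
# VAP expansion
# ---------------------------------------------------------------------------

def expand_to_vaps(
    call: VariantCall,
    pset: ParalogSet,
    transcripts: Sequence["TranscriptModel"] = (),
    genome: Genome | None = None,
) -> VAP:
    """Expand a VAP-heterozygous call into one candidate per paralog.

    Indels are left-aligned within the alignment and anchored to the last
    non-gap column; members lacking the column are flagged non-projectable
    but still counted, so |candidates| == n_members always holds.
    """
    if call.zygosity_class != "vap_het":
        raise ValueError("only vap_het calls are expanded")
    u = pset.unmasked_member
    offset = pset.genomic_to_member_offset(u, call.chrom, call.pos)
    col = pset.offset_to_column(u, offset)
    candidates: list[VapCandidate] = []
    for m in range(pset.n_members):
        off_map = pset.column_offsets(m)
        target = int(off_map[col])
        projectable = target >= 0
        if not projectable and call.is_indel:
            # anchor to the last non-gap column at or before col
            prior = off_map[: col + 1]
            nz = prior[prior >= 0]
            if nz.size:
                target = int(nz[-1])
                projectable = True
        if target < 0:
            candidates.append(VapCandidate(
                member_index=m, chrom=pset.members[m].chrom, pos=-1,
                ref=call.ref, alt=call.alt, projectable=False,
            ))
            continue
        chrom, gpos = pset.member_offset_to_genomic(m, target)
        if call.is_indel:
            ref, alt = call.ref, call.alt
        else:
            ref = pset.seqs[m][target]
            alt = call.alt
        consequence = "other"
        for tx in transcripts:
            c = annotate_consequence(chrom, gpos, ref, alt, tx, genome)
            if c != "other":
                consequence = c
                break
        candidates.append(VapCandidate(
            member_index=m, chrom=chrom, pos=gpos, ref=ref, alt=alt,
            consequence=consequence, projectable=projectable,
        ))
    return VAP(parent=call, candidates=candidates)


# ---------------------------------------------------------------------------
# Conversion-introduced variants
# ---------------------------------------------------------------------------

def conversion_introduced_variants(
    acceptor_member: int,
    donor_member: int,
    interval: GenomicInterval,
    pset: ParalogSet,
    suns: Sequence[SunRecord],
) -> list[dict]:
    """Homozygous site-specific variants implied by a conversion event.

    For every SUN inside the converted interval the donor allele appears at
    the acceptor coordinate. A conversion interval without SUNs is silent.
    """
    out: list[dict] = []
    for sun in suns:
        pos_entry = sun.member_positions[acceptor_member]
        acc_allele = sun.per_member_allele[acceptor_member]
        don_allele = sun.per_member_allele[donor_member]
        if don_allele == acc_allele:
            continue
        if pos_entry is None:
            # acceptor gapped: insertion of donor bases; anchor left of the gap
            anchor = _anchor_before(pset, acceptor_member, sun.column)
            if anchor is None:
                continue
            chrom, gpos = anchor
            if not interval.contains_point(gpos):
                continue
            base = pset.seqs[acceptor_member][
                pset.genomic_to_member_offset(acceptor_member, chrom, gpos)
            ]
            out.append({"chrom": chrom, "pos": gpos, "ref": base,
                        "alt": base + don_allele, "zygosity": "hom",
                        "kind": "indel"})
            continue
        chrom, gpos = pos_entry
        if not interval.contains_point(gpos):
            continue
        if sun.kind == "snv":
            out.append({"chrom": chrom, "pos": gpos, "ref": acc_allele,
                        "alt": don_allele, "zygosity": "hom", "kind": "snv"})
        else:
            if don_allele == "":
                # donor gapped: conversion deletes the acceptor bases
                anchor = _anchor_before(pset, acceptor_member, sun.column)
                if anchor is None:
                    continue
                achrom, apos = anchor
                base = pset.seqs[acceptor_member][
                    pset.genomic_to_member_offset(acceptor_member, achrom, apos)
                ]
                out.append({"chrom": achrom, "pos": apos,
                            "ref": base + acc_allele, "alt": base,
                            "zygosity": "hom", "kind": "indel"})
            else:
                out.append({"chrom": chrom, "pos": gpos, "ref": acc_allele,
                            "alt": don_allele, "zygosity": "hom",
                            "kind": "indel"})
    return out


def _anchor_before(pset: ParalogSet, member: int, col: int) -> tuple[str, int] | None:
    off_map = pset.column_offsets(member)
    prior = off_map[:col]
    nz = prior[prior >= 0]
    if nz.size == 0:
        return None
    return pset.member_offset_to_genomic(member, int(nz[-1]))


# ---------------------------------------------------------------------------
# Consequence annotation (toy, canonical-transcript level)
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """A minimal coding transcript: ordered CDS intervals plus strand."""

    gene_name: str
    chrom: str
    strand: str
    cds: list[GenomicInterval]

    def cds_positions(self) -> list[int]:
        pos = [p for iv in sorted(self.cds, key=lambda i: i.start)
               for p in range(iv.start, iv.end)]
        return pos if self.strand == "+" else pos[::-1]


def annotate_consequence(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    tx: TranscriptModel,
    genome: Genome | None,
) -> str:
    """Codon-level classification on one transcript.

    Stop-gain, frameshift and canonical-splice hits are LoF; coding
    substitutions are synonymous/missense; everything else is 'other'.
    """
    if chrom != tx.chrom:
        return "other"
    positions = tx.cds_positions()
    pos_index = {p: i for i, p in enumerate(positions)}
    if len(ref) != len(alt):
        span = range(pos, pos + max(len(ref), 1))
        if any(p in pos_index for p in span):
            return "LoF" if abs(len(ref) - len(alt)) % 3 else "other"
        if _near_splice(pos, tx):
            return "LoF"
        return "other"
    if pos not in pos_index:
        return "LoF" if _near_splice(pos, tx) else "other"
    if genome is None:
        return "other"
    cds_seq = "".join(genome.fetch(chrom, p, p + 1) for p in sorted(pos_index))
    if tx.strand == "-":
        from .model import revcomp
        cds_seq = revcomp(cds_seq)
    i = pos_index[pos]
    base = alt
    if tx.strand == "-":
        from .model import revcomp as _rc
        base = _rc(alt)
    codon_i = i // 3
    codon = cds_seq[codon_i * 3 : codon_i * 3 + 3]
    if len(codon) < 3:
        return "other"
    mutated = codon[: i % 3] + base + codon[i % 3 + 1 :]
    old_aa, new_aa = translate_codon(codon), translate_codon(mutated)
    if new_aa == old_aa:
        return "synonymous"
    if new_aa == "*":
        return "LoF"
    return "missense"


def _near_splice(pos: int, tx: TranscriptModel) -> bool:
    if len(tx.cds) < 2:
        return False
    ordered = sorted(tx.cds, key=lambda i: i.start)
    for k, iv in enumerate(ordered):
        if k > 0 and iv.start - 2 <= pos < iv.start:
            return True
        if k < len(ordered) - 1 and iv.end <= pos < iv.end + 2:
            return True
    return False


# ---------------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------------

def filter_cascade(
    raw_calls: Sequence[VariantCall],
    cohort_size: int,
    genome: Genome,
    sets_and_suns: Sequence[tuple[ParalogSet, Sequence[SunRecord]]] = (),
    cohort_calls: Sequence[VariantCall] | None = None,
    subregions: Sequence[SubRegion] | None = None,
    max_caf: float = MAX_CAF,
) -> tuple[list[VariantCall], dict[int, FilterTrace]]:
    """Apply the four cohort/context filters in order.

    1. cohort allele frequency strictly > ``max_caf`` removes the variant;
    2. more than twice as many samples at VAF > 0.05 than at VAF > 0.15
       marks a systematically low-quality variant;
    3. variants within 2 bp of a >=6 bp homopolymer tract are dropped;
    4. variants in subregions with 5 SUNs inside a 10 bp stretch are
       dropped (alignment ambiguity inflates false calls there).

    Returns the surviving calls and one FilterTrace per input index.
    """
    if cohort_size <= 0:
        raise ValueError("cohort of size 0")
    pool = list(cohort_calls) if cohort_calls is not None else list(raw_calls)

    carriers: dict[tuple, set[str]] = defaultdict(set)
    for c in raw_calls:
        carriers[c.key].add(c.sample_id)
    n_gt05: Counter = Counter()
    n_gt15: Counter = Counter()
    seen05: set[tuple] = set()
    seen15: set[tuple] = set()
    for c in pool:
        if c.vaf > 0.05 and (c.key, c.sample_id) not in seen05:
            seen05.add((c.key, c.sample_id))
            n_gt05[c.key] += 1
        if c.vaf > 0.15 and (c.key, c.sample_id) not in seen15:
            seen15.add((c.key, c.sample_id))
            n_gt15[c.key] += 1

    dense = _sun_dense_regions(sets_and_suns, subregions)

    surviving: list[VariantCall] = []
    traces: dict[int, FilterTrace] = {}
    for idx, call in enumerate(raw_calls):
        trace = FilterTrace()
        trace.caf_fail = len(carriers[call.key]) / cohort_size > max_caf
        trace.vaf_consistency_fail = n_gt05[call.key] > 2 * n_gt15[call.key]
        trace.homopolymer_fail = near_homopolymer(genome, call.chrom, call.pos)
        trace.sun_dense_fail = any(
            iv.chrom == call.chrom and iv.contains_point(call.pos) for iv in dense
        )
        traces[idx] = trace
        if trace.surviving:
            surviving.append(call)
    return surviving, traces


def near_homopolymer(
    genome: Genome,
    chrom: str,
    pos: int,
    min_run: int = HOMOPOLYMER_MIN_RUN,
    pad: int = HOMOPOLYMER_PAD,
    scan: int = 40,
) -> bool:
    """True when ``pos`` lies within ``pad`` bp of a homopolymer >= min_run.

    Tracts are computed from the reference on the fly.
    """
    clen = genome.contig_length(chrom)
    w0 = max(0, pos - scan)
    w1 = min(clen, pos + scan)
    seq = genome.fetch(chrom, w0, w1)
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            if w0 + i - pad <= pos < w0 + j + pad:
                return True
        i = j
    return False


def _sun_dense_regions(
    sets_and_suns: Sequence[tuple[ParalogSet, Sequence[SunRecord]]],
    subregions: Sequence[SubRegion] | None,
    count: int = SUN_DENSE_COUNT,
    span: int = SUN_DENSE_SPAN,
) -> list[GenomicInterval]:
    """Regions whose SUN spacing disqualifies variant calls.

    The unit is the subregion containing a 5-SUN/10-bp stretch, or the whole
    unmasked member when no subregion list is supplied.
    """
    out: list[GenomicInterval] = []
    for pset, suns in sets_and_suns:
        u = pset.unmasked_member
        member = pset.members[u]
        positions = sorted(
            p[1] for sun in suns
            if (p := sun.member_positions[u]) is not None
        )
        windows = [
            (positions[i], positions[i + count - 1])
            for i in range(len(positions) - count + 1)
            if positions[i + count - 1] - positions[i] + 1 <= span
        ]
        if not windows:
            continue
        units = [s.interval for s in subregions or []
                 if s.set_id == pset.set_id and s.member_index == u] or [member]
        for lo, hi in windows:
            for unit in units:
                if unit.contains_point(lo) or unit.contains_point(hi):
                    out.append(unit)
    return out
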