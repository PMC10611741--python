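"""Masked-reference construction and re-alignment of extracted reads.

All but one member of each paralog set is N-filled in the reference; reads
extracted around the paralogous regions are then re-aligned so that every
read from a set lands uniquely on the unmasked member. The internal aligner
is a k-mer seed + edit-distance extension: masked references make placements
unique by construction, so a production-sensitivity aligner is unnecessary.
An external hook accepts any tool that produces SAM.
"""
from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import edlib
import numpy as np

from .model import AlignmentStore, Genome, GenomicInterval, ParalogSet, Read, revcomp

logger = logging.getLogger("paraloscope")

SEED_K = 15
MAX_EDIT_FRACTION = 0.10


# ---------------------------------------------------------------------------
# Masked reference
# ---------------------------------------------------------------------------

@dataclass
class MaskedReference:
    genome: Genome
    masked_intervals: list[GenomicInterval]


def mask_reference(genome: Genome, sets: Sequence[ParalogSet]) -> MaskedReference:
    """N-fill every member except the chosen unmasked one, per set."""
    masked: list[GenomicInterval] = []
    for pset in sets:
        for m, iv in enumerate(pset.members):
            if m != pset.unmasked_member:
                masked.append(iv)
    for i, a in enumerate(masked):
        for b in masked[i + 1:]:
            if a.overlaps(b):
                raise ValueError(
                    f"mask intervals overlap across sets: {a} vs {b}"
                )
    contigs = {name: bytearray(seq.encode()) for name, seq in genome.contigs.items()}
    for iv in masked:
        contigs[iv.chrom][iv.start : iv.end] = b"N" * len(iv)
    return MaskedReference(
        genome=Genome({k: v.decode() for k, v in contigs.items()}),
        masked_intervals=masked,
    )


# ---------------------------------------------------------------------------
# Extraction and pair hygiene
# ---------------------------------------------------------------------------

def extract_reads(store: AlignmentStore, regions: Sequence[GenomicInterval]) -> list[Read]:
    """Every read overlapping a region by >=1 bp, exactly once (MQ 0 included)."""
    seen: set[int] = set()
    out: list[Read] = []
    for region in regions:
        for read in store.fetch(region.chrom, region.start, region.end):
            key = id(read)
            if key not in seen:
                seen.add(key)
                out.append(read)
    return out


def drop_broken_pairs(reads: Sequence[Read]) -> tuple[list[Read], int]:
    """Remove reads whose mate was not extracted; no-op for single-end."""
    paired = [r for r in reads if r.is_paired]
    if not paired:
        return list(reads), 0
    names = Counter(r.name for r in paired)
    kept = [r for r in reads if not r.is_paired or names[r.name] == 2]
    return kept, len(reads) - len(kept)


# ---------------------------------------------------------------------------
# Internal aligner
# ---------------------------------------------------------------------------

class KmerIndex:
    """Exact k-mer index over the non-N portion of a genome."""

    def __init__(self, genome: Genome, k: int = SEED_K) -> None:
        self.k = k
        self.genome = genome
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, seq in genome.contigs.items():
            for i in range(0, len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" not in kmer:
                    self._index[kmer].append((chrom, i))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])


@dataclass
class RemapResult:
    store: AlignmentStore
    counters: dict[str, int] = field(default_factory=dict)


def realign(
    reads: Sequence[Read],
    masked_ref: MaskedReference,
    aligner: str | Callable[[Sequence[Read], MaskedReference], AlignmentStore] = "internal",
    seed_k: int = SEED_K,
    max_edit_fraction: float = MAX_EDIT_FRACTION,
) -> RemapResult:
    """Re-align reads to the masked reference and collapse duplicates.

    Duplicates share (chrom, start, end, strand, sequence). Counters satisfy
    input = aligned + broken_pairs + duplicates + unplaced.
    """
    n_input = len(reads)
    kept, n_broken = drop_broken_pairs(reads)

    if callable(aligner):
        store = aligner(kept, masked_ref)
        counters = {
            "input": n_input, "broken_pairs": n_broken,
            "aligned": len(store), "duplicates": 0,
            "unplaced": len(kept) - len(store),
        }
        return RemapResult(store=store, counters=counters)

    index = KmerIndex(masked_ref.genome, k=seed_k)
    placed: list[Read] = []
    n_unplaced = 0
    for read in kept:
        hit = _place_read(read, index, max_edit_fraction)
        if hit is None:
            n_unplaced += 1
            continue
        placed.append(hit)

    deduped: list[Read] = []
    seen: set[tuple] = set()
    for read in sorted(placed, key=lambda r: (r.chrom, r.start, r.name)):
        key = (read.chrom, read.start, read.end, read.strand, read.seq)
        if key in seen:
            continue
        seen.add(key)
        deduped.append(read)
    n_dup = len(placed) - len(deduped)

    counters = {
        "input": n_input,
        "broken_pairs": n_broken,
        "aligned": len(deduped),
        "duplicates": n_dup,
        "unplaced": n_unplaced,
    }
    store = AlignmentStore(deduped)
    return RemapResult(store=store, counters=counters)


def _place_read(read: Read, index: KmerIndex, max_edit_fraction: float) -> Read | None:
    best: tuple[int, str, int, str, str] | None = None  # (dist, chrom, pos, cigar, strand)
    max_dist = max(1, int(len(read.seq) * max_edit_fraction))
    for seq, strand in ((read.seq, "+"), (revcomp(read.seq), "-")):
        candidates: set[tuple[str, int]] = set()
        k = index.k
        for off in range(0, len(seq) - k + 1, k):
            for chrom, pos in index.lookup(seq[off : off + k]):
                candidates.add((chrom, pos - off))
            if len(candidates) >= 64:
                break
        for chrom, pos in candidates:
            contig = index.genome.contigs[chrom]
            if 0 <= pos and contig[pos : pos + len(seq)] == seq:
                best = (0, chrom, pos, f"{len(seq)}=", strand)
                break
            pad = 8
            w0 = max(0, pos - pad)
            w1 = min(len(contig), pos + len(seq) + pad)
            window = contig[w0:w1]
            res = edlib.align(seq, window, mode="HW", task="path", k=max_dist)
            if res["editDistance"] < 0:
                continue
            dist = res["editDistance"]
            loc = res["locations"][0]
            start = w0 + loc[0]
            cigar = res["cigar"]
            if best is None or dist < best[0]:
                best = (dist, chrom, start, cigar, strand)
            if dist == 0:
                break
        if best is not None and best[0] == 0:
            break
    if best is None:
        return None
    dist, chrom, start, cigar, strand = best
    seq = read.seq if strand == "+" else revcomp(read.seq)
    return Read(
        name=read.name,
        chrom=chrom,
        start=start,
        seq=seq,
        mapq=60,
        strand=strand,
        cigar=cigar,
        sample_id=read.sample_id,
        origin_member=read.origin_member,
    )


def remap_sample(
    store: AlignmentStore,
    extraction: Sequence[GenomicInterval],
    masked_ref: MaskedReference,
    index: "KmerIndex | None" = None,
    max_edit_fraction: float = MAX_EDIT_FRACTION,
) -> RemapResult:
    """extract -> drop broken pairs -> realign, reusing a prebuilt index."""
    reads = extract_reads(store, extraction)
    if index is None:
        return realign(reads, masked_ref, max_edit_fraction=max_edit_fraction)
    # same as realign() but with a shared k-mer index across samples
    n_input = len(reads)
    kept, n_broken = drop_broken_pairs(reads)
    placed = []
    n_unplaced = 0
    for read in kept:
        hit = _place_read(read, index, max_edit_fraction)
        if hit is None:
            n_unplaced += 1
        else:
            placed.append(hit)
    deduped: list[Read] = []
    seen: set[tuple] = set()
    for read in sorted(placed, key=lambda r: (r.chrom, r.start, r.name)):
        key = (read.chrom, read.start, read.end, read.strand, read.seq)
        if key not in seen:
            seen.add(key)
            deduped.append(read)
    counters = {
        "input": n_input,
        "broken_pairs": n_broken,
        "aligned": len(deduped),
        "duplicates": len(placed) - len(deduped),
        "unplaced": n_unplaced,
    }
    return RemapResult(store=AlignmentStore(deduped), counters=counters)
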