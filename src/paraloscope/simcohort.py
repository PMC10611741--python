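"""Synthetic paralog loci and diploid cohorts with injected events.

The simulator emulates the read-level signature of paralogy in exome data:
reads whose sequence matches two or more paralogs equally well carry mapping
quality 0, reads covering a singly unique nucleotide (SUN) map uniquely, and
reads originating from the acceptor of a homozygous ectopic conversion carry
the donor's alleles and therefore pile up on the donor locus. Reads are
emitted pre-placed at their best-matching member (ties resolve to the true
origin with MQ 0) rather than through an external aligner; a FASTQ/SAM
export hook serves real aligners.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from .model import AlignmentStore, Genome, GenomicInterval, ParalogSet, Read

logger = logging.getLogger("paraloscope")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
DEFAULT_DEPTH = 100.0
DEFAULT_READ_LEN = 100
DEFAULT_ERR = 0.001
HIGH_MAPQ = 60


# ---------------------------------------------------------------------------
# Locus construction
# ---------------------------------------------------------------------------

@dataclass
class SimLocusSpec:
    """Parameters of one simulated set of paralogous regions."""

    n_members: int = 2
    length: int = 1500
    identity: float = 0.99
    sun_positions: Sequence[int] | None = None
    seed: int = 0
    chrom: str = "chrS"
    set_id: str = "simset"
    flank: int = 300
    spacer: int = 400

    def __post_init__(self) -> None:
        if not (0 < self.identity <= 1):
            raise ValueError("identity must be in (0, 1]")
        if self.length < 200:
            raise ValueError("length must be >= 200")


def _random_dna(rng: np.random.Generator, n: int, max_run: int = 3) -> np.ndarray:
    """Random sequence with homopolymer runs capped at ``max_run``."""
    out = np.empty(n, dtype=np.uint8)
    run = 0
    prev = -1
    draws = rng.integers(0, 4, size=2 * n + 16)
    j = 0
    for i in range(n):
        while True:
            if j >= len(draws):
                draws = rng.integers(0, 4, size=n)
                j = 0
            b = int(draws[j])
            j += 1
            if b == prev and run >= max_run:
                continue
            break
        run = run + 1 if b == prev else 1
        prev = b
        out[i] = _BASES[b]
    return out


def make_locus(spec: SimLocusSpec) -> tuple[ParalogSet, Genome]:
    """Build a paralog set of shared ancestry with the requested divergence.

    All members lie on one contig separated by unique spacer sequence. SUNs
    are substitution differences: at each SUN position one member carries a
    private allele, so pairwise identities are >= the requested identity and
    the SUN count is ~ length x (1 - identity). Deterministic under seed.
    """
    rng = np.random.default_rng(spec.seed)
    L, n = spec.length, spec.n_members
    expected = int(round(L * (1 - spec.identity)))
    if spec.sun_positions is not None:
        positions = sorted(int(p) for p in spec.sun_positions)
        if any(p < 0 or p >= L for p in positions):
            raise ValueError("sun_positions outside locus")
        if spec.identity < 1 and abs(len(positions) - expected) > max(2, expected // 2):
            raise ValueError(
                f"sun_positions ({len(positions)}) inconsistent with "
                f"identity {spec.identity} (expected ~{expected})"
            )
    else:
        positions = _draw_sun_positions(rng, L, expected)

    ancestor = _random_dna(rng, L)
    member_arrays = [ancestor.copy() for _ in range(n)]
    for k, pos in enumerate(positions):
        target = int(rng.integers(0, n)) if n > 2 else k % n
        ref = member_arrays[target][pos]
        alts = _BASES[_BASES != ref]
        member_arrays[target][pos] = alts[rng.integers(0, len(alts))]

    pieces: list[np.ndarray] = [_random_dna(rng, spec.flank)]
    members: list[GenomicInterval] = []
    offset = spec.flank
    for m in range(n):
        members.append(GenomicInterval(spec.chrom, offset, offset + L))
        pieces.append(member_arrays[m])
        offset += L
        if m < n - 1:
            pieces.append(_random_dna(rng, spec.spacer))
            offset += spec.spacer
    pieces.append(_random_dna(rng, spec.flank))
    contig = b"".join(p.tobytes() for p in pieces).decode()

    seqs = [arr.tobytes().decode() for arr in member_arrays]
    pset = ParalogSet(
        set_id=spec.set_id,
        members=members,
        seqs=seqs,
        alignment=list(seqs),  # gapless common ancestry: columns == offsets
        origin="set2",
    )
    return pset, Genome({spec.chrom: contig})


def _draw_sun_positions(
    rng: np.random.Generator, length: int, count: int, min_gap: int = 12
) -> list[int]:
    """Distinct SUN positions kept sparse so no 5 fall within 10 bp."""
    positions: list[int] = []
    attempts = 0
    margin = 5
    while len(positions) < count and attempts < 100 * max(count, 1):
        attempts += 1
        p = int(rng.integers(margin, length - margin))
        if all(abs(p - q) >= min_gap for q in positions):
            positions.append(p)
    return sorted(positions)


# ---------------------------------------------------------------------------
# Events and truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimEvent:
    """An injected genetic event in one simulated sample."""

    sample_id: str
    kind: str  # snv | indel | deletion_single | deletion_both | conversion
    member_index: int
    start: int  # genomic
    end: int
    ref: str = ""
    alt: str = ""
    zygosity: str = "hom"  # het | hom
    donor_member: int = -1

    def __post_init__(self) -> None:
        if self.kind == "conversion" and self.donor_member < 0:
            raise ValueError("conversion event needs a donor_member")


@dataclass
class SimTruth:
    events: list[SimEvent] = field(default_factory=list)
    expected_masked_vaf: dict[int, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Per-sample read simulation
# ---------------------------------------------------------------------------

def simulate_sample(
    pset: ParalogSet,
    events: Sequence[SimEvent],
    depth: float = DEFAULT_DEPTH,
    read_len: int = DEFAULT_READ_LEN,
    err: float = DEFAULT_ERR,
    seed: int = 0,
    sample_id: str = "S0",
    len_jitter: float = 0.10,
) -> tuple[list[Read], SimTruth]:
    """Simulate one diploid sample over a paralog set.

    Every member contributes two haplotypes. A read's mapping quality is 0
    when its sequence matches >=2 members equally well; otherwise it is
    placed on the best-matching member with high MQ, which reproduces the
    donor pile-up of conversions. Homozygously deleted intervals emit no
    reads. Read lengths vary uniformly within +-``len_jitter`` of
    ``read_len``, emulating adapter/quality trimming; without this, fixed
    single-end lengths would make position-based duplicate collapsing
    conflate distinct molecules at high depth.
    """
    rng = np.random.default_rng(seed)
    n = pset.n_members
    L = read_len
    member_lens = [len(s) for s in pset.seqs]
    if len(set(member_lens)) != 1:
        raise ValueError("simulator members must be equal length (gapless ancestry)")
    mlen = member_lens[0]
    member_refs = [np.frombuffer(s.encode(), dtype=np.uint8).copy() for s in pset.seqs]

    # haplotypes: substitution layer (n x 2 arrays) + optional indel edits
    haps = [[member_refs[m].copy() for _ in range(2)] for m in range(n)]
    indel_edits: dict[tuple[int, int], tuple[int, str, str]] = {}
    deleted: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    truth = SimTruth(events=list(events))

    for ei, ev in enumerate(events):
        m = ev.member_index
        if ev.kind != "deletion_both" and not (0 <= m < n):
            raise ValueError(f"event member {m} outside locus")
        if ev.kind in ("snv", "indel", "conversion", "deletion_single"):
            o0 = pset.genomic_to_member_offset(m, pset.members[m].chrom, ev.start)
            o1 = o0 + (ev.end - ev.start)
            if o1 > mlen:
                raise ValueError("event outside locus")
        if ev.kind == "snv":
            o0 = pset.genomic_to_member_offset(m, pset.members[m].chrom, ev.start)
            hap_ids = (0, 1) if ev.zygosity == "hom" else (0,)
            for h in hap_ids:
                haps[m][h][o0] = ord(ev.alt)
            truth.expected_masked_vaf[ei] = len(hap_ids) / (2 * n)
        elif ev.kind == "indel":
            o0 = pset.genomic_to_member_offset(m, pset.members[m].chrom, ev.start)
            hap_ids = (0, 1) if ev.zygosity == "hom" else (0,)
            for h in hap_ids:
                indel_edits[(m, h)] = (o0, ev.ref, ev.alt)
            truth.expected_masked_vaf[ei] = len(hap_ids) / (2 * n)
        elif ev.kind == "conversion":
            o0 = pset.genomic_to_member_offset(m, pset.members[m].chrom, ev.start)
            o1 = o0 + (ev.end - ev.start)
            donor = member_refs[ev.donor_member]
            for h in range(2):
                haps[m][h][o0:o1] = donor[o0:o1]
        elif ev.kind == "deletion_single":
            o0 = pset.genomic_to_member_offset(m, pset.members[m].chrom, ev.start)
            o1 = o0 + (ev.end - ev.start)
            deleted[m].append((o0, o1))
        elif ev.kind == "deletion_both":
            for mm in range(n):
                deleted[mm].append((0, mlen))
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")

    reads: list[Read] = []
    ridx = 0
    lmin = max(30, int(round(L * (1 - len_jitter))))
    lmax = int(round(L * (1 + len_jitter)))
    for m in range(n):
        n_total = int(round(depth * mlen / L))
        n_h0 = int(rng.binomial(n_total, 0.5))
        for h, n_reads in ((0, n_h0), (1, n_total - n_h0)):
            if n_reads == 0:
                continue
            lengths = rng.integers(lmin, lmax + 1, size=n_reads)
            starts = np.array([
                rng.integers(0, mlen - l + 1) for l in lengths
            ])
            # suppress reads over homozygously deleted intervals
            keep = np.ones(n_reads, dtype=bool)
            for d0, d1 in deleted[m]:
                keep &= (starts + lengths <= d0) | (starts >= d1)
            starts, lengths = starts[keep], lengths[keep]
            if len(starts) == 0:
                continue
            hap = haps[m][h]
            indel = indel_edits.get((m, h))
            for l in np.unique(lengths):
                sel = lengths == l
                sub_starts = starts[sel]
                seqs = hap[sub_starts[:, None] + np.arange(l)[None, :]].copy()
                # independent per-base substitution errors
                err_mask = rng.random(seqs.shape) < err
                if err_mask.any():
                    shift = rng.integers(1, 4, size=int(err_mask.sum()))
                    base_idx = np.searchsorted(_BASES, seqs[err_mask])
                    seqs[err_mask] = _BASES[(base_idx + shift) % 4]

                mism = np.empty((len(sub_starts), n), dtype=int)
                for mm in range(n):
                    refw = member_refs[mm][sub_starts[:, None] + np.arange(l)[None, :]]
                    mism[:, mm] = (seqs != refw).sum(axis=1)

                read_strs = [row.tobytes().decode() for row in seqs]
                if indel is not None:
                    read_strs, mism = _apply_indel(
                        read_strs, mism, sub_starts, indel, hap, member_refs, int(l)
                    )

                best = mism.min(axis=1)
                n_best = (mism == best[:, None]).sum(axis=1)
                argbest = mism.argmin(axis=1)
                for i, s in enumerate(sub_starts):
                    tie = n_best[i] >= 2
                    placed = m if tie else int(argbest[i])
                    chrom, gpos = pset.member_offset_to_genomic(placed, int(s))
                    reads.append(Read(
                        name=f"{sample_id}_r{ridx}",
                        chrom=chrom,
                        start=gpos,
                        seq=read_strs[i],
                        mapq=0 if tie else HIGH_MAPQ,
                        sample_id=sample_id,
                        origin_member=m,
                    ))
                    ridx += 1
    return reads, truth


def _apply_indel(
    read_strs: list[str],
    mism: np.ndarray,
    starts: np.ndarray,
    indel: tuple[int, str, str],
    hap: np.ndarray,
    member_refs: list[np.ndarray],
    L: int,
) -> tuple[list[str], np.ndarray]:
    """Redraw sequences of reads spanning an indel from the edited haplotype."""
    o0, ref, alt = indel
    hap_str = hap.tobytes().decode()
    edited = hap_str[:o0] + alt + hap_str[o0 + len(ref):]
    for i, s in enumerate(starts):
        s = int(s)
        if not (s <= o0 < s + L):
            continue
        read_strs[i] = edited[s : s + L]
        for mm, ref_arr in enumerate(member_refs):
            w0, w1 = s, min(len(ref_arr), s + L + 8)
            window = ref_arr[w0:w1].tobytes().decode()
            mism[i, mm] = edlib.align(read_strs[i], window, mode="HW")["editDistance"]
    return read_strs, mism


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortStore:
    """Simulated cohort: genome, paralog sets, per-sample reads and truth."""

    genome: Genome
    psets: list[ParalogSet]
    samples: list[str]
    stores: dict[str, AlignmentStore]
    kit_group: dict[str, str]
    truth: pd.DataFrame

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def simulate_cohort(
    locus_specs: Sequence[SimLocusSpec],
    n_samples: int,
    event_freqs: Mapping[str, float],
    depth: float = DEFAULT_DEPTH,
    read_len: int = DEFAULT_READ_LEN,
    err: float = DEFAULT_ERR,
    seed: int = 0,
    kit_groups: Sequence[str] = ("V5",),
    het_fraction: float = 1.0,
) -> CohortStore:
    """Simulate a cohort over one or more loci; events hit the first locus.

    ``event_freqs`` maps event kinds to per-sample probabilities. Coverage
    events (conversion / deletion_single / deletion_both) are mutually
    exclusive within a sample; at most one is drawn, with any SNV/indel
    suppressed alongside it. Reproducible under ``seed``.
    """
    if any(not (0 <= f <= 1) for f in event_freqs.values()):
        raise ValueError("event frequencies must be in [0, 1]")
    rng = np.random.default_rng(seed)

    psets: list[ParalogSet] = []
    contigs: dict[str, str] = {}
    for k, spec in enumerate(locus_specs):
        if spec.chrom in contigs:
            raise ValueError("locus specs must use distinct contig names")
        pset, genome = make_locus(spec)
        pset.set_id = spec.set_id if len(locus_specs) == 1 else f"{spec.set_id}_{k}"
        psets.append(pset)
        contigs.update(genome.contigs)
    genome = Genome(contigs)
    target = psets[0]
    target_len = len(target.seqs[0])

    samples = [f"S{i:04d}" for i in range(n_samples)]
    stores: dict[str, AlignmentStore] = {}
    kit_map: dict[str, str] = {}
    truth_rows: list[dict] = []
    coverage_kinds = ("deletion_both", "deletion_single", "conversion")

    for i, sample in enumerate(samples):
        kit_map[sample] = kit_groups[i % len(kit_groups)]
        events: list[SimEvent] = []
        drawn_cov = [k for k in coverage_kinds
                     if event_freqs.get(k, 0.0) > 0 and rng.random() < event_freqs[k]]
        if drawn_cov:
            kind = drawn_cov[int(rng.integers(0, len(drawn_cov)))]
            events.append(_draw_coverage_event(rng, target, sample, kind))
        else:
            for kind in ("snv", "indel"):
                if event_freqs.get(kind, 0.0) > 0 and rng.random() < event_freqs[kind]:
                    events.append(
                        _draw_small_event(rng, target, sample, kind, het_fraction)
                    )
        sample_seed = int(rng.integers(0, 2**31 - 1))
        all_reads: list[Read] = []
        for k, pset in enumerate(psets):
            locus_events = events if k == 0 else []
            reads, truth = simulate_sample(
                pset, locus_events, depth=depth, read_len=read_len, err=err,
                seed=sample_seed + k, sample_id=sample,
            )
            all_reads.extend(reads)
            if k == 0:
                for ei, ev in enumerate(truth.events):
                    truth_rows.append({
                        "sample_id": sample,
                        "kind": ev.kind,
                        "member_index": ev.member_index,
                        "chrom": target.members[max(ev.member_index, 0)].chrom,
                        "start": ev.start,
                        "end": ev.end,
                        "ref": ev.ref,
                        "alt": ev.alt,
                        "zygosity": ev.zygosity,
                        "donor_member": ev.donor_member,
                        "expected_masked_vaf": truth.expected_masked_vaf.get(ei, np.nan),
                    })
        stores[sample] = AlignmentStore(all_reads)

    truth_df = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "kind", "member_index", "chrom", "start", "end",
                 "ref", "alt", "zygosity", "donor_member", "expected_masked_vaf"],
    )
    return CohortStore(
        genome=genome, psets=psets, samples=samples, stores=stores,
        kit_group=kit_map, truth=truth_df,
    )


def _draw_coverage_event(
    rng: np.random.Generator, pset: ParalogSet, sample: str, kind: str
) -> SimEvent:
    mlen = len(pset.seqs[0])
    if kind == "deletion_both":
        iv = pset.members[0]
        return SimEvent(sample_id=sample, kind=kind, member_index=-1,
                        start=iv.start, end=iv.end)
    m = int(rng.integers(0, pset.n_members))
    iv = pset.members[m]
    if kind == "deletion_single":
        return SimEvent(sample_id=sample, kind=kind, member_index=m,
                        start=iv.start, end=iv.end)
    donor = int(rng.integers(0, pset.n_members - 1))
    if donor >= m:
        donor += 1
    return SimEvent(sample_id=sample, kind="conversion", member_index=m,
                    start=iv.start, end=iv.end, donor_member=donor)


def _draw_small_event(
    rng: np.random.Generator,
    pset: ParalogSet,
    sample: str,
    kind: str,
    het_fraction: float,
) -> SimEvent:
    mlen = len(pset.seqs[0])
    sun_offsets = {
        o for m in range(pset.n_members) for o in range(mlen)
        if len({s[o] for s in pset.seqs}) > 1
    }
    margin = 60
    while True:
        off = int(rng.integers(margin, mlen - margin))
        if off not in sun_offsets and (off + 1) not in sun_offsets:
            break
    m = int(rng.integers(0, pset.n_members))
    chrom, gpos = pset.member_offset_to_genomic(m, off)
    zyg = "het" if rng.random() < het_fraction else "hom"
    ref = pset.seqs[m][off]
    if kind == "snv":
        alt = rng.choice([b for b in "ACGT" if b != ref])
        return SimEvent(sample_id=sample, kind="snv", member_index=m,
                        start=gpos, end=gpos + 1, ref=ref, alt=str(alt),
                        zygosity=zyg)
    # 1 bp deletion anchored on the preceding base
    ref2 = pset.seqs[m][off : off + 2]
    return SimEvent(sample_id=sample, kind="indel", member_index=m,
                    start=gpos, end=gpos + 2, ref=ref2, alt=ref2[0],
                    zygosity=zyg)


def write_truth_tsv(cohort: CohortStore, path: str) -> None:
    cohort.truth.to_csv(path, sep="\t", index=False)


def write_fastq(reads: Sequence[Read], path: str) -> None:
    """Export simulated reads for an external aligner."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")
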