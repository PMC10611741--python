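"""Derivation of paralogous region sets, SUN catalogs and subregions.

Two sources of paralogy are combined: Set I pairs every protein-coding gene
with its annotated pseudogene(s) and keeps stretches of >=90% windowed
identity; Set II recovers paralogy directly from the footprints of
low-mapping-quality reads. Both feed the masked reference, the SUN catalog
and the exon-resolution subregions used by coverage-based CNV calling.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    Genome,
    GenomicInterval,
    IntervalIndex,
    ParalogSet,
    SubRegion,
    SunRecord,
    alignment_identity,
    global_align,
    identity_score,
    merge_intervals,
    progressive_msa,
    revcomp,
)

logger = logging.getLogger("paraloscope")

DEFAULT_IDENTITY_MIN = 0.90
DEFAULT_WINDOW = 100
DEFAULT_EXTRACTION_SLOP = 500
DEFAULT_SUBREGION_FLANK = 200
SET2_MIN_DEPTH = 10
SET2_MIN_REGION = 50
SET2_MAX_MEMBERS = 5
SET2_SLOPS = (250, 500, 0.05)


# ---------------------------------------------------------------------------
# Set I: genes with annotated pseudogenes
# ---------------------------------------------------------------------------

def _windowed_keep_mask(g_gene: str, g_pseudo: str, window: int, identity_min: float) -> np.ndarray:
    """Boolean per alignment column: covered by >=1 window of identity >= min.

    Windows of ``window`` alignment columns slide with step 1; a column is
    kept when any window containing it matches in >= identity_min of its
    columns.
    """
    match = np.array([a == b and a != "-" for a, b in zip(g_gene, g_pseudo)], dtype=float)
    ncols = len(match)
    if ncols < window:
        frac = match.mean() if ncols else 0.0
        return np.full(ncols, frac >= identity_min)
    csum = np.concatenate([[0.0], np.cumsum(match)])
    win_id = (csum[window:] - csum[:-window]) / window  # one per window start
    keep_win = win_id >= identity_min
    keep_col = np.zeros(ncols, dtype=bool)
    # mark columns covered by any kept window (union of kept windows)
    starts = np.nonzero(keep_win)[0]
    for s in starts:
        keep_col[s : s + window] = True
    return keep_col


def build_set1(
    gene_models: pd.DataFrame,
    genome: Genome,
    identity_min: float = DEFAULT_IDENTITY_MIN,
    window: int = DEFAULT_WINDOW,
) -> list[ParalogSet]:
    """Pair protein-coding genes with their pseudogenes and keep regions of
    high windowed identity where exactly one pseudogene is homologous.

    ``gene_models`` needs columns gene_name, feature_type
    ('protein_coding'/'pseudogene'), chrom, start, end, strand.
    """
    sets: list[ParalogSet] = []
    for gene_name, group in gene_models.groupby("gene_name", sort=True):
        coding = group[group.feature_type == "protein_coding"]
        pseudos = group[group.feature_type == "pseudogene"]
        if coding.empty:
            continue
        if pseudos.empty:
            logger.info("gene %s has no pseudogene partner; skipped", gene_name)
            continue
        gene_row = coding.iloc[0]
        gene_iv = GenomicInterval(gene_row.chrom, int(gene_row.start), int(gene_row.end),
                                  str(gene_row.strand))
        gene_seq = genome.fetch(gene_iv.chrom, gene_iv.start, gene_iv.end)

        # per-pseudogene kept intervals in gene coordinates, plus the alignment
        per_pseudo: list[tuple[GenomicInterval, str, str, list[tuple[int, int]]]] = []
        coverage = np.zeros(len(gene_iv), dtype=int)
        for _, prow in pseudos.iterrows():
            ps_iv = GenomicInterval(prow.chrom, int(prow.start), int(prow.end), str(prow.strand))
            ps_seq = genome.fetch(ps_iv.chrom, ps_iv.start, ps_iv.end)
            score, strand = identity_score(gene_seq, ps_seq)
            oriented = revcomp(ps_seq) if strand == "-" else ps_seq
            g_gene, g_ps = global_align(gene_seq, oriented)
            keep_col = _windowed_keep_mask(g_gene, g_ps, window, identity_min)
            gene_off = _column_offsets(g_gene)
            runs = _mask_runs(keep_col)
            gene_runs: list[tuple[int, int]] = []
            for c0, c1 in runs:
                offs = gene_off[c0:c1]
                offs = offs[offs >= 0]
                if len(offs) == 0:
                    continue
                gene_runs.append((int(offs[0]), int(offs[-1]) + 1))
                coverage[offs[0] : offs[-1] + 1] += 1
            ps_iv = replace(ps_iv, strand=strand)
            per_pseudo.append((ps_iv, g_gene, g_ps, gene_runs))

        # keep gene positions covered by exactly one pseudogene
        for ps_iv, g_gene, g_ps, gene_runs in per_pseudo:
            for o0, o1 in gene_runs:
                sub = np.nonzero(coverage[o0:o1] == 1)[0]
                for s0, s1 in _mask_runs_from_indices(sub):
                    a, b = o0 + s0, o0 + s1
                    pset = _pair_set_from_alignment(
                        gene_name, gene_iv, ps_iv, g_gene, g_ps, a, b
                    )
                    if pset is not None:
                        sets.append(pset)
    for i, pset in enumerate(sets):
        pset.set_id = f"set1_{i:04d}_{pset.set_id}"
    return sets


def _column_offsets(gapped: str) -> np.ndarray:
    arr = np.frombuffer(gapped.encode(), dtype=np.uint8)
    is_base = arr != ord("-")
    off = np.cumsum(is_base) - 1
    off[~is_base] = -1
    return off


def _mask_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean mask as half-open (start, end)."""
    if mask.size == 0:
        return []
    diff = np.diff(mask.astype(int))
    starts = list(np.nonzero(diff == 1)[0] + 1)
    ends = list(np.nonzero(diff == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def _mask_runs_from_indices(idx: np.ndarray) -> list[tuple[int, int]]:
    if idx.size == 0:
        return []
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(idx) - 1]])
    return [(int(idx[s]), int(idx[e]) + 1) for s, e in zip(starts, ends)]


def _pair_set_from_alignment(
    gene_name: str,
    gene_iv: GenomicInterval,
    ps_iv: GenomicInterval,
    g_gene: str,
    g_ps: str,
    gene_o0: int,
    gene_o1: int,
) -> ParalogSet | None:
    """Cut the gene/pseudogene alignment to gene offsets [o0, o1)."""
    gene_off = _column_offsets(g_gene)
    cols = np.nonzero((gene_off >= gene_o0) & (gene_off < gene_o1))[0]
    if cols.size == 0:
        return None
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    ps_off = _column_offsets(g_ps)
    ps_offs = ps_off[c0:c1]
    ps_offs = ps_offs[ps_offs >= 0]
    if ps_offs.size == 0:
        return None
    gene_member = GenomicInterval(
        gene_iv.chrom, gene_iv.start + gene_o0, gene_iv.start + gene_o1, gene_iv.strand
    )
    p0, p1 = int(ps_offs[0]), int(ps_offs[-1]) + 1
    if ps_iv.strand == "+":
        ps_member = GenomicInterval(ps_iv.chrom, ps_iv.start + p0, ps_iv.start + p1, "+")
    else:
        ps_member = GenomicInterval(ps_iv.chrom, ps_iv.end - p1, ps_iv.end - p0, "-")
    aln_gene = g_gene[c0:c1]
    aln_ps = g_ps[c0:c1]
    return ParalogSet(
        set_id=gene_name,
        members=[gene_member, ps_member],
        seqs=[aln_gene.replace("-", ""), aln_ps.replace("-", "")],
        alignment=[aln_gene, aln_ps],
        origin="set1",
    )


# ---------------------------------------------------------------------------
# Set II: low-mapping-quality footprints
# ---------------------------------------------------------------------------

def build_set2(
    lowmq_footprints: Mapping[str, Sequence[GenomicInterval]],
    depths: Mapping[str, np.ndarray],
    genome: Genome,
    exons: Sequence[GenomicInterval] = (),
    min_depth: int = SET2_MIN_DEPTH,
    score_min: float = DEFAULT_IDENTITY_MIN,
) -> list[ParalogSet]:
    """Derive paralog sets from the footprints of MQ<10 reads.

    Footprint positions with depth < ``min_depth`` are removed; the surviving
    positions are merged into regions with three different gap tolerances
    (250 bp, 500 bp, 5% of region length; regions <50 bp dropped from the 5%
    list); mutually homologous regions (normalized global-alignment score
    >= ``score_min``, reverse complements considered) form sets; lists are
    merged 500 -> 250 -> 5% keeping only non-overlapping additions.
    """
    if not lowmq_footprints or all(len(v) == 0 for v in lowmq_footprints.values()):
        logger.warning("empty low-MQ footprint input; no Set II regions")
        return []

    # union footprint mask per chrom, then depth filter
    base_regions: list[GenomicInterval] = []
    chroms = {iv.chrom for ivs in lowmq_footprints.values() for iv in ivs}
    for chrom in sorted(chroms):
        clen = genome.contig_length(chrom)
        mask = np.zeros(clen, dtype=bool)
        for ivs in lowmq_footprints.values():
            for iv in ivs:
                if iv.chrom == chrom:
                    mask[iv.start : iv.end] = True
        depth = depths.get(chrom)
        if depth is not None:
            mask &= np.asarray(depth)[:clen] >= min_depth
        for s, e in _mask_runs(mask):
            base_regions.append(GenomicInterval(chrom, s, e))

    lists: dict[float, list[GenomicInterval]] = {}
    for slop in SET2_SLOPS:
        if isinstance(slop, float):
            merged = _merge_fractional(base_regions, slop)
            merged = [iv for iv in merged if len(iv) >= SET2_MIN_REGION]
        else:
            merged = merge_intervals(base_regions, max_gap=slop)
        lists[slop] = merged

    exon_index = IntervalIndex(exons)
    per_list_sets = {slop: _group_mutual(lists[slop], genome, score_min, exon_index)
                     for slop in SET2_SLOPS}

    # merge: 500 bp list first, then 250 bp, then 5%
    accepted: list[ParalogSet] = []
    accepted_index = IntervalIndex()
    for slop in (500, 250, 0.05):
        for pset in per_list_sets[slop]:
            if any(accepted_index.any_overlap(m) for m in pset.members):
                logger.info("set2 set %s overlaps accepted regions; skipped", pset.set_id)
                continue
            accepted.append(pset)
            for m in pset.members:
                accepted_index.add(m)
    for i, pset in enumerate(accepted):
        pset.set_id = f"set2_{i:04d}"
    return accepted


def _merge_fractional(regions: Sequence[GenomicInterval], frac: float) -> list[GenomicInterval]:
    """Merge neighbours separated by at most ``frac`` of the left region."""
    out: list[GenomicInterval] = []
    for iv in sorted(regions, key=lambda i: (i.chrom, i.start, i.end)):
        if out and out[-1].chrom == iv.chrom and iv.start - out[-1].end <= frac * len(out[-1]):
            if iv.end > out[-1].end:
                out[-1] = replace(out[-1], end=iv.end)
        else:
            out.append(iv)
    return out


def _group_mutual(
    regions: Sequence[GenomicInterval],
    genome: Genome,
    score_min: float,
    exon_index: IntervalIndex,
) -> list[ParalogSet]:
    """Sets = connected components of the >=score_min graph that are cliques.

    A component that is not a clique contains a member scoring >= score_min
    against a region outside any mutual group, so all its regions are
    rejected. Sets with no exonic overlap or >5 members are removed.
    """
    n = len(regions)
    if n == 0:
        return []
    seqs = [genome.fetch_interval(iv) for iv in regions]
    score = np.zeros((n, n))
    strand = np.full((n, n), "+", dtype=object)
    for i, j in itertools.combinations(range(n), 2):
        s, st = identity_score(seqs[i], seqs[j])
        score[i, j] = score[j, i] = s
        strand[i, j] = strand[j, i] = st
    adj = score >= score_min
    np.fill_diagonal(adj, False)

    seen: set[int] = set()
    out: list[ParalogSet] = []
    for root in range(n):
        if root in seen:
            continue
        comp = _component(adj, root)
        seen |= comp
        comp = sorted(comp)
        if len(comp) < 2:
            continue
        if not all(adj[i, j] for i, j in itertools.combinations(comp, 2)):
            logger.info("regions %s form a non-mutual homology group; rejected", comp)
            continue
        if len(comp) > SET2_MAX_MEMBERS:
            logger.info("homology group with %d members (>%d); removed",
                        len(comp), SET2_MAX_MEMBERS)
            continue
        members = [regions[i] for i in comp]
        if len(exon_index) and not any(exon_index.any_overlap(m) for m in members):
            continue
        first = comp[0]
        oriented_members = [members[0]]
        oriented_seqs = [seqs[first]]
        for k in comp[1:]:
            st = strand[first, k]
            oriented_members.append(replace(regions[k], strand=st))
            oriented_seqs.append(revcomp(seqs[k]) if st == "-" else seqs[k])
        msa = progressive_msa(oriented_seqs)
        out.append(ParalogSet(
            set_id="pending",
            members=oriented_members,
            seqs=oriented_seqs,
            alignment=msa,
            origin="set2",
        ))
    return out


def _component(adj: np.ndarray, root: int) -> set[int]:
    comp = {root}
    frontier = [root]
    while frontier:
        node = frontier.pop()
        for nb in np.nonzero(adj[node])[0]:
            if nb not in comp:
                comp.add(int(nb))
                frontier.append(int(nb))
    return comp


# ---------------------------------------------------------------------------
# Merging, extraction regions, masking choice
# ---------------------------------------------------------------------------

def merge_region_sets(set1: Sequence[ParalogSet], set2: Sequence[ParalogSet]) -> list[ParalogSet]:
    """Start from all Set I regions; append Set II sets that overlap nothing."""
    accepted: list[ParalogSet] = list(set1)
    index = IntervalIndex(m for pset in set1 for m in pset.members)
    for pset in set2:
        if any(index.any_overlap(m) for m in pset.members):
            logger.info("set %s overlaps the accepted list; skipped", pset.set_id)
            continue
        accepted.append(pset)
        for m in pset.members:
            index.add(m)
    return accepted


def extraction_regions(
    sets: Sequence[ParalogSet], genome: Genome, slop: int = DEFAULT_EXTRACTION_SLOP
) -> list[GenomicInterval]:
    """Every member widened by ``slop`` both sides, clipped at contig bounds."""
    if slop < 0:
        raise ValueError("slop must be >= 0")
    return [
        m.expand(slop, genome.contig_length(m.chrom))
        for pset in sets
        for m in pset.members
    ]


def choose_unmasked(pset: ParalogSet, cds: Sequence[GenomicInterval]) -> int:
    """Member with maximal CDS overlap stays unmasked; ties -> lowest coords."""
    overlaps = [
        sum(m.overlap_len(c) for c in cds) for m in pset.members
    ]
    best = max(overlaps)
    candidates = [i for i, o in enumerate(overlaps) if o == best]
    return min(candidates, key=lambda i: (pset.members[i].chrom, pset.members[i].start))


def assign_unmasked(sets: Sequence[ParalogSet], cds: Sequence[GenomicInterval]) -> None:
    for pset in sets:
        pset.unmasked_member = choose_unmasked(pset, cds)


# ---------------------------------------------------------------------------
# SUNs
# ---------------------------------------------------------------------------

def compute_suns(pset: ParalogSet) -> list[SunRecord]:
    """One record per alignment column where members disagree.

    Runs of columns with an identical gap pattern collapse into a single
    indel-type record; substitution columns yield one snv record each.
    Alleles are reported on the extracted orientation of each member.
    """
    if not pset.alignment:
        raise ValueError(f"set {pset.set_id} has no alignment")
    ncols = {len(row) for row in pset.alignment}
    if len(ncols) != 1:
        raise ValueError("malformed alignment: unequal column counts")
    ncols = ncols.pop()
    n = pset.n_members
    offsets = [pset.column_offsets(m) for m in range(n)]

    records: list[SunRecord] = []
    col = 0
    while col < ncols:
        alleles = [pset.alignment[m][col] for m in range(n)]
        has_gap = "-" in alleles
        if not has_gap:
            if len(set(alleles)) > 1:
                records.append(_sun_at(pset, offsets, col, 1, "snv"))
            col += 1
            continue
        # extend run of identical gap pattern
        pattern = tuple(a == "-" for a in alleles)
        end = col + 1
        while end < ncols:
            nxt = tuple(pset.alignment[m][end] == "-" for m in range(n))
            if nxt != pattern:
                break
            end += 1
        records.append(_sun_at(pset, offsets, col, end - col, "indel"))
        col = end
    return records


def _sun_at(
    pset: ParalogSet, offsets: list[np.ndarray], col: int, span: int, kind: str
) -> SunRecord:
    alleles = []
    positions = []
    for m in range(pset.n_members):
        bases = pset.alignment[m][col : col + span].replace("-", "")
        alleles.append(bases)
        offs = offsets[m][col : col + span]
        offs = offs[offs >= 0]
        positions.append(
            pset.member_offset_to_genomic(m, int(offs[0])) if offs.size else None
        )
    return SunRecord(
        set_id=pset.set_id,
        column=col,
        n_columns=span,
        per_member_allele=tuple(alleles),
        member_positions=tuple(positions),
        kind=kind,
    )


# ---------------------------------------------------------------------------
# Subregions
# ---------------------------------------------------------------------------

def project_interval(
    pset: ParalogSet, from_member: int, iv: GenomicInterval, to_member: int
) -> GenomicInterval | None:
    """Project a genomic interval on one member onto a paralog."""
    src = pset.members[from_member]
    clipped = iv.intersect(src)
    if clipped is None:
        return None
    o0 = pset.genomic_to_member_offset(from_member, clipped.chrom, clipped.start)
    o1 = pset.genomic_to_member_offset(from_member, clipped.chrom, clipped.end - 1)
    lo, hi = min(o0, o1), max(o0, o1)
    col_off = pset.column_offsets(to_member)
    c0 = pset.offset_to_column(from_member, lo)
    c1 = pset.offset_to_column(from_member, hi)
    targets = col_off[c0 : c1 + 1]
    targets = targets[targets >= 0]
    if targets.size == 0:
        return None
    t0, t1 = int(targets.min()), int(targets.max())
    g0 = pset.member_offset_to_genomic(to_member, t0)
    g1 = pset.member_offset_to_genomic(to_member, t1)
    lo_pos, hi_pos = sorted((g0[1], g1[1]))
    return GenomicInterval(g0[0], lo_pos, hi_pos + 1, pset.members[to_member].strand)


def derive_subregions(
    sets: Sequence[ParalogSet],
    exons: Sequence[GenomicInterval],
    flank: int = DEFAULT_SUBREGION_FLANK,
) -> list[SubRegion]:
    """Exon-resolution subregions for coverage-based CNV calling.

    Set I regions are intersected with protein-coding exons extended by
    ``flank`` bp of intron; Set II regions are kept whole but only for sets
    of exactly two members.
    """
    flanked = [e.expand(flank) for e in exons]
    exon_index = IntervalIndex(flanked)
    out: list[SubRegion] = []
    for pset in sets:
        if pset.origin == "set2":
            if pset.n_members != 2:
                continue
            for m in range(2):
                out.append(SubRegion(
                    set_id=pset.set_id,
                    member_index=m,
                    interval=pset.members[m],
                    partner_intervals=(pset.members[1 - m],),
                ))
            continue
        for m, member in enumerate(pset.members):
            pieces = merge_intervals(
                iv for e in exon_index.overlapping(member)
                if (iv := member.intersect(e)) is not None
            )
            for piece in pieces:
                partners = tuple(
                    p for other in range(pset.n_members) if other != m
                    if (p := project_interval(pset, m, piece, other)) is not None
                )
                out.append(SubRegion(
                    set_id=pset.set_id,
                    member_index=m,
                    interval=piece,
                    partner_intervals=partners,
                ))
    return out
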