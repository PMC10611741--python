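"""Coverage-based calling of homozygous deletions and ectopic conversions.

All coverage work reads the ORIGINAL alignment (no masking): a homozygous
deletion and the acceptor of a homozygous conversion both leave a coverage
hole, but only the conversion doubles the unique coverage on its donor
paralog. Cohort-scale kernel-density clustering separates event carriers
from the bulk; a percentile-based threshold decides deletion vs conversion.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema
from sklearn.neighbors import KernelDensity

from .model import AlignmentStore, GenomicInterval, ParalogSet, SubRegion

logger = logging.getLogger("paraloscope")

KDE_BANDWIDTH = 1.0
KDE_GRID = 512
MIN_TOTAL_READS_BOTH = 120
MAX_PEAK_READS = 10
MAX_CLUSTER_FRAC = 0.10
MIN_UNIQUE_TOTAL = 30
MIN_PARALOG_MEDIAN = 60
MAX_X_UNIQUE = 10
MAX_R = 0.05
DONOR_RATIO = 4.0 / 3.0
R_SCALE = 100.0  # ratio clustered on a percent scale


# ---------------------------------------------------------------------------
# Coverage matrix
# ---------------------------------------------------------------------------

@dataclass
class CoverageMatrix:
    """samples x subregions read counts on the original alignments.

    ``unique`` counts MQ>0 reads, ``all`` counts every read including MQ 0;
    ``partner_*`` hold the same quantities over each subregion's paralogous
    projection (the Y side of the X/Y ratio R).
    """

    samples: list[str]
    subregions: list[SubRegion]
    unique: np.ndarray
    all: np.ndarray
    partner_unique: np.ndarray
    partner_all: np.ndarray
    kit_group: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.all < self.unique).any():
            raise ValueError("all_counts must be >= unique_counts elementwise")

    def sample_rows(self, kit: str | None) -> np.ndarray:
        if kit is None:
            return np.arange(len(self.samples))
        return np.array([
            i for i, s in enumerate(self.samples) if self.kit_group.get(s) == kit
        ])

    def set_columns(self, set_id: str) -> list[int]:
        return [j for j, s in enumerate(self.subregions) if s.set_id == set_id]

    def to_frame(self, layer: str = "unique") -> pd.DataFrame:
        data = getattr(self, layer)
        return pd.DataFrame(data, index=self.samples,
                            columns=[s.key for s in self.subregions])


def count_subregions(
    stores: Mapping[str, AlignmentStore],
    subregions: Sequence[SubRegion],
    kit_group: Mapping[str, str] | None = None,
) -> CoverageMatrix:
    """Count reads per subregion; a read overlapping two subregions counts
    in both. MQ>0 reads feed ``unique``; all reads feed ``all``."""
    samples = list(stores)
    S, R = len(samples), len(subregions)
    unique = np.zeros((S, R), dtype=np.int64)
    allc = np.zeros((S, R), dtype=np.int64)
    p_unique = np.zeros((S, R), dtype=np.int64)
    p_all = np.zeros((S, R), dtype=np.int64)
    for i, sample in enumerate(samples):
        store = stores[sample]
        for j, sub in enumerate(subregions):
            u, a = _count_interval(store, sub.interval)
            unique[i, j], allc[i, j] = u, a
            pu = pa = 0
            for piv in sub.partner_intervals:
                u2, a2 = _count_interval(store, piv)
                pu += u2
                pa += a2
            p_unique[i, j], p_all[i, j] = pu, pa
    return CoverageMatrix(
        samples=samples, subregions=list(subregions),
        unique=unique, all=allc, partner_unique=p_unique, partner_all=p_all,
        kit_group=dict(kit_group or {}),
    )


def _count_interval(store: AlignmentStore, iv: GenomicInterval) -> tuple[int, int]:
    return store.count_overlap(iv.chrom, iv.start, iv.end)


# ---------------------------------------------------------------------------
# KDE clustering
# ---------------------------------------------------------------------------

@dataclass
class KdeCluster:
    peak_value: float
    member_samples: list[int]  # indices into the input vector
    boundaries: tuple[float, float]

    @property
    def size(self) -> int:
        return len(self.member_samples)


def kde_clusters(
    values: np.ndarray,
    bandwidth: float = KDE_BANDWIDTH,
    grid_points: int = KDE_GRID,
) -> list[KdeCluster]:
    """Cluster a 1-D sample by local minima of an exponential-kernel KDE.

    Density is evaluated on a uniform grid spanning [min-3b, max+3b];
    samples are assigned to the segment between flanking local minima.
    Deterministic given bandwidth and grid.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("kde_clusters requires at least one value")
    if np.ptp(values) == 0:
        return [KdeCluster(peak_value=float(values[0]),
                           member_samples=list(range(values.size)),
                           boundaries=(-np.inf, np.inf))]
    lo, hi = values.min() - 3 * bandwidth, values.max() + 3 * bandwidth
    grid = np.linspace(lo, hi, grid_points)
    kde = KernelDensity(kernel="exponential", bandwidth=bandwidth)
    kde.fit(values[:, None])
    dens = np.exp(kde.score_samples(grid[:, None]))
    cut_values = grid[_valley_minima(dens)]
    edges = np.concatenate([[-np.inf], cut_values, [np.inf]])
    clusters: list[KdeCluster] = []
    assignment = np.searchsorted(cut_values, values, side="left")
    for seg in range(len(edges) - 1):
        members = np.nonzero(assignment == seg)[0]
        if members.size == 0:
            continue
        g0 = np.searchsorted(grid, edges[seg]) if np.isfinite(edges[seg]) else 0
        g1 = (np.searchsorted(grid, edges[seg + 1])
              if np.isfinite(edges[seg + 1]) else len(grid))
        g1 = max(g1, g0 + 1)
        peak = grid[g0 + int(np.argmax(dens[g0:g1]))]
        clusters.append(KdeCluster(
            peak_value=float(peak),
            member_samples=[int(m) for m in members],
            boundaries=(float(edges[seg]), float(edges[seg + 1])),
        ))
    return clusters


def _valley_minima(dens: np.ndarray) -> np.ndarray:
    """Indices of genuine density valleys, robust to flat plateaus.

    Local-minimum candidates (non-strict comparison) are grouped into runs
    whose middle is taken; a cut survives only while its density is strictly
    below the highest density on both sides between neighbouring cuts, which
    discards tail plateaus and flat cluster tops.
    """
    cand = argrelextrema(dens, np.less_equal, order=1)[0]
    if cand.size == 0:
        return cand
    runs: list[int] = []
    start = prev = int(cand[0])
    for c in cand[1:]:
        if c == prev + 1:
            prev = int(c)
            continue
        runs.append((start + prev) // 2)
        start = prev = int(c)
    runs.append((start + prev) // 2)

    cuts = runs
    while True:
        edges = [0] + cuts + [len(dens) - 1]
        keep = []
        for i, c in enumerate(cuts):
            left_peak = dens[edges[i] : c + 1].max()
            right_peak = dens[c : edges[i + 2] + 1].max()
            if dens[c] < left_peak and dens[c] < right_peak:
                keep.append(c)
        if keep == cuts:
            return np.array(cuts, dtype=int)
        cuts = keep


# ---------------------------------------------------------------------------
# Percentiles and the conversion threshold
# ---------------------------------------------------------------------------

def percdpn(values: np.ndarray) -> np.ndarray:
    """One-sided (lower) percentile, inclusive, max-rank at ties.

    percdpn[i] = fraction of samples with value <= values[i]; the lowest of
    n samples gets 1/n, the highest 1.0.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    order = np.argsort(values, kind="stable")
    sorted_vals = values[order]
    counts = np.searchsorted(sorted_vals, values, side="right")
    return counts / n


def upper_percentile(values: np.ndarray) -> np.ndarray:
    """Fraction of samples with value >= each sample's (high-side tail)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    sorted_vals = np.sort(values)
    below = np.searchsorted(sorted_vals, values, side="left")
    return (n - below) / n


def compute_R(x_unique: int, y_unique: int) -> float:
    """Unique-read ratio R = X / (X + Y) in [0, 1]."""
    total = x_unique + y_unique
    if total <= 0:
        raise ValueError("R undefined when no unique reads align to X or Y")
    return x_unique / total


def threshold_T(percdpn_x: float) -> float:
    """Donor-side stringency threshold T = p^(1/(3(1-3p))).

    Near p=0 this approaches the cube root of p (stringent); at p=0.1 it is
    close to the square root (lenient). The exponent is singular at p=1/3;
    beyond the guard we fall back to the least stringent square-root regime.
    """
    if percdpn_x <= 0:
        raise ValueError("percdpn must be > 0")
    if percdpn_x >= 1 / 3:
        logger.info("percdpn %.3f >= 1/3; square-root guard applied", percdpn_x)
        return percdpn_x ** 0.5
    return percdpn_x ** (1.0 / (3.0 * (1.0 - 3.0 * percdpn_x)))


# ---------------------------------------------------------------------------
# CNV events
# ---------------------------------------------------------------------------

@dataclass
class CnvEvent:
    sample_id: str
    kind: str  # deletion_both | deletion_single | conversion
    set_id: str
    chrom: str
    start: int
    end: int
    member_index: int = -1       # acceptor member
    donor_member: int = -1       # conversion only
    support: dict = field(default_factory=dict)
    genes: tuple[str, ...] = ()

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


def _normalization_factors(
    matrix: CoverageMatrix, rows: np.ndarray, set_id: str
) -> np.ndarray:
    """Per-sample multiplicative depth factors: cohort-median total / total.

    Totals are all-read counts over every analysed subregion outside the
    focal set, mirroring the genome-scale situation where any single set
    contributes negligibly to a sample's total; with a single simulated set
    the focal set itself is used.
    """
    other = [j for j, s in enumerate(matrix.subregions) if s.set_id != set_id]
    cols = other if other else list(range(len(matrix.subregions)))
    totals = matrix.all[np.ix_(rows, cols)].sum(axis=1).astype(float)
    totals[totals == 0] = np.nan
    med = np.nanmedian(totals)
    factors = med / totals
    return np.nan_to_num(factors, nan=0.0)


def call_deletion_both(
    matrix: CoverageMatrix,
    pset: ParalogSet,
    kit: str | None = None,
    min_total: int = MIN_TOTAL_READS_BOTH,
    max_peak_reads: float = MAX_PEAK_READS,
    max_cluster_frac: float = MAX_CLUSTER_FRAC,
    bandwidth: float = KDE_BANDWIDTH,
) -> list[CnvEvent]:
    """Deletions removing every member of a set, from all-read totals.

    Sets whose cohort-median total is below ``min_total`` are skipped; KDE
    clusters with peak > ``max_peak_reads`` reads (a few read ends may still
    align inside a true deletion) or covering more than ``max_cluster_frac``
    of the cohort are excluded as non-events.
    """
    rows = matrix.sample_rows(kit)
    if rows.size < 20:
        logger.warning("cohort of %d samples: KDE/percentiles are unstable", rows.size)
    cols = matrix.set_columns(pset.set_id)
    if not cols:
        return []
    totals = matrix.all[np.ix_(rows, cols)].sum(axis=1)
    if np.median(totals) < min_total:
        logger.info("set %s median total %d < %d; skipped",
                    pset.set_id, int(np.median(totals)), min_total)
        return []
    events: list[CnvEvent] = []
    span = _set_span(pset)
    for cluster in kde_clusters(totals.astype(float), bandwidth=bandwidth):
        if cluster.peak_value > max_peak_reads:
            continue
        if cluster.size > max_cluster_frac * rows.size:
            continue
        for local in cluster.member_samples:
            sample = matrix.samples[rows[local]]
            events.append(CnvEvent(
                sample_id=sample, kind="deletion_both", set_id=pset.set_id,
                chrom=span.chrom, start=span.start, end=span.end,
                support={"total_reads": int(totals[local]),
                         "cluster_peak": cluster.peak_value},
            ))
    return events


def _set_span(pset: ParalogSet) -> GenomicInterval:
    chrom = pset.members[0].chrom
    start = min(m.start for m in pset.members if m.chrom == chrom)
    end = max(m.end for m in pset.members if m.chrom == chrom)
    return GenomicInterval(chrom, start, end)


def call_single_region(
    matrix: CoverageMatrix,
    pset: ParalogSet,
    sub_x_index: int,
    kit: str | None = None,
    genes: Sequence[GenomicInterval] = (),
    min_unique_total: int = MIN_UNIQUE_TOTAL,
    min_paralog_median: float = MIN_PARALOG_MEDIAN,
    max_x_unique: int = MAX_X_UNIQUE,
    max_r: float = MAX_R,
    donor_ratio: float = DONOR_RATIO,
    max_cluster_frac: float = MAX_CLUSTER_FRAC,
    bandwidth: float = KDE_BANDWIDTH,
) -> list[CnvEvent]:
    """Deletion or conversion of one region X of a two-paralog pair.

    Samples with <30 unique reads over the pair are excluded; so are pairs
    whose per-paralog unique median is below 60. Candidates need <=10 unique
    reads on X and R <= 0.05 and must fall outside KDE clusters holding more
    than 10% of samples. A candidate is a conversion when the donor-side
    coverage is extreme (upper one-sided percentile of normalized Y below
    T(percdpn_X)) and elevated (normalized Y > 4/3 x median), else a
    deletion of X; events outside protein-coding genes are discarded.
    """
    sub_x = matrix.subregions[sub_x_index]
    if not sub_x.partner_intervals:
        return []
    rows = matrix.sample_rows(kit)
    x_u = matrix.unique[rows, sub_x_index].astype(float)
    y_u = matrix.partner_unique[rows, sub_x_index].astype(float)

    included = (x_u + y_u) >= min_unique_total
    if included.sum() == 0:
        return []
    if (np.median(x_u[included]) < min_paralog_median
            or np.median(y_u[included]) < min_paralog_median):
        logger.info("pair %s: a paralog median is below %d; excluded",
                    sub_x.key, min_paralog_median)
        return []

    inc_idx = np.nonzero(included)[0]
    R = x_u[inc_idx] / (x_u[inc_idx] + y_u[inc_idx])

    excluded_common = np.zeros(inc_idx.size, dtype=bool)
    for cluster in kde_clusters(R * R_SCALE, bandwidth=bandwidth):
        if cluster.size > max_cluster_frac * inc_idx.size:
            excluded_common[cluster.member_samples] = True

    factors = _normalization_factors(matrix, rows, sub_x.set_id)[inc_idx]
    x_norm = x_u[inc_idx] * factors
    y_norm = y_u[inc_idx] * factors
    perc_x = percdpn(x_norm)
    perc_y_upper = upper_percentile(y_norm)
    median_y = float(np.median(y_norm))

    events: list[CnvEvent] = []
    iv = sub_x.interval
    if genes and not any(iv.overlaps(g) for g in genes):
        return []
    for k, local in enumerate(inc_idx):
        if excluded_common[k]:
            continue
        if x_u[local] > max_x_unique or R[k] > max_r:
            continue
        t = threshold_T(float(perc_x[k]))
        is_conversion = (perc_y_upper[k] < t) and (y_norm[k] > donor_ratio * median_y)
        sample = matrix.samples[rows[local]]
        donor = (sub_x.partner_intervals[0], )
        events.append(CnvEvent(
            sample_id=sample,
            kind="conversion" if is_conversion else "deletion_single",
            set_id=sub_x.set_id,
            chrom=iv.chrom, start=iv.start, end=iv.end,
            member_index=sub_x.member_index,
            donor_member=(1 - sub_x.member_index) if is_conversion and
                         len(sub_x.partner_intervals) == 1 else -1,
            support={
                "x_unique": int(x_u[local]), "y_unique": int(y_u[local]),
                "R": float(R[k]), "percdpn_x": float(perc_x[k]),
                "perc_y_upper": float(perc_y_upper[k]), "T": float(t),
                "y_norm": float(y_norm[k]), "median_y_norm": median_y,
            },
        ))
    return events


# ---------------------------------------------------------------------------
# CNV merging
# ---------------------------------------------------------------------------

def merge_cnv_calls(
    events: Sequence[CnvEvent],
    coding_genes: pd.DataFrame,
) -> list[CnvEvent]:
    """Merge same-sample same-kind calls in direct proximity.

    Calls are first combined within a gene, then across neighbouring genes
    tolerating up to 3 coding genes (>=1 bp of CDS) strictly between the two
    event envelopes. ``coding_genes`` needs columns gene_name, chrom, start,
    end describing CDS extents.
    """
    out: list[CnvEvent] = []
    keyfn = lambda e: (e.sample_id, e.kind, e.set_id, e.chrom)
    groups: dict[tuple, list[CnvEvent]] = {}
    for ev in events:
        groups.setdefault(keyfn(ev), []).append(ev)
    for _, group in sorted(groups.items()):
        group.sort(key=lambda e: (e.start, e.end))
        merged: list[CnvEvent] = [group[0]]
        for ev in group[1:]:
            prev = merged[-1]
            if ev.start <= prev.end or _coding_genes_between(
                coding_genes, ev.chrom, prev, ev
            ) <= 3:
                prev.end = max(prev.end, ev.end)
                prev.start = min(prev.start, ev.start)
                prev.support = {**prev.support, **ev.support}
            else:
                merged.append(ev)
        out.extend(merged)
    for ev in out:
        ev.genes = _overlapping_genes(coding_genes, ev)
    return sorted(out, key=lambda e: (e.sample_id, e.chrom, e.start))


def _coding_genes_between(
    genes: pd.DataFrame, chrom: str, prev: CnvEvent, ev: CnvEvent
) -> int:
    """Coding genes with >=1 bp of CDS strictly between two event envelopes.

    Genes overlapping either event host the calls and do not count as
    intervening.
    """
    lo, hi = prev.end, ev.start
    if lo >= hi or genes.empty:
        return 0
    sel = genes[(genes.chrom == chrom) & (genes.end > lo) & (genes.start < hi)]
    count = 0
    for _, g in sel.iterrows():
        gs, ge = int(g.start), int(g.end)
        if ge > prev.start and gs < prev.end:
            continue
        if ge > ev.start and gs < ev.end:
            continue
        if min(ge, hi) - max(gs, lo) >= 1:
            count += 1
    return count


def _overlapping_genes(genes: pd.DataFrame, ev: CnvEvent) -> tuple[str, ...]:
    if genes.empty:
        return ()
    sel = genes[(genes.chrom == ev.chrom) & (genes.end > ev.start) & (genes.start < ev.end)]
    return tuple(sorted(set(sel.gene_name)))


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def call_cnvs(
    matrix: CoverageMatrix,
    sets: Sequence[ParalogSet],
    coding_genes: pd.DataFrame,
    kit: str | None = None,
    **kwargs,
) -> list[CnvEvent]:
    """Both-paralog deletions per set plus single-region calls per pair."""
    gene_ivs = [
        GenomicInterval(r.chrom, int(r.start), int(r.end))
        for _, r in coding_genes.iterrows()
    ] if not coding_genes.empty else []
    events: list[CnvEvent] = []
    by_id = {pset.set_id: pset for pset in sets}
    for pset in sets:
        events.extend(call_deletion_both(matrix, pset, kit=kit))
    for j, sub in enumerate(matrix.subregions):
        pset = by_id.get(sub.set_id)
        if pset is None or pset.n_members != 2:
            continue
        events.extend(call_single_region(matrix, pset, j, kit=kit, genes=gene_ivs))
    return merge_cnv_calls(events, coding_genes)
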