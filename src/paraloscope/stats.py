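"""Side statistics: VAF-threshold sensitivity, coding fraction of VAPs,
trio concordance and cohort allele frequency."""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

from scipy.stats import binom

from .varcall import VariantCall


# ---------------------------------------------------------------------------
# Binomial sensitivity of the VAF threshold
# ---------------------------------------------------------------------------

def binomial_sensitivity(depth: int, p: float, vaf_threshold: float) -> float:
    """P(observed VAF >= threshold) for alt reads ~ Binomial(depth, p).

    The threshold is inclusive: k_min is the smallest integer with
    k/depth >= vaf_threshold, and the tail P(K >= k_min) is summed exactly.
    At depth 60, p = 0.25 (a het variant in 1 of 2 paralogs) and threshold
    0.15 this evaluates to ~0.979.
    """
    if not (0 < p < 1):
        raise ValueError("p must be in (0, 1)")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if vaf_threshold <= 0:
        return 1.0
    k_min = math.ceil(vaf_threshold * depth)
    return float(binom.sf(k_min - 1, depth, p))


# ---------------------------------------------------------------------------
# Coding fraction of VAPs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodingFractionInput:
    """Mean per-sample VAP counts by consequence plus exome-wide ratios."""

    syn_per_sample: float
    mis_per_sample: float
    lof_per_sample: float
    mis_syn_ratio: float
    lof_syn_ratio: float

    def __post_init__(self) -> None:
        if min(self.syn_per_sample, self.mis_per_sample, self.lof_per_sample,
               self.mis_syn_ratio, self.lof_syn_ratio) < 0:
            raise ValueError("all inputs must be >= 0")


@dataclass(frozen=True)
class CodingFractionResult:
    missense_proportion: float      # of missense VAPs truly coding
    lof_proportion: float
    missense_per_sample: float      # coding missense VAPs per sample
    lof_per_sample: float
    lof_proportion_unrounded: float


def coding_fraction(inp: CodingFractionInput) -> CodingFractionResult:
    """Estimate the fraction of protein-altering VAPs that truly reside in
    coding sequence.

    Assuming synonymous variants are not under strong selection, half of
    synonymous VAPs originate in the coding paralog; scaling by the
    exome-wide missense:synonymous and LoF:synonymous ratios gives the
    coding missense/LoF expectation. The LoF per-sample count is rounded to
    2 decimals before forming its proportion (the headline pair quotes the
    rounded count; the unrounded proportion is also reported).
    """
    if inp.syn_per_sample <= 0 or inp.mis_per_sample <= 0 or inp.lof_per_sample <= 0:
        raise ValueError("per-sample counts must be > 0 for a defined estimate")
    coding_syn = inp.syn_per_sample / 2.0
    coding_mis = coding_syn * inp.mis_syn_ratio
    coding_lof = coding_syn * inp.lof_syn_ratio
    coding_lof_rounded = round(coding_lof, 2)
    return CodingFractionResult(
        missense_proportion=coding_mis / inp.mis_per_sample,
        lof_proportion=coding_lof_rounded / inp.lof_per_sample,
        missense_per_sample=coding_mis,
        lof_per_sample=coding_lof_rounded,
        lof_proportion_unrounded=coding_lof / inp.lof_per_sample,
    )


# ---------------------------------------------------------------------------
# Trio concordance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrioRecord:
    call: VariantCall
    father_vaf: float
    mother_vaf: float
    classification: str  # inherited | de_novo | unresolved


DENOVO_MAX_VAF = 0.01
INHERITED_MIN_VAF = 0.15
TRIO_MIN_DEPTH = 60

VafLookup = Callable[[tuple[str, int, str, str]], tuple[float, int] | None]


def trio_classify(
    child_calls: Sequence[VariantCall],
    father_vaf: VafLookup,
    mother_vaf: VafLookup,
    min_depth: int = TRIO_MIN_DEPTH,
) -> tuple[list[TrioRecord], float]:
    """Classify child calls against parental masked-alignment VAFs.

    Sites with parental depth < 60 are skipped. A call is de novo when both
    parental VAFs are below 1%, inherited when either exceeds 15%, otherwise
    unresolved. Returns the records and inherited/(inherited+de_novo).
    """
    records: list[TrioRecord] = []
    n_inh = n_dn = 0
    for call in child_calls:
        fv = father_vaf(call.key)
        mv = mother_vaf(call.key)
        if fv is None or mv is None or fv[1] < min_depth or mv[1] < min_depth:
            continue
        f, m = fv[0], mv[0]
        if f > INHERITED_MIN_VAF or m > INHERITED_MIN_VAF:
            cls = "inherited"
            n_inh += 1
        elif f < DENOVO_MAX_VAF and m < DENOVO_MAX_VAF:
            cls = "de_novo"
            n_dn += 1
        else:
            cls = "unresolved"
        records.append(TrioRecord(call=call, father_vaf=f, mother_vaf=m,
                                  classification=cls))
    total = n_inh + n_dn
    fraction = n_inh / total if total else float("nan")
    return records, fraction


# ---------------------------------------------------------------------------
# Cohort allele frequency
# ---------------------------------------------------------------------------

def cohort_allele_frequency(
    variant_key: tuple[str, int, str, str],
    calls_by_sample: Mapping[str, Iterable[VariantCall]],
) -> float:
    """Fraction of cohort samples carrying the variant (masked coordinates
    plus alleles)."""
    if not calls_by_sample:
        raise ValueError("empty cohort")
    carriers = sum(
        1 for calls in calls_by_sample.values()
        if any(c.key == variant_key for c in calls)
    )
    return carriers / len(calls_by_sample)
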