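import numpy as np
import pytest

from paraloscope import regions, varcall
from paraloscope.model import AlignmentStore, Genome, GenomicInterval, ParalogSet, Read
from paraloscope.varcall import TranscriptModel, VariantCall


def _column_store(genome, chrom, pos, ref, alt, n_ref, n_alt, read_len=60):
    """Reads covering one site with a controlled ref/alt split."""
    start = max(0, pos - read_len // 2)
    reads = []
    base = genome.fetch(chrom, start, start + read_len)
    i = pos - start
    for k in range(n_ref):
        reads.append(Read(f"ref{k}", chrom, start - k % 7,
                          genome.fetch(chrom, start - k % 7, start - k % 7 + read_len),
                          mapq=60))
    alt_seq = base[:i] + alt + base[i + 1:]
    for k in range(n_alt):
        reads.append(Read(f"alt{k}", chrom, start, alt_seq, mapq=60))
    return AlignmentStore(reads)


@pytest.fixture(scope="module")
def flat_genome():
    rng = np.random.default_rng(123)
    return Genome({"c": "".join(rng.choice(list("ACGT"), 600))})


class TestPileupCall:
    def test_vaf_quarter_at_sixty_reads(self, flat_genome):
        g = flat_genome
        ref = g.fetch("c", 300, 301)
        alt = "A" if ref != "A" else "G"
        store = _column_store(g, "c", 300, ref, alt, n_ref=45, n_alt=15)
        calls = varcall.pileup_call(store, [GenomicInterval("c", 250, 350)], g)
        [call] = [c for c in calls if c.pos == 300]
        assert call.depth == 60
        assert call.vaf == pytest.approx(0.25)

    def test_single_read_support_not_called(self, flat_genome):
        g = flat_genome
        ref = g.fetch("c", 300, 301)
        alt = "A" if ref != "A" else "G"
        store = _column_store(g, "c", 300, ref, alt, n_ref=59, n_alt=1)
        calls = varcall.pileup_call(store, [GenomicInterval("c", 250, 350)], g)
        assert [c for c in calls if c.pos == 300] == []

    def test_two_alt_alleles_give_two_calls(self, flat_genome):
        g = flat_genome
        ref = g.fetch("c", 300, 301)
        alts = [b for b in "ACGT" if b != ref][:2]
        store = _column_store(g, "c", 300, ref, alts[0], n_ref=40, n_alt=10)
        for k in range(10):
            base = g.fetch("c", 270, 330)
            seq = base[:30] + alts[1] + base[31:]
            store.add(Read(f"alt2_{k}", "c", 270, seq, mapq=60))
        calls = varcall.pileup_call(store, [GenomicInterval("c", 250, 350)], g)
        site = sorted(c.alt for c in calls if c.pos == 300)
        assert site == sorted(alts)

    def test_indel_called_from_cigar(self, flat_genome):
        g = flat_genome
        base = g.fetch("c", 200, 260)
        del_seq = base[:30] + base[31:]  # 1 bp deletion after offset 29
        reads = [Read(f"d{k}", "c", 200, del_seq, 60, cigar="30M1D29M")
                 for k in range(5)]
        reads += [Read(f"r{k}", "c", 200, base, 60) for k in range(5)]
        calls = varcall.pileup_call(AlignmentStore(reads),
                                    [GenomicInterval("c", 200, 260)], g)
        dels = [c for c in calls if c.is_indel]
        assert len(dels) == 1
        assert dels[0].pos == 229 and len(dels[0].ref) == 2 and len(dels[0].alt) == 1

    def test_region_outside_alignment_is_empty(self, flat_genome):
        calls = varcall.pileup_call(AlignmentStore(),
                                    [GenomicInterval("c", 0, 100)], flat_genome)
        assert calls == []


class TestRawCallset:
    def _call(self, depth, vaf, pos=10, alt="T"):
        return VariantCall("S", "c", pos, "A", alt, depth, vaf)

    def test_depth_boundary_exclusive_below_sixty(self, flat_genome):
        raw = varcall.build_raw_callset([self._call(59, 0.30)], set(), set(),
                                        flat_genome)
        assert raw == []

    def test_inclusive_boundaries_kept(self, flat_genome):
        raw = varcall.build_raw_callset([self._call(60, 0.15)], set(), set(),
                                        flat_genome)
        assert len(raw) == 1

    def test_sun_allele_match_routed_to_sun_site(self, flat_genome):
        call = self._call(100, 0.5)
        raw = varcall.build_raw_callset([call], {("c", 10, "T")}, set(),
                                        flat_genome)
        assert raw == [] and call.zygosity_class == "sun_site"

    def test_original_vcf_match_excluded(self, flat_genome):
        call = self._call(100, 0.5)
        key = varcall.normalize_variant("c", 10, "A", "T", flat_genome)
        raw = varcall.build_raw_callset([call], set(), {key}, flat_genome)
        assert raw == [] and call.in_original_vcf

    def test_hom_classification_threshold(self, flat_genome):
        hom = self._call(100, 0.9)
        het = self._call(100, 0.25)
        varcall.build_raw_callset([hom, het], set(), set(), flat_genome)
        assert hom.zygosity_class == "hom_all_paralogs"
        assert het.zygosity_class == "vap_het"

    def test_missing_original_vcf_is_hard_error(self, flat_genome):
        with pytest.raises(ValueError):
            varcall.build_raw_callset([self._call(100, 0.5)], set(), None,
                                      flat_genome)


def _gapless_pset(n_members, length=60, seed=0):
    rng = np.random.default_rng(seed)
    base = "".join(rng.choice(list("ACGT"), length))
    seqs = []
    for m in range(n_members):
        s = list(base)
        s[5 + m] = "A" if s[5 + m] != "A" else "C"  # one private allele each
        seqs.append("".join(s))
    members = [GenomicInterval("c", 1000 * m, 1000 * m + length)
               for m in range(n_members)]
    return ParalogSet("s", members, seqs, list(seqs))


class TestVapExpansion:
    @pytest.mark.parametrize("n_members", [2, 5])
    def test_candidate_count_equals_paralog_count(self, n_members):
        pset = _gapless_pset(n_members)
        call = VariantCall("S", "c", 30, pset.seqs[0][30], "T", 80, 0.25)
        vap = varcall.expand_to_vaps(call, pset)
        assert len(vap.candidates) == n_members

    def test_round_trip_to_parent_position(self):
        pset = _gapless_pset(3)
        call = VariantCall("S", "c", 30, pset.seqs[0][30], "T", 80, 0.25)
        vap = varcall.expand_to_vaps(call, pset)
        u = pset.unmasked_member
        parent_off = pset.genomic_to_member_offset(u, call.chrom, call.pos)
        for cand in vap.candidates:
            off = pset.genomic_to_member_offset(cand.member_index, cand.chrom,
                                                cand.pos)
            back = pset.project(cand.member_index, off, u)
            assert back == parent_off

    def test_hom_call_not_expanded(self):
        pset = _gapless_pset(2)
        call = VariantCall("S", "c", 30, "A", "T", 80, 0.95,
                           zygosity_class="hom_all_paralogs")
        with pytest.raises(ValueError):
            varcall.expand_to_vaps(call, pset)

    def test_gap_column_candidate_flagged_non_projectable(self):
        aln = ["ACGTACGTAC", "ACG--CGTAC"]
        pset = ParalogSet("s", [GenomicInterval("c", 0, 10),
                                GenomicInterval("c", 100, 108)],
                          [a.replace("-", "") for a in aln], list(aln))
        call = VariantCall("S", "c", 3, "T", "G", 80, 0.25)
        vap = varcall.expand_to_vaps(call, pset)
        assert len(vap.candidates) == 2
        assert not vap.candidates[1].projectable


class TestConversionIntroducedVariants:
    def test_suns_inside_interval_become_hom_variants(self):
        pset = _gapless_pset(2)
        suns = regions.compute_suns(pset)
        assert len(suns) == 2
        out = varcall.conversion_introduced_variants(
            0, 1, GenomicInterval("c", 0, 60), pset, suns)
        assert len(out) == 2
        assert all(v["zygosity"] == "hom" for v in out)
        for v in out:
            off = v["pos"]
            assert v["ref"] == pset.seqs[0][off]
            assert v["alt"] == pset.seqs[1][off]

    def test_no_suns_in_interval_is_silent(self):
        pset = _gapless_pset(2)
        suns = regions.compute_suns(pset)
        out = varcall.conversion_introduced_variants(
            0, 1, GenomicInterval("c", 30, 60), pset, suns)
        assert out == []

    def test_indel_sun_introduces_indel(self):
        aln = ["ACGTACGTAC", "ACG--CGTAC"]
        pset = ParalogSet("s", [GenomicInterval("c", 0, 10),
                                GenomicInterval("c", 100, 108)],
                          [a.replace("-", "") for a in aln], list(aln))
        suns = regions.compute_suns(pset)
        out = varcall.conversion_introduced_variants(
            0, 1, GenomicInterval("c", 0, 10), pset, suns)
        assert len(out) == 1
        v = out[0]
        assert v["kind"] == "indel" and len(v["ref"]) != len(v["alt"])


class TestAnnotateConsequence:
    @pytest.fixture()
    def toy_tx(self):
        genome = Genome({"c": "NNNATGGCTGCTTGGTAAGGNNNN"})
        tx = TranscriptModel("G", "c", "+", [GenomicInterval("c", 3, 18)])
        return genome, tx

    def test_synonymous_missense_lof(self, toy_tx):
        genome, tx = toy_tx
        # codon 2 = GCT (Ala) at positions 6..8
        assert varcall.annotate_consequence("c", 8, "T", "C", tx, genome) == "synonymous"
        assert varcall.annotate_consequence("c", 7, "C", "T", tx, genome) == "missense"
        # TGG (Trp) -> TGA (stop) at codon 4
        assert varcall.annotate_consequence("c", 14, "G", "A", tx, genome) == "LoF"

    def test_frameshift_and_noncoding(self, toy_tx):
        genome, tx = toy_tx
        assert varcall.annotate_consequence("c", 7, "CT", "C", tx, genome) == "LoF"
        assert varcall.annotate_consequence("c", 20, "G", "A", tx, genome) == "other"
        assert varcall.annotate_consequence("x", 7, "C", "T", tx, genome) == "other"


class TestFilterCascade:
    def _cohort_calls(self, n_carriers, cohort=100, vaf=0.3, pos=200):
        return [VariantCall(f"S{i}", "c", pos, "A", "T", 100, vaf)
                for i in range(n_carriers)]

    def test_caf_strictly_above_ten_percent_fails(self, flat_genome):
        surv, traces = varcall.filter_cascade(
            self._cohort_calls(11), 100, flat_genome)
        assert surv == [] and all(t.caf_fail for t in traces.values())
        surv, traces = varcall.filter_cascade(
            self._cohort_calls(10), 100, flat_genome)
        assert len(surv) == 10  # 10.0% survives

    def test_vaf_consistency_twice_rule(self, flat_genome):
        raw = self._cohort_calls(4, vaf=0.3)
        low = [VariantCall(f"L{i}", "c", 200, "A", "T", 100, 0.08)
               for i in range(6)]
        surv, traces = varcall.filter_cascade(
            raw, 100, flat_genome, cohort_calls=raw + low)
        # n(VAF>0.05)=10 > 2 x n(VAF>0.15)=8 -> removed
        assert surv == [] and all(t.vaf_consistency_fail for t in traces.values())
        surv2, _ = varcall.filter_cascade(
            raw, 100, flat_genome, cohort_calls=raw + low[:4])
        assert len(surv2) == 4  # 8 == 2x4 is not strictly more

    def test_homopolymer_six_fails_five_passes(self):
        genome = Genome({"c": "GC" * 20 + "AAAAAA" + "GC" * 20,
                         "d": "GC" * 20 + "AAAAA" + "GC" * 20})
        near6 = [VariantCall("S", "c", 47, "G", "T", 100, 0.3)]  # 2 bp downstream
        near5 = [VariantCall("S", "d", 46, "G", "T", 100, 0.3)]
        surv, traces = varcall.filter_cascade(near6, 100, genome)
        assert surv == [] and traces[0].homopolymer_fail
        surv, traces = varcall.filter_cascade(near5, 100, genome)
        assert len(surv) == 1

    def test_sun_dense_subregion_fails(self, flat_genome):
        base = list(flat_genome.fetch("c"))
        seq0 = "".join(base[:60])
        s1 = list(seq0)
        for i in (20, 22, 24, 26, 28):  # 5 SUNs in 9 bp
            s1[i] = "A" if s1[i] != "A" else "C"
        pset = ParalogSet("s", [GenomicInterval("c", 0, 60),
                                GenomicInterval("c", 200, 260)],
                          [seq0, "".join(s1)], [seq0, "".join(s1)])
        suns = regions.compute_suns(pset)
        call = VariantCall("S", "c", 40, "A", "T", 100, 0.3, set_id="s")
        surv, traces = varcall.filter_cascade([call], 100, flat_genome,
                                              sets_and_suns=[(pset, suns)])
        assert surv == [] and traces[0].sun_dense_fail

    def test_monotone_and_idempotent(self, flat_genome):
        raw = (self._cohort_calls(11) + self._cohort_calls(5, pos=300)
               + self._cohort_calls(3, pos=400))
        surv1, _ = varcall.filter_cascade(raw, 100, flat_genome)
        assert len(surv1) <= len(raw)
        surv2, _ = varcall.filter_cascade(surv1, 100, flat_genome)
        assert [c.key for c in surv2] == [c.key for c in surv1]

    def test_empty_cohort_is_hard_error(self, flat_genome):
        with pytest.raises(ValueError):
            varcall.filter_cascade([], 0, flat_genome)


class TestNormalizeVariant:
    def test_left_alignment_in_repeat(self):
        genome = Genome({"c": "ACGTTTTGCA"})
        assert varcall.normalize_variant("c", 5, "TT", "T", genome) == \
            ("c", 3, "TT", "T")

    def test_minimal_representation(self):
        genome = Genome({"c": "ACGTACGTAC"})
        assert varcall.normalize_variant("c", 2, "GTA", "GCA", genome) == \
            ("c", 3, "T", "C")
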