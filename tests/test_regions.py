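import itertools

import numpy as np
import pandas as pd
import pytest

from paraloscope import regions
from paraloscope.model import (
    Genome,
    GenomicInterval,
    IntervalIndex,
    ParalogSet,
    identity_score,
    revcomp,
)

from conftest import make_pair_genome, random_dna


def gene_models(gene_iv, ps_iv):
    return pd.DataFrame([
        {"gene_name": "G1", "feature_type": "protein_coding", "chrom": gene_iv.chrom,
         "start": gene_iv.start, "end": gene_iv.end, "strand": "+"},
        {"gene_name": "G1", "feature_type": "pseudogene", "chrom": ps_iv.chrom,
         "start": ps_iv.start, "end": ps_iv.end, "strand": "+"},
    ])


class TestBuildSet1:
    def test_identical_pair_spans_full_length(self):
        rng = np.random.default_rng(5)
        gene = random_dna(rng, 1000)
        genome, gi, pi = make_pair_genome(rng, gene, gene)
        sets = regions.build_set1(gene_models(gi, pi), genome)
        assert len(sets) == 1
        assert [len(m) for m in sets[0].members] == [1000, 1000]

    def test_uniform_identity_below_threshold_yields_nothing(self):
        # mismatches every 9th base over the whole pair: every 100 bp window
        # holds 11-12 mismatches, so windowed identity stays below 0.90
        rng = np.random.default_rng(6)
        gene = random_dna(rng, 1000)
        ps = list(gene)
        for i in range(0, 1000, 9):
            ps[i] = "A" if ps[i] != "A" else "C"
        genome, gi, pi = make_pair_genome(rng, gene, "".join(ps))
        assert regions.build_set1(gene_models(gi, pi), genome) == []

    def test_low_identity_block_splits_region(self):
        # oracle: sliding a 100 bp window with step 1 over the constructed
        # pair keeps only windows avoiding most of the 50%-identity block
        rng = np.random.default_rng(7)
        gene = random_dna(rng, 600)
        ps = list(gene)
        for i in range(200, 400, 2):
            ps[i] = "A" if ps[i] != "A" else "C"
        ps = "".join(ps)
        genome, gi, pi = make_pair_genome(rng, gene, ps)

        match = np.array([a == b for a, b in zip(gene, ps)], dtype=float)
        keep = np.zeros(600, dtype=bool)
        for s in range(0, 501):
            if match[s : s + 100].mean() >= 0.90:
                keep[s : s + 100] = True
        runs = regions._mask_runs(keep)
        assert len(runs) == 2  # the oracle itself sees two flanking regions

        sets = regions.build_set1(gene_models(gi, pi), genome)
        got = sorted((p.members[0].start - gi.start, p.members[0].end - gi.start)
                     for p in sets)
        assert len(got) == 2
        for (g0, g1), (o0, o1) in zip(got, runs):
            assert abs(g0 - o0) <= 100 and abs(g1 - o1) <= 100
        # boundaries within one window of the block edges
        assert abs(got[0][1] - 200) <= 100
        assert abs(got[1][0] - 400) <= 100

    def test_gene_without_pseudogene_skipped(self):
        rng = np.random.default_rng(8)
        gene = random_dna(rng, 400)
        genome, gi, _ = make_pair_genome(rng, gene, gene)
        gm = pd.DataFrame([{
            "gene_name": "G1", "feature_type": "protein_coding",
            "chrom": gi.chrom, "start": gi.start, "end": gi.end, "strand": "+",
        }])
        assert regions.build_set1(gm, genome) == []

    @pytest.mark.parametrize("p", [0.85, 0.88, 0.92, 0.95])
    def test_uniform_identity_sweep(self, p):
        # evenly spaced mismatches give every window identity ~= p: the pair
        # is fully kept iff p >= 0.90
        rng = np.random.default_rng(int(p * 100))
        gene = random_dna(rng, 900)
        n_mismatch = round(900 * (1 - p))
        ps = list(gene)
        step = 900 / n_mismatch
        for k in range(n_mismatch):
            i = int(k * step)
            ps[i] = "A" if ps[i] != "A" else "C"
        genome, gi, pi = make_pair_genome(rng, gene, "".join(ps))
        sets = regions.build_set1(gene_models(gi, pi), genome)
        if p >= 0.90:
            assert len(sets) == 1 and len(sets[0].members[0]) >= 850
        else:
            assert sets == []


class TestBuildSet2:
    def _genome_with_copies(self, rng, seq, n_copies, spacer=150):
        parts = [random_dna(rng, 100)]
        ivs = []
        off = 100
        for _ in range(n_copies):
            ivs.append(GenomicInterval("c1", off, off + len(seq)))
            parts.append(seq)
            off += len(seq)
            parts.append(random_dna(rng, spacer))
            off += spacer
        return Genome({"c1": "".join(parts)}), ivs

    def test_short_region_dropped_from_5pct_list(self):
        # a 40 bp surviving region never reaches the homology stage
        rng = np.random.default_rng(9)
        genome = Genome({"c1": random_dna(rng, 1000)})
        fp = {"s1": [GenomicInterval("c1", 100, 140)]}
        depths = {"c1": np.full(1000, 50)}
        out = regions.build_set2(fp, depths, genome,
                                 exons=[GenomicInterval("c1", 0, 1000)])
        assert out == []

    def test_more_than_five_members_removed(self):
        rng = np.random.default_rng(10)
        seq = random_dna(rng, 300)
        genome, ivs = self._genome_with_copies(rng, seq, 6)
        fp = {"s1": ivs}
        depths = {"c1": np.full(genome.contig_length("c1"), 50)}
        out = regions.build_set2(fp, depths, genome,
                                 exons=[GenomicInterval("c1", 0, 10_000)])
        assert out == []

    def test_cross_group_homology_rejects_both_groups(self):
        # two two-member groups plus one cross-group 0.95 edge: the merged
        # component is not a clique, so all four regions are rejected
        rng = np.random.default_rng(12)
        a = random_dna(rng, 300)
        b = list(a)  # ~95% identical to a
        for i in range(0, 300, 20):
            b[i] = "A" if b[i] != "A" else "C"
        b = "".join(b)
        c = random_dna(rng, 300)
        seqs = [a, b, c, c]
        parts, ivs, off = [random_dna(rng, 100)], [], 100
        for s in seqs:
            ivs.append(GenomicInterval("c1", off, off + 300))
            parts.append(s)
            parts.append(random_dna(rng, 150))
            off += 450
        genome = Genome({"c1": "".join(parts)})
        exon_index = IntervalIndex([GenomicInterval("c1", 0, off)])
        groups = regions._group_mutual(ivs, genome, 0.90, exon_index)
        members = {tuple(sorted((m.start, m.end) for m in g.members)) for g in groups}
        # only the (c, c) pair forms a valid set; (a, b) stands if their
        # identity >= 0.9, unless a cross edge breaks mutuality
        for g in groups:
            for m1, m2 in itertools.combinations(range(len(g.members)), 2):
                s, _ = identity_score(g.seqs[m1], g.seqs[m2])
                assert s >= 0.90

    def test_clustering_matches_brute_force_on_random_regions(self):
        # oracle: valid sets are connected components of the >=0.9 graph
        # that are cliques (mutual rule + no outside edge)
        rng = np.random.default_rng(13)
        base1 = random_dna(rng, 250)
        base2 = random_dna(rng, 250)
        seqs = [base1, base1, base2, base2, base2, random_dna(rng, 250)]
        parts, ivs, off = [random_dna(rng, 80)], [], 80
        for s in seqs:
            ivs.append(GenomicInterval("c1", off, off + 250))
            parts.append(s)
            parts.append(random_dna(rng, 120))
            off += 370
        genome = Genome({"c1": "".join(parts)})

        n = len(ivs)
        score = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            s, _ = identity_score(genome.fetch_interval(ivs[i]),
                                  genome.fetch_interval(ivs[j]))
            score[i, j] = score[j, i] = s
        adj = score >= 0.9
        np.fill_diagonal(adj, False)
        expected = []
        seen = set()
        for root in range(n):
            if root in seen:
                continue
            comp = regions._component(adj, root)
            seen |= comp
            comp = sorted(comp)
            if len(comp) >= 2 and all(
                adj[i, j] for i, j in itertools.combinations(comp, 2)
            ):
                expected.append(tuple(comp))

        exon_index = IntervalIndex([GenomicInterval("c1", 0, off)])
        groups = regions._group_mutual(ivs, genome, 0.90, exon_index)
        got = sorted(
            tuple(sorted(ivs.index(m) for m in g.members)) for g in groups
        )
        assert got == sorted(expected)


class TestMergeRegionSets:
    def _pset(self, set_id, *spans, origin="set2"):
        members = [GenomicInterval("c", s, e) for s, e in spans]
        seqs = ["A" * (e - s) for s, e in spans]
        return ParalogSet(set_id, members, seqs, list(seqs), origin=origin)

    def test_nested_set2_region_skipped(self):
        s1 = [self._pset("a", (0, 100), (200, 300), origin="set1")]
        s2 = [self._pset("b", (40, 60), (400, 420))]
        merged = regions.merge_region_sets(s1, s2)
        assert [p.set_id for p in merged] == ["a"]

    def test_disjoint_set2_region_appended(self):
        s1 = [self._pset("a", (0, 100), (200, 300), origin="set1")]
        s2 = [self._pset("b", (400, 500), (600, 700))]
        assert len(regions.merge_region_sets(s1, s2)) == 2

    def test_iterative_rule_on_three_sets(self):
        # replay by hand: b accepted after a; c overlaps b so it is skipped
        s1 = [self._pset("a", (0, 100), (200, 300), origin="set1")]
        s2 = [self._pset("b", (400, 500), (600, 700)),
              self._pset("c", (450, 550), (800, 900))]
        merged = regions.merge_region_sets(s1, s2)
        assert [p.set_id for p in merged] == ["a", "b"]

    def test_outputs_pairwise_disjoint(self):
        s1 = [self._pset("a", (0, 100), (200, 300), origin="set1")]
        s2 = [self._pset("b", (90, 190), (500, 600)),
              self._pset("c", (350, 450), (700, 800))]
        merged = regions.merge_region_sets(s1, s2)
        ivs = [m for p in merged for m in p.members]
        for x, y in itertools.combinations(ivs, 2):
            assert not x.overlaps(y)


class TestExtractionAndMasking:
    def test_slop_clipped_at_contig_start(self):
        genome = Genome({"c": "A" * 10_000})
        pset = ParalogSet("s", [GenomicInterval("c", 100, 200),
                                GenomicInterval("c", 5000, 5100)],
                          ["A" * 100] * 2, ["A" * 100] * 2)
        out = regions.extraction_regions([pset], genome, slop=500)
        assert (out[0].start, out[0].end) == (0, 700)
        assert (out[1].start, out[1].end) == (4500, 5600)

    def test_slop_zero_is_identity(self):
        genome = Genome({"c": "A" * 1000})
        pset = ParalogSet("s", [GenomicInterval("c", 100, 200)], ["A" * 100],
                          ["A" * 100])
        assert regions.extraction_regions([pset], genome, slop=0) == \
            [GenomicInterval("c", 100, 200)]

    def test_overlapping_extraction_regions_kept_unmerged(self):
        genome = Genome({"c": "A" * 10_000})
        pset = ParalogSet("s", [GenomicInterval("c", 1000, 1100),
                                GenomicInterval("c", 1700, 1800)],
                          ["A" * 100] * 2, ["A" * 100] * 2)
        out = regions.extraction_regions([pset], genome, slop=500)
        assert len(out) == 2 and out[0].overlaps(out[1])

    def test_choose_unmasked_by_cds_overlap_and_tie(self):
        pset = ParalogSet("s", [GenomicInterval("c", 0, 1000),
                                GenomicInterval("c", 2000, 3000),
                                GenomicInterval("c", 4000, 5000)],
                          ["A" * 1000] * 3, ["A" * 1000] * 3)
        cds = [GenomicInterval("c", 0, 10), GenomicInterval("c", 2000, 2020),
               GenomicInterval("c", 4000, 4030)]
        assert regions.choose_unmasked(pset, cds) == 2
        assert regions.choose_unmasked(pset, [GenomicInterval("c", 0, 500)]) == 0
        assert regions.choose_unmasked(pset, []) == 0  # tie -> lowest coords


class TestComputeSuns:
    def test_identical_members_have_no_suns(self, identical_locus):
        pset, _ = identical_locus
        assert regions.compute_suns(pset) == []

    def test_three_substitution_columns(self):
        a = "ACGTACGTAC"
        b = "TCGAACGTCC"  # differs at columns 0, 3, 8
        pset = ParalogSet("s", [GenomicInterval("c", 0, 10),
                                GenomicInterval("c", 100, 110)],
                          [a, b], [a, b])
        suns = regions.compute_suns(pset)
        assert [(s.column, s.kind) for s in suns] == \
            [(0, "snv"), (3, "snv"), (8, "snv")]
        assert suns[0].per_member_allele == ("A", "T")
        assert suns[0].member_positions == (("c", 0), ("c", 100))

    def test_two_bp_deletion_is_one_indel_sun(self):
        a = "ACGTACGTAC"
        b = "ACG--CGTAC"
        pset = ParalogSet("s", [GenomicInterval("c", 0, 10),
                                GenomicInterval("c", 100, 108)],
                          [a.replace("-", ""), b.replace("-", "")], [a, b])
        suns = regions.compute_suns(pset)
        assert len(suns) == 1
        assert (suns[0].kind, suns[0].column, suns[0].n_columns) == ("indel", 3, 2)
        assert suns[0].per_member_allele == ("TA", "")

    def test_round_trip_positions(self, divergent_locus):
        pset, _ = divergent_locus
        for sun in regions.compute_suns(pset):
            for m, entry in enumerate(sun.member_positions):
                assert entry is not None
                chrom, pos = entry
                off = pset.genomic_to_member_offset(m, chrom, pos)
                assert pset.offset_to_column(m, off) == sun.column

    def test_malformed_alignment_rejected(self):
        pset = ParalogSet("s", [GenomicInterval("c", 0, 4),
                                GenomicInterval("c", 10, 14)],
                          ["ACGT", "ACGT"], ["ACGT", "ACGT"])
        pset.alignment = ["ACGT", "AC"]
        with pytest.raises(ValueError):
            regions.compute_suns(pset)


class TestDeriveSubregions:
    def test_set1_region_spanning_three_exons(self):
        seqs = ["A" * 3000, "A" * 3000]
        pset = ParalogSet("s", [GenomicInterval("c", 0, 3000),
                                GenomicInterval("c", 10_000, 13_000)],
                          seqs, seqs, origin="set1")
        exons = [GenomicInterval("c", 100, 200), GenomicInterval("c", 1000, 1100),
                 GenomicInterval("c", 2500, 2600)]
        subs = regions.derive_subregions([pset], exons, flank=200)
        gene_side = [s for s in subs if s.member_index == 0]
        assert len(gene_side) == 3
        assert all(s.partner_intervals for s in gene_side)

    def test_set2_three_member_set_emits_nothing(self):
        seqs = ["A" * 100] * 3
        pset = ParalogSet("s", [GenomicInterval("c", i * 1000, i * 1000 + 100)
                                for i in range(3)], seqs, seqs, origin="set2")
        assert regions.derive_subregions([pset], []) == []

    def test_exon_outside_regions_ignored(self):
        seqs = ["A" * 100, "A" * 100]
        pset = ParalogSet("s", [GenomicInterval("c", 0, 100),
                                GenomicInterval("c", 1000, 1100)],
                          seqs, seqs, origin="set1")
        subs = regions.derive_subregions(
            [pset], [GenomicInterval("c", 5000, 5100)], flank=200)
        assert subs == []
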