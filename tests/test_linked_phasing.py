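"""Barcode-graph phasing: evidence counting, greedy block assembly,
block merging, pathogenic-variant anchoring and block statistics."""

import numpy as np
import pytest

from conftest import diplotype, tiny_panel
from haplonipt import linked_phasing as lp
from haplonipt import simdata
from haplonipt.types import ALT, BarcodeObservationTable, MISSING, REF


def obs_table(records):
    """records: list of (barcode, snp_index, allele)"""
    bc, si, al = zip(*records)
    return BarcodeObservationTable(
        np.array(bc, np.int64), np.array(si, np.int64), np.array(al, np.int8))


class TestEvidenceGraph:
    def test_single_barcode_both_alt_counts_cis(self):
        obs = obs_table([(0, 0, 1), (0, 1, 1)])
        ev = lp.build_allele_barcode_graph(obs, [0, 1])
        assert ev[(0, 1)] == (1, 0)

    def test_opposite_alleles_count_trans(self):
        obs = obs_table([(0, 0, 1), (0, 1, 0), (1, 0, 0), (1, 1, 1)])
        ev = lp.build_allele_barcode_graph(obs, [0, 1])
        assert ev[(0, 1)] == (0, 2)

    def test_within_barcode_conflicts_resolved_by_majority(self):
        # barcode sees alt twice and ref once at SNP 0 -> consensus alt
        obs = obs_table([(0, 0, 1), (0, 0, 1), (0, 0, 0), (0, 1, 1)])
        ev = lp.build_allele_barcode_graph(obs, [0, 1])
        assert ev[(0, 1)] == (1, 0)

    def test_error_free_single_molecule_partitions_give_no_trans(self, small_family):
        panel, mom, _ = small_family
        obs = simdata.simulate_linked_reads(
            mom, panel, error_rate=0.0, molecules_per_partition=1, seed=21)
        het = np.flatnonzero(mom.het_mask)
        ev = lp.build_allele_barcode_graph(obs, het, panel)
        # each barcode = one molecule = one haplotype: evidence is pure
        for (i, j), (cis, trans) in ev.items():
            truth_cis = (mom.hap1[i] == mom.hap1[j])
            assert (trans == 0) if truth_cis else (cis == 0)

    def test_graph_matches_brute_force_recount(self, small_family):
        panel, mom, _ = small_family
        obs = simdata.simulate_linked_reads(
            mom, panel, error_rate=0.01, target_depth=10, seed=22)
        # restrict to <= 50 barcodes for the brute-force recount
        keep = obs.barcode < 50
        obs_small = BarcodeObservationTable(
            obs.barcode[keep], obs.snp_index[keep], obs.allele[keep])
        het = list(range(len(panel)))
        ev = lp.build_allele_barcode_graph(obs_small, het, panel, max_pair_dist=None)

        brute = {}
        for bc in np.unique(obs_small.barcode):
            m = obs_small.barcode == bc
            cons = {}
            for si in np.unique(obs_small.snp_index[m]):
                alleles = obs_small.allele[m & (obs_small.snp_index == si)]
                n_alt = int(alleles.sum())
                n_ref = len(alleles) - n_alt
                if n_alt != n_ref:
                    cons[int(si)] = 1 if n_alt > n_ref else 0
            sites = sorted(cons)
            for x in range(len(sites)):
                for y in range(x + 1, len(sites)):
                    key = (sites[x], sites[y])
                    c, t = brute.get(key, (0, 0))
                    if cons[sites[x]] == cons[sites[y]]:
                        brute[key] = (c + 1, t)
                    else:
                        brute[key] = (c, t + 1)
        assert ev == brute


class TestBlockAssembly:
    def test_perfect_evidence_reproduces_truth_up_to_flip(self, small_family):
        panel, mom, _ = small_family
        obs = simdata.simulate_linked_reads(
            mom, panel, error_rate=0.0, molecules_per_partition=1, seed=23)
        het = np.flatnonzero(mom.het_mask)
        ev = lp.build_allele_barcode_graph(obs, het, panel)
        blocks = lp.assemble_phase_blocks(ev, het, panel)
        assert len(blocks) == 1
        b = blocks[0]
        agree = np.mean(b.hap1_alleles == mom.hap1[b.snp_indices])
        assert max(agree, 1 - agree) == 1.0

    def test_evidence_gap_forces_block_boundary(self):
        panel = tiny_panel([100, 200, 300, 400, 500, 600])
        # strong cis chains 0-1-2 and 3-4-5, nothing across 2|3
        ev = {(i, i + 1): (5, 0) for i in [0, 1, 3, 4]}
        blocks = lp.assemble_phase_blocks(ev, range(6), panel)
        assert len(blocks) == 2
        assert blocks[0].end == 300 and blocks[1].start == 400

    def test_conflicting_instance_matches_exhaustive_search(self):
        # 6 het SNPs with one noisy trans edge: the greedy partition must
        # attain the globally optimal number of satisfied evidence units
        panel = tiny_panel([100, 200, 300, 400, 500, 600])
        ev = {
            (0, 1): (6, 1), (1, 2): (5, 0), (2, 3): (0, 6),
            (3, 4): (4, 1), (4, 5): (6, 0), (0, 2): (4, 0),
            (2, 4): (1, 5),
        }
        blocks = lp.assemble_phase_blocks(ev, range(6), panel, min_support=1, min_margin=1)
        assert len(blocks) == 1
        phase = {int(s): (1 if a == ALT else -1)
                 for s, a in zip(blocks[0].snp_indices, blocks[0].hap1_alleles)}

        def satisfied(assign):
            tot = 0
            for (i, j), (cis, trans) in ev.items():
                tot += cis if assign[i] == assign[j] else trans
            return tot

        import itertools

        best = max(satisfied(dict(enumerate(a)))
                   for a in itertools.product([1, -1], repeat=6))
        assert satisfied(phase) == best

    def test_isolated_snps_become_singletons(self):
        panel = tiny_panel([10, 20, 30])
        blocks = lp.assemble_phase_blocks({}, range(3), panel)
        assert [b.n_snps for b in blocks] == [1, 1, 1]


class TestMerge:
    def _block(self, panel, sites, hap1, block_id=0):
        idx = np.array(sites, np.int64)
        h1 = np.array(hap1, np.int8)
        return lp.PhaseBlock(
            block_id, panel.chrom, int(panel.positions[idx[0]]),
            int(panel.positions[idx[-1]]), idx, panel.positions[idx].copy(),
            h1, (1 - h1).astype(np.int8), np.ones(len(idx), np.int64))

    def test_disjoint_blocks_pass_through(self):
        panel = tiny_panel([10, 20, 30, 40])
        a = self._block(panel, [0, 1], [1, 0])
        b = self._block(panel, [2, 3], [0, 1], 1)
        merged = lp.merge_blocks_by_overlap([a], [b])
        assert len(merged) == 2
        assert {m.start for m in merged} == {10, 30}

    def test_consistent_overlap_merges_to_union_span(self):
        panel = tiny_panel([10, 20, 30, 40, 50])
        a = self._block(panel, [0, 1, 2], [1, 0, 1])
        b = self._block(panel, [1, 2, 3, 4], [1, 0, 0, 1], 1)  # flipped orientation
        merged = lp.merge_blocks_by_overlap([a], [b])
        assert len(merged) == 1
        m = merged[0]
        assert (m.start, m.end) == (10, 50)
        assert m.end - m.start == max(a.end, b.end) - min(a.start, b.start)
        # b's alleles flipped into a's frame
        assert list(m.hap1_alleles) == [1, 0, 1, 1, 0]

    def test_contradictory_5050_overlap_not_merged(self, caplog):
        panel = tiny_panel([10, 20, 30])
        a = self._block(panel, [0, 1], [1, 0])
        b = self._block(panel, [0, 1], [1, 1], 1)  # one agrees, one not
        with caplog.at_level("WARNING"):
            merged = lp.merge_blocks_by_overlap([a], [b])
        assert len(merged) == 2
        assert "contradictory" in caplog.text


class TestAnchoring:
    def test_variant_on_hap2_labels_hap2_as_pathogenic(self):
        panel = tiny_panel([10, 20, 30])
        blocks = [TestMerge._block(None, panel, [0, 1, 2], [0, 1, 0])]
        # alt (variant) allele at SNP 1 on hap1? hap1_alleles[1]=1 -> P=hap1
        pair = lp.anchor_pathogenic_variant(blocks, panel, 20, "mother")
        assert pair.covered
        assert list(pair.p_allele) == [0, 1, 0]
        assert list(pair.n_allele) == [1, 0, 1]

    def test_anchoring_is_involutive(self):
        panel = tiny_panel([10, 20, 30])
        blocks = [TestMerge._block(None, panel, [0, 1, 2], [1, 1, 0])]
        p1 = lp.anchor_pathogenic_variant(blocks, panel, 20, "m")
        p2 = lp.anchor_pathogenic_variant(blocks, panel, 20, "m")
        assert np.array_equal(p1.p_allele, p2.p_allele)
        assert np.array_equal(p1.n_allele, p2.n_allele)

    def test_uncovered_variant_marks_phasing_failure(self):
        panel = tiny_panel([10, 20, 30])
        blocks = [TestMerge._block(None, panel, [0, 1], [1, 0])]
        pair = lp.anchor_pathogenic_variant(blocks, panel, 30, "father")
        assert not pair.covered
        assert np.all(pair.p_allele == MISSING)

    def test_hom_fill_covers_non_het_sites(self):
        panel = tiny_panel([10, 20, 30, 40])
        dip = diplotype([1, 0, 1, 0], [0, 1, 1, 0])
        blocks = [TestMerge._block(None, panel, [0, 1], [1, 0])]
        pair = lp.anchor_pathogenic_variant(blocks, panel, 10, "m", dip)
        assert pair.covered
        assert pair.p_allele[2] == pair.n_allele[2] == 1
        assert pair.p_allele[3] == pair.n_allele[3] == 0

    def test_singleton_block_cannot_anchor(self):
        panel = tiny_panel([10, 20, 30])
        blocks = [TestMerge._block(None, panel, [1], [1])]
        pair = lp.anchor_pathogenic_variant(blocks, panel, 20, "m")
        assert not pair.covered


class TestStats:
    def test_single_block_n50_equals_length(self):
        panel = tiny_panel([100, 5000])
        b = TestMerge._block(None, panel, [0, 1], [1, 0])
        s = lp.phase_block_stats([b])
        assert s.n50_length == s.longest_block == b.length == 4901

    def test_n50_definition_on_three_blocks(self):
        # lengths 100/200/300 kb: the longest block alone holds >= half
        # the phased span, so N50 = 300 kb
        panel = tiny_panel(
            [1, 100_000, 200_001, 400_000, 500_000, 799_999])
        blocks = [
            TestMerge._block(None, panel, [0, 1], [1, 0], 0),
            TestMerge._block(None, panel, [2, 3], [1, 0], 1),
            TestMerge._block(None, panel, [4, 5], [1, 0], 2),
        ]
        s = lp.phase_block_stats(blocks)
        assert s.n50_length == 300_000
        assert s.total_blocks == 3

    def test_published_anchor_block_span(self):
        # the largest maternal HBB anchoring block: chr11:4249489-6238960
        # spans 1989.5 kb under the 1-based inclusive convention
        span_kb = (6_238_960 - 4_249_489 + 1) / 1000.0
        assert span_kb == pytest.approx(1989.5, abs=0.1)

    def test_block_intervals_disjoint_after_assembly(self, small_family):
        panel, mom, _ = small_family
        obs = simdata.simulate_linked_reads(
            mom, panel, molecule_len_mean=60_000, target_depth=30,
            error_rate=0.01, seed=24)
        het = np.flatnonzero(mom.het_mask)
        ev = lp.build_allele_barcode_graph(obs, het, panel)
        blocks = lp.assemble_phase_blocks(ev, het, panel)
        for a, b in zip(blocks, blocks[1:]):
            assert a.end < b.start


def test_n50_monotone_in_molecule_length(small_family):
    """Longer HMW molecules must not shrink phasing contiguity."""
    panel, mom, _ = small_family
    het = np.flatnonzero(mom.het_mask)
    n50 = {}
    for mol_len in (30_000, 150_000):
        vals = []
        for seed in range(10):
            obs = simdata.simulate_linked_reads(
                mom, panel, molecule_len_mean=mol_len, target_depth=60,
                error_rate=0.005, seed=100 + seed)
            ev = lp.build_allele_barcode_graph(obs, het, panel)
            blocks = lp.assemble_phase_blocks(ev, het, panel)
            vals.append(lp.phase_block_stats(blocks).n50_length)
        n50[mol_len] = np.median(vals)
    assert n50[150_000] >= n50[30_000]
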