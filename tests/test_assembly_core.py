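import numpy as np
import pytest

from depthmeta import assembly_core as ac
from depthmeta import synthetic_community as sc
from depthmeta import report_stats
from depthmeta.assembly_core import (
    Contig,
    anchor_contigs,
    assemble_short_reads,
    hybrid_merge,
    polish,
    remove_redundancy,
)
from depthmeta.sequence_io import SequenceRecord, reverse_complement

from conftest import random_dna


def tile_reads(seq, read_length=150, step=2, both_strands=True, prefix="r"):
    reads = []
    for i in range(0, len(seq) - read_length + 1, step):
        reads.append(SequenceRecord(f"{prefix}{i}", seq[i : i + read_length]))
        if both_strands:
            reads.append(
                SequenceRecord(f"{prefix}{i}b", reverse_complement(seq[i : i + read_length]))
            )
    return reads


class TestAssembleShortReads:
    def test_exact_reconstruction(self, rng):
        genome = random_dna(rng, 10_000)
        contigs = assemble_short_reads(tile_reads(genome), k=31)
        assert len(contigs) == 1
        assert contigs[0].sequence in (genome, reverse_complement(genome))

    def test_repeat_splits_assembly(self, rng):
        repeat = random_dna(rng, 2_000)
        a, b, c = random_dna(rng, 3_000), random_dna(rng, 3_000), random_dna(rng, 3_000)
        genome = a + repeat + b + repeat + c
        contigs = assemble_short_reads(tile_reads(genome), k=31)
        assert len(contigs) >= 2
        # graph-theoretic consequence: no contig spans a repeat copy
        # together with both of its flanks
        for rs in (3_000, 3_000 + 2_000 + 3_000):
            junction = genome[rs - 31 : rs + 2_000 + 31]
            for contig in contigs:
                assert junction not in contig.sequence
                assert junction not in reverse_complement(contig.sequence)

    def test_empty_read_set(self):
        assert assemble_short_reads([], k=31) == []

    def test_no_solid_kmer_warns_and_returns_empty(self, rng, caplog):
        reads = [SequenceRecord("r", random_dna(rng, 50))]
        out = assemble_short_reads(reads, k=31, min_kmer_count=2)
        assert out == []

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            assemble_short_reads([], k=30)

    def test_deterministic_ordering(self, rng):
        genome = random_dna(rng, 5_000)
        reads = tile_reads(genome)
        a = assemble_short_reads(reads, k=31)
        b = assemble_short_reads(list(reversed(reads)), k=31)
        assert [c.sequence for c in a] == [c.sequence for c in b]


class TestAnchorContigs:
    def test_noiseless_chain_in_read_order(self, rng):
        a, b = random_dna(rng, 3_000), random_dna(rng, 3_000)
        contigs = [Contig("A", a), Contig("B", b)]
        read = SequenceRecord("lr", a + b)
        (chain,) = anchor_contigs(contigs, [read], k_anchor=17)
        assert [(x.contig_id, x.orientation) for x in chain.anchors] == [
            ("A", "+"), ("B", "+"),
        ]

    def test_reverse_orientation_detected(self, rng):
        a, b = random_dna(rng, 3_000), random_dna(rng, 3_000)
        contigs = [Contig("A", a), Contig("B", b)]
        read = SequenceRecord("lr", a + reverse_complement(b))
        (chain,) = anchor_contigs(contigs, [read], k_anchor=17)
        assert [(x.contig_id, x.orientation) for x in chain.anchors] == [
            ("A", "+"), ("B", "-"),
        ]

    def test_noisy_chain_recovery(self, rng):
        # 15% read error, k_anchor=13: chain recovered for >=90% of 200 reads
        a, b = random_dna(rng, 4_000), random_dna(rng, 4_000)
        contigs = [Contig("A", a), Contig("B", b)]
        template = a + b
        recovered = 0
        reads = []
        for i in range(200):
            noisy = sc._apply_long_read_errors(template, 0.015, 0.090, 0.045, rng)
            reads.append(SequenceRecord(f"lr{i}", noisy))
        chains = anchor_contigs(contigs, reads, k_anchor=13)
        for chain in chains:
            ids = [x.contig_id for x in chain.anchors]
            if ids == ["A", "B"]:
                recovered += 1
        assert recovered / 200 >= 0.90

    def test_foreign_read_empty_chain(self, rng):
        contigs = [Contig("A", random_dna(rng, 3_000))]
        read = SequenceRecord("lr", random_dna(rng, 3_000))
        (chain,) = anchor_contigs(contigs, [read], k_anchor=17)
        assert chain.anchors == []

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            anchor_contigs([], [SequenceRecord("r", "ACGT")])

    def test_read_intervals_non_overlapping(self, rng):
        pieces = [random_dna(rng, 2_000) for _ in range(4)]
        contigs = [Contig(f"C{i}", p) for i, p in enumerate(pieces)]
        read = SequenceRecord("lr", "".join(pieces))
        (chain,) = anchor_contigs(contigs, [read], k_anchor=17)
        for x, y in zip(chain.anchors, chain.anchors[1:]):
            assert x.read_end <= y.read_start


class TestHybridMerge:
    def _repeat_case(self, rng, n_reads=5):
        flank_a = random_dna(rng, 4_000)
        repeat = random_dna(rng, 1_500)
        flank_b = random_dna(rng, 4_000)
        genome = flank_a + repeat + flank_b
        contigs = [Contig("A", flank_a), Contig("B", flank_b)]
        reads = [
            SequenceRecord(f"lr{i}", genome[500 + 37 * i : len(genome) - 500 - 23 * i])
            for i in range(n_reads)
        ]
        return genome, contigs, reads

    def test_merge_spans_repeat(self, rng):
        genome, contigs, reads = self._repeat_case(rng)
        chains = anchor_contigs(contigs, reads, k_anchor=17)
        merged = hybrid_merge(contigs, chains, reads, min_support=2)
        assert len(merged) == 1
        # truth-alignment oracle: merged contig covers both flanks and
        # the repeat (error-free reads -> exact reconstruction of span)
        m = merged[0].sequence
        target = genome[500:-500]
        assert m in (target, reverse_complement(target)) or len(m) >= len(target) - 100
        assert flanked(m, genome)

    def test_insufficient_support_no_merge(self, rng):
        genome, contigs, reads = self._repeat_case(rng, n_reads=1)
        chains = anchor_contigs(contigs, reads, k_anchor=17)
        merged = hybrid_merge(contigs, chains, reads, min_support=2)
        assert {c.id for c in merged} == {"A", "B"}

    def test_no_chains_identity(self, rng):
        contigs = [Contig("A", random_dna(rng, 1_000))]
        assert hybrid_merge(contigs, [], [], min_support=2) == contigs

    def test_contradictory_orientations_dropped(self, rng):
        a, b = random_dna(rng, 3_000), random_dna(rng, 3_000)
        contigs = [Contig("A", a), Contig("B", b)]
        fwd_reads = [
            SequenceRecord(f"f{i}", (a + b)[200 + i : 5_800 + i]) for i in range(2)
        ]
        rev_reads = [
            SequenceRecord(f"g{i}", (a + reverse_complement(b))[200 + i : 5_800 + i])
            for i in range(2)
        ]
        reads = fwd_reads + rev_reads
        chains = anchor_contigs(contigs, reads, k_anchor=17)
        merged = hybrid_merge(contigs, chains, reads, min_support=2)
        assert {c.id for c in merged} == {"A", "B"}

    def test_n50_never_decreases_with_spanning_reads(self, rng):
        genome, contigs, reads = self._repeat_case(rng)
        chains = anchor_contigs(contigs, reads, k_anchor=17)
        merged = hybrid_merge(contigs, chains, reads, min_support=2)
        n50_in = report_stats.n50([len(c) for c in contigs])
        n50_out = report_stats.n50([len(c) for c in merged])
        assert n50_out >= n50_in

    def test_total_sequence_bounded(self, rng):
        genome, contigs, reads = self._repeat_case(rng)
        chains = anchor_contigs(contigs, reads, k_anchor=17)
        merged = hybrid_merge(contigs, chains, reads, min_support=2)
        total_in = sum(len(c) for c in contigs)
        max_fill = max(len(r) for r in reads)
        assert sum(len(c) for c in merged) <= total_in + max_fill


def flanked(merged_seq, genome):
    """merged contig contains material from both ends of the genome span."""
    left = genome[600:1_000]
    right = genome[-1_000:-600]
    m_rc = reverse_complement(merged_seq)
    return (left in merged_seq or left in m_rc) and (right in merged_seq or right in m_rc)


class TestRemoveRedundancy:
    def test_exact_duplicates_collapse(self, rng):
        seq = random_dna(rng, 2_000)
        contigs = [Contig("a", seq), Contig("b", seq)]
        kept = remove_redundancy(contigs)
        assert len(kept) == 1

    def test_contained_high_identity_copy_removed(self, rng):
        long_seq = random_dna(rng, 5_000)
        copy = list(long_seq[1_000:3_000])
        positions = rng.choice(2_000, size=80, replace=False)  # 96% identity
        for pos in positions:
            copy[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy[pos]]
        contigs = [Contig("long", long_seq), Contig("copy", "".join(copy))]
        kept = remove_redundancy(contigs, min_identity=0.95, min_containment=0.95)
        assert [c.id for c in kept] == ["long"]

    def test_revcomp_duplicate_removed(self, rng):
        seq = random_dna(rng, 2_000)
        contigs = [Contig("a", seq + random_dna(rng, 100)), Contig("b", reverse_complement(seq))]
        kept = remove_redundancy(contigs)
        assert [c.id for c in kept] == ["a"]

    def test_unrelated_contigs_kept(self, rng):
        contigs = [Contig("a", random_dna(rng, 2_000)), Contig("b", random_dna(rng, 2_000))]
        assert len(remove_redundancy(contigs)) == 2

    def test_idempotent(self, rng):
        seq = random_dna(rng, 3_000)
        contigs = [
            Contig("a", seq),
            Contig("b", seq[:2_900]),
            Contig("c", random_dna(rng, 1_500)),
        ]
        once = remove_redundancy(contigs)
        twice = remove_redundancy(once)
        assert [c.id for c in once] == [c.id for c in twice]


class TestMergeOverlaps:
    def test_adjacent_pieces_stitched(self, rng):
        genome = random_dna(rng, 10_000)
        contigs = [
            ac.Contig("left", genome[:6_000]),
            ac.Contig("right", genome[4_500:]),  # 1.5 kbp overlap
        ]
        merged = ac.merge_overlaps(contigs, min_overlap=1_000)
        assert len(merged) == 1
        assert merged[0].sequence in (genome, reverse_complement(genome))

    def test_reverse_orientation_stitched(self, rng):
        genome = random_dna(rng, 10_000)
        contigs = [
            ac.Contig("left", genome[:6_000]),
            ac.Contig("right", reverse_complement(genome[4_500:])),
        ]
        merged = ac.merge_overlaps(contigs, min_overlap=1_000)
        assert len(merged) == 1
        assert merged[0].sequence in (genome, reverse_complement(genome))

    def test_short_overlap_not_stitched(self, rng):
        genome = random_dna(rng, 8_000)
        contigs = [ac.Contig("a", genome[:4_200]), ac.Contig("b", genome[3_800:])]
        merged = ac.merge_overlaps(contigs, min_overlap=1_000)
        assert len(merged) == 2

    def test_repeat_only_overlap_rejected(self, rng):
        # two different genomes ending/starting with the same repeat:
        # the full overlapping span mismatches beyond the repeat
        repeat = random_dna(rng, 2_000)
        a = random_dna(rng, 5_000) + repeat + random_dna(rng, 1_500)
        b = random_dna(rng, 1_500) + repeat + random_dna(rng, 5_000)
        merged = ac.merge_overlaps(
            [ac.Contig("a", a), ac.Contig("b", b)], min_overlap=1_000
        )
        assert len(merged) == 2

    def test_contained_contig_absorbed(self, rng):
        genome = random_dna(rng, 8_000)
        contigs = [ac.Contig("big", genome), ac.Contig("small", genome[2_000:5_000])]
        merged = ac.merge_overlaps(contigs, min_overlap=1_000)
        assert len(merged) == 1
        assert merged[0].sequence == genome

    def test_three_way_chain(self, rng):
        genome = random_dna(rng, 15_000)
        contigs = [
            ac.Contig("a", genome[:6_000]),
            ac.Contig("b", genome[4_000:11_000]),
            ac.Contig("c", genome[9_500:]),
        ]
        merged = ac.merge_overlaps(contigs, min_overlap=1_000)
        assert len(merged) == 1
        assert merged[0].sequence in (genome, reverse_complement(genome))


class TestPolish:
    def test_planted_errors_all_corrected(self, rng):
        genome = random_dna(rng, 5_000)
        corrupted = list(genome)
        error_positions = [500, 1_500, 2_500, 3_500, 4_500]
        for pos in error_positions:
            corrupted[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[corrupted[pos]]
        contig = Contig("c", "".join(corrupted))
        reads = tile_reads(genome, step=10)  # 30x error-free
        polished, corrections = polish([contig], reads)
        assert polished[0].sequence == genome
        assert corrections["c"] == 5

    def test_zero_mapped_reads_unchanged(self, rng):
        contig = Contig("c", random_dna(rng, 1_000))
        polished, corrections = polish([contig], [])
        assert polished[0].sequence == contig.sequence
        assert corrections["c"] == 0

    def test_identity_monotone_vs_truth(self, rng):
        # polished identity to truth >= pre-polish identity
        for seed in range(3):
            local = np.random.default_rng(seed)
            genome = random_dna(local, 4_000)
            corrupted = list(genome)
            for pos in local.choice(4_000, size=8, replace=False):
                corrupted[pos] = {"A": "G", "C": "T", "G": "A", "T": "C"}[corrupted[pos]]
            contig = Contig("c", "".join(corrupted))
            reads = tile_reads(genome, step=12)
            polished, _ = polish([contig], reads)
            before = sum(a == b for a, b in zip(contig.sequence, genome))
            after = sum(a == b for a, b in zip(polished[0].sequence, genome))
            assert after >= before


class TestEndToEndDirection:
    def test_depth_hybrid_beats_short_only(self, rng):
        # 2 genomes sharing a repeat: short-only fragments; with
        # spanning long reads the hybrid path has fewer contigs and
        # higher N50
        repeat = random_dna(rng, 2_000)
        g1 = random_dna(rng, 6_000) + repeat + random_dna(rng, 6_000)
        g2 = random_dna(rng, 5_000) + repeat + random_dna(rng, 5_000)
        reads = tile_reads(g1, step=3, prefix="a") + tile_reads(g2, step=3, prefix="b")
        short_contigs = assemble_short_reads(reads, k=31)
        long_reads = [
            SequenceRecord(f"l1_{i}", g1[1_000 + i * 61 : 13_000 - i * 37]) for i in range(4)
        ] + [
            SequenceRecord(f"l2_{i}", g2[800 + i * 53 : 11_200 - i * 41]) for i in range(4)
        ]
        chains = anchor_contigs(short_contigs, long_reads, k_anchor=17)
        merged = hybrid_merge(short_contigs, chains, long_reads, min_support=2)
        merged = remove_redundancy(merged)
        assert len(merged) < len(short_contigs)
        assert report_stats.n50([len(c) for c in merged]) > report_stats.n50(
            [len(c) for c in short_contigs]
        )
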