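import numpy as np
import pytest

from depthmeta import binning_qc as bq
from depthmeta import synthetic_community as sc
from depthmeta import mapping_depth as md
from depthmeta.assembly_core import Contig
from depthmeta.binning_qc import (
    TNF_CLASSES,
    UNRESOLVED,
    GenomeBin,
    bin_contigs,
    bin_metrics,
    evaluate_bin,
    filter_bins,
    majority_lineage,
    reassemble_bin,
    tnf_vector,
)
from depthmeta.mapping_depth import DepthProfile
from depthmeta.sequence_io import SequenceRecord, reverse_complement
from depthmeta.taxonomy_lca import TaxonomyTree

from conftest import random_dna


class TestTnfVector:
    def test_class_count_by_enumeration(self):
        # oracle: enumerate all 256 4-mers, identify each with its
        # reverse complement; (256 + 16 palindromes) / 2 = 136
        canonical = set()
        palindromes = 0
        for i in range(256):
            kmer = "".join("ACGT"[(i >> (2 * (3 - j))) & 3] for j in range(4))
            rc = reverse_complement(kmer)
            if kmer == rc:
                palindromes += 1
            canonical.add(min(kmer, rc))
        assert palindromes == 16
        assert len(canonical) == (256 + 16) // 2 == 136
        assert len(TNF_CLASSES) == 136
        assert sorted(TNF_CLASSES) == sorted(canonical)

    def test_homopolymer_mass(self):
        vec = tnf_vector(Contig("c", "A" * 100))
        assert vec.sum() == pytest.approx(1.0)
        assert vec[TNF_CLASSES.index("AAAA")] == pytest.approx(1.0)

    def test_revcomp_invariance(self, rng):
        seq = random_dna(rng, 5_000)
        a = tnf_vector(Contig("c", seq))
        b = tnf_vector(Contig("c", reverse_complement(seq)))
        np.testing.assert_allclose(a, b)

    def test_short_contig_rejected(self):
        with pytest.raises(ValueError):
            tnf_vector(Contig("c", "ACG"))

    def test_windows_with_n_skipped(self):
        vec = tnf_vector(Contig("c", "AAAANAAAA"))
        assert vec[TNF_CLASSES.index("AAAA")] == pytest.approx(1.0)


def _uniform_profiles(contigs, depths_by_prefix):
    profiles = {}
    for c in contigs:
        prefix = c.id.split("_")[0]
        d = depths_by_prefix[prefix]
        profiles[c.id] = DepthProfile(c.id, len(c.sequence), dict(d), {s: 1 for s in d})
    return profiles


def _fragment(genome, gid, size=5_000):
    return [
        Contig(f"{gid}_{i}", genome[start : start + size])
        for i, start in enumerate(range(0, len(genome) - size + 1, size))
    ]


class TestBinContigs:
    def test_three_genomes_recovered(self, rng):
        genomes = {
            "a": random_dna(rng, 40_000, gc=0.35),
            "b": random_dna(rng, 40_000, gc=0.50),
            "c": random_dna(rng, 40_000, gc=0.65),
        }
        contigs = sum((_fragment(seq, gid) for gid, seq in genomes.items()), [])
        depths = {
            "a": {"s1": 100.0, "s2": 5.0},
            "b": {"s1": 20.0, "s2": 20.0},
            "c": {"s1": 2.0, "s2": 80.0},
        }
        bins = bin_contigs(contigs, _uniform_profiles(contigs, depths), seed=1)
        assert len(bins) == 3
        n_pure = 0
        total = 0
        for b in bins:
            prefixes = [cid.split("_")[0] for cid in b.contig_ids]
            majority = max(set(prefixes), key=prefixes.count)
            n_pure += sum(p == majority for p in prefixes)
            total += len(prefixes)
        assert n_pure / total >= 0.95

    def test_length_filter_strict(self, rng):
        contigs = [
            Contig("big_0", random_dna(rng, 5_000)),
            Contig("big_1", random_dna(rng, 5_000)),
            Contig("small_0", random_dna(rng, 2_400)),
        ]
        profiles = _uniform_profiles(contigs, {"big": {"s": 10.0}, "small": {"s": 10.0}})
        bins = bin_contigs(contigs, profiles, seed=1)
        binned = {cid for b in bins for cid in b.contig_ids}
        assert "small_0" not in binned

    def test_exactly_2500_excluded(self, rng):
        contigs = [
            Contig("a_0", random_dna(rng, 2_500)),
            Contig("b_0", random_dna(rng, 5_000)),
            Contig("b_1", random_dna(rng, 5_000)),
        ]
        profiles = _uniform_profiles(contigs, {"a": {"s": 1.0}, "b": {"s": 1.0}})
        bins = bin_contigs(contigs, profiles, seed=1)
        binned = {cid for b in bins for cid in b.contig_ids}
        assert "a_0" not in binned

    def test_single_genome_one_bin(self, rng):
        genome = random_dna(rng, 60_000, gc=0.5)
        contigs = _fragment(genome, "g")
        profiles = _uniform_profiles(contigs, {"g": {"s": 30.0}})
        bins = bin_contigs(contigs, profiles, seed=1)
        assert len(bins) == 1
        assert len(bins[0].contig_ids) == len(contigs)

    def test_too_few_contigs_rejected(self, rng):
        contigs = [Contig("only_0", random_dna(rng, 5_000))]
        with pytest.raises(ValueError):
            bin_contigs(contigs, _uniform_profiles(contigs, {"only": {"s": 1.0}}), seed=1)

    def test_input_order_invariance(self, rng):
        genomes = {
            "a": random_dna(rng, 30_000, gc=0.35),
            "b": random_dna(rng, 30_000, gc=0.62),
        }
        contigs = sum((_fragment(seq, gid) for gid, seq in genomes.items()), [])
        depths = {"a": {"s": 50.0}, "b": {"s": 3.0}}
        profiles = _uniform_profiles(contigs, depths)
        bins1 = bin_contigs(contigs, profiles, seed=1)
        bins2 = bin_contigs(list(reversed(contigs)), profiles, seed=1)
        assert [sorted(b.contig_ids) for b in bins1] == [
            sorted(b.contig_ids) for b in bins2
        ]


class TestEvaluateBin:
    def _markers(self, rng, m=4):
        return {f"m{i}": random_dna(rng, 120) for i in range(m)}

    def test_complete_clean_bin(self, rng):
        markers = self._markers(rng)
        genome = random_dna(rng, 5_000)
        for i, mseq in enumerate(markers.values()):
            genome = genome[: 1_000 * (i + 1)] + mseq + genome[1_000 * (i + 1) + 120 :]
        b = GenomeBin("b", ["c1"])
        comp, cont = evaluate_bin(b, {"c1": genome}, markers)
        assert (comp, cont) == (1.0, 0.0)

    def test_three_of_four_markers(self, rng):
        markers = self._markers(rng)
        present = dict(list(markers.items())[:3])
        genome = random_dna(rng, 3_000) + "".join(present.values()) + random_dna(rng, 500)
        b = GenomeBin("b", ["c1"])
        comp, cont = evaluate_bin(b, {"c1": genome}, markers)
        assert (comp, cont) == (0.75, 0.0)

    def test_merged_genomes_census_arithmetic(self, rng):
        # oracle: two complete genomes, M=4 each -> completeness 1.0,
        # contamination sum(max(0, 2-1))/4 = 1.0
        markers = self._markers(rng)
        g1 = random_dna(rng, 2_000) + "".join(markers.values())
        g2 = random_dna(rng, 3_000) + "".join(markers.values())
        b = GenomeBin("b", ["c1", "c2"])
        comp, cont = evaluate_bin(b, {"c1": g1, "c2": g2}, markers)
        assert (comp, cont) == (1.0, 1.0)

    def test_near_exact_marker_detected(self, rng):
        markers = self._markers(rng, m=1)
        mseq = list(markers["m0"])
        for pos in (10, 60, 110):  # 3 substitutions: 97.5% identity
            mseq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mseq[pos]]
        genome = random_dna(rng, 2_000) + "".join(mseq) + random_dna(rng, 2_000)
        b = GenomeBin("b", ["c1"])
        comp, _ = evaluate_bin(b, {"c1": genome}, markers)
        assert comp == 1.0

    def test_empty_marker_set_rejected(self, rng):
        with pytest.raises(ValueError):
            evaluate_bin(GenomeBin("b", []), {}, {})

    def test_bounds(self, rng):
        markers = self._markers(rng)
        b = GenomeBin("b", ["c1"])
        comp, cont = evaluate_bin(b, {"c1": random_dna(rng, 5_000)}, markers)
        assert 0.0 <= comp <= 1.0
        assert cont == 0.0  # no duplicated marker -> zero contamination


class TestFilterBins:
    @pytest.mark.parametrize(
        "completeness,contamination,kept",
        [
            (0.59, 0.00, False),  # <60% completeness discarded
            (0.60, 0.20, True),   # boundaries kept
            (1.00, 0.21, False),  # >20% contamination discarded
            (0.90, 0.05, True),
        ],
    )
    def test_boundaries(self, completeness, contamination, kept):
        b = GenomeBin("b", ["c"], completeness=completeness, contamination=contamination)
        assert (len(filter_bins([b])) == 1) is kept


@pytest.fixture
def lineage_tree():
    nodes = [
        (1, 1, "root", "root"),
        (2, 1, "superkingdom", "sk"),
        (3, 2, "phylum", "p"),
        (4, 3, "class", "c"),
        (5, 4, "order", "o"),
        (6, 5, "family", "F"),
        (7, 6, "genus", "G"),
        (8, 6, "genus", "H"),
        (9, 7, "species", "G.s1"),
        (10, 7, "species", "G.s2"),
        (11, 8, "species", "H.s1"),
    ]
    return TaxonomyTree(nodes)


class TestMajorityLineage:
    def test_three_of_four_at_genus(self, lineage_tree):
        # 3 say genus G, 1 says genus H: 3/4 = 0.75 meets the threshold
        result = majority_lineage([9, 9, 10, 11], lineage_tree)
        assert result == 7

    def test_tie_falls_back_to_family(self, lineage_tree):
        # 2 vs 2 at genus within one family -> family
        result = majority_lineage([9, 9, 11, 11], lineage_tree)
        assert result == 6

    def test_single_classification_full_lineage(self, lineage_tree):
        assert majority_lineage([9], lineage_tree) == 9

    def test_unresolvable(self):
        nodes = [
            (1, 1, "root", "root"),
            (2, 1, "superkingdom", "a"),
            (3, 1, "superkingdom", "b"),
            (4, 2, "phylum", "pa"),
            (5, 3, "phylum", "pb"),
        ]
        tree = TaxonomyTree(nodes)
        assert majority_lineage([4, 5], tree) == UNRESOLVED

    def test_empty_rejected(self, lineage_tree):
        with pytest.raises(ValueError):
            majority_lineage([], lineage_tree)


class TestReassembleBin:
    def test_contamination_drops(self, rng):
        # bin = genome A's contig plus a junk contig carrying duplicate
        # markers but no read support; re-assembly drops the junk
        markers = {f"m{i}": random_dna(rng, 120) for i in range(4)}
        genome = random_dna(rng, 9_000)
        pos = 1_000
        for mseq in markers.values():
            genome = genome[:pos] + mseq + genome[pos + 120 :]
            pos += 2_000
        junk = random_dna(rng, 500) + "".join(markers.values()) + random_dna(rng, 500)
        contigs = {"good": genome, "junk": junk}
        reads = []
        for i in range(0, len(genome) - 150 + 1, 4):
            reads.append(SequenceRecord(f"r{i}", genome[i : i + 150]))
            reads.append(SequenceRecord(f"r{i}b", reverse_complement(genome[i : i + 150])))
        alns = [
            md.AlignmentRecord(r.id, "good", 0, 10, "+") for r in reads
        ]
        b = GenomeBin("b0", ["good", "junk"])
        evaluate_bin(b, contigs, markers)
        assert b.contamination > 0
        out = reassemble_bin(b, contigs, reads, [], alns, markers)
        assert out.provenance == "reassembled"
        assert out.contamination < b.contamination
        assert out.completeness == 1.0

    def test_no_mapped_reads_unchanged(self, rng):
        markers = {"m0": random_dna(rng, 120)}
        b = GenomeBin("b0", ["c"], completeness=1.0)
        out = reassemble_bin(b, {"c": random_dna(rng, 1_000)}, [], [], [], markers)
        assert out is b

    def test_clean_bin_keep_or_equal(self, rng):
        markers = {f"m{i}": random_dna(rng, 120) for i in range(3)}
        genome = random_dna(rng, 6_000)
        pos = 1_000
        for mseq in markers.values():
            genome = genome[:pos] + mseq + genome[pos + 120 :]
            pos += 1_500
        reads = []
        for i in range(0, len(genome) - 150 + 1, 4):
            reads.append(SequenceRecord(f"r{i}", genome[i : i + 150]))
            reads.append(SequenceRecord(f"r{i}b", reverse_complement(genome[i : i + 150])))
        alns = [md.AlignmentRecord(r.id, "c", 0, 10, "+") for r in reads]
        b = GenomeBin("b0", ["c"])
        evaluate_bin(b, {"c": genome}, markers)
        out = reassemble_bin(b, {"c": genome}, reads, [], alns, markers)
        assert out.completeness >= b.completeness
        assert out.contamination <= b.contamination


class TestBinMetrics:
    def test_single_contig_bin(self, rng):
        seq = random_dna(rng, 4_000)
        b = GenomeBin("b0", ["c"], completeness=1.0, contamination=0.0)
        rows, medians = bin_metrics([b], {"c": seq})
        assert rows[0]["n_contigs"] == 1
        assert rows[0]["n50"] == 4_000

    def test_manual_medians(self, rng):
        contigs = {
            "a1": random_dna(rng, 3_000), "a2": random_dna(rng, 1_000),
            "b1": random_dna(rng, 8_000),
            "c1": random_dna(rng, 2_000), "c2": random_dna(rng, 2_000),
            "c3": random_dna(rng, 2_000),
        }
        bins = [
            GenomeBin("a", ["a1", "a2"], completeness=0.9, contamination=0.0),
            GenomeBin("b", ["b1"], completeness=1.0, contamination=0.1),
            GenomeBin("c", ["c1", "c2", "c3"], completeness=0.8, contamination=0.2),
        ]
        rows, medians = bin_metrics(bins, contigs)
        assert medians["n_contigs"] == 2  # manual: median(2, 1, 3)
        assert medians["n50"] == 3_000  # manual: median(3000, 8000, 2000)
        assert medians["completeness"] == pytest.approx(0.9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bin_metrics([], {})
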