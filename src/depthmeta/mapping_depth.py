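"""Built-in k-mer read mapping, per-contig coverage depth, and the
depth-based partitioning of contigs and reads into phylotypes.

A phylotype here is a coverage-depth stratum: contigs whose combined
mean depth falls into one of ``n_bins`` geometric (log-uniform) depth
intervals, together with the reads whose primary alignment lands on
those contigs.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _kmers
from .sequence_io import AlignmentRecord, SequenceRecord, reverse_complement

__all__ = [
    "UNMAPPED",
    "DepthProfile",
    "DepthPhylotype",
    "KmerIndex",
    "build_kmer_index",
    "map_short_read",
    "map_long_read",
    "compute_depths",
    "partition_by_depth",
    "assign_reads",
    "canonical",
]

UNMAPPED = "UNMAPPED"


def canonical(kmer: str) -> str:
    """Lexicographic canonical form of a k-mer (string convenience)."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def _revcomp_encoded(arr: np.ndarray) -> np.ndarray:
    out = arr[::-1].copy()
    mask = out != 4
    out[mask] = 3 - out[mask]
    return out


@dataclass
class DepthProfile:
    contig_id: str
    length: int
    mean_depth: dict[str, float]  # sample -> mapped bases / contig length
    n_mapped_reads: dict[str, int]

    @property
    def combined_depth(self) -> float:
        return sum(self.mean_depth.values())


@dataclass
class DepthPhylotype:
    label: int | str  # 1..n_bins or UNMAPPED
    depth_interval: tuple[float, float]
    member_contigs: list[str] = field(default_factory=list)
    member_short_reads: list[str] = field(default_factory=list)
    member_long_reads: list[str] = field(default_factory=list)


class KmerIndex:
    """Canonical k-mer -> occurrence list over a contig set.

    Occurrences are (contig_id, position, forward?) where forward means
    the contig's k-mer at that position equals the canonical form.
    """

    def __init__(self, contigs: Sequence[SequenceRecord], k: int = 21):
        if k % 2 == 0:
            raise ValueError("k must be odd")
        if not 11 <= k <= 31:
            raise ValueError("k must lie in [11, 31]")
        self.k = k
        self.contigs = {c.id: c.sequence for c in contigs}
        self.encoded = {c.id: _kmers.encode(c.sequence) for c in contigs}
        self.occurrences: dict[int, list[tuple[str, int, bool]]] = defaultdict(list)
        for cid in sorted(self.contigs):
            canon, forward, valid = _kmers.kmer_table(self.encoded[cid], k)
            for pos in np.nonzero(valid)[0]:
                self.occurrences[int(canon[pos])].append(
                    (cid, int(pos), bool(forward[pos]))
                )
        self.occurrences.default_factory = None  # freeze

    def __len__(self) -> int:
        return len(self.occurrences)


def build_kmer_index(contigs: Sequence[SequenceRecord], k: int = 21) -> KmerIndex:
    return KmerIndex(contigs, k)


def _seed_votes(encoded_read: np.ndarray, index: KmerIndex, step: int = 1):
    """Yield (contig, strand, offset, contig_pos) for every seed hit;
    ``offset`` is the implied start of the (possibly reverse-
    complemented) read on the contig."""
    k = index.k
    n = len(encoded_read)
    canon, forward, valid = _kmers.kmer_table(encoded_read, k)
    occ = index.occurrences
    for q in range(0, n - k + 1, step):
        if not valid[q]:
            continue
        hits = occ.get(int(canon[q]))
        if hits is None:
            continue
        read_forward = bool(forward[q])
        for cid, pos, contig_forward in hits:
            if contig_forward == read_forward:
                yield cid, "+", pos - q, pos
            else:
                yield cid, "-", pos - (n - k - q), pos


def map_short_read(
    read: SequenceRecord,
    index: KmerIndex,
    max_mismatch_frac: float = 0.05,
    min_overlap: int = 50,
) -> AlignmentRecord | None:
    """Seed-and-vote ungapped placement of a short read.

    The candidate (contig, strand, offset) with the most seed hits is
    verified base-by-base over the overlapping span; bases hanging past
    a contig end are soft-clipped, and the aligned span must reach
    ``min_overlap`` (reads fully inside a contig align end-to-end).
    Ties break on (contig_id, strand, offset) so mapping is
    deterministic. Returns None when unmapped.
    """
    n = len(read)
    if n < index.k:
        return None
    enc = _kmers.encode(read.sequence)
    votes: Counter = Counter()
    for cid, strand, offset, _pos in _seed_votes(enc, index):
        votes[(cid, strand, offset)] += 1
    if not votes:
        return None
    best_count = max(votes.values())
    cid, strand, offset = min(
        key for key, cnt in votes.items() if cnt == best_count
    )
    target = index.encoded[cid]
    oriented = enc if strand == "+" else _revcomp_encoded(enc)
    lo = max(offset, 0)
    hi = min(offset + n, len(target))
    span = hi - lo
    if span < min(min_overlap, n):
        return None
    mismatches = int((target[lo:hi] != oriented[lo - offset : hi - offset]).sum())
    if mismatches > max_mismatch_frac * span:
        return None
    return AlignmentRecord(read.id, cid, lo, hi, strand, score=span - mismatches)


def map_long_read(
    read: SequenceRecord,
    index: KmerIndex,
    min_chain_seeds: int = 5,
    band_frac: float = 0.2,
    seed_step: int = 3,
) -> AlignmentRecord | None:
    """Banded seed-chaining placement of a (noisy) long read.

    Seeds are binned by (contig, strand, diagonal band of ``band_frac``
    x read length); the fullest bin wins when it holds at least
    ``min_chain_seeds`` seeds. The reported interval spans the first to
    last chained seed on the contig.
    """
    n = len(read)
    if n < index.k:
        return None
    enc = _kmers.encode(read.sequence)
    band = max(1, int(band_frac * n))
    bins: dict[tuple[str, str, int], list[int]] = defaultdict(list)
    for cid, strand, offset, pos in _seed_votes(enc, index, step=seed_step):
        bins[(cid, strand, offset // band)].append(pos)
    if not bins:
        return None
    best_key = min(bins, key=lambda key: (-len(bins[key]), key))
    positions = bins[best_key]
    if len(positions) < min_chain_seeds:
        return None
    cid, strand, _band_idx = best_key
    start = min(positions)
    end = min(max(positions) + index.k, len(index.contigs[cid]))
    return AlignmentRecord(read.id, cid, start, end, strand, score=len(positions))


def compute_depths(
    alignments_by_sample: Mapping[str, Sequence[AlignmentRecord]],
    contigs: Sequence[SequenceRecord],
) -> dict[str, DepthProfile]:
    """Per-contig mean depth (aligned reference bases / length) and
    mapped-read counts, per sample. Only primary alignments count."""
    lengths = {c.id: len(c.sequence) for c in contigs}
    bases: dict[str, dict[str, int]] = {cid: {} for cid in lengths}
    counts: dict[str, dict[str, int]] = {cid: {} for cid in lengths}
    for sample, alns in alignments_by_sample.items():
        for aln in alns:
            if not aln.is_primary:
                continue
            if aln.contig_id not in lengths:
                raise ValueError(f"alignment to unknown contig {aln.contig_id!r}")
            bases[aln.contig_id][sample] = (
                bases[aln.contig_id].get(sample, 0) + aln.reference_span
            )
            counts[aln.contig_id][sample] = counts[aln.contig_id].get(sample, 0) + 1
    samples = list(alignments_by_sample)
    profiles = {}
    for cid, length in lengths.items():
        profiles[cid] = DepthProfile(
            contig_id=cid,
            length=length,
            mean_depth={s: bases[cid].get(s, 0) / length for s in samples},
            n_mapped_reads={s: counts[cid].get(s, 0) for s in samples},
        )
    return profiles


def _natural_breaks_1d(values: np.ndarray, k: int) -> np.ndarray:
    """Contiguous 1-D clustering by cutting the k-1 largest gaps.

    ``values`` must be sorted ascending. Single-linkage behaviour:
    tight runs of values are never split while loose regions absorb the
    extra cuts. Ties break toward the leftmost gap; deterministic.
    """
    m = len(values)
    if m == 0:
        return np.zeros(0, dtype=int)
    n_cuts = min(k - 1, m - 1)
    gaps = np.diff(values)
    # sort gap indices by (-gap, index) for a deterministic choice
    ranked = sorted(range(len(gaps)), key=lambda i: (-gaps[i], i))
    cuts = set(ranked[:n_cuts])
    labels = np.zeros(m, dtype=int)
    lab = 0
    for i in range(1, m):
        if i - 1 in cuts:
            lab += 1
        labels[i] = lab
    return labels


def partition_by_depth(
    profiles: Mapping[str, DepthProfile],
    n_bins: int = 11,
    scheme: str = "geometric",
) -> tuple[list[DepthPhylotype], dict[str, int]]:
    """Assign positive-depth contigs to ``n_bins`` depth strata.

    Two boundary schemes (the source procedure leaves this open):

    - "geometric": log-uniform boundaries between the smallest and
      largest positive combined-sample mean depth; bins may be empty.
    - "natural": cut at the n_bins-1 largest log-depth gaps, so
      boundaries fall in gaps of the observed depth distribution
      instead of splitting tight same-organism strata.

    Returns the phylotype list (labels 1..n_bins, low depth first) and a
    contig -> label map. Zero-depth contigs are left out of the map.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if scheme not in ("geometric", "natural"):
        raise ValueError(f"unknown boundary scheme {scheme!r}")
    depths = {
        cid: p.combined_depth for cid, p in profiles.items() if p.combined_depth > 0
    }
    if not depths:
        raise ValueError("nothing mapped: all contig depths are zero")
    lo = min(depths.values())
    hi = max(depths.values())

    if scheme == "natural" and hi > lo:
        order = sorted(depths, key=lambda cid: (depths[cid], cid))
        values = np.log(np.array([depths[cid] for cid in order]))
        labels_sorted = _natural_breaks_1d(values, n_bins)
        n_real = int(labels_sorted.max()) + 1
        edges = [lo]
        for b in range(1, n_real):
            left = max(depths[cid] for cid, lb in zip(order, labels_sorted) if lb == b - 1)
            right = min(depths[cid] for cid, lb in zip(order, labels_sorted) if lb == b)
            edges.append(float(np.sqrt(left * right)))
        edges.append(hi)
        phylotypes = [
            DepthPhylotype(
                label=b + 1,
                depth_interval=(
                    (edges[b], edges[b + 1]) if b < n_real else (hi, hi)
                ),
            )
            for b in range(n_bins)
        ]
        contig_map = {}
        for cid, lb in zip(order, labels_sorted):
            phylotypes[int(lb)].member_contigs.append(cid)
            contig_map[cid] = int(lb) + 1
        for p in phylotypes:
            p.member_contigs.sort()
        return phylotypes, {cid: contig_map[cid] for cid in sorted(contig_map)}

    if hi > lo:
        edges = np.geomspace(lo, hi, n_bins + 1)
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    phylotypes = [
        DepthPhylotype(label=b + 1, depth_interval=(float(edges[b]), float(edges[b + 1])))
        for b in range(n_bins)
    ]
    contig_map: dict[str, int] = {}
    for cid in sorted(depths):
        d = depths[cid]
        if hi == lo:
            b = 0
        else:
            b = int(np.floor(np.log(d / lo) / np.log(hi / lo) * n_bins))
            b = min(max(b, 0), n_bins - 1)
        phylotypes[b].member_contigs.append(cid)
        contig_map[cid] = b + 1
    return phylotypes, contig_map


def _mate_base(read_id: str) -> tuple[str, str]:
    if read_id.endswith("/1") or read_id.endswith("/2"):
        return read_id[:-2], read_id[-1]
    return read_id, ""


def assign_reads(
    alignments: Sequence[AlignmentRecord],
    contig_map: Mapping[str, int],
    phylotypes: Sequence[DepthPhylotype],
    all_read_ids: Iterable[str],
    long_read_ids: Iterable[str] = (),
    pair_mates: bool = True,
) -> tuple[list[DepthPhylotype], DepthPhylotype]:
    """Route every read to its contig's phylotype; fill the member lists.

    Mate 2 of a pair follows mate 1's assignment when ``pair_mates``.
    Reads without a usable primary alignment go to the UNMAPPED pool.
    Conservation holds: assigned + unmapped = total.
    """
    long_ids = set(long_read_ids)
    assigned: dict[str, int] = {}
    for aln in alignments:
        if not aln.is_primary:
            continue
        label = contig_map.get(aln.contig_id)
        if label is not None and aln.read_id not in assigned:
            assigned[aln.read_id] = label
    if pair_mates:
        for rid in list(assigned):
            base, mate = _mate_base(rid)
            if mate == "1":
                assigned[base + "/2"] = assigned[rid]
    unmapped = DepthPhylotype(label=UNMAPPED, depth_interval=(0.0, 0.0))
    for phylo in phylotypes:
        phylo.member_short_reads = []
        phylo.member_long_reads = []
    by_label = {p.label: p for p in phylotypes}
    for rid in all_read_ids:
        label = assigned.get(rid)
        target = by_label.get(label, unmapped) if label is not None else unmapped
        if rid in long_ids:
            target.member_long_reads.append(rid)
        else:
            target.member_short_reads.append(rid)
    return list(phylotypes), unmapped
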