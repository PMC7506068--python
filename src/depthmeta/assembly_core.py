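"""Desk-scale assembly machinery.

A canonical-k-mer de Bruijn unitig assembler for short reads, long-read
contig anchoring and chaining, a hybrid merge that joins contigs along
long-read chains (gap-filled from the read), and substitution-only
pileup polishing from short reads. Redundancy removal collapses contigs
contained in longer ones at high identity; overlap stitching joins
contigs whose ends overlap without containment.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _kmers
from .sequence_io import SequenceRecord, reverse_complement
from .mapping_depth import KmerIndex, canonical, map_short_read

logger = logging.getLogger(__name__)

__all__ = [
    "Contig",
    "Anchor",
    "AnchorChain",
    "assemble_short_reads",
    "anchor_contigs",
    "hybrid_merge",
    "remove_redundancy",
    "merge_overlaps",
    "polish",
]


@dataclass
class Contig:
    id: str
    sequence: str
    provenance: str = "short-only"  # short-only | hybrid | merged | polished
    phylotype: int | str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"contig {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    def as_record(self) -> SequenceRecord:
        return SequenceRecord(self.id, self.sequence)


# ---------------------------------------------------------------------------
# de Bruijn short-read assembly


def count_canonical_kmers(
    reads: Iterable[SequenceRecord], k: int
) -> tuple[np.ndarray, np.ndarray]:
    """(codes, counts) of canonical k-mers across a read set."""
    chunks = []
    for read in reads:
        canon, _forward, valid = _kmers.kmer_table(_kmers.encode(read.sequence), k)
        if valid.any():
            chunks.append(canon[valid])
    if not chunks:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty.copy()
    return np.unique(np.concatenate(chunks), return_counts=True)


def assemble_short_reads(
    reads: Sequence[SequenceRecord],
    k: int = 31,
    min_kmer_count: int = 2,
    min_edge_frac: float = 0.05,
    id_prefix: str = "ctg",
) -> list[Contig]:
    """Unitigs of the de Bruijn graph over canonical k-mers with count
    >= ``min_kmer_count``.

    Sequencing-error branches are cleaned with a relative-abundance
    rule: at a branching node, edges carrying less than
    ``min_edge_frac`` of the strongest sibling edge's k-mer count are
    dropped (in both orientations, keeping the graph strand-symmetric).
    Genuine branches between organisms of comparable depth survive.

    The graph holds both orientations of every surviving k-mer; maximal
    non-branching paths are emitted once (reverse-complement duplicates
    collapsed), ordered by (length desc, sequence) for determinism.
    k must be odd so no k-mer equals its own reverse complement.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    codes, counts = count_canonical_kmers(reads, k)
    keep = counts >= min_kmer_count
    solid = codes[keep]
    solid_counts = counts[keep]
    if len(solid) == 0:
        logger.warning("no k-mer survives the count filter; empty assembly")
        return []

    # both orientations of every solid k-mer become directed edges
    oriented = np.concatenate([solid, _kmers.revcomp_codes(solid, k)])
    both_counts = np.concatenate([solid_counts, solid_counts])
    canon_of = np.concatenate([solid, solid])
    suffix_mask = (np.int64(1) << (2 * (k - 1))) - 1
    prefixes = oriented >> 2
    suffixes = oriented & suffix_mask

    out_edges: dict[int, list[int]] = defaultdict(list)
    count_of: dict[int, int] = {}
    canon_lookup: dict[int, int] = {}
    for o, cnt, cn, p in zip(
        oriented.tolist(), both_counts.tolist(), canon_of.tolist(), prefixes.tolist()
    ):
        out_edges[p].append(o)
        count_of[o] = cnt
        canon_lookup[o] = cn
    # relative-abundance cleaning: a k-mer weak at either of its branch
    # nodes is dropped entirely (strand-symmetric by construction)
    weak_canon: set[int] = set()
    if min_edge_frac > 0:
        for node, edges in out_edges.items():
            if len(edges) < 2:
                continue
            strongest = max(count_of[o] for o in edges)
            for o in edges:
                if count_of[o] < min_edge_frac * strongest:
                    weak_canon.add(canon_lookup[o])
    if weak_canon:
        mask = np.array([c not in weak_canon for c in canon_of.tolist()])
        oriented = oriented[mask]
        prefixes = prefixes[mask]
        suffixes = suffixes[mask]
        out_edges = defaultdict(list)
        for o, p in zip(oriented.tolist(), prefixes.tolist()):
            out_edges[p].append(o)

    in_deg: Counter = Counter()
    for s in suffixes.tolist():
        in_deg[s] += 1
    for node in out_edges:
        out_edges[node].sort()

    def is_through(node: int) -> bool:
        return len(out_edges.get(node, ())) == 1 and in_deg[node] == 1

    used: set[int] = set()
    unitigs: list[str] = []
    alphabet = "ACGT"

    def walk(first: int) -> None:
        if first in used:
            return
        path_last = [alphabet[first & 3]]
        used.add(first)
        node = first & suffix_mask
        while is_through(node):
            nxt = out_edges[node][0]
            if nxt in used:
                break
            path_last.append(alphabet[nxt & 3])
            used.add(nxt)
            node = nxt & suffix_mask
        seq = _kmers.decode(first >> 2, k - 1) + "".join(path_last)
        unitigs.append(seq)

    for node in sorted(out_edges):
        if not is_through(node):
            for o in out_edges[node]:
                walk(o)
    for node in sorted(out_edges):  # leftover cycles
        for o in out_edges[node]:
            walk(o)

    unique = sorted(
        {min(s, reverse_complement(s)) for s in unitigs if len(s) >= k},
        key=lambda s: (-len(s), s),
    )
    return [
        Contig(f"{id_prefix}_{i}", seq, provenance="short-only")
        for i, seq in enumerate(unique)
    ]


# ---------------------------------------------------------------------------
# Long-read anchoring


@dataclass(frozen=True)
class Anchor:
    contig_id: str
    orientation: str  # contig orientation relative to the read
    read_start: int
    read_end: int
    contig_start: int  # interval on the ORIENTED contig
    contig_end: int
    n_kmers: int


@dataclass
class AnchorChain:
    long_read_id: str
    anchors: list[Anchor] = field(default_factory=list)


def _unique_contig_kmers(
    contigs: Sequence[Contig], k: int
) -> dict[int, tuple[str, int, bool]]:
    """Canonical k-mer codes occurring exactly once across the contig
    set, mapped to (contig_id, position, forward?)."""
    tables = []
    for contig in sorted(contigs, key=lambda c: c.id):
        canon, forward, valid = _kmers.kmer_table(_kmers.encode(contig.sequence), k)
        tables.append((contig.id, canon, forward, valid))
    all_codes = np.concatenate([c[v] for _, c, _, v in tables]) if tables else None
    if all_codes is None or len(all_codes) == 0:
        return {}
    codes, counts = np.unique(all_codes, return_counts=True)
    singles = codes[counts == 1]
    unique: dict[int, tuple[str, int, bool]] = {}
    for cid, canon, forward, valid in tables:
        member = np.isin(canon, singles) & valid
        for pos in np.nonzero(member)[0]:
            unique[int(canon[pos])] = (cid, int(pos), bool(forward[pos]))
    return unique


def anchor_contigs(
    contigs: Sequence[Contig],
    long_reads: Sequence[SequenceRecord],
    k_anchor: int = 17,
    min_anchor_kmers: int = 10,
    band_frac: float = 0.2,
) -> list[AnchorChain]:
    """Locate contigs on long reads via contig-unique k-mers.

    Hits per (read, contig, orientation) are clustered by diagonal into
    anchors; anchors with >= ``min_anchor_kmers`` hits are chained left
    to right, discarding overlaps by keeping the higher k-mer count.
    """
    if not contigs or not long_reads:
        raise ValueError("contigs and long reads must be non-empty")
    unique = _unique_contig_kmers(contigs, k_anchor)
    contig_len = {c.id: len(c) for c in contigs}
    chains: list[AnchorChain] = []
    for read in long_reads:
        n = len(read)
        band = max(100, int(band_frac * n))
        canon, forward, valid = _kmers.kmer_table(_kmers.encode(read.sequence), k_anchor)
        groups: dict[tuple[str, str, int], list[tuple[int, int]]] = defaultdict(list)
        for q in range(len(canon)):
            if not valid[q]:
                continue
            hit = unique.get(int(canon[q]))
            if hit is None:
                continue
            cid, cpos, contig_forward = hit
            if contig_forward == bool(forward[q]):
                orient, opos = "+", cpos
            else:
                orient, opos = "-", contig_len[cid] - cpos - k_anchor
            groups[(cid, orient, (q - opos) // band)].append((q, opos))
        anchors: list[Anchor] = []
        for (cid, orient, _band), hits in groups.items():
            if len(hits) < min_anchor_kmers:
                continue
            qs = [h[0] for h in hits]
            os = [h[1] for h in hits]
            anchors.append(
                Anchor(
                    contig_id=cid,
                    orientation=orient,
                    read_start=min(qs),
                    read_end=max(qs) + k_anchor,
                    contig_start=min(os),
                    contig_end=max(os) + k_anchor,
                    n_kmers=len(hits),
                )
            )
        # greedy overlap resolution: strongest anchors first
        anchors.sort(key=lambda a: (-a.n_kmers, a.read_start, a.contig_id))
        selected: list[Anchor] = []
        for a in anchors:
            if all(
                a.read_end <= b.read_start or a.read_start >= b.read_end
                for b in selected
            ):
                selected.append(a)
        selected.sort(key=lambda a: a.read_start)
        chains.append(AnchorChain(read.id, selected))
    return chains


# ---------------------------------------------------------------------------
# Hybrid merge


def _flip(orient: str) -> str:
    return "-" if orient == "+" else "+"


@dataclass
class _EdgeSupport:
    read_id: str
    gap: int  # negative -> overlap to trim from the next contig
    fill: str  # read subsequence filling a positive gap (stored direction)
    strength: int


def _junction(read_seq: str, a: Anchor, b: Anchor, len_a: int) -> tuple[int, str]:
    """Gap between the oriented end of contig A and the oriented start of
    contig B as implied by their anchors on one read; fill sequence when
    positive."""
    a_end_on_read = a.read_end + (len_a - a.contig_end)
    b_start_on_read = b.read_start - b.contig_start
    gap = b_start_on_read - a_end_on_read
    if gap > 0:
        lo = max(0, a_end_on_read)
        hi = min(len(read_seq), a_end_on_read + gap)
        return gap, read_seq[lo:hi]
    return gap, ""


def hybrid_merge(
    contigs: Sequence[Contig],
    chains: Sequence[AnchorChain],
    long_reads: Sequence[SequenceRecord],
    min_support: int = 2,
    id_prefix: str = "merged",
) -> list[Contig]:
    """Join contigs along long-read chains into super-contigs.

    Consecutive anchor pairs vote for oriented adjacencies; adjacencies
    supported by >= ``min_support`` distinct reads are kept (ambiguous
    ports and equal-support orientation conflicts are dropped). Positive
    gaps are filled with the subsequence of the strongest supporting
    read; negative gaps trim the joined contig.
    """
    by_id = {c.id: c for c in contigs}
    reads = {r.id: r for r in long_reads}
    support: dict[frozenset, dict[tuple, list[_EdgeSupport]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for chain in chains:
        read = reads.get(chain.long_read_id)
        if read is None:
            raise ValueError(f"chain references unknown read {chain.long_read_id!r}")
        for a, b in zip(chain.anchors, chain.anchors[1:]):
            if a.contig_id not in by_id or b.contig_id not in by_id:
                raise ValueError("chain references unknown contig")
            if a.contig_id == b.contig_id:
                continue
            gap, fill = _junction(read.sequence, a, b, len(by_id[a.contig_id]))
            key = frozenset((a.contig_id, b.contig_id))
            fwd = (a.contig_id, a.orientation, b.contig_id, b.orientation)
            rev = (b.contig_id, _flip(b.orientation), a.contig_id, _flip(a.orientation))
            canon_dir = min(fwd, rev)
            if canon_dir == fwd:
                sup = _EdgeSupport(read.id, gap, fill, a.n_kmers + b.n_kmers)
            else:
                sup = _EdgeSupport(
                    read.id, gap, reverse_complement(fill), a.n_kmers + b.n_kmers
                )
            support[key][canon_dir].append(sup)

    # resolve orientation conflicts per contig pair
    accepted: list[tuple[tuple, _EdgeSupport]] = []
    for key in sorted(support, key=sorted):
        classes = support[key]
        scored = sorted(
            (
                (len({s.read_id for s in sups}), direction)
                for direction, sups in classes.items()
            ),
            reverse=True,
        )
        n_best, best_dir = scored[0]
        if n_best < min_support:
            continue
        if len(scored) > 1 and scored[1][0] == n_best:
            logger.warning(
                "contradictory orientations with equal support for %s; dropped",
                sorted(key),
            )
            continue
        best_sup = max(classes[best_dir], key=lambda s: (s.strength, s.read_id))
        accepted.append((best_dir, best_sup))

    # each contig end may participate in at most one join
    port_edges: dict[tuple[str, str], list[int]] = defaultdict(list)
    for idx, (direction, _sup) in enumerate(accepted):
        a_id, a_or, b_id, b_or = direction
        port_edges[(a_id, "R" if a_or == "+" else "L")].append(idx)
        port_edges[(b_id, "L" if b_or == "+" else "R")].append(idx)
    busy = {port for port, idxs in port_edges.items() if len(idxs) > 1}
    usable = [
        (direction, sup)
        for direction, sup in accepted
        if (direction[0], "R" if direction[1] == "+" else "L") not in busy
        and (direction[2], "L" if direction[3] == "+" else "R") not in busy
    ]

    join_at: dict[tuple[str, str], tuple[str, str, int, str]] = {}
    for direction, sup in usable:
        a_id, a_or, b_id, b_or = direction
        join_at[(a_id, "R" if a_or == "+" else "L")] = (b_id, b_or, sup.gap, sup.fill)
        join_at[(b_id, "L" if b_or == "+" else "R")] = (
            a_id,
            _flip(a_or),
            sup.gap,
            reverse_complement(sup.fill),
        )

    def oriented_seq(cid: str, orient: str) -> str:
        seq = by_id[cid].sequence
        return seq if orient == "+" else reverse_complement(seq)

    def start_orientation(cid: str) -> str:
        # start so the free (unjoined) end is on the left
        if (cid, "L") not in join_at:
            return "+"
        if (cid, "R") not in join_at:
            return "-"
        return "+"  # cycle; break arbitrarily

    visited: set[str] = set()
    merged: list[Contig] = []
    counter = 0
    for contig in sorted(contigs, key=lambda c: (-len(c), c.id)):
        if contig.id in visited:
            continue
        if (contig.id, "L") not in join_at and (contig.id, "R") not in join_at:
            visited.add(contig.id)
            merged.append(contig)
            continue
        orient = start_orientation(contig.id)
        parts = [oriented_seq(contig.id, orient)]
        members = [contig.id]
        visited.add(contig.id)
        current, cur_or = contig.id, orient
        while True:
            nxt = join_at.get((current, "R" if cur_or == "+" else "L"))
            if nxt is None:
                break
            n_id, n_or, gap, fill = nxt
            if n_id in visited:
                break  # cycle
            n_seq = oriented_seq(n_id, n_or)
            if gap > 0:
                parts.append(fill)
                parts.append(n_seq)
            else:
                parts.append(n_seq[min(-gap, len(n_seq) - 1) :])
            members.append(n_id)
            visited.add(n_id)
            current, cur_or = n_id, n_or
        if len(members) == 1:
            merged.append(contig)
        else:
            merged.append(
                Contig(f"{id_prefix}_{counter}", "".join(parts), provenance="merged")
            )
            counter += 1
    merged.sort(key=lambda c: (-len(c), c.sequence))
    return merged


# ---------------------------------------------------------------------------
# Redundancy removal


def remove_redundancy(
    contigs: Sequence[Contig],
    min_identity: float = 0.95,
    min_containment: float = 0.95,
    k: int = 21,
    seed_step: int = 13,
) -> list[Contig]:
    """Drop contigs contained in a longer retained contig at
    >= ``min_identity`` over >= ``min_containment`` of their own length.

    Contigs are processed longest-first against an incrementally built
    k-mer index of retained contigs; comparison is ungapped at the
    best-voted offset. Deterministic and idempotent.
    """
    ordered = sorted(contigs, key=lambda c: (-len(c), c.sequence, c.id))
    index: dict[int, list[tuple[str, int, bool]]] = defaultdict(list)
    retained: list[Contig] = []
    encoded: dict[str, np.ndarray] = {}

    for contig in ordered:
        enc = _kmers.encode(contig.sequence)
        n = len(enc)
        canon, forward, valid = _kmers.kmer_table(enc, k)
        votes: Counter = Counter()
        for q in range(0, len(canon), seed_step):
            if not valid[q]:
                continue
            for cid, pos, target_forward in index.get(int(canon[q]), ()):
                if target_forward == bool(forward[q]):
                    votes[(cid, "+", pos - q)] += 1
                else:
                    votes[(cid, "-", pos - (n - k - q))] += 1
        contained = False
        if votes:
            best_count = max(votes.values())
            cid, strand, offset = min(
                key for key, cnt in votes.items() if cnt == best_count
            )
            target = encoded[cid]
            query = enc if strand == "+" else _revcomp_encoded(enc)
            lo = max(offset, 0)
            hi = min(offset + n, len(target))
            aligned = hi - lo
            if aligned > 0:
                matches = aligned - int(
                    (target[lo:hi] != query[lo - offset : hi - offset]).sum()
                )
                if matches / aligned >= min_identity and aligned / n >= min_containment:
                    contained = True
        if not contained:
            retained.append(contig)
            encoded[contig.id] = enc
            for pos in np.nonzero(valid)[0]:
                index[int(canon[pos])].append(
                    (contig.id, int(pos), bool(forward[pos]))
                )
    return retained


def _revcomp_encoded(arr: np.ndarray) -> np.ndarray:
    out = arr[::-1].copy()
    mask = out != 4
    out[mask] = 3 - out[mask]
    return out


def merge_overlaps(
    contigs: Sequence[Contig],
    min_overlap: int = 1000,
    min_identity: float = 0.95,
    k: int = 21,
    seed_step: int = 13,
    id_prefix: str = "stitch",
) -> list[Contig]:
    """Stitch contigs whose ends overlap at high identity.

    Complements remove_redundancy: contigs assembled from adjacent read
    partitions overlap without containment; joining them avoids
    duplicated sequence in the pooled assembly. The full overlapping
    span is verified ungapped, so repeat-only partial matches do not
    merge. Iterates to a fixpoint; deterministic.
    """
    current = [Contig(c.id, c.sequence, c.provenance, c.phylotype) for c in contigs]
    counter = 0
    merged_something = True
    while merged_something:
        merged_something = False
        current.sort(key=lambda c: (-len(c), c.sequence, c.id))
        for ai in range(len(current)):
            target = current[ai]
            t_enc = _kmers.encode(target.sequence)
            canon_t, fwd_t, valid_t = _kmers.kmer_table(t_enc, k)
            t_index: dict[int, list[tuple[int, bool]]] = defaultdict(list)
            for pos in np.nonzero(valid_t)[0]:
                t_index[int(canon_t[pos])].append((int(pos), bool(fwd_t[pos])))
            for bi in range(ai + 1, len(current)):
                query = current[bi]
                q_enc = _kmers.encode(query.sequence)
                nq, nt = len(q_enc), len(t_enc)
                canon_q, fwd_q, valid_q = _kmers.kmer_table(q_enc, k)
                votes: Counter = Counter()
                for q in range(0, len(canon_q), seed_step):
                    if not valid_q[q]:
                        continue
                    for pos, t_forward in t_index.get(int(canon_q[q]), ()):
                        if t_forward == bool(fwd_q[q]):
                            votes[("+", pos - q)] += 1
                        else:
                            votes[("-", pos - (nq - k - q))] += 1
                if not votes:
                    continue
                best_count = max(votes.values())
                strand, offset = min(
                    key for key, cnt in votes.items() if cnt == best_count
                )
                oriented = q_enc if strand == "+" else _revcomp_encoded(q_enc)
                lo = max(offset, 0)
                hi = min(offset + nq, nt)
                span = hi - lo
                if span < min_overlap:
                    continue
                matches = span - int(
                    (t_enc[lo:hi] != oriented[lo - offset : hi - offset]).sum()
                )
                if matches / span < min_identity:
                    continue
                q_seq = (
                    query.sequence
                    if strand == "+"
                    else reverse_complement(query.sequence)
                )
                if offset < 0:
                    new_seq = q_seq[: -offset] + target.sequence
                elif offset + nq > nt:
                    new_seq = target.sequence + q_seq[nt - offset :]
                else:
                    new_seq = target.sequence  # contained; drop the query
                current[ai] = Contig(
                    f"{id_prefix}_{counter}", new_seq, provenance="merged",
                    phylotype=target.phylotype,
                )
                counter += 1
                del current[bi]
                merged_something = True
                break
            if merged_something:
                break
    current.sort(key=lambda c: (-len(c), c.sequence))
    return current


# ---------------------------------------------------------------------------
# Polishing


def polish(
    contigs: Sequence[Contig],
    reads: Sequence[SequenceRecord],
    rounds: int = 1,
    min_depth: int = 3,
    min_majority: float = 0.6,
    mapping_k: int = 21,
    max_mismatch_frac: float = 0.05,
) -> tuple[list[Contig], dict[str, int]]:
    """Substitution-only pileup polishing from short reads.

    Reads are mapped ungapped; positions with pileup depth >=
    ``min_depth`` where a majority base (>= ``min_majority`` of the
    pileup) differs from the contig are substituted. Returns the
    polished contigs and a per-contig correction count.
    """
    current = [Contig(c.id, c.sequence, c.provenance, c.phylotype) for c in contigs]
    corrections: dict[str, int] = {c.id: 0 for c in contigs}
    if not current:
        return current, corrections
    encoded_reads = {}
    for _round in range(rounds):
        idx = KmerIndex([c.as_record() for c in current], k=mapping_k)
        piles = {c.id: np.zeros((4, len(c)), dtype=np.int32) for c in current}
        for read in reads:
            aln = map_short_read(read, idx, max_mismatch_frac=max_mismatch_frac)
            if aln is None or aln.end - aln.start != len(read):
                continue  # unmapped or clipped at a contig end
            enc = encoded_reads.get(read.id)
            if enc is None:
                enc = _kmers.encode(read.sequence)
                encoded_reads[read.id] = enc
            oriented = enc if aln.strand == "+" else _revcomp_encoded(enc)
            ok = oriented != 4
            pile = piles[aln.contig_id]
            positions = np.arange(aln.start, aln.end)[ok]
            np.add.at(pile, (oriented[ok], positions), 1)
        changed = False
        bases = np.frombuffer(b"ACGT", dtype="S1")
        for contig in current:
            pile = piles[contig.id]
            depth = pile.sum(axis=0)
            best = pile.argmax(axis=0)
            best_count = pile.max(axis=0)
            seq = np.frombuffer(contig.sequence.encode(), dtype="S1").copy()
            eligible = (depth >= min_depth) & (best_count >= min_majority * depth)
            wanted = bases[best]
            to_fix = eligible & (wanted != seq)
            n_fix = int(to_fix.sum())
            if n_fix:
                seq[to_fix] = wanted[to_fix]
                contig.sequence = seq.tobytes().decode()
                corrections[contig.id] += n_fix
                changed = True
            contig.provenance = "polished"
        if not changed:
            break
    return current, corrections
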