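"""Tetranucleotide + depth genome binning, marker-based completeness and
contamination scoring, bin filtering, lineage calls, and the bin
re-assembly loop."""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from statistics import median
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from . import _kmers
from .sequence_io import SequenceRecord, reverse_complement
from .mapping_depth import DepthProfile
from .taxonomy_lca import RANKS, TaxonomyTree
from . import assembly_core, gene_catalog, report_stats

logger = logging.getLogger(__name__)

__all__ = [
    "UNRESOLVED",
    "GenomeBin",
    "tnf_vector",
    "TNF_CLASSES",
    "bin_contigs",
    "evaluate_bin",
    "filter_bins",
    "majority_lineage",
    "reassemble_bin",
    "bin_metrics",
]

UNRESOLVED = "UNRESOLVED"


def _canonical_4mers() -> list[str]:
    seen = set()
    for a in "ACGT":
        for b in "ACGT":
            for c in "ACGT":
                for d in "ACGT":
                    kmer = a + b + c + d
                    rc = reverse_complement(kmer)
                    seen.add(min(kmer, rc))
    return sorted(seen)


TNF_CLASSES: list[str] = _canonical_4mers()  # 136 canonical tetranucleotides
_TNF_INDEX = {kmer: i for i, kmer in enumerate(TNF_CLASSES)}
_TNF_CODES = np.array(
    [sum({"A": 0, "C": 1, "G": 2, "T": 3}[b] * 4 ** (3 - i) for i, b in enumerate(km))
     for km in TNF_CLASSES],
    dtype=np.int64,
)  # packed codes of the classes, ascending (TNF_CLASSES is sorted)


@dataclass
class GenomeBin:
    bin_id: str
    contig_ids: list[str]
    depth: dict[str, float] = field(default_factory=dict)  # per-sample mean
    marker_census: dict[str, int] = field(default_factory=dict)
    completeness: float = 0.0
    contamination: float = 0.0
    lineage: int | str = UNRESOLVED
    provenance: str = "initial"


def tnf_vector(contig) -> np.ndarray:
    """136-dimensional canonical tetranucleotide frequency vector,
    normalized to sum 1; windows containing N are skipped."""
    seq = contig.sequence.upper()
    if len(seq) < 4:
        raise ValueError(f"contig {contig.id!r} shorter than 4 bp")
    canon, _forward, valid = _kmers.kmer_table(_kmers.encode(seq), 4)
    counts = np.zeros(len(TNF_CLASSES), dtype=float)
    idx = np.searchsorted(_TNF_CODES, canon[valid])
    np.add.at(counts, idx, 1)
    total = counts.sum()
    if total == 0:
        raise ValueError(f"contig {contig.id!r} has no valid tetranucleotide window")
    return counts / total


def bin_contigs(
    contigs: Sequence,
    profiles: Mapping[str, DepthProfile],
    min_contig_length: int = 2500,
    n_bins: int | None = None,
    depth_weight: float = 3.0,
    seed: int = 0,
) -> list[GenomeBin]:
    """Cluster contigs longer than ``min_contig_length`` (strict) by
    standardized TNF plus log-depth features, average linkage.

    With ``n_bins=None`` the dendrogram cut is chosen by the best Dunn
    index over candidate cluster counts, falling back to one bin when no
    cut shows real structure. Contigs at or below the length filter stay
    unbinned. Deterministic.
    """
    eligible = sorted(
        (c for c in contigs if len(c.sequence) > min_contig_length),
        key=lambda c: c.id,
    )
    if len(eligible) < 2:
        raise ValueError("fewer than 2 contigs pass the length filter")
    samples = sorted(next(iter(profiles.values())).mean_depth) if profiles else []
    tnf = np.vstack([tnf_vector(c) for c in eligible])
    depths = np.array(
        [
            [profiles[c.id].mean_depth.get(s, 0.0) if c.id in profiles else 0.0 for s in samples]
            for c in eligible
        ]
    )
    feats = [tnf]
    if samples:
        feats.append(np.log10(depths + 0.1))
    X = np.hstack(feats)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd
    # block balancing: 136 standardized TNF features would otherwise
    # drown the handful of depth features
    X[:, : tnf.shape[1]] /= np.sqrt(tnf.shape[1])
    if samples:
        X[:, tnf.shape[1] :] *= depth_weight

    Z = linkage(pdist(X), method="average")
    if n_bins is not None:
        labels = fcluster(Z, t=max(1, n_bins), criterion="maxclust")
    else:
        # pick the dendrogram cut maximizing the Dunn index (smallest
        # between-cluster point distance / largest cluster diameter);
        # unstructured data tops out near 1, so below the floor the
        # contigs stay together. Dunn handles singleton clusters, which
        # zero out silhouette; a largest-merge-gap rule proved brittle
        # at small n.
        n = len(eligible)
        D = squareform(pdist(X))
        labels = np.ones(n, dtype=int)
        best = 1.1
        for K in range(2, min(20, n - 2) + 1):
            candidate = fcluster(Z, t=K, criterion="maxclust")
            uniq = np.unique(candidate)
            if len(uniq) < 2:
                continue
            inter = min(
                float(D[np.ix_(candidate == a, candidate == b)].min())
                for i, a in enumerate(uniq)
                for b in uniq[i + 1 :]
            )
            diameter = max(
                float(D[np.ix_(candidate == u, candidate == u)].max()) for u in uniq
            )
            if diameter == 0.0:
                continue
            score = inter / diameter
            if score > best:
                best = score
                labels = candidate

    groups: dict[int, list] = defaultdict(list)
    for contig, label in zip(eligible, labels):
        groups[int(label)].append(contig)
    bins: list[GenomeBin] = []
    for b, label in enumerate(sorted(groups)):
        members = groups[label]
        lengths = np.array([len(c.sequence) for c in members], dtype=float)
        depth_vec: dict[str, float] = {}
        for si, s in enumerate(samples):
            d = np.array(
                [profiles[c.id].mean_depth.get(s, 0.0) if c.id in profiles else 0.0 for c in members]
            )
            depth_vec[s] = float((d * lengths).sum() / lengths.sum())
        bins.append(
            GenomeBin(
                bin_id=f"bin_{b}",
                contig_ids=[c.id for c in members],
                depth=depth_vec,
            )
        )
    return bins


# ---------------------------------------------------------------------------
# Marker census


def _find_marker_occurrences(
    contig_seq: str,
    marker: str,
    kmer_index: Mapping[str, list[int]],
    k: int,
    min_identity: float,
) -> int:
    """Count non-overlapping near-exact occurrences of ``marker`` (either
    strand) in one contig via seeded offset voting."""
    m = len(marker)
    hits: set[int] = set()
    for oriented in (marker, reverse_complement(marker)):
        votes: defaultdict[int, int] = defaultdict(int)
        for q in range(0, m - k + 1, max(1, k // 2)):
            for pos in kmer_index.get(oriented[q : q + k], ()):
                votes[pos - q] += 1
        for offset, n in votes.items():
            if n < 2:
                continue
            if offset < 0 or offset + m > len(contig_seq):
                continue
            window = contig_seq[offset : offset + m]
            matches = sum(1 for a, b in zip(window, oriented) if a == b)
            if matches >= min_identity * m:
                hits.add(offset)
    # merge overlapping verified offsets into occurrences
    occurrences = 0
    last_end = -1
    for offset in sorted(hits):
        if offset >= last_end:
            occurrences += 1
            last_end = offset + m // 2
    return occurrences


def evaluate_bin(
    genome_bin: GenomeBin,
    contigs: Mapping[str, str],
    marker_seqs: Mapping[str, str],
    min_identity: float = 0.95,
    k: int = 21,
) -> tuple[float, float]:
    """Marker census of a bin: completeness = markers present / M;
    contamination = excess copies / M. Updates the bin in place."""
    if not marker_seqs:
        raise ValueError("marker set is empty")
    census: dict[str, int] = {m: 0 for m in marker_seqs}
    for cid in genome_bin.contig_ids:
        seq = contigs[cid]
        index: defaultdict[str, list[int]] = defaultdict(list)
        for pos in range(len(seq) - k + 1):
            index[seq[pos : pos + k]].append(pos)
        for marker_id, mseq in marker_seqs.items():
            census[marker_id] += _find_marker_occurrences(
                seq, mseq, index, k, min_identity
            )
    M = len(marker_seqs)
    completeness = sum(1 for c in census.values() if c >= 1) / M
    contamination = sum(max(0, c - 1) for c in census.values()) / M
    genome_bin.marker_census = census
    genome_bin.completeness = completeness
    genome_bin.contamination = contamination
    return completeness, contamination


def filter_bins(
    bins: Sequence[GenomeBin],
    min_completeness: float = 0.60,
    max_contamination: float = 0.20,
) -> list[GenomeBin]:
    """Keep bins with completeness >= 60% and contamination <= 20%;
    boundaries are kept (the discard conditions are strict)."""
    return [
        b
        for b in bins
        if b.completeness >= min_completeness and b.contamination <= max_contamination
    ]


def majority_lineage(
    classifications: Sequence[int],
    tree: TaxonomyTree,
    agreement: float = 0.75,
) -> int | str:
    """Deepest rank at which one taxon collects >= ``agreement`` of the
    per-marker classifications; UNRESOLVED if no rank qualifies."""
    if not classifications:
        raise ValueError("no classifications")
    n = len(classifications)
    for rank in reversed(RANKS):  # species upward
        counts: defaultdict[int, int] = defaultdict(int)
        for taxon in classifications:
            node = tree.ancestor_at_rank(taxon, rank)
            if node is not None:
                counts[node] += 1
        for node, c in sorted(counts.items()):
            if c >= agreement * n:
                return node
    return UNRESOLVED


def reassemble_bin(
    genome_bin: GenomeBin,
    contigs: Mapping[str, str],
    short_reads: Sequence[SequenceRecord],
    long_reads: Sequence[SequenceRecord],
    alignments: Sequence,
    marker_seqs: Mapping[str, str],
    assembly_k: int = 31,
    anchor_k: int = 17,
    min_kmer_count: int = 2,
    min_contig_length: int = 200,
) -> GenomeBin:
    """Re-assemble a bin from the reads mapping to it; replace the bin
    only when quality improves (contamination down, or completeness up
    without contamination rising)."""
    bin_contig_ids = set(genome_bin.contig_ids)
    wanted = {
        a.read_id for a in alignments if a.is_primary and a.contig_id in bin_contig_ids
    }
    # mate rescue: an unmapped mate still belongs to the bin's fragment
    for rid in list(wanted):
        if rid.endswith("/1"):
            wanted.add(rid[:-2] + "/2")
        elif rid.endswith("/2"):
            wanted.add(rid[:-2] + "/1")
    bin_short = [r for r in short_reads if r.id in wanted]
    bin_long = [r for r in long_reads if r.id in wanted]
    if not bin_short:
        logger.warning("bin %s has no mapped short reads; unchanged", genome_bin.bin_id)
        return genome_bin
    new_contigs = assembly_core.assemble_short_reads(
        bin_short,
        k=assembly_k,
        min_kmer_count=min_kmer_count,
        id_prefix=f"{genome_bin.bin_id}_re",
    )
    new_contigs = [c for c in new_contigs if len(c) >= min_contig_length]
    if new_contigs and bin_long:
        chains = assembly_core.anchor_contigs(new_contigs, bin_long, k_anchor=anchor_k)
        new_contigs = assembly_core.hybrid_merge(
            new_contigs, chains, bin_long, id_prefix=f"{genome_bin.bin_id}_rem"
        )
        new_contigs, _ = assembly_core.polish(new_contigs, bin_short)
    if not new_contigs:
        logger.warning("bin %s re-assembly empty; unchanged", genome_bin.bin_id)
        return genome_bin
    candidate = GenomeBin(
        bin_id=genome_bin.bin_id,
        contig_ids=[c.id for c in new_contigs],
        depth=dict(genome_bin.depth),
        provenance="reassembled",
    )
    seqs = {c.id: c.sequence for c in new_contigs}
    evaluate_bin(candidate, seqs, marker_seqs)
    improved = candidate.contamination < genome_bin.contamination or (
        candidate.completeness > genome_bin.completeness
        and candidate.contamination <= genome_bin.contamination
    )
    if improved:
        candidate.reassembled_contigs = new_contigs  # type: ignore[attr-defined]
        return candidate
    logger.info("bin %s re-assembly kept original", genome_bin.bin_id)
    return genome_bin


def bin_metrics(
    bins: Sequence[GenomeBin],
    contigs: Mapping[str, str],
    min_gene_length: int = 100,
    min_contig_length_genes: int = 500,
) -> tuple[list[dict], dict[str, float]]:
    """Per-bin (n_contigs, N50, n_genes, completeness, contamination)
    table plus medians across bins."""
    if not bins:
        raise ValueError("no bins")
    rows = []
    for b in bins:
        lengths = [len(contigs[cid]) for cid in b.contig_ids]
        records = [SequenceRecord(cid, contigs[cid]) for cid in b.contig_ids]
        genes = gene_catalog.find_orfs(
            records,
            min_gene_length=min_gene_length,
            min_contig_length=min_contig_length_genes,
        )
        rows.append(
            {
                "bin_id": b.bin_id,
                "n_contigs": len(b.contig_ids),
                "n50": report_stats.n50(lengths),
                "n_genes": len(genes),
                "completeness": b.completeness,
                "contamination": b.contamination,
            }
        )
    medians = {
        key: float(median(r[key] for r in rows))
        for key in ("n_contigs", "n50", "n_genes", "completeness", "contamination")
    }
    return rows, medians
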