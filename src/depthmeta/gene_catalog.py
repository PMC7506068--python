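"""ORF prediction, greedy non-redundant clustering, catalog merging,
and catalog statistics."""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .sequence_io import SequenceRecord, reverse_complement
from .mapping_depth import KmerIndex, canonical, map_short_read

__all__ = [
    "PredictedGene",
    "GeneCluster",
    "GeneCatalog",
    "CatalogStats",
    "find_orfs",
    "cluster_nr",
    "merge_catalogs",
    "catalog_stats",
    "map_reads_to_catalog",
]

_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class PredictedGene:
    gene_id: str
    contig_id: str
    start: int  # 0-based half-open on the contig, forward coordinates
    end: int
    strand: str
    sequence: str  # oriented (coding) sequence
    complete: bool
    source_catalog: str = ""

    @property
    def id(self) -> str:  # SequenceRecord-compatible
        return self.gene_id

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneCluster:
    representative: PredictedGene
    members: list[str]
    sources: set[str] = field(default_factory=set)


@dataclass
class GeneCatalog:
    label: str
    clusters: list[GeneCluster]

    @property
    def representatives(self) -> list[PredictedGene]:
        return [c.representative for c in self.clusters]

    def __len__(self) -> int:
        return len(self.clusters)


@dataclass(frozen=True)
class CatalogStats:
    label: str
    n_orfs: int
    total_length: int
    average_length: float
    pct_complete: float


# ---------------------------------------------------------------------------
# ORF prediction


def _scan_frame(seq: str, frame: int, min_len: int):
    """Yield (start, end, complete) intervals on ``seq`` for one frame.

    An ORF is a maximal in-frame run ending at a stop codon and starting
    at the first ATG after the previous stop. Runs truncated by either
    contig edge are reported as incomplete.
    """
    n = len(seq)
    prev_stop_end: int | None = None  # None -> frame begins at contig edge
    atg: int | None = None
    pos = frame
    while pos + 3 <= n:
        codon = seq[pos : pos + 3]
        if codon in _STOPS:
            if atg is not None:
                if pos + 3 - atg >= min_len:
                    yield atg, pos + 3, True
            elif prev_stop_end is None:
                # contig starts mid-gene: no ATG before the first stop
                if pos + 3 - frame >= min_len:
                    yield frame, pos + 3, False
            prev_stop_end = pos + 3
            atg = None
        elif codon == "ATG" and atg is None:
            atg = pos
        pos += 3
    # runs truncated by the right edge (no stop before the contig end)
    run_end = pos  # last full in-frame codon boundary
    if atg is not None:
        if run_end - atg >= min_len:
            yield atg, run_end, False
    elif prev_stop_end is None:
        if run_end - frame >= min_len:
            yield frame, run_end, False


def find_orfs(
    contigs: Sequence,
    min_gene_length: int = 100,
    min_contig_length: int = 500,
    source_catalog: str = "",
) -> list[PredictedGene]:
    """Six-frame ORF scan over contigs of at least ``min_contig_length``.

    Complete ORFs have an in-frame ATG and stop codon inside the contig;
    edge-truncated runs of sufficient length are reported incomplete.
    Accepts Contig or SequenceRecord inputs.
    """
    genes: list[PredictedGene] = []
    for contig in contigs:
        seq = contig.sequence.upper()
        if len(seq) < min_contig_length:
            continue
        found: list[tuple[int, int, str, bool]] = []
        for frame in range(3):
            for s, e, complete in _scan_frame(seq, frame, min_gene_length):
                found.append((s, e, "+", complete))
        rc = reverse_complement(seq)
        L = len(seq)
        for frame in range(3):
            for s, e, complete in _scan_frame(rc, frame, min_gene_length):
                found.append((L - e, L - s, "-", complete))
        found.sort()
        for i, (s, e, strand, complete) in enumerate(found):
            sub = seq[s:e]
            genes.append(
                PredictedGene(
                    gene_id=f"{contig.id}_{i}",
                    contig_id=contig.id,
                    start=s,
                    end=e,
                    strand=strand,
                    sequence=sub if strand == "+" else reverse_complement(sub),
                    complete=complete,
                    source_catalog=source_catalog,
                )
            )
    return genes


# ---------------------------------------------------------------------------
# Greedy non-redundant clustering


def _ungapped_align(rep: str, gene: str, k: int, index: Mapping[str, list[tuple[int, bool]]]) -> tuple[float, float]:
    """Best ungapped (identity, coverage-of-shorter) of ``gene`` against
    ``rep`` using the representative's k-mer index."""
    n = len(gene)
    votes: Counter = Counter()
    for q in range(0, n - k + 1):
        kmer = gene[q : q + k]
        canon = canonical(kmer)
        forward = kmer == canon
        for pos, rep_forward in index.get(canon, ()):
            if rep_forward == forward:
                votes[("+", pos - q)] += 1
            else:
                votes[("-", pos - (n - k - q))] += 1
    if not votes:
        return 0.0, 0.0
    best_count = max(votes.values())
    strand, offset = min(key for key, cnt in votes.items() if cnt == best_count)
    oriented = gene if strand == "+" else reverse_complement(gene)
    lo = max(offset, 0)
    hi = min(offset + n, len(rep))
    aligned = hi - lo
    if aligned <= 0:
        return 0.0, 0.0
    matches = sum(1 for i in range(lo, hi) if rep[i] == oriented[i - offset])
    shorter = min(n, len(rep))
    return matches / aligned, aligned / shorter


def cluster_nr(
    genes: Sequence[PredictedGene],
    min_identity: float = 0.95,
    min_coverage: float = 0.90,
    k: int = 15,
    label: str = "custom",
) -> GeneCatalog:
    """Greedy incremental clustering, longest gene first.

    Each gene joins the first existing cluster whose representative
    aligns to it ungapped at >= ``min_identity`` over >=
    ``min_coverage`` of the shorter sequence; otherwise it founds a new
    cluster. Deterministic: ties in length break lexicographically.
    """
    if not genes:
        raise ValueError("no genes to cluster")
    ordered = sorted(genes, key=lambda g: (-len(g), g.sequence, g.gene_id))
    clusters: list[GeneCluster] = []
    rep_seqs: list[str] = []
    rep_indexes: list[dict[str, list[tuple[int, bool]]]] = []
    kmer_to_reps: dict[str, set[int]] = defaultdict(set)

    for gene in ordered:
        seq = gene.sequence
        candidates: set[int] = set()
        for q in range(0, len(seq) - k + 1, max(1, k // 2)):
            candidates |= kmer_to_reps.get(canonical(seq[q : q + k]), set())
        joined = False
        for rep_idx in sorted(candidates):
            identity, coverage = _ungapped_align(
                rep_seqs[rep_idx], seq, k, rep_indexes[rep_idx]
            )
            if identity >= min_identity and coverage >= min_coverage:
                clusters[rep_idx].members.append(gene.gene_id)
                clusters[rep_idx].sources.add(gene.source_catalog)
                joined = True
                break
        if not joined:
            rep_idx = len(clusters)
            clusters.append(
                GeneCluster(gene, [gene.gene_id], {gene.source_catalog})
            )
            rep_seqs.append(seq)
            rep_index: dict[str, list[tuple[int, bool]]] = defaultdict(list)
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                canon = canonical(kmer)
                rep_index[canon].append((pos, kmer == canon))
                kmer_to_reps[canon].add(rep_idx)
            rep_indexes.append(dict(rep_index))
    return GeneCatalog(label, clusters)


def merge_catalogs(
    catalogs: Sequence[GeneCatalog],
    min_identity: float = 0.95,
    min_coverage: float = 0.90,
    label: str = "RGC",
) -> GeneCatalog:
    """Re-cluster the pooled representatives of several catalogs.

    Every merged cluster records which source catalogs contributed
    members (for overlap accounting).
    """
    if len(catalogs) < 2:
        raise ValueError("need at least two catalogs to merge")
    pooled: list[PredictedGene] = []
    for cat in catalogs:
        for cluster in cat.clusters:
            rep = cluster.representative
            pooled.append(
                PredictedGene(
                    gene_id=f"{cat.label}|{rep.gene_id}",
                    contig_id=rep.contig_id,
                    start=rep.start,
                    end=rep.end,
                    strand=rep.strand,
                    sequence=rep.sequence,
                    complete=rep.complete,
                    source_catalog=cat.label,
                )
            )
    return cluster_nr(
        pooled, min_identity=min_identity, min_coverage=min_coverage, label=label
    )


def average_length(total_length: int, n_orfs: int) -> float:
    """Catalog average ORF length, rounded to 2 decimals."""
    if n_orfs <= 0:
        raise ValueError("n_orfs must be positive")
    return round(total_length / n_orfs, 2)


def catalog_stats(catalog: GeneCatalog) -> CatalogStats:
    """Table-style catalog statistics over cluster representatives."""
    if not catalog.clusters:
        raise ValueError("empty catalog")
    n = len(catalog.clusters)
    total = sum(len(c.representative) for c in catalog.clusters)
    n_complete = sum(1 for c in catalog.clusters if c.representative.complete)
    return CatalogStats(
        label=catalog.label,
        n_orfs=n,
        total_length=total,
        average_length=average_length(total, n),
        pct_complete=round(100.0 * n_complete / n, 2),
    )


def map_reads_to_catalog(
    reads: Sequence[SequenceRecord],
    catalog: GeneCatalog,
    mapping_k: int = 21,
    max_mismatch_frac: float = 0.05,
) -> tuple[float, list[str]]:
    """Short-read mapping ratio against catalog representatives, plus the
    representatives receiving zero reads."""
    records = [
        SequenceRecord(c.representative.gene_id, c.representative.sequence)
        for c in catalog.clusters
    ]
    index = KmerIndex(records, k=mapping_k)
    mapped_per_gene: Counter = Counter()
    n_mapped = 0
    for read in reads:
        aln = map_short_read(read, index, max_mismatch_frac=max_mismatch_frac)
        if aln is not None:
            n_mapped += 1
            mapped_per_gene[aln.contig_id] += 1
    ratio = n_mapped / len(reads) if reads else 0.0
    unmapped = [r.id for r in records if mapped_per_gene[r.id] == 0]
    return ratio, unmapped
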