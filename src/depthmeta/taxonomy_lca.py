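"""Taxonomy tree handling, LCA gene assignment from hit tables, and
rank-level summaries."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "RANKS",
    "UNCLASSIFIED",
    "TaxonomyTree",
    "TaxonHit",
    "GeneAssignment",
    "lca",
    "assign_gene",
    "rank_summary",
    "classified_fraction",
]

RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")
_RANK_DEPTH = {r: i for i, r in enumerate(RANKS)}
UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class TaxonHit:
    """One row of a gene-vs-reference hit table."""

    gene_id: str
    taxon_id: int
    bitscore: float
    evalue: float


@dataclass(frozen=True)
class GeneAssignment:
    gene_id: str
    taxon_id: int | str  # taxon id, or UNCLASSIFIED
    rank: str | None
    n_hits_used: int

    @property
    def classified(self) -> bool:
        return self.taxon_id != UNCLASSIFIED


class TaxonomyTree:
    """Rooted taxonomy with named ranks.

    Nodes are (taxon_id, parent_id, rank, name); the root is its own
    parent and carries rank "root". Ranks deepen along every path.
    """

    def __init__(self, nodes: Iterable[tuple[int, int, str, str]]):
        self._parent: dict[int, int] = {}
        self._rank: dict[int, str] = {}
        self._name: dict[int, str] = {}
        root = None
        for taxon_id, parent_id, rank, name in nodes:
            if taxon_id in self._parent:
                raise ValueError(f"duplicate taxon id {taxon_id}")
            self._parent[taxon_id] = parent_id
            self._rank[taxon_id] = rank
            self._name[taxon_id] = name
            if taxon_id == parent_id:
                if root is not None:
                    raise ValueError("more than one root")
                root = taxon_id
        if root is None:
            raise ValueError("no root (node with parent == itself)")
        self.root = root
        for taxon_id, parent_id in self._parent.items():
            if parent_id not in self._parent:
                raise ValueError(f"parent {parent_id} of {taxon_id} unknown")
        # cache root-paths; also detects cycles
        self._path: dict[int, tuple[int, ...]] = {}
        for taxon_id in self._parent:
            self._path[taxon_id] = self._compute_path(taxon_id)

    def _compute_path(self, taxon_id: int) -> tuple[int, ...]:
        path = []
        seen = set()
        node = taxon_id
        while True:
            if node in seen:
                raise ValueError(f"cycle through taxon {node}")
            seen.add(node)
            path.append(node)
            parent = self._parent[node]
            if parent == node:
                break
            node = parent
        return tuple(reversed(path))  # root first

    def __contains__(self, taxon_id: int) -> bool:
        return taxon_id in self._parent

    def __len__(self) -> int:
        return len(self._parent)

    def parent(self, taxon_id: int) -> int:
        return self._parent[taxon_id]

    def rank(self, taxon_id: int) -> str:
        return self._rank[taxon_id]

    def name(self, taxon_id: int) -> str:
        return self._name[taxon_id]

    def path_to_root(self, taxon_id: int) -> tuple[int, ...]:
        """Root-first path from the root down to ``taxon_id`` inclusive."""
        return self._path[taxon_id]

    def depth(self, taxon_id: int) -> int:
        return len(self._path[taxon_id]) - 1

    def ancestor_at_rank(self, taxon_id: int, rank: str) -> int | None:
        """The ancestor-or-self of ``taxon_id`` at ``rank``, or None if the
        lineage does not reach that rank."""
        for node in self._path[taxon_id]:
            if self._rank[node] == rank:
                return node
        return None

    def children(self, taxon_id: int) -> list[int]:
        return [t for t, p in self._parent.items() if p == taxon_id and t != taxon_id]

    def taxa_at_rank(self, rank: str) -> list[int]:
        return sorted(t for t, r in self._rank.items() if r == rank)

    # -- I/O (NCBI-nodes-like TSV: taxon_id, parent_id, rank, name) --------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyTree":
        nodes = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                taxon_id, parent_id, rank, name = line.split("\t")[:4]
                nodes.append((int(taxon_id), int(parent_id), rank, name))
        return cls(nodes)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#taxon_id\tparent_id\trank\tname\n")
            for taxon_id in sorted(self._parent):
                fh.write(
                    f"{taxon_id}\t{self._parent[taxon_id]}\t"
                    f"{self._rank[taxon_id]}\t{self._name[taxon_id]}\n"
                )


def percentage(count: int, total: int, decimals: int = 2) -> float:
    """Share of ``count`` in ``total`` as a rounded percentage (the
    rounding rule used by every summary in this module)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, decimals)


def lca(taxa: Iterable[int], tree: TaxonomyTree) -> int:
    """Deepest node that is an ancestor-or-self of every input taxon."""
    taxa = list(taxa)
    if not taxa:
        raise ValueError("lca of empty taxon set")
    paths = [tree.path_to_root(t) for t in taxa]
    result = tree.root
    for level in range(min(len(p) for p in paths)):
        nodes = {p[level] for p in paths}
        if len(nodes) != 1:
            break
        result = nodes.pop()
    return result


def assign_gene(
    hits: Sequence[TaxonHit],
    tree: TaxonomyTree,
    max_evalue: float = 1e-5,
    score_margin: float = 0.90,
) -> GeneAssignment:
    """Bitscore-margin LCA assignment of one gene from its hit rows.

    Hits failing the e-value cut-off are discarded; of the remainder,
    hits scoring at least ``score_margin`` of the best bitscore vote,
    and the assignment is their LCA. No surviving hit -> UNCLASSIFIED.
    """
    gene_id = hits[0].gene_id if hits else "?"
    usable = []
    for hit in hits:
        if hit.taxon_id not in tree:
            warnings.warn(f"hit taxon {hit.taxon_id} absent from tree; dropped")
            continue
        if hit.evalue <= max_evalue:
            usable.append(hit)
    if not usable:
        return GeneAssignment(gene_id, UNCLASSIFIED, None, 0)
    best = max(h.bitscore for h in usable)
    kept = [h for h in usable if h.bitscore >= score_margin * best]
    taxon = lca((h.taxon_id for h in kept), tree)
    rank = tree.rank(taxon)
    return GeneAssignment(gene_id, taxon, rank, len(kept))


def rank_summary(
    assignments: Sequence[GeneAssignment],
    tree: TaxonomyTree,
    rank: str,
) -> list[tuple[str, int, float]]:
    """Distribution of assignments projected to ``rank``.

    Genes unclassified, or assigned above the requested rank, count as
    "unclassified at rank". Percentages are over all genes, 2 decimals.
    """
    if rank not in _RANK_DEPTH:
        raise ValueError(f"unknown rank {rank!r}")
    counts: dict[str, int] = {}
    unclassified = 0
    for a in assignments:
        node = None
        if a.classified:
            node = tree.ancestor_at_rank(a.taxon_id, rank)
        if node is None:
            unclassified += 1
        else:
            name = tree.name(node)
            counts[name] = counts.get(name, 0) + 1
    total = len(assignments)
    rows = [
        (name, n, percentage(n, total))
        for name, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    rows.append((f"unclassified_at_{rank}", unclassified, percentage(unclassified, total)))
    return rows


def classified_fraction(
    assignments: Sequence[GeneAssignment],
    subset_ids: Iterable[str] | None = None,
) -> float:
    """Percentage of genes (optionally restricted to ``subset_ids``) with
    a non-UNCLASSIFIED assignment, 2 decimals."""
    if subset_ids is None:
        selected = list(assignments)
    else:
        wanted = set(subset_ids)
        missing = wanted - {a.gene_id for a in assignments}
        if missing:
            raise ValueError(f"subset ids not among assignments: {sorted(missing)[:3]}")
        selected = [a for a in assignments if a.gene_id in wanted]
    if not selected:
        raise ValueError("empty subset")
    return percentage(sum(a.classified for a in selected), len(selected))


def read_hit_table(path: str | Path) -> list[TaxonHit]:
    hits = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene_id, taxon_id, bitscore, evalue = line.split("\t")[:4]
            hits.append(TaxonHit(gene_id, int(taxon_id), float(bitscore), float(evalue)))
    return hits


def write_hit_table(hits: Sequence[TaxonHit], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#gene_id\ttaxon_id\tbitscore\tevalue\n")
        for h in hits:
            fh.write(f"{h.gene_id}\t{h.taxon_id}\t{h.bitscore:g}\t{h.evalue:g}\n")
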