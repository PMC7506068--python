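"""Ground-truthed mock metagenome generator.

Builds a panel of random genomes with planted single-copy markers,
shared repeats and protein-coding genes, samples per-sample abundance
profiles, and simulates HiSeq-like paired short reads and PacBio-like
noisy long reads with full origin tracking, so that every downstream
stage of the pipeline can be scored against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .sequence_io import SequenceRecord, reverse_complement, write_fasta, write_fastq
from .taxonomy_lca import RANKS, TaxonHit, TaxonomyTree

__all__ = [
    "CommunityTruth",
    "ReadOrigin",
    "PlantedGene",
    "generate_genomes",
    "sample_abundances",
    "simulate_short_reads",
    "simulate_long_reads",
    "generate_hit_table",
    "infer_gene_taxa",
    "make_community_taxonomy",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# 61 sense codons (64 minus TAA/TAG/TGA)
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


@dataclass(frozen=True)
class ReadOrigin:
    genome_id: str
    start: int
    strand: str


@dataclass(frozen=True)
class PlantedGene:
    genome_id: str
    start: int
    end: int
    strand: str


@dataclass
class CommunityTruth:
    """Everything the simulator knows about the community it built."""

    genomes: list[SequenceRecord]
    gc_targets: dict[str, float]
    marker_seqs: dict[str, str]  # marker_id -> 120-bp sequence
    markers: dict[str, dict[str, tuple[int, int]]]  # genome -> marker -> interval
    repeats: list[tuple[str, str, int, int]]  # (repeat_id, genome_id, start, end)
    genes: list[PlantedGene] = field(default_factory=list)
    taxonomy: TaxonomyTree | None = None
    genome_taxon: dict[str, int] = field(default_factory=dict)
    abundances: np.ndarray | None = None  # shape (n_samples, n_genomes)
    read_origins: dict[str, ReadOrigin] = field(default_factory=dict)

    @property
    def genome_ids(self) -> list[str]:
        return [g.id for g in self.genomes]

    def genome_by_id(self, genome_id: str) -> SequenceRecord:
        for g in self.genomes:
            if g.id == genome_id:
                return g
        raise KeyError(genome_id)


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode()


def _marker_sequence(marker_index: int) -> str:
    """Fixed 120-bp sequence per marker id, independent of community seed."""
    rng = np.random.default_rng(987_000 + marker_index)
    return _random_seq(rng, 120)


def _place_interval(
    rng: np.random.Generator,
    genome_length: int,
    size: int,
    occupied: list[tuple[int, int]],
    max_tries: int = 2000,
) -> int:
    """Pick a start so [start, start+size) avoids every occupied interval."""
    for _ in range(max_tries):
        start = int(rng.integers(0, genome_length - size + 1))
        end = start + size
        if all(end <= s or start >= e for s, e in occupied):
            occupied.append((start, end))
            return start
    raise RuntimeError("could not place interval without overlap")


def make_community_taxonomy(n_genomes: int) -> tuple[TaxonomyTree, dict[int, int]]:
    """A small full-rank taxonomy for ``n_genomes`` organisms.

    Each genome gets its own species; species are grouped pairwise into
    genera, genera pairwise into families, and so on up to two
    superkingdoms. An extra sibling species is added under every genus
    so lineage-neighborhood sampling always has a neighbor.

    Returns (tree, genome index -> species taxon id).
    """
    nodes: list[tuple[int, int, str, str]] = [(1, 1, "root", "root")]
    next_id = 2

    def add(parent: int, rank: str, name: str) -> int:
        nonlocal next_id
        nodes.append((next_id, parent, rank, name))
        next_id += 1
        return next_id - 1

    genome_species: dict[int, int] = {}
    # parent index at each level: group genomes in blocks of 2**(levels below)
    level_nodes: dict[tuple[str, int], int] = {}

    for i in range(n_genomes):
        parent = 1
        for depth, rank in enumerate(RANKS[:-1]):  # superkingdom..genus
            block = i // (2 ** (len(RANKS) - 1 - depth))
            key = (rank, block)
            if key not in level_nodes:
                level_nodes[key] = add(parent, rank, f"{rank}_{block}")
            parent = level_nodes[key]
        genome_species[i] = add(parent, "species", f"species_g{i}")
    # sibling species per genus so neighborhoods are non-trivial
    for (rank, block), node in list(level_nodes.items()):
        if rank == "genus":
            add(node, "species", f"species_sib_{block}")
    return TaxonomyTree(nodes), genome_species


def generate_genomes(
    n_genomes: int,
    length_range: tuple[int, int] = (50_000, 200_000),
    gc_range: tuple[float, float] = (0.35, 0.65),
    n_markers: int = 6,
    repeat_spec: Sequence[tuple[int, int, Sequence[int]]] = (),
    n_genes_per_genome: int = 20,
    gene_length_range: tuple[int, int] = (300, 1500),
    seed: int = 0,
) -> CommunityTruth:
    """Build the genome panel with planted markers, repeats, and genes.

    ``repeat_spec`` entries are (repeat_length, copies_per_genome,
    genome_indices); every copy is an exact duplicate of the same
    randomly drawn repeat sequence.
    """
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    marker_seqs = {f"marker_{m}": _marker_sequence(m) for m in range(n_markers)}
    for rep_len, _copies, _members in repeat_spec:
        if rep_len >= lo:
            raise ValueError(f"repeat length {rep_len} >= minimum genome length {lo}")

    genomes: list[SequenceRecord] = []
    gc_targets: dict[str, float] = {}
    markers: dict[str, dict[str, tuple[int, int]]] = {}
    occupied_by_genome: list[list[tuple[int, int]]] = []
    raw: list[np.ndarray] = []

    for i in range(n_genomes):
        gid = f"genome_{i}"
        length = int(rng.integers(lo, hi + 1))
        gc = float(rng.uniform(*gc_range)) if gc_range[0] < gc_range[1] else gc_range[0]
        seq = np.frombuffer(_random_seq(rng, length, gc).encode(), dtype="S1").copy()
        occupied: list[tuple[int, int]] = []
        marker_map: dict[str, tuple[int, int]] = {}
        for marker_id, mseq in marker_seqs.items():
            start = _place_interval(rng, length, len(mseq), occupied)
            seq[start : start + len(mseq)] = np.frombuffer(mseq.encode(), dtype="S1")
            marker_map[marker_id] = (start, start + len(mseq))
        raw.append(seq)
        gc_targets[gid] = gc
        markers[gid] = marker_map
        occupied_by_genome.append(occupied)

    repeats: list[tuple[str, str, int, int]] = []
    for r, (rep_len, copies, members) in enumerate(repeat_spec):
        rep_seq = np.frombuffer(_random_seq(rng, rep_len).encode(), dtype="S1")
        for gi in members:
            for _ in range(copies):
                start = _place_interval(
                    rng, len(raw[gi]), rep_len, occupied_by_genome[gi]
                )
                raw[gi][start : start + rep_len] = rep_seq
                repeats.append((f"repeat_{r}", f"genome_{gi}", start, start + rep_len))

    genes: list[PlantedGene] = []
    for i in range(n_genomes):
        gid = f"genome_{i}"
        length = len(raw[i])
        for _ in range(n_genes_per_genome):
            n_codons = int(rng.integers(gene_length_range[0] // 3, gene_length_range[1] // 3))
            codon_idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
            coding = "ATG" + "".join(_SENSE_CODONS[j] for j in codon_idx) + "TAA"
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = coding if strand == "+" else reverse_complement(coding)
            try:
                start = _place_interval(rng, length, len(inserted), occupied_by_genome[i])
            except RuntimeError:
                continue  # crowded genome; skip this gene
            raw[i][start : start + len(inserted)] = np.frombuffer(
                inserted.encode(), dtype="S1"
            )
            genes.append(PlantedGene(gid, start, start + len(inserted), strand))

    for i in range(n_genomes):
        genomes.append(SequenceRecord(f"genome_{i}", raw[i].tobytes().decode()))

    tree, genome_species = make_community_taxonomy(n_genomes)
    truth = CommunityTruth(
        genomes=genomes,
        gc_targets=gc_targets,
        marker_seqs=marker_seqs,
        markers=markers,
        repeats=repeats,
        genes=genes,
        taxonomy=tree,
        genome_taxon={f"genome_{i}": t for i, t in genome_species.items()},
    )
    return truth


def sample_abundances(
    n_genomes: int,
    profile: float | Sequence[float] = 4.0,
    n_samples: int = 2,
    seed: int = 0,
) -> np.ndarray:
    """Per-sample relative abundances, shape (n_samples, n_genomes).

    ``profile`` is either a geometric ratio r (> 1), giving proportions
    r^0 : r^-1 : ... before normalization, or an explicit non-negative
    vector. Samples share the organisms but carry independently permuted
    abundance vectors (the first sample keeps the canonical order).
    """
    if np.isscalar(profile):
        r = float(profile)
        if r <= 1:
            raise ValueError("geometric ratio must be > 1")
        base = r ** -np.arange(n_genomes, dtype=float)
    else:
        base = np.asarray(profile, dtype=float)
        if base.shape != (n_genomes,):
            raise ValueError("explicit abundance vector has wrong length")
        if (base < 0).any():
            raise ValueError("abundances must be non-negative")
    base = base / base.sum()
    rng = np.random.default_rng(seed)
    rows = [base]
    for _ in range(1, n_samples):
        rows.append(base[rng.permutation(n_genomes)])
    return np.vstack(rows)


def _pick_genomes(
    truth: CommunityTruth, sample: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    if truth.abundances is None:
        raise ValueError("truth has no abundances; call sample_abundances first")
    lengths = np.array([len(g) for g in truth.genomes], dtype=float)
    weights = truth.abundances[sample] * lengths
    weights = weights / weights.sum()
    return rng.choice(len(truth.genomes), size=n, p=weights)


def simulate_short_reads(
    truth: CommunityTruth,
    n_pairs: int,
    read_length: int = 150,
    insert_mean: int = 250,
    insert_sd: float = 25.0,
    sub_rate: float = 0.001,
    sample: int = 0,
    seed: int = 0,
    id_prefix: str = "sr",
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Simulate paired-end short reads; returns (R1 list, R2 list).

    Fragments are drawn from genomes proportionally to abundance x
    length, with uniform start; mate 2 is the reverse complement of the
    fragment's 3' end. Substitutions are i.i.d. per base. Origins of
    both mates are recorded in ``truth.read_origins``.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    rng = np.random.default_rng(seed)
    picks = _pick_genomes(truth, sample, n_pairs, rng)
    r1: list[SequenceRecord] = []
    r2: list[SequenceRecord] = []
    for i, gi in enumerate(picks):
        genome = truth.genomes[gi]
        gseq = genome.sequence
        insert = max(read_length, int(round(rng.normal(insert_mean, insert_sd))))
        insert = min(insert, len(gseq))
        start = int(rng.integers(0, len(gseq) - insert + 1))
        frag = gseq[start : start + insert]
        fwd = frag[:read_length]
        rev = reverse_complement(frag[-read_length:])
        fwd, rev = (_mutate_subs(fwd, sub_rate, rng), _mutate_subs(rev, sub_rate, rng))
        rid = f"{id_prefix}{sample}_{i}"
        qual = [37] * len(fwd)
        r1.append(SequenceRecord(rid + "/1", fwd, qual))
        r2.append(SequenceRecord(rid + "/2", rev, [37] * len(rev)))
        truth.read_origins[rid + "/1"] = ReadOrigin(genome.id, start, "+")
        truth.read_origins[rid + "/2"] = ReadOrigin(
            genome.id, start + insert - read_length, "-"
        )
    return r1, r2


def _mutate_subs(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for pos in hits:
        current = arr[pos]
        choices = [b for b in _BASES if b != current]
        arr[pos] = choices[int(rng.integers(0, 3))]
    return arr.tobytes().decode()


def simulate_long_reads(
    truth: CommunityTruth,
    n_reads: int,
    mean_length: float = 7604.0,
    sigma: float = 1.0,
    min_length: int = 50,
    sub_rate: float = 0.015,
    ins_rate: float = 0.090,
    del_rate: float = 0.045,
    quality_model: Callable[[np.random.Generator], float] | None = None,
    sample: int = 0,
    seed: int = 0,
    id_prefix: str = "lr",
) -> list[SequenceRecord]:
    """Simulate noisy long reads with a truncated log-normal length model.

    Errors are applied left to right: before each template base an
    insertion may add a random base; the base itself may be deleted or
    substituted. Each read carries a read-level quality score in
    [0, 100]. Origins are recorded against the template start.
    """
    for rate in (sub_rate, ins_rate, del_rate):
        if not 0 <= rate < 0.3:
            raise ValueError("error rates must lie in [0, 0.3)")
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(seed)
    # log-normal mean is exp(mu + sigma^2/2); calibrate mu to the target
    mu = np.log(mean_length) - sigma**2 / 2
    picks = _pick_genomes(truth, sample, n_reads, rng)
    reads: list[SequenceRecord] = []
    for i, gi in enumerate(picks):
        genome = truth.genomes[gi]
        glen = len(genome)
        length = max(min_length, int(round(rng.lognormal(mu, sigma))))
        length = min(length, glen)
        start = int(rng.integers(0, glen - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        template = genome.sequence[start : start + length]
        if strand == "-":
            template = reverse_complement(template)
        noisy = _apply_long_read_errors(template, sub_rate, ins_rate, del_rate, rng)
        if not noisy:
            noisy = "A"  # fully deleted tiny template; keep record valid
        if quality_model is not None:
            q = float(quality_model(rng))
        else:
            q = float(np.clip(rng.normal(85.0, 6.0), 0.0, 100.0))
        rid = f"{id_prefix}{sample}_{i}"
        reads.append(SequenceRecord(rid, noisy, q))
        truth.read_origins[rid] = ReadOrigin(genome.id, start, strand)
    return reads


def _apply_long_read_errors(
    template: str,
    sub_rate: float,
    ins_rate: float,
    del_rate: float,
    rng: np.random.Generator,
) -> str:
    out = []
    n = len(template)
    ins = rng.random(n) < ins_rate
    dele = rng.random(n) < del_rate
    subs = rng.random(n) < sub_rate
    ins_bases = rng.integers(0, 4, size=n)
    sub_shift = rng.integers(1, 4, size=n)
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 0}
    alphabet = "ACGT"
    for j, base in enumerate(template):
        if ins[j]:
            out.append(alphabet[ins_bases[j]])
        if dele[j]:
            continue
        if subs[j]:
            out.append(alphabet[(base_index[base] + sub_shift[j]) % 4])
        else:
            out.append(base)
    return "".join(out)


# ---------------------------------------------------------------------------
# Simulated reference hit tables


def infer_gene_taxa(
    truth: CommunityTruth,
    genes: Sequence,
    k: int = 31,
    min_votes: int = 3,
) -> dict[str, int | None]:
    """Attribute each gene to a source genome by k-mer voting, returning
    gene_id -> species taxon id (None when no genome wins).

    Genes may be SequenceRecord-like (``id``/``sequence`` attributes).
    """
    index: dict[str, set[str]] = {}
    for genome in truth.genomes:
        seq = genome.sequence
        for j in range(0, len(seq) - k + 1):
            kmer = seq[j : j + k]
            index.setdefault(kmer, set()).add(genome.id)
    out: dict[str, int | None] = {}
    for gene in genes:
        votes: dict[str, int] = {}
        for oriented in (gene.sequence, reverse_complement(gene.sequence)):
            for j in range(0, len(oriented) - k + 1, k):  # non-overlapping probes
                for gid in index.get(oriented[j : j + k], ()):
                    votes[gid] = votes.get(gid, 0) + 1
        if votes:
            gid, n = max(votes.items(), key=lambda kv: (kv[1], kv[0]))
            out[gene.id] = truth.genome_taxon[gid] if n >= min_votes else None
        else:
            out[gene.id] = None
    return out


def generate_hit_table(
    truth: CommunityTruth,
    genes: Sequence,
    n_hits_per_gene: int = 5,
    decoy_rate: float = 0.0,
    seed: int = 0,
    gene_taxa: dict[str, int | None] | None = None,
) -> list[TaxonHit]:
    """Simulate a protein-search hit table for catalog genes.

    Hits are drawn from the true taxon's lineage neighborhood (same
    species, then sibling species of the same genus, then the wider
    family) with decreasing bitscores. With probability ``decoy_rate``
    the top-scoring hit is a decoy from a random species; decoys carry
    e-values on both sides of the downstream cut-off, so a fraction of
    them is filtered before LCA.
    """
    if not 0 <= decoy_rate <= 1:
        raise ValueError("decoy_rate must lie in [0, 1]")
    tree = truth.taxonomy
    if tree is None:
        raise ValueError("truth has no taxonomy")
    rng = np.random.default_rng(seed)
    if gene_taxa is None:
        gene_taxa = infer_gene_taxa(truth, genes)
    all_species = tree.taxa_at_rank("species")
    hits: list[TaxonHit] = []
    for gene in genes:
        taxon = gene_taxa.get(gene.id)
        if taxon is None:
            continue  # no reference hit at all -> unclassified downstream
        best_score = float(rng.uniform(180, 260))
        rows: list[TaxonHit] = []
        if rng.random() < decoy_rate:
            decoy = int(all_species[rng.integers(0, len(all_species))])
            if rng.random() < 0.7:
                # decoy fails the e-value filter downstream
                rows.append(TaxonHit(gene.id, decoy, best_score * 1.05, 1e-4))
            else:
                rows.append(TaxonHit(gene.id, decoy, best_score * 1.05, 1e-20))
        rows.append(TaxonHit(gene.id, taxon, best_score, 1e-30))
        genus = tree.ancestor_at_rank(taxon, "genus")
        genus_species = [t for t in tree.children(genus) if t != taxon] if genus else []
        family = tree.ancestor_at_rank(taxon, "family")
        family_species = []
        if family is not None:
            for g in tree.children(family):
                family_species.extend(t for t in tree.children(g) if t != taxon)
        for _ in range(max(0, n_hits_per_gene - len(rows))):
            u = rng.random()
            if u < 0.5 or not genus_species:
                rows.append(
                    TaxonHit(gene.id, taxon, best_score * float(rng.uniform(0.93, 0.99)), 1e-25)
                )
            elif u < 0.8:
                t = int(genus_species[rng.integers(0, len(genus_species))])
                rows.append(
                    TaxonHit(gene.id, t, best_score * float(rng.uniform(0.91, 0.95)), 1e-20)
                )
            else:
                t = (
                    int(family_species[rng.integers(0, len(family_species))])
                    if family_species
                    else taxon
                )
                # below the 0.90 score margin: present but not voting
                rows.append(
                    TaxonHit(gene.id, t, best_score * float(rng.uniform(0.70, 0.85)), 1e-10)
                )
        hits.extend(rows)
    return hits


# ---------------------------------------------------------------------------
# Truth table output


def write_truth_tables(truth: CommunityTruth, out_dir: str | Path) -> None:
    """Dump genomes plus TSV truth tables into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(truth.genomes, out / "genomes.fasta")
    write_fasta(
        [SequenceRecord(mid, seq) for mid, seq in sorted(truth.marker_seqs.items())],
        out / "marker_seqs.fasta",
    )
    with open(out / "markers.tsv", "w", encoding="utf-8") as fh:
        fh.write("#genome_id\tmarker_id\tstart\tend\n")
        for gid, mm in truth.markers.items():
            for marker_id, (s, e) in sorted(mm.items()):
                fh.write(f"{gid}\t{marker_id}\t{s}\t{e}\n")
    with open(out / "genes.tsv", "w", encoding="utf-8") as fh:
        fh.write("#genome_id\tstart\tend\tstrand\n")
        for g in truth.genes:
            fh.write(f"{g.genome_id}\t{g.start}\t{g.end}\t{g.strand}\n")
    if truth.abundances is not None:
        with open(out / "abundances.tsv", "w", encoding="utf-8") as fh:
            fh.write("#genome_id\t" + "\t".join(
                f"sample{s + 1}" for s in range(truth.abundances.shape[0])
            ) + "\n")
            for i, gid in enumerate(truth.genome_ids):
                vals = "\t".join(f"{truth.abundances[s, i]:.8f}"
                                 for s in range(truth.abundances.shape[0]))
                fh.write(f"{gid}\t{vals}\n")
    with open(out / "origins.tsv", "w", encoding="utf-8") as fh:
        fh.write("#read_id\tgenome_id\tstart\tstrand\n")
        for rid, origin in truth.read_origins.items():
            fh.write(f"{rid}\t{origin.genome_id}\t{origin.start}\t{origin.strand}\n")
    if truth.taxonomy is not None:
        truth.taxonomy.to_tsv(out / "taxonomy.tsv")
        with open(out / "genome_taxa.tsv", "w", encoding="utf-8") as fh:
            fh.write("#genome_id\ttaxon_id\n")
            for gid, t in truth.genome_taxon.items():
                fh.write(f"{gid}\t{t}\n")
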