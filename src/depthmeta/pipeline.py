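"""End-to-end orchestration: demo community generation and the
three-stage depth-stratified hybrid assembly pipeline with downstream
gene catalogs, taxonomy, binning, and reports.

Stage 1 maps all reads to a merged short-read assembly and divides
contigs and reads into depth phylotypes. Stage 2 assembles each
phylotype's short reads and merges the contigs with that phylotype's
long reads. Stage 3 pools all phylotypes, removes redundancy, and
polishes with the short reads. Short-only and plain-hybrid variants are
produced from the same inputs for comparison.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import (
    assembly_core,
    binning_qc,
    gene_catalog,
    mapping_depth,
    report_stats,
    sequence_io,
    synthetic_community,
    taxonomy_lca,
)
from .assembly_core import Contig
from .sequence_io import SequenceRecord

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "make_demo", "run_pipeline"]


@dataclass
class PipelineConfig:
    out_dir: str | Path
    seed: int
    # community panel
    n_genomes: int = 5
    genome_length_range: tuple[int, int] = (40_000, 80_000)
    gc_range: tuple[float, float] = (0.35, 0.65)
    n_markers: int = 6
    geometric_ratio: float = 4.0
    n_short_pairs: tuple[int, int] = (48_000, 24_000)
    n_long_reads: tuple[int, int] = (1_000, 500)
    long_read_mean_length: float = 7_604.0
    # QC (long reads)
    qc_min_length: int = 50
    qc_min_quality: float = 75.0
    # mapping / partitioning
    mapping_k: int = 21
    n_bins: int = 11
    boundary_scheme: str = "natural"  # geometric boundaries split tight depth strata
    # assembly
    assembly_k: int = 31
    min_kmer_count: int = 3  # demo depths are high enough; count 2 keeps error branches
    min_assembly_contig_length: int = 200  # drop micro-unitigs (repeat cores, tips)
    anchor_k: int = 17
    min_anchor_kmers: int = 10
    min_support: int = 2
    dedup_identity: float = 0.95
    dedup_containment: float = 0.95
    stitch_min_overlap: int = 1_000
    polish_rounds: int = 1
    # genes / catalogs
    min_gene_length: int = 100
    min_contig_length: int = 500
    cluster_identity: float = 0.95
    cluster_coverage: float = 0.90
    # taxonomy
    max_evalue: float = 1e-5
    score_margin: float = 0.90
    hit_decoy_rate: float = 0.0
    n_hits_per_gene: int = 5
    # binning
    bin_min_contig_length: int = 2_500
    min_completeness: float = 0.60
    max_contamination: float = 0.20
    lineage_agreement: float = 0.75
    reassemble_bins: bool = True
    reassemble_min_completeness: float = 0.90
    reassemble_max_contamination: float = 0.05
    # reporting
    mapping_ratio_sample: int = 8_000

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is required")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        for name, value, lo, hi in [
            ("cluster_identity", self.cluster_identity, 0, 1),
            ("cluster_coverage", self.cluster_coverage, 0, 1),
            ("score_margin", self.score_margin, 0, 1),
            ("min_completeness", self.min_completeness, 0, 1),
            ("max_contamination", self.max_contamination, 0, 10),
            ("lineage_agreement", self.lineage_agreement, 0, 1),
        ]:
            if not lo <= value <= hi:
                raise ValueError(f"{name}={value} outside [{lo}, {hi}]")


@dataclass
class DemoInputs:
    truth: synthetic_community.CommunityTruth
    short_reads: dict[str, list[SequenceRecord]]  # sample -> interleaved mates
    long_reads: dict[str, list[SequenceRecord]]


@dataclass
class VariantResult:
    label: str
    contigs: list[Contig]
    stats: report_stats.AssemblyStats
    catalog: gene_catalog.GeneCatalog | None = None
    catalog_stats: gene_catalog.CatalogStats | None = None


@dataclass
class PipelineResult:
    config: PipelineConfig
    demo: DemoInputs
    phylotypes: list
    contig_depth_map: dict[str, int]
    variants: dict[str, VariantResult]
    rgc: gene_catalog.GeneCatalog
    rgc_stats: gene_catalog.CatalogStats
    assignments: list[taxonomy_lca.GeneAssignment]
    bins: dict[str, list[binning_qc.GenomeBin]]
    kept_bins: dict[str, list[binning_qc.GenomeBin]]
    bin_tables: dict[str, tuple[list[dict], dict[str, float]]]
    rgc_mapping_ratio: float
    events: list[tuple[str, str, str]]
    out_dir: Path


def make_demo(config: PipelineConfig) -> DemoInputs:
    """The standard seeded community: 5 genomes, geometric abundances
    (r=4), a 3-kbp repeat shared by two genomes plus two smaller
    within-genome repeats, 6 markers per genome, two samples.

    Sample 2 carries the reversed abundance vector at half the
    sequencing effort, so combined depths stay distinct per genome while
    every genome is well covered in at least one sample.
    """
    cfg = config
    repeat_spec = [(3_000, 1, (0, 1))]  # shared between the two most abundant
    for gi in (2, 3):  # within-genome tandem-style repeats where genomes exist
        if gi < cfg.n_genomes:
            repeat_spec.append((1_500, 2, (gi,)))
    truth = synthetic_community.generate_genomes(
        n_genomes=cfg.n_genomes,
        length_range=cfg.genome_length_range,
        gc_range=cfg.gc_range,
        n_markers=cfg.n_markers,
        repeat_spec=repeat_spec,
        seed=cfg.seed,
    )
    base = synthetic_community.sample_abundances(
        cfg.n_genomes, profile=cfg.geometric_ratio, n_samples=1, seed=cfg.seed
    )[0]
    truth.abundances = np.vstack([base, base[::-1]])
    short: dict[str, list[SequenceRecord]] = {}
    long: dict[str, list[SequenceRecord]] = {}
    for s, sample in enumerate(("sample1", "sample2")):
        r1, r2 = synthetic_community.simulate_short_reads(
            truth,
            n_pairs=cfg.n_short_pairs[s],
            sample=s,
            seed=cfg.seed + 100 + s,
        )
        interleaved: list[SequenceRecord] = []
        for a, b in zip(r1, r2):
            interleaved.append(a)
            interleaved.append(b)
        short[sample] = interleaved
        long[sample] = synthetic_community.simulate_long_reads(
            truth,
            n_reads=cfg.n_long_reads[s],
            mean_length=cfg.long_read_mean_length,
            sample=s,
            seed=cfg.seed + 200 + s,
        )
    return DemoInputs(truth=truth, short_reads=short, long_reads=long)


def _to_records(contigs: Sequence[Contig]) -> list[SequenceRecord]:
    return [c.as_record() for c in contigs]


def _hybrid_stage(
    contigs: list[Contig],
    long_reads: list[SequenceRecord],
    cfg: PipelineConfig,
    id_prefix: str,
) -> list[Contig]:
    if not contigs or not long_reads:
        return contigs
    chains = assembly_core.anchor_contigs(
        contigs,
        long_reads,
        k_anchor=cfg.anchor_k,
        min_anchor_kmers=cfg.min_anchor_kmers,
    )
    return assembly_core.hybrid_merge(
        contigs, chains, long_reads, min_support=cfg.min_support, id_prefix=id_prefix
    )


def run_pipeline(config: PipelineConfig, demo: DemoInputs | None = None) -> PipelineResult:
    """Execute QC, mapping, depth partitioning, per-phylotype assembly,
    hybrid merging, pooling/dedup/polish, gene catalogs, LCA taxonomy,
    binning, and reports. Deterministic under a fixed config."""
    cfg = config
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    events: list[tuple[str, str, str]] = []

    def log_event(stage: str, key: str, value) -> None:
        events.append((stage, key, str(value)))

    try:
        result = _run(cfg, demo, out, events, log_event)
    except Exception as exc:  # noqa: BLE001 - report the failing stage
        stage = events[-1][0] if events else "setup"
        (out / "status.json").write_text(
            json.dumps({"status": "error", "stage": stage, "error": str(exc)})
        )
        raise
    (out / "status.json").write_text(json.dumps({"status": "ok"}))
    return result


def _run(cfg, demo, out, events, log_event) -> PipelineResult:
    # ---- inputs -----------------------------------------------------------
    if demo is None:
        demo = make_demo(cfg)
    truth = demo.truth
    all_short = [r for sample in sorted(demo.short_reads) for r in demo.short_reads[sample]]
    log_event("input", "n_short_reads", len(all_short))

    qc_long: dict[str, list[SequenceRecord]] = {}
    for sample in sorted(demo.long_reads):
        kept, removed = sequence_io.qc_filter_long_reads(
            demo.long_reads[sample],
            min_length=cfg.qc_min_length,
            min_quality=cfg.qc_min_quality,
        )
        qc_long[sample] = kept
        log_event("qc", f"{sample}_long_removed", removed)
    all_long = [r for sample in sorted(qc_long) for r in qc_long[sample]]
    log_event("qc", "n_long_reads_kept", len(all_long))

    inputs_dir = out / "inputs"
    synthetic_community.write_truth_tables(truth, inputs_dir)
    for sample in sorted(demo.short_reads):
        sequence_io.write_fastq(demo.short_reads[sample], inputs_dir / f"{sample}_short.fastq")
    for sample in sorted(demo.long_reads):
        sequence_io.write_fastq(demo.long_reads[sample], inputs_dir / f"{sample}_long.fastq")

    # ---- merged short-read assembly (baseline / short-only variant) -------
    log_event("stage0", "begin", "merged short-read assembly")
    base_contigs = assembly_core.assemble_short_reads(
        all_short, k=cfg.assembly_k, min_kmer_count=cfg.min_kmer_count, id_prefix="base"
    )
    base_contigs = [c for c in base_contigs if len(c) >= cfg.min_assembly_contig_length]
    log_event("stage0", "n_contigs", len(base_contigs))
    if not base_contigs:
        raise RuntimeError("merged assembly produced no contigs")

    # ---- stage 1: map and partition by depth ------------------------------
    log_event("stage1", "begin", "mapping and depth partitioning")
    index = mapping_depth.KmerIndex(_to_records(base_contigs), k=cfg.mapping_k)
    short_alns: dict[str, list] = {}
    for sample in sorted(demo.short_reads):
        alns = []
        for read in demo.short_reads[sample]:
            aln = mapping_depth.map_short_read(read, index)
            if aln is not None:
                alns.append(aln)
        short_alns[sample] = alns
        log_event("stage1", f"{sample}_short_mapped", len(alns))
    long_alns: dict[str, list] = {}
    for sample in sorted(qc_long):
        alns = []
        for read in qc_long[sample]:
            aln = mapping_depth.map_long_read(read, index)
            if aln is not None:
                alns.append(aln)
        long_alns[sample] = alns
        log_event("stage1", f"{sample}_long_mapped", len(alns))

    profiles = mapping_depth.compute_depths(short_alns, _to_records(base_contigs))
    phylotypes, contig_map = mapping_depth.partition_by_depth(
        profiles, n_bins=cfg.n_bins, scheme=cfg.boundary_scheme
    )
    all_alns = [a for alns in short_alns.values() for a in alns] + [
        a for alns in long_alns.values() for a in alns
    ]
    long_ids = {r.id for r in all_long}
    phylotypes, unmapped_pool = mapping_depth.assign_reads(
        all_alns,
        contig_map,
        phylotypes,
        [r.id for r in all_short] + sorted(long_ids),
        long_read_ids=long_ids,
    )
    n_assigned = sum(
        len(p.member_short_reads) + len(p.member_long_reads) for p in phylotypes
    )
    log_event("stage1", "n_reads_assigned", n_assigned)
    log_event(
        "stage1",
        "n_reads_unmapped",
        len(unmapped_pool.member_short_reads) + len(unmapped_pool.member_long_reads),
    )
    with open(out / "stage1_depth.tsv", "w", encoding="utf-8") as fh:
        fh.write("#contig_id\tcombined_depth\tphylotype\n")
        for cid in sorted(profiles):
            fh.write(
                f"{cid}\t{profiles[cid].combined_depth:.4f}\t{contig_map.get(cid, 'UNBINNED')}\n"
            )

    # ---- stage 2: per-phylotype assembly + hybrid merge -------------------
    log_event("stage2", "begin", "per-phylotype assembly and hybrid merge")
    short_by_id = {r.id: r for r in all_short}
    long_by_id = {r.id: r for r in all_long}
    stage2_contigs: list[Contig] = []
    for phylo in phylotypes:
        s_reads = [short_by_id[rid] for rid in phylo.member_short_reads]
        l_reads = [long_by_id[rid] for rid in phylo.member_long_reads]
        if not s_reads:
            continue
        contigs = assembly_core.assemble_short_reads(
            s_reads,
            k=cfg.assembly_k,
            min_kmer_count=cfg.min_kmer_count,
            id_prefix=f"p{phylo.label}",
        )
        contigs = [c for c in contigs if len(c) >= cfg.min_assembly_contig_length]
        if contigs and l_reads:
            contigs = _hybrid_stage(contigs, l_reads, cfg, id_prefix=f"p{phylo.label}m")
        for c in contigs:
            c.phylotype = phylo.label
        log_event("stage2", f"phylotype_{phylo.label}_contigs", len(contigs))
        stage2_contigs.extend(contigs)
    log_event("stage2", "n_contigs_pooled", len(stage2_contigs))

    # ---- stage 3: pool, dedup, polish -------------------------------------
    log_event("stage3", "begin", "pooling, redundancy removal, polishing")
    dedup = assembly_core.remove_redundancy(
        stage2_contigs,
        min_identity=cfg.dedup_identity,
        min_containment=cfg.dedup_containment,
    )
    log_event("stage3", "n_contigs_after_dedup", len(dedup))
    dedup = assembly_core.merge_overlaps(
        dedup, min_overlap=cfg.stitch_min_overlap, min_identity=cfg.dedup_identity
    )
    log_event("stage3", "n_contigs_after_stitch", len(dedup))
    depth_contigs, corrections = assembly_core.polish(
        dedup, all_short, rounds=cfg.polish_rounds
    )
    log_event("stage3", "n_corrections", sum(corrections.values()))

    # ---- comparison variants ---------------------------------------------
    log_event("variants", "begin", "short-only and plain-hybrid variants")
    hybrid_contigs = _hybrid_stage(list(base_contigs), all_long, cfg, id_prefix="hyb")
    hybrid_contigs = assembly_core.remove_redundancy(hybrid_contigs)
    hybrid_contigs, _ = assembly_core.polish(
        hybrid_contigs, all_short, rounds=cfg.polish_rounds
    )

    ratio_sample = all_short[: cfg.mapping_ratio_sample]
    variants: dict[str, VariantResult] = {}
    for label, contigs in (
        ("short_only", list(base_contigs)),
        ("hybrid", hybrid_contigs),
        ("depth_hybrid", depth_contigs),
    ):
        ratio = report_stats.mapping_ratio(ratio_sample, contigs, mapping_k=cfg.mapping_k)
        stats = report_stats.assembly_stats(
            contigs, label=label, mapping_ratio_value=ratio
        )
        variants[label] = VariantResult(label=label, contigs=contigs, stats=stats)
        sequence_io.write_fasta(_to_records(contigs), out / f"contigs_{label}.fasta")
        log_event("variants", f"{label}_n50", stats.n50)

    # ---- gene catalogs ----------------------------------------------------
    log_event("genes", "begin", "ORF prediction and catalog clustering")
    catalog_labels = {"short_only": "HGC", "hybrid": "POGC", "depth_hybrid": "PDGC"}
    for label, variant in variants.items():
        genes = gene_catalog.find_orfs(
            variant.contigs,
            min_gene_length=cfg.min_gene_length,
            min_contig_length=cfg.min_contig_length,
            source_catalog=catalog_labels[label],
        )
        if not genes:
            raise RuntimeError(f"no genes predicted for variant {label}")
        variant.catalog = gene_catalog.cluster_nr(
            genes,
            min_identity=cfg.cluster_identity,
            min_coverage=cfg.cluster_coverage,
            label=catalog_labels[label],
        )
        variant.catalog_stats = gene_catalog.catalog_stats(variant.catalog)
        log_event("genes", f"{label}_n_orfs", variant.catalog_stats.n_orfs)
    rgc = gene_catalog.merge_catalogs(
        [variants[v].catalog for v in ("short_only", "hybrid", "depth_hybrid")],
        min_identity=cfg.cluster_identity,
        min_coverage=cfg.cluster_coverage,
        label="RGC",
    )
    rgc_stats = gene_catalog.catalog_stats(rgc)
    log_event("genes", "rgc_n_orfs", rgc_stats.n_orfs)
    with open(out / "catalog_stats.tsv", "w", encoding="utf-8") as fh:
        fh.write("#catalog\tn_orfs\ttotal_length\taverage_length\tpct_complete\n")
        for st in [rgc_stats] + [v.catalog_stats for v in variants.values()]:
            fh.write(
                f"{st.label}\t{st.n_orfs}\t{st.total_length}\t"
                f"{st.average_length}\t{st.pct_complete}\n"
            )

    rgc_ratio, rgc_unmapped = gene_catalog.map_reads_to_catalog(
        ratio_sample, rgc, mapping_k=cfg.mapping_k
    )
    log_event("genes", "rgc_mapping_ratio", f"{rgc_ratio:.4f}")
    log_event("genes", "rgc_unmapped_orfs", len(rgc_unmapped))

    # ---- taxonomy ---------------------------------------------------------
    log_event("taxonomy", "begin", "hit simulation and LCA assignment")
    reps = rgc.representatives
    hits = synthetic_community.generate_hit_table(
        truth,
        reps,
        n_hits_per_gene=cfg.n_hits_per_gene,
        decoy_rate=cfg.hit_decoy_rate,
        seed=cfg.seed + 300,
    )
    by_gene: dict[str, list] = {}
    for h in hits:
        by_gene.setdefault(h.gene_id, []).append(h)
    assignments = []
    for rep in reps:
        gene_hits = by_gene.get(rep.gene_id, [])
        if gene_hits:
            assignments.append(
                taxonomy_lca.assign_gene(
                    gene_hits,
                    truth.taxonomy,
                    max_evalue=cfg.max_evalue,
                    score_margin=cfg.score_margin,
                )
            )
        else:
            assignments.append(
                taxonomy_lca.GeneAssignment(rep.gene_id, taxonomy_lca.UNCLASSIFIED, None, 0)
            )
    n_classified = sum(a.classified for a in assignments)
    log_event("taxonomy", "n_classified", n_classified)
    with open(out / "taxonomy_summary.tsv", "w", encoding="utf-8") as fh:
        fh.write("#rank\tname\tcount\tpercent\n")
        for rank in ("superkingdom", "phylum", "genus", "species"):
            for name, count, pct in taxonomy_lca.rank_summary(
                assignments, truth.taxonomy, rank
            ):
                fh.write(f"{rank}\t{name}\t{count}\t{pct}\n")

    # ---- binning ----------------------------------------------------------
    log_event("binning", "begin", "TNF+depth binning and marker QC")
    assignment_by_gene = {a.gene_id: a for a in assignments}
    bins: dict[str, list[binning_qc.GenomeBin]] = {}
    kept: dict[str, list[binning_qc.GenomeBin]] = {}
    tables: dict[str, tuple[list[dict], dict[str, float]]] = {}
    for label in ("short_only", "depth_hybrid"):
        contigs = variants[label].contigs
        records = _to_records(contigs)
        bin_index = mapping_depth.KmerIndex(records, k=cfg.mapping_k)
        alns_by_sample: dict[str, list] = {}
        for sample in sorted(demo.short_reads):
            alns = []
            for read in demo.short_reads[sample]:
                aln = mapping_depth.map_short_read(read, bin_index)
                if aln is not None:
                    alns.append(aln)
            alns_by_sample[sample] = alns
        bin_profiles = mapping_depth.compute_depths(alns_by_sample, records)
        try:
            label_bins = binning_qc.bin_contigs(
                contigs,
                bin_profiles,
                min_contig_length=cfg.bin_min_contig_length,
                seed=cfg.seed,
            )
        except ValueError as exc:
            log_event("binning", f"{label}_skipped", str(exc))
            continue
        seqs = {c.id: c.sequence for c in contigs}
        for b in label_bins:
            binning_qc.evaluate_bin(b, seqs, truth.marker_seqs)
        # lineage from the classified genes on each bin's contigs
        gene_by_contig: dict[str, list[int]] = {}
        for rep in reps:
            a = assignment_by_gene[rep.gene_id]
            if a.classified:
                gene_by_contig.setdefault(rep.contig_id, []).append(a.taxon_id)
        for b in label_bins:
            taxa = [t for cid in b.contig_ids for t in gene_by_contig.get(cid, [])]
            if taxa:
                b.lineage = binning_qc.majority_lineage(
                    taxa, truth.taxonomy, agreement=cfg.lineage_agreement
                )
        if cfg.reassemble_bins and label == "depth_hybrid":
            # the paper's loop: re-assemble the reads of low-quality bins
            all_bin_alns = [a for alns in alns_by_sample.values() for a in alns]
            refreshed = []
            for b in label_bins:
                needs_work = (
                    b.contamination > cfg.reassemble_max_contamination
                    or b.completeness < cfg.reassemble_min_completeness
                )
                if not needs_work:
                    refreshed.append(b)
                    continue
                out_bin = binning_qc.reassemble_bin(
                    b, seqs, all_short, all_long, all_bin_alns, truth.marker_seqs,
                    assembly_k=cfg.assembly_k, anchor_k=cfg.anchor_k,
                    min_kmer_count=cfg.min_kmer_count,
                    min_contig_length=cfg.min_assembly_contig_length,
                )
                if out_bin.provenance == "reassembled":
                    new_contigs = out_bin.reassembled_contigs
                    for c in new_contigs:
                        seqs[c.id] = c.sequence
                    log_event("binning", f"{label}_{b.bin_id}_reassembled", "improved")
                else:
                    log_event("binning", f"{label}_{b.bin_id}_reassembled", "kept")
                refreshed.append(out_bin)
            label_bins = refreshed
        bins[label] = label_bins
        kept[label] = binning_qc.filter_bins(
            label_bins,
            min_completeness=cfg.min_completeness,
            max_contamination=cfg.max_contamination,
        )
        tables[label] = binning_qc.bin_metrics(label_bins, seqs)
        log_event("binning", f"{label}_n_bins", len(label_bins))
        log_event("binning", f"{label}_n_kept", len(kept[label]))
        with open(out / f"bins_{label}.tsv", "w", encoding="utf-8") as fh:
            fh.write("#bin_id\tcontig_id\tcompleteness\tcontamination\tlineage\n")
            for b in label_bins:
                for cid in b.contig_ids:
                    fh.write(
                        f"{b.bin_id}\t{cid}\t{b.completeness:.4f}\t"
                        f"{b.contamination:.4f}\t{b.lineage}\n"
                    )

    # ---- reports ----------------------------------------------------------
    log_event("report", "begin", "comparison tables")
    comparison = report_stats.compare_runs(
        [variants[v].stats for v in ("short_only", "hybrid", "depth_hybrid")]
    )
    report_stats.write_comparison_tsv(comparison, out / "comparison.tsv")
    with open(out / "log.tsv", "w", encoding="utf-8") as fh:
        fh.write("#stage\tkey\tvalue\n")
        for stage, key, value in events:
            fh.write(f"{stage}\t{key}\t{value}\n")

    return PipelineResult(
        config=cfg,
        demo=demo,
        phylotypes=phylotypes,
        contig_depth_map=contig_map,
        variants=variants,
        rgc=rgc,
        rgc_stats=rgc_stats,
        assignments=assignments,
        bins=bins,
        kept_bins=kept,
        bin_tables=tables,
        rgc_mapping_ratio=rgc_ratio,
        events=events,
        out_dir=out,
    )
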