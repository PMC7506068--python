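# depthmeta

Depth-stratified hybrid metagenome assembly at desk scale: a fully
self-contained pipeline that partitions reads into coverage-depth
phylotypes, assembles each stratum from short reads, merges the contigs
with long reads, builds non-redundant gene catalogs, assigns taxonomy by
bitscore-margin LCA, and bins contigs by tetranucleotide frequency plus
per-sample depth with marker-based completeness/contamination QC and a
bin re-assembly loop.

Everything runs on synthetic communities with full ground truth: the
simulator plants single-copy markers, shared repeats, and protein-coding
genes in random genomes, then generates HiSeq-like 150-bp paired reads
(250-bp inserts) and PacBio-like long reads (log-normal lengths with a
7.6-kbp mean, ~15% indel-dominated error, read-level quality scores).
No external assembler, mapper, or database is required.

## Layout

| module | what it does |
| --- | --- |
| `sequence_io` | FASTA/FASTQ/SAM-subset readers and writers, long-read QC filter |
| `synthetic_community` | ground-truthed genome/read/hit-table simulator |
| `mapping_depth` | built-in k-mer mapper, per-contig depth, depth-phylotype partitioning |
| `assembly_core` | de Bruijn unitig assembler, long-read anchoring + hybrid merge, overlap stitching, redundancy removal, pileup polishing |
| `gene_catalog` | six-frame ORF scan, greedy 95%/90% clustering, catalog merging and statistics |
| `taxonomy_lca` | taxonomy trees, e-value/bitscore-filtered LCA assignment, rank summaries |
| `binning_qc` | TNF + log-depth binning, marker census, bin filters, lineage calls, bin re-assembly |
| `report_stats` | N50/Nx, cumulative length curves, mapping ratios, run comparison tables |
| `pipeline` / `cli` | end-to-end orchestration and the `depthmeta` command |

## CLI

Each stage is a subcommand (`depthmeta --help` lists them all):

```bash
depthmeta simulate --seed 42 --out-dir demo_inputs        # mock community + truth tables
depthmeta qc demo_inputs/sample1_long.fastq --out kept.fastq
depthmeta assemble demo_inputs/sample1_short.fastq --out contigs.fasta
depthmeta map reads.fastq contigs.fasta --out alns.sam
depthmeta partition contigs.fasta --alignments alns.sam --n-bins 11 --out-dir part
depthmeta hybrid contigs.fasta long.fastq --out merged.fasta
depthmeta dedup merged.fasta --out nr.fasta
depthmeta polish nr.fasta reads.fastq --out polished.fasta
depthmeta genes polished.fasta --out genes.fasta
depthmeta catalog genes.fasta --out-prefix catalog
depthmeta taxonomy hits.tsv taxonomy.tsv --out assignments.tsv
depthmeta stats polished.fasta
depthmeta run --seed 42 --out-dir run42                   # full pipeline on the demo panel
```

`depthmeta run` executes the three-stage procedure (map → partition into
11 depth phylotypes → per-phylotype assembly → hybrid merge → pool,
de-duplicate, polish), then gene catalogs (per-variant plus a merged
reference catalog), LCA taxonomy, and binning with marker QC, writing
contigs, TSV reports, and a structured event log into the run directory.
Reruns with the same config are bit-identical.

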