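"""Assembly contiguity statistics and run comparison tables."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "AssemblyStats",
    "n50",
    "nx",
    "cumulative_curve",
    "mapping_ratio",
    "assembly_stats",
    "compare_runs",
]

DEFAULT_THRESHOLDS = (1_000, 10_000, 100_000, 1_000_000)


def nx(lengths: Sequence[int], x: float) -> int:
    """Smallest length L such that contigs of length >= L hold at least
    x% of the total assembly bases."""
    if not lengths:
        raise ValueError("empty length set")
    if not 0 < x <= 100:
        raise ValueError("x must lie in (0, 100]")
    ordered = sorted(lengths, reverse=True)
    target = sum(ordered) * x / 100.0
    acc = 0
    for length in ordered:
        acc += length
        if acc >= target:
            return length
    return ordered[-1]


def n50(lengths: Sequence[int]) -> int:
    return nx(lengths, 50)


def cumulative_curve(
    lengths: Sequence[int], thresholds: Sequence[int]
) -> dict[int, int]:
    """threshold -> total bases in contigs of length >= threshold."""
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    return {t: sum(l for l in lengths if l >= t) for t in thresholds}


@dataclass
class AssemblyStats:
    label: str
    n_contigs: int
    total_bp: int
    max_contig: int
    n50: int
    nx_curve: dict[int, int] = field(default_factory=dict)  # x -> Nx
    counts_above: dict[int, int] = field(default_factory=dict)
    cumulative_bp: dict[int, int] = field(default_factory=dict)
    mapping_ratio: float | None = None

    def as_flat_dict(self) -> dict[str, float]:
        out: dict[str, float] = {
            "n_contigs": self.n_contigs,
            "total_bp": self.total_bp,
            "max_contig": self.max_contig,
            "n50": self.n50,
        }
        for x, v in self.nx_curve.items():
            out[f"n{x}"] = v
        for t, v in self.counts_above.items():
            out[f"count_ge_{t}"] = v
        for t, v in self.cumulative_bp.items():
            out[f"bp_ge_{t}"] = v
        if self.mapping_ratio is not None:
            out["mapping_ratio"] = self.mapping_ratio
        return out


def assembly_stats(
    contigs: Sequence,
    label: str = "assembly",
    thresholds: Sequence[int] = DEFAULT_THRESHOLDS,
    mapping_ratio_value: float | None = None,
) -> AssemblyStats:
    """Contiguity summary of a contig set (Contig or SequenceRecord)."""
    lengths = [len(c.sequence) for c in contigs]
    if not lengths:
        raise ValueError("no contigs")
    return AssemblyStats(
        label=label,
        n_contigs=len(lengths),
        total_bp=sum(lengths),
        max_contig=max(lengths),
        n50=n50(lengths),
        nx_curve={x: nx(lengths, x) for x in range(10, 100, 10)},
        counts_above={t: sum(1 for l in lengths if l >= t) for t in thresholds},
        cumulative_bp=cumulative_curve(lengths, list(thresholds)),
        mapping_ratio=mapping_ratio_value,
    )


def mapping_ratio(
    reads: Sequence,
    contigs: Sequence,
    mapping_k: int = 21,
    max_mismatch_frac: float = 0.05,
) -> float:
    """Fraction of reads with a primary placement on the contig set."""
    from .mapping_depth import KmerIndex, map_short_read

    if not reads:
        return 0.0
    records = [c if hasattr(c, "quality") else c.as_record() for c in contigs]
    index = KmerIndex(records, k=mapping_k)
    n_mapped = sum(
        1
        for r in reads
        if map_short_read(r, index, max_mismatch_frac=max_mismatch_frac) is not None
    )
    return n_mapped / len(reads)


def compare_runs(
    stats_records: Sequence[AssemblyStats],
    labels: Sequence[str] | None = None,
) -> list[dict]:
    """Metric table across runs with differences and ratios against the
    first (baseline) run. All runs must expose the same metric set."""
    if len(stats_records) < 2:
        raise ValueError("need at least two runs to compare")
    labels = list(labels) if labels is not None else [s.label for s in stats_records]
    flats = [s.as_flat_dict() for s in stats_records]
    metric_sets = [set(f) for f in flats]
    if any(m != metric_sets[0] for m in metric_sets[1:]):
        raise ValueError("runs expose mismatched metric sets")
    baseline = flats[0]
    rows = []
    for metric in sorted(baseline):
        row: dict = {"metric": metric}
        for label, flat in zip(labels, flats):
            row[label] = flat[metric]
            row[f"{label}_diff"] = flat[metric] - baseline[metric]
            row[f"{label}_ratio"] = (
                flat[metric] / baseline[metric] if baseline[metric] else float("nan")
            )
        rows.append(row)
    return rows


def write_comparison_tsv(rows: Sequence[Mapping], path) -> None:
    if not rows:
        raise ValueError("empty comparison")
    cols = list(rows[0])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
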