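"""End-to-end sample analysis: prep -> classify -> mine unmapped -> count.

Convenience composition of the pipeline stages for one sample: stringent
trimming and filtering, mapped/unmapped partitioning against a reference
k-mer index, pattern scanning of the unmapped set, and assembly of the
per-sample :class:`~polyscan.report.CountsSummary`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .classify import (
    ClassifiedRead,
    ReferenceIndex,
    build_index,
    classify_reads,
    extract_unmapped,
    unmapped_fraction,
)
from .io import Read
from .prep import PipelineParams, TrimReport, prep_pipeline
from .report import CountsSummary
from .scan import PatternCounts, count_reads_with_patterns

__all__ = ["SampleResult", "analyze_sample"]


@dataclass
class SampleResult:
    """Everything the pipeline computes for one sample."""

    summary: CountsSummary
    unmapped_fraction: float
    filtered_reads: list[Read]
    unmapped_reads: list[Read]
    classified: list[ClassifiedRead]
    trim_reports: list[TrimReport]
    pattern_counts: PatternCounts


def analyze_sample(
    reads: Sequence[Read],
    reference: str | ReferenceIndex | Sequence[tuple[str, str]],
    params: PipelineParams | None = None,
    sample_id: str = "sample",
) -> SampleResult:
    """Run the full unmapped-read mining pipeline on one read set.

    ``reference`` may be a bare sequence string, ``(name, sequence)`` pairs,
    or a prebuilt :class:`ReferenceIndex`.
    """
    if params is None:
        params = PipelineParams()
    if isinstance(reference, ReferenceIndex):
        index = reference
    elif isinstance(reference, str):
        index = build_index([("reference", reference)], k=params.kmer_k)
    else:
        index = build_index(list(reference), k=params.kmer_k)

    filtered, reports, total = prep_pipeline(reads, params, mode="unmapped_analysis")
    classified = classify_reads(filtered, index, tau=params.mapped_kmer_fraction)
    unmapped = list(extract_unmapped(filtered, classified))
    counts = count_reads_with_patterns(unmapped, params)
    summary = CountsSummary(
        sample_id=sample_id,
        total_filtered_reads=total,
        unmapped_reads=len(unmapped),
        class_counts=dict(counts.counts),
    )
    frac = unmapped_fraction(classified) if classified else 0.0
    return SampleResult(
        summary=summary,
        unmapped_fraction=frac,
        filtered_reads=filtered,
        unmapped_reads=unmapped,
        classified=classified,
        trim_reports=reports,
        pattern_counts=counts,
    )
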