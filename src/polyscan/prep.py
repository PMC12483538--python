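"""Stringent read trimming and filtering.

Front-end applied before unmapped-read mining: 3' quality trimming at Phred
cutoff q, error-tolerant 3' adapter removal, and a minimum-length filter, with
the defaults the analysis uses throughout (e=0.2, O=10, q=30, minimum length
45 nt for unmapped-read analysis and 15 nt for the plain mapping pass).

Quality trimming is the classic partial-sum suffix cut: remove the 3' suffix
starting at the index i* maximising the sum of (q - quality_j) over j >= i*,
keeping more bases on ties. Adapter removal finds the leftmost position where
the read matches a prefix of the adapter — either a full internal adapter
occurrence (everything from the adapter onward is removed, which is what
tiling the adapter across offsets achieves) or a partial adapter prefix
abutting the 3' end with matched length >= O — allowing floor(e * matched
length) Hamming mismatches; N in the read never matches an adapter base.

The pipeline repeats quality and adapter trimming until neither fires: a cut
can expose a new qualifying 3' suffix, and the contract is that no retained
read carries any residual adapter signal, so a single pass is not enough.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .io import Read, encode

__all__ = [
    "PipelineParams",
    "TrimReport",
    "quality_trim",
    "adapter_trim",
    "length_filter",
    "prep_pipeline",
]

DEFAULT_ADAPTER = "AGATCGGAAGAGC"  # Illumina 3' adapter stem


@dataclass
class PipelineParams:
    """All thresholds used by the trimming, classification and scanning stages.

    Attributes
    ----------
    max_error_rate:
        Adapter-match error rate e; allowed mismatches are floor(e * matched
        length).
    min_overlap:
        Minimum adapter overlap O at the read 3' end.
    quality_cutoff:
        Phred cutoff q for 3' quality trimming.
    min_length_unmapped, min_length_mapping:
        Post-trim length minima for the stringent (unmapped-analysis) and the
        plain mapping pass respectively.
    homopolymer_min_len, max_mismatch, chimera_half_len:
        Scanner thresholds: window length L, mismatch allowance m, and the
        half-length of the dA/dT junction window.
    kmer_k, mapped_kmer_fraction:
        k-mer classifier settings (k and the mapped-call threshold tau).
    """

    max_error_rate: float = 0.2
    min_overlap: int = 10
    quality_cutoff: int = 30
    min_length_unmapped: int = 45
    min_length_mapping: int = 15
    adapter_sequence: str = DEFAULT_ADAPTER
    homopolymer_min_len: int = 25
    max_mismatch: int = 1
    chimera_half_len: int = 10
    kmer_k: int = 31
    mapped_kmer_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.max_error_rate < 0.5:
            raise ValueError("max_error_rate must lie in [0, 0.5)")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not self.homopolymer_min_len > self.max_mismatch >= 0:
            raise ValueError("need homopolymer_min_len > max_mismatch >= 0")
        if self.chimera_half_len < 1:
            raise ValueError("chimera_half_len must be >= 1")
        if not 0 < self.mapped_kmer_fraction <= 1:
            raise ValueError("mapped_kmer_fraction must lie in (0, 1]")
        if self.kmer_k % 2 == 0:
            raise ValueError("kmer_k must be odd")


@dataclass
class TrimReport:
    """Per-read trimming audit row."""

    read_id: str
    original_length: int
    quality_cut: int
    adapter_cut_position: Optional[int]
    final_length: int
    passed_length_filter: bool


def quality_trim(read: Read, q: int) -> tuple[Read, int]:
    """Cut the 3' suffix maximising the partial sum of (q - quality).

    Returns the trimmed read and the number of bases removed. Ties keep more
    bases; an all-low-quality read may become empty.
    """
    n = len(read)
    if n == 0:
        return read, 0
    diffs = (q - read.qualities).astype(np.int64)
    # suffix_sum[i] = sum(diffs[i:]); suffix_sum[n] = 0 (no cut)
    suffix_sum = np.zeros(n + 1, dtype=np.int64)
    suffix_sum[:n] = np.cumsum(diffs[::-1])[::-1]
    best = int(np.flatnonzero(suffix_sum == suffix_sum.max()).max())
    if best == n:
        return read, 0
    return Read(read.read_id, read.sequence[:best], read.qualities[:best]), n - best


def _adapter_codes(adapter: str) -> np.ndarray:
    codes = encode(adapter)
    if (codes > 3).any():
        raise ValueError("adapter must contain only A/C/G/T")
    return codes


def adapter_trim(
    read: Read,
    adapter: str,
    e: float = 0.2,
    O: int = 10,
) -> tuple[Read, Optional[int]]:
    """Remove the leftmost internal or 3'-suffix adapter occurrence.

    A full internal adapter match (anywhere in the read) removes the adapter
    and everything 3' of it; a partial match must abut the 3' end with matched
    length >= O. Mismatch budget is floor(e * matched length); N counts as a
    mismatch. Returns the (possibly unchanged) read and the 0-based cut
    position, or None when no qualifying match exists.
    """
    acodes = _adapter_codes(adapter)
    alen = len(acodes)
    if alen < O:
        raise ValueError("adapter shorter than min_overlap")
    n = len(read)
    if n == 0:
        return read, None
    codes = read.codes
    candidates: list[int] = []
    if n >= alen:
        windows = np.lib.stride_tricks.sliding_window_view(codes, alen)
        mism = (windows != acodes).sum(axis=1)
        allowed = int(e * alen)
        full = np.flatnonzero(mism <= allowed)
        if full.size:
            candidates.append(int(full[0]))
    # partial adapter prefix abutting the 3' end, matched length in [O, alen)
    for ell in range(O, min(alen, n + 1)):
        if ell == alen and n >= alen:
            continue  # covered by the full-match scan
        p = n - ell
        mism = int((codes[p:] != acodes[:ell]).sum())
        if mism <= int(e * ell):
            candidates.append(p)
    if not candidates:
        return read, None
    p = min(candidates)
    return Read(read.read_id, read.sequence[:p], read.qualities[:p]), p


def length_filter(
    reads: Sequence[Read], min_len: int
) -> tuple[list[Read], int]:
    """Retain reads of final length >= ``min_len``; order preserved."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    passing = [r for r in reads if len(r) >= min_len]
    return passing, len(reads) - len(passing)


def prep_pipeline(
    reads: Iterable[Read],
    params: PipelineParams | None = None,
    mode: str = "unmapped_analysis",
) -> tuple[list[Read], list[TrimReport], int]:
    """Quality-trim, adapter-trim and length-filter a read stream.

    Trimming iterates to a fixpoint, so the output is idempotent under
    re-application and carries no residual adapter suffix. Returns the
    retained reads, one :class:`TrimReport` per input read, and
    ``total_filtered_reads`` — the retained-read count used downstream as the
    per-million normalisation denominator.
    """
    if params is None:
        params = PipelineParams()
    if mode not in ("mapping", "unmapped_analysis"):
        raise ValueError(f"unknown mode {mode!r}")
    min_len = (
        params.min_length_unmapped
        if mode == "unmapped_analysis"
        else params.min_length_mapping
    )
    retained: list[Read] = []
    reports: list[TrimReport] = []
    for read in reads:
        original = len(read)
        quality_cut = 0
        adapter_pos: Optional[int] = None
        current = read
        while True:
            current, qc = quality_trim(current, params.quality_cutoff)
            quality_cut += qc
            current, ap = adapter_trim(
                current,
                params.adapter_sequence,
                params.max_error_rate,
                params.min_overlap,
            )
            if ap is not None and adapter_pos is None:
                adapter_pos = ap
            if qc == 0 and ap is None:
                break
        passed = len(current) >= min_len
        reports.append(
            TrimReport(
                read.read_id, original, quality_cut, adapter_pos, len(current), passed
            )
        )
        if passed:
            retained.append(current)
    return retained, reports, len(retained)
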