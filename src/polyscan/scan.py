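"""Mismatch-tolerant homopolymer and chimeric-junction scanning.

The discovery statistic: a read "contains" a homopolymer when some window of
``L`` consecutive positions matches a single target base at all but at most
``m`` positions (default L=25, m=1), and contains a chimeric junction when a
window of ``2*half_len`` positions is poly-dA in its first half and poly-dT in
its second (orientation AT) or the inverse (TA), again within ``m`` mismatches.
N never matches any target and therefore always counts as a mismatch.

Window bookkeeping: all qualifying windows are found with a sliding mismatch
counter; overlapping qualifying windows of the same class are merged into
maximal intervals, each reported with the minimal mismatch count among its
constituent windows. Presence (the per-read count statistic) depends only on
whether at least one window qualifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from .io import N, Read, encode

if TYPE_CHECKING:  # pragma: no cover
    from .prep import PipelineParams

__all__ = [
    "PatternHit",
    "RunAnnotation",
    "PatternCounts",
    "PATTERN_CLASSES",
    "scan_homopolymer",
    "scan_chimera",
    "annotate_runs",
    "count_reads_with_patterns",
]

HOMOPOLYMER_CLASSES = (
    "homopolymer_A",
    "homopolymer_C",
    "homopolymer_G",
    "homopolymer_T",
)
CHIMERA_CLASSES = ("chimera_AT", "chimera_TA")
PATTERN_CLASSES = HOMOPOLYMER_CLASSES + CHIMERA_CLASSES

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class PatternHit:
    """A located homopolymer or chimera window (merged maximal interval)."""

    read_id: str
    pattern: str
    start: int
    length: int
    mismatches: int


@dataclass(frozen=True)
class RunAnnotation:
    """A maximal exact single-base run (0-based half-open coordinates)."""

    read_id: str
    base: str
    start: int
    length: int


@dataclass
class PatternCounts:
    """Per-class pattern-containing read counts for one read set.

    A read contributes at most once per class however many windows it holds;
    a read may contribute to several classes (classes are not exclusive), and
    ``reads_in_multiple_classes`` reports how many did.
    """

    total_reads: int = 0
    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in PATTERN_CLASSES}
    )
    reads_in_multiple_classes: int = 0


def _window_mismatches(mismatch: np.ndarray, width: int) -> np.ndarray:
    """Per-window mismatch totals for all width-sized windows (1-D int array in)."""
    cs = np.concatenate(([0], np.cumsum(mismatch, dtype=np.int64)))
    return cs[width:] - cs[:-width]


def _merge_windows(
    starts: np.ndarray, mismatches: np.ndarray, width: int
) -> list[tuple[int, int, int]]:
    """Merge overlapping qualifying windows into maximal (start, length, min_mm)."""
    merged: list[tuple[int, int, int]] = []
    if starts.size == 0:
        return merged
    lo = int(starts[0])
    hi = lo + width
    mm = int(mismatches[0])
    for s, e in zip(starts[1:], mismatches[1:]):
        s = int(s)
        if s < hi:  # overlaps the current interval
            hi = s + width
            mm = min(mm, int(e))
        else:
            merged.append((lo, hi - lo, mm))
            lo, hi, mm = s, s + width, int(e)
    merged.append((lo, hi - lo, mm))
    return merged


def scan_homopolymer(
    sequence: str,
    base: str,
    L: int = 25,
    m: int = 1,
    read_id: str = "",
) -> tuple[bool, list[PatternHit]]:
    """Find length-``L`` windows matching ``base`` with at most ``m`` mismatches.

    Returns ``(presence, hits)`` where hits are merged maximal intervals. A
    sequence shorter than ``L`` yields ``(False, [])``.
    """
    if base not in _BASE_CODE:
        raise ValueError(f"base must be one of A/C/G/T, got {base!r}")
    if not (L > m >= 0):
        raise ValueError(f"need L > m >= 0, got L={L}, m={m}")
    if len(sequence) < L:
        return False, []
    codes = encode(sequence)
    mism = (codes != _BASE_CODE[base]).astype(np.int64)
    win = _window_mismatches(mism, L)
    starts = np.flatnonzero(win <= m)
    hits = [
        PatternHit(read_id, f"homopolymer_{base}", s, ln, mm)
        for s, ln, mm in _merge_windows(starts, win[starts], L)
    ]
    return bool(hits), hits


def scan_chimera(
    sequence: str,
    half_len: int = 10,
    m: int = 1,
    read_id: str = "",
) -> tuple[list[PatternHit], list[PatternHit]]:
    """Find dA-block/dT-block junction windows in both orientations.

    A window of ``2*half_len`` starting at ``p`` is an AT hit when the number
    of non-A positions in its first half plus non-T positions in its second
    half is at most ``m``; TA symmetrically. Returns merged maximal intervals
    per orientation.
    """
    if half_len < 1:
        raise ValueError("half_len must be >= 1")
    if not (0 <= m < 2 * half_len):
        raise ValueError("need 0 <= m < 2*half_len")
    width = 2 * half_len
    if len(sequence) < width:
        return [], []
    codes = encode(sequence)
    mm_a = _window_mismatches((codes != _BASE_CODE["A"]).astype(np.int64), half_len)
    mm_t = _window_mismatches((codes != _BASE_CODE["T"]).astype(np.int64), half_len)
    out: list[list[PatternHit]] = []
    for pattern, first, second in (
        ("chimera_AT", mm_a, mm_t),
        ("chimera_TA", mm_t, mm_a),
    ):
        win = first[: len(first) - half_len] + second[half_len:]
        starts = np.flatnonzero(win <= m)
        out.append(
            [
                PatternHit(read_id, pattern, s, ln, mm)
                for s, ln, mm in _merge_windows(starts, win[starts], width)
            ]
        )
    return out[0], out[1]


def annotate_runs(sequence: str, read_id: str = "", min_len: int = 2) -> list[RunAnnotation]:
    """All maximal exact single-base runs of length >= ``min_len``, by start."""
    if not sequence:
        return []
    codes = encode(sequence)
    boundaries = np.flatnonzero(codes[1:] != codes[:-1]) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(codes)]))
    out = []
    for s, e in zip(starts, ends):
        if e - s >= min_len and codes[s] != N:
            out.append(RunAnnotation(read_id, sequence[s], int(s), int(e - s)))
    return out


# ---------------------------------------------------------------------------
# Batched presence counting
# ---------------------------------------------------------------------------

def _batch_matrix(reads: Sequence[Read]) -> tuple[np.ndarray, np.ndarray]:
    """Stack reads into a padded code matrix; padding never matches anything."""
    lengths = np.array([len(r) for r in reads], dtype=np.int64)
    width = int(lengths.max()) if len(lengths) else 0
    mat = np.full((len(reads), width), N, dtype=np.uint8)
    for i, r in enumerate(reads):
        mat[i, : lengths[i]] = r.codes
    return mat, lengths


def _presence_homopolymer(
    mat: np.ndarray, lengths: np.ndarray, target: int, L: int, m: int
) -> np.ndarray:
    # Padding weight L+1 > m guarantees any window touching padding fails.
    mism = np.where(mat == target, 0, 1).astype(np.int32)
    pad = np.arange(mat.shape[1]) >= lengths[:, None]
    mism[pad] = L + 1
    if mat.shape[1] < L:
        return np.zeros(mat.shape[0], dtype=bool)
    cs = np.zeros((mat.shape[0], mat.shape[1] + 1), dtype=np.int32)
    np.cumsum(mism, axis=1, out=cs[:, 1:])
    win = cs[:, L:] - cs[:, :-L]
    return (win <= m).any(axis=1)


def _presence_chimera(
    mat: np.ndarray, lengths: np.ndarray, half_len: int, m: int
) -> tuple[np.ndarray, np.ndarray]:
    width = 2 * half_len
    if mat.shape[1] < width:
        z = np.zeros(mat.shape[0], dtype=bool)
        return z, z.copy()
    pad = np.arange(mat.shape[1]) >= lengths[:, None]
    sums = {}
    for name, target in (("A", _BASE_CODE["A"]), ("T", _BASE_CODE["T"])):
        mism = np.where(mat == target, 0, 1).astype(np.int32)
        mism[pad] = width + 1
        cs = np.zeros((mat.shape[0], mat.shape[1] + 1), dtype=np.int32)
        np.cumsum(mism, axis=1, out=cs[:, 1:])
        sums[name] = cs[:, half_len:] - cs[:, :-half_len]
    n_win = mat.shape[1] - width + 1
    at = sums["A"][:, :n_win] + sums["T"][:, half_len : half_len + n_win]
    ta = sums["T"][:, :n_win] + sums["A"][:, half_len : half_len + n_win]
    return (at <= m).any(axis=1), (ta <= m).any(axis=1)


def count_reads_with_patterns(
    reads: Iterable[Read],
    params: "PipelineParams | None" = None,
    chunk_size: int = 20_000,
) -> PatternCounts:
    """Count pattern-containing reads per class across a read stream.

    Uses the thresholds in ``params`` (homopolymer window L, mismatch allowance
    m, chimera half-length); scanning is batched internally, and results agree
    exactly with per-read :func:`scan_homopolymer` / :func:`scan_chimera`
    presence.
    """
    if params is None:
        from .prep import PipelineParams

        params = PipelineParams()
    result = PatternCounts()
    chunk: list[Read] = []

    def flush(chunk: list[Read]) -> None:
        mat, lengths = _batch_matrix(chunk)
        flags = []
        for cls in HOMOPOLYMER_CLASSES:
            target = _BASE_CODE[cls[-1]]
            p = _presence_homopolymer(
                mat, lengths, target, params.homopolymer_min_len, params.max_mismatch
            )
            result.counts[cls] += int(p.sum())
            flags.append(p)
        at, ta = _presence_chimera(
            mat, lengths, params.chimera_half_len, params.max_mismatch
        )
        result.counts["chimera_AT"] += int(at.sum())
        result.counts["chimera_TA"] += int(ta.sum())
        flags += [at, ta]
        result.reads_in_multiple_classes += int(
            (np.sum(flags, axis=0) >= 2).sum()
        )
        result.total_reads += len(chunk)

    for read in reads:
        chunk.append(read)
        if len(chunk) >= chunk_size:
            flush(chunk)
            chunk = []
    if chunk:
        flush(chunk)
    return result
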