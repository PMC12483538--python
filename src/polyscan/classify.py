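"""Mapped/unmapped read partitioning via exact canonical k-mer membership.

Deterministic stand-in for an aligner's mapped/unmapped split: a read is
"mapped" when at least a fraction tau of its k-mers (canonicalised as the
lexicographic minimum of the k-mer and its reverse complement, so both strands
are covered) occur in the reference index. On reads drawn verbatim from the
reference this reproduces an aligner's partition exactly; homopolymer and
spike-derived reads share no k-mers with a reference built without long
single-base runs and land in the unmapped set.

k-mers are packed 2 bits per base into uint64, which bounds k at 31 for the
fast path; larger odd k (up to 63) falls back to hashed string k-mers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

from .io import Read, encode, revcomp

__all__ = [
    "ReferenceIndex",
    "ClassifiedRead",
    "build_index",
    "classify_read",
    "classify_reads",
    "unmapped_fraction",
    "extract_unmapped",
]

_SENTINEL = np.uint64(0xFFFFFFFFFFFFFFFF)  # > any packed k-mer for k <= 31


@dataclass
class ReferenceIndex:
    """Sorted canonical k-mer set built from reference sequences."""

    k: int
    kmers: np.ndarray  # sorted uint64 (packed) or sorted object array of strings
    source_names: list[str]
    packed: bool = True

    def __len__(self) -> int:
        return len(self.kmers)


@dataclass(frozen=True)
class ClassifiedRead:
    read_id: str
    status: str  # "mapped" | "unmapped"
    kmer_hit_fraction: float


def _packed_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical packed k-mer per window; sentinel where the window holds N."""
    n_win = len(codes) - k + 1
    if n_win <= 0:
        return np.empty(0, dtype=np.uint64)
    c = codes.astype(np.uint64)
    fwd = np.zeros(n_win, dtype=np.uint64)
    rev = np.zeros(n_win, dtype=np.uint64)
    four = np.uint64(4)
    for i in range(k):
        fwd = fwd * four + np.minimum(c[i : i + n_win], np.uint64(3))
        # reverse complement read 3'->5': base at offset k-1-i, complemented
        rev = rev * four + np.minimum(
            np.uint64(3) - np.minimum(c[k - 1 - i : k - 1 - i + n_win], np.uint64(3)),
            np.uint64(3),
        )
    canonical = np.minimum(fwd, rev)
    # invalidate windows containing N
    has_n = np.convolve((codes > 3).astype(np.int64), np.ones(k, dtype=np.int64))[
        k - 1 : k - 1 + n_win
    ]
    canonical[has_n > 0] = _SENTINEL
    return canonical


def _string_kmers(sequence: str, k: int) -> Iterator[str | None]:
    for i in range(len(sequence) - k + 1):
        kmer = sequence[i : i + k]
        if "N" in kmer:
            yield None
        else:
            yield min(kmer, revcomp(kmer))


def build_index(
    references: Sequence[tuple[str, str]], k: int = 31
) -> ReferenceIndex:
    """Index every canonical k-mer of every reference sequence.

    References shorter than k are skipped with a warning; k-mers containing N
    are skipped. ``references`` is a sequence of ``(name, sequence)`` pairs.
    """
    if k % 2 == 0 or not 11 <= k <= 63:
        raise ValueError("k must be odd and in [11, 63]")
    if not references:
        raise ValueError("empty reference set")
    names: list[str] = []
    packed = k <= 31
    parts: list[np.ndarray] = []
    strings: set[str] = set()
    for name, seq in references:
        if len(seq) < k:
            warnings.warn(f"reference {name!r} shorter than k={k}; skipped")
            continue
        names.append(name)
        if packed:
            kmers = _packed_kmers(encode(seq), k)
            parts.append(kmers[kmers != _SENTINEL])
        else:
            strings.update(km for km in _string_kmers(seq, k) if km is not None)
    if not names:
        raise ValueError("no reference sequence of length >= k")
    if packed:
        kmers = np.unique(np.concatenate(parts)) if parts else np.empty(0, np.uint64)
        return ReferenceIndex(k, kmers, names, packed=True)
    return ReferenceIndex(k, np.sort(np.array(sorted(strings), dtype=object)), names, packed=False)


def _hit_fractions(
    reads: Sequence[Read], index: ReferenceIndex
) -> np.ndarray:
    k = index.k
    fractions = np.zeros(len(reads), dtype=np.float64)
    if not index.packed:
        kmer_set = set(index.kmers.tolist())
        for i, read in enumerate(reads):
            kmers = list(_string_kmers(read.sequence, k))
            if not kmers:
                continue
            hits = sum(1 for km in kmers if km is not None and km in kmer_set)
            fractions[i] = hits / len(kmers)
        return fractions
    # group reads by length so each group scans as one vectorised batch
    lengths = np.array([len(r) for r in reads])
    for length in np.unique(lengths):
        if length < k:
            continue
        idx = np.flatnonzero(lengths == length)
        mat = np.empty((len(idx), length), dtype=np.uint8)
        for row, j in enumerate(idx):
            mat[row] = reads[j].codes
        n_win = length - k + 1
        four = np.uint64(4)
        c = np.minimum(mat.astype(np.uint64), np.uint64(3))
        rc = np.uint64(3) - c
        fwd = np.zeros((len(idx), n_win), dtype=np.uint64)
        rev = np.zeros((len(idx), n_win), dtype=np.uint64)
        for i in range(k):
            fwd = fwd * four + c[:, i : i + n_win]
            rev = rev * four + rc[:, k - 1 - i : k - 1 - i + n_win]
        canonical = np.minimum(fwd, rev)
        has_n = mat > 3
        if has_n.any():
            cs = np.zeros((len(idx), length + 1), dtype=np.int32)
            np.cumsum(has_n, axis=1, out=cs[:, 1:])
            canonical[(cs[:, k:] - cs[:, :-k]) > 0] = _SENTINEL
        pos = np.searchsorted(index.kmers, canonical)
        pos[pos >= len(index.kmers)] = max(len(index.kmers) - 1, 0)
        if len(index.kmers):
            hit = index.kmers[pos] == canonical
        else:
            hit = np.zeros_like(canonical, dtype=bool)
        hit[canonical == _SENTINEL] = False
        fractions[idx] = hit.sum(axis=1) / n_win
    return fractions


def classify_reads(
    reads: Sequence[Read], index: ReferenceIndex, tau: float = 0.5
) -> list[ClassifiedRead]:
    """Classify a batch of reads; mapped iff hit fraction >= tau.

    Reads shorter than k are unmapped with fraction 0.
    """
    if not 0 < tau <= 1:
        raise ValueError("tau must lie in (0, 1]")
    fractions = _hit_fractions(reads, index)
    return [
        ClassifiedRead(
            r.read_id,
            "mapped" if f >= tau else "unmapped",
            float(f),
        )
        for r, f in zip(reads, fractions)
    ]


def classify_read(read: Read, index: ReferenceIndex, tau: float = 0.5) -> ClassifiedRead:
    """Classify a single read (see :func:`classify_reads`)."""
    return classify_reads([read], index, tau)[0]


def unmapped_fraction(classified: Sequence[ClassifiedRead]) -> float:
    """(#unmapped)/(#total) over a non-empty classified collection."""
    if not classified:
        raise ValueError("empty classified collection")
    return sum(c.status == "unmapped" for c in classified) / len(classified)


def extract_unmapped(
    reads: Iterable[Read], classified: Iterable[ClassifiedRead]
) -> Iterator[Read]:
    """Yield exactly the unmapped reads, order preserved; ids must align."""
    sentinel = object()
    from itertools import zip_longest

    for read, cls in zip_longest(reads, classified, fillvalue=sentinel):
        if read is sentinel or cls is sentinel:
            raise ValueError("read and classification streams differ in length")
        if read.read_id != cls.read_id:
            raise ValueError(
                f"stream mismatch: read {read.read_id!r} vs classification "
                f"{cls.read_id!r}"
            )
        if cls.status == "unmapped":
            yield read
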