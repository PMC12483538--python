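"""Sequencing records and file round-trips.

A :class:`Read` is the unit flowing through every pipeline stage: one FASTQ
record with Phred+33-decoded integer qualities. FASTA/FASTQ parsing and
serialisation go through Biopython; paths ending in ``.gz`` are transparently
(de)compressed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Read",
    "encode",
    "decode",
    "revcomp",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
]

# 2-bit base codes; 4 marks N / anything unrecognised.
A, C, G, T, N = 0, 1, 2, 3, 4

_CODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(sequence: str) -> np.ndarray:
    """Encode a base string to uint8 codes (A=0, C=1, G=2, T=3, N=4)."""
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _BASES[codes].tobytes().decode("ascii")


def revcomp(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass
class Read:
    """One sequencing record.

    Parameters
    ----------
    read_id:
        Non-empty identifier, unique within a file.
    sequence:
        Base string over ``{A, C, G, T, N}``.
    qualities:
        Integer Phred scores, one per base, each in ``[0, 60]``.
    """

    read_id: str
    sequence: str
    qualities: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValueError("read_id must be non-empty")
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"{self.read_id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )
        if self.qualities.size and (
            self.qualities.min() < 0 or self.qualities.max() > 60
        ):
            raise ValueError(f"{self.read_id}: Phred scores must lie in [0, 60]")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        return encode(self.sequence)


def _open_text(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def _to_record(read: Read) -> SeqRecord:
    rec = SeqRecord(Seq(read.sequence), id=read.read_id, description="")
    rec.letter_annotations["phred_quality"] = [int(q) for q in read.qualities]
    return rec


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Iterate FASTQ records (Phred+33) from a plain or gzipped file."""
    with _open_text(path, "r") as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            yield Read(
                rec.id,
                str(rec.seq).upper(),
                np.array(rec.letter_annotations["phred_quality"], dtype=np.int16),
            )


def write_fastq(reads: Iterable[Read], path: str | Path) -> int:
    """Write reads as Phred+33 FASTQ; returns the number written."""
    with _open_text(path, "w") as handle:
        return SeqIO.write((_to_record(r) for r in reads), handle, "fastq")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Return ``(name, sequence)`` pairs from a FASTA file."""
    with _open_text(path, "r") as handle:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]


def write_fasta(sequences: Iterable[tuple[str, str]], path: str | Path) -> int:
    """Write ``(name, sequence)`` pairs as 60-column-wrapped FASTA."""
    records = (SeqRecord(Seq(s), id=n, description="") for n, s in sequences)
    with _open_text(path, "w") as handle:
        return SeqIO.write(records, handle, "fasta")
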