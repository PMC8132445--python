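"""Read container and FASTQ input/output.

Reads are stored as plain strings with per-read Sanger-encoded quality
strings. The simulator emits constant-high qualities by default, so the
container allows a shared quality character instead of materializing one
string per read until FASTQ serialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

from Bio import SeqIO

DEFAULT_QUALITY_CHAR = "I"  # Phred 40


@dataclass
class ReadBatch:
    """A flat collection of (possibly heterogeneous-length) reads."""

    ids: list[str] = field(default_factory=list)
    sequences: list[str] = field(default_factory=list)
    qualities: Optional[list[str]] = None  # None -> constant quality_char
    quality_char: str = DEFAULT_QUALITY_CHAR

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences length mismatch")
        if self.qualities is not None and len(self.qualities) != len(self.sequences):
            raise ValueError("qualities length mismatch")

    def __len__(self) -> int:
        return len(self.sequences)

    def quality_of(self, i: int) -> str:
        if self.qualities is not None:
            return self.qualities[i]
        return self.quality_char * len(self.sequences[i])

    def subset(self, indices) -> "ReadBatch":
        quals = [self.qualities[i] for i in indices] if self.qualities else None
        return ReadBatch(
            [self.ids[i] for i in indices],
            [self.sequences[i] for i in indices],
            quals,
            self.quality_char,
        )

    def extend(self, other: "ReadBatch") -> None:
        if (self.qualities is None) != (other.qualities is None):
            self.qualities = [self.quality_of(i) for i in range(len(self))]
            other = ReadBatch(
                other.ids,
                other.sequences,
                [other.quality_of(i) for i in range(len(other))],
                other.quality_char,
            )
        self.ids.extend(other.ids)
        self.sequences.extend(other.sequences)
        if self.qualities is not None and other.qualities is not None:
            self.qualities.extend(other.qualities)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(zip(self.ids, self.sequences))


def write_fastq(batch: ReadBatch, path) -> None:
    """Write standard 4-line FASTQ records (Sanger quality encoding)."""
    with open(path, "w") as fh:
        for i, (rid, seq) in enumerate(batch):
            fh.write(f"@{rid}\n{seq}\n+\n{batch.quality_of(i)}\n")


def read_fastq(path) -> ReadBatch:
    ids: list[str] = []
    seqs: list[str] = []
    quals: list[str] = []
    for rec in SeqIO.parse(str(path), "fastq"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
        quals.append(
            "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        )
    return ReadBatch(ids, seqs, quals)
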