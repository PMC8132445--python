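"""Nucleotide sequence primitives and IUPAC pattern matching.

All coordinates in the package are 0-based, half-open. Sequences are kept as
plain uppercase strings over {A, C, G, T, N}; IUPAC ambiguity letters are
accepted on input and normalized to N (they are only meaningful in
restriction-site *patterns*, which stay as IUPAC strings).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_LETTERS = set("ACGTNRYSWKMBDHV")

# degenerate letters collapse to N in stored sequences
_NORMALIZE = str.maketrans({c: "N" for c in "RYSWKMBDHV"})

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

#: IUPAC letter -> set of concrete bases it stands for
IUPAC_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def normalize_bases(raw: str) -> str:
    """Uppercase, transliterate RNA U to T, collapse degenerate letters to N.

    Raises ValueError on characters outside the IUPAC alphabet.
    """
    s = raw.upper().replace("U", "T")
    bad = set(s) - IUPAC_LETTERS
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return s.translate(_NORMALIZE)


def reverse_complement(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NucleotideSequence:
    """An immutable named DNA sequence, canonicalized to uppercase ACGTN."""

    bases: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError("empty sequence")
        object.__setattr__(self, "bases", normalize_bases(self.bases))

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases

    def reverse_complement(self) -> "NucleotideSequence":
        name = f"{self.name}_rc" if self.name else ""
        return NucleotideSequence(reverse_complement(self.bases), name)


def iupac_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC pattern to a regex finding overlapping matches."""
    pattern = pattern.upper().replace("U", "T")
    bad = set(pattern) - IUPAC_LETTERS
    if bad:
        raise ValueError(f"non-IUPAC characters in pattern: {sorted(bad)}")
    body = "".join(
        c if len(IUPAC_EXPAND[c]) == 1
        else "[" + IUPAC_EXPAND[c] + ("N" if c == "N" else "") + "]"
        for c in pattern
    )
    return re.compile(f"(?={body})")


def iupac_find(pattern: str, seq: str) -> list[int]:
    """All start positions where the IUPAC ``pattern`` matches ``seq``.

    Overlapping occurrences are reported. N in ``seq`` matches nothing
    (an unknown base cannot be claimed to satisfy a recognition site) unless
    the pattern position is itself N.
    """
    # regex classes above do not include N on the sequence side by design
    return [m.start() for m in iupac_regex(pattern).finditer(seq)]


def read_fasta(path) -> list[NucleotideSequence]:
    return [
        NucleotideSequence(str(rec.seq), rec.id)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(seqs: Iterator[NucleotideSequence] | list[NucleotideSequence], path) -> None:
    records = [
        SeqRecord(Seq(s.bases), id=s.name or f"seq{i}", description="")
        for i, s in enumerate(seqs)
    ]
    SeqIO.write(records, str(path), "fasta")
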