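"""Nucleotide sequence handling: FASTA I/O, region extraction, translation.

Coordinates throughout the public interface are 1-based and inclusive, the
convention used by curators reading genome-browser coordinates and GFF.
Intervals always store ascending forward-strand coordinates; the strand flag
says how the sequence is read, never how it is stored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Seq import Seq

VALID_NT = set("ACGTN")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceError(ValueError):
    """Raised for malformed sequence input or out-of-range coordinates."""


@dataclass(frozen=True)
class ScaffoldSequence:
    """A named genome scaffold; the subject of all coordinate lookups."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("scaffold id must be non-empty")
        residues = self.residues.upper()
        bad = re.search(r"[^ACGTN]", residues)
        if bad:
            raise SequenceError(
                f"record {self.id!r}: invalid nucleotide {bad.group()!r} "
                f"at position {bad.start() + 1}"
            )
        object.__setattr__(self, "residues", residues)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """1-based inclusive interval on a scaffold's forward strand.

    ``start <= end`` always; minus-strand features keep ascending forward
    coordinates and carry strand as a flag.
    """

    scaffold_id: str = field(compare=False)
    start: int
    end: int
    strand: str = field(default="+", compare=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise SequenceError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise SequenceError(
                f"invalid interval {self.start}-{self.end}: "
                "need 1 <= start <= end"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution, N maps to N."""
    seq = seq.upper()
    bad = set(seq) - VALID_NT
    if bad:
        raise SequenceError(f"invalid nucleotides {sorted(bad)} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


def extract_region(scaffold: ScaffoldSequence, interval: GenomicInterval) -> str:
    """Sequence of ``interval`` read 5'->3' on its own strand.

    Forward-strand substring for '+', reverse complement of it for '-'.
    """
    if interval.end > len(scaffold):
        raise SequenceError(
            f"interval {interval.start}-{interval.end} out of bounds for "
            f"{scaffold.id!r} (length {len(scaffold)})"
        )
    sub = scaffold.residues[interval.start - 1 : interval.end]
    return sub if interval.strand == "+" else reverse_complement(sub)


def translate(cds: str) -> tuple[str, int]:
    """Translate a CDS with the standard nuclear code; stops render '*'.

    Returns ``(peptide, remainder)`` where remainder is the 1-2 trailing
    nucleotides that do not fill a codon (0 for in-frame input). Codons
    containing N translate to 'X'.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise SequenceError(f"CDS too short to translate ({len(cds)} nt)")
    remainder = len(cds) % 3
    trimmed = cds[: len(cds) - remainder] if remainder else cds
    peptide = str(Seq(trimmed).translate())
    if "N" in trimmed:
        peptide = "".join(
            "X" if "N" in trimmed[i * 3 : i * 3 + 3] else aa
            for i, aa in enumerate(peptide)
        )
    return peptide, remainder


def read_fasta(source: str | Path | TextIO) -> list[ScaffoldSequence]:
    """Read a multi-record FASTA into validated scaffolds.

    The header token before the first whitespace becomes the id. Duplicate
    ids, empty files and non-nucleotide residues are errors.
    """
    records = list(SeqIO.parse(source, "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records found in {source!r}")
    scaffolds: list[ScaffoldSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise SequenceError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        scaffolds.append(ScaffoldSequence(id=rec.id, residues=str(rec.seq)))
    return scaffolds


def write_fasta(
    records: Iterable[tuple[str, str]], path: str | Path, width: int = 60
) -> None:
    """Write (id, sequence) pairs as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
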