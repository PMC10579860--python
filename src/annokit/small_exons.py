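"""Phase-constrained ORF search for small or weakly conserved coding exons.

Similarity searches miss coding exons that are very short (well under 30
bp) or too diverged to align. When the flanking exons of a model are known,
the missing exon's splice-site phases are known too, which turns the hunt
into a small constrained search: find every interval in a genomic window
that is flanked by the right splice sites, has a length congruent to the
required phases modulo 3 (a coding exon of length L between an acceptor of
phase a and a donor of phase d satisfies L = a + 3k + d), and contains no
stop codon among its complete codons in the implied reading frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .sequence import (
    STOP_CODONS,
    GenomicInterval,
    SequenceError,
    reverse_complement,
)

CDS_TYPES = ("initial", "internal", "terminal")


class SearchError(ValueError):
    """Raised for contradictory or malformed search constraints."""


@dataclass(frozen=True)
class ExonSearchConstraints:
    """Biological constraints a candidate coding exon must satisfy.

    ``acceptor_phase`` is ignored for initial exons (they start at a start
    codon, not an acceptor) and ``donor_phase`` for terminal exons (they
    end at a stop codon, not a donor). Lengths well below 30 nt are the
    point of this search and are fully supported. Initial candidates
    include the ATG; terminal candidates include the stop codon.
    """

    cds_type: str
    min_length: int
    max_length: int
    acceptor_phase: int = 0
    donor_phase: int = 0
    allow_gc_donor: bool = False

    def __post_init__(self) -> None:
        if self.cds_type not in CDS_TYPES:
            raise SearchError(f"cds_type must be one of {CDS_TYPES}")
        if self.min_length < 1:
            raise SearchError("min_length must be >= 1")
        if self.min_length > self.max_length:
            raise SearchError(
                f"contradictory constraints: min_length {self.min_length} > "
                f"max_length {self.max_length}"
            )
        for name in ("acceptor_phase", "donor_phase"):
            if getattr(self, name) not in (0, 1, 2):
                raise SearchError(f"{name} must be 0, 1 or 2")

    @property
    def required_length_mod(self) -> int:
        """Required exon length modulo 3, from L = a + 3k + d."""
        if self.cds_type == "initial":
            return self.donor_phase % 3
        if self.cds_type == "terminal":
            return self.acceptor_phase % 3
        return (self.acceptor_phase + self.donor_phase) % 3


@dataclass(frozen=True)
class ExonCandidate:
    interval: GenomicInterval
    sequence: str
    flanking_acceptor: Optional[str]
    flanking_donor: Optional[str]
    score_rank: int

    @property
    def length(self) -> int:
        return len(self.interval)


def satisfies_constraints(
    window: str, start: int, end: int, constraints: ExonSearchConstraints
) -> bool:
    """Predicate: does window[start:end] (0-based, half-open, transcript
    orientation) satisfy the constraints? Shared by the search and usable
    as an independent re-validation of its output."""
    c = constraints
    length = end - start
    if not (c.min_length <= length <= c.max_length):
        return False
    if length % 3 != c.required_length_mod:
        return False
    seq = window[start:end]
    if c.cds_type in ("internal", "terminal"):
        if start < 2 or window[start - 2 : start] != "AG":
            return False
        leading = c.acceptor_phase
    else:
        if seq[:3] != "ATG":
            return False
        leading = 0
    if c.cds_type in ("internal", "initial"):
        donor = window[end : end + 2]
        if donor != "GT" and not (c.allow_gc_donor and donor == "GC"):
            return False
    if length <= leading:
        return False
    # complete codons in the implied frame
    n_codons, last_stop_ok = 0, False
    for i in range(start + leading, end - 2, 3):
        codon = window[i : i + 3]
        if codon in STOP_CODONS:
            if c.cds_type == "terminal" and i + 3 == end:
                last_stop_ok = True
            else:
                return False
        n_codons += 1
    if c.cds_type == "terminal" and not last_stop_ok:
        return False
    return True


def find_small_exons(
    window_sequence: str,
    window_offset: int,
    constraints: ExonSearchConstraints,
    strand: str = "+",
    scaffold_id: str = "window",
) -> list[ExonCandidate]:
    """All intervals in the window satisfying the constraints.

    ``window_offset`` is the 1-based forward-strand scaffold coordinate of
    the window's first base; returned intervals are forward-strand scaffold
    coordinates. For '-' the window is searched in transcript orientation
    (reverse complement) and coordinates mapped back. Candidates are
    ordered by ascending start then descending length (transcript
    orientation); ``score_rank`` records that ordinal.
    """
    if strand not in ("+", "-"):
        raise SearchError(f"strand must be '+' or '-', got {strand!r}")
    window = window_sequence.upper()
    if set(window) - set("ACGTN"):
        raise SequenceError("window contains non-nucleotide characters")
    tx_window = window if strand == "+" else reverse_complement(window)
    c = constraints
    L = len(tx_window)
    hits: list[tuple[int, int]] = []  # 0-based half-open in tx orientation
    starts: list[int]
    if c.cds_type in ("internal", "terminal"):
        starts = [
            i + 2 for i in range(L - 1) if tx_window[i : i + 2] == "AG"
        ]
    else:
        starts = [i for i in range(L - 2) if tx_window[i : i + 3] == "ATG"]
    for s in starts:
        lo = max(c.min_length, 1)
        for length in range(lo, min(c.max_length, L - s) + 1):
            if satisfies_constraints(tx_window, s, s + length, c):
                hits.append((s, s + length))
    hits.sort(key=lambda h: (h[0], -(h[1] - h[0])))

    out: list[ExonCandidate] = []
    for rank, (s, e) in enumerate(hits, start=1):
        if strand == "+":
            f_start = window_offset + s
            f_end = window_offset + e - 1
        else:
            f_start = window_offset + (L - e)
            f_end = window_offset + (L - s) - 1
        acceptor = tx_window[s - 2 : s] if c.cds_type != "initial" else None
        donor = tx_window[e : e + 2] if c.cds_type != "terminal" else None
        out.append(
            ExonCandidate(
                interval=GenomicInterval(scaffold_id, f_start, f_end, strand),
                sequence=tx_window[s:e],
                flanking_acceptor=acceptor,
                flanking_donor=donor,
                score_rank=rank,
            )
        )
    return out
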