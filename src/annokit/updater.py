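"""Consensus-error correction: apply VCF edits to a scaffold and lift
gene-model coordinates onto the corrected sequence.

Assembly consensus errors (wrong bases, extra or missing nucleotides)
produce apparent frameshifts and premature stops in otherwise sound gene
models. The fix is an edit file — a minimal Variant Call Format (VCF)
record per correction — applied to the scaffold before validation. Only
CHROM, POS, REF and ALT are honoured; indels use VCF anchoring (REF and
ALT share their first base). A piecewise-constant coordinate map lifts
model coordinates across the applied edits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .models import IsoformModel, make_model
from .sequence import ScaffoldSequence


class EditError(ValueError):
    """Raised for invalid, mismatching or overlapping edits."""


@dataclass(frozen=True)
class SequenceEdit:
    """One consensus correction at a 1-based scaffold position."""

    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise EditError("position must be >= 1")
        if not self.ref_allele or not self.alt_allele:
            raise EditError("REF and ALT must be non-empty")
        for name, allele in (("REF", self.ref_allele), ("ALT", self.alt_allele)):
            if set(allele.upper()) - set("ACGTN"):
                raise EditError(f"{name} allele {allele!r} is not nucleotide")
        object.__setattr__(self, "ref_allele", self.ref_allele.upper())
        object.__setattr__(self, "alt_allele", self.alt_allele.upper())

    @property
    def kind(self) -> str:
        if len(self.ref_allele) == len(self.alt_allele):
            return "substitution"
        return "insertion" if len(self.alt_allele) > len(self.ref_allele) else "deletion"

    @property
    def span_end(self) -> int:
        """Last scaffold position covered by REF."""
        return self.position + len(self.ref_allele) - 1

    @property
    def length_change(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)


def parse_edits(
    vcf: str | Path, scaffold: ScaffoldSequence
) -> list[SequenceEdit]:
    """Read a minimal VCF into validated, sorted, non-overlapping edits.

    QUAL/FILTER/INFO and any genotype columns are ignored; multi-allelic
    ALT is rejected; every REF allele must match the scaffold.
    """
    if isinstance(vcf, Path) or (
        isinstance(vcf, str) and "\n" not in vcf and Path(vcf).exists()
    ):
        text = Path(vcf).read_text()
    else:
        text = str(vcf)
    edits: list[SequenceEdit] = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 5:
            raise EditError(f"line {lineno}: expected >= 5 VCF columns")
        chrom, pos, _, ref, alt = cols[:5]
        if chrom != scaffold.id:
            raise EditError(
                f"line {lineno}: record on {chrom!r}, scaffold is {scaffold.id!r}"
            )
        if "," in alt:
            raise EditError(f"line {lineno}: multi-allelic ALT not supported")
        edits.append(SequenceEdit(int(pos), ref, alt))
    edits.sort(key=lambda e: e.position)
    for e in edits:
        observed = scaffold.residues[e.position - 1 : e.span_end]
        if observed != e.ref_allele:
            raise EditError(
                f"REF mismatch at {scaffold.id}:{e.position}: VCF states "
                f"{e.ref_allele!r}, scaffold holds {observed!r}"
            )
    for a, b in zip(edits, edits[1:]):
        if b.position <= a.span_end:
            raise EditError(
                f"overlapping edits at positions {a.position} and {b.position}"
            )
    return edits


def write_edits(
    edits: Iterable[SequenceEdit], scaffold_id: str, path: str | Path | None = None
) -> str:
    """Serialize edits as a minimal VCF v4.2 file; returns the text."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={scaffold_id}>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for e in sorted(edits, key=lambda e: e.position):
        lines.append(
            f"{scaffold_id}\t{e.position}\t.\t{e.ref_allele}\t{e.alt_allele}"
            "\t.\t.\t."
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


class CoordinateMap:
    """Piecewise offsets from original to corrected coordinates.

    Positions inside a deleted span have no image and raise; positions
    inserted by an edit have no preimage. Outside edited spans the map is
    strictly monotone and invertible.
    """

    def __init__(self, edits: Sequence[SequenceEdit]):
        self._edits = tuple(sorted(edits, key=lambda e: e.position))
        self._starts = [e.position for e in self._edits]

    def lift(self, position: int) -> int:
        """Original scaffold position -> corrected scaffold position."""
        offset = 0
        for e in self._edits:
            if position <= e.position:
                break
            if position <= e.span_end:  # inside the replaced span, after anchor
                raise EditError(
                    f"position {position} lies inside the span edited at "
                    f"{e.position} ({e.kind}) and has no corrected image"
                )
            offset += e.length_change
        return position + offset

    def unlift(self, position: int) -> int:
        """Corrected scaffold position -> original scaffold position."""
        offset = 0
        for e in self._edits:
            new_anchor = e.position + offset
            if position <= new_anchor:
                break
            new_span_end = new_anchor + len(e.alt_allele) - 1
            if position <= new_span_end:
                raise EditError(
                    f"corrected position {position} lies inside the span "
                    f"written by the edit at {e.position} and has no preimage"
                )
            offset += e.length_change
        return position - offset


def apply_edits(
    scaffold: ScaffoldSequence, edits: Sequence[SequenceEdit]
) -> tuple[ScaffoldSequence, CoordinateMap]:
    """Corrected scaffold plus the coordinate map onto it.

    Corrected length = original length + sum of (len ALT - len REF).
    """
    pieces: list[str] = []
    cursor = 0  # 0-based, next original base to copy
    for e in sorted(edits, key=lambda e: e.position):
        if e.position - 1 < cursor:
            raise EditError(f"overlapping edit at position {e.position}")
        pieces.append(scaffold.residues[cursor : e.position - 1])
        observed = scaffold.residues[e.position - 1 : e.span_end]
        if observed != e.ref_allele:
            raise EditError(
                f"REF mismatch at {scaffold.id}:{e.position}: edit states "
                f"{e.ref_allele!r}, scaffold holds {observed!r}"
            )
        pieces.append(e.alt_allele)
        cursor = e.span_end
    pieces.append(scaffold.residues[cursor:])
    corrected = ScaffoldSequence(scaffold.id, "".join(pieces))
    return corrected, CoordinateMap(edits)


def lift_model(model: IsoformModel, cmap: CoordinateMap) -> IsoformModel:
    """Re-anchor a model's exon coordinates onto the corrected sequence.

    An exon boundary inside a deleted span cannot be lifted and is an
    error naming the exon.
    """
    coords = []
    for exon in model.exons:
        try:
            coords.append(
                (cmap.lift(exon.interval.start), cmap.lift(exon.interval.end))
            )
        except EditError as err:
            raise EditError(
                f"exon {exon.ordinal} of {model.isoform_name}: {err}"
            ) from err
    return make_model(
        model.gene_symbol, model.isoform_name, model.scaffold_id, model.strand,
        coords, assembly_id=model.assembly_id, complete=model.complete,
        allowances=model.allowances,
    )
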