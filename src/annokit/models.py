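"""Gene-model data types, GFF3/FNA/FAA serialization, and reference records.

An :class:`IsoformModel` is the unit being curated: the ordered coding-exon
coordinates of one protein isoform on one scaffold. Only CDS features are
modelled — the curation protocol annotates coding regions, not UTRs.

A :class:`ReferenceIsoformRecord` summarizes the structure of the reference
species' isoform (exon count, per-exon peptide segments): the template the
proposed model is checked against.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .sequence import (
    GenomicInterval,
    ScaffoldSequence,
    extract_region,
    read_fasta,
    reverse_complement,
    translate,
)


class ModelError(ValueError):
    """Raised for structurally invalid gene models or annotation files."""


@dataclass(frozen=True)
class CodingExon:
    """One coding exon; ordinal is its 1-based index in transcript order."""

    ordinal: int
    interval: GenomicInterval

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class IsoformModel:
    """Ordered coding-exon coordinates of one isoform, plus declared
    exceptions (allowances) the checker should warn on instead of failing.

    Exons are stored in ascending scaffold order; transcript order for
    minus-strand models is descending coordinate order. ``complete`` is
    False for partial models (e.g. genes broken by an assembly gap), which
    demotes start/stop checks to warnings.
    """

    gene_symbol: str
    isoform_name: str
    scaffold_id: str
    strand: str
    exons: tuple[CodingExon, ...]
    assembly_id: str = ""
    complete: bool = True
    allowances: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ModelError(f"{self.isoform_name}: model needs at least one exon")
        if self.strand not in ("+", "-"):
            raise ModelError(f"strand must be '+' or '-', got {self.strand!r}")
        ivs = [e.interval for e in self.exons]
        if any(iv.scaffold_id != self.scaffold_id for iv in ivs):
            raise ModelError(f"{self.isoform_name}: exon on a different scaffold")
        if sorted(ivs, key=lambda iv: iv.start) != list(ivs):
            raise ModelError(f"{self.isoform_name}: exons not in ascending order")
        for a, b in zip(ivs, ivs[1:]):
            if b.start <= a.end:
                raise ModelError(
                    f"{self.isoform_name}: exons {a.start}-{a.end} and "
                    f"{b.start}-{b.end} overlap"
                )
        object.__setattr__(self, "allowances", dict(self.allowances))

    @property
    def transcript_exons(self) -> tuple[CodingExon, ...]:
        """Exons in transcript (5'->3') order."""
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.scaffold_id, self.exons[0].interval.start,
            self.exons[-1].interval.end, self.strand,
        )

    @property
    def cds_length(self) -> int:
        return sum(e.length for e in self.exons)

    def exon_coordinate_set(self) -> tuple[tuple[int, int], ...]:
        return tuple((e.interval.start, e.interval.end) for e in self.exons)


def make_model(
    gene_symbol: str,
    isoform_name: str,
    scaffold_id: str,
    strand: str,
    exon_coords: Sequence[tuple[int, int]],
    **kwargs,
) -> IsoformModel:
    """Build an IsoformModel from (start, end) pairs in any order."""
    coords = sorted(exon_coords)
    n = len(coords)
    exons = []
    for i, (s, e) in enumerate(coords):
        ordinal = i + 1 if strand == "+" else n - i
        exons.append(
            CodingExon(ordinal, GenomicInterval(scaffold_id, s, e, strand))
        )
    return IsoformModel(
        gene_symbol, isoform_name, scaffold_id, strand, tuple(exons), **kwargs
    )


def assemble_cds(model: IsoformModel, scaffold: ScaffoldSequence) -> str:
    """Spliced CDS: exon sequences concatenated in transcript order,
    minus-strand exons reverse-complemented."""
    if model.scaffold_id != scaffold.id:
        raise ModelError(
            f"model {model.isoform_name} is on {model.scaffold_id!r}, "
            f"not {scaffold.id!r}"
        )
    return "".join(
        extract_region(scaffold, e.interval) for e in model.transcript_exons
    )


# ---------------------------------------------------------------------------
# GFF3 (CDS features only)

_GFF_COLS = 9


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:  # GFF3 style
            key, _, val = part.partition("=")
            attrs[key.strip()] = val.strip()
        else:  # GTF style: key "value"
            key, _, val = part.partition(" ")
            attrs[key.strip()] = val.strip().strip('"')
    return attrs


def parse_model_gff(source: str | Path) -> list[IsoformModel]:
    """Parse CDS features grouped by transcript into isoform models.

    Accepts GFF3 ``Parent=``/``ID=`` or GTF ``transcript_id`` grouping.
    Unsorted CDS lines are accepted and sorted; mixed strands within one
    transcript are an error. The transcript identifier is taken as the
    isoform name; the gene symbol is its prefix before ``-P`` when the
    reference naming style (e.g. Rheb-PA) is used.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)

    groups: dict[str, list[tuple[str, int, int, str]]] = {}
    order: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != _GFF_COLS:
            raise ModelError(f"line {lineno}: expected 9 tab-separated columns")
        scaffold_id, _, ftype, start, end, _, strand, _, attr_text = cols
        if ftype.upper() != "CDS":
            continue
        attrs = _parse_attributes(attr_text)
        tid = (
            attrs.get("Parent")
            or attrs.get("transcript_id")
            or attrs.get("ID")
        )
        if tid is None:
            raise ModelError(f"line {lineno}: CDS has no Parent/transcript_id")
        if tid not in groups:
            groups[tid] = []
            order.append(tid)
        groups[tid].append((scaffold_id, int(start), int(end), strand))

    models: list[IsoformModel] = []
    for tid in order:
        feats = groups[tid]
        scaffolds = {f[0] for f in feats}
        if len(scaffolds) > 1:
            raise ModelError(f"{tid}: CDS features on multiple scaffolds")
        strands = {f[3] for f in feats}
        if len(strands) > 1:
            raise ModelError(f"{tid}: mixed strands within one transcript")
        gene = tid.rsplit("-P", 1)[0] if "-P" in tid else tid
        models.append(
            make_model(
                gene, tid, scaffolds.pop(), strands.pop(),
                [(s, e) for _, s, e, _ in feats],
            )
        )
    return models


def write_model_gff(models: Iterable[IsoformModel], source_tag: str = "annokit") -> str:
    """Serialize models as GFF3 CDS features (1-based inclusive)."""
    lines = ["##gff-version 3"]
    for m in models:
        for exon in m.exons:
            iv = exon.interval
            lines.append(
                "\t".join(
                    [
                        m.scaffold_id, source_tag, "CDS",
                        str(iv.start), str(iv.end), ".",
                        m.strand, ".",
                        f"ID=CDS:{m.isoform_name}:{exon.ordinal};"
                        f"Parent={m.isoform_name};gene={m.gene_symbol}",
                    ]
                )
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Reference isoform records

@dataclass(frozen=True)
class ReferenceIsoformRecord:
    """Structure summary of a reference-species isoform: the per-exon
    peptide segments curators map one exon at a time."""

    isoform_name: str
    exon_count: int
    exon_peptides: tuple[str, ...]
    full_peptide: str
    junction_classes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.exon_count != len(self.exon_peptides):
            raise ModelError(
                f"{self.isoform_name}: exon_count {self.exon_count} != "
                f"{len(self.exon_peptides)} peptide segments"
            )
        if "".join(self.exon_peptides) != self.full_peptide:
            raise ModelError(
                f"{self.isoform_name}: exon peptides do not concatenate to "
                "the full peptide"
            )

    def to_json(self) -> str:
        return json.dumps(
            {
                "isoform_name": self.isoform_name,
                "exon_count": self.exon_count,
                "exon_peptides": list(self.exon_peptides),
                "full_peptide": self.full_peptide,
                "junction_classes": list(self.junction_classes),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ReferenceIsoformRecord":
        d = json.loads(text)
        return cls(
            d["isoform_name"], d["exon_count"],
            tuple(d["exon_peptides"]), d["full_peptide"],
            tuple(d.get("junction_classes", ())),
        )


def split_peptide_by_exons(cds: str, exon_lengths: Sequence[int]) -> list[str]:
    """Assign each amino acid of the spliced CDS to a coding exon.

    A codon split across a splice junction contributes its amino acid to
    the exon holding at least two of its three nucleotides (splits are
    always 1+2 or 2+1, so there is no tie). Trailing partial codons are
    dropped, matching translation.
    """
    peptide, _ = translate(cds)
    boundaries = []
    cum = 0
    for length in exon_lengths:
        cum += length
        boundaries.append(cum)
    segments = ["" for _ in exon_lengths]
    for i, aa in enumerate(peptide):
        codon_nt = (i * 3 + 1, i * 3 + 2, i * 3 + 3)  # 1-based CDS positions
        votes = []
        for nt in codon_nt:
            for exon_idx, b in enumerate(boundaries):
                if nt <= b:
                    votes.append(exon_idx)
                    break
        # exon holding >=2 of the codon's nucleotides
        winner = max(set(votes), key=votes.count)
        segments[winner] += aa
    return segments


def build_reference_record(
    reference_gff: str | Path,
    reference_genome: str | Path | ScaffoldSequence | Sequence[ScaffoldSequence],
    isoform_name: str,
) -> ReferenceIsoformRecord:
    """Summarize one isoform of a reference annotation: exon count and the
    peptide segment encoded by each coding exon."""
    models = {m.isoform_name: m for m in parse_model_gff(reference_gff)}
    if isoform_name not in models:
        raise ModelError(
            f"isoform {isoform_name!r} not in reference annotation; "
            f"available: {sorted(models)}"
        )
    model = models[isoform_name]
    if isinstance(reference_genome, ScaffoldSequence):
        scaffolds = {reference_genome.id: reference_genome}
    elif isinstance(reference_genome, (str, Path)):
        scaffolds = {s.id: s for s in read_fasta(reference_genome)}
    else:
        scaffolds = {s.id: s for s in reference_genome}
    if model.scaffold_id not in scaffolds:
        raise ModelError(f"scaffold {model.scaffold_id!r} not in reference genome")
    scaffold = scaffolds[model.scaffold_id]
    cds = assemble_cds(model, scaffold)
    exon_lengths = [e.length for e in model.transcript_exons]
    segments = split_peptide_by_exons(cds, exon_lengths)
    peptide, _ = translate(cds)
    # classify junctions by their boundary dinucleotides
    classes = []
    tx = model.transcript_exons
    for up, down in zip(tx, tx[1:]):
        donor, acceptor = _junction_dinucleotides(scaffold, model.strand, up, down)
        if donor == "GT" and acceptor == "AG":
            classes.append("canonical")
        elif donor == "GC" and acceptor == "AG":
            classes.append("gc_donor")
        else:
            classes.append("non_canonical")
    return ReferenceIsoformRecord(
        isoform_name=isoform_name,
        exon_count=len(model.exons),
        exon_peptides=tuple(segments),
        full_peptide=peptide,
        junction_classes=tuple(classes),
    )


def _junction_dinucleotides(
    scaffold: ScaffoldSequence, strand: str, up: CodingExon, down: CodingExon
) -> tuple[str, str]:
    """Donor and acceptor dinucleotides of the intron between two exons,
    read in transcript orientation."""
    if strand == "+":
        donor = scaffold.residues[up.interval.end : up.interval.end + 2]
        acceptor = scaffold.residues[down.interval.start - 3 : down.interval.start - 1]
    else:
        donor = reverse_complement(
            scaffold.residues[up.interval.start - 3 : up.interval.start - 1]
        )
        acceptor = reverse_complement(
            scaffold.residues[down.interval.end : down.interval.end + 2]
        )
    return donor, acceptor


# ---------------------------------------------------------------------------
# Annotation bundles and the merger

@dataclass(frozen=True)
class AnnotationBundle:
    """The GFF/FNA/FAA trio describing one submission's isoforms."""

    model_coordinates: str  # GFF text
    transcript_sequences: str  # FNA text
    peptide_sequences: str  # FAA text


def _fasta_text(records: Iterable[tuple[str, str]], width: int = 60) -> str:
    buf = io.StringIO()
    for name, seq in records:
        buf.write(f">{name}\n")
        for i in range(0, len(seq), width):
            buf.write(seq[i : i + width] + "\n")
    return buf.getvalue()


def build_bundle(
    models: Sequence[IsoformModel], scaffolds: Mapping[str, ScaffoldSequence]
) -> AnnotationBundle:
    """Serialize models plus their transcript and peptide sequences."""
    fna, faa = [], []
    for m in models:
        cds = assemble_cds(m, scaffolds[m.scaffold_id])
        pep, _ = translate(cds)
        fna.append((m.isoform_name, cds))
        faa.append((m.isoform_name, pep.rstrip("*")))
    return AnnotationBundle(
        model_coordinates=write_model_gff(models),
        transcript_sequences=_fasta_text(fna),
        peptide_sequences=_fasta_text(faa),
    )


def merge_annotation_files(bundles: Sequence[AnnotationBundle]) -> AnnotationBundle:
    """Combine per-isoform submissions into one bundle, collapsing isoforms
    with identical coding-exon coordinate sets to a single entry.

    Collapsed names are cross-referenced in a ``same_cds_as`` GFF attribute.
    The same isoform name with *different* coordinates across bundles is a
    conflict and raises.
    """
    if not bundles:
        raise ModelError("no bundles to merge")

    def _fasta_map(text: str) -> dict[str, str]:
        out: dict[str, str] = {}
        name = None
        for line in text.splitlines():
            if line.startswith(">"):
                name = line[1:].split()[0]
                out[name] = ""
            elif name is not None:
                out[name] += line.strip()
        return out

    kept: list[IsoformModel] = []
    by_name: dict[str, IsoformModel] = {}
    by_coords: dict[tuple, IsoformModel] = {}
    aliases: dict[str, list[str]] = {}
    fna_all: dict[str, str] = {}
    faa_all: dict[str, str] = {}
    for bundle in bundles:
        fna_all.update(_fasta_map(bundle.transcript_sequences))
        faa_all.update(_fasta_map(bundle.peptide_sequences))
        for model in parse_model_gff(bundle.model_coordinates):
            key = (model.scaffold_id, model.strand, model.exon_coordinate_set())
            prior = by_name.get(model.isoform_name)
            if prior is not None:
                prior_key = (
                    prior.scaffold_id, prior.strand, prior.exon_coordinate_set()
                )
                if prior_key != key:
                    raise ModelError(
                        f"conflict: isoform {model.isoform_name!r} submitted "
                        "with different coordinates across bundles"
                    )
                continue  # exact duplicate of an already-kept name
            by_name[model.isoform_name] = model
            if key in by_coords:
                holder = by_coords[key]
                aliases.setdefault(holder.isoform_name, []).append(
                    model.isoform_name
                )
                continue
            by_coords[key] = model
            kept.append(model)

    lines = ["##gff-version 3"]
    for m in kept:
        alias = aliases.get(m.isoform_name)
        alias_attr = f";same_cds_as={','.join(alias)}" if alias else ""
        for exon in m.exons:
            iv = exon.interval
            lines.append(
                "\t".join(
                    [
                        m.scaffold_id, "annokit", "CDS",
                        str(iv.start), str(iv.end), ".",
                        m.strand, ".",
                        f"ID=CDS:{m.isoform_name}:{exon.ordinal};"
                        f"Parent={m.isoform_name};gene={m.gene_symbol}"
                        + alias_attr,
                    ]
                )
            )
    names = [m.isoform_name for m in kept]
    return AnnotationBundle(
        model_coordinates="\n".join(lines) + "\n",
        transcript_sequences=_fasta_text(
            [(n, fna_all[n]) for n in names if n in fna_all]
        ),
        peptide_sequences=_fasta_text(
            [(n, faa_all[n]) for n in names if n in faa_all]
        ),
    )
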