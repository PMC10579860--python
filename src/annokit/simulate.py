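"""Deterministic synthetic-locus generator for curation testing.

Real curation needs a genome assembly, a reference annotation and
similarity evidence. For testing the toolkit end-to-end none of that is
required: this module generates scaffolds containing protein-coding loci
with known structure (exon/intron lengths, splice-site classes, strand,
start/stop codons), the matching reference records and gene neighborhoods,
and controlled corruptions of each error class the checker and the
reconciler are supposed to catch. Everything is seeded and byte-identical
across runs for a given spec.

Exon interiors are built from random non-stop codons, so a valid-mode
locus passes the checker by construction; intron interiors are random with
forced boundary dinucleotides. With ``clean_splice_windows`` set, competing
canonical splice-site motifs near the true boundaries are mutated away so
that boundary-refinement searches have a unique canonical answer inside
the window — the regime in which exact recovery is guaranteed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .checker import check_model
from .models import (
    IsoformModel,
    ReferenceIsoformRecord,
    assemble_cds,
    make_model,
    split_peptide_by_exons,
)
from .orthology import NeighborhoodMap
from .sequence import STOP_CODONS, ScaffoldSequence, reverse_complement
from .updater import SequenceEdit, apply_edits, lift_model, write_edits

_NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


class SimulationError(ValueError):
    """Raised when a locus spec cannot be realized."""


@dataclass(frozen=True)
class SyntheticLocusSpec:
    """Blueprint of one synthetic locus.

    Sum of ``exon_lengths`` must be a multiple of three (a complete model
    from start through stop codon); introns must be at least 4 nt to hold
    both boundary dinucleotides. ``donor_classes`` gives the donor
    dinucleotide per junction (default all GT). With
    ``skip_exon_isoform`` set to an internal exon ordinal whose length is
    a multiple of three, a second isoform (-PB) skipping that exon is
    generated alongside the full-length -PA.
    """

    seed: int = 0
    exon_lengths: tuple[int, ...] = (90, 120, 75)
    intron_lengths: tuple[int, ...] = (60, 55)
    strand: str = "+"
    donor_classes: tuple[str, ...] = ()
    start_codon: str = "ATG"
    stop_codon: str = "TAA"
    gc_content: float = 0.45
    flank_length: int = 120
    gene_symbol: str = "genA"
    scaffold_id: str = "scaffold_1"
    assembly_id: str = "synth1"
    clean_splice_windows: int = 0
    skip_exon_isoform: Optional[int] = None
    nested_host: Optional[str] = None
    coordinate_offset: int = 0

    def __post_init__(self) -> None:
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise SimulationError("need exactly one intron per adjacent exon pair")
        if sum(self.exon_lengths) % 3 != 0:
            raise SimulationError("total exon length must be divisible by three")
        if sum(self.exon_lengths) < 9:
            raise SimulationError("CDS must hold at least start, one codon, stop")
        if any(l < 1 for l in self.exon_lengths):
            raise SimulationError("exon lengths must be positive")
        if any(l < 4 for l in self.intron_lengths):
            raise SimulationError("introns must be >= 4 nt (both dinucleotides)")
        if self.strand not in ("+", "-"):
            raise SimulationError("strand must be '+' or '-'")
        donors = self.donor_classes or ("GT",) * len(self.intron_lengths)
        if len(donors) != len(self.intron_lengths):
            raise SimulationError("one donor class per junction required")
        if any(d not in ("GT", "GC") for d in donors):
            raise SimulationError("donor classes limited to GT and GC")
        object.__setattr__(self, "donor_classes", donors)
        if self.skip_exon_isoform is not None:
            k = self.skip_exon_isoform
            if not (1 < k < len(self.exon_lengths)):
                raise SimulationError("skip_exon_isoform must be an internal exon")
            if self.exon_lengths[k - 1] % 3 != 0:
                raise SimulationError(
                    "skipped exon length must be divisible by three so both "
                    "isoforms stay in frame"
                )


@dataclass(frozen=True)
class LocusBundle:
    """Everything generate_locus knows about the locus it made."""

    spec: SyntheticLocusSpec
    scaffold: ScaffoldSequence
    models: tuple[IsoformModel, ...]
    reference_records: dict[str, ReferenceIsoformRecord]
    neighborhood: NeighborhoodMap
    cds: dict[str, str]
    peptides: dict[str, str]

    @property
    def model(self) -> IsoformModel:
        return self.models[0]

    @property
    def reference_record(self) -> ReferenceIsoformRecord:
        return self.reference_records[self.model.isoform_name]


def _random_base(rng: random.Random, gc: float) -> str:
    if rng.random() < gc:
        return rng.choice("GC")
    return rng.choice("AT")


def _random_seq(rng: random.Random, n: int, gc: float) -> str:
    return "".join(_random_base(rng, gc) for _ in range(n))


def _random_cds(rng: random.Random, spec: SyntheticLocusSpec) -> str:
    total = sum(spec.exon_lengths)
    n_mid = total // 3 - 2
    mid = "".join(rng.choice(_NON_STOP_CODONS) for _ in range(n_mid))
    return spec.start_codon + mid + spec.stop_codon


def _clean_windows(
    contig: list[str],
    spots: Sequence[tuple[int, int, tuple[str, ...], int]],
    protected: frozenset[int],
    rng: random.Random,
    max_rounds: int = 50,
) -> bool:
    """Mutate away competing splice/start motifs inside refinement windows.

    Each spot is (lo, hi, patterns, keep): scan 0-based contig positions
    lo..hi for any pattern occurrence not starting at ``keep`` and mutate
    one of its non-protected bases. Repeats until a round makes no change.
    """
    for _ in range(max_rounds):
        changed = False
        for lo, hi, patterns, keep in spots:
            for pat in patterns:
                plen = len(pat)
                for p in range(max(0, lo), min(len(contig) - plen, hi) + 1):
                    if p == keep:
                        continue
                    if "".join(contig[p : p + plen]) != pat:
                        continue
                    free = [i for i in range(p, p + plen) if i not in protected]
                    if not free:
                        return False
                    i = rng.choice(free)
                    contig[i] = rng.choice([b for b in "ACGT" if b != contig[i]])
                    changed = True
        if not changed:
            return True
    return False


def _build_contig(
    rng: random.Random, spec: SyntheticLocusSpec
) -> tuple[str, list[tuple[int, int]]]:
    """Transcript-orientation contig and 1-based (start, end) exon positions
    within it, or raises if a clean locus could not be realized."""
    cds = _random_cds(rng, spec)
    exon_seqs = []
    cursor = 0
    for length in spec.exon_lengths:
        exon_seqs.append(cds[cursor : cursor + length])
        cursor += length
    introns = [
        spec.donor_classes[i]
        + _random_seq(rng, spec.intron_lengths[i] - 4, spec.gc_content)
        + "AG"
        for i in range(len(spec.intron_lengths))
    ]
    pieces = [_random_seq(rng, spec.flank_length, spec.gc_content)]
    exon_pos: list[tuple[int, int]] = []
    t = spec.flank_length
    for i, exon in enumerate(exon_seqs):
        exon_pos.append((t + 1, t + len(exon)))
        pieces.append(exon)
        t += len(exon)
        if i < len(introns):
            pieces.append(introns[i])
            t += len(introns[i])
    pieces.append(_random_seq(rng, spec.flank_length, spec.gc_content))
    contig = list("".join(pieces))

    if spec.clean_splice_windows:
        w = spec.clean_splice_windows + 3  # cover perturbed approximations too
        protected: set[int] = set()
        s0 = exon_pos[0][0] - 1  # 0-based start-codon position
        protected.update(range(s0, s0 + 3))
        e_last = exon_pos[-1][1] - 1
        protected.update(range(e_last - 2, e_last + 1))
        spots: list[tuple[int, int, tuple[str, ...], int]] = []
        for i in range(len(exon_pos) - 1):
            d = exon_pos[i][1]  # 0-based donor dinucleotide start
            a = exon_pos[i + 1][0] - 3  # 0-based acceptor dinucleotide start
            protected.update((d, d + 1, a, a + 1))
            spots.append((d - w, d + w, ("GT", "GC"), d))
            spots.append((a - w, a + w, ("AG",), a))
        spots.append((s0 - w, s0 + w, ("ATG",), s0))
        if not _clean_windows(contig, spots, frozenset(protected), rng):
            raise SimulationError("could not clean splice windows")
    return "".join(contig), exon_pos


def generate_locus(spec: SyntheticLocusSpec, max_attempts: int = 200) -> LocusBundle:
    """Generate a scaffold with a valid gene model matching the spec.

    Deterministic for a given spec (seed included). The generated model(s)
    pass the checker; window cleaning or the skip-exon isoform can require
    rejection sampling, capped at ``max_attempts`` before erroring.
    """
    rng = random.Random(spec.seed)
    last_error: Optional[str] = None
    for _ in range(max_attempts):
        try:
            contig, exon_pos_t = _build_contig(rng, spec)
        except SimulationError as err:
            last_error = str(err)
            continue
        L = len(contig)
        if spec.strand == "+":
            forward = contig
            exon_pos = exon_pos_t
        else:
            forward = reverse_complement(contig)
            exon_pos = [(L - e + 1, L - s + 1) for s, e in exon_pos_t]
            exon_pos.reverse()  # ascending forward coordinates
        if spec.coordinate_offset:
            forward = "N" * spec.coordinate_offset + forward
            exon_pos = [
                (s + spec.coordinate_offset, e + spec.coordinate_offset)
                for s, e in exon_pos
            ]
        scaffold = ScaffoldSequence(spec.scaffold_id, forward)

        allowances: dict[str, object] = {}
        if spec.start_codon != "ATG":
            allowances["non_canonical_start"] = spec.start_codon
        names = {"PA": f"{spec.gene_symbol}-PA"}
        models = [
            make_model(
                spec.gene_symbol, names["PA"], spec.scaffold_id, spec.strand,
                exon_pos, assembly_id=spec.assembly_id, allowances=allowances,
            )
        ]
        if spec.skip_exon_isoform is not None:
            keep_t = [
                pos for i, pos in enumerate(exon_pos_t, start=1)
                if i != spec.skip_exon_isoform
            ]
            if spec.strand == "+":
                keep = keep_t
            else:
                keep = sorted((L - e + 1, L - s + 1) for s, e in keep_t)
            if spec.coordinate_offset:
                keep = [
                    (s + spec.coordinate_offset, e + spec.coordinate_offset)
                    for s, e in keep
                ]
            names["PB"] = f"{spec.gene_symbol}-PB"
            models.append(
                make_model(
                    spec.gene_symbol, names["PB"], spec.scaffold_id, spec.strand,
                    keep, assembly_id=spec.assembly_id,
                )
            )

        records: dict[str, ReferenceIsoformRecord] = {}
        cds_map: dict[str, str] = {}
        pep_map: dict[str, str] = {}
        ok = True
        for model in models:
            report = check_model(model, scaffold)
            if report.overall == "fail":
                ok = False
                last_error = (
                    f"{model.isoform_name}: {report.first_failure.message}"
                )
                break
            cds = assemble_cds(model, scaffold)
            lengths = [e.length for e in model.transcript_exons]
            segments = split_peptide_by_exons(cds, lengths)
            classes = []
            for i in range(len(lengths) - 1):
                donor = (
                    spec.donor_classes[i]
                    if model.isoform_name.endswith("-PA")
                    else "GT"
                )
                classes.append("canonical" if donor == "GT" else "gc_donor")
            records[model.isoform_name] = ReferenceIsoformRecord(
                isoform_name=model.isoform_name,
                exon_count=len(lengths),
                exon_peptides=tuple(segments),
                full_peptide=report.peptide,
                junction_classes=tuple(classes),
            )
            cds_map[model.isoform_name] = cds
            pep_map[model.isoform_name] = report.peptide
        if not ok:
            continue
        neighborhood = NeighborhoodMap(
            focal_gene=spec.gene_symbol,
            upstream=(
                (f"{spec.gene_symbol}_up1", rng.choice("+-")),
                (f"{spec.gene_symbol}_up2", rng.choice("+-")),
            ),
            downstream=(
                (f"{spec.gene_symbol}_dn1", rng.choice("+-")),
                (f"{spec.gene_symbol}_dn2", rng.choice("+-")),
            ),
            nested_in=spec.nested_host,
        )
        return LocusBundle(
            spec=spec,
            scaffold=scaffold,
            models=tuple(models),
            reference_records=records,
            neighborhood=neighborhood,
            cds=cds_map,
            peptides=pep_map,
        )
    raise SimulationError(
        f"could not realize locus spec after {max_attempts} attempts "
        f"(last problem: {last_error})"
    )


def locus_for_exon_coordinates(
    exon_coords: Sequence[tuple[int, int]],
    *,
    seed: int = 0,
    gene_symbol: str = "genA",
    scaffold_id: str = "scaffold_1",
    flank_length: int = 120,
    clean_splice_windows: int = 15,
) -> LocusBundle:
    """A plus-strand locus whose coding exons occupy exactly the given
    forward-strand coordinates (ascending, 1-based inclusive).

    Any sequence upstream of the locus window is padded with N, the way an
    unsequenced flank would appear, so published browser coordinates can be
    used verbatim as test inputs.
    """
    coords = sorted(exon_coords)
    exon_lengths = tuple(e - s + 1 for s, e in coords)
    intron_lengths = tuple(
        coords[i + 1][0] - coords[i][1] - 1 for i in range(len(coords) - 1)
    )
    offset = coords[0][0] - flank_length - 1
    if offset < 0:
        raise SimulationError(
            f"first exon at {coords[0][0]} leaves no room for a "
            f"{flank_length} nt flank"
        )
    spec = SyntheticLocusSpec(
        seed=seed,
        exon_lengths=exon_lengths,
        intron_lengths=intron_lengths,
        gene_symbol=gene_symbol,
        scaffold_id=scaffold_id,
        flank_length=flank_length,
        clean_splice_windows=clean_splice_windows,
        coordinate_offset=offset,
    )
    return generate_locus(spec)


# ---------------------------------------------------------------------------
# Controlled corruptions

CORRUPTION_KINDS = (
    "splice_shift",
    "drop_exon",
    "add_exon",
    "swap_isoform_labels",
    "relocate_locus",
    "consensus_indel",
)


@dataclass(frozen=True)
class CorruptionSpec:
    """One injected error. ``kind`` selects the class; the remaining fields
    parameterize it (unused ones are ignored)."""

    kind: str
    seed: int = 0
    junction: int = 1  # splice_shift: which junction's donor boundary
    shift: int = 1  # splice_shift: signed nt
    exon_ordinal: int = 2  # drop_exon / add_exon / consensus_indel target
    indel_length: int = 1  # consensus_indel: >0 deletes, <0 inserts

    def __post_init__(self) -> None:
        if self.kind not in CORRUPTION_KINDS:
            raise SimulationError(f"unknown corruption kind {self.kind!r}")


@dataclass(frozen=True)
class CorruptionResult:
    models: tuple[IsoformModel, ...]
    scaffold: ScaffoldSequence
    injected_class: str  # reconciliation category, or consensus_error
    repair_vcf: Optional[str]
    details: str


def _shift_exon_boundary(
    model: IsoformModel, junction: int, shift: int
) -> IsoformModel:
    """Move the donor-side boundary of the exon upstream of ``junction``
    by ``shift`` nt (transcript orientation)."""
    tx = list(model.transcript_exons)
    if not (1 <= junction <= len(tx) - 1):
        raise SimulationError(f"model has no junction {junction}")
    target = tx[junction - 1]
    iv = target.interval
    if model.strand == "+":
        new_iv = replace(iv, end=iv.end + shift)
    else:
        new_iv = replace(iv, start=iv.start - shift)
    coords = [
        (new_iv.start, new_iv.end) if e is target else (e.interval.start, e.interval.end)
        for e in model.exons
    ]
    return make_model(
        model.gene_symbol, model.isoform_name, model.scaffold_id, model.strand,
        coords, assembly_id=model.assembly_id, complete=model.complete,
        allowances=model.allowances,
    )


def corrupt_model(
    models: IsoformModel | Sequence[IsoformModel],
    scaffold: ScaffoldSequence,
    corruption: CorruptionSpec,
) -> CorruptionResult:
    """Apply one controlled corruption, returning the perturbed artifacts
    plus the truth record naming the injected error class.

    ``consensus_indel`` perturbs the scaffold instead of the model and also
    emits the repair VCF that restores the original sequence.
    """
    if isinstance(models, IsoformModel):
        model_list: list[IsoformModel] = [models]
    else:
        model_list = list(models)
    model = model_list[0]
    rng = random.Random(corruption.seed)
    kind = corruption.kind

    if kind == "splice_shift":
        shifted = _shift_exon_boundary(model, corruption.junction, corruption.shift)
        return CorruptionResult(
            (shifted, *model_list[1:]), scaffold, "splice_site", None,
            f"donor boundary of junction {corruption.junction} shifted "
            f"{corruption.shift:+d} nt",
        )

    if kind == "drop_exon":
        if len(model.exons) < 2:
            raise SimulationError("cannot drop an exon from a single-exon model")
        k = corruption.exon_ordinal
        coords = [
            (e.interval.start, e.interval.end)
            for e in model.transcript_exons
            if e.ordinal != k
        ]
        if len(coords) == len(model.exons):
            raise SimulationError(f"model has no exon ordinal {k}")
        dropped = make_model(
            model.gene_symbol, model.isoform_name, model.scaffold_id,
            model.strand, coords, assembly_id=model.assembly_id,
        )
        return CorruptionResult(
            (dropped, *model_list[1:]), scaffold, "exon_gain_loss", None,
            f"exon {k} dropped",
        )

    if kind == "add_exon":
        tx = list(model.transcript_exons)
        target = max(tx, key=lambda e: e.length)
        iv = target.interval
        if iv.length < 30:
            raise SimulationError("no exon long enough to split")
        cut = iv.start + iv.length // 2
        gap = 8  # carve a pseudo-intron out of the exon
        coords = [
            (e.interval.start, e.interval.end) for e in model.exons if e is not target
        ]
        coords += [(iv.start, cut - 1), (cut + gap, iv.end)]
        split = make_model(
            model.gene_symbol, model.isoform_name, model.scaffold_id,
            model.strand, coords, assembly_id=model.assembly_id,
        )
        return CorruptionResult(
            (split, *model_list[1:]), scaffold, "exon_gain_loss", None,
            f"exon {target.ordinal} split into two at {cut}",
        )

    if kind == "swap_isoform_labels":
        if len(model_list) < 2:
            raise SimulationError("label swap needs at least two isoforms")
        a, b = model_list[0], model_list[1]
        swapped = [
            replace(a, isoform_name=b.isoform_name),
            replace(b, isoform_name=a.isoform_name),
            *model_list[2:],
        ]
        return CorruptionResult(
            tuple(swapped), scaffold, "isoform_missing_mislabeled", None,
            f"labels {a.isoform_name} and {b.isoform_name} swapped",
        )

    if kind == "relocate_locus":
        span = model.span
        width = span.end - span.start + 1
        pad = max(10, width // 2)
        if span.end + width + pad <= len(scaffold):
            offset, target_scaffold = width + pad, model.scaffold_id
            detail = f"locus relocated by {offset:+d} nt"
        elif span.start - width - pad >= 1:
            offset, target_scaffold = -(width + pad), model.scaffold_id
            detail = f"locus relocated by {offset:+d} nt"
        else:
            # no room on this scaffold: the wrong locus sits elsewhere
            offset, target_scaffold = 0, f"{model.scaffold_id}_alt"
            detail = f"locus relocated to {target_scaffold}"
        coords = [
            (e.interval.start + offset, e.interval.end + offset)
            for e in model.exons
        ]
        moved = make_model(
            model.gene_symbol, model.isoform_name, target_scaffold,
            model.strand, coords, assembly_id=model.assembly_id,
        )
        return CorruptionResult(
            (moved, *model_list[1:]), scaffold, "ortholog_mismatch", None, detail,
        )

    # consensus_indel
    k = corruption.exon_ordinal
    by_ordinal = {e.ordinal: e for e in model.exons}
    if k not in by_ordinal:
        raise SimulationError(f"model has no exon ordinal {k}")
    iv = by_ordinal[k].interval
    n = abs(corruption.indel_length)
    if n < 1:
        raise SimulationError("indel length must be non-zero")
    if iv.length < n + 6:
        raise SimulationError(f"exon {k} too short for a {n}-nt indel")
    pos = rng.randrange(iv.start + 2, iv.end - n - 1)  # interior anchor
    seq = scaffold.residues
    anchor = seq[pos - 1]
    if corruption.indel_length > 0:
        # corruption deletes n bases after the anchor
        removed = seq[pos : pos + n]
        forward = SequenceEdit(pos, anchor + removed, anchor)
        repair = SequenceEdit(pos, anchor, anchor + removed)
        detail = f"{n}-nt deletion inside exon {k} at {pos + 1}"
    else:
        inserted = _random_seq(rng, n, 0.45)
        forward = SequenceEdit(pos, anchor, anchor + inserted)
        repair = SequenceEdit(pos, anchor + inserted, anchor)
        detail = f"{n}-nt insertion inside exon {k} at {pos + 1}"
    corrupted_scaffold, forward_map = apply_edits(scaffold, [forward])
    # models as an annotator would build them: on the flawed consensus
    lifted_models = tuple(lift_model(m, forward_map) for m in model_list)
    vcf = write_edits([repair], scaffold.id)
    return CorruptionResult(
        lifted_models, corrupted_scaffold, "consensus_error", vcf, detail
    )
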