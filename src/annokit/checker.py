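"""Gene-model validation: the biological-constraint checklist.

A proposed protein-coding model must begin with a start codon, end with a
stop codon, maintain an open reading frame across every splice junction,
and use canonical splice sites (GT donor / AG acceptor; the rare GC donor
draws a warning). Checklist items are ordered 5'->3' in transcript
orientation so that the first failing item points at the most upstream
defect — a single incompatible splice site shifts the reading frame of
everything downstream and typically cascades into in-frame stop codons and
a CDS length not divisible by three, so troubleshooting starts at the
first failure.

Splice phases follow the curator's definition: the donor phase is the
number of nucleotides between the end of the last complete codon and the
donor site; the acceptor phase is the number of nucleotides between the
acceptor site and the start of the first complete codon. A compatible
junction has donor + acceptor phase equal to 0 (no split codon) or 3 (one
codon split across the intron). Donor phases are anchored at the start
codon (prefix CDS length mod 3) and acceptor phases independently at the
stop codon (suffix CDS length mod 3), so a model whose total length is not
a multiple of three shows detectable phase incompatibility rather than
phases that agree by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .models import IsoformModel, ReferenceIsoformRecord, assemble_cds
from .sequence import (
    STOP_CODONS,
    GenomicInterval,
    ScaffoldSequence,
    SequenceError,
    reverse_complement,
    translate,
)

START_CODONS = frozenset({"ATG"})


class CheckerError(ValueError):
    """Raised for inputs the checker cannot evaluate."""


# ---------------------------------------------------------------------------
# Junctions and phases

@dataclass(frozen=True)
class IntronJunction:
    """Donor/acceptor dinucleotides and phases of one intron."""

    upstream_exon_ordinal: int
    donor_dinucleotide: str
    acceptor_dinucleotide: str
    donor_phase: int
    acceptor_phase: int

    @property
    def phase_sum(self) -> int:
        return self.donor_phase + self.acceptor_phase

    @property
    def phases_compatible(self) -> bool:
        return self.phase_sum in (0, 3)

    @property
    def canonical_class(self) -> str:
        if self.donor_dinucleotide == "GT" and self.acceptor_dinucleotide == "AG":
            return "canonical"
        if self.donor_dinucleotide == "GC" and self.acceptor_dinucleotide == "AG":
            return "gc_donor"
        return "non_canonical"


class _TranscriptView:
    """1-based transcript-orientation coordinate access to a scaffold.

    For minus-strand features, transcript position t maps to forward
    position L - t + 1 and bases are complemented, so all splice-site and
    frame logic can be written once, strand-free.
    """

    def __init__(self, scaffold: ScaffoldSequence, strand: str):
        self.scaffold = scaffold
        self.strand = strand
        self.length = len(scaffold)

    def to_transcript(self, forward_pos: int) -> int:
        if self.strand == "+":
            return forward_pos
        return self.length - forward_pos + 1

    def to_forward(self, t_pos: int) -> int:
        return self.to_transcript(t_pos)  # involution

    def slice(self, t_start: int, t_end: int) -> str:
        """Sequence between transcript positions t_start..t_end inclusive."""
        if t_start < 1 or t_end > self.length or t_start > t_end:
            raise SequenceError(
                f"transcript positions {t_start}-{t_end} out of bounds "
                f"(scaffold length {self.length})"
            )
        if self.strand == "+":
            return self.scaffold.residues[t_start - 1 : t_end]
        f_start = self.to_forward(t_end)
        f_end = self.to_forward(t_start)
        return reverse_complement(self.scaffold.residues[f_start - 1 : f_end])

    def exon_interval_t(self, iv: GenomicInterval) -> tuple[int, int]:
        """Transcript-coordinate (start, end) of a forward-coordinate exon."""
        if self.strand == "+":
            return iv.start, iv.end
        return self.to_transcript(iv.end), self.to_transcript(iv.start)


def compute_junctions(
    model: IsoformModel, scaffold: ScaffoldSequence
) -> list[IntronJunction]:
    """One junction per adjacent exon pair, in transcript order.

    Donor phase = cumulative CDS length through the upstream exon, mod 3.
    Acceptor phase = total CDS length of the downstream exons, mod 3
    (anchored at the stop codon), computed independently of the donor so
    that incompatible splice-site choices are detectable.
    """
    if model.scaffold_id != scaffold.id:
        raise CheckerError(
            f"model {model.isoform_name} is on {model.scaffold_id!r}, "
            f"not {scaffold.id!r}"
        )
    view = _TranscriptView(scaffold, model.strand)
    tx = model.transcript_exons
    lengths = [e.length for e in tx]
    total = sum(lengths)
    junctions: list[IntronJunction] = []
    cum = 0
    for k, (up, down) in enumerate(zip(tx, tx[1:]), start=1):
        cum += up.length
        up_s, up_e = view.exon_interval_t(up.interval)
        down_s, down_e = view.exon_interval_t(down.interval)
        if down_s - up_e < 2:
            raise CheckerError(
                f"{model.isoform_name}: intron {k} has zero or negative "
                f"length between exons ending {up_e} and starting {down_s} "
                "(transcript coordinates)"
            )
        donor = view.slice(up_e + 1, up_e + 2)
        acceptor = view.slice(down_s - 2, down_s - 1)
        junctions.append(
            IntronJunction(
                upstream_exon_ordinal=k,
                donor_dinucleotide=donor,
                acceptor_dinucleotide=acceptor,
                donor_phase=cum % 3,
                acceptor_phase=(total - cum) % 3,
            )
        )
    return junctions


# ---------------------------------------------------------------------------
# Checklist

@dataclass(frozen=True)
class ChecklistItem:
    key: str
    status: str  # pass | warn | fail
    message: str
    location: Optional[GenomicInterval] = None
    junction_ordinal: Optional[int] = None


@dataclass(frozen=True)
class ChecklistReport:
    """Ordered pass/warn/fail items plus the translated product."""

    items: tuple[ChecklistItem, ...]
    peptide: str
    cds_length: int

    @property
    def overall(self) -> str:
        if any(i.status == "fail" for i in self.items):
            return "fail"
        if any(i.status == "warn" for i in self.items):
            return "pass_with_warnings"
        return "pass"

    @property
    def first_failure(self) -> Optional[ChecklistItem]:
        for item in self.items:
            if item.status == "fail":
                return item
        return None

    def item(self, key: str) -> ChecklistItem:
        for it in self.items:
            if it.key == key:
                return it
        raise KeyError(key)

    def to_dict(self) -> dict:
        return {
            "overall": self.overall,
            "cds_length": self.cds_length,
            "peptide": self.peptide,
            "first_failure": self.first_failure.key if self.first_failure else None,
            "items": [
                {
                    "key": i.key,
                    "status": i.status,
                    "message": i.message,
                    "junction": i.junction_ordinal,
                }
                for i in self.items
            ],
        }


def _internal_stop_positions(
    exon_seq: str, leading: int, *, exclude_final: bool = False
) -> list[int]:
    """0-based offsets of stop codons among the exon's complete codons.

    ``leading`` nucleotides complete the codon split across the upstream
    junction and are skipped; with ``exclude_final`` the codon ending at
    the exon's last base is not reported (it is the stop-codon item's job).
    """
    stops = []
    end = len(exon_seq) - (len(exon_seq) - leading) % 3
    for i in range(leading, end - 2, 3):
        codon = exon_seq[i : i + 3]
        if codon in STOP_CODONS:
            if exclude_final and i + 3 == len(exon_seq):
                continue
            stops.append(i)
    return stops


def check_model(
    model: IsoformModel,
    scaffold: ScaffoldSequence,
    reference: Optional[ReferenceIsoformRecord] = None,
) -> ChecklistReport:
    """Evaluate the biological-constraint checklist for one isoform model.

    Items appear in transcript 5'->3' order: start codon; then per exon its
    internal-stop item followed by its downstream junction's donor,
    acceptor and phase-compatibility items; then the stop codon and the
    global length-divisibility and exon-count items. ``overall`` is fail
    iff any item fails; declared allowances demote specific failures to
    warnings; an incomplete model demotes start/stop items to warnings.
    """
    cds = assemble_cds(model, scaffold)
    junctions = compute_junctions(model, scaffold)
    allowances = model.allowances
    tx = model.transcript_exons
    items: list[ChecklistItem] = []

    def add(key, status, message, junction=None, location=None):
        items.append(ChecklistItem(key, status, message, location, junction))

    # start codon
    start = cds[:3]
    if start in START_CODONS:
        add("start_codon", "pass", f"starts with {start}")
    elif not model.complete:
        add("start_codon", "warn", f"incomplete model; first codon {start}")
    elif allowances.get("non_canonical_start") == start:
        add(
            "start_codon", "warn",
            f"non-canonical start codon {start} declared as allowance",
        )
    else:
        add("start_codon", "fail", f"first codon {start} is not ATG")

    allowed_donors = {
        (ordinal, dinuc)
        for ordinal, dinuc in allowances.get("non_canonical_donor", ())
    }
    allowed_acceptors = {
        (ordinal, dinuc)
        for ordinal, dinuc in allowances.get("non_canonical_acceptor", ())
    }

    # per-exon and per-junction items, 5'->3'
    cum = 0
    for idx, exon in enumerate(tx):
        exon_seq = cds[cum : cum + exon.length]
        leading = (3 - cum % 3) % 3
        is_last = idx == len(tx) - 1
        stops = _internal_stop_positions(exon_seq, leading, exclude_final=is_last)
        key = f"internal_stops:{exon.ordinal}"
        if stops:
            status = "warn" if allowances.get("stop_readthrough") else "fail"
            add(
                key, status,
                f"exon {exon.ordinal}: in-frame stop codon(s) at exon "
                f"offset(s) {[s + 1 for s in stops]}",
                location=exon.interval,
            )
        else:
            add(key, "pass", f"exon {exon.ordinal}: no internal stop codons",
                location=exon.interval)
        cum += exon.length
        if is_last:
            break
        j = junctions[idx]
        k = j.upstream_exon_ordinal
        if j.donor_dinucleotide == "GT":
            add(f"donor_site:{k}", "pass", f"canonical GT donor", junction=k)
        elif j.donor_dinucleotide == "GC":
            add(
                f"donor_site:{k}", "warn",
                "non-canonical GC donor (rare but naturally occurring)",
                junction=k,
            )
        elif (k, j.donor_dinucleotide) in allowed_donors:
            add(
                f"donor_site:{k}", "warn",
                f"non-canonical {j.donor_dinucleotide} donor declared as "
                "allowance", junction=k,
            )
        else:
            add(
                f"donor_site:{k}", "fail",
                f"non-canonical {j.donor_dinucleotide} donor", junction=k,
            )
        if j.acceptor_dinucleotide == "AG":
            add(f"acceptor_site:{k}", "pass", "canonical AG acceptor", junction=k)
        elif (k, j.acceptor_dinucleotide) in allowed_acceptors:
            add(
                f"acceptor_site:{k}", "warn",
                f"non-canonical {j.acceptor_dinucleotide} acceptor declared "
                "as allowance", junction=k,
            )
        else:
            add(
                f"acceptor_site:{k}", "fail",
                f"non-canonical {j.acceptor_dinucleotide} acceptor", junction=k,
            )
        if j.phases_compatible:
            add(
                f"phase_compat:{k}", "pass",
                f"donor phase {j.donor_phase} + acceptor phase "
                f"{j.acceptor_phase} = {j.phase_sum}", junction=k,
            )
        else:
            add(
                f"phase_compat:{k}", "fail",
                f"incompatible phases: donor {j.donor_phase} + acceptor "
                f"{j.acceptor_phase} = {j.phase_sum} (must be 0 or 3)",
                junction=k,
            )

    # stop codon
    final = cds[-3:]
    if final in STOP_CODONS:
        add("stop_codon", "pass", f"ends with stop codon {final}")
    elif not model.complete:
        add("stop_codon", "warn", f"incomplete model; final codon {final}")
    else:
        add("stop_codon", "fail", f"final codon {final} is not a stop codon")

    # global items
    if len(cds) % 3 == 0:
        add("length_divisible_by_3", "pass", f"CDS length {len(cds)} nt")
    else:
        add(
            "length_divisible_by_3", "fail",
            f"CDS length {len(cds)} nt is not divisible by three",
        )
    if reference is None:
        add("exon_count_match", "warn", "no reference record supplied; skipped")
    elif len(model.exons) == reference.exon_count:
        add("exon_count_match", "pass", f"{len(model.exons)} coding exons")
    else:
        add(
            "exon_count_match", "fail",
            f"model has {len(model.exons)} coding exons, reference "
            f"{reference.isoform_name} has {reference.exon_count}",
        )

    peptide, _ = translate(cds)
    return ChecklistReport(items=tuple(items), peptide=peptide, cds_length=len(cds))


def diagnose_first_failure(report: ChecklistReport) -> Optional[ChecklistItem]:
    """The 5'-most failing checklist item, or None when nothing fails.

    Troubleshooting starts at the beginning of the gene: correcting the
    most upstream error usually resolves the cascade of failures reported
    downstream of it.
    """
    return report.first_failure


# ---------------------------------------------------------------------------
# Boundary refinement

@dataclass(frozen=True)
class RefinedExon:
    """Result of refining one exon's approximate boundaries."""

    interval: GenomicInterval
    start_shift: int  # refined - approximate, forward-strand coordinates
    end_shift: int
    justification: str


def refine_boundary(
    approx_exon: GenomicInterval,
    role: str,
    cds_length_before: int,
    scaffold: ScaffoldSequence,
    window: int = 15,
    *,
    allow_gc_donor: bool = False,
    start_codons: Iterable[str] = START_CODONS,
    expected_length_mod: Optional[int] = None,
) -> RefinedExon:
    """Refine an exon's approximate boundaries to the nearest coordinates
    satisfying the splice-site and reading-frame constraints.

    Approximate coordinates from a similarity search cover only complete
    codons, so they routinely miss the 1-2 nucleotides of a codon split
    across a junction and may over- or under-shoot a splice site. Within
    ``window`` nt of each approximate boundary this searches for a
    (start, end) pair such that: an initial exon starts at a start codon,
    an internal/terminal exon start immediately follows an AG acceptor;
    an initial/internal exon end immediately precedes a GT donor (GC when
    allowed); a terminal exon ends exactly at an in-frame stop codon; and
    no in-frame stop codon appears inside the exon given the running
    reading frame (``cds_length_before`` = spliced CDS nucleotides 5' of
    this exon). Among valid candidates the minimal total absolute shift
    wins; ties prefer extension over truncation.

    ``expected_length_mod``, when given (e.g. from the reference exon's
    known donor phase), additionally constrains the refined exon length
    modulo 3.
    """
    if role not in ("initial", "internal", "terminal"):
        raise CheckerError(f"unknown exon role {role!r}")
    if window < 0:
        raise CheckerError("window must be >= 0")
    view = _TranscriptView(scaffold, approx_exon.strand)
    t_start, t_end = view.exon_interval_t(approx_exon)
    starts = set(c.upper() for c in start_codons)
    leading = 0 if role == "initial" else (3 - cds_length_before % 3) % 3

    best: Optional[tuple[tuple[int, int, int], int, int]] = None
    for ds in range(-window, window + 1):
        s = t_start + ds
        if role == "initial":
            if s < 1 or s + 2 > view.length:
                continue
            if view.slice(s, s + 2) not in starts:
                continue
        else:
            if s < 3:  # need room for the upstream acceptor dinucleotide
                continue
            if view.slice(s - 2, s - 1) != "AG":
                continue
        for de in range(-window, window + 1):
            e = t_end + de
            needs_donor = role != "terminal"
            if e <= s or e + (2 if needs_donor else 0) > view.length:
                continue
            length = e - s + 1
            if length <= leading:
                continue
            if expected_length_mod is not None and length % 3 != expected_length_mod:
                continue
            exon_seq = view.slice(s, e)
            if role == "terminal":
                if (length - leading) % 3 != 0:
                    continue
                if exon_seq[-3:] not in STOP_CODONS:
                    continue
                if _internal_stop_positions(exon_seq, leading, exclude_final=True):
                    continue
            else:
                donor = view.slice(e + 1, e + 2)
                if donor != "GT" and not (allow_gc_donor and donor == "GC"):
                    continue
                if _internal_stop_positions(exon_seq, leading):
                    continue
            # rank: minimal total shift; ties prefer the longer exon, then
            # the more upstream start (deterministic)
            rank = (abs(ds) + abs(de), -length, s)
            if best is None or rank < best[0]:
                best = (rank, s, e)

    if best is None:
        raise CheckerError(
            f"no valid boundary candidate within +/-{window} nt of "
            f"{approx_exon.start}-{approx_exon.end}; widen the window or "
            "declare a non-canonical site"
        )
    _, s, e = best
    if approx_exon.strand == "+":
        f_start, f_end = s, e
        start_shift, end_shift = s - t_start, e - t_end
    else:
        f_start, f_end = view.to_forward(e), view.to_forward(s)
        start_shift = f_start - approx_exon.start
        end_shift = f_end - approx_exon.end
    refined = GenomicInterval(
        approx_exon.scaffold_id, f_start, f_end, approx_exon.strand
    )
    just = (
        f"{role} exon refined by (start {start_shift:+d}, end {end_shift:+d}) nt "
        f"to {f_start}-{f_end}"
    )
    return RefinedExon(refined, start_shift, end_shift, just)


def refine_model(
    approx_exons: Sequence[GenomicInterval],
    scaffold: ScaffoldSequence,
    window: int = 15,
    *,
    allow_gc_donor: bool = False,
    start_codons: Iterable[str] = START_CODONS,
) -> list[RefinedExon]:
    """Refine every exon of a model 5'->3', propagating the reading frame.

    ``approx_exons`` are given in transcript order; each refined exon's
    length feeds the running frame used to refine the next one.
    """
    refined: list[RefinedExon] = []
    cds_before = 0
    n = len(approx_exons)
    for i, approx in enumerate(approx_exons):
        role = "initial" if i == 0 else ("terminal" if i == n - 1 else "internal")
        result = refine_boundary(
            approx, role, cds_before, scaffold, window,
            allow_gc_donor=allow_gc_donor, start_codons=start_codons,
        )
        refined.append(result)
        cds_before += len(result.interval)
    return refined


# ---------------------------------------------------------------------------
# Peptide comparison (dot plot + global alignment)

@dataclass(frozen=True)
class GapAnomaly:
    """A long gap run in the alignment — a signature of a wrong splice
    site, or of a missing or extra exon."""

    in_sequence: str  # 'model' or 'reference'
    start_column: int
    length: int


@dataclass(frozen=True)
class PeptideComparison:
    dotplot: np.ndarray
    aligned_model: str
    aligned_reference: str
    score: float
    percent_identity: float
    gap_anomalies: tuple[GapAnomaly, ...]


def dot_plot_matrix(a: str, b: str, word_size: int = 3) -> np.ndarray:
    """Binary matrix of exact word matches: M[i, j] = 1 iff
    a[i:i+word_size] == b[j:j+word_size]."""
    rows = max(len(a) - word_size + 1, 0)
    cols = max(len(b) - word_size + 1, 0)
    m = np.zeros((rows, cols), dtype=bool)
    words: dict[str, list[int]] = {}
    for j in range(cols):
        words.setdefault(b[j : j + word_size], []).append(j)
    for i in range(rows):
        for j in words.get(a[i : i + word_size], ()):
            m[i, j] = True
    return m


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def compare_peptides(
    model_peptide: str,
    reference_peptide: str,
    word_size: int = 3,
    gap_anomaly_min: int = 5,
) -> PeptideComparison:
    """Compare the proposed model's peptide with the reference ortholog's.

    Returns the exact-word dot-plot matrix, a BLOSUM62 global alignment
    with affine gaps (open -11, extend -1), percent identity over aligned
    columns, and gap runs of at least ``gap_anomaly_min`` residues flagged
    as anomalies — large gaps usually indicate a wrong splice site or a
    missing/extra exon rather than real divergence.
    """
    if not model_peptide or not reference_peptide:
        raise CheckerError("both peptides must be non-empty")
    model_peptide = model_peptide.rstrip("*")
    reference_peptide = reference_peptide.rstrip("*")
    aligner = _make_aligner()
    alignment = aligner.align(model_peptide, reference_peptide)[0]
    a_row, b_row = str(alignment[0]), str(alignment[1])
    matches = sum(
        1 for x, y in zip(a_row, b_row) if x == y and x != "-"
    )
    identity = 100.0 * matches / len(a_row)

    anomalies: list[GapAnomaly] = []
    for name, row in (("model", a_row), ("reference", b_row)):
        col = 0
        while col < len(row):
            if row[col] == "-":
                run = col
                while run < len(row) and row[run] == "-":
                    run += 1
                if run - col >= gap_anomaly_min:
                    anomalies.append(GapAnomaly(name, col + 1, run - col))
                col = run
            else:
                col += 1
    return PeptideComparison(
        dotplot=dot_plot_matrix(model_peptide, reference_peptide, word_size),
        aligned_model=a_row,
        aligned_reference=b_row,
        score=float(alignment.score),
        percent_identity=identity,
        gap_anomalies=tuple(anomalies),
    )
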