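"""Reconciliation: compare independently built models of the same gene and
classify their discrepancies.

When two annotators model the same gene independently, a third curator
reconciles the submissions. Differences fall into four classes: a wrong
ortholog (the models are not even at the same locus), an extra or missing
coding exon, a different splice-site choice, or a missing/mislabeled
isoform. Classification here uses a fixed precedence — locus disagreement
over exon count over boundary offsets — so every comparison gets exactly
one category; additional co-occurring differences are noted in the details.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .checker import compare_peptides
from .models import IsoformModel, ReferenceIsoformRecord, assemble_cds
from .sequence import ScaffoldSequence, translate

CATEGORIES = (
    "congruent",
    "splice_site",
    "exon_gain_loss",
    "isoform_missing_mislabeled",
    "ortholog_mismatch",
)


class ReconciliationError(ValueError):
    """Raised for incomparable submissions."""


@dataclass(frozen=True)
class DiscrepancyReport:
    """Classified difference between two models of one isoform."""

    gene_symbol: str
    isoform_name: str
    category: str
    boundary_diffs: tuple[tuple[int, int], ...] = ()  # per-exon (dstart, dend)
    details: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ReconciliationError(f"unknown category {self.category!r}")


def _spans_overlap(a: IsoformModel, b: IsoformModel) -> bool:
    if a.scaffold_id != b.scaffold_id:
        return False
    sa, sb = a.span, b.span
    return sa.start <= sb.end and sb.start <= sa.end


def compare_models(model_a: IsoformModel, model_b: IsoformModel) -> DiscrepancyReport:
    """Classify the difference between two models of the same isoform.

    Precedence: different scaffold or non-overlapping genomic spans ->
    ortholog_mismatch; differing exon counts -> exon_gain_loss; equal
    counts with any boundary offset -> splice_site with per-boundary signed
    offsets (b minus a); identical -> congruent.
    """
    if model_a.assembly_id != model_b.assembly_id:
        raise ReconciliationError(
            f"models are on different assemblies "
            f"({model_a.assembly_id!r} vs {model_b.assembly_id!r})"
        )
    gene = model_a.gene_symbol
    name = model_a.isoform_name
    if not _spans_overlap(model_a, model_b):
        return DiscrepancyReport(
            gene, name, "ortholog_mismatch",
            details=f"non-overlapping loci {model_a.scaffold_id}:"
            f"{model_a.span.start}-{model_a.span.end} vs "
            f"{model_b.scaffold_id}:{model_b.span.start}-{model_b.span.end}",
        )
    if len(model_a.exons) != len(model_b.exons):
        return DiscrepancyReport(
            gene, name, "exon_gain_loss",
            details=f"{len(model_a.exons)} vs {len(model_b.exons)} coding exons",
        )
    diffs = tuple(
        (eb.interval.start - ea.interval.start, eb.interval.end - ea.interval.end)
        for ea, eb in zip(model_a.exons, model_b.exons)
    )
    if any(ds or de for ds, de in diffs):
        n_bound = sum((ds != 0) + (de != 0) for ds, de in diffs)
        return DiscrepancyReport(
            gene, name, "splice_site", boundary_diffs=diffs,
            details=f"{n_bound} boundary offset(s)",
        )
    return DiscrepancyReport(gene, name, "congruent", boundary_diffs=diffs)


def _structure_matches(
    model: IsoformModel,
    record: ReferenceIsoformRecord,
    scaffold: Optional[ScaffoldSequence],
    min_identity: float = 95.0,
) -> bool:
    """Does a model's structure match a reference isoform's signature
    (exon count, peptide length, and high peptide identity when sequence
    is available)?"""
    if len(model.exons) != record.exon_count:
        return False
    if scaffold is None:
        return True
    peptide, _ = translate(assemble_cds(model, scaffold))
    peptide = peptide.rstrip("*")
    ref_pep = record.full_peptide.rstrip("*")
    if not peptide or not ref_pep:
        return False
    if abs(len(peptide) - len(ref_pep)) > max(2, 0.05 * len(ref_pep)):
        return False
    return compare_peptides(peptide, ref_pep).percent_identity >= min_identity


def compare_isoform_sets(
    submission_a: Sequence[IsoformModel],
    submission_b: Sequence[IsoformModel],
    reference_isoform_names: Sequence[str],
    *,
    reference_records: Optional[Mapping[str, ReferenceIsoformRecord]] = None,
    scaffold: Optional[ScaffoldSequence] = None,
) -> list[DiscrepancyReport]:
    """Compare two whole submissions isoform by isoform.

    An isoform present in one submission but absent from the other is
    flagged ``isoform_missing_mislabeled``, as is an isoform whose label
    points at one reference isoform while its structure (exon count and
    peptide signature) matches a different one. Isoforms present in both
    are classified with :func:`compare_models`.
    """
    a_by_name = {m.isoform_name: m for m in submission_a}
    b_by_name = {m.isoform_name: m for m in submission_b}
    reports: list[DiscrepancyReport] = []
    names = list(reference_isoform_names)
    for name in sorted(set(a_by_name) | set(b_by_name), key=lambda n: (
        names.index(n) if n in names else len(names), n)):
        ma, mb = a_by_name.get(name), b_by_name.get(name)
        if ma is None or mb is None:
            present = ma or mb
            missing_from = "A" if ma is None else "B"
            reports.append(
                DiscrepancyReport(
                    present.gene_symbol, name, "isoform_missing_mislabeled",
                    details=f"isoform absent from submission {missing_from}",
                )
            )
            continue
        mislabeled = False
        if reference_records:
            own = reference_records.get(name)
            for other_name, other_rec in reference_records.items():
                if other_name == name:
                    continue
                for model in (ma, mb):
                    if _structure_matches(model, other_rec, scaffold) and not (
                        own and _structure_matches(model, own, scaffold)
                    ):
                        mislabeled = True
                        reports.append(
                            DiscrepancyReport(
                                model.gene_symbol, name,
                                "isoform_missing_mislabeled",
                                details=f"labeled {name} but structure matches "
                                f"reference isoform {other_name}",
                            )
                        )
                        break
                if mislabeled:
                    break
        if not mislabeled:
            reports.append(compare_models(ma, mb))
    return reports


@dataclass(frozen=True)
class CongruenceSummary:
    n_models: int
    n_congruent: int
    percent_congruent: int
    error_category_percent: Mapping[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_models": self.n_models,
            "n_congruent": self.n_congruent,
            "percent_congruent": self.percent_congruent,
            "error_category_percent": dict(self.error_category_percent),
        }


def summarize_error_rates(reports: Sequence[DiscrepancyReport]) -> CongruenceSummary:
    """Percent congruent over all reports and, over the non-congruent ones,
    each error category's share, rounded to whole percent."""
    if not reports:
        raise ReconciliationError("no reports to summarize")
    n = len(reports)
    n_congruent = sum(1 for r in reports if r.category == "congruent")
    errors = [r for r in reports if r.category != "congruent"]
    shares: dict[str, int] = {}
    if errors:
        for cat in CATEGORIES[1:]:
            count = sum(1 for r in errors if r.category == cat)
            shares[cat] = round(100 * count / len(errors))
    return CongruenceSummary(
        n_models=n,
        n_congruent=n_congruent,
        percent_congruent=round(100 * n_congruent / n),
        error_category_percent=shares,
    )
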