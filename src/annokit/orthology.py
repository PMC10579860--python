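"""Ortholog assignment support: reciprocal best hits and local synteny.

The ortholog of a gene in a newly assembled genome is proposed from
sequence similarity and confirmed by local synteny — conservation of the
identity, order, orientation and nesting of the nearest flanking genes.
This module consumes evidence that was produced elsewhere: 12-column
tab-separated similarity hit tables (the standard tabular output dialect:
qseqid sseqid pident length mismatch gapopen qstart qend sstart send
evalue bitscore) and gene-neighborhood maps; it never runs an aligner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .sequence import GenomicInterval

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


class OrthologyError(ValueError):
    """Raised for unusable orthology evidence."""


def read_hit_table(source: str | Path) -> pd.DataFrame:
    """Read a 12-column tab-separated hit table."""
    df = pd.read_csv(source, sep="\t", header=None, comment="#")
    if df.shape[1] != len(HIT_COLUMNS):
        raise OrthologyError(
            f"expected {len(HIT_COLUMNS)} tab-separated columns, "
            f"got {df.shape[1]}"
        )
    df.columns = HIT_COLUMNS
    return df


def best_hits(table: pd.DataFrame) -> dict[str, str]:
    """Best subject per query: lowest e-value, ties broken by highest bit
    score, then highest percent identity, then input order."""
    best: dict[str, str] = {}
    if table.empty:
        return best
    ranked = table.reset_index().sort_values(
        by=["evalue", "bitscore", "pident", "index"],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    for row in ranked.itertuples():
        if row.qseqid not in best:
            best[row.qseqid] = row.sseqid
    return best


@dataclass(frozen=True)
class RBHResult:
    pairs: tuple[tuple[str, str], ...]
    unpaired: tuple[tuple[str, str], ...]  # (id, reason)


def reciprocal_best_hits(
    forward_hits: pd.DataFrame, reverse_hits: pd.DataFrame
) -> RBHResult:
    """Ortholog pairs by the reciprocal-best-hits strategy.

    A pair (a, b) is emitted iff a's best hit in the forward table is b and
    b's best hit in the reverse table is a. Queries of either table that do
    not end up in a pair are flagged with the reason. Empty tables give an
    empty result.
    """
    fwd = best_hits(forward_hits)
    rev = best_hits(reverse_hits)
    pairs: list[tuple[str, str]] = []
    unpaired: list[tuple[str, str]] = []
    for a, b in fwd.items():
        if b not in rev:
            unpaired.append((a, f"best hit {b} has no hits in reverse table"))
        elif rev[b] != a:
            unpaired.append((a, f"best hit {b} reciprocates to {rev[b]}"))
        else:
            pairs.append((a, b))
    paired_b = {b for _, b in pairs}
    for b, a in rev.items():
        if b in paired_b:
            continue
        if a not in fwd:
            unpaired.append((b, f"best hit {a} has no hits in forward table"))
        else:
            unpaired.append((b, f"best hit {a} reciprocates to {fwd[a]}"))
    return RBHResult(pairs=tuple(sorted(pairs)), unpaired=tuple(sorted(unpaired)))


# ---------------------------------------------------------------------------
# Local synteny

@dataclass(frozen=True)
class NeighborhoodMap:
    """The nearest flanking genes of a locus, nearest-first, plus nesting.

    The protocol records the nearest two genes on each side with their
    orientations relative to the focal gene, whether the focal gene is
    nested inside a host gene's span, and any genes nested within the
    focal gene's span.
    """

    focal_gene: str
    upstream: tuple[tuple[str, str], ...] = ()
    downstream: tuple[tuple[str, str], ...] = ()
    nested_in: Optional[str] = None
    nested_genes: tuple[str, ...] = ()
    depth: int = 2

    def __post_init__(self) -> None:
        for side, genes in (("upstream", self.upstream), ("downstream", self.downstream)):
            if len(genes) > self.depth:
                raise OrthologyError(
                    f"{side} list longer than neighborhood depth {self.depth}"
                )
            for _, orient in genes:
                if orient not in ("+", "-"):
                    raise OrthologyError(f"orientation must be '+'/'-', got {orient!r}")

    @property
    def is_empty(self) -> bool:
        return not (self.upstream or self.downstream or self.nested_in
                    or self.nested_genes)

    def to_json(self) -> str:
        return json.dumps(
            {
                "focal_gene": self.focal_gene,
                "upstream": [list(g) for g in self.upstream],
                "downstream": [list(g) for g in self.downstream],
                "nested_in": self.nested_in,
                "nested_genes": list(self.nested_genes),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "NeighborhoodMap":
        d = json.loads(text)
        return cls(
            focal_gene=d["focal_gene"],
            upstream=tuple((g, o) for g, o in d.get("upstream", [])),
            downstream=tuple((g, o) for g, o in d.get("downstream", [])),
            nested_in=d.get("nested_in"),
            nested_genes=tuple(d.get("nested_genes", ())),
        )


@dataclass(frozen=True)
class SyntenyVerdict:
    status: str  # conserved | partial | not_conserved | not_assessable
    matched_neighbors: int
    orientation_matches: int
    nesting_consistent: bool
    details: str = ""


def assess_local_synteny(
    reference_map: NeighborhoodMap, target_map: NeighborhoodMap
) -> SyntenyVerdict:
    """Compare two gene neighborhoods position-wise, nearest-first.

    ``conserved`` requires all four flanking genes to match with their
    orientations and consistent nesting; ``partial`` at least two matched
    neighbors; anything less is ``not_conserved``. Two empty maps are
    ``not_assessable``.
    """
    if reference_map.is_empty and target_map.is_empty:
        return SyntenyVerdict("not_assessable", 0, 0, False,
                              "both neighborhood maps are empty")
    matched = 0
    oriented = 0
    total_slots = 0
    for side in ("upstream", "downstream"):
        ref_side = getattr(reference_map, side)
        tgt_side = getattr(target_map, side)
        total_slots += max(len(ref_side), len(tgt_side))
        for (rg, ro), (tg, to) in zip(ref_side, tgt_side):
            if rg == tg:
                matched += 1
                if ro == to:
                    oriented += 1
    nesting = (
        reference_map.nested_in == target_map.nested_in
        and set(reference_map.nested_genes) == set(target_map.nested_genes)
    )
    if matched == 4 and oriented == 4 and nesting:
        status = "conserved"
    elif matched >= 2:
        status = "partial"
    else:
        status = "not_conserved"
    return SyntenyVerdict(
        status=status,
        matched_neighbors=matched,
        orientation_matches=oriented,
        nesting_consistent=nesting,
        details=f"{matched}/{total_slots} neighbors matched, "
        f"{oriented} with orientation; nesting "
        f"{'consistent' if nesting else 'inconsistent'}",
    )


# ---------------------------------------------------------------------------
# Resolving similarity/synteny disagreement

@dataclass(frozen=True)
class LocusDecision:
    decision: str  # accept_hit | prefer_synteny | conflict
    hit_locus: Optional[GenomicInterval]
    synteny_locus: Optional[GenomicInterval]
    rationale: str


def _overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.scaffold_id == b.scaffold_id and a.start <= b.end and b.start <= a.end


def resolve_ambiguous_locus(
    best_hit_locus: Optional[GenomicInterval],
    synteny_locus: Optional[GenomicInterval],
) -> LocusDecision:
    """Arbitrate between the best similarity hit and the synteny-implied
    location of an ortholog.

    Agreement (overlapping spans on one scaffold) accepts the hit; a
    missing hit defers to synteny; disagreement is reported as a conflict
    with both loci for curator review — similarity alone can land on the
    wrong paralog, and the protocol leaves the final call to a human.
    """
    if best_hit_locus is None and synteny_locus is None:
        raise OrthologyError("neither a best hit nor a synteny locus was given")
    if synteny_locus is None:
        return LocusDecision(
            "accept_hit", best_hit_locus, None,
            "no synteny evidence; accepting the best similarity hit",
        )
    if best_hit_locus is None:
        return LocusDecision(
            "prefer_synteny", None, synteny_locus,
            "no similarity hit; location implied by conserved local synteny",
        )
    if _overlap(best_hit_locus, synteny_locus):
        return LocusDecision(
            "accept_hit", best_hit_locus, synteny_locus,
            "best hit agrees with the synteny-implied location",
        )
    return LocusDecision(
        "conflict", best_hit_locus, synteny_locus,
        "best similarity hit and synteny-implied location disagree; "
        "curator review required",
    )
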