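"""Assign an ortholog by reciprocal best hits, confirmed by local synteny.

Similarity alone can land on the wrong member of a gene family; the
neighborhood — which genes flank the locus, in what orientation, and what
is nested in what — breaks the tie. This example pairs genes from two hit
tables, then compares the neighborhoods of an insulin-like peptide gene,
and finally shows the conflict report when similarity and synteny disagree.
"""

import pandas as pd

from annokit import (
    GenomicInterval,
    NeighborhoodMap,
    assess_local_synteny,
    reciprocal_best_hits,
    resolve_ambiguous_locus,
)
from annokit.orthology import HIT_COLUMNS


def hit(q, s, evalue, bits):
    return [q, s, 92.0, 300, 20, 1, 1, 300, 1, 300, evalue, bits]


forward = pd.DataFrame(
    [hit("Ilp2", "scf_g1200", 1e-80, 350), hit("Ilp3", "scf_g0400", 1e-12, 90)],
    columns=HIT_COLUMNS,
)
reverse = pd.DataFrame(
    [hit("scf_g1200", "Ilp2", 1e-75, 330), hit("scf_g0400", "Ilp1", 1e-15, 95)],
    columns=HIT_COLUMNS,
)
result = reciprocal_best_hits(forward, reverse)
print("reciprocal best hits:", list(result.pairs))
for name, reason in result.unpaired:
    print(f"  unpaired {name}: {reason}")

reference = NeighborhoodMap(
    "Ilp2", upstream=(("Ilp1", "+"), ("Zasp67", "+")),
    downstream=(("Ilp3", "+"), ("Ilp4", "+")), nested_in="CG32052",
)
target = NeighborhoodMap(
    "Ilp2", upstream=(("Ilp1", "+"), ("Zasp67", "+")),
    downstream=(("Ilp3", "+"), ("Ilp4", "+")), nested_in="CG32052",
)
verdict = assess_local_synteny(reference, target)
print(f"\nlocal synteny: {verdict.status} ({verdict.details})")

# similarity hit overlapping a paralog while synteny points elsewhere
hit_locus = GenomicInterval("scf1", 100, 400, "+")
synteny_locus = GenomicInterval("scf1", 2000, 2400, "+")
decision = resolve_ambiguous_locus(hit_locus, synteny_locus)
print(f"\nwhen they disagree: {decision.decision} -> {decision.rationale}")
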