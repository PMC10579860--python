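"""Find a coding exon too small for similarity search to detect.

When flanking exons fix the splice phases of a missing exon, the search
space collapses: the exon must sit between an AG acceptor and a GT donor,
have a length congruent to the phases modulo 3, and contain no in-frame
stop codon. Here a 21-nt internal exon is planted and recovered.
"""

from annokit import ExonSearchConstraints, compute_junctions, find_small_exons
from annokit.simulate import SyntheticLocusSpec, generate_locus

bundle = generate_locus(
    SyntheticLocusSpec(seed=13, exon_lengths=(90, 21, 120),
                       intron_lengths=(40, 45))
)
target = bundle.model.transcript_exons[1].interval
junctions = compute_junctions(bundle.model, bundle.scaffold)

constraints = ExonSearchConstraints(
    cds_type="internal", min_length=6, max_length=60,
    acceptor_phase=junctions[0].acceptor_phase,
    donor_phase=junctions[1].donor_phase,
)
lo, hi = target.start - 30, target.end + 30
window = bundle.scaffold.residues[lo - 1 : hi]
hits = find_small_exons(window, lo, constraints, scaffold_id=bundle.scaffold.id)

print(f"planted exon: {target.start}-{target.end} ({len(target)} nt), "
      f"acceptor phase {constraints.acceptor_phase}, "
      f"donor phase {constraints.donor_phase}")
print(f"candidates satisfying the constraints in a {len(window)} nt window:")
for h in hits:
    marker = "  <- planted" if (h.interval.start, h.interval.end) == (
        target.start, target.end) else ""
    print(f"  rank {h.score_rank}: {h.interval.start}-{h.interval.end} "
          f"({h.length} nt) AG|...|{h.flanking_donor}{marker}")
print("every candidate is flanked by the required splice sites and keeps an"
      " open reading frame at the required phases")
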