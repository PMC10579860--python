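"""Refine approximate coding-exon coordinates to exact splice boundaries.

Translated similarity searches align only complete codons, so their exon
coordinates routinely miss the 1-2 nucleotides of codons split across
splice junctions. This example plants a five-exon gene at published browser
coordinates, perturbs the boundaries the way a similarity search would, and
refines them back.
"""

from annokit import GenomicInterval, compute_junctions, refine_model
from annokit.simulate import locus_for_exon_coordinates

refined_truth = [
    (17_358_666, 17_358_714),
    (17_358_842, 17_358_913),
    (17_359_011, 17_359_218),
    (17_359_278, 17_359_407),
    (17_359_470, 17_359_559),
]
approximate = [
    (17_358_666, 17_358_713),
    (17_358_844, 17_358_912),
    (17_359_013, 17_359_216),
    (17_359_279, 17_359_407),
    (17_359_470, 17_359_559),
]

bundle = locus_for_exon_coordinates(refined_truth, seed=1)
approx = [GenomicInterval(bundle.scaffold.id, s, e, "+") for s, e in approximate]
results = refine_model(approx, bundle.scaffold, window=15)

print("exon  approx start-stop        refined start-stop       shift")
for i, (a, r) in enumerate(zip(approx, results), start=1):
    print(f"{i}     {a.start:,}-{a.end:,}  {r.interval.start:,}-"
          f"{r.interval.end:,}  ({r.start_shift:+d}, {r.end_shift:+d})")

junctions = compute_junctions(bundle.model, bundle.scaffold)
j1 = junctions[0]
print(f"\nintron 1: donor phase {j1.donor_phase} + acceptor phase "
      f"{j1.acceptor_phase} = {j1.phase_sum}")
print("a phase sum of 3 means one codon is split across the intron; sums of"
      " 0 or 3 keep the reading frame intact after splicing")
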