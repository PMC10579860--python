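"""Correct an assembly consensus error so a sound gene model validates.

A 1-nt deletion in the assembly consensus makes a correct model appear
frameshifted. The fix is a VCF edit file: apply it to the scaffold, and the
same model coordinates (lifted across the edit) pass the checker again.
"""

from annokit import apply_edits, check_model, lift_model, parse_edits
from annokit.simulate import CorruptionSpec, SyntheticLocusSpec, corrupt_model, generate_locus

bundle = generate_locus(SyntheticLocusSpec(seed=5))
res = corrupt_model(
    bundle.model, bundle.scaffold,
    CorruptionSpec(kind="consensus_indel", seed=5, exon_ordinal=2,
                   indel_length=1),
)
print(f"injected: {res.details}")

broken = check_model(res.models[0], res.scaffold, bundle.reference_record)
print(f"model on the flawed consensus: {broken.overall} "
      f"(first failure: {broken.first_failure.key})")

edits = parse_edits(res.repair_vcf, res.scaffold)
corrected, coord_map = apply_edits(res.scaffold, edits)
lifted = lift_model(res.models[0], coord_map)
fixed = check_model(lifted, corrected, bundle.reference_record)
print(f"after applying {len(edits)} edit(s) and lifting coordinates: "
      f"{fixed.overall}")
print(f"consensus length {len(res.scaffold)} -> {len(corrected)} nt; the"
      " corrected sequence equals the error-free original:"
      f" {corrected.residues == bundle.scaffold.residues}")
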