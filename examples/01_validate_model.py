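"""Validate a proposed gene model against the biological-constraint checklist.

Builds a synthetic three-exon locus with a known-correct model, runs the
checker, then truncates one donor boundary by a single nucleotide to show
the frameshift cascade and the first-failure diagnosis.
"""

from annokit import check_model, diagnose_first_failure
from annokit.simulate import CorruptionSpec, SyntheticLocusSpec, corrupt_model, generate_locus

bundle = generate_locus(SyntheticLocusSpec(seed=42))
report = check_model(bundle.model, bundle.scaffold, bundle.reference_record)
print(f"valid model: overall={report.overall}, CDS {report.cds_length} nt, "
      f"peptide {len(report.peptide) - 1} aa + stop")

# one nucleotide off at the first donor site
broken = corrupt_model(
    bundle.model, bundle.scaffold,
    CorruptionSpec(kind="splice_shift", junction=1, shift=-1),
).models[0]
report = check_model(broken, bundle.scaffold, bundle.reference_record)
print(f"\nafter a 1-nt donor truncation: overall={report.overall}")
for item in report.items:
    if item.status != "pass":
        print(f"  [{item.status}] {item.key}: {item.message}")
first = diagnose_first_failure(report)
print(f"\nstart troubleshooting at: {first.key}")
print("a single upstream splice-site error shifts the reading frame of every"
      " downstream exon, so the stop-codon and length failures below it are"
      " symptoms, not separate errors")
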