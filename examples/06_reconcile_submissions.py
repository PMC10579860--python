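"""Reconcile two independent submissions of the same gene.

Two annotators model the same locus; a reconciler classifies every
disagreement into one of four error classes (wrong ortholog, extra/missing
exon, splice-site choice, missing/mislabeled isoform) and summarizes the
congruence rate.
"""

from annokit import compare_isoform_sets, summarize_error_rates
from annokit.simulate import CorruptionSpec, SyntheticLocusSpec, corrupt_model, generate_locus

bundle = generate_locus(
    SyntheticLocusSpec(seed=7, exon_lengths=(90, 120, 75), skip_exon_isoform=2)
)
names = [m.isoform_name for m in bundle.models]

# submission A is correct; submission B shifted one donor boundary of -PA
shifted = corrupt_model(
    bundle.models[0], bundle.scaffold,
    CorruptionSpec(kind="splice_shift", junction=2, shift=3),
).models[0]
submission_b = [shifted, bundle.models[1]]

reports = compare_isoform_sets(
    list(bundle.models), submission_b, names,
    reference_records=bundle.reference_records, scaffold=bundle.scaffold,
)
for r in reports:
    diffs = [d for d in r.boundary_diffs if d != (0, 0)]
    extra = f" boundary diffs {diffs}" if diffs else ""
    print(f"{r.isoform_name}: {r.category}{extra} {r.details}")

summary = summarize_error_rates(reports)
print(f"\ncongruent: {summary.n_congruent}/{summary.n_models} "
      f"({summary.percent_congruent}%)")
print("per-category shares over the erroneous models:",
      dict(summary.error_category_percent))
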