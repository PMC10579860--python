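import pytest

from annokit import check_model, compute_junctions, write_model_gff
from annokit.simulate import (
    CorruptionSpec,
    SimulationError,
    SyntheticLocusSpec,
    corrupt_model,
    generate_locus,
)


class TestSpecValidation:
    def test_total_length_must_be_codon_multiple(self):
        with pytest.raises(SimulationError, match="divisible"):
            SyntheticLocusSpec(exon_lengths=(10, 10), intron_lengths=(30,))

    def test_intron_floor(self):
        with pytest.raises(SimulationError, match="4 nt"):
            SyntheticLocusSpec(exon_lengths=(9, 9), intron_lengths=(3,))

    def test_skip_exon_must_be_internal_and_in_frame(self):
        with pytest.raises(SimulationError, match="internal"):
            SyntheticLocusSpec(exon_lengths=(9, 9), intron_lengths=(10,),
                               skip_exon_isoform=1)
        with pytest.raises(SimulationError, match="divisible by three"):
            SyntheticLocusSpec(exon_lengths=(90, 100, 110),
                               intron_lengths=(30, 30), skip_exon_isoform=2)


class TestGenerateLocus:
    def test_same_seed_byte_identical(self):
        spec = SyntheticLocusSpec(seed=17, clean_splice_windows=6,
                                  skip_exon_isoform=None)
        a, b = generate_locus(spec), generate_locus(spec)
        assert a.scaffold.residues == b.scaffold.residues
        assert write_model_gff(a.models) == write_model_gff(b.models)
        assert a.cds == b.cds and a.peptides == b.peptides

    def test_requested_structure_realized(self):
        spec = SyntheticLocusSpec(seed=3, exon_lengths=(45, 60, 30),
                                  intron_lengths=(40, 50), strand="-")
        bundle = generate_locus(spec)
        tx = bundle.model.transcript_exons
        assert [e.length for e in tx] == [45, 60, 30]
        junctions = compute_junctions(bundle.model, bundle.scaffold)
        assert [
            (j.donor_dinucleotide, j.acceptor_dinucleotide) for j in junctions
        ] == [("GT", "AG"), ("GT", "AG")]

    def test_gc_donor_requested_at_specific_junction(self):
        spec = SyntheticLocusSpec(seed=5, exon_lengths=(90, 120, 75),
                                  donor_classes=("GT", "GC"))
        bundle = generate_locus(spec)
        junctions = compute_junctions(bundle.model, bundle.scaffold)
        assert junctions[0].canonical_class == "canonical"
        assert junctions[1].canonical_class == "gc_donor"

    def test_coordinate_offset_places_locus_at_printed_coordinates(self):
        spec = SyntheticLocusSpec(seed=2, coordinate_offset=10_000)
        bundle = generate_locus(spec)
        assert bundle.model.exons[0].interval.start > 10_000
        assert bundle.scaffold.residues[:10_000] == "N" * 10_000
        assert check_model(bundle.model, bundle.scaffold,
                           bundle.reference_record).overall == "pass"

    def test_truth_peptide_matches_checker(self, simple_locus):
        report = check_model(simple_locus.model, simple_locus.scaffold)
        assert report.peptide == simple_locus.peptides[
            simple_locus.model.isoform_name
        ]


class TestCorruptions:
    def test_each_class_detected_by_its_consumer(self, two_isoform_locus):
        """Cross-module property: every corruption class is caught by the
        checker or the reconciler."""
        from annokit import compare_isoform_sets, compare_models

        bundle = two_isoform_locus
        pa = bundle.models[0]

        res = corrupt_model(pa, bundle.scaffold,
                            CorruptionSpec(kind="splice_shift", shift=1))
        report = check_model(res.models[0], bundle.scaffold,
                             bundle.reference_record)
        assert report.overall == "fail"
        assert compare_models(pa, res.models[0]).category == "splice_site"

        res = corrupt_model(pa, bundle.scaffold,
                            CorruptionSpec(kind="drop_exon", exon_ordinal=2))
        assert compare_models(pa, res.models[0]).category == "exon_gain_loss"

        res = corrupt_model(pa, bundle.scaffold, CorruptionSpec(kind="add_exon"))
        assert compare_models(pa, res.models[0]).category == "exon_gain_loss"

        res = corrupt_model(pa, bundle.scaffold,
                            CorruptionSpec(kind="relocate_locus"))
        assert compare_models(pa, res.models[0]).category == "ortholog_mismatch"

        res = corrupt_model(list(bundle.models), bundle.scaffold,
                            CorruptionSpec(kind="swap_isoform_labels"))
        reports = compare_isoform_sets(
            list(bundle.models), list(res.models),
            [m.isoform_name for m in bundle.models],
            reference_records=bundle.reference_records, scaffold=bundle.scaffold,
        )
        assert all(r.category == "isoform_missing_mislabeled" for r in reports)

    def test_splice_shift_fails_at_corrupted_junction(self, simple_locus):
        res = corrupt_model(
            simple_locus.model, simple_locus.scaffold,
            CorruptionSpec(kind="splice_shift", junction=1, shift=1),
        )
        report = check_model(res.models[0], simple_locus.scaffold,
                             simple_locus.reference_record)
        assert report.overall == "fail"
        keys = [i.key for i in report.items]
        assert keys.index(report.first_failure.key) <= keys.index("phase_compat:1")

    def test_inapplicable_corruptions_error(self, simple_locus):
        single = generate_locus(
            SyntheticLocusSpec(seed=1, exon_lengths=(90,), intron_lengths=())
        )
        with pytest.raises(SimulationError, match="single-exon"):
            corrupt_model(single.model, single.scaffold,
                          CorruptionSpec(kind="drop_exon"))
        with pytest.raises(SimulationError, match="two isoforms"):
            corrupt_model(simple_locus.model, simple_locus.scaffold,
                          CorruptionSpec(kind="swap_isoform_labels"))
        with pytest.raises(SimulationError):
            CorruptionSpec(kind="unknown_kind")

    def test_consensus_indel_emits_valid_repair(self, simple_locus):
        from annokit import apply_edits, parse_edits

        res = corrupt_model(
            simple_locus.model, simple_locus.scaffold,
            CorruptionSpec(kind="consensus_indel", seed=8, exon_ordinal=1,
                           indel_length=-2),
        )
        assert res.injected_class == "consensus_error"
        edits = parse_edits(res.repair_vcf, res.scaffold)
        restored, _ = apply_edits(res.scaffold, edits)
        assert restored.residues == simple_locus.scaffold.residues
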