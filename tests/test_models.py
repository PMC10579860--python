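import pytest

from annokit import (
    ModelError,
    ScaffoldSequence,
    assemble_cds,
    build_bundle,
    build_reference_record,
    make_model,
    merge_annotation_files,
    parse_model_gff,
    reverse_complement,
    split_peptide_by_exons,
    translate,
    write_model_gff,
)
from annokit.simulate import SyntheticLocusSpec, generate_locus

GFF_TWO_EXONS = """##gff-version 3
s1\tsrc\tCDS\t10\t30\t.\t+\t.\tParent=genX-PA
s1\tsrc\tCDS\t50\t70\t.\t+\t.\tParent=genX-PA
"""


class TestParseGff:
    def test_two_cds_one_transcript(self):
        (model,) = parse_model_gff(GFF_TWO_EXONS)
        assert model.isoform_name == "genX-PA"
        assert model.gene_symbol == "genX"
        assert model.exon_coordinate_set() == ((10, 30), (50, 70))

    def test_unsorted_input_sorted(self):
        text = GFF_TWO_EXONS.splitlines()
        text[1], text[2] = text[2], text[1]
        (model,) = parse_model_gff("\n".join(text))
        assert model.exon_coordinate_set() == ((10, 30), (50, 70))

    def test_gtf_style_grouping(self):
        text = 's1\tsrc\tCDS\t5\t10\t.\t-\t0\ttranscript_id "g-PA"; gene_id "g"\n'
        (model,) = parse_model_gff(text)
        assert model.isoform_name == "g-PA" and model.strand == "-"

    def test_mixed_strands_rejected(self):
        text = GFF_TWO_EXONS.replace("50\t70\t.\t+", "50\t70\t.\t-")
        with pytest.raises(ModelError, match="mixed strands"):
            parse_model_gff(text)

    def test_overlapping_cds_rejected(self):
        text = GFF_TWO_EXONS.replace("50\t70", "25\t70")
        with pytest.raises(ModelError, match="overlap"):
            parse_model_gff(text)

    def test_roundtrip_identity(self, simple_locus):
        models = list(simple_locus.models)
        parsed = parse_model_gff(write_model_gff(models))
        assert [m.exon_coordinate_set() for m in parsed] == [
            m.exon_coordinate_set() for m in models
        ]
        assert [m.strand for m in parsed] == [m.strand for m in models]
        assert [m.isoform_name for m in parsed] == [m.isoform_name for m in models]


class TestAssembleCds:
    def test_single_exon(self):
        scaffold = ScaffoldSequence("s1", "ATGAAATAAGGG")
        model = make_model("g", "g-PA", "s1", "+", [(1, 9)])
        assert assemble_cds(model, scaffold) == "ATGAAATAA"

    def test_plus_strand_concatenation(self):
        scaffold = ScaffoldSequence("s1", "AAATTTGGGCCC")
        model = make_model("g", "g-PA", "s1", "+", [(1, 3), (10, 12)])
        assert assemble_cds(model, scaffold) == "AAACCC"

    def test_minus_strand_matches_manual_construction(self):
        # independent manual construction: revcomp each exon, descending order
        residues = "AAGGCTTACGTAGGATCCA"
        scaffold = ScaffoldSequence("s1", residues)
        exons = [(2, 7), (12, 17)]
        model = make_model("g", "g-PA", "s1", "-", exons)
        manual = reverse_complement(residues[11:17]) + reverse_complement(
            residues[1:7]
        )
        assert assemble_cds(model, scaffold) == manual

    def test_scaffold_mismatch(self):
        model = make_model("g", "g-PA", "s1", "+", [(1, 3)])
        with pytest.raises(ModelError, match="s2"):
            assemble_cds(model, ScaffoldSequence("s2", "AAAT"))


class TestReferenceRecord:
    def test_single_exon_segment_equals_full_peptide(self, tmp_path):
        scaffold = ScaffoldSequence("s1", "ATGAAACCCTAAGG")
        gff = "s1\tsrc\tCDS\t1\t12\t.\t+\t.\tParent=g-PA\n"
        genome = tmp_path / "g.fa"
        genome.write_text(f">s1\n{scaffold.residues}\n")
        rec = build_reference_record(gff, genome, "g-PA")
        assert rec.exon_count == 1
        assert rec.exon_peptides == (rec.full_peptide,)

    def test_junction_codon_assigned_to_exon_with_two_nucleotides(
        self, simple_locus
    ):
        # brute-force oracle: assign each peptide position by counting the
        # codon's nucleotides per exon directly
        cds = simple_locus.cds[simple_locus.model.isoform_name]
        lengths = [e.length for e in simple_locus.model.transcript_exons]
        peptide, _ = translate(cds)
        expected = [""] * len(lengths)
        bounds = []
        acc = 0
        for l in lengths:
            acc += l
            bounds.append(acc)

        def exon_of(nt):  # 1-based CDS position
            for i, b in enumerate(bounds):
                if nt <= b:
                    return i

        for i, aa in enumerate(peptide):
            counts = {}
            for nt in (3 * i + 1, 3 * i + 2, 3 * i + 3):
                counts[exon_of(nt)] = counts.get(exon_of(nt), 0) + 1
            expected[max(counts, key=counts.get)] += aa
        assert split_peptide_by_exons(cds, lengths) == expected

    def test_two_exon_lengths_49_and_72_give_16_and_24_residues(self):
        bundle = generate_locus(
            SyntheticLocusSpec(seed=5, exon_lengths=(49, 72, 29),
                               intron_lengths=(40, 40))
        )
        cds = bundle.cds[bundle.model.isoform_name]
        segments = split_peptide_by_exons(cds[:121], [49, 72])
        assert [len(s) for s in segments] == [16, 24]

    def test_missing_isoform_lists_available(self, tmp_path):
        genome = tmp_path / "g.fa"
        genome.write_text(">s1\nATGAAACCCTAA\n")
        gff = "s1\tsrc\tCDS\t1\t12\t.\t+\t.\tParent=g-PA\n"
        with pytest.raises(ModelError, match="g-PA"):
            build_reference_record(gff, genome, "g-PZ")

    def test_segment_lengths_sum_to_peptide(self, two_isoform_locus):
        for rec in two_isoform_locus.reference_records.values():
            assert sum(len(s) for s in rec.exon_peptides) == len(rec.full_peptide)
            assert rec.exon_count == len(rec.exon_peptides)


class TestMerger:
    @pytest.fixture()
    def scaffolds(self, two_isoform_locus):
        return {two_isoform_locus.scaffold.id: two_isoform_locus.scaffold}

    def test_single_bundle_idempotent(self, two_isoform_locus, scaffolds):
        bundle = build_bundle(list(two_isoform_locus.models), scaffolds)
        merged = merge_annotation_files([bundle])
        again = merge_annotation_files([merged])
        assert merged == again
        assert merged.transcript_sequences == bundle.transcript_sequences

    def test_distinct_isoforms_both_kept(self, two_isoform_locus, scaffolds):
        a, b = two_isoform_locus.models
        merged = merge_annotation_files(
            [build_bundle([a], scaffolds), build_bundle([b], scaffolds)]
        )
        names = [m.isoform_name for m in parse_model_gff(merged.model_coordinates)]
        assert names == [a.isoform_name, b.isoform_name]

    def test_identical_cds_collapsed_with_cross_reference(
        self, two_isoform_locus, scaffolds
    ):
        a = two_isoform_locus.models[0]
        import dataclasses

        dup = dataclasses.replace(a, isoform_name=a.isoform_name + "dup")
        merged = merge_annotation_files(
            [build_bundle([a], scaffolds), build_bundle([dup], scaffolds)]
        )
        models = parse_model_gff(merged.model_coordinates)
        assert len(models) == 1
        assert f"same_cds_as={dup.isoform_name}" in merged.model_coordinates

    def test_name_conflict_rejected(self, two_isoform_locus, scaffolds):
        a, b = two_isoform_locus.models
        import dataclasses

        clash = dataclasses.replace(b, isoform_name=a.isoform_name)
        with pytest.raises(ModelError, match="conflict"):
            merge_annotation_files(
                [build_bundle([a], scaffolds), build_bundle([clash], scaffolds)]
            )
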