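import random

import pytest

import propcheck
from annokit import (
    GenomicInterval,
    ScaffoldSequence,
    check_model,
    compare_peptides,
    compute_junctions,
    diagnose_first_failure,
    make_model,
    refine_boundary,
    refine_model,
)
from annokit.checker import CheckerError
from annokit.simulate import CorruptionSpec, SyntheticLocusSpec, corrupt_model, generate_locus


class TestJunctions:
    def test_single_exon_no_junctions(self):
        scaffold = ScaffoldSequence("s1", "ATGAAATAA")
        model = make_model("g", "g-PA", "s1", "+", [(1, 9)])
        assert compute_junctions(model, scaffold) == []

    def test_phase_anchoring_five_exon_structure(self):
        """Exon lengths 49/72/208/130/90: the first donor sits one nt past
        the last complete codon (phase 1) and the first acceptor two nt
        before the next one (phase 2), summing to one split codon."""
        bundle = generate_locus(
            SyntheticLocusSpec(
                seed=11, exon_lengths=(49, 72, 208, 130, 90),
                intron_lengths=(129, 97, 59, 62),
            )
        )
        j = compute_junctions(bundle.model, bundle.scaffold)
        assert j[0].donor_phase == 1
        assert j[0].acceptor_phase == 2
        assert j[0].phase_sum == 3
        assert all(x.phases_compatible for x in j)

    def test_full_codon_exons_have_zero_phases(self):
        bundle = generate_locus(
            SyntheticLocusSpec(seed=2, exon_lengths=(6, 9), intron_lengths=(20,))
        )
        (j,) = compute_junctions(bundle.model, bundle.scaffold)
        assert (j.donor_phase, j.acceptor_phase) == (0, 0)

    def test_abutting_exons_rejected(self):
        scaffold = ScaffoldSequence("s1", "ATGAAACCCTAAGGTTT")
        model = make_model("g", "g-PA", "s1", "+", [(1, 6), (7, 12)])
        with pytest.raises(CheckerError, match="intron"):
            compute_junctions(model, scaffold)


class TestCheckModel:
    def test_minimal_single_exon_pass(self):
        scaffold = ScaffoldSequence("s1", "ATGAAATAA")
        model = make_model("g", "g-PA", "s1", "+", [(1, 9)])
        report = check_model(model, scaffold)
        assert report.overall != "fail"
        assert report.peptide == "MK*"
        assert report.item("start_codon").status == "pass"
        assert report.item("stop_codon").status == "pass"
        assert report.item("length_divisible_by_3").status == "pass"

    def test_truncated_donor_cascade_and_single_nt_fix(self, cascade_locus):
        """Ending exon 1 one nt short of the GT donor yields a GG donor,
        in-frame stops in downstream exons and a CDS length not divisible
        by three; extending the same boundary by one nt resolves it all."""
        bundle = cascade_locus
        broken = corrupt_model(
            bundle.model, bundle.scaffold,
            CorruptionSpec(kind="splice_shift", junction=1, shift=-1),
        ).models[0]
        report = check_model(broken, bundle.scaffold, bundle.reference_record)
        assert report.overall == "fail"
        assert report.item("donor_site:1").status == "fail"
        assert "GG" in report.item("donor_site:1").message
        downstream_stop_fails = [
            i for i in report.items
            if i.key.startswith("internal_stops:") and i.status == "fail"
        ]
        assert len(downstream_stop_fails) >= 2
        assert report.item("length_divisible_by_3").status == "fail"
        assert diagnose_first_failure(report).key == "donor_site:1"

        fixed = corrupt_model(
            broken, bundle.scaffold,
            CorruptionSpec(kind="splice_shift", junction=1, shift=1),
        ).models[0]
        assert check_model(fixed, bundle.scaffold,
                           bundle.reference_record).overall == "pass"

    def test_gc_donor_single_warning(self):
        bundle = generate_locus(
            SyntheticLocusSpec(seed=4, exon_lengths=(90, 120, 75),
                               donor_classes=("GT", "GC"))
        )
        report = check_model(bundle.model, bundle.scaffold, bundle.reference_record)
        assert report.overall == "pass_with_warnings"
        warns = [i for i in report.items if i.status == "warn"]
        assert [w.key for w in warns] == ["donor_site:2"]

    def test_non_canonical_start_needs_allowance(self):
        bundle = generate_locus(SyntheticLocusSpec(seed=9, start_codon="ACG"))
        # the generated model declares the allowance: warn, not fail
        report = check_model(bundle.model, bundle.scaffold)
        assert report.item("start_codon").status == "warn"
        undeclared = make_model(
            "g", bundle.model.isoform_name, bundle.model.scaffold_id,
            bundle.model.strand,
            [(e.interval.start, e.interval.end) for e in bundle.model.exons],
        )
        report = check_model(undeclared, bundle.scaffold)
        assert report.item("start_codon").status == "fail"
        assert "ACG" in report.item("start_codon").message

    def test_incomplete_model_demotes_start_stop(self, simple_locus):
        m = simple_locus.model
        # trim the model to its internal exon only: no start, no stop
        inner = m.transcript_exons[1]
        partial = make_model(
            m.gene_symbol, m.isoform_name, m.scaffold_id, m.strand,
            [(inner.interval.start, inner.interval.end)], complete=False,
        )
        report = check_model(partial, simple_locus.scaffold)
        assert report.item("start_codon").status == "warn"
        assert report.item("stop_codon").status == "warn"

    def test_exon_count_mismatch_reports_counts(self, simple_locus):
        m = simple_locus.model
        dropped = corrupt_model(
            m, simple_locus.scaffold, CorruptionSpec(kind="drop_exon", exon_ordinal=2)
        ).models[0]
        report = check_model(dropped, simple_locus.scaffold,
                             simple_locus.reference_record)
        item = report.item("exon_count_match")
        assert item.status == "fail"
        assert "2" in item.message and "3" in item.message

    def test_all_pass_report_has_no_first_failure(self, simple_locus):
        report = check_model(simple_locus.model, simple_locus.scaffold,
                             simple_locus.reference_record)
        assert diagnose_first_failure(report) is None

    def test_pass_invariants_on_seeded_fixtures(self):
        ok, n = propcheck.check_validity(30)
        assert ok == n

    def test_frame_propagation_property(self):
        cascades, localized, n = propcheck.check_frame_propagation(60)
        assert localized == n
        assert cascades >= 0.95 * n


@pytest.fixture(scope="module")
def clean_locus():
    return generate_locus(
        SyntheticLocusSpec(
            seed=21, exon_lengths=(60, 90, 72), intron_lengths=(50, 60),
            clean_splice_windows=15,
        )
    )


class TestRefineBoundary:

    def test_partial_codon_recovered_upstream(self, clean_locus):
        """An approximate internal-exon start that excludes the 2-nt partial
        codon before the acceptor is pulled 2 nt upstream."""
        m = clean_locus.model
        exon2 = m.transcript_exons[1].interval
        approx = GenomicInterval(m.scaffold_id, exon2.start + 2, exon2.end, "+")
        refined = refine_boundary(
            approx, "internal", cds_length_before=60,
            scaffold=clean_locus.scaffold,
        )
        assert refined.start_shift == -2 and refined.end_shift == 0
        assert refined.interval == exon2

    def test_donor_one_nt_short_extended(self, clean_locus):
        m = clean_locus.model
        exon1 = m.transcript_exons[0].interval
        approx = GenomicInterval(m.scaffold_id, exon1.start, exon1.end - 1, "+")
        refined = refine_boundary(approx, "initial", 0, clean_locus.scaffold)
        assert (refined.start_shift, refined.end_shift) == (0, 1)

    def test_fixed_point_when_already_canonical(self, clean_locus):
        m = clean_locus.model
        for i, role in ((0, "initial"), (1, "internal"), (2, "terminal")):
            exon = m.transcript_exons[i].interval
            before = sum(e.length for e in m.transcript_exons[:i])
            refined = refine_boundary(exon, role, before, clean_locus.scaffold)
            assert (refined.start_shift, refined.end_shift) == (0, 0)

    def test_no_candidate_raises_with_suggestion(self):
        # a motif-free scaffold has no acceptor or donor anywhere
        scaffold = ScaffoldSequence("bare", "A" * 200)
        approx = GenomicInterval("bare", 80, 120, "+")
        with pytest.raises(CheckerError, match="window"):
            refine_boundary(approx, "internal", 60, scaffold, window=4)

    def test_recovery_property_small_perturbations(self):
        ok, n = propcheck.check_refinement_recovery(25)
        assert ok == n

    def test_chained_refinement_minus_strand(self):
        bundle = generate_locus(
            SyntheticLocusSpec(
                seed=33, exon_lengths=(60, 90, 72), intron_lengths=(50, 60),
                strand="-", clean_splice_windows=8,
            )
        )
        rng = random.Random(1)
        truth = [
            (e.interval.start, e.interval.end)
            for e in bundle.model.transcript_exons
        ]
        approx = [
            GenomicInterval(bundle.scaffold.id, s + rng.randint(-2, 2),
                            e + rng.randint(-2, 2), "-")
            for s, e in truth
        ]
        refined = refine_model(approx, bundle.scaffold, window=8)
        assert [(r.interval.start, r.interval.end) for r in refined] == truth


# brute-force affine-gap global alignment (Gotoh), the oracle for scores
def _oracle_align_score(a: str, b: str, open_: float = -11, ext: float = -1):
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = open_ + (i - 1) * ext
    for j in range(1, m + 1):
        Iy[0][j] = open_ + (j - 1) * ext
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = blosum[a[i - 1], b[j - 1]]
            M[i][j] = s + max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            Ix[i][j] = max(M[i - 1][j] + open_, Ix[i - 1][j] + ext,
                           Iy[i - 1][j] + open_)
            Iy[i][j] = max(M[i][j - 1] + open_, Ix[i][j - 1] + open_,
                           Iy[i][j - 1] + ext)
    return max(M[n][m], Ix[n][m], Iy[n][m])


class TestComparePeptides:
    AA = "ACDEFGHIKLMNPQRSTVWY"

    def test_identical_peptides(self):
        pep = "MSTNPKPQRKTKRNTNRRPQDVKFPGG"
        res = compare_peptides(pep, pep)
        assert res.percent_identity == 100.0
        assert res.gap_anomalies == ()
        # full diagonal in the dot plot
        assert all(res.dotplot[i, i] for i in range(res.dotplot.shape[0]))

    def test_internal_deletion_reported_as_gap_anomaly(self):
        rng = random.Random(0)
        pep = "".join(rng.choice(self.AA) for _ in range(80))
        cut = pep[:40] + pep[50:]
        res = compare_peptides(cut, pep)
        assert len(res.gap_anomalies) == 1
        anomaly = res.gap_anomalies[0]
        assert anomaly.in_sequence == "model" and anomaly.length == 10

    def test_unrelated_random_peptides_low_identity(self):
        rng = random.Random(7)
        below = 0
        for _ in range(100):
            a = "".join(rng.choice(self.AA) for _ in range(50))
            b = "".join(rng.choice(self.AA) for _ in range(50))
            if compare_peptides(a, b).percent_identity < 30.0:
                below += 1
        assert below == 100

    def test_alignment_score_matches_dynamic_programming_oracle(self):
        rng = random.Random(3)
        for _ in range(25):
            a = "".join(rng.choice(self.AA) for _ in range(rng.randint(5, 30)))
            b = "".join(rng.choice(self.AA) for _ in range(rng.randint(5, 30)))
            res = compare_peptides(a, b)
            assert res.score == pytest.approx(_oracle_align_score(a, b))

    def test_empty_peptide_rejected(self):
        with pytest.raises(CheckerError):
            compare_peptides("", "MK")
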