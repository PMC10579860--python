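"""Shared property-suite helpers: each pits a toolkit operation against an
independent oracle or a cross-module invariant on seeded synthetic inputs
and returns (successes, trials). Module tests run them at modest sizes;
the acceptance tests run them at full size.
"""

from __future__ import annotations

import random

import pandas as pd

from annokit import (
    GenomicInterval,
    apply_edits,
    check_model,
    compare_isoform_sets,
    compare_models,
    find_small_exons,
    lift_model,
    parse_edits,
    reciprocal_best_hits,
    refine_model,
)
from annokit.simulate import (
    CorruptionSpec,
    SyntheticLocusSpec,
    corrupt_model,
    generate_locus,
)
from annokit.small_exons import ExonSearchConstraints

STOPS = {"TAA", "TAG", "TGA"}


def random_locus_spec(seed: int, **overrides) -> SyntheticLocusSpec:
    rng = random.Random(seed)
    n = rng.randint(2, 5)
    lengths = [rng.randrange(30, 180) for _ in range(n)]
    lengths[-1] += (-sum(lengths)) % 3
    fields = dict(
        seed=seed,
        exon_lengths=tuple(lengths),
        intron_lengths=tuple(rng.randrange(30, 90) for _ in range(n - 1)),
        strand=rng.choice("+-"),
        gc_content=rng.uniform(0.35, 0.55),
    )
    fields.update(overrides)
    return SyntheticLocusSpec(**fields)


# ---------------------------------------------------------------------------
# checker invariants on valid loci

def check_validity(n_seeds: int, base_seed: int = 0) -> tuple[int, int]:
    """Valid-mode loci must pass the checker with compatible phases."""
    ok = 0
    for i in range(n_seeds):
        seed = base_seed + i
        bundle = generate_locus(random_locus_spec(seed))
        report = check_model(bundle.model, bundle.scaffold, bundle.reference_record)
        peptide_ok = report.peptide.count("*") == 1 and report.peptide.endswith("*")
        if report.overall == "pass" and report.cds_length % 3 == 0 and peptide_ok:
            ok += 1
    return ok, n_seeds


# ---------------------------------------------------------------------------
# frame propagation: one boundary error cascades downstream

def check_frame_propagation(n_seeds: int, base_seed: int = 0) -> tuple[int, int, int]:
    """Returns (cascades, first_failure_localized, trials): a 1-nt donor
    boundary error should produce >=1 downstream internal-stop failure in
    nearly all fixtures, and the first failing item must sit at or
    upstream of the corrupted junction in every fixture."""
    cascades = localized = 0
    n = 0
    for i in range(n_seeds):
        seed = base_seed + i
        rng = random.Random(10_000 + seed)
        n_ex = rng.randint(3, 5)
        lengths = [rng.randrange(60, 160) for _ in range(n_ex)]
        lengths[-1] += (-sum(lengths)) % 3
        spec = SyntheticLocusSpec(
            seed=seed,
            exon_lengths=tuple(lengths),
            intron_lengths=tuple(rng.randrange(30, 90) for _ in range(n_ex - 1)),
            strand=rng.choice("+-"),
        )
        bundle = generate_locus(spec)
        junction = rng.randint(1, n_ex - 2) if n_ex > 2 else 1
        shift = rng.choice((-1, 1))
        res = corrupt_model(
            bundle.model, bundle.scaffold,
            CorruptionSpec(kind="splice_shift", junction=junction, shift=shift),
        )
        report = check_model(res.models[0], bundle.scaffold, bundle.reference_record)
        n += 1
        if report.overall != "fail":
            continue
        keys = [item.key for item in report.items]
        cutoff = keys.index(f"phase_compat:{junction}")
        if keys.index(report.first_failure.key) <= cutoff:
            localized += 1
        downstream_stop = any(
            item.key.startswith("internal_stops:") and item.status == "fail"
            and keys.index(item.key) > cutoff
            for item in report.items
        )
        if downstream_stop:
            cascades += 1
    return cascades, localized, n


# ---------------------------------------------------------------------------
# boundary refinement recovers the truth under small perturbations

def check_refinement_recovery(n_seeds: int, window: int = 6, base_seed: int = 0) -> tuple[int, int]:
    ok = 0
    for i in range(n_seeds):
        seed = base_seed + i
        rng = random.Random(20_000 + seed)
        n_ex = rng.randint(2, 4)
        lengths = [rng.randrange(40, 150) for _ in range(n_ex)]
        lengths[-1] += (-sum(lengths)) % 3
        spec = SyntheticLocusSpec(
            seed=seed,
            exon_lengths=tuple(lengths),
            intron_lengths=tuple(rng.randrange(30, 80) for _ in range(n_ex - 1)),
            clean_splice_windows=window,
        )
        bundle = generate_locus(spec)
        truth = [
            (e.interval.start, e.interval.end)
            for e in bundle.model.transcript_exons
        ]
        approx = [
            GenomicInterval(
                bundle.scaffold.id,
                s + rng.randint(-2, 2),
                e + rng.randint(-2, 2),
                "+",
            )
            for s, e in truth
        ]
        refined = refine_model(approx, bundle.scaffold, window=window)
        if [(r.interval.start, r.interval.end) for r in refined] == truth:
            ok += 1
    return ok, n_seeds


# ---------------------------------------------------------------------------
# small-exon search vs an exhaustive enumerator

def _oracle_valid(w: str, s: int, e: int, c: ExonSearchConstraints) -> bool:
    """Naive re-derivation of the exon constraint predicate on a 0-based
    half-open substring of the transcript-orientation window."""
    length = e - s
    if c.cds_type == "initial":
        if w[s : s + 3] != "ATG":
            return False
        lead = 0
        if length % 3 != c.donor_phase % 3:
            return False
    elif c.cds_type == "internal":
        if s < 2 or w[s - 2 : s] != "AG":
            return False
        lead = c.acceptor_phase
        if length % 3 != (c.acceptor_phase + c.donor_phase) % 3:
            return False
    else:
        if s < 2 or w[s - 2 : s] != "AG":
            return False
        lead = c.acceptor_phase
        if length % 3 != c.acceptor_phase % 3:
            return False
    if length <= lead:
        return False
    if c.cds_type in ("initial", "internal"):
        donor = w[e : e + 2]
        if donor != "GT" and not (c.allow_gc_donor and donor == "GC"):
            return False
    codons = [w[i : i + 3] for i in range(s + lead, e - 2, 3)]
    if c.cds_type == "terminal":
        if not codons or codons[-1] not in STOPS:
            return False
        if any(x in STOPS for x in codons[:-1]):
            return False
    elif any(x in STOPS for x in codons):
        return False
    return True


def _oracle_hits(w: str, c: ExonSearchConstraints) -> set[tuple[int, int]]:
    hits = set()
    for s in range(len(w)):
        for length in range(c.min_length, c.max_length + 1):
            e = s + length
            if e > len(w):
                break
            if _oracle_valid(w, s, e, c):
                hits.add((s, e))
    return hits


def check_small_exon_oracle(
    n_windows: int, window_len: int = 200, min_len: int = 6, max_len: int = 40,
    base_seed: int = 0,
) -> tuple[int, int]:
    """Implementation candidate set == brute-force enumeration, for every
    window x cds type x (acceptor, donor) phase pair."""
    agree = total = 0
    for i in range(n_windows):
        rng = random.Random(30_000 + base_seed + i)
        window = "".join(rng.choice("ACGT") for _ in range(window_len))
        for cds_type in ("initial", "internal", "terminal"):
            for a in range(3):
                for d in range(3):
                    c = ExonSearchConstraints(
                        cds_type=cds_type, min_length=min_len, max_length=max_len,
                        acceptor_phase=a, donor_phase=d,
                    )
                    impl = {
                        (cand.interval.start - 1, cand.interval.end)
                        for cand in find_small_exons(window, 1, c)
                    }
                    total += 1
                    if impl == _oracle_hits(window, c):
                        agree += 1
    return agree, total


# ---------------------------------------------------------------------------
# consensus corruption / repair round trip

def check_updater_roundtrip(n_seeds: int, base_seed: int = 0) -> tuple[int, int]:
    ok = 0
    for i in range(n_seeds):
        seed = base_seed + i
        rng = random.Random(40_000 + seed)
        bundle = generate_locus(random_locus_spec(seed))
        eligible = [
            e.ordinal for e in bundle.model.exons if e.length >= 12
        ]
        indel = rng.choice((1, 2, -1, -2, 4, -4))
        res = corrupt_model(
            bundle.model, bundle.scaffold,
            CorruptionSpec(
                kind="consensus_indel", seed=seed,
                exon_ordinal=rng.choice(eligible), indel_length=indel,
            ),
        )
        edits = parse_edits(res.repair_vcf, res.scaffold)
        restored, repair_map = apply_edits(res.scaffold, edits)
        good = restored.residues == bundle.scaffold.residues
        if abs(indel) % 3 != 0:
            broken = check_model(res.models[0], res.scaffold,
                                 bundle.reference_record)
            good = good and broken.overall == "fail"
        relifted = lift_model(res.models[0], repair_map)
        repaired = check_model(relifted, restored, bundle.reference_record)
        good = good and repaired.overall == "pass"
        good = good and relifted.exon_coordinate_set() == \
            bundle.model.exon_coordinate_set()
        if good:
            ok += 1
    return ok, n_seeds


# ---------------------------------------------------------------------------
# reciprocal best hits vs brute force

def _random_hit_table(rng: random.Random, queries, subjects) -> pd.DataFrame:
    rows = []
    for q in queries:
        for s in rng.sample(subjects, rng.randint(0, min(4, len(subjects)))):
            length = rng.randrange(50, 400)
            rows.append(
                [
                    q, s, rng.choice((70.0, 80.0, 90.0, 95.0)), length,
                    rng.randrange(0, 30), rng.randrange(0, 5),
                    1, length, 1, length,
                    rng.choice((1e-50, 1e-20, 1e-10, 1e-5)),
                    float(rng.choice((100, 200, 300, 400))),
                ]
            )
    from annokit.orthology import HIT_COLUMNS

    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def _oracle_rbh(fwd: pd.DataFrame, rev: pd.DataFrame) -> set[tuple[str, str]]:
    def best(table: pd.DataFrame) -> dict[str, str]:
        out: dict[str, str] = {}
        ranked: dict[str, tuple] = {}
        for idx, row in enumerate(table.itertuples()):
            key = (row.evalue, -row.bitscore, -row.pident, idx)
            if row.qseqid not in ranked or key < ranked[row.qseqid]:
                ranked[row.qseqid] = key
                out[row.qseqid] = row.sseqid
        return out

    fb, rb = best(fwd), best(rev)
    return {(a, b) for a, b in fb.items() if rb.get(b) == a}


def check_rbh_oracle(n_tables: int, size: int = 20, base_seed: int = 0) -> tuple[int, int]:
    agree = 0
    for i in range(n_tables):
        rng = random.Random(50_000 + base_seed + i)
        a_genes = [f"a{i}" for i in range(size)]
        b_genes = [f"b{i}" for i in range(size)]
        fwd = _random_hit_table(rng, a_genes, b_genes)
        rev = _random_hit_table(rng, b_genes, a_genes)
        result = reciprocal_best_hits(fwd, rev)
        mirrored = reciprocal_best_hits(rev, fwd)
        symmetric = set(result.pairs) == {(b, a) for a, b in mirrored.pairs}
        if set(result.pairs) == _oracle_rbh(fwd, rev) and symmetric:
            agree += 1
    return agree, n_tables


# ---------------------------------------------------------------------------
# reconciliation classifier on injected error classes

def _classifier_base(seed: int):
    rng = random.Random(60_000 + seed)
    l2 = 3 * rng.randrange(20, 50)
    lengths = [rng.randrange(60, 150), l2, rng.randrange(60, 150),
               rng.randrange(60, 150)]
    lengths[-1] += (-sum(lengths)) % 3
    spec = SyntheticLocusSpec(
        seed=seed,
        exon_lengths=tuple(lengths),
        intron_lengths=tuple(rng.randrange(30, 80) for _ in range(3)),
        strand=rng.choice("+-"),
        skip_exon_isoform=2,
    )
    return generate_locus(spec), rng


def check_classifier_recovery(n_per_class: int, base_seed: int = 0) -> tuple[int, int]:
    """Each injected error class must be assigned its own category."""
    ok = total = 0
    for i in range(n_per_class):
        seed = base_seed + i
        bundle, rng = _classifier_base(seed)
        pa = bundle.models[0]
        names = [m.isoform_name for m in bundle.models]

        cases = [
            CorruptionSpec(kind="splice_shift", seed=seed,
                           junction=rng.randint(1, 3),
                           shift=rng.choice((-2, -1, 1, 2))),
            CorruptionSpec(kind="drop_exon", seed=seed,
                           exon_ordinal=rng.choice((2, 3)))
            if seed % 2 == 0
            else CorruptionSpec(kind="add_exon", seed=seed),
            CorruptionSpec(kind="relocate_locus", seed=seed),
        ]
        for spec in cases:
            res = corrupt_model(pa, bundle.scaffold, spec)
            total += 1
            if compare_models(pa, res.models[0]).category == res.injected_class:
                ok += 1

        res = corrupt_model(bundle.models, bundle.scaffold,
                            CorruptionSpec(kind="swap_isoform_labels"))
        reports = compare_isoform_sets(
            list(bundle.models), list(res.models), names,
            reference_records=bundle.reference_records,
            scaffold=bundle.scaffold,
        )
        total += 1
        if all(r.category == "isoform_missing_mislabeled" for r in reports):
            ok += 1
    return ok, total
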