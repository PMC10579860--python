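# annokit

A curation toolkit for manual annotation of protein-coding genes in newly
assembled genomes. It implements the computational core of the
comparative-annotation workflow used to curate orthologs of well-annotated
reference genes (e.g. *Drosophila melanogaster* genes projected onto other
*Drosophila* assemblies): validate proposed gene models against biological
constraints, refine approximate exon boundaries to exact splice sites, find
phase-constrained small exons, correct assembly consensus errors, assign
orthologs by reciprocal best hits and local synteny, merge per-isoform
submissions, and reconcile independently built models into a classified
discrepancy report.

It is written for annotators, curators and instructors of annotation
projects who want scriptable, testable versions of these checks rather than
web tools, and for anyone building training data or QC pipelines around
manually curated gene models.

## The checks, in brief

A proposed model is an ordered set of coding-exon coordinates
(1-based, inclusive, forward strand + strand flag) on a genome scaffold. A
valid complete model must:

- begin with `ATG` and end with a stop codon (`TAA`/`TAG`/`TGA`);
- use canonical splice sites — `GT` donor and `AG` acceptor (the rare
  naturally occurring `GC` donor draws a warning, not a failure);
- keep the reading frame across every intron: with donor phase
  *d* = (nucleotides between the last complete codon and the donor site)
  and acceptor phase *a* = (nucleotides between the acceptor site and the
  first complete codon), every junction must satisfy *d* + *a* ∈ {0, 3};
- contain no in-frame stop codon inside any exon, and have total CDS
  length ≡ 0 (mod 3).

Donor phases are anchored at the start codon (*d* = prefix length mod 3)
and acceptor phases independently at the stop codon (*a* = suffix length
mod 3), so incompatible splice-site choices are detectable instead of true
by construction. Checklist items are ordered 5′→3′: a single upstream
boundary error shifts the frame of everything downstream and cascades into
spurious stop-codon and length failures, so troubleshooting starts at the
first failing item.

Boundary refinement searches a small window (default ±15 nt) around
approximate, similarity-derived exon coordinates for the unique coordinates
that satisfy all of the above; small-exon search solves the constrained ORF
problem *L* = *a* + 3*k* + *d* between an `AG` and a `GT` for exons too
small or too diverged for similarity search; peptide comparison uses a
BLOSUM62 global alignment (affine gaps −11/−1) plus an exact-word dot plot.

A deterministic synthetic-locus generator (`annokit.simulate`) produces
scaffolds, true models, reference records, neighborhoods and controlled
corruptions, so the entire toolkit is testable with no external data.

## Worked example

`examples/02_refine_boundaries.py` plants a five-exon gene at published
browser coordinates and refines the approximate coordinates a translated
similarity search would report:

```
exon  approx start-stop        refined start-stop       shift
1     17,358,666-17,358,713  17,358,666-17,358,714  (+0, +1)
2     17,358,844-17,358,912  17,358,842-17,358,913  (-2, +1)
3     17,359,013-17,359,216  17,359,011-17,359,218  (-2, +2)
4     17,359,279-17,359,407  17,359,278-17,359,407  (-1, +0)
5     17,359,470-17,359,559  17,359,470-17,359,559  (+0, +0)

intron 1: donor phase 1 + acceptor phase 2 = 3
```

Each shift is the correction a curator would make by eye: exon 2's start
moves 2 nt upstream to include the partial codon in front of the acceptor
(a phase-2 acceptor), exon 1's end moves 1 nt downstream onto the GT donor,
and so on. The phase sum of 3 at intron 1 means one codon is split across
the intron — the reading frame survives splicing.

The other examples each demonstrate one capability end to end: checklist
validation and first-failure diagnosis (01), small-exon search (03),
consensus-error repair via VCF (04), reciprocal best hits + local synteny
(05), reconciliation and error-rate summary (06), and the annotation merger
(07). All print the numbers they compute and what they mean.

A thin CLI mirrors the library:

```bash
annokit check --genome genome.fa --model model.gff --reference-record ref.json
annokit find-exons --genome genome.fa --region scf1:200-320 --type internal \
    --acceptor-phase 2 --donor-phase 1 --min 6 --max 60
annokit update-seq --genome genome.fa --vcf edits.vcf --out corrected.fa
annokit rbh --forward fwd.tsv --reverse rev.tsv
annokit reconcile --genome genome.fa --models a.gff --models b.gff
```

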