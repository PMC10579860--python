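# Methods

This note records the models, conventions and design choices behind
annokit, in the order a curator meets them.

## Coordinates, strands and data types

All public coordinates are 1-based and inclusive, matching genome browsers
and GFF. Intervals always store ascending forward-strand coordinates plus a
strand flag; transcript order on the minus strand is descending coordinate
order. Internally, strand-dependent logic (splice sites, reading frames,
boundary search) runs on a transcript-orientation view that maps transcript
position *t* to forward position *L* − *t* + 1 on the minus strand, so the
same code serves both strands.

Only coding exons are modelled. Gene models carry a `complete` flag
(False for genes truncated by assembly gaps, which demotes start/stop
checks to warnings) and an `allowances` mapping for declared exceptions:
a non-canonical start codon (such as the conserved ACG start some genes
use), a non-canonical donor or acceptor at a named junction, or stop-codon
readthrough. Allowed exceptions downgrade the corresponding checklist item
from fail to warn; undeclared ones fail. Translation uses the standard
nuclear genetic code only — non-standard initiation and readthrough are
curation decisions (allowances), not translation-table variants.

## Splice phases and the checklist

Donor phase = nucleotides between the end of the last complete codon and
the donor site; acceptor phase = nucleotides between the acceptor site and
the first complete codon. A junction is frame-compatible iff the phases sum
to 0 or 3.

Two anchoring choices matter:

- Donor phases are computed from the 5′ end (cumulative CDS length through
  the upstream exon, mod 3); acceptor phases are computed independently
  from the 3′ end (remaining CDS length, mod 3, anchored at the stop
  codon). If both were derived from one running frame the sum would be 0
  or 3 by construction; with two anchors, a model whose total length is
  not a multiple of three exhibits genuinely incompatible phases at its
  junctions, which is what the phase-compatibility item reports. The
  corollary is that a single interior indel can surface as a phase failure
  at an upstream junction — the frame disagreement is real, and the
  per-exon internal-stop items localize the culprit.
- The stop codon is part of the CDS and of the length-divisibility check.

Checklist items are emitted in transcript 5′→3′ order — start codon, then
per exon its internal-stop item followed by its downstream junction's
donor, acceptor and phase items, then stop codon, length divisibility and
exon-count-vs-reference — so the first failing item is the most upstream
defect. This ordering encodes the troubleshooting heuristic that a single
boundary error produces a cascade of downstream failures: fixing the first
failure usually clears the rest. `GC` donors warn rather than fail (a rare
but real donor class); all other non-canonical sites fail unless declared.

## Boundary refinement

Approximate exon coordinates from translated similarity searches cover only
complete codons and can over- or under-shoot splice sites. Refinement does
a joint search over (start, end) candidates within a window (default
±15 nt, configurable; published corrections are almost always ≤2 nt, and a
small window limits spurious candidates) subject to: initial exons start at
a start codon; internal/terminal exon starts immediately follow an `AG`;
initial/internal exon ends immediately precede a `GT` (`GC` optional);
terminal exons end exactly at an in-frame stop; and no in-frame stop may
appear inside the exon given the incoming frame (CDS length accumulated 5′
of the exon). Among valid candidates the minimal total absolute shift wins;
ties prefer the longer exon (extension over truncation), then the more
upstream start, making the result deterministic. `refine_model` chains the
per-exon search 5′→3′, feeding each refined length into the next exon's
frame.

Exact recovery is guaranteed only when the true splice site is the unique
canonical site within the window; the generator's `clean_splice_windows`
option constructs that regime (see below), and the recovery property is
tested there.

## Small-exon search

For a coding exon between an acceptor of phase *a* and a donor of phase
*d*, the length satisfies *L* = *a* + 3*k* + *d*. The finder enumerates all
intervals in a window that are flanked by the required sites (`AG`
upstream for internal/terminal, `GT`/`GC` downstream for initial/internal,
`ATG` start for initial, in-frame stop for terminal), have the required
length congruence, and contain no stop among their complete codons in the
implied frame. Initial candidates include the ATG; terminal candidates
include the stop codon. Candidates are ordered by ascending start then
descending length — a deliberate, deterministic choice; no
conservation-based ranking is attempted. Lengths far below 30 nt are fully
supported; that is the point of the tool.

## Consensus-error correction

Edits are a minimal VCF subset: CHROM, POS, REF, ALT only; QUAL, FILTER,
INFO and genotypes ignored; multi-allelic records rejected; indels follow
VCF anchoring (REF and ALT share their first base). Every REF is validated
against the scaffold, edits must be sorted and non-overlapping. Applying
edits yields the corrected scaffold plus a piecewise-constant coordinate
map; model coordinates are lifted across it, and a boundary inside a
deleted span is an error naming the exon. The VCF dialect is parsed and
written directly in this module: the format here is a bare five-column edit
container, and full-featured VCF libraries require header/contig machinery
that adds nothing to it.

## Orthology evidence

The toolkit never runs an aligner. Reciprocal best hits consume two
12-column tab-separated hit tables (qseqid sseqid pident length mismatch
gapopen qstart qend sstart send evalue bitscore); the best hit per query is
lowest e-value, then highest bit score, then highest percent identity, then
input order, and a pair is emitted iff the choice is mutual. Local synteny
compares neighborhood maps — the nearest two genes per side, nearest-first,
with orientations, plus nesting relations. `conserved` requires all four
neighbors with orientations and consistent nesting; `partial` requires at
least two matched neighbors (a calibration of qualitative practice, chosen
here); fewer is `not_conserved`; two empty maps are `not_assessable`. When
the best similarity hit and the synteny-implied location disagree, the
resolver reports a conflict with both loci rather than deciding — the
protocol leaves that call to the curator.

## Reconciliation

Two submissions of the same gene are compared isoform by isoform.
Classification precedence: different scaffolds or non-overlapping spans →
`ortholog_mismatch`; different exon counts → `exon_gain_loss`; equal counts
with any boundary offset → `splice_site` (with per-boundary signed
offsets); otherwise `congruent`. The precedence is this package's
resolution of overlapping categories — each comparison gets exactly one
class, and co-occurring differences go into the details text. An isoform
present in only one submission, or labeled as one reference isoform while
structurally matching a different one (same exon count, peptide length
within 5%, peptide identity ≥95% to the other reference isoform and not
its own), is `isoform_missing_mislabeled`. Summaries report percent
congruent over all reports and each category's share over the non-congruent
ones, rounded to whole percent. No final model is synthesized — the module
reports, the human reconciler decides.

## Peptide comparison

Global alignment uses BLOSUM62 with affine gaps (−11 open, −1 extend per
additional gap position), the familiar protein-search scoring; percent
identity is matches over aligned columns, and gap runs of ≥5 residues are
flagged as anomalies because long gaps usually mean a wrong splice site or
a missing/extra exon rather than divergence. The dot plot is a binary
exact-word-match matrix (default word size 3). Alignment scores are
verified in the tests against an independent affine-gap dynamic-programming
implementation on short peptides.

## The synthetic-locus generator

`generate_locus` builds: a CDS of random non-stop codons between the
requested start and stop codons, split into the requested exon lengths;
introns of requested lengths with forced boundary dinucleotides (donor `GT`
or `GC` per junction, acceptor `AG`; minimum intron 4 nt — a floor chosen
here so both dinucleotides exist); random flanks at the requested GC
content (default 0.45, typical of *Drosophila* euchromatin); and optional
N-padding so a locus can sit at arbitrary published coordinates. Everything
derives from one seed and is byte-identical across runs. Validity is
enforced by construction plus rejection sampling (regenerate on the rare
failure, capped attempts), e.g. when an exon-skipping second isoform is
requested (the skipped exon's length must be ≡0 mod 3) or when
`clean_splice_windows` asks that competing `GT`/`GC`, `AG` or `ATG` motifs
near the true boundaries be mutated away, which makes boundary-refinement
recovery exact.

`corrupt_model` injects exactly one error of a named class: a splice-shift
of a donor boundary, a dropped or added exon, swapped isoform labels, a
relocated locus, or a consensus indel. The consensus indel perturbs the
scaffold, re-anchors the models onto the flawed consensus (as an annotator
working on that assembly would build them) and emits the repair VCF whose
application restores the original sequence exactly.

What the generator does not emulate: realistic intron length and splice-
site strength distributions, codon usage bias, repeats, sequencing-error
models, UTRs and non-coding features, and RNA-Seq evidence. Passing tests
therefore demonstrate the correctness of the constraint logic and the
bookkeeping on idealized loci, not performance on real assemblies, where
evidence conflicts and non-canonical biology dominate the hard cases.

## Problem sizes and numerical choices

The test and acceptance suites run at desk scale by design: 100 seeded loci
for checker validity, 200 for frameshift-cascade detection (the cascade is
expected in ≥95% of fixtures — a shifted frame meets a stop codon quickly
but not always), 100 refinement recoveries, 50 random 200-nt windows × 27
constraint combinations against the brute-force exon enumerator, 100
corruption/repair round trips, 30 random 20×20 hit-table pairs against the
brute-force RBH oracle, and 200 injected corruptions for the classifier.
Exon lengths in random fixtures are 30–180 nt, introns 30–90 nt. All
randomness flows from explicit seeds; ties everywhere break
deterministically (documented above per operation).

Reconciliation-scale congruence arithmetic is checked on constructed
multisets: 257 congruent of 310 gives 83% congruent, and the error-class
ratio 38:41:19:2 is realized exactly on a multiset whose error count is a
multiple of 100 (at 53 errors the closest integer split rounds one share to
42, so the exact-ratio check uses the scaled multiset).

## Known limitations

- Boundary refinement is per-exon with frame chaining; it does not
  backtrack across exons, so a window containing multiple valid canonical
  candidates can refine to a minimal-shift candidate that is not the true
  one (uniqueness in the window is the guarantee's precondition).
- The checker evaluates one isoform at a time; cross-isoform consistency
  (shared splice sites, nested CDS) is not checked.
- GFF support is deliberately narrow: CDS features grouped by
  `Parent`/`transcript_id`, GFF3 emitted. UTR/exon features are out of
  scope, as is GTF emission.
- Phase anchoring at the stop codon assumes the model ends at a stop; for
  incomplete models the acceptor phases are still reported on that
  convention, with start/stop items demoted to warnings.
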