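# Methods

This note documents the models, conventions and design choices behind
`dropindesign`, in the order a design run uses them. It states what the
code computes and what the synthetic fixtures do and do not emulate; every
number quoted here is recomputed by the test suite or by
`scripts/acceptance.py`, not asserted from memory.

## Coordinates

All internal coordinates are 0-based, half-open, on the forward strand of
the reference ("interbase"). GFF3 (1-based closed) and VCF (1-based) are
converted at the I/O boundary and converted back on export; the GFF3
round trip is coordinate-exact. Interbase arithmetic is what makes the cut
site a single integer and the homology arms exact string slices.

## Gene models and coding introns

A gene is a set of transcripts, each a sorted tuple of exon and CDS
intervals. An intron qualifies as *coding* when a CDS segment abuts it on
both sides — equivalently, both flanking exons contain CDS at the
junction. Its **phase** is the cumulative CDS length transcriptionally
upstream of the intron, mod 3: the number of nucleotides of the
interrupted codon already emitted. Phase is computed per transcript; an
intron is flagged `shared_by_all_coding_transcripts` only when every
coding transcript contains it with identical boundaries *and* phase.

Design targets only shared coding introns by default (an `any_isoform`
switch relaxes this). Public annotations do not say which isoform a given
published insertion assumed; truncating every isoform is the conservative
default, and it is documented here as this package's choice rather than
asserted as anyone's practice. Splice dinucleotides are checked against
GT..AG when a genome is supplied; non-canonical junctions warn but do not
abort, since real annotations contain minor-spliceosome introns.

## Guide model

SpCas9 guides are exact N20-NGG matches, both strands, enumerated by
sliding a 23-mer window (verified in tests against an independent
brute-force enumeration). The blunt cut falls 3 nt 5' of the PAM:
`cut = protospacer_end − 3` on the plus strand, `protospacer_start + 3`
on the minus strand. This one rule drives the arm coordinates, plasmid
linearization and re-cut checks, so it is tested by hand cases, strand
symmetry and oracle comparison.

Filtering and ranking:

* **Strain variants** — any variant overlapping protospacer+PAM (plus an
  optional pad, default 0) marks the guide not-clean; such guides are
  demoted, not discarded, since a mismatch near the PAM may still cut.
  Variants are first validated against the reference and dropped (with a
  warning) on ref mismatch.
* **Splice-junction buffer** — cuts closer than `min_splice_distance`
  (default 50 nt) to either junction are excluded so the arms and insert
  do not encroach on splicing signals. The published protocols do not
  state their buffer; 50 nt is this package's default and configurable.
* **Ranking** — variant-clean first, then arm-feasible (arms fit in the
  contig, contain no N and no forbidden motif), then centrality in the
  intron; ties break by coordinate then strand, so output is
  deterministic. On-target efficiency scores are deliberately out of
  scope. Off-target reporting is exact-match only and non-blocking.

## Homology arms

Arms default to 100/100 nt abutting the blunt cut on the gene's coding
strand (minus-strand genes: slices are reverse-complemented and swapped so
the LHA is always transcriptionally upstream). The source protocol wording
admits an alternative reading in which the right arm starts 3 nt
downstream (a 97-nt arm); the symmetric reading is the only one consistent
with the printed donor totals (1442 = 1242 + 2×100), so symmetric is the
default and both are constructible via `lha_len`/`rha_len`. Asymmetric-arm
strategies get no special logic. Any N in an arm disqualifies the site;
restriction-site and gRNA1 occurrences (searched on both strands) are
flags that cause the pipeline to fall through to the next guide.

## Donor classes

**ssDNA drop-in.** The long primers are `LHA + 26-nt forward priming
segment` and `revcomp(RHA) + 24-nt reverse priming segment`, where the
priming segments are the ends of the cassette core; the predicted PCR
duplex is `LHA + core + RHA`. Lambda exonuclease is modeled as: the
5'-phosphorylated strand is removed, the other survives. With the default
reverse-primer phosphorylation the surviving donor is the top (coding)
strand; flipping the phosphorylation yields the reverse complement.

**Synthesized dsDNA drop-in.** Insert layout is
`gRNA1 · LHA · cassette · RHA · gRNA1(rc)` in a circular vector. The
gRNA1 protospacer+PAM must have zero exact matches in the supplied genome
(both strands, checked before assembly; the bundled spacer is a stand-in —
any unit passing the check may be substituted). Units are oriented
PAM-inward so the released fragment keeps only a 3-nt + PAM (6 nt) remnant
per end; the orientation is configurable data, not hard-coded behavior.
Two lengths are reported because published totals are ambiguous about the
release sites: `cassette_plus_arms_len` (excludes the gRNA1 units; this is
the figure-style number, e.g. 715 and 1968 for the two bundled gene
traps) and `full_insert_len` (+46).

**int100 plasmid.** The synthesized insert carries `RE1 site · spacer ·
RE2 site` between the arms. Enzyme choice walks a fixed catalog of
palindromic 5'-overhang cutters (EcoRI, NotI, BamHI, XhoI, NheI, AscI,
SpeI, AvrII) and takes the first two whose sites are absent from LHA,
RHA, cassette and backbone — deterministic, with a structured error
listing per-enzyme conflicts otherwise. Digestion is modeled as top-strand
cut positions plus 5'-overhang strings; because top-strand cuts partition
the sequence, ligation is exact concatenation, digest→ligate→digest is
idempotent, and a cassette presented with swapped ends fails on
incompatible overhangs (RE1 ≠ RE2 enforces directionality). The
reconstituted recognition sites remain as cloning scars flanking the
cassette; the directly synthesized donor uses the same layout, so direct
and subcloned products are byte-identical. Restricting the catalog to
palindromic 5'-overhang enzymes keeps the overhang-matching rule exact;
3'-overhang and non-palindromic cutters are out of scope. The bundled
pUC57-class backbone is a deterministic 2.7-kb synthetic stand-in scrubbed
of catalog sites and the gRNA1 target; any circular record can replace it.

## Edited allele and trap prediction

Only the intended seamless HDR product is modeled (integrations are
verified by junction PCR in practice; error-prone repair is out of scope).
The edited contig is `ref[:cut] + core + ref[cut:]` with the core oriented
to the gene strand; two invariants are enforced on every product: deleting
the insert restores the reference exactly, and no intact protospacer+PAM
of the design guide survives on either strand (the insertion splits the
protospacer 3 nt from the PAM).

Cassette phase variants derive from the phase-0 template: a phase-p intron
interrupts a codon after p nt, so the artificial exon opens with
`(3−p) % 3` pad nt, and protein-trap (SA…SD) cassettes additionally take
p pad nt before the splice donor so the exon length stays ≡ 0 mod 3 and
the downstream CDS keeps frame. Pad bases are chosen so no stop codon can
form against any host context (stops all start with T and none end in C).

Trap prediction builds the model mature transcript — upstream native
exons spliced to the artificial exon at its splice acceptor, terminating
at the cassette polyA (gene trap) or continuing through the splice donor
into the downstream exons (protein trap) — and translates the fusion ORF
from the host ATG. It reports frame agreement between intron phase and
cassette phase, the stop position for gene traps, and retention of the
native stop for protein traps. Classification is molecular-qualitative
only: attP-3XP3-EGFP-attP in an intron is a neutral landing site,
SA…polyA cassettes are gene traps, SA…SD cassettes protein traps, and any
exonic insertion is flagged disruptive. Quantitative expression effects
are biological measurements and are not predicted.

## Validation PCR

Each junction is covered by one in/out pair: a genomic primer within
700 nt of the junction and an outward-facing cassette-internal primer
within 250 nt of the cassette end. Candidates must be 18–25 nt, GC
35–65%, Tm 57–63 °C, runs ≤ 4, and have exactly one perfect-match site in
the whole edited allele (both strands); the pair minimizing
|amplicon − 500| within [200, 800] nt wins, with deterministic
tie-breaks. Every emitted pair is re-verified by virtual PCR — exact
binding sites, convergent orientation, recomputed product length — and the
in/out asymmetry guarantees no product on the unedited allele. The
thermodynamic constraints are this package's choices; the source protocol
fixes only the orientations and the 200–800 nt window. Virtual PCR is
exact-match only; mismatch-tolerant binding is out of scope.

Melting temperatures use the unified nearest-neighbor parameters of
Allawi & SantaLucia (1997) with the SantaLucia (1998) entropic salt
correction (`ΔS + 0.368 (N−1) ln[Na+]`), Tm = ΔH / (ΔS + R ln k) − 273.15
with k = c₁ − c₂/2 (or c₁ for self-complementary primers, with the −1.4
cal/mol/K symmetry term). Defaults: 50 mM Na⁺, 25 nM per strand. The
implementation is independent of Biopython's and is cross-checked against
it to 0.01 °C in the tests.

## Synthetic fixtures

`generate_locus` emits a single-contig, single-gene locus from one seeded
PRNG stream: ~43% GC (fly-like), 2+ coding exons of 120–300 CDS nt,
introns of 400–800 nt with canonical GT..AG ends, 150-nt UTRs, 1.5-kb
flanks (so the primer search windows always fit), a clean ORF
(ATG…stop, stop-free internally), plus planted NGG guides, planted
SNV/insertion/deletion variants and an optional decoy gRNA1 target, all
recorded with coordinates in a truth report. Identical spec + seed gives
byte-identical FASTA/GFF3/VCF/JSON. What it does *not* emulate: repeats
and low-complexity tracts, soft-masking, alternative isoforms, overlapping
genes, non-canonical splice sites, realistic codon usage or variant
density. Passing tests therefore demonstrate correct coordinate
arithmetic, assembly and simulation logic — not robustness to annotation
pathology in real genomes.

The bundled cassette library is likewise synthetic: real short elements
where public and unambiguous (T2A, FRT, a triple-stop block with stops in
all three frames, AATAAA polyA signals, (Gly-Gly-Ser)×4 linkers), seeded
filler elsewhere, with core lengths fixed to the published construct
arithmetic — 1242 (EGFP landing site), 1192 (sfGFP protein trap),
515 (3XSTOP gene trap), 1768 (T2A-miniGAL4 gene trap), 4103 (full
artificial-exon cassette) — so donors with two 100-nt arms measure
1442 / 1392 / 715 / 1968 nt. The U6-gRNA1 marker region embeds the gRNA1
spacer followed by a T-tract so no accidental third Cas9 target arises on
the plasmid.

## Problem sizes and determinism

The test suite and acceptance script run on generated loci of ~4–7 kb and
panels of 8–50 random fixtures per property (50 × 2-kb windows for the
guide-scan oracle; 8–10 full end-to-end designs for HDR, re-cut and
amplicon properties); these sizes give full coverage of the combinatorial
cases (both gene strands, both guide strands, all cassette classes) while
keeping a full run in seconds. All randomness flows from explicit seeds;
two runs with the same config are byte-identical, which the tests assert.

## Known limitations

* Exact-match models throughout: off-target search, variant overlap and
  virtual PCR do not model mismatch tolerance or bulges.
* No on-target efficiency scoring; guide ranking is purely structural.
* Restriction model limited to palindromic 5'-overhang enzymes; no
  Gibson/Golden-Gate planning, no vendor synthesis-constraint screening
  beyond GC logging.
* Single-locus scale; no whole-genome fixture simulation, liftover or
  transcript assembly.
* NHEJ and partial-HDR outcomes are not modeled.
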