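# dropindesign

Design and in-silico simulation of CRISPR "drop-in" knock-in reagents with
**short (100 nt) homology arms** for *Drosophila*-style gene tagging: ssDNA
donors made by PCR, small synthesized dsDNA donors released from a plasmid
in vivo, and single-step-cloning plasmids for large artificial exons —
plus the genotyping PCR that verifies the integration.

## Who this is for

Groups building gene-trap / protein-trap libraries (or tagging single
genes) who want every orderable molecule — long primers, synthesis
fragments, donor plasmids — computed from a genome, an annotation and a
cassette template library, with the resulting edited allele simulated and
sanity-checked before anything is ordered.

## The design model

All three donor classes integrate by homology-directed repair (HDR) at a
single blunt SpCas9 cut inside a **coding intron** (an intron flanked by
two CDS-containing exons). For a 20-nt protospacer with an NGG PAM, Cas9
cuts between protospacer positions 17 and 18, i.e. 3 nt 5' of the PAM; in
interbase coordinates

```
+ strand:  cut = protospacer_end − 3
− strand:  cut = protospacer_start + 3
```

The **left homology arm** (LHA) is the 100 nt immediately 5' of the cut on
the gene's coding strand and the **right arm** (RHA) the 100 nt immediately
3' of it, so `LHA + RHA` reconstructs the reference window around the cut
exactly (seamless HDR). Guides are filtered against strain variants
(a variant inside the protospacer/PAM prevents cutting), kept ≥ 50 nt from
splice junctions, and ranked by variant cleanliness, arm feasibility and
centrality.

Three donor classes are assembled from annotated cassette templates
(attP…attP cores):

1. **ssDNA drop-in** — the cassette core is PCR-amplified with universal
   26-nt forward / 24-nt reverse priming segments carrying the arms as 5'
   overhangs (126/124-nt long primers); the reverse primer is
   5'-phosphorylated, lambda exonuclease degrades the phosphorylated
   strand, and the surviving strand is the donor.
2. **Synthesized dsDNA drop-in** — `gRNA1target–LHA–cassette–RHA–gRNA1target`
   in a pUC57-class vector, where gRNA1 is a guide with **no target in the
   host genome**; Cas9 releases the donor in vivo, leaving a minimal
   3-nt + PAM remnant at each end (PAM-inward units).
3. **int100 plasmid** — the synthesized insert carries a two-enzyme
   restriction stuffer instead of the cassette; a large artificial exon
   (e.g. the full attP-FRT-SA-T2A-GAL4-polyA-3XP3-EGFP-FRT-attP cassette)
   is subcloned directionally in a single step.

The edited allele is simulated (insert at the cut; excising it must
restore the reference byte-for-byte; no intact protospacer+PAM may
survive), the gene-trap / protein-trap transcript and ORF are predicted
with intron-phase matching, and in/out genotyping primers are designed so
that each junction gives one 200–800 nt amplicon on the edited allele and
none on the reference.

The bundled cassette templates are *synthetic stand-ins*: element layout
and core lengths (1242 / 1192 / 515 / 1768 nt) are faithful to the
published constructs, filler sequence is generated deterministically. Real
vector records can be supplied instead; every operation takes templates as
data.

## Worked example

Generate a deterministic synthetic locus and design an ssDNA landing-site
donor for it:

```bash
dropin fixtures --seed 2 --outdir locus --plant-guide 0:+:150
# wrote locus (4698 nt, 2 coding introns) to locus

dropin design --genome locus/genome.fa --gff3 locus/annotation.gff3 \
    --gene geneA --cassette attP-3XP3-EGFP-attP --outdir out
# {
#  "genes_designed": [
#   "geneA"
#  ],
#  "failures": {}
# }
```

`out/geneA/design_summary.json` then contains (abridged):

```json
"donor": {
 "class": "ssdna",
 "total_len": 1442,
 "surviving_strand": "top",
 "forward_primer_len": 126,
 "reverse_primer_len": 124
},
"validation": {
 "amplicons": [
  {"pair": "5prime_junction", "length": 500},
  {"pair": "3prime_junction", "length": 500}
 ]
}
```

Reading: the 1242-nt EGFP landing-site template plus two 100-nt arms gives
the expected 1442-nt donor; the long primers are arm + priming segment
(100+26, 100+24); both junction PCRs sit at the 500-nt target inside the
200–800 nt genotyping window. Alongside the summary the run writes the
guide report, GenBank records of the donor and the edited allele, the
validation-primer TSV/BED and an ordering sheet. The same library calls
are available in Python (`dropindesign.pipeline.run_design`, or the
individual `scan_guides` / `design_arms` / `build_ssdna_design` /
`simulate_hdr` / `design_validation_primers` operations).

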