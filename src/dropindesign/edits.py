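"""Simulation of the HDR-edited allele and its molecular consequence.

Only the intended, seamless HDR product is modeled (integrations are
verified by junction PCR/sequencing in practice; error-prone repair
outcomes are out of scope). The edited chromosome is the reference with
the cassette inserted exactly at the blunt cut, which by construction
destroys the guide's protospacer/PAM juxtaposition so the allele cannot
be re-cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from ._util import revcomp, translate
from .arms import HomologyArmPair
from .cassettes import CassetteTemplate
from .genome import GeneModel, GenomeSequence
from .guides import GuideTarget

log = logging.getLogger(__name__)

ALLELE_CLASSES = ("gene_trap", "protein_trap", "neutral_landing_site")


class EditError(ValueError):
    pass


@dataclass(frozen=True)
class EditedAllele:
    contig_id: str
    sequence: str
    insert_interval: tuple[int, int]  # interbase on the edited contig
    guide_used: GuideTarget
    cassette_name: str
    gene_strand: str

    @property
    def insert_seq(self) -> str:
        s, e = self.insert_interval
        return self.sequence[s:e]

    def excised(self) -> str:
        """Edited sequence with the insert removed (must equal reference)."""
        s, e = self.insert_interval
        return self.sequence[:s] + self.sequence[e:]


def simulate_hdr(
    genome: GenomeSequence,
    arms: HomologyArmPair,
    core_seq: str,
    guide: GuideTarget,
    cassette_name: str = "",
) -> EditedAllele:
    """Insert the cassette core at the blunt cut via seamless HDR.

    The arms are re-verified against the reference flanks (a mismatch
    signals a stale genome or wrong strand normalization), the core is
    oriented to the gene strand, and the result is checked for absence of
    an intact protospacer+PAM of the guide on either strand.
    """
    cut = arms.cut_site
    ref = genome.sequence
    if arms.orientation == "+":
        ok = (ref[cut - arms.lha_len : cut] == arms.lha
              and ref[cut : cut + arms.rha_len] == arms.rha)
        oriented_core = core_seq
    else:
        ok = (ref[cut : cut + arms.lha_len] == revcomp(arms.lha)
              and ref[cut - arms.rha_len : cut] == revcomp(arms.rha))
        oriented_core = revcomp(core_seq)
    if not ok:
        raise EditError(
            f"homology arms do not match the reference around cut {cut} "
            f"(orientation {arms.orientation})"
        )
    edited = ref[:cut] + oriented_core + ref[cut:]
    target = guide.protospacer + guide.pam
    if target in edited or revcomp(target) in edited:
        raise EditError(
            "intact protospacer+PAM survives in the edited allele; "
            "the cassette recreates the target site"
        )
    return EditedAllele(
        genome.contig_id, edited, (cut, cut + len(oriented_core)),
        guide, cassette_name, arms.orientation,
    )


def classify_allele(cassette: CassetteTemplate, insertion_context: str) -> str:
    """Molecular consequence of inserting this cassette here.

    In a coding intron: an attP-3XP3-EGFP-attP cassette only creates a
    landing site; SA...polyA cassettes truncate the transcript (gene trap);
    SA...SD cassettes splice in as an internal tag and translation
    continues (protein trap). Any cassette dropped into an exon disrupts
    the coding sequence and is flagged gene_trap-like.
    """
    if insertion_context not in ("intron", "exon"):
        raise ValueError(f"insertion_context must be intron|exon, got "
                         f"{insertion_context!r}")
    if cassette.mutagenic_class not in ALLELE_CLASSES:
        raise EditError(f"unknown cassette class {cassette.mutagenic_class!r}")
    if insertion_context == "exon":
        return "gene_trap"
    return cassette.mutagenic_class


def _upstream_exonic(
    gene: GeneModel, intron: tuple[int, int]
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """(exons, cds) transcriptionally upstream of the intron, genomic coords.

    Uses the first coding transcript containing the intron boundaries."""
    for t in gene.coding_transcripts:
        boundaries = {(t.exons[i][1], t.exons[i + 1][0])
                      for i in range(len(t.exons) - 1)}
        if intron in boundaries:
            if gene.strand == "+":
                ex = [e for e in t.exons if e[1] <= intron[0]]
                cds = [c for c in t.cds if c[1] <= intron[0]]
            else:
                ex = [e for e in t.exons if e[0] >= intron[1]]
                cds = [c for c in t.cds if c[0] >= intron[1]]
            return ex, cds
    raise EditError("insertion intron not found in any coding transcript")


def _downstream_exonic(gene: GeneModel, intron: tuple[int, int]):
    for t in gene.coding_transcripts:
        boundaries = {(t.exons[i][1], t.exons[i + 1][0])
                      for i in range(len(t.exons) - 1)}
        if intron in boundaries:
            if gene.strand == "+":
                return ([e for e in t.exons if e[0] >= intron[1]],
                        [c for c in t.cds if c[0] >= intron[1]])
            return ([e for e in t.exons if e[1] <= intron[0]],
                    [c for c in t.cds if c[1] <= intron[0]])
    raise EditError("insertion intron not found in any coding transcript")


def predict_trap_transcript(
    edited: EditedAllele,
    gene: GeneModel,
    genome: GenomeSequence,
    cassette: CassetteTemplate,
    intron: tuple[int, int],
) -> dict:
    """Model the mature transcript and ORF of the trapped allele.

    Gene trap (SA...polyA): upstream native exons splice onto the
    artificial exon at its splice acceptor and the transcript terminates
    at the cassette polyA; translation continues from the host reading
    frame into the cassette payload and stops at the first in-frame stop.

    Protein trap (SA...SD): the artificial exon splices in between the
    native exons; when cassette phase matches intron phase the ORF reads
    through the tag and retains the native stop codon.
    """
    if not cassette.has_feature("SA"):
        raise EditError(f"{cassette.name}: cassette has no splice acceptor")
    is_protein_trap = cassette.has_feature("SD")
    if not is_protein_trap and not (cassette.has_feature("polyA")
                                    or cassette.has_feature("minipolyA")):
        raise EditError(f"{cassette.name}: gene-trap cassette has no polyA")

    strand = gene.strand
    up_exons, up_cds = _upstream_exonic(gene, intron)
    upstream_cds = "".join(genome.sequence[s:e] for s, e in up_cds)
    upstream_exonic = "".join(genome.sequence[s:e] for s, e in up_exons)
    if strand == "-":
        upstream_cds = revcomp(upstream_cds)
        upstream_exonic = revcomp(upstream_exonic)
    intron_phase = len(upstream_cds) % 3

    sa_end = cassette.feature("SA")[1]
    if is_protein_trap:
        exon_end = cassette.feature("SD")[0]
    else:
        pa_label = "minipolyA" if cassette.has_feature("minipolyA") else "polyA"
        exon_end = cassette.feature(pa_label)[1]
    artificial_exon = cassette.core_seq[sa_end:exon_end]

    cassette_phase = cassette.phase_variant
    in_frame = (cassette_phase == intron_phase)

    orf_head = upstream_cds + artificial_exon  # host ATG fixes frame 0
    protein = translate(orf_head)
    stop_idx = protein.find("*")
    report = {
        "cassette": cassette.name,
        "trap_type": "protein_trap" if is_protein_trap else "gene_trap",
        "intron_phase": intron_phase,
        "cassette_phase": cassette_phase,
        "payload_in_frame": in_frame,
        "upstream_cds_nt": len(upstream_cds),
        "artificial_exon_nt": len(artificial_exon),
    }
    if not in_frame:
        report["frame_violation"] = (
            f"intron phase {intron_phase} != cassette phase {cassette_phase}"
        )
    if is_protein_trap:
        down_exons, down_cds = _downstream_exonic(gene, intron)
        downstream_cds = "".join(genome.sequence[s:e] for s, e in down_cds)
        downstream_exonic = "".join(genome.sequence[s:e] for s, e in down_exons)
        if strand == "-":
            downstream_cds = revcomp(downstream_cds)
            downstream_exonic = revcomp(downstream_exonic)
        full_cds = upstream_cds + artificial_exon + downstream_cds
        protein = translate(full_cds)
        stop_idx = protein.find("*")
        report["transcript_nt"] = (len(upstream_exonic) + len(artificial_exon)
                                   + len(downstream_exonic))
        report["orf_nt"] = len(full_cds)
        report["retains_native_stop"] = (
            in_frame and stop_idx == len(protein) - 1
        )
        report["premature_stop"] = stop_idx != -1 and stop_idx < len(protein) - 1
    else:
        report["transcript_nt"] = len(upstream_exonic) + len(artificial_exon)
        report["downstream_native_exons_in_transcript"] = 0
        report["stop_codon_nt_offset_in_orf"] = (
            stop_idx * 3 if stop_idx != -1 else None
        )
    return report
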