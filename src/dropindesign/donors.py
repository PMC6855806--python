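"""Assembly of the three drop-in donor classes.

1. **ssDNA drop-in**: the cassette core is PCR-amplified with a long primer
   pair — 26/24-nt universal priming segments carrying the 100-nt homology
   arms as 5' overhangs — and the 5'-phosphorylated strand is removed with
   lambda exonuclease, leaving a single-stranded donor.
2. **Synthesized dsDNA drop-in**: gRNA1 target — LHA — payload — RHA —
   gRNA1 target, synthesized into a pUC57-class vector; Cas9 releases the
   donor in vivo by cutting both gRNA1 sites.
3. **int100 plasmid donor**: the synthesized insert carries a two-enzyme
   restriction stuffer instead of the payload; a large cassette (e.g. the
   full CRIMIC artificial exon) is then subcloned directionally in one step.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from typing import Mapping

from ._util import circular_slice, gc_fraction, revcomp
from .arms import HomologyArmPair
from .cassettes import CassetteTemplate, GRNA1_PAM, GRNA1_PROTOSPACER
from .enzymes import (
    CATALOG, Enzyme, Fragment, digest_circular, digest_linear_ends,
    ligate_circular,
)
from .guides import CUT_OFFSET, count_genome_matches
from .genome import GenomeSequence

log = logging.getLogger(__name__)


class DonorDesignError(ValueError):
    pass


@dataclass(frozen=True)
class GRna1Unit:
    """The donor-release guide: a protospacer+PAM with no genomic target.

    Units are placed PAM-inward (PAM facing the homology arms) so the
    Cas9-released donor carries only a minimal 3-nt + PAM (6 nt) remnant
    at each end.
    """

    protospacer: str = GRNA1_PROTOSPACER
    pam: str = GRNA1_PAM

    @property
    def target(self) -> str:
        return self.protospacer + self.pam

    @property
    def left_unit(self) -> str:
        """Forward-strand unit 5' of the LHA (PAM faces right/inward)."""
        return self.target

    @property
    def right_unit(self) -> str:
        """Forward-strand unit 3' of the RHA (PAM faces left/inward)."""
        return revcomp(self.target)

    @property
    def remnant_len(self) -> int:
        return CUT_OFFSET + len(self.pam)


@dataclass(frozen=True)
class LongPrimerPair:
    """Homology arms as 5' overhangs on the universal priming segments."""

    forward: str  # LHA + 26-nt forward priming segment
    reverse: str  # revcomp(RHA) + 24-nt reverse priming segment
    reverse_5prime_phosphorylated: bool = True


@dataclass(frozen=True)
class SsDNADonor:
    duplex_top: str  # LHA + core + RHA
    ssdna_seq: str  # strand surviving lambda exonuclease, 5'->3'
    surviving_strand: str  # {top, bottom}

    @property
    def total_len(self) -> int:
        return len(self.duplex_top)


@dataclass(frozen=True)
class SynthesisConstruct:
    insert_seq: str  # gRNA1 + LHA + payload + RHA + gRNA1(rc)
    payload: str
    vector_seq: str  # circular; insert + backbone
    grna1: GRna1Unit
    arms: HomologyArmPair
    re_pair: tuple[Enzyme, Enzyme] | None = None  # stuffer mode only

    @property
    def cassette_plus_arms_len(self) -> int:
        """Donor length as printed in construct schematics: arms + payload,
        excluding the two flanking gRNA1 units."""
        return self.arms.lha_len + len(self.payload) + self.arms.rha_len

    @property
    def full_insert_len(self) -> int:
        return len(self.insert_seq)


@dataclass(frozen=True)
class DropInPlasmid:
    sequence: str  # circular, rotated so the donor region starts at 0
    donor_region: tuple[int, int]
    sic_name: str
    provenance: str  # {direct_synthesis, subcloned}
    grna1: GRna1Unit
    arms: HomologyArmPair

    def donor_region_seq(self) -> str:
        return self.sequence[self.donor_region[0] : self.donor_region[1]]


def simulate_lambda_exo(duplex_top: str, phosphorylated_strand: str) -> str:
    """Return the strand surviving lambda exonuclease, 5'->3'.

    The enzyme degrades 5'-phosphorylated strands preferentially, so the
    non-phosphorylated strand survives.
    """
    if phosphorylated_strand == "bottom":
        return duplex_top
    if phosphorylated_strand == "top":
        return revcomp(duplex_top)
    raise ValueError(f"phosphorylated_strand must be top|bottom, got "
                     f"{phosphorylated_strand!r}")


def build_ssdna_design(
    arms: HomologyArmPair,
    template: CassetteTemplate,
    phosphorylate_forward: bool = False,
) -> tuple[LongPrimerPair, SsDNADonor]:
    """Long primers and the predicted PCR/exonuclease products.

    By default the reverse primer is 5'-phosphorylated, so the bottom
    strand is degraded and the surviving ssDNA donor equals the top strand
    LHA + core + RHA.
    """
    for arm, label in ((arms.lha, "LHA"), (arms.rha, "RHA")):
        if template.fwd_priming in arm or template.rev_priming in arm:
            log.warning(
                "%s contains a universal priming segment: mispriming risk", label
            )
    primers = LongPrimerPair(
        forward=arms.lha + template.fwd_priming,
        reverse=revcomp(arms.rha) + revcomp(template.rev_priming),
        reverse_5prime_phosphorylated=not phosphorylate_forward,
    )
    duplex_top = arms.lha + template.core_seq + arms.rha
    phosphorylated = "top" if phosphorylate_forward else "bottom"
    ssdna = simulate_lambda_exo(duplex_top, phosphorylated)
    donor = SsDNADonor(
        duplex_top, ssdna,
        surviving_strand="bottom" if phosphorylate_forward else "top",
    )
    return primers, donor


DEFAULT_STUFFER_SPACER = "ACTGGTCAAGTTCACCTGAG"


def make_stuffer(re1: Enzyme, re2: Enzyme,
                 spacer: str = DEFAULT_STUFFER_SPACER) -> str:
    """RE1 site + spacer + RE2 site: the replaceable restriction cassette."""
    return re1.site + spacer + re2.site


def synthetic_puc57_backbone(seed: int = 57) -> str:
    """Synthetic stand-in for a pUC57-class circular vector backbone.

    Deterministic 2.7-kb sequence scrubbed of every catalog enzyme site and
    of the gRNA1 target; any real circular vector record can be used
    instead.
    """
    rng = random.Random(seed)
    seq = "".join(rng.choice("ACGT") for _ in range(2700))
    motifs = [e.site for e in CATALOG]
    g = GRna1Unit()
    motifs += [g.target, revcomp(g.target)]
    changed = True
    while changed:
        changed = False
        wrapped = seq + seq[:12]
        for motif in motifs:
            idx = wrapped.find(motif)
            if idx != -1:
                mid = (idx + len(motif) // 2) % len(seq)
                seq = (seq[:mid]
                       + {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[mid]]
                       + seq[mid + 1 :])
                changed = True
    return seq


def build_synthesis_construct(
    arms: HomologyArmPair,
    payload: str,
    grna1: GRna1Unit,
    genome_map: Mapping[str, GenomeSequence],
    backbone: str | None = None,
    re_pair: tuple[Enzyme, Enzyme] | None = None,
) -> SynthesisConstruct:
    """Assemble gRNA1 - LHA - payload - RHA - gRNA1 in a circular vector.

    ``payload`` is either a cassette core (direct synthesis of a small
    donor) or a restriction stuffer from :func:`make_stuffer` (pass the
    matching ``re_pair``). The gRNA1 protospacer+PAM must have zero exact
    matches in the target genome, both strands — otherwise Cas9 would cut
    the host chromosome at the release sites.
    """
    n_hits = count_genome_matches(genome_map, grna1.protospacer, grna1.pam)
    if n_hits:
        raise DonorDesignError(
            f"gRNA1 target {grna1.target} has {n_hits} exact match(es) in "
            "the target genome; choose a different release guide"
        )
    backbone = synthetic_puc57_backbone() if backbone is None else backbone
    if re_pair is not None:
        re1, re2 = re_pair
        if re1.name == re2.name:
            raise DonorDesignError("RE1 and RE2 must differ for directional cloning")
        conflicts = []
        for enz in (re1, re2):
            for label, ctx in (("LHA", arms.lha), ("RHA", arms.rha),
                               ("backbone", backbone)):
                if enz.sites_in(ctx):
                    conflicts.append(f"{enz.name} site in {label}")
        if conflicts:
            alternatives = [
                e.name for e in CATALOG
                if e.name not in (re1.name, re2.name)
                and not any(e.sites_in(c) for c in (arms.lha, arms.rha, backbone))
            ]
            raise DonorDesignError(
                "; ".join(conflicts)
                + f"; suggested alternative enzymes: {', '.join(alternatives)}"
            )
    insert = grna1.left_unit + arms.lha + payload + arms.rha + grna1.right_unit
    vector = insert + backbone
    return SynthesisConstruct(insert, payload, vector, grna1, arms, re_pair)


def simulate_subcloning(
    synthesis: SynthesisConstruct, sic_core: str, sic_name: str
) -> DropInPlasmid:
    """Replace the restriction stuffer with a cassette, directionally.

    In-silico digest of the stuffer plasmid at RE1/RE2, discard of the
    stuffer fragment, and ligation of the cassette carrying matching RE1/RE2
    ends. The reconstituted recognition sites remain as 6-8 nt cloning
    scars flanking the cassette; a cassette presented with swapped ends is
    rejected by the incompatible overhangs.
    """
    if synthesis.re_pair is None:
        raise DonorDesignError("synthesis construct has no restriction stuffer")
    re1, re2 = synthesis.re_pair
    sic_frag = digest_linear_ends(sic_core, re1, re2)
    _stuffer, backbone_frag = digest_circular(synthesis.vector_seq, re1, re2)
    circle = ligate_circular(backbone_frag, sic_frag)
    return _finalize_plasmid(circle, synthesis, sic_core, sic_name, "subcloned")


def build_direct_plasmid(
    arms: HomologyArmPair,
    sic_core: str,
    sic_name: str,
    grna1: GRna1Unit,
    genome_map: Mapping[str, GenomeSequence],
    re_pair: tuple[Enzyme, Enzyme],
    backbone: str | None = None,
) -> DropInPlasmid:
    """Directly synthesized donor plasmid, byte-identical to the subcloned
    product for the same inputs (the RE scars are part of the layout)."""
    re1, re2 = re_pair
    payload = re1.site + sic_core + re2.site
    synth = build_synthesis_construct(arms, payload, grna1, genome_map,
                                      backbone=backbone)
    return _finalize_plasmid(synth.vector_seq, synth, sic_core, sic_name,
                             "direct_synthesis", re_pair=re_pair)


def _finalize_plasmid(
    circle: str,
    synthesis: SynthesisConstruct,
    sic_core: str,
    sic_name: str,
    provenance: str,
    re_pair: tuple[Enzyme, Enzyme] | None = None,
) -> DropInPlasmid:
    re1, re2 = re_pair or synthesis.re_pair
    grna1, arms = synthesis.grna1, synthesis.arms
    donor = (grna1.left_unit + arms.lha + re1.site + sic_core + re2.site
             + arms.rha + grna1.right_unit)
    # rotate the circle so the donor region starts at position 0
    doubled = circle + circle
    idx = doubled.find(donor)
    if idx == -1 or idx >= len(circle):
        raise DonorDesignError("assembled plasmid lacks the expected donor region")
    rotated = doubled[idx : idx + len(circle)]
    plasmid = DropInPlasmid(
        rotated, (0, len(donor)), sic_name, provenance, grna1, arms
    )
    log.info("donor plasmid %s: %d bp, donor region %d bp, GC %.1f%%",
             sic_name, len(rotated), len(donor), 100 * gc_fraction(rotated))
    return plasmid


def simulate_linearization(
    plasmid_seq: str, grna1: GRna1Unit
) -> tuple[Fragment, ...]:
    """Blunt Cas9 cuts at every gRNA1 target on the circular plasmid.

    Requires exactly two cut sites (the designed release sites); returns
    the two blunt fragments, donor first when identifiable by the caller.
    Cut positions follow the 3-nt rule on each strand.
    """
    n = len(plasmid_seq)
    wrapped = plasmid_seq + plasmid_seq[: len(grna1.target) - 1]
    cuts = []
    target, rc = grna1.target, revcomp(grna1.target)
    for i in range(n):
        if wrapped.startswith(target, i):
            cuts.append((i + len(grna1.protospacer) - CUT_OFFSET) % n)
        if wrapped.startswith(rc, i):
            cuts.append((i + len(grna1.pam) + CUT_OFFSET) % n)
    if len(cuts) != 2:
        raise DonorDesignError(
            f"expected exactly 2 gRNA1 cut sites on the plasmid, found {len(cuts)}"
        )
    c1, c2 = sorted(cuts)
    return (
        Fragment(circular_slice(plasmid_seq, c1, c2), "", ""),
        Fragment(circular_slice(plasmid_seq, c2, c1), "", ""),
    )


def released_donor(
    plasmid: DropInPlasmid,
) -> tuple[str, tuple[int, int]]:
    """Cas9-released donor fragment and its (left, right) remnant lengths.

    The donor fragment is the linearization product carrying LHA..RHA; with
    PAM-inward gRNA1 units it equals the donor region minus the PAM-distal
    17 nt of each unit, i.e. a 3-nt + PAM remnant on each end.
    """
    frags = simulate_linearization(plasmid.sequence, plasmid.grna1)
    marker = plasmid.arms.lha
    donor = next((f for f in frags if marker in f.seq and plasmid.arms.rha in f.seq),
                 None)
    if donor is None:
        raise DonorDesignError("no linearization fragment contains both arms")
    left_remnant = donor.seq.find(marker)
    right_remnant = len(donor.seq) - (donor.seq.rfind(plasmid.arms.rha)
                                      + plasmid.arms.rha_len)
    return donor.seq, (left_remnant, right_remnant)
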