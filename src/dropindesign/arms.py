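"""Homology-arm extraction around the blunt Cas9 cut.

The left homology arm (LHA) is the ``lha_len`` nt immediately 5' of the
blunt cut and the right arm (RHA) the ``rha_len`` nt immediately 3' of it,
both expressed on the *gene coding strand* so that LHA is always
transcriptionally upstream of the insertion. Defaults are the symmetric
100/100 nt arms used throughout the drop-in strategy; asymmetric lengths
are supported but carry no special logic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from ._util import revcomp
from .genome import GenomeSequence, StrainVariant
from .guides import GuideTarget


class ArmDesignError(ValueError):
    """Arm cannot be extracted (contig edge, N content)."""


@dataclass(frozen=True)
class HomologyArmPair:
    lha: str  # gene coding-strand orientation, transcriptionally upstream
    rha: str
    cut_site: int  # interbase genomic
    orientation: str  # gene strand used for normalization
    flags: frozenset[str] = frozenset()

    @property
    def lha_len(self) -> int:
        return len(self.lha)

    @property
    def rha_len(self) -> int:
        return len(self.rha)

    def genomic_window(self) -> str:
        """Reference forward-strand window [cut-lha, cut+rha) the arms cover."""
        if self.orientation == "+":
            return self.lha + self.rha
        return revcomp(self.rha) + revcomp(self.lha)


def design_arms(
    genome: GenomeSequence,
    guide: GuideTarget,
    gene_strand: str = "+",
    lha_len: int = 100,
    rha_len: int = 100,
    forbidden_sites: Iterable[str] = (),
    variants: Sequence[StrainVariant] = (),
    grna1_site: str | None = None,
) -> HomologyArmPair:
    """Extract and vet homology arms around ``guide.cut_site``.

    Arms are taken on the reference forward strand then reverse-complemented
    and swapped for minus-strand genes. Any N in an arm is a hard error;
    variant overlap, forbidden restriction motifs and gRNA1 occurrences are
    reported as flags (both strands searched for motifs) so the caller can
    demote the site and try the next guide.
    """
    if lha_len < 20 or rha_len < 20:
        raise ArmDesignError("arm lengths must be >= 20 nt")
    cut = guide.cut_site
    if cut - lha_len < 0 or cut + rha_len > len(genome.sequence):
        raise ArmDesignError(
            f"cut site {cut} within {max(lha_len, rha_len)} nt of the edge of "
            f"contig {genome.contig_id!r}"
        )
    if gene_strand == "+":
        lha = genome.slice(cut - lha_len, cut)
        rha = genome.slice(cut, cut + rha_len)
        window = (cut - lha_len, cut + rha_len)
    else:
        lha = revcomp(genome.slice(cut, cut + lha_len))
        rha = revcomp(genome.slice(cut - rha_len, cut))
        window = (cut - rha_len, cut + lha_len)

    flags = set()
    if "N" in lha or "N" in rha:
        raise ArmDesignError(
            f"homology arm around cut {cut} contains N; site disqualified"
        )
    both = lha + rha
    for motif in forbidden_sites:
        if motif in both or revcomp(motif) in both:
            flags.add("contains_forbidden_RE_site")
    if grna1_site and (grna1_site in both or revcomp(grna1_site) in both):
        flags.add("contains_gRNA1_site")
    for v in variants:
        vs, ve = v.interval
        if vs < window[1] and ve > window[0]:
            flags.add("contains_variant")
            break
    return HomologyArmPair(lha, rha, cut, gene_strand, frozenset(flags))
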