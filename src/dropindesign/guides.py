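"""SpCas9 guide enumeration, variant-aware filtering and ranking.

Model: a guide is a 20-nt protospacer immediately 5' of an NGG PAM on
either strand. Cas9 cuts bluntly between positions 17 and 18 of the
protospacer, i.e. 3 nt 5' of the PAM. In interbase genomic coordinates:

* plus strand:  cut_site = protospacer_end - 3
* minus strand: cut_site = protospacer_start + 3

so the left homology arm of a donor ends exactly 3 nt before the PAM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import revcomp
from .genome import GenomeSequence, CodingIntron, StrainVariant

log = logging.getLogger(__name__)

PROTOSPACER_LEN = 20
PAM_LEN = 3
CUT_OFFSET = 3  # nt between blunt cut and PAM-proximal protospacer end


@dataclass(frozen=True)
class GuideTarget:
    protospacer: str  # guide-strand sequence, 20 nt
    pam: str  # guide-strand NGG, immediately 3' of the protospacer
    strand: str  # {+, -} relative to the reference
    protospacer_start: int  # interbase genomic
    protospacer_end: int
    cut_site: int  # interbase genomic blunt-cut coordinate
    variant_clean: bool = True
    distance_to_nearest_splice_junction: int | None = None

    @property
    def footprint(self) -> tuple[int, int]:
        """Genomic interval covered by protospacer + PAM."""
        if self.strand == "+":
            return (self.protospacer_start, self.protospacer_end + PAM_LEN)
        return (self.protospacer_start - PAM_LEN, self.protospacer_end)


class NoViableGuideError(RuntimeError):
    """Raised when every candidate guide was excluded; carries the reasons."""

    def __init__(self, exclusions: dict[str, str]):
        self.exclusions = exclusions
        detail = "; ".join(f"{k}: {v}" for k, v in exclusions.items()) or "no candidates"
        super().__init__(f"no viable guide ({detail})")


def _is_pam(s: str) -> bool:
    return len(s) == 3 and s[1:] == "GG" and s[0] in "ACGT"


def scan_guides(genome: GenomeSequence, window: tuple[int, int]) -> list[GuideTarget]:
    """Enumerate every N20-NGG guide fully inside `window`, both strands.

    Protospacers containing N are excluded. Result is sorted by cut site,
    then coordinate, then strand (+ before -).
    """
    start, end = window
    if end - start < PROTOSPACER_LEN + PAM_LEN:
        raise ValueError("window shorter than 23 nt")
    seq = genome.slice(start, end)
    guides: list[GuideTarget] = []
    n = len(seq)
    for i in range(n - 22):
        kmer = seq[i : i + 23]
        # plus strand: [proto 20][NGG]
        if _is_pam(kmer[20:]) and "N" not in kmer[:20]:
            ps, pe = start + i, start + i + 20
            guides.append(
                GuideTarget(kmer[:20], kmer[20:], "+", ps, pe, cut_site=pe - CUT_OFFSET)
            )
        # minus strand: forward-strand image is [CCN][proto-revcomp 20]
        if kmer.startswith("CC") and kmer[2] in "ACGT" and "N" not in kmer[3:]:
            ps, pe = start + i + 3, start + i + 23
            guides.append(
                GuideTarget(
                    revcomp(kmer[3:]), revcomp(kmer[:3]), "-", ps, pe,
                    cut_site=ps + CUT_OFFSET,
                )
            )
    guides.sort(key=lambda g: (g.cut_site, g.protospacer_start, g.strand != "+"))
    return guides


def filter_by_variants(
    guides: Sequence[GuideTarget],
    variants: Sequence[StrainVariant],
    pad: int = 0,
) -> list[GuideTarget]:
    """Flag guides whose protospacer+PAM (padded) overlaps any variant.

    Non-clean guides are retained but marked ``variant_clean=False`` so the
    ranker demotes them; strain variation in the target site prevents
    cutting and is a common cause of failed integrations.
    """
    out = []
    for g in guides:
        fs, fe = g.footprint
        fs, fe = fs - pad, fe + pad
        clean = all(v.interval[1] <= fs or v.interval[0] >= fe for v in variants)
        out.append(replace(g, variant_clean=clean))
    return out


def arm_feasible(
    genome: GenomeSequence,
    guide: GuideTarget,
    lha_len: int = 100,
    rha_len: int = 100,
    forbidden_sites: Iterable[str] = (),
) -> bool:
    """Can 100-nt-class homology arms be taken around this cut?

    Fails when the arms would run off the contig, contain N, or contain a
    forbidden motif (restriction site or gRNA1 target, either strand).
    """
    cut = guide.cut_site
    if cut - lha_len < 0 or cut + rha_len > len(genome.sequence):
        return False
    window = genome.sequence[cut - lha_len : cut + rha_len]
    if "N" in window:
        return False
    for motif in forbidden_sites:
        if motif in window or revcomp(motif) in window:
            return False
    return True


def rank_guides(
    guides: Sequence[GuideTarget],
    intron: CodingIntron,
    min_splice_distance: int = 50,
    genome: GenomeSequence | None = None,
    lha_len: int = 100,
    rha_len: int = 100,
    forbidden_sites: Iterable[str] = (),
) -> list[GuideTarget]:
    """Exclude junction-proximal guides and rank the rest.

    Order: variant-clean first, then arm-feasible, then by centrality in
    the intron; ties broken by genomic coordinate then strand (+ before -).
    Raises :class:`NoViableGuideError` with per-guide reasons when nothing
    survives.
    """
    exclusions: dict[str, str] = {}
    kept: list[tuple[tuple, GuideTarget]] = []
    midpoint = (intron.start + intron.end) / 2
    for g in guides:
        if not (intron.start <= g.cut_site < intron.end):
            raise ValueError(
                f"guide cut site {g.cut_site} outside intron "
                f"[{intron.start},{intron.end})"
            )
        dist = min(g.cut_site - intron.start, intron.end - g.cut_site)
        g = replace(g, distance_to_nearest_splice_junction=dist)
        label = f"{g.protospacer_start}{g.strand}"
        if dist < min_splice_distance:
            exclusions[label] = (
                f"cut {dist} nt from splice junction (< {min_splice_distance})"
            )
            continue
        feasible = (
            arm_feasible(genome, g, lha_len, rha_len, forbidden_sites)
            if genome is not None
            else True
        )
        key = (
            not g.variant_clean,
            not feasible,
            abs(g.cut_site - midpoint),
            g.protospacer_start,
            g.strand != "+",
        )
        kept.append((key, g))
    if not kept:
        raise NoViableGuideError(exclusions)
    kept.sort(key=lambda kg: kg[0])
    return [g for _, g in kept]


def find_exact_matches(
    genome_map: Mapping[str, GenomeSequence], protospacer: str, pam: str
) -> list[tuple[str, int, str]]:
    """Exact protospacer+PAM match sites genome-wide, both strands.

    Returns (contig, forward-strand start of the 23-mer, strand). Used for
    the reported (non-blocking) off-target listing of gene guides and for
    the blocking gRNA1 absence check.
    """
    target = protospacer + pam
    rc = revcomp(target)
    hits = []
    for cid, contig in genome_map.items():
        seq = contig.sequence
        for query, strand in ((target, "+"), (rc, "-")):
            pos = seq.find(query)
            while pos != -1:
                hits.append((cid, pos, strand))
                pos = seq.find(query, pos + 1)
    return sorted(hits)


def count_genome_matches(
    genome_map: Mapping[str, GenomeSequence], protospacer: str, pam: str
) -> int:
    """Number of exact protospacer+PAM occurrences genome-wide, both strands."""
    return len(find_exact_matches(genome_map, protospacer, pam))


def guide_report(
    gene_id: str, intron_index: int, guides: Sequence[GuideTarget]
) -> pd.DataFrame:
    """Guide report table (cut sites shown 1-based for display)."""
    return pd.DataFrame(
        {
            "gene_id": gene_id,
            "intron_index": intron_index,
            "protospacer": [g.protospacer for g in guides],
            "pam": [g.pam for g in guides],
            "strand": [g.strand for g in guides],
            "cut_site_1based": [g.cut_site + 1 for g in guides],
            "variant_clean": [g.variant_clean for g in guides],
            "splice_junction_distance": [
                g.distance_to_nearest_splice_junction for g in guides
            ],
        }
    )
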