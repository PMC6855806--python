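"""Minimal restriction digestion / ligation model for directional subcloning.

The catalog is restricted to palindromic enzymes leaving 5' overhangs, which
is all the single-step drop-in cloning scheme needs: two *different*
enzymes flanking the stuffer give incompatible overhangs and therefore force
the orientation of the incoming cassette.

A linear :class:`Fragment` carries its top-strand sequence between the two
top-strand cut positions plus the 5'-overhang strings at each end. Because
top-strand cut positions partition the parent sequence, ligation is exact
string concatenation and digest -> ligate -> digest is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._util import circular_slice, revcomp


class CloningError(ValueError):
    pass


@dataclass(frozen=True)
class Enzyme:
    name: str
    site: str  # palindromic recognition site
    cut_top: int  # top-strand cut offset from site start
    cut_bottom: int  # bottom-strand cut offset; > cut_top => 5' overhang

    @property
    def overhang(self) -> str:
        return self.site[self.cut_top : self.cut_bottom]

    def sites_in(self, seq: str, circular: bool = False) -> list[int]:
        probe = seq + seq[: len(self.site) - 1] if circular else seq
        hits, pos = [], probe.find(self.site)
        while pos != -1:
            hits.append(pos % len(seq) if circular else pos)
            pos = probe.find(self.site, pos + 1)
        return hits


#: Stable catalog order: `choose_re_pair` picks the first conflict-free pair.
CATALOG: tuple[Enzyme, ...] = (
    Enzyme("EcoRI", "GAATTC", 1, 5),
    Enzyme("NotI", "GCGGCCGC", 2, 6),
    Enzyme("BamHI", "GGATCC", 1, 5),
    Enzyme("XhoI", "CTCGAG", 1, 5),
    Enzyme("NheI", "GCTAGC", 1, 5),
    Enzyme("AscI", "GGCGCGCC", 2, 6),
    Enzyme("SpeI", "ACTAGT", 1, 5),
    Enzyme("AvrII", "CCTAGG", 1, 5),
)


@dataclass(frozen=True)
class Fragment:
    seq: str  # top strand between top-strand cut positions
    left_ov: str  # 5' overhang carried at the left end
    right_ov: str  # 5' overhang expected to pair at the right end

    def __len__(self) -> int:
        return len(self.seq)

    def flipped(self) -> "Fragment":
        """The same physical molecule read from the other strand."""
        return Fragment(revcomp(self.seq), revcomp(self.right_ov),
                        revcomp(self.left_ov))


def digest_circular(seq: str, enz_a: Enzyme, enz_b: Enzyme) -> tuple[Fragment, Fragment]:
    """Cut a circular molecule once with each enzyme.

    Returns (fragment from A's cut to B's cut, fragment from B's to A's),
    walking the top strand forward. Each enzyme must cut exactly once.
    """
    for enz in (enz_a, enz_b):
        n = len(enz.sites_in(seq, circular=True))
        if n != 1:
            raise CloningError(f"{enz.name} cuts {n} times; need exactly 1")
    ca = (enz_a.sites_in(seq, circular=True)[0] + enz_a.cut_top) % len(seq)
    cb = (enz_b.sites_in(seq, circular=True)[0] + enz_b.cut_top) % len(seq)
    frag_ab = Fragment(circular_slice(seq, ca, cb), enz_a.overhang, enz_b.overhang)
    frag_ba = Fragment(circular_slice(seq, cb, ca), enz_b.overhang, enz_a.overhang)
    return frag_ab, frag_ba


def digest_linear_ends(core: str, enz_a: Enzyme, enz_b: Enzyme) -> Fragment:
    """Digest ``enz_a.site + core + enz_b.site`` and keep the middle fragment.

    This is how an insert released (or synthesized) with terminal sites is
    prepared for ligation. The core must not contain either site.
    """
    for enz in (enz_a, enz_b):
        if enz.sites_in(core):
            raise CloningError(f"internal {enz.name} site in insert")
    full = enz_a.site + core + enz_b.site
    return Fragment(
        full[enz_a.cut_top : len(enz_a.site) + len(core) + enz_b.cut_top],
        enz_a.overhang,
        enz_b.overhang,
    )


def ligate_circular(a: Fragment, b: Fragment) -> str:
    """Join two fragments at both ends into a circle.

    5'-overhang ends pair when the overhang strings match (palindromic
    overhangs are self-complementary), which rejects a flipped insert
    whenever the two ends came from different enzymes.
    """
    if a.right_ov != b.left_ov or b.right_ov != a.left_ov:
        raise CloningError(
            f"incompatible overhangs: {a.right_ov}/{b.left_ov} and "
            f"{b.right_ov}/{a.left_ov}"
        )
    return a.seq + b.seq


def choose_re_pair(
    candidates: tuple[Enzyme, ...], context_seqs: tuple[str, ...]
) -> tuple[Enzyme, Enzyme]:
    """First catalog-order pair of distinct enzymes absent from every
    context sequence (arms, cassette core, vector backbone).

    Palindromic sites make a top-strand search cover both strands. Raises a
    structured error listing each enzyme's conflict when no pair works.
    """
    conflicts: dict[str, str] = {}
    viable = []
    for enz in candidates:
        hit = next(
            (i for i, ctx in enumerate(context_seqs) if enz.sites_in(ctx)), None
        )
        if hit is None:
            viable.append(enz)
        else:
            conflicts[enz.name] = f"site {enz.site} present in context sequence {hit}"
    if len(viable) >= 2:
        return viable[0], viable[1]
    detail = "; ".join(f"{k}: {v}" for k, v in conflicts.items())
    raise CloningError(f"no viable enzyme pair ({detail})")
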