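"""Cassette template data model and the bundled synthetic template library.

A :class:`CassetteTemplate` is the attP...attP cassette core that gets
flanked by gene-specific homology arms: a neutral landing site
(attP-3XP3-EGFP-attP), a protein trap (attP-SA-Linker-sfGFP-Linker-SD-attP),
the two synthesized gene traps (attP-SA-3XSTOP-minipolyA-U6gRNA1-attP and
attP-SA-T2A-miniGAL4-minipolyA-U6gRNA1-attP) and the full CRIMIC artificial
exon (attP-FRT-SA-T2A-GAL4-polyA-3XP3-EGFP-FRT-attP).

The bundled library consists of *synthetic stand-in* sequences: element
layout, feature intervals and core lengths are faithful to the published
constructs (1242 / 1192 / 515 / 1768 nt cores, giving 1442 / 1392 / 715 /
1968 nt with two 100-nt arms), but filler nucleotides are generated
deterministically rather than copied from the distributed vector files.
Real template records can be supplied in their place; every design
operation takes templates as data.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace

from ._util import DNA_ALPHABET

MUTAGENIC_CLASSES = ("gene_trap", "protein_trap", "neutral_landing_site")

FWD_PRIMING_LEN = 26  # M13-derived universal forward priming segment
REV_PRIMING_LEN = 24  # M13-derived universal reverse priming segment


class CassetteError(ValueError):
    pass


@dataclass(frozen=True)
class CassetteTemplate:
    """An annotated cassette core plus universal priming segments.

    ``features`` maps label -> half-open interval in core coordinates.
    ``phase_variant`` is the reading-frame offset (0/1/2) the splice
    acceptor junction expects of the host intron, or None for cassettes
    without a reading frame (landing sites).
    """

    name: str
    core_seq: str
    features: tuple[tuple[str, tuple[int, int]], ...]
    mutagenic_class: str
    phase_variant: int | None = 0
    synthetic_stand_in: bool = False

    def __post_init__(self):
        if set(self.core_seq) - DNA_ALPHABET:
            raise CassetteError(f"{self.name}: non-DNA characters in core")
        if len(self.core_seq) < FWD_PRIMING_LEN + REV_PRIMING_LEN:
            raise CassetteError(f"{self.name}: core shorter than priming segments")
        if self.mutagenic_class not in MUTAGENIC_CLASSES:
            raise CassetteError(f"{self.name}: unknown class {self.mutagenic_class}")
        for label, (s, e) in self.features:
            if not (0 <= s < e <= len(self.core_seq)):
                raise CassetteError(f"{self.name}: feature {label} outside core")

    @property
    def fwd_priming(self) -> str:
        """26-nt universal priming segment at the core 5' end."""
        return self.core_seq[:FWD_PRIMING_LEN]

    @property
    def rev_priming(self) -> str:
        """24-nt segment at the core 3' end (primer is its revcomp)."""
        return self.core_seq[-REV_PRIMING_LEN:]

    def feature(self, label: str) -> tuple[int, int]:
        for lab, iv in self.features:
            if lab == label:
                return iv
        raise KeyError(f"{self.name}: no feature {label!r}")

    def has_feature(self, label: str) -> bool:
        return any(lab == label for lab, _ in self.features)

    def with_phase(self, phase: int) -> "CassetteTemplate":
        """Derive the phase variant matching an intron of the given phase.

        A phase-p intron interrupts a codon after p of its nucleotides, so
        the artificial exon must open with (3-p) % 3 pad nt to complete
        that codon before the cassette reading frame starts. Protein-trap
        (SA...SD) cassettes additionally get p pad nt just before the
        splice donor so the exon length stays a multiple of 3 and the
        downstream native CDS keeps its frame. Phase 0 is the canonical
        template.
        """
        if self.phase_variant is None:
            raise CassetteError(f"{self.name}: cassette has no reading frame")
        if phase not in (0, 1, 2):
            raise CassetteError(f"invalid phase {phase}")
        if phase == self.phase_variant:
            return self
        if self.phase_variant != 0:
            raise CassetteError("derive phase variants from the phase-0 template")
        # pad bases chosen so no stop codon can form with the flanking
        # host nucleotides (stops all start with T, none end in C)
        start_pad_seq = {0: "", 1: "GC", 2: "C"}[phase]
        end_pad_seq = ({0: "", 1: "G", 2: "GC"}[phase]
                       if self.has_feature("SD") else "")
        start_pad, end_pad = len(start_pad_seq), len(end_pad_seq)
        sa_end = self.feature("SA")[1]
        sd_start = self.feature("SD")[0] if end_pad else None

        # insert pads (end pad first so earlier coordinates stay valid)
        core = self.core_seq
        if end_pad:
            core = core[:sd_start] + end_pad_seq + core[sd_start:]
        core = core[:sa_end] + start_pad_seq + core[sa_end:]
        feats = []
        for lab, (s, e) in self.features:
            ns = s + (start_pad if s >= sa_end else 0)
            ne = e + (start_pad if e > sa_end else 0)
            if sd_start is not None:
                ns += end_pad if s >= sd_start else 0
                ne += end_pad if e > sd_start else 0
            feats.append((lab, (ns, ne)))
        return replace(
            self, name=f"{self.name}.phase{phase}", core_seq=core,
            features=tuple(feats), phase_variant=phase,
        )


# -- synthetic stand-in elements ------------------------------------------
# Fixed real element sequences where they are short and public knowledge;
# everything else is deterministic filler from a dedicated PRNG stream.

T2A = "GAGGGCAGAGGAAGTCTGCTAACATGCGGTGACGTCGAGGAGAATCCTGGACCT"  # 54 nt
FRT = "GAAGTTCCTATTCTCTAGAAAGTATAGGAACTTC"  # 34 nt
TRIPLE_STOP = "TAAGTAAGTAAG"  # stop codons in all three frames
POLYA_SIGNAL = "AATAAA"

# gRNA1: a guide with no target in the host genome, used to release the
# donor from its plasmid in vivo. Synthetic stand-in spacer; the absence
# check against the supplied genome is always enforced at design time.
GRNA1_PROTOSPACER = "GTCGTAAGCTGACCGTACTA"
GRNA1_PAM = "CGG"

_SAFE_CODONS = (
    "GCT GCA GCC GGT GGA GGC TCT TCC AGC ACT ACC ACA CTG CTC TTG GTT GTC GTG "
    "GAT GAC GAA GAG AAA AAG AAT AAC CAA CAG CAT CAC ATT ATC ATG TGG TTT TTC "
    "CCT CCA CCG CGT CGC AGA"
).split()


def _rng_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _orf(rng: random.Random, n_nt: int, stop: bool) -> str:
    """Stop-free reading frame of n_nt (multiple of 3), optional final stop."""
    assert n_nt % 3 == 0
    n_codons = n_nt // 3 - (1 if stop else 0)
    body = "ATG" + "".join(rng.choice(_SAFE_CODONS) for _ in range(n_codons - 1))
    return body + ("TAA" if stop else "")


def _splice_acceptor(rng: random.Random, n: int) -> str:
    """Intron-side acceptor region: branch-point-ish filler, a pyrimidine
    tract, and the invariant terminal AG."""
    tract = "".join(rng.choice("CT") for _ in range(12))
    return _rng_dna(rng, n - 14) + tract + "AG"


def _splice_donor(rng: random.Random, n: int) -> str:
    return "GT" + _rng_dna(rng, n - 2)


def _u6_grna1(rng: random.Random, n: int) -> str:
    """U6-promoter-driven gRNA1 marker region.

    Contains the gRNA1 spacer followed by a T-rich scaffold start so the
    spacer is never followed by NGG (no accidental third Cas9 target on
    the plasmid)."""
    promoter = _rng_dna(rng, n - len(GRNA1_PROTOSPACER) - 30)
    return promoter + GRNA1_PROTOSPACER + "TTTT" + _rng_dna(rng, 26)


def _assemble(parts: list[tuple[str, str]]) -> tuple[str, tuple]:
    feats, chunks, pos = [], [], 0
    for label, seq in parts:
        if label:
            feats.append((label, (pos, pos + len(seq))))
        chunks.append(seq)
        pos += len(seq)
    return "".join(chunks), tuple(feats)


def synthetic_template_library(seed: int = 20191101) -> dict[str, CassetteTemplate]:
    """The five bundled cassette templates as synthetic stand-ins.

    Core lengths reproduce the published construct arithmetic:
    1242 (EGFP landing site), 1192 (sfGFP protein trap), 515 (3XSTOP gene
    trap), 1768 (T2A-miniGAL4 gene trap), so that with two 100-nt arms the
    donors measure 1442 / 1392 / 715 / 1968 nt.
    """
    rng = random.Random(seed)
    attp = _rng_dna(rng, 40)
    linker = "GGTGGAAGCGGAGGTAGTGGCGGTTCAGGAGGCAGT"  # (Gly-Gly-Ser)x4, 36 nt

    def pA(n: int) -> str:
        return POLYA_SIGNAL + _rng_dna(rng, n - 6)

    lib: dict[str, CassetteTemplate] = {}

    core, feats = _assemble([
        ("attP_L", attp),
        ("3XP3", _rng_dna(rng, 300)),
        ("EGFP", _orf(rng, 720, stop=True)),
        ("polyA", pA(142)),
        ("attP_R", attp),
    ])
    lib["attP-3XP3-EGFP-attP"] = CassetteTemplate(
        "attP-3XP3-EGFP-attP", core, feats, "neutral_landing_site",
        phase_variant=None, synthetic_stand_in=True,
    )

    core, feats = _assemble([
        ("attP_L", attp),
        ("SA", _splice_acceptor(rng, 200)),
        ("linker_L", linker),
        ("sfGFP", _orf(rng, 714, stop=False)),
        ("linker_R", linker),
        ("SD", _splice_donor(rng, 126)),
        ("attP_R", attp),
    ])
    lib["attP-SA-Linker-sfGFP-Linker-SD-attP"] = CassetteTemplate(
        "attP-SA-Linker-sfGFP-Linker-SD-attP", core, feats, "protein_trap",
        phase_variant=0, synthetic_stand_in=True,
    )

    core, feats = _assemble([
        ("attP_L", attp),
        ("SA", _splice_acceptor(rng, 100)),
        ("3XSTOP", TRIPLE_STOP),
        ("minipolyA", pA(35)),
        ("U6-gRNA1", _u6_grna1(rng, 288)),
        ("attP_R", attp),
    ])
    lib["attP-SA-3XSTOP-minipolyA-U6gRNA1-attP"] = CassetteTemplate(
        "attP-SA-3XSTOP-minipolyA-U6gRNA1-attP", core, feats, "gene_trap",
        phase_variant=0, synthetic_stand_in=True,
    )

    core, feats = _assemble([
        ("attP_L", attp),
        ("SA", _splice_acceptor(rng, 100)),
        ("T2A", T2A),
        ("miniGAL4", _orf(rng, 1200, stop=True)),
        ("minipolyA", pA(35)),
        ("U6-gRNA1", _u6_grna1(rng, 299)),
        ("attP_R", attp),
    ])
    lib["attP-SA-T2A-miniGAL4-minipolyA-U6gRNA1-attP"] = CassetteTemplate(
        "attP-SA-T2A-miniGAL4-minipolyA-U6gRNA1-attP", core, feats, "gene_trap",
        phase_variant=0, synthetic_stand_in=True,
    )

    core, feats = _assemble([
        ("attP_L", attp),
        ("FRT_L", FRT),
        ("SA", _splice_acceptor(rng, 100)),
        ("T2A", T2A),
        ("GAL4", _orf(rng, 2646, stop=True)),
        ("polyA", pA(135)),
        ("3XP3", _rng_dna(rng, 300)),
        ("EGFP", _orf(rng, 720, stop=True)),
        ("FRT_R", FRT),
        ("attP_R", attp),
    ])
    lib["attP-FRT-SA-T2A-GAL4-polyA-3XP3-EGFP-FRT-attP"] = CassetteTemplate(
        "attP-FRT-SA-T2A-GAL4-polyA-3XP3-EGFP-FRT-attP", core, feats, "gene_trap",
        phase_variant=0, synthetic_stand_in=True,
    )
    return lib
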