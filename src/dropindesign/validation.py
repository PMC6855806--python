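"""In/out genotyping PCR design on the edited allele.

Each integration junction is covered by one pair: a genomic primer on the
reference flank combined with an outward-facing cassette-internal primer
(reverse-oriented in the cassette 5' region, forward-oriented in its 3'
region). Amplicons are constrained to the 200-800 nt window that single-fly
genotyping PCR handles comfortably, targeting 500 nt. Because one primer of
each pair sits inside the insert, the unedited allele gives no product —
that asymmetry is what makes the assay diagnostic for integration.

Melting temperatures use the unified nearest-neighbor parameters of
Allawi & SantaLucia (1997) with the SantaLucia (1998) entropic salt
correction; defaults assume 50 mM monovalent cation and 25 nM of each
primer.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass

import pandas as pd

from ._util import gc_fraction, max_mononucleotide_run, revcomp
from .edits import EditedAllele

R_GAS = 1.987  # cal / (mol K)

# Allawi & SantaLucia 1997 unified NN parameters: dH kcal/mol, dS cal/mol/K
_NN: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT = {"A": (2.3, 4.1), "T": (2.3, 4.1), "G": (0.1, -2.8), "C": (0.1, -2.8)}


class PrimerDesignError(ValueError):
    pass


@dataclass(frozen=True)
class PrimerParams:
    min_len: int = 18
    max_len: int = 25
    gc_min: float = 0.35
    gc_max: float = 0.65
    tm_min: float = 57.0
    tm_max: float = 63.0
    max_run: int = 4
    search_window: int = 700  # genomic flank searched beyond each junction
    internal_window: int = 250  # cassette region searched inside each end
    amplicon_min: int = 200
    amplicon_max: int = 800
    amplicon_target: int = 500
    na_mM: float = 50.0
    primer_nM: float = 25.0


def compute_tm(primer: str, params: PrimerParams = PrimerParams()) -> float:
    """Nearest-neighbor duplex melting temperature in deg C.

    Tm = dH / (dS_salt + R ln k) with k = (c1 - c2/2) for non-self-
    complementary duplexes and the 0.368 (N-1) ln[Na+] entropy correction.
    Strand-symmetric, so Tm(p) == Tm(revcomp(p)).
    """
    if not (10 <= len(primer) <= 40):
        raise PrimerDesignError(f"primer length {len(primer)} outside [10, 40]")
    if "N" in primer:
        raise PrimerDesignError("N in primer")
    d_h, d_s = 0.0, 0.0
    for base in (primer[0], primer[-1]):
        ih, is_ = _INIT[base]
        d_h += ih
        d_s += is_
    for i in range(len(primer) - 1):
        nh, ns = _NN[primer[i : i + 2]]
        d_h += nh
        d_s += ns
    selfcomp = primer == revcomp(primer)
    if selfcomp:
        d_s += -1.4
        k = params.primer_nM * 1e-9
    else:
        k = (params.primer_nM - params.primer_nM / 2) * 1e-9
    d_s += 0.368 * (len(primer) - 1) * math.log(params.na_mM / 1000.0)
    return d_h * 1000.0 / (d_s + R_GAS * math.log(k)) - 273.15


@dataclass(frozen=True)
class Primer:
    name: str
    seq: str
    site: tuple[int, int]  # binding footprint on the edited allele, interbase
    orientation: str  # {+, -} on the edited allele
    tm: float
    gc: float


@dataclass(frozen=True)
class ValidationPrimerSet:
    genomic_fwd: Primer
    insert_rev_5p: Primer
    insert_fwd_3p: Primer
    genomic_rev: Primer
    predicted_amplicons: tuple[tuple[str, int, tuple[int, int]], ...]

    @property
    def primers(self) -> tuple[Primer, ...]:
        return (self.genomic_fwd, self.insert_rev_5p,
                self.insert_fwd_3p, self.genomic_rev)


def _passes(seq: str, p: PrimerParams) -> bool:
    if "N" in seq:
        return False
    if not (p.gc_min <= gc_fraction(seq) <= p.gc_max):
        return False
    if max_mononucleotide_run(seq) > p.max_run:
        return False
    return p.tm_min <= compute_tm(seq, p) <= p.tm_max


def _unique_in(allele: str, seq: str) -> bool:
    return allele.count(seq) + allele.count(revcomp(seq)) == 1


def _candidates(
    allele: str, lo: int, hi: int, orientation: str, p: PrimerParams
) -> list[tuple[int, int, str]]:
    """(site_start, site_end, primer_seq) for every passing candidate whose
    binding footprint lies within [lo, hi)."""
    out = []
    for start in range(lo, hi - p.min_len + 1):
        for length in range(p.min_len, p.max_len + 1):
            end = start + length
            if end > hi:
                break
            site = allele[start:end]
            seq = site if orientation == "+" else revcomp(site)
            if _passes(seq, p) and _unique_in(allele, seq):
                out.append((start, end, seq))
    return out


def _best_pair(
    fwd: list[tuple[int, int, str]],
    rev: list[tuple[int, int, str]],
    p: PrimerParams,
) -> tuple[tuple[int, int, str], tuple[int, int, str], int]:
    """Pair minimizing |amplicon - target| within bounds; deterministic
    tie-break on (length, fwd start, rev end)."""
    if not fwd or not rev:
        raise PrimerDesignError("no candidate primer on one side of a junction")
    rev_sorted = sorted(rev, key=lambda c: c[1])
    rev_ends = [c[1] for c in rev_sorted]
    best = None
    for f in fwd:
        ideal = f[0] + p.amplicon_target
        i = bisect.bisect_left(rev_ends, ideal)
        for j in range(max(0, i - 2), min(len(rev_sorted), i + 3)):
            r = rev_sorted[j]
            length = r[1] - f[0]
            if not (p.amplicon_min <= length <= p.amplicon_max):
                continue
            key = (abs(length - p.amplicon_target), length, f[0], r[1])
            if best is None or key < best[0]:
                best = (key, f, r, length)
    if best is None:
        raise PrimerDesignError(
            "no primer pair yields an amplicon within "
            f"[{p.amplicon_min}, {p.amplicon_max}] nt"
        )
    return best[1], best[2], best[3]


def design_validation_primers(
    edited: EditedAllele,
    params: PrimerParams = PrimerParams(),
    name_prefix: str = "val",
) -> ValidationPrimerSet:
    """Design the four in/out genotyping primers on an edited allele.

    Candidates are filtered on length, GC 35-65%, Tm window, mononucleotide
    runs and single-site uniqueness across the whole edited allele; each
    junction pair is then chosen to put the amplicon nearest the target
    length. Raises a structured error when a junction cannot be covered.
    """
    allele = edited.sequence
    ins_s, ins_e = edited.insert_interval
    p = params

    g_lo = max(0, ins_s - p.search_window)
    fwd_gen = _candidates(allele, g_lo, ins_s, "+", p)
    rev_ins = _candidates(allele, ins_s, min(ins_s + p.internal_window, ins_e),
                          "-", p)
    fwd_ins = _candidates(allele, max(ins_e - p.internal_window, ins_s), ins_e,
                          "+", p)
    g_hi = min(len(allele), ins_e + p.search_window)
    rev_gen = _candidates(allele, ins_e, g_hi, "-", p)

    try:
        f5, r5, len5 = _best_pair(fwd_gen, rev_ins, p)
        f3, r3, len3 = _best_pair(fwd_ins, rev_gen, p)
    except PrimerDesignError as exc:
        raise PrimerDesignError(
            f"{exc}; candidate counts: genomic_fwd={len(fwd_gen)}, "
            f"insert_rev_5p={len(rev_ins)}, insert_fwd_3p={len(fwd_ins)}, "
            f"genomic_rev={len(rev_gen)}"
        ) from exc

    def mk(name: str, cand: tuple[int, int, str], orient: str) -> Primer:
        start, end, seq = cand
        return Primer(f"{name_prefix}_{name}", seq, (start, end), orient,
                      round(compute_tm(seq, p), 2), round(gc_fraction(seq), 3))

    pset = ValidationPrimerSet(
        genomic_fwd=mk("genomic_fwd", f5, "+"),
        insert_rev_5p=mk("insert_rev_5p", r5, "-"),
        insert_fwd_3p=mk("insert_fwd_3p", f3, "+"),
        genomic_rev=mk("genomic_rev", r3, "-"),
        predicted_amplicons=(
            ("5prime_junction", len5, (f5[0], r5[1])),
            ("3prime_junction", len3, (f3[0], r3[1])),
        ),
    )
    # re-verify every pair by virtual PCR before emitting
    for label, length, (s, e) in pset.predicted_amplicons:
        fwd = pset.genomic_fwd if label.startswith("5") else pset.insert_fwd_3p
        rev = pset.insert_rev_5p if label.startswith("5") else pset.genomic_rev
        products = virtual_pcr(allele, fwd.seq, rev.seq)
        assert products == [length], (label, products, length)
    return pset


def virtual_pcr(template: str, fwd: str, rev: str,
                max_len: int | None = None) -> list[int]:
    """Product lengths from exact-match, convergent primer binding sites."""
    fwd_sites = _find_all(template, fwd)
    rev_sites = [i + len(rev) for i in _find_all(template, revcomp(rev))]
    products = []
    for f in fwd_sites:
        for r in rev_sites:
            if r > f and (max_len is None or r - f <= max_len):
                products.append(r - f)
    return sorted(products)


def _find_all(s: str, sub: str) -> list[int]:
    out, i = [], s.find(sub)
    while i != -1:
        out.append(i)
        i = s.find(sub, i + 1)
    return out


def primer_table(pset: ValidationPrimerSet) -> pd.DataFrame:
    amp_by_primer = {}
    for label, length, _ in pset.predicted_amplicons:
        amp_by_primer[label] = length
    rows = []
    for primer in pset.primers:
        pair = ("5prime_junction" if "5p" in primer.name or "genomic_fwd" in primer.name
                else "3prime_junction")
        rows.append(
            {
                "name": primer.name,
                "sequence": primer.seq,
                "tm_C": primer.tm,
                "gc_frac": primer.gc,
                "pair": pair,
                "expected_product_nt": amp_by_primer[pair],
            }
        )
    return pd.DataFrame(rows)


def primer_bed(pset: ValidationPrimerSet, contig_id: str) -> str:
    """BED6 of primer binding sites on the edited allele."""
    lines = []
    for primer in pset.primers:
        s, e = primer.site
        strand = "+" if primer.orientation == "+" else "-"
        lines.append(f"{contig_id}\t{s}\t{e}\t{primer.name}\t0\t{strand}")
    return "\n".join(lines) + "\n"
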