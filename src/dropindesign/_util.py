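"""Small sequence helpers shared across modules.

All coordinates in this package are 0-based, half-open, on the forward
strand of the reference unless a function says otherwise.
"""

from __future__ import annotations

from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGTN")
# IUPAC ambiguity codes other than N are degraded to N on load.
IUPAC_AMBIGUOUS = frozenset("RYSWKMBDHV")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(seq: str) -> str:
    """Translate a DNA string; trailing partial codon is dropped."""
    trimmed = seq[: len(seq) - len(seq) % 3]
    return str(Seq(trimmed).translate())


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_mononucleotide_run(seq: str) -> int:
    best = run = 0
    prev = ""
    for ch in seq:
        run = run + 1 if ch == prev else 1
        prev = ch
        best = max(best, run)
    return best


def circular_slice(seq: str, start: int, end: int) -> str:
    """Slice a circular sequence; `end` may be <= `start` (wraps around)."""
    n = len(seq)
    start %= n
    end %= n
    if end > start:
        return seq[start:end]
    return seq[start:] + seq[:end]
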