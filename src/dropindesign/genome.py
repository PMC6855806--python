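"""Genome, gene-model and strain-variant ingestion.

Builds gene models from FASTA + GFF3, identifies coding introns (introns
flanked by two CDS-containing exons) together with their phase, and loads
strain variants from VCF with reference-consistency checks.

Coordinate convention: everything internal is 0-based, half-open, forward
strand ("interbase"). GFF3 (1-based closed) and VCF (1-based) are converted
at the boundary and converted back on export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO

from ._util import DNA_ALPHABET, IUPAC_AMBIGUOUS, revcomp

log = logging.getLogger(__name__)


class GenomeError(ValueError):
    """Malformed genome/annotation/variant input."""


@dataclass(frozen=True)
class GenomeSequence:
    """One contig: uppercase sequence plus a soft-mask flag per position."""

    contig_id: str
    sequence: str
    softmask: tuple[tuple[int, int], ...] = ()  # half-open lowercase runs

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        if start < 0 or end > len(self.sequence):
            raise GenomeError(
                f"window [{start}, {end}) outside contig {self.contig_id!r} "
                f"of length {len(self.sequence)}"
            )
        return self.sequence[start:end]


@dataclass(frozen=True)
class TranscriptModel:
    transcript_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # sorted by genomic start
    cds: tuple[tuple[int, int], ...]  # sorted by genomic start

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    contig_id: str
    strand: str
    transcripts: tuple[TranscriptModel, ...]

    @property
    def coding_transcripts(self) -> tuple[TranscriptModel, ...]:
        return tuple(t for t in self.transcripts if t.is_coding)


@dataclass(frozen=True)
class CodingIntron:
    """An intron flanked by two CDS-containing exons.

    ``phase`` is (cumulative CDS nt transcriptionally upstream of the
    intron) mod 3 — the reading-frame offset an artificial exon inserted
    here must match.
    """

    start: int
    end: int
    phase: int
    flanking_exon_ids: tuple[str, str]
    shared_by_all_coding_transcripts: bool = False


@dataclass(frozen=True)
class StrainVariant:
    contig_id: str
    pos: int  # interbase start of ref allele
    ref: str
    alt: str

    @property
    def kind(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return "SNV"
        if len(self.ref) == len(self.alt):
            return "MNV"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @property
    def interval(self) -> tuple[int, int]:
        """Genomic footprint of the ref allele (insertions anchor 1 nt)."""
        return (self.pos, self.pos + max(len(self.ref), 1))


def load_genome(path: str | Path) -> dict[str, GenomeSequence]:
    """Read a (multi-)FASTA into uppercase contigs.

    Lowercase (soft-masked) stretches are preserved as interval flags.
    IUPAC ambiguity codes other than N become N with a warning; any other
    character is a hard error naming the contig and position.
    """
    contigs: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise GenomeError(f"duplicate contig id {rec.id!r} in {path}")
        raw = str(rec.seq)
        mask_runs: list[tuple[int, int]] = []
        run_start: int | None = None
        chars = []
        for i, ch in enumerate(raw):
            lower = ch.islower()
            if lower and run_start is None:
                run_start = i
            elif not lower and run_start is not None:
                mask_runs.append((run_start, i))
                run_start = None
            up = ch.upper()
            if up in DNA_ALPHABET:
                chars.append(up)
            elif up in IUPAC_AMBIGUOUS:
                log.warning(
                    "contig %s position %d: ambiguity code %r converted to N",
                    rec.id, i, ch,
                )
                chars.append("N")
            else:
                raise GenomeError(
                    f"non-DNA character {ch!r} at contig {rec.id!r} position {i}"
                )
        if run_start is not None:
            mask_runs.append((run_start, len(raw)))
        contigs[rec.id] = GenomeSequence(rec.id, "".join(chars), tuple(mask_runs))
    if not contigs:
        raise GenomeError(f"no FASTA records in {path}")
    return contigs


def load_gene_models(gff3_path: str | Path) -> dict[str, GeneModel]:
    """Parse gene/mRNA/exon/CDS features (Parent-linked) into GeneModels."""
    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique",
        keep_order=True,
    )
    genes: dict[str, GeneModel] = {}
    for g in db.features_of_type("gene"):
        transcripts = []
        for t in db.children(g, featuretype="mRNA", order_by="start"):
            exons = tuple(
                sorted((e.start - 1, e.end) for e in db.children(t, featuretype="exon"))
            )
            cds = tuple(
                sorted((c.start - 1, c.end) for c in db.children(t, featuretype="CDS"))
            )
            transcripts.append(TranscriptModel(t.id, t.strand, exons, cds))
        genes[g.id] = GeneModel(g.id, g.seqid, g.strand, tuple(transcripts))
    return genes


def _transcript_coding_introns(
    t: TranscriptModel, gene_strand: str
) -> list[tuple[int, int, int, tuple[str, str]]]:
    """(start, end, phase, flanking exon ids) per coding intron of one transcript."""
    out = []
    exons = t.exons
    for i in range(len(exons) - 1):
        left_exon, right_exon = exons[i], exons[i + 1]
        intron = (left_exon[1], right_exon[0])
        # coding intron: CDS must abut the intron on both sides
        left_ok = any(c[1] == left_exon[1] for c in t.cds)
        right_ok = any(c[0] == right_exon[0] for c in t.cds)
        if not (left_ok and right_ok):
            continue
        if gene_strand == "+":
            upstream_cds = sum(e - s for s, e in t.cds if e <= intron[0])
        else:
            upstream_cds = sum(e - s for s, e in t.cds if s >= intron[1])
        phase = upstream_cds % 3
        ids = (f"{t.transcript_id}.exon{i + 1}", f"{t.transcript_id}.exon{i + 2}")
        out.append((intron[0], intron[1], phase, ids))
    return out


def find_coding_introns(
    gene: GeneModel,
    genome: Mapping[str, GenomeSequence] | None = None,
    canonical_splice_check: bool = False,
) -> list[CodingIntron]:
    """Introns flanked by two CDS-containing exons, with phase.

    An intron is flagged ``shared_by_all_coding_transcripts`` iff every
    coding transcript of the gene contains it with identical boundaries and
    phase. With ``canonical_splice_check`` the GT..AG dinucleotides are
    verified against the genome (forward-strand sense of the gene); a
    non-canonical junction warns but is kept.
    """
    coding = gene.coding_transcripts
    if not coding:
        log.warning("gene %s has no transcript with CDS", gene.gene_id)
        return []
    per_transcript = [
        set((s, e, p) for s, e, p, _ in _transcript_coding_introns(t, gene.strand))
        for t in coding
    ]
    shared = set.intersection(*per_transcript)
    seen: dict[tuple[int, int, int], tuple[str, str]] = {}
    for t in coding:
        for s, e, p, ids in _transcript_coding_introns(t, gene.strand):
            seen.setdefault((s, e, p), ids)
    introns = [
        CodingIntron(s, e, p, ids, shared_by_all_coding_transcripts=(s, e, p) in shared)
        for (s, e, p), ids in sorted(seen.items())
    ]
    if canonical_splice_check and genome is not None:
        contig = genome[gene.contig_id]
        for intron in introns:
            body = contig.slice(intron.start, intron.end)
            if gene.strand == "-":
                body = revcomp(body)
            if not (body.startswith("GT") and body.endswith("AG")):
                log.warning(
                    "gene %s intron [%d,%d): non-canonical splice sites %s..%s",
                    gene.gene_id, intron.start, intron.end, body[:2], body[-2:],
                )
    return introns


def load_variants(
    path: str | Path,
    contig_id: str,
    start: int,
    end: int,
    genome: Mapping[str, GenomeSequence] | None = None,
) -> list[StrainVariant]:
    """Load VCF records overlapping [start, end) on one contig.

    Positions are converted from 1-based VCF to interbase. When a genome is
    supplied, each ref allele is checked against it; mismatching records are
    dropped with a warning.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error classes vary
        raise GenomeError(f"cannot read VCF {path}: {exc}") from exc
    out: list[StrainVariant] = []
    for rec in vcf:
        if rec.CHROM != contig_id:
            continue
        pos = rec.POS - 1
        ref = rec.REF.upper()
        if pos + max(len(ref), 1) <= start or pos >= end:
            continue
        for alt in rec.ALT:
            var = StrainVariant(rec.CHROM, pos, ref, alt.upper())
            if genome is not None:
                observed = genome[contig_id].sequence[pos : pos + len(ref)]
                if observed != ref:
                    log.warning(
                        "variant at %s:%d ref %r does not match genome %r; dropped",
                        contig_id, rec.POS, ref, observed,
                    )
                    continue
            out.append(var)
    vcf.close()
    return sorted(out, key=lambda v: (v.pos, v.ref, v.alt))


def gene_to_gff3(gene: GeneModel, lines: bool = False) -> str | list[str]:
    """Re-export a GeneModel as GFF3 (1-based closed coordinates)."""
    rows: list[str] = []
    all_exons = [e for t in gene.transcripts for e in t.exons]
    gs, ge = min(s for s, _ in all_exons), max(e for _, e in all_exons)

    def row(ftype: str, s: int, e: int, attrs: str) -> str:
        return "\t".join(
            [gene.contig_id, "dropindesign", ftype, str(s + 1), str(e),
             ".", gene.strand, ".", attrs]
        )

    rows.append(row("gene", gs, ge, f"ID={gene.gene_id}"))
    for t in gene.transcripts:
        ts = min(s for s, _ in t.exons)
        te = max(e for _, e in t.exons)
        rows.append(row("mRNA", ts, te, f"ID={t.transcript_id};Parent={gene.gene_id}"))
        for i, (s, e) in enumerate(t.exons, 1):
            rows.append(
                row("exon", s, e,
                    f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}")
            )
        for i, (s, e) in enumerate(t.cds, 1):
            rows.append(
                row("CDS", s, e,
                    f"ID={t.transcript_id}.cds{i};Parent={t.transcript_id}")
            )
    return rows if lines else "\n".join(["##gff-version 3", *rows]) + "\n"


def spliced_cds(gene: GeneModel, transcript: TranscriptModel,
                genome: Mapping[str, GenomeSequence]) -> str:
    """Concatenated CDS of one transcript in translation (5'->3') order."""
    contig = genome[gene.contig_id]
    parts = [contig.slice(s, e) for s, e in transcript.cds]
    seq = "".join(parts)
    return revcomp(seq) if gene.strand == "-" else seq


def iter_genes(genes: Mapping[str, GeneModel], ids: Iterable[str] | None):
    wanted = list(ids) if ids else list(genes)
    for gid in wanted:
        if gid not in genes:
            raise GenomeError(f"gene {gid!r} not found in annotation")
        yield genes[gid]
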