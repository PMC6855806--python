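"""Deterministic synthetic test loci: FASTA + GFF3 + VCF + truth report.

`generate_locus` emits a single-contig genome carrying one multi-exon
protein-coding gene with coding introns, optionally planted NGG guide
targets, strain variants and a decoy gRNA1 site, together with a JSON-able
truth report recording every planted feature. The same seed and spec
always reproduce byte-identical files, so every pipeline stage can be
tested against ground truth without downloading a real genome.

The emulated locus is a compact fly-like gene: short coding exons, modest
introns with canonical GT..AG ends, ~43% GC. It deliberately omits
repeats, soft-masking, alternative isoforms and non-canonical splice
sites; passing tests therefore exercise coordinate arithmetic and design
logic, not annotation pathology.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass
from pathlib import Path

from ._util import revcomp
from .cassettes import GRNA1_PAM, GRNA1_PROTOSPACER, _SAFE_CODONS
from .genome import GeneModel, TranscriptModel, gene_to_gff3


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedGuide:
    intron_index: int  # 0-based, transcription order
    strand: str  # relative to the final reference
    offset: int  # protospacer-proximal 23-mer start within the intron body


@dataclass(frozen=True)
class PlantedVariant:
    intron_index: int
    offset: int  # within the intron body
    kind: str  # {SNV, insertion, deletion}


@dataclass(frozen=True)
class SyntheticLocusSpec:
    seed: int = 0
    contig_id: str = "chrF"
    gene_id: str = "geneA"
    n_exons: int = 3
    exon_cds_len: tuple[int, int] = (120, 300)  # CDS nt per exon
    intron_len: tuple[int, int] = (400, 800)
    utr5_len: int = 150
    utr3_len: int = 150
    flank_len: int = 1500
    gc_frac: float = 0.43
    gene_strand: str = "+"
    planted_guides: tuple[PlantedGuide, ...] = ()
    planted_variants: tuple[PlantedVariant, ...] = ()
    decoy_grna1: bool = False


@dataclass
class LocusTruth:
    spec: SyntheticLocusSpec
    contig_id: str
    contig_len: int
    gene_id: str
    strand: str
    exons: list[tuple[int, int]]  # genomic, sorted
    cds: list[tuple[int, int]]
    introns: list[dict]  # transcription order: start/end/phase
    guides: list[dict]  # planted: protospacer, pam, strand, cut_site
    variants: list[dict]
    decoy_grna1_pos: int | None

    def to_json(self) -> str:
        d = asdict(self)
        d["spec"] = asdict(self.spec)
        return json.dumps(d, indent=1)


def _dna(rng: random.Random, n: int, gc: float) -> str:
    return "".join(
        rng.choice("GC") if rng.random() < gc else rng.choice("AT")
        for _ in range(n)
    )


def generate_locus(spec: SyntheticLocusSpec, out_dir: str | Path | None = None):
    """Build the locus; optionally write FASTA/GFF3/VCF/truth to ``out_dir``.

    Returns (contig sequence, GeneModel, truth, vcf_text).
    """
    if spec.n_exons < 2:
        raise FixtureError("need at least 2 exons to have an intron")
    if spec.gene_strand not in "+-":
        raise FixtureError(f"bad strand {spec.gene_strand!r}")
    rng = random.Random(spec.seed)

    cds_lens = [rng.randint(*spec.exon_cds_len) for _ in range(spec.n_exons)]
    cds_lens[-1] += (3 - sum(cds_lens) % 3) % 3  # ORF divisible by 3
    total_cds = sum(cds_lens)
    orf = ("ATG"
           + "".join(rng.choice(_SAFE_CODONS) for _ in range(total_cds // 3 - 2))
           + "TAA")
    assert len(orf) == total_cds

    intron_lens = [rng.randint(*spec.intron_len) for _ in range(spec.n_exons - 1)]
    introns_local = []
    for g in spec.planted_guides:
        if not (0 <= g.intron_index < len(intron_lens)):
            raise FixtureError(f"planted guide in nonexistent intron {g.intron_index}")
        if not (2 <= g.offset and g.offset + 23 <= intron_lens[g.intron_index] - 2):
            raise FixtureError("planted guide does not fit inside the intron body")
    for v in spec.planted_variants:
        if not (0 <= v.intron_index < len(intron_lens)):
            raise FixtureError("planted variant in nonexistent intron")
        if not (2 <= v.offset and v.offset + 4 <= intron_lens[v.intron_index] - 2):
            raise FixtureError("planted variant does not fit inside the intron body")

    # assemble in transcription-forward local coordinates
    parts: list[str] = []
    pos = 0

    def emit(seq: str) -> tuple[int, int]:
        nonlocal pos
        parts.append(seq)
        iv = (pos, pos + len(seq))
        pos += len(seq)
        return iv

    emit(_dna(rng, spec.flank_len, spec.gc_frac))
    exon_ivs, cds_ivs = [], []
    guide_truth: list[dict] = []
    orf_cursor = 0
    for i in range(spec.n_exons):
        chunks = []
        if i == 0:
            chunks.append(_dna(rng, spec.utr5_len, spec.gc_frac))
        cds_part = orf[orf_cursor : orf_cursor + cds_lens[i]]
        orf_cursor += cds_lens[i]
        chunks.append(cds_part)
        if i == spec.n_exons - 1:
            chunks.append(_dna(rng, spec.utr3_len, spec.gc_frac))
        exon_seq = "".join(chunks)
        exon_start = pos
        cds_start = pos + (spec.utr5_len if i == 0 else 0)
        emit(exon_seq)
        exon_ivs.append((exon_start, exon_start + len(exon_seq)))
        cds_ivs.append((cds_start, cds_start + len(cds_part)))
        if i < spec.n_exons - 1:
            body = list("GT" + _dna(rng, intron_lens[i] - 4, spec.gc_frac) + "AG")
            for g in spec.planted_guides:
                if g.intron_index != i:
                    continue
                proto = _dna(rng, 20, 0.5)
                if g.strand == "+":
                    site = proto + rng.choice("ACGT") + "GG"
                else:
                    site = "CC" + rng.choice("ACGT") + revcomp(proto)
                body[g.offset : g.offset + 23] = site
                intron_start_local = pos
                fwd_start = intron_start_local + g.offset
                if g.strand == "+":
                    cut = fwd_start + 20 - 3
                    pam = site[20:]
                else:
                    cut = fwd_start + 3 + 3
                    pam = revcomp(site[:3])
                guide_truth.append(
                    {"intron_index": i, "strand": g.strand,
                     "protospacer": proto, "pam": pam,
                     "protospacer_fwd_start": fwd_start + (0 if g.strand == "+"
                                                           else 3),
                     "cut_site": cut}
                )
            introns_local.append((pos, pos + intron_lens[i]))
            emit("".join(body))
    emit(_dna(rng, spec.flank_len, spec.gc_frac))
    contig = "".join(parts)

    decoy_pos = None
    if spec.decoy_grna1:
        decoy_pos = spec.flank_len // 3
        target = GRNA1_PROTOSPACER + GRNA1_PAM
        contig = (contig[:decoy_pos] + target
                  + contig[decoy_pos + len(target):])

    L = len(contig)
    if spec.gene_strand == "-":
        contig = revcomp(contig)
        flip = lambda iv: (L - iv[1], L - iv[0])
        exon_ivs = sorted(flip(iv) for iv in exon_ivs)
        cds_ivs = sorted(flip(iv) for iv in cds_ivs)
        introns_local = [flip(iv) for iv in introns_local]
        for g in guide_truth:
            g["strand"] = "-" if g["strand"] == "+" else "+"
            g["protospacer_fwd_start"] = L - (g["protospacer_fwd_start"] + 20)
            g["cut_site"] = L - g["cut_site"]
        if decoy_pos is not None:
            decoy_pos = L - (decoy_pos + 23)

    transcript = TranscriptModel(
        f"{spec.gene_id}.t1", spec.gene_strand,
        tuple(exon_ivs), tuple(cds_ivs),
    )
    gene = GeneModel(spec.gene_id, spec.contig_id, spec.gene_strand,
                     (transcript,))

    # intron truth with phase, in transcription order
    introns_sorted = sorted(introns_local)
    if spec.gene_strand == "-":
        order = list(reversed(introns_sorted))
    else:
        order = introns_sorted
    intron_truth = []
    for k, (s, e) in enumerate(order):
        if spec.gene_strand == "+":
            upstream = sum(ce - cs for cs, ce in cds_ivs if ce <= s)
        else:
            upstream = sum(ce - cs for cs, ce in cds_ivs if cs >= e)
        intron_truth.append({"index": k, "start": s, "end": e,
                             "phase": upstream % 3})

    # strain variants against the final reference
    variant_truth = []
    intron_by_tx_index = {d["index"]: (d["start"], d["end"])
                          for d in intron_truth}
    for v in spec.planted_variants:
        s, e = intron_by_tx_index[v.intron_index]
        vpos = s + v.offset
        ref_base = contig[vpos]
        if v.kind == "SNV":
            ref, alt = ref_base, rng.choice([b for b in "ACGT" if b != ref_base])
        elif v.kind == "insertion":
            ref, alt = ref_base, ref_base + _dna(rng, 3, 0.5)
        elif v.kind == "deletion":
            ref, alt = contig[vpos : vpos + 4], ref_base
        else:
            raise FixtureError(f"unknown variant kind {v.kind!r}")
        variant_truth.append({"pos": vpos, "ref": ref, "alt": alt,
                              "kind": v.kind, "intron_index": v.intron_index})
    variant_truth.sort(key=lambda d: d["pos"])

    truth = LocusTruth(
        spec=spec, contig_id=spec.contig_id, contig_len=L,
        gene_id=spec.gene_id, strand=spec.gene_strand,
        exons=list(exon_ivs), cds=list(cds_ivs), introns=intron_truth,
        guides=guide_truth, variants=variant_truth,
        decoy_grna1_pos=decoy_pos,
    )
    vcf_text = _vcf_text(spec.contig_id, L, variant_truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "genome.fa").write_text(_fasta_text(spec.contig_id, contig))
        (out / "annotation.gff3").write_text(gene_to_gff3(gene))
        (out / "variants.vcf").write_text(vcf_text)
        (out / "truth.json").write_text(truth.to_json())
    return contig, gene, truth, vcf_text


def _fasta_text(contig_id: str, seq: str) -> str:
    lines = [f">{contig_id}"]
    for i in range(0, len(seq), 60):
        lines.append(seq[i : i + 60])
    return "\n".join(lines) + "\n"


def _vcf_text(contig_id: str, length: int, variants: list[dict]) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={contig_id},length={length}>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for v in variants:
        lines.append(
            f"{contig_id}\t{v['pos'] + 1}\t.\t{v['ref']}\t{v['alt']}\t.\tPASS\t."
        )
    return "\n".join(lines) + "\n"


def bundle_cassette_fixtures(seed: int = 20191101):
    """The bundled cassette template library (synthetic stand-ins).

    Core lengths are chosen so the published donor-length arithmetic holds
    (see :mod:`dropindesign.cassettes`); records loaded from real vector
    files may be substituted freely.
    """
    from .cassettes import synthetic_template_library

    return synthetic_template_library(seed)
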