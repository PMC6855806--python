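"""GenBank record export for donors, plasmids and edited alleles."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .cassettes import CassetteTemplate
from .donors import DropInPlasmid, SsDNADonor, SynthesisConstruct
from .edits import EditedAllele


def _feat(start: int, end: int, label: str, ftype: str = "misc_feature",
          strand: int = 1) -> SeqFeature:
    return SeqFeature(FeatureLocation(start, end, strand=strand), type=ftype,
                      qualifiers={"label": [label]})


def _record(seq: str, name: str, topology: str = "linear") -> SeqRecord:
    rec = SeqRecord(Seq(seq), id=name[:16] or "record", name=name[:16] or "record",
                    description=name)
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = topology
    return rec


def ssdna_donor_record(donor: SsDNADonor, template: CassetteTemplate,
                       lha_len: int, name: str) -> SeqRecord:
    rec = _record(donor.duplex_top, name)
    rec.features.append(_feat(0, lha_len, "LHA"))
    for label, (s, e) in template.features:
        rec.features.append(_feat(lha_len + s, lha_len + e, label))
    core_end = lha_len + len(template.core_seq)
    rec.features.append(_feat(core_end, len(donor.duplex_top), "RHA"))
    return rec


def plasmid_record(plasmid: DropInPlasmid,
                   cassette: CassetteTemplate | None = None) -> SeqRecord:
    rec = _record(plasmid.sequence, f"dropin_{plasmid.sic_name}",
                  topology="circular")
    s, e = plasmid.donor_region
    rec.features.append(_feat(s, e, "donor_region"))
    g = plasmid.grna1
    rec.features.append(_feat(0, len(g.target), "gRNA1_target"))
    rec.features.append(
        _feat(e - len(g.target), e, "gRNA1_target", strand=-1))
    arm_s = len(g.target)
    rec.features.append(_feat(arm_s, arm_s + plasmid.arms.lha_len, "LHA"))
    rec.features.append(
        _feat(e - len(g.target) - plasmid.arms.rha_len, e - len(g.target), "RHA"))
    return rec


def synthesis_record(synth: SynthesisConstruct, name: str) -> SeqRecord:
    rec = _record(synth.vector_seq, name, topology="circular")
    g = synth.grna1
    rec.features.append(_feat(0, len(synth.insert_seq), "synthesized_insert"))
    rec.features.append(_feat(0, len(g.target), "gRNA1_target"))
    pos = len(g.target)
    rec.features.append(_feat(pos, pos + synth.arms.lha_len, "LHA"))
    pos += synth.arms.lha_len
    rec.features.append(_feat(pos, pos + len(synth.payload), "payload"))
    pos += len(synth.payload)
    rec.features.append(_feat(pos, pos + synth.arms.rha_len, "RHA"))
    pos += synth.arms.rha_len
    rec.features.append(_feat(pos, pos + len(g.target), "gRNA1_target", strand=-1))
    return rec


def edited_allele_record(edited: EditedAllele) -> SeqRecord:
    rec = _record(edited.sequence, f"{edited.contig_id}_edited")
    s, e = edited.insert_interval
    strand = 1 if edited.gene_strand == "+" else -1
    rec.features.append(_feat(s, e, f"insert:{edited.cassette_name}", strand=strand))
    rec.features.append(_feat(max(0, s - 30), s, "junction_5prime"))
    rec.features.append(_feat(e, min(len(edited.sequence), e + 30),
                              "junction_3prime"))
    return rec


def write_genbank(rec: SeqRecord, path: str | Path) -> None:
    SeqIO.write([rec], str(path), "genbank")
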