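"""End-to-end design orchestration: config -> per-gene design artifacts.

`run_design` is the library entry point behind the CLI: it loads the
inputs, walks each requested gene through intron selection, guide ranking,
arm design, donor assembly, HDR simulation and validation-PCR design, and
writes the artifact set (guide report, ordering sheet, GenBank records,
primer TSV/BED, JSON summary). Per-gene failures are isolated; the run
fails only if a requested gene produces nothing.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .arms import ArmDesignError, design_arms
from .cassettes import CassetteTemplate
from .donors import (
    GRna1Unit, build_direct_plasmid, build_ssdna_design,
    build_synthesis_construct, released_donor, synthetic_puc57_backbone,
)
from .edits import classify_allele, predict_trap_transcript, simulate_hdr
from .enzymes import CATALOG, choose_re_pair
from .fixtures import bundle_cassette_fixtures
from .genome import find_coding_introns, iter_genes, load_gene_models, load_genome, load_variants
from .guides import (
    NoViableGuideError, filter_by_variants, guide_report, rank_guides, scan_guides,
)
from .records import (
    edited_allele_record, plasmid_record, ssdna_donor_record, write_genbank,
)
from .validation import PrimerParams, design_validation_primers, primer_bed, primer_table

log = logging.getLogger(__name__)

DELIVERY_MODES = ("ssdna", "synthesis", "plasmid")

#: default delivery route per cassette class
_DEFAULT_DELIVERY = {
    "attP-3XP3-EGFP-attP": "ssdna",
    "attP-SA-Linker-sfGFP-Linker-SD-attP": "ssdna",
    "attP-SA-3XSTOP-minipolyA-U6gRNA1-attP": "synthesis",
    "attP-SA-T2A-miniGAL4-minipolyA-U6gRNA1-attP": "synthesis",
    "attP-FRT-SA-T2A-GAL4-polyA-3XP3-EGFP-FRT-attP": "plasmid",
}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class DesignConfig:
    genome: str
    gff3: str
    genes: tuple[str, ...]
    cassette: str
    outdir: str
    vcf: str | None = None
    delivery: str | None = None  # ssdna | synthesis | plasmid (default by cassette)
    lha_len: int = 100
    rha_len: int = 100
    min_splice_distance: int = 50
    variant_pad: int = 0
    any_isoform: bool = False
    seed: int = 0
    primer: PrimerParams = field(default_factory=PrimerParams)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "DesignConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "DesignConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "primer" in raw and isinstance(raw["primer"], dict):
            pknown = {f.name for f in dataclasses.fields(PrimerParams)}
            punknown = set(raw["primer"]) - pknown
            if punknown:
                raise ConfigError(f"unknown primer keys: {sorted(punknown)}")
            raw = dict(raw, primer=PrimerParams(**raw["primer"]))
        if "genes" in raw:
            raw = dict(raw, genes=tuple(raw["genes"]))
        cfg = cls(**raw)
        if cfg.delivery is not None and cfg.delivery not in DELIVERY_MODES:
            raise ConfigError(f"delivery must be one of {DELIVERY_MODES}")
        return cfg


def _design_one_gene(
    gene, genome_map, variants, template: CassetteTemplate, delivery: str,
    cfg: DesignConfig, outdir: Path,
) -> dict:
    contig = genome_map[gene.contig_id]
    introns = find_coding_introns(gene, genome_map, canonical_splice_check=True)
    if not cfg.any_isoform:
        introns = [i for i in introns if i.shared_by_all_coding_transcripts]
    if not introns:
        raise NoViableGuideError({gene.gene_id: "no usable coding intron"})

    grna1 = GRna1Unit()
    errors: dict[str, str] = {}
    for intron_index, intron in enumerate(introns):
        candidates = scan_guides(contig, (intron.start, intron.end))
        candidates = filter_by_variants(candidates, variants, pad=cfg.variant_pad)
        forbidden = [grna1.target] if delivery in ("synthesis", "plasmid") else []
        try:
            ranked = rank_guides(
                candidates, intron, cfg.min_splice_distance, genome=contig,
                lha_len=cfg.lha_len, rha_len=cfg.rha_len,
                forbidden_sites=forbidden,
            )
        except NoViableGuideError as exc:
            errors.update(exc.exclusions)
            continue
        for guide in ranked:
            try:
                arms = design_arms(
                    contig, guide, gene.strand, cfg.lha_len, cfg.rha_len,
                    variants=variants, grna1_site=grna1.target,
                )
            except ArmDesignError as exc:
                errors[f"{guide.protospacer_start}{guide.strand}"] = str(exc)
                continue
            if "contains_gRNA1_site" in arms.flags and delivery != "ssdna":
                errors[f"{guide.protospacer_start}{guide.strand}"] = (
                    "homology arm contains the gRNA1 release target"
                )
                continue
            cassette = template
            if template.phase_variant is not None:
                cassette = template.with_phase(intron.phase)
            return _assemble_outputs(
                gene, contig, genome_map, intron, intron_index, guide, arms,
                cassette, delivery, cfg, outdir,
                guide_report(gene.gene_id, intron_index, ranked),
            )
    raise NoViableGuideError(errors or {gene.gene_id: "no guide candidates"})


def _assemble_outputs(gene, contig, genome_map, intron, intron_index, guide,
                      arms, cassette, delivery, cfg, outdir, report_df) -> dict:
    gdir = outdir / gene.gene_id
    gdir.mkdir(parents=True, exist_ok=True)
    report_df.to_csv(gdir / "guide_report.tsv", sep="\t", index=False)
    grna1 = GRna1Unit()
    order_rows = []
    summary: dict = {
        "gene_id": gene.gene_id,
        "strand": gene.strand,
        "cassette": cassette.name,
        "delivery": delivery,
        "intron": {"start": intron.start, "end": intron.end,
                   "phase": intron.phase, "index": intron_index},
        "guide": {
            "protospacer": guide.protospacer, "pam": guide.pam,
            "strand": guide.strand, "cut_site": guide.cut_site,
            "variant_clean": guide.variant_clean,
        },
        "arms": {"lha_len": arms.lha_len, "rha_len": arms.rha_len,
                 "flags": sorted(arms.flags)},
    }

    insert_core = cassette.core_seq
    if delivery == "ssdna":
        primers, donor = build_ssdna_design(arms, cassette)
        write_genbank(
            ssdna_donor_record(donor, cassette, arms.lha_len,
                               f"ssdna_{gene.gene_id}"),
            gdir / "donor.gb",
        )
        order_rows += [
            {"name": f"{gene.gene_id}_long_fwd", "sequence": primers.forward,
             "phosphorylated_5prime": False, "scale_note": "IDT Ultramer"},
            {"name": f"{gene.gene_id}_long_rev", "sequence": primers.reverse,
             "phosphorylated_5prime": primers.reverse_5prime_phosphorylated,
             "scale_note": "IDT Ultramer"},
        ]
        summary["donor"] = {
            "class": "ssdna", "total_len": donor.total_len,
            "surviving_strand": donor.surviving_strand,
            "forward_primer_len": len(primers.forward),
            "reverse_primer_len": len(primers.reverse),
        }
    elif delivery == "synthesis":
        synth = build_synthesis_construct(arms, insert_core, grna1, genome_map)
        from .records import synthesis_record

        write_genbank(synthesis_record(synth, f"synth_{gene.gene_id}"),
                      gdir / "donor.gb")
        order_rows.append(
            {"name": f"{gene.gene_id}_synthesis", "sequence": synth.insert_seq,
             "phosphorylated_5prime": False,
             "scale_note": "gene synthesis in pUC57-class vector"}
        )
        summary["donor"] = {
            "class": "synthesized_dsdna",
            "cassette_plus_arms_len": synth.cassette_plus_arms_len,
            "full_insert_len": synth.full_insert_len,
        }
    else:  # plasmid: stuffer synthesis + directional subcloning
        re1, re2 = choose_re_pair(
            CATALOG,
            (arms.lha, arms.rha, insert_core, synthetic_puc57_backbone()),
        )
        plasmid = build_direct_plasmid(
            arms, insert_core, cassette.name, grna1, genome_map, (re1, re2)
        )
        insert_core = re1.site + insert_core + re2.site
        write_genbank(plasmid_record(plasmid), gdir / "donor.gb")
        order_rows.append(
            {"name": f"{gene.gene_id}_int100_synthesis",
             "sequence": grna1.left_unit + arms.lha + re1.site
             + "..stuffer.." + re2.site + arms.rha + grna1.right_unit,
             "phosphorylated_5prime": False,
             "scale_note": f"synthesis + subcloning via {re1.name}/{re2.name}"}
        )
        donor_seq, remnants = released_donor(plasmid)
        summary["donor"] = {
            "class": "int100_plasmid",
            "cassette_plus_arms_len": arms.lha_len + len(cassette.core_seq)
            + arms.rha_len,
            "released_fragment_len": len(donor_seq),
            "end_remnant_lengths": list(remnants),
            "re_pair": [re1.name, re2.name],
        }

    edited = simulate_hdr(contig, arms, insert_core, guide, cassette.name)
    write_genbank(edited_allele_record(edited), gdir / "edited_allele.gb")
    context = "intron"
    summary["allele_class"] = classify_allele(cassette, context)
    if cassette.has_feature("SA"):
        orf_report = predict_trap_transcript(
            edited, gene, contig, cassette, (intron.start, intron.end)
        )
        (gdir / "orf_report.json").write_text(json.dumps(orf_report, indent=1))
        summary["trap_transcript"] = orf_report

    pset = design_validation_primers(edited, cfg.primer,
                                     name_prefix=gene.gene_id)
    primer_table(pset).to_csv(gdir / "validation_primers.tsv", sep="\t",
                              index=False)
    (gdir / "primer_sites.bed").write_text(
        primer_bed(pset, f"{gene.contig_id}_edited"))
    summary["validation"] = {
        "amplicons": [
            {"pair": label, "length": length, "interval": list(iv)}
            for label, length, iv in pset.predicted_amplicons
        ]
    }
    for p in pset.primers:
        order_rows.append({"name": p.name, "sequence": p.seq,
                           "phosphorylated_5prime": False,
                           "scale_note": "standard desalted oligo"})
    pd.DataFrame(order_rows).to_csv(gdir / "ordering_sheet.tsv", sep="\t",
                                    index=False)
    (gdir / "design_summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def run_design(cfg: DesignConfig) -> tuple[int, dict]:
    """Run the full design for every requested gene.

    Returns (exit_status, summary). Exit status is nonzero iff at least one
    requested gene wholly failed; other genes are unaffected.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "design.log")
    logging.getLogger("dropindesign").addHandler(handler)
    try:
        genome_map = load_genome(cfg.genome)
        genes = load_gene_models(cfg.gff3)
        templates = bundle_cassette_fixtures()
        if cfg.cassette not in templates:
            raise ConfigError(
                f"unknown cassette {cfg.cassette!r}; available: "
                f"{sorted(templates)}"
            )
        template = templates[cfg.cassette]
        delivery = cfg.delivery or _DEFAULT_DELIVERY.get(cfg.cassette, "ssdna")
        summary: dict = {"config_seed": cfg.seed, "cassette": cfg.cassette,
                         "delivery": delivery, "genes": {}, "failures": {}}
        for gene in iter_genes(genes, cfg.genes):
            variants = (
                load_variants(cfg.vcf, gene.contig_id, 0,
                              len(genome_map[gene.contig_id].sequence),
                              genome=genome_map)
                if cfg.vcf else []
            )
            try:
                summary["genes"][gene.gene_id] = _design_one_gene(
                    gene, genome_map, variants, template, delivery, cfg, outdir
                )
            except (NoViableGuideError, ArmDesignError, ValueError) as exc:
                log.error("gene %s failed: %s", gene.gene_id, exc)
                summary["failures"][gene.gene_id] = str(exc)
        (outdir / "run_summary.json").write_text(json.dumps(summary, indent=1))
        status = 1 if summary["failures"] else 0
        return status, summary
    finally:
        logging.getLogger("dropindesign").removeHandler(handler)
        handler.close()
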