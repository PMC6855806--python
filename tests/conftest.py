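"""Shared fixtures: synthetic loci, template library, and one design run."""

from __future__ import annotations

import pytest

from dropindesign.fixtures import (
    PlantedGuide, PlantedVariant, SyntheticLocusSpec, bundle_cassette_fixtures,
    generate_locus,
)
from dropindesign.genome import load_gene_models, load_genome


@pytest.fixture(scope="session")
def templates():
    return bundle_cassette_fixtures()


@pytest.fixture(scope="session")
def locus_spec():
    """Plus-strand 3-exon gene with planted guides and variants."""
    return SyntheticLocusSpec(
        seed=1,
        planted_guides=(PlantedGuide(0, "+", 150), PlantedGuide(1, "-", 220)),
        planted_variants=(
            PlantedVariant(0, 60, "SNV"),
            PlantedVariant(0, 320, "deletion"),
            PlantedVariant(1, 90, "insertion"),
            PlantedVariant(1, 250, "SNV"),
            PlantedVariant(1, 330, "SNV"),
        ),
    )


@pytest.fixture(scope="session")
def locus_dir(tmp_path_factory, locus_spec):
    out = tmp_path_factory.mktemp("locus")
    generate_locus(locus_spec, out_dir=out)
    return out


@pytest.fixture(scope="session")
def locus(locus_spec, locus_dir):
    contig, gene, truth, vcf = generate_locus(locus_spec)
    return {"contig": contig, "gene": gene, "truth": truth, "vcf": vcf}


@pytest.fixture(scope="session")
def genome_map(locus_dir):
    return load_genome(locus_dir / "genome.fa")


@pytest.fixture(scope="session")
def contig(genome_map, locus):
    return genome_map[locus["truth"].contig_id]


@pytest.fixture(scope="session")
def gene(locus_dir, locus):
    genes = load_gene_models(locus_dir / "annotation.gff3")
    return genes[locus["truth"].gene_id]


@pytest.fixture(scope="session")
def design_run(tmp_path_factory, locus_dir):
    """One full ssDNA design run on the shared locus, reused read-only."""
    from dropindesign.pipeline import DesignConfig, run_design

    outdir = tmp_path_factory.mktemp("design_out")
    cfg = DesignConfig(
        genome=str(locus_dir / "genome.fa"),
        gff3=str(locus_dir / "annotation.gff3"),
        vcf=str(locus_dir / "variants.vcf"),
        genes=("geneA",),
        cassette="attP-3XP3-EGFP-attP",
        outdir=str(outdir),
    )
    status, summary = run_design(cfg)
    return {"status": status, "summary": summary, "outdir": outdir,
            "config": cfg}
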