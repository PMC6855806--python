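"""Donor assembly: long primers, ssDNA, synthesized dsDNA, plasmid cloning."""

import random

import pytest

from dropindesign._util import revcomp
from dropindesign.arms import HomologyArmPair
from dropindesign.donors import (
    DonorDesignError, GRna1Unit, build_direct_plasmid, build_ssdna_design,
    build_synthesis_construct, make_stuffer, released_donor,
    simulate_lambda_exo, simulate_linearization, simulate_subcloning,
    synthetic_puc57_backbone,
)
from dropindesign.enzymes import (
    CATALOG, CloningError, choose_re_pair, digest_circular, digest_linear_ends,
    ligate_circular,
)
from dropindesign.genome import GenomeSequence


def mk_arms(seed=0, lha_len=100, rha_len=100):
    rng = random.Random(seed)
    lha = "".join(rng.choice("ACGT") for _ in range(lha_len))
    rha = "".join(rng.choice("ACGT") for _ in range(rha_len))
    return HomologyArmPair(lha, rha, cut_site=5000, orientation="+")


@pytest.fixture(scope="module")
def empty_genome():
    rng = random.Random(99)
    seq = "".join(rng.choice("ACGT") for _ in range(5000))
    return {"c": GenomeSequence("c", seq)}


class TestSsDNA:
    def test_egfp_donor_totals_1442_with_100nt_arms(self, templates):
        primers, donor = build_ssdna_design(
            mk_arms(), templates["attP-3XP3-EGFP-attP"])
        assert donor.total_len == 1442
        assert len(primers.forward) == 126  # 100-nt arm + 26-nt priming
        assert len(primers.reverse) == 124  # 100-nt arm + 24-nt priming
        assert primers.reverse_5prime_phosphorylated

    def test_sfgfp_donor_totals_1392(self, templates):
        _, donor = build_ssdna_design(
            mk_arms(), templates["attP-SA-Linker-sfGFP-Linker-SD-attP"])
        assert donor.total_len == 1392

    def test_duplex_is_lha_core_rha_and_primers_carry_arms(self, templates):
        t = templates["attP-3XP3-EGFP-attP"]
        arms = mk_arms()
        primers, donor = build_ssdna_design(arms, t)
        assert donor.duplex_top == arms.lha + t.core_seq + arms.rha
        assert primers.forward == arms.lha + t.core_seq[:26]
        assert primers.reverse == revcomp(arms.rha) + revcomp(t.core_seq[-24:])
        assert donor.ssdna_seq == donor.duplex_top  # bottom strand degraded

    def test_flipping_phosphorylation_selects_bottom_strand(self, templates):
        _, donor = build_ssdna_design(
            mk_arms(), templates["attP-3XP3-EGFP-attP"],
            phosphorylate_forward=True)
        assert donor.ssdna_seq == revcomp(donor.duplex_top)
        assert donor.surviving_strand == "bottom"

    def test_priming_segment_in_arm_warns(self, templates, caplog):
        t = templates["attP-3XP3-EGFP-attP"]
        arms = mk_arms()
        bad = HomologyArmPair(t.fwd_priming + arms.lha[26:], arms.rha,
                              arms.cut_site, "+")
        with caplog.at_level("WARNING"):
            build_ssdna_design(bad, t)
        assert "mispriming" in caplog.text


class TestLambdaExo:
    def test_bottom_phosphorylated_keeps_top(self):
        assert simulate_lambda_exo("ACGT", "bottom") == "ACGT"

    def test_top_phosphorylated_of_palindrome(self):
        assert simulate_lambda_exo("ACGT", "top") == "ACGT"  # revcomp == self

    def test_random_500mer_matches_revcomp_oracle(self):
        rng = random.Random(1)
        seq = "".join(rng.choice("ACGT") for _ in range(500))
        assert simulate_lambda_exo(seq, "top") == revcomp(seq)
        assert simulate_lambda_exo(seq, "bottom") == seq


class TestSynthesisConstruct:
    def test_3xstop_cassette_plus_arms_is_715(self, templates, empty_genome):
        t = templates["attP-SA-3XSTOP-minipolyA-U6gRNA1-attP"]
        s = build_synthesis_construct(mk_arms(), t.core_seq, GRna1Unit(),
                                      empty_genome)
        assert s.cassette_plus_arms_len == 715
        assert s.full_insert_len == 715 + 2 * 23

    def test_minigal4_cassette_plus_arms_is_1968(self, templates, empty_genome):
        t = templates["attP-SA-T2A-miniGAL4-minipolyA-U6gRNA1-attP"]
        s = build_synthesis_construct(mk_arms(), t.core_seq, GRna1Unit(),
                                      empty_genome)
        assert s.cassette_plus_arms_len == 1968

    def test_insert_layout_and_pam_inward_orientation(self, empty_genome):
        arms = mk_arms()
        g = GRna1Unit()
        s = build_synthesis_construct(arms, "AAATTTCCCGGG", g, empty_genome)
        assert s.insert_seq == (g.target + arms.lha + "AAATTTCCCGGG"
                                + arms.rha + revcomp(g.target))

    def test_grna1_with_genomic_match_is_hard_error(self):
        g = GRna1Unit()
        seq = "C" * 200 + g.target + "C" * 200
        gm = {"c": GenomeSequence("c", seq)}
        with pytest.raises(DonorDesignError, match="match"):
            build_synthesis_construct(mk_arms(), "AAATTT", g, gm)

    def test_re_site_in_arm_errors_with_alternatives(self, empty_genome):
        arms = mk_arms()
        bad = HomologyArmPair("GAATTC" + arms.lha[6:], arms.rha,
                              arms.cut_site, "+")
        re1 = next(e for e in CATALOG if e.name == "EcoRI")
        re2 = next(e for e in CATALOG if e.name == "NotI")
        with pytest.raises(DonorDesignError, match="EcoRI site in LHA"):
            build_synthesis_construct(
                bad, make_stuffer(re1, re2), GRna1Unit(), empty_genome,
                re_pair=(re1, re2))


class TestChooseRePair:
    def test_conflicting_enzyme_skipped(self):
        ctx = ("AAA" + CATALOG[0].site + "AAA",)  # EcoRI present
        re1, re2 = choose_re_pair(CATALOG, ctx)
        assert re1.name == "NotI" and re2.name == "BamHI"

    def test_all_conflicting_is_structured_failure(self):
        ctx = ("".join(e.site for e in CATALOG),)
        with pytest.raises(CloningError, match="no viable enzyme pair"):
            choose_re_pair(CATALOG, ctx)

    def test_chosen_pair_passes_substring_absence_oracle(self):
        rng = random.Random(17)
        for _ in range(25):
            ctxs = tuple(
                "".join(rng.choice("ACGT") for _ in range(rng.randrange(50, 400)))
                for _ in range(3)
            )
            try:
                re1, re2 = choose_re_pair(CATALOG, ctxs)
            except CloningError:
                continue
            for ctx in ctxs:
                assert re1.site not in ctx and re2.site not in ctx
                assert revcomp(re1.site) not in ctx
                assert revcomp(re2.site) not in ctx


@pytest.fixture(scope="module")
def stuffer_setup(templates, empty_genome):
    arms = mk_arms(seed=4)
    backbone = synthetic_puc57_backbone()
    sic = templates["attP-FRT-SA-T2A-GAL4-polyA-3XP3-EGFP-FRT-attP"].core_seq
    re1, re2 = choose_re_pair(CATALOG, (arms.lha, arms.rha, sic, backbone))
    synth = build_synthesis_construct(
        arms, make_stuffer(re1, re2), GRna1Unit(), empty_genome,
        backbone=backbone, re_pair=(re1, re2))
    return {"arms": arms, "synth": synth, "re": (re1, re2), "sic": sic,
            "backbone": backbone}


class TestSubcloning:
    def test_donor_region_string_assembly_oracle(self, stuffer_setup):
        s = stuffer_setup
        plasmid = simulate_subcloning(s["synth"], s["sic"], "crimic")
        re1, re2 = s["re"]
        g = GRna1Unit()
        expected = (g.target + s["arms"].lha + re1.site + s["sic"] + re2.site
                    + s["arms"].rha + revcomp(g.target))
        assert plasmid.donor_region_seq() == expected
        assert plasmid.provenance == "subcloned"

    def test_swapped_ends_rejected_by_directionality(self, stuffer_setup):
        s = stuffer_setup
        re1, re2 = s["re"]
        flipped = digest_linear_ends(revcomp(s["sic"]), re2, re1)
        _, backbone_frag = digest_circular(s["synth"].vector_seq, re1, re2)
        with pytest.raises(CloningError, match="incompatible overhangs"):
            ligate_circular(backbone_frag, flipped)

    def test_digest_ligate_digest_round_trip(self, stuffer_setup):
        s = stuffer_setup
        re1, re2 = s["re"]
        plasmid = simulate_subcloning(s["synth"], s["sic"], "crimic")
        insert_frag, backbone_frag = digest_circular(plasmid.sequence, re1, re2)
        assert s["sic"] in insert_frag.seq
        religated = ligate_circular(backbone_frag, insert_frag)
        again_insert, again_backbone = digest_circular(religated, re1, re2)
        assert {again_insert.seq, again_backbone.seq} == {
            insert_frag.seq, backbone_frag.seq}

    def test_internal_re_site_in_sic_errors(self, stuffer_setup):
        s = stuffer_setup
        re1, _ = s["re"]
        bad_sic = s["sic"][:100] + re1.site + s["sic"][100:]
        with pytest.raises(CloningError, match="internal"):
            simulate_subcloning(s["synth"], bad_sic, "bad")

    def test_subcloned_equals_direct_synthesis(self, stuffer_setup,
                                               empty_genome):
        s = stuffer_setup
        subcloned = simulate_subcloning(s["synth"], s["sic"], "crimic")
        direct = build_direct_plasmid(
            s["arms"], s["sic"], "crimic", GRna1Unit(), empty_genome,
            s["re"], backbone=s["backbone"])
        assert subcloned.donor_region_seq() == direct.donor_region_seq()
        # same rotation convention => byte-identical circles
        assert subcloned.sequence == direct.sequence


class TestLinearization:
    def test_two_cut_circle_releases_donor_and_backbone(self, stuffer_setup,
                                                        empty_genome):
        s = stuffer_setup
        plasmid = simulate_subcloning(s["synth"], s["sic"], "crimic")
        frags = simulate_linearization(plasmid.sequence, GRna1Unit())
        assert len(frags) == 2
        assert sum(len(f.seq) for f in frags) == len(plasmid.sequence)

    def test_plasmid_without_sites_errors(self):
        with pytest.raises(DonorDesignError, match="2 gRNA1 cut sites"):
            simulate_linearization("ACGT" * 500, GRna1Unit())

    def test_released_donor_matches_cut_position_oracle(self, stuffer_setup):
        """With PAM-inward units the released donor equals the donor region
        minus the PAM-distal 17 nt of each gRNA1 unit (6-nt remnants)."""
        s = stuffer_setup
        plasmid = simulate_subcloning(s["synth"], s["sic"], "crimic")
        donor_seq, remnants = released_donor(plasmid)
        region = plasmid.donor_region_seq()
        assert donor_seq == region[17:-17]
        assert remnants == (6, 6)
        g = GRna1Unit()
        assert donor_seq.startswith(g.target[-6:])
        assert donor_seq.endswith(revcomp(g.target)[:6])

    def test_length_accounting_cassette_plus_arms(self, templates,
                                                  empty_genome):
        """Total donor length decomposes as lha + core + rha for every
        bundled cassette."""
        for t in templates.values():
            arms = mk_arms(seed=8)
            s = build_synthesis_construct(arms, t.core_seq, GRna1Unit(),
                                          empty_genome)
            assert s.cassette_plus_arms_len == 100 + len(t.core_seq) + 100
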