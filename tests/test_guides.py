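"""Guide scanning, the blunt-cut rule, variant filtering and ranking."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from dropindesign._util import revcomp
from dropindesign.genome import CodingIntron, GenomeSequence, StrainVariant
from dropindesign.guides import (
    GuideTarget, NoViableGuideError, count_genome_matches, filter_by_variants,
    rank_guides, scan_guides,
)


def brute_force_guides(seq: str, origin: int = 0):
    """Independent oracle: test all 23-mers on both strands for N20-NGG."""
    found = set()
    for i in range(len(seq) - 22):
        k = seq[i:i + 23]
        if k[21:23] == "GG" and "N" not in k[:20] and "N" not in k[20]:
            found.add((k[:20], k[20:23], "+", origin + i, origin + i + 20,
                       origin + i + 17))
        rc = revcomp(k)
        if rc[21:23] == "GG" and "N" not in rc:
            found.add((rc[:20], rc[20:23], "-", origin + i + 3,
                       origin + i + 23, origin + i + 6))
    return found


def as_tuples(guides):
    return {(g.protospacer, g.pam, g.strand, g.protospacer_start,
             g.protospacer_end, g.cut_site) for g in guides}


class TestScanGuides:
    def test_poly_a_window_has_no_guides(self):
        g = GenomeSequence("c", "A" * 50)
        assert scan_guides(g, (0, 50)) == []

    def test_single_plus_guide_cut_rule_by_hand(self):
        # [A x20][AGG]: one +-strand guide, blunt cut 3 nt before the PAM
        g = GenomeSequence("c", "T" * 10 + "A" * 20 + "AGG" + "T" * 10)
        guides = scan_guides(g, (10, 33))
        assert len(guides) == 1
        (guide,) = guides
        assert guide.strand == "+"
        assert guide.cut_site == 10 + 17
        assert guide.protospacer == "A" * 20 and guide.pam == "AGG"

    @pytest.mark.parametrize("seed", [7, 8, 9])
    def test_matches_brute_force_oracle_on_random_2kb(self, seed):
        rng = random.Random(seed)
        seq = "".join(rng.choice("ACGT") for _ in range(2000))
        g = GenomeSequence("c", seq)
        assert as_tuples(scan_guides(g, (0, 2000))) == brute_force_guides(seq)

    def test_window_must_be_inside_contig(self):
        g = GenomeSequence("c", "ACGT" * 20)
        with pytest.raises(Exception):
            scan_guides(g, (0, 1000))

    def test_protospacer_with_n_excluded(self):
        g = GenomeSequence("c", "A" * 10 + "N" + "A" * 9 + "AGG")
        assert scan_guides(g, (0, 23)) == []

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=30, max_size=120))
    def test_strand_symmetry(self, seq):
        """Scanning the reverse complement yields the mirror-image set."""
        n = len(seq)
        fwd = scan_guides(GenomeSequence("c", seq), (0, n))
        rev = scan_guides(GenomeSequence("c", revcomp(seq)), (0, n))
        mirrored = {
            (g.protospacer, g.pam, "-" if g.strand == "+" else "+",
             n - g.protospacer_end, n - g.protospacer_start, n - g.cut_site)
            for g in rev
        }
        assert as_tuples(fwd) == mirrored

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_genome_slice_recovers_protospacer_and_pam(self, seed):
        rng = random.Random(seed)
        seq = "".join(rng.choice("ACGT") for _ in range(300))
        g = GenomeSequence("c", seq)
        for guide in scan_guides(g, (0, 300)):
            span = seq[guide.protospacer_start:guide.protospacer_end]
            if guide.strand == "+":
                pam = seq[guide.protospacer_end:guide.protospacer_end + 3]
            else:
                span = revcomp(span)
                pam = revcomp(seq[guide.protospacer_start - 3:
                                  guide.protospacer_start])
            assert span == guide.protospacer and pam == guide.pam


def mk_guide(start, strand, clean=True):
    if strand == "+":
        return GuideTarget("A" * 20, "AGG", "+", start, start + 20,
                           start + 17, variant_clean=clean)
    return GuideTarget("A" * 20, "AGG", "-", start, start + 20, start + 3,
                       variant_clean=clean)


class TestFilterByVariants:
    def test_snv_in_pam_flags_guide(self):
        g = mk_guide(100, "+")
        snv = StrainVariant("c", 121, "A", "T")  # inside PAM [120, 123)
        (out,) = filter_by_variants([g], [snv])
        assert not out.variant_clean

    def test_distant_snv_keeps_guide_clean(self):
        g = mk_guide(100, "+")
        snv = StrainVariant("c", 133, "A", "T")  # 10 nt past the PAM
        (out,) = filter_by_variants([g], [snv], pad=0)
        assert out.variant_clean

    def test_pad_extends_the_window(self):
        g = mk_guide(100, "+")
        snv = StrainVariant("c", 130, "A", "T")
        assert filter_by_variants([g], [snv], pad=0)[0].variant_clean
        assert not filter_by_variants([g], [snv], pad=10)[0].variant_clean

    def test_random_guides_match_interval_overlap_oracle(self):
        rng = random.Random(11)
        guides = [mk_guide(rng.randrange(0, 5000), rng.choice("+-"))
                  for _ in range(100)]
        variants = []
        for _ in range(20):
            pos = rng.randrange(0, 5000)
            kind = rng.choice(["SNV", "del", "ins"])
            ref = "A" * (4 if kind == "del" else 1)
            alt = "A" + ("CG" if kind == "ins" else "")
            variants.append(StrainVariant("c", pos, ref,
                                          alt if kind != "SNV" else "T"))
        out = filter_by_variants(guides, variants)
        for g_in, g_out in zip(guides, out):
            fs, fe = g_in.footprint
            overlap = any(
                max(fs, v.interval[0]) < min(fe, v.interval[1])
                for v in variants
            )
            assert g_out.variant_clean == (not overlap)


class TestRankGuides:
    INTRON = CodingIntron(1000, 1600, 0, ("e1", "e2"))

    def test_single_clean_guide_mid_intron_returned_first(self):
        g = mk_guide(1280, "+")  # cut 1297, near midpoint 1300
        assert rank_guides([g], self.INTRON)[0] is not None
        assert rank_guides([g], self.INTRON)[0].cut_site == 1297

    def test_junction_proximal_guide_excluded_at_default_threshold(self):
        near = mk_guide(1573, "+")  # cut 1590, 10 nt from the acceptor
        mid = mk_guide(1280, "+")
        ranked = rank_guides([near, mid], self.INTRON)
        assert [g.cut_site for g in ranked] == [1297]

    def test_all_excluded_raises_structured_error(self):
        near = mk_guide(1573, "+")
        with pytest.raises(NoViableGuideError) as err:
            rank_guides([near], self.INTRON)
        assert "splice junction" in str(err.value)
        assert err.value.exclusions

    def test_ordering_matches_explicit_sort_key_oracle(self):
        guides = [
            mk_guide(1100, "+", clean=True),
            mk_guide(1260, "+", clean=False),
            mk_guide(1300, "-", clean=True),
            mk_guide(1297, "+", clean=True),
            mk_guide(1450, "+", clean=True),
        ]
        ranked = rank_guides(guides, self.INTRON)
        mid = (self.INTRON.start + self.INTRON.end) / 2

        def key(g):
            return (not g.variant_clean, abs(g.cut_site - mid),
                    g.protospacer_start, g.strand != "+")

        expected = sorted(guides, key=key)
        assert [(g.protospacer_start, g.strand) for g in ranked] == [
            (g.protospacer_start, g.strand) for g in expected
        ]

    def test_cut_outside_intron_rejected(self):
        with pytest.raises(ValueError, match="outside intron"):
            rank_guides([mk_guide(100, "+")], self.INTRON)


class TestGenomeMatches:
    def test_planted_target_counted_on_both_strands(self):
        proto, pam = "GATTACAGATTACAGATTAC", "TGG"
        site = proto + pam
        seq = "C" * 50 + site + "C" * 50 + revcomp(site) + "C" * 50
        gm = {"c": GenomeSequence("c", seq)}
        assert count_genome_matches(gm, proto, pam) == 2
        assert count_genome_matches(gm, "A" * 20, "AGG") == 0
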