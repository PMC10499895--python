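import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fusionbreak.assay import (
    AmbiguousPrimingError,
    Fragment,
    Primer,
    RestrictionEnzyme,
    ScreenConfig,
    breakpoint_detectability,
    control_band_sizes,
    digest,
    find_primer_sites,
    inverse_pcr_product,
    load_enzyme_db,
    load_primers,
    multiplex_products,
    revcomp,
    screen_enzymes,
)
from fusionbreak.simulate import generate_reference

SPHI = RestrictionEnzyme("SphI", "GCATGC", 5, 1)
BAMHI = RestrictionEnzyme("BamHI", "GGATCC", 1, 5)
TAQI = RestrictionEnzyme("TaqI", "TCGA", 1, 3)
ECORV = RestrictionEnzyme("EcoRV", "GATATC", 3, 3)


def plant(base: str, inserts: dict[int, str]) -> str:
    """Overwrite ``base`` with substrings at 0-based offsets."""
    seq = list(base)
    for pos, sub in inserts.items():
        seq[pos:pos + len(sub)] = sub
    return "".join(seq)


class TestEnzymeProperties:
    def test_shipped_db(self):
        db = {e.name: e for e in load_enzyme_db()}
        assert db["BamHI"].recognition == "GGATCC"  # canonical site, not the printed truncation
        assert db["SphI"].is_palindromic and db["SphI"].is_sticky
        assert not db["EcoRV"].is_sticky
        assert db["BstXI"].is_degenerate
        assert db["TaqI"].recognition == "TCGA"

    def test_palindromy(self):
        assert SPHI.is_palindromic
        assert not RestrictionEnzyme("odd", "GGTACA", 1, 5).is_palindromic

    def test_degenerate_detection(self):
        assert RestrictionEnzyme("x", "GGTNACC", 1, 5).is_degenerate
        assert not SPHI.is_degenerate

    def test_invalid_cut_offset(self):
        with pytest.raises(ValueError):
            RestrictionEnzyme("x", "GCATGC", 7, 1)


class TestDigest:
    def test_no_site_linear_identity(self):
        frags = digest("A" * 50, SPHI, "linear")
        assert len(frags) == 1 and frags[0].sequence == "A" * 50
        assert frags[0].left_end == "molecule_end"

    def test_toy_two_sites_hand_cut(self):
        # SphI sites at 1-based 10 and 40 on a 60-bp molecule;
        # cuts after GCATG -> boundaries at 14 and 44 -> lengths 14/30/16
        seq = plant("A" * 60, {9: "GCATGC", 39: "GCATGC"})
        frags = digest(seq, SPHI, "linear")
        assert [len(f) for f in frags] == [14, 30, 16]
        assert sum(len(f) for f in frags) == 60
        assert "".join(f.sequence for f in frags) == seq
        assert frags[1].circularizable

    def test_circular_single_site_gives_full_length_linear(self):
        seq = plant("A" * 80, {20: "GCATGC"})
        frags = digest(seq, SPHI, "circular")
        assert len(frags) == 1 and len(frags[0]) == 80
        assert frags[0].circularizable

    def test_circular_no_site(self):
        frags = digest("A" * 30, SPHI, "circular")
        assert len(frags) == 1 and frags[0].left_end == "circular"

    def test_circular_site_spanning_origin(self):
        # site GCATGC split as ...TGC | GCA...
        seq = "TGC" + "A" * 40 + "GCA"
        frags = digest(seq, SPHI, "circular")
        assert len(frags) == 1 and len(frags[0]) == 46

    def test_linear_site_counts(self, rng):
        seq = generate_reference(20_000, 0.5, rng)
        frags = digest(seq, TAQI, "linear")
        n_sites = seq.count("TCGA")  # TCGA cannot overlap itself
        assert len(frags) == n_sites + 1

    @given(st.text(alphabet="ACGT", min_size=1, max_size=400),
           st.sampled_from([SPHI, BAMHI, TAQI, ECORV]),
           st.sampled_from(["linear", "circular"]))
    @settings(max_examples=120, deadline=None)
    def test_conservation(self, seq, enzyme, topology):
        frags = digest(seq, enzyme, topology)
        assert sum(len(f) for f in frags) == len(seq)


class TestFindPrimerSites:
    def test_unique_plus_hit(self):
        seq = plant("A" * 100, {40: "CCGGTTAACCGGTTA"})
        primer = Primer("p", "CCGGTTAACCGGTTA")
        assert find_primer_sites(seq, primer) == [(41, "+")]

    def test_minus_hit_position_is_five_prime_end(self):
        primer = Primer("p", "CCGGTTAACCGGTTA")
        seq = plant("A" * 100, {40: revcomp(primer.sequence)})
        assert find_primer_sites(seq, primer) == [(55, "-")]

    def test_three_plants_match_naive_scan(self):
        primer = Primer("p", "CGTACGTACGTACGT")
        seq = plant("A" * 300, {10: primer.sequence, 100: primer.sequence,
                                250: primer.sequence})
        hits = find_primer_sites(seq, primer)
        naive = [(i + 1, "+") for i in range(len(seq))
                 if seq[i:i + 15] == primer.sequence]
        assert [h for h in hits if h[1] == "+"] == naive
        assert len(naive) == 3

    def test_primer_validation(self):
        with pytest.raises(ValueError):
            Primer("short", "ACGTACGTACGT")
        with pytest.raises(ValueError):
            Primer("bad", "ACGTACGTACGTACGN")


class TestInversePcr:
    @pytest.fixture()
    def frag100(self):
        return generate_reference(100, 0.5, 5)

    def test_hand_computed_size_40(self, frag100):
        fwd = Primer("F", frag100[80:96])            # 5' end at plus 81
        rev = Primer("R", revcomp(frag100[4:20]))    # 5' end at plus 20
        product = inverse_pcr_product(Fragment(0, frag100, "enzyme", "enzyme"), fwd, rev)
        assert product is not None and product.size == 40
        assert product.contains_junction

    def test_convergent_orientation_gives_none(self, frag100):
        fwd = Primer("F", frag100[4:20])
        rev = Primer("R", revcomp(frag100[80:96]))
        assert inverse_pcr_product(Fragment(0, frag100, "enzyme", "enzyme"), fwd, rev) is None

    def test_absent_primer_gives_none(self, frag100):
        fwd = Primer("F", frag100[80:96])
        rev = Primer("R", "CCCCGGGGCCCCGGGG")
        assert inverse_pcr_product(Fragment(0, frag100, "enzyme", "enzyme"), fwd, rev) is None

    def test_non_circularizable_fragment_gives_none(self, frag100):
        fwd = Primer("F", frag100[80:96])
        rev = Primer("R", revcomp(frag100[4:20]))
        assert inverse_pcr_product(Fragment(0, frag100, "molecule_end", "enzyme"),
                                   fwd, rev) is None

    def test_size_invariant_under_rotation(self, frag100):
        fwd = Primer("F", frag100[80:96])
        rev = Primer("R", revcomp(frag100[4:20]))
        for r in range(0, 100, 3):
            rotated = frag100[r:] + frag100[:r]
            product = inverse_pcr_product(Fragment(0, rotated, "enzyme", "enzyme"),
                                          fwd, rev, junction_only=False)
            assert product is not None and product.size == 40

    def test_double_binding_raises_ambiguity(self):
        fwd = Primer("F", "CGTACGTACGTACGT")
        seq = plant("A" * 200, {10: fwd.sequence, 100: fwd.sequence})
        rev = Primer("R", revcomp("A" * 15 + "C"))
        with pytest.raises(AmbiguousPrimingError):
            inverse_pcr_product(Fragment(0, seq, "enzyme", "enzyme"), fwd, rev)


FWD16 = "ACGTACGTACGTACGA"
REV_SITE16 = "CCGGTTAACCGGTTAA"


class TestControlBands:
    def make_reference(self):
        # BamHI cuts at boundaries 101 and 701; middle fragment spans [101, 701)
        return plant("A" * 1000, {
            100: "GGATCC", 700: "GGATCC",
            150: REV_SITE16,   # reverse primer 5' end at in-fragment pos 65
            600: FWD16,        # forward primer 5' end at in-fragment pos 500
        })

    def test_synthetic_reference_hand_computed(self):
        ref = self.make_reference()
        fwd = Primer("F", FWD16)
        rev = Primer("R", revcomp(REV_SITE16))
        sizes = control_band_sizes(ref, BAMHI, [(fwd, rev)])
        # fragment length 600; size = (600 - 500 + 1) + 65
        assert sizes[("F", "R")] == 166

    def test_absent_forward_reported_none(self):
        ref = self.make_reference()
        fwd = Primer("F", "GGGGCCCCGGGGCCCC")
        rev = Primer("R", revcomp(REV_SITE16))
        sizes = control_band_sizes(ref, BAMHI, [(fwd, rev)])
        assert sizes[("F", "R")] is None

    def test_equals_direct_string_arithmetic(self, rng):
        # randomized plant positions; oracle computes the size from coordinates
        for _ in range(20):
            cut1, cut2 = 100, int(rng.integers(500, 900))
            frag_len = cut2 + 1 - (cut1 + 1)
            p_r_off = int(rng.integers(cut1 + 10, cut1 + 150))
            p_f_off = int(rng.integers(cut1 + 200, cut2 - 30))
            ref = plant("A" * 1000, {cut1: "GGATCC", cut2: "GGATCC",
                                     p_r_off: REV_SITE16, p_f_off: FWD16})
            fwd, rev = Primer("F", FWD16), Primer("R", revcomp(REV_SITE16))
            p_f = p_f_off - cut1  # 1-based within fragment
            p_r = p_r_off - cut1 + 15
            expected = (frag_len - p_f + 1) + p_r
            sizes = control_band_sizes(ref, BAMHI, [(fwd, rev)])
            assert sizes[("F", "R")] == expected


class TestScreenEnzymes:
    def region_seq(self):
        return plant("A" * 2000, {100: "GCATGC", 1500: "GCATGC",
                                  200: "TCGA", 1200: "TCGA",
                                  300: "GATATC", 1300: "GATATC",
                                  400: "GGTCACC", 1400: "GGTCACC"})

    def test_screen_criteria(self):
        db = load_enzyme_db()
        results = screen_enzymes(db, self.region_seq(), 500, 1000)
        names = [r.enzyme.name for r in results]
        assert "SphI" in names and "TaqI" in names
        assert "EcoRV" not in names   # blunt
        assert "BstXI" not in names   # degenerate
        assert "NotI" not in names    # 8-cutter
        assert "BamHI" not in names   # no flanking site planted

    def test_flanking_distances(self):
        results = screen_enzymes([SPHI], self.region_seq(), 500, 1000)
        (r,) = results
        assert r.left_distance == 499 - 105
        assert r.right_distance == 1505 - 1000

    def test_max_fragment_excludes_distant_sites(self):
        results = screen_enzymes([SPHI], self.region_seq(), 500, 1000,
                                 ScreenConfig(max_fragment=300))
        assert results == []

    def test_empty_db(self):
        assert screen_enzymes([], "ACGT" * 100, 10, 20) == []


class TestBreakpointDetectability:
    def test_site_between_primers_and_junction_not_detectable(self):
        der = plant("A" * 1200, {100: "GGATCC", 500: "GGATCC", 900: "GGATCC",
                                 150: REV_SITE16, 300: FWD16})
        result = breakpoint_detectability(der, 700, BAMHI,
                                          Primer("F", FWD16),
                                          Primer("R", revcomp(REV_SITE16)))
        assert not result.detectable

    def test_junction_on_primer_fragment_detectable(self):
        der = plant("A" * 1200, {100: "GGATCC", 500: "GGATCC",
                                 150: REV_SITE16, 300: FWD16})
        result = breakpoint_detectability(der, 450, BAMHI,
                                          Primer("F", FWD16),
                                          Primer("R", revcomp(REV_SITE16)))
        # fragment [101,501): length 400; p_f = 200, p_r = 65
        assert result.detectable
        assert result.size == (400 - 200 + 1) + 65

    def test_destroyed_site_extends_fragment_into_partner(self):
        # same geometry but the fusion removed the middle site: the junction
        # fragment now reaches the next site at 900 and is still detectable
        der = plant("A" * 1200, {100: "GGATCC", 900: "GGATCC",
                                 150: REV_SITE16, 300: FWD16})
        result = breakpoint_detectability(der, 500, BAMHI,
                                          Primer("F", FWD16),
                                          Primer("R", revcomp(REV_SITE16)))
        assert result.detectable
        assert result.size == (800 - 200 + 1) + 65

    def test_product_over_max_size_not_detectable(self):
        der = plant("A" * 1200, {100: "GGATCC", 900: "GGATCC",
                                 150: REV_SITE16, 300: FWD16})
        result = breakpoint_detectability(der, 500, BAMHI,
                                          Primer("F", FWD16),
                                          Primer("R", revcomp(REV_SITE16)),
                                          max_size=500)
        assert not result.detectable and result.size == 666

    def test_junction_outside_amplified_arc(self):
        # junction between the reverse and forward sites (the unamplified arc)
        der = plant("A" * 1200, {100: "GGATCC", 900: "GGATCC",
                                 150: REV_SITE16, 600: FWD16})
        result = breakpoint_detectability(der, 400, BAMHI,
                                          Primer("F", FWD16),
                                          Primer("R", revcomp(REV_SITE16)))
        assert not result.detectable
        assert "arc" in result.reason


class TestMultiplex:
    def setup_der(self):
        rev1 = plant("A" * 2000, {100: FWD16,
                                  584: REV_SITE16,    # 5' end at 600
                                  1384: REV_SITE16})  # 5' end at 1400
        return rev1

    def test_nearest_panel_primer_only_within_max_size(self):
        der = self.setup_der()
        preds = multiplex_products(der, Primer("F", FWD16),
                                   [Primer("R1", revcomp(REV_SITE16))],
                                   junction_pos=400, max_size=1000)
        assert len(preds) == 1
        assert preds[0].size == 600 - 101 + 1

    def test_two_panel_primers_within_max_size(self):
        der = plant("A" * 2000, {100: FWD16, 584: REV_SITE16,
                                 1384: "GGCCAATTGGCCAATT"})
        preds = multiplex_products(der, Primer("F", FWD16),
                                   [Primer("R1", revcomp(REV_SITE16)),
                                    Primer("R2", revcomp("GGCCAATTGGCCAATT"))],
                                   junction_pos=400, max_size=2000)
        assert [p.size for p in preds] == [500, 1300]

    def test_junction_outside_covered_region_empty(self):
        der = self.setup_der()
        preds = multiplex_products(der, Primer("F", FWD16),
                                   [Primer("R1", revcomp(REV_SITE16))],
                                   junction_pos=1500, max_size=10_000)
        assert preds == []


def test_load_primers_shipped():
    primers = load_primers()
    assert primers["TCF3-F2"].sequence.startswith("CTCCCTGACC")
    assert primers["TCF3-qF"].sequence == "CAGGCAGACTTTCCAAGTACCTT"
    assert len(primers) == 18
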