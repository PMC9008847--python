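import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

import wrkyfam as w
from wrkyfam.errors import AnnotationError, InputError

AA = "ACDEFGHIKLMNPQRSTVWY"
# alphabet enriched in C/H so random strings contain zinc-finger-like runs
AA_CH = AA + "CCCHHH"


def c2h2(s1=4, s2=22, x="A"):
    return "C" + x * s1 + "C" + x * s2 + "H" + x + "H"


def c2hc(x="A"):
    return "C" + x * 7 + "C" + x * 23 + "H" + x + "C"


class TestHeptapeptides:
    def test_single_canonical_site(self):
        assert w.find_heptapeptides("AAWRKYGQKAA") == [(2, "WRKYGQK")]

    def test_two_variant_sites_in_order(self):
        p = "WRKYGEK" + "A" * 10 + "WRKYGQK"
        assert w.find_heptapeptides(p) == [(0, "WRKYGEK"), (17, "WRKYGQK")]

    def test_unknown_variant_not_matched(self):
        assert w.find_heptapeptides("WRKYGAK") == []

    def test_non_amino_acid_rejected(self):
        with pytest.raises(InputError):
            w.find_heptapeptides("WRKYGQK1")

    def test_agrees_with_naive_oracle_on_random_strings(self, rng):
        for _ in range(300):
            p = "".join(rng.choice("WRKYGEQK") for _ in range(60))
            expected = [
                (i, v)
                for i in range(len(p) - 6)
                for v in w.HEPTAPEPTIDE_VARIANTS
                if p[i : i + 7] == v
            ]
            assert w.find_heptapeptides(p) == expected


def _zf_oracle(protein, from_index, window=80):
    """Naive position-by-position zinc-finger search mirroring pattern priority."""
    region_end = min(len(protein), from_index + window)
    for start in range(from_index, region_end):
        # C2HC first (more specific), then C2H2 with greedy spacers
        span = 1 + 7 + 1 + 23 + 1 + 1 + 1
        if start + span <= region_end:
            s = protein[start : start + span]
            if s[0] == "C" and s[8] == "C" and s[32] == "H" and s[34] == "C":
                return ("C2HC", start, start + span, 7, 23)
        for s1 in (5, 4):
            for s2 in (23, 22):
                span = 1 + s1 + 1 + s2 + 1 + 1 + 1
                if start + span > region_end:
                    continue
                s = protein[start : start + span]
                if s[0] == "C" and s[1 + s1] == "C" and s[2 + s1 + s2] == "H" and s[4 + s1 + s2] == "H":
                    return ("C2H2", start, start + span, s1, s2)
    return ("none", None, None, None, None)


class TestZincFinger:
    def test_constructed_c2h2(self):
        p = "WRKYGQK" + c2h2(4, 22)
        hit = w.find_zinc_finger(p, 7)
        assert (hit.zf_type, hit.spacer1, hit.spacer2) == ("C2H2", 4, 22)

    def test_constructed_c2hc(self):
        p = "WRKYGQK" + c2hc()
        hit = w.find_zinc_finger(p, 7)
        assert (hit.zf_type, hit.spacer1, hit.spacer2) == ("C2HC", 7, 23)

    def test_absence_is_a_value(self):
        hit = w.find_zinc_finger("WRKYGQK" + "A" * 60, 7)
        assert hit.zf_type == "none" and not hit.complete

    def test_agrees_with_naive_oracle_on_random_strings(self, rng):
        for _ in range(500):
            p = "".join(rng.choice(AA_CH) for _ in range(200))
            got = w.find_zinc_finger(p, 0)
            typ, start, end, s1, s2 = _zf_oracle(p, 0)
            assert got.zf_type == typ
            if typ != "none":
                assert got.zf_span == (start, end)
                assert (got.spacer1, got.spacer2) == (s1, s2)


class TestClassifyGroup:
    def test_two_c2h2_domains_is_group_one(self):
        p = "M" + "WRKYGQK" + c2h2() + "GGG" + "WRKYGQK" + c2h2()
        assert w.classify_group(w.scan_protein(p)) == "I"

    def test_one_c2hc_is_group_three(self):
        p = "M" + "WRKYGQK" + c2hc()
        assert w.classify_group(w.scan_protein(p)) == "III"

    def test_one_c2h2_is_group_two(self):
        p = "M" + "WRKYGQK" + c2h2(5, 23)
        assert w.classify_group(w.scan_protein(p)) == "II"

    def test_heptapeptide_without_finger_is_unresolved(self):
        p = "M" + "WRKYGQK" + "A" * 90
        assert w.classify_group(w.scan_protein(p)) == "unresolved"

    def test_empty_hits_rejected(self):
        with pytest.raises(AnnotationError):
            w.classify_group([])

    def test_permutation_invariant_in_hit_order(self):
        hits = w.scan_protein("M" + "WRKYGQK" + c2h2() + "GGG" + "WRKYGQK" + c2h2())
        assert w.classify_group(hits) == w.classify_group(list(reversed(hits)))


class TestAssignSubgroup:
    def test_self_match_wins_with_positive_margin(self, refs):
        ref = next(r for r in refs if r.label == "IIa")
        label, score, margin = w.assign_subgroup(ref.sequence, refs)
        assert label == "IIa" and score > 0 and margin > 0

    def test_tie_broken_by_smaller_ref_id(self):
        refs = [
            w.ReferenceDomain("R2", "IIb", "WRKYGQKAAAA"),
            w.ReferenceDomain("R1", "IIa", "WRKYGQKAAAA"),
        ]
        label, _, margin = w.assign_subgroup("WRKYGQKAAAA", refs)
        assert label == "IIa" and margin == 0

    def test_nonmatching_query_is_unassigned(self):
        refs = [w.ReferenceDomain("R1", "IIa", "KKKKKKKK")]
        label, score, _ = w.assign_subgroup("DDDDDDDD", refs)
        assert label == "unassigned" and score <= 0

    def test_deterministic(self, refs):
        q = refs[3].sequence[5:-5]
        assert w.assign_subgroup(q, refs) == w.assign_subgroup(q, refs)


class TestPhysicochemical:
    def test_mw_glycine_and_diglycine(self):
        # 75.07 Da and 2x57.0519 + 18.0153 Da from a standard mass table
        assert w.protein_mw("G") == pytest.approx(0.0751, abs=1e-4)
        assert w.protein_mw("GG") == pytest.approx(0.1321, abs=1e-4)

    def test_mw_empty_rejected(self):
        with pytest.raises(InputError):
            w.protein_mw("")

    @settings(derandomize=True, max_examples=40)
    @given(st.text(alphabet=AA, min_size=1, max_size=30),
           st.text(alphabet=AA, min_size=1, max_size=30))
    def test_mw_additive_up_to_water(self, a, b):
        water = 18.01524 / 1000.0
        assert w.protein_mw(a + b) == pytest.approx(w.protein_mw(a) + w.protein_mw(b) - water, abs=1e-6)

    def test_pi_sign_checks(self):
        assert w.protein_pi("K" * 10) > 9
        assert w.protein_pi("D" * 10) < 5

    def test_pi_glycine_equals_independent_root(self):
        # closed-form two-group equation solved independently
        f = lambda ph: 1 / (1 + 10 ** (ph - 8.6)) - 1 / (1 + 10 ** (3.6 - ph))
        root = brentq(f, 0, 14, xtol=1e-10)
        assert w.protein_pi("G") == pytest.approx(root, abs=0.02)

    def test_pi_root_has_small_residual_charge(self, rng):
        from wrkyfam.wrky_scan import net_charge

        for _ in range(20):
            p = "".join(rng.choice(AA) for _ in range(rng.randint(5, 60)))
            pi = w.protein_pi(p)
            # charge is monotone decreasing; the bracket width bounds |charge|
            assert net_charge(p, pi - 0.02) >= 0 >= net_charge(p, pi + 0.02)


class TestIntronsAndSummary:
    @pytest.mark.parametrize("n_exons,expected", [(3, 2), (1, 0), (7, 6)])
    def test_intron_count(self, n_exons, expected):
        exons = [(i * 20, i * 20 + 10) for i in range(n_exons)]
        g = w.GeneModel("g", "c", "+", (0, exons[-1][1]), exons=exons, cds=exons)
        assert w.count_introns(g) == expected

    def test_no_exons_rejected(self):
        g = w.GeneModel("g", "c", "+", (0, 10))
        with pytest.raises(AnnotationError):
            w.count_introns(g)

    def test_single_row_summary_degenerates_to_that_row(self, table1):
        s = w.summarize_family_table(table1.iloc[[0]])
        assert s["n_members"] == 1
        assert s["cds_bp"]["min"] == s["cds_bp"]["max"] == s["cds_bp"]["mean"] == 1140

    def test_empty_table_rejected(self, table1):
        with pytest.raises(InputError):
            w.summarize_family_table(table1.iloc[0:0])
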