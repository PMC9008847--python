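import itertools
import math
import random

import pytest
from Bio.Seq import Seq

import wrkyfam as w
from wrkyfam.errors import InputError, SaturationError, TranslationError

SENSE_CODONS = [
    "".join(c) for c in itertools.product("ACGT", repeat=3)
    if str(Seq("".join(c)).translate()) != "*"
]


def aa_of(codon):
    """Amino acid via Biopython, '*' for stop (independent of the module's table)."""
    return str(Seq(codon).translate())


def oracle_site_counts(cds_a, cds_b):
    """Exhaustive NG86 site/difference counter written from the definitions."""

    def syn_sites(codon):
        s = 0.0
        for pos in range(3):
            for base in "ACGT":
                if base == codon[pos]:
                    continue
                alt = codon[:pos] + base + codon[pos + 1:]
                if aa_of(alt) != "*" and aa_of(alt) == aa_of(codon):
                    s += 1 / 3
        return s

    def diff_counts(ca, cb):
        diff = [i for i in range(3) if ca[i] != cb[i]]
        if not diff:
            return 0.0, 0.0
        results = []
        for order in itertools.permutations(diff):
            cur, sd, nd, blocked = ca, 0.0, 0.0, False
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                if aa_of(nxt) == "*" and nxt != cb:
                    blocked = True
                    break
                if aa_of(cur) != "*" and aa_of(nxt) != "*" and aa_of(cur) == aa_of(nxt):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            if not blocked:
                results.append((sd, nd))
        if not results:  # all pathways pass through stops: count them, nonsyn steps
            for order in itertools.permutations(diff):
                cur, sd, nd = ca, 0.0, 0.0
                for pos in order:
                    nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                    if aa_of(cur) != "*" and aa_of(nxt) != "*" and aa_of(cur) == aa_of(nxt):
                        sd += 1
                    else:
                        nd += 1
                    cur = nxt
                results.append((sd, nd))
        sd = sum(r[0] for r in results) / len(results)
        nd = sum(r[1] for r in results) / len(results)
        return sd, nd

    S = Sd = Nd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i:i + 3], cds_b[i:i + 3]
        S += (syn_sites(ca) + syn_sites(cb)) / 2
        sd, nd = diff_counts(ca, cb)
        Sd += sd
        Nd += nd
    return S, 3 * len(cds_a) / 3 - S, Sd, Nd


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert w.pairwise_protein_identity("MKTAYIAK", "MKTAYIAK") == (1.0, 1.0)

    def test_three_of_four_identity(self):
        ident, _ = w.pairwise_protein_identity("AAAA", "AAAT")
        assert ident == pytest.approx(0.75)

    def test_prefix_coverage_half(self):
        parent = "MKTAYIAKQR" * 10
        ident, cov = w.pairwise_protein_identity(parent[:50], parent)
        assert cov == pytest.approx(0.5)
        assert ident == pytest.approx(1.0)

    def test_symmetry(self, rng):
        a = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(80))
        b = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(60))
        assert w.pairwise_protein_identity(a, b) == pytest.approx(w.pairwise_protein_identity(b, a))

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            w.pairwise_protein_identity("", "AAA")


class TestNg86:
    def test_identical_cds_zero_rates(self):
        cds = "ATGAAACCCGGG"
        assert w.ng86_kaks(cds, cds) == (0.0, 0.0)

    def test_phe_leu_single_nonsynonymous_change(self):
        # TTT vs TTA: S=0.5, N=2.5, Nd=1, Sd=0 by pathway enumeration
        S, N, Sd, Nd = w.ng86_site_counts("TTT", "TTA")
        assert (S, N, Sd, Nd) == pytest.approx((0.5, 2.5, 0.0, 1.0))
        ka, ks = w.ng86_kaks("TTT", "TTA")
        assert ks == 0.0
        assert ka == pytest.approx(-0.75 * math.log(1 - 4 * 0.4 / 3))

    def test_synonymous_third_position_change(self):
        # padded context keeps pS below the Jukes-Cantor ceiling
        ka, ks = w.ng86_kaks("TTTGGGAAA", "TTCGGGAAA")
        assert ka == 0.0 and ks > 0.0

    def test_single_codon_synonymous_change_saturates(self):
        with pytest.raises(SaturationError):
            w.ng86_kaks("TTT", "TTC")

    def test_length_mismatch_and_frame_errors(self):
        with pytest.raises(InputError):
            w.ng86_site_counts("ATG", "ATGAAA")
        with pytest.raises(InputError):
            w.ng86_site_counts("ATGA", "ATGA")

    def test_symmetric_in_argument_order(self, rng):
        for _ in range(50):
            n = rng.randint(5, 20)
            a = "".join(rng.choice(SENSE_CODONS) for _ in range(n))
            b = "".join(rng.choice(SENSE_CODONS) for _ in range(n))
            Sa, Na, Sda, Nda = w.ng86_site_counts(a, b)
            Sb, Nb, Sdb, Ndb = w.ng86_site_counts(b, a)
            assert (Sa, Na, Sda, Nda) == pytest.approx((Sb, Nb, Sdb, Ndb), abs=1e-12)

    def test_counts_equal_exhaustive_oracle(self, rng):
        for _ in range(500):
            n = rng.randint(2, 30)
            a = "".join(rng.choice(SENSE_CODONS) for _ in range(n))
            # b: a with scattered substitutions, keeping sense codons
            b = list(a)
            for _ in range(rng.randint(0, n)):
                i = rng.randrange(n)
                cod = rng.choice(SENSE_CODONS)
                b[3 * i: 3 * i + 3] = cod
            b = "".join(b)
            got = w.ng86_site_counts(a, b)
            exp = oracle_site_counts(a, b)
            assert got == pytest.approx(exp, abs=1e-12)


class TestDatingAndRegime:
    def test_dating_is_ks_over_two_lambda(self):
        assert w.date_duplication(0.0) == 0.0
        assert w.date_duplication(0.39, 6.1e-9) == pytest.approx(0.39 / (2 * 6.1e-9) / 1e6)
        assert w.date_duplication(0.39, 6.1e-9) == pytest.approx(31.97, abs=0.005)
        assert w.date_duplication(1.22e-2, 6.1e-9) == pytest.approx(1.0)

    def test_dating_linear_in_ks_and_inverse_in_lambda(self):
        assert w.date_duplication(0.8) == pytest.approx(2 * w.date_duplication(0.4))
        assert w.date_duplication(0.4, 2 * 6.1e-9) == pytest.approx(w.date_duplication(0.4) / 2)

    def test_negative_ks_rejected(self):
        with pytest.raises(InputError):
            w.date_duplication(-0.1)

    @pytest.mark.parametrize(
        "ka,ks,regime",
        [(0.1, 0.5, "purifying"), (0.2, 0.2, "neutral"), (0.5, 0.2, "positive"),
         (0.3, 0.0, "undefined")],
    )
    def test_regime_thresholds(self, ka, ks, regime):
        assert w.classify_regime(ka, ks) == regime


def _toy_model(gene_id, chrom, start, cds_len=90, strand="+"):
    return w.GeneModel(gene_id, chrom, strand, (start, start + cds_len),
                       exons=[(start, start + cds_len)], cds=[(start, start + cds_len)])


class TestDuplicatePairs:
    def setup_method(self):
        rng = random.Random(77)
        self.cds = "".join(rng.choice(SENSE_CODONS) for _ in range(100))
        self.prot = str(Seq(self.cds).translate())

    def _family(self, positions):
        models = [_toy_model(f"g{i}", chrom, pos) for i, (chrom, pos) in enumerate(positions)]
        proteins = {m.gene_id: self.prot for m in models}
        cds = {m.gene_id: self.cds for m in models}
        return models, proteins, cds

    def test_tandem_within_100kb_same_chromosome(self):
        models, proteins, cds = self._family([("c1", 0), ("c1", 50_000)])
        (pair,) = w.find_duplicate_pairs(models, proteins, cds)
        assert pair.dup_type == "tandem"
        assert pair.regime == "undefined"  # identical sequences, Ks = 0

    def test_different_chromosomes_are_segmental(self):
        models, proteins, cds = self._family([("c1", 0), ("c2", 0)])
        (pair,) = w.find_duplicate_pairs(models, proteins, cds)
        assert pair.dup_type == "segmental"

    def test_beyond_100kb_same_chromosome_is_segmental(self):
        models, proteins, cds = self._family([("c1", 0), ("c1", 150_000)])
        (pair,) = w.find_duplicate_pairs(models, proteins, cds)
        assert pair.dup_type == "segmental"

    def test_intervening_family_member_blocks_tandem(self):
        models, proteins, cds = self._family([("c1", 0), ("c1", 80_000), ("c1", 40_000)])
        pairs = {frozenset((p.gene_a, p.gene_b)): p for p in
                 w.find_duplicate_pairs(models, proteins, cds)}
        assert pairs[frozenset(("g0", "g2"))].dup_type == "tandem"
        assert pairs[frozenset(("g0", "g1"))].dup_type == "segmental"
        cfg = w.AnalysisConfig(tandem_requires_adjacency=False)
        pairs2 = {frozenset((p.gene_a, p.gene_b)): p for p in
                  w.find_duplicate_pairs(models, proteins, cds, cfg)}
        assert pairs2[frozenset(("g0", "g1"))].dup_type == "tandem"

    def test_low_identity_pair_excluded(self):
        rng = random.Random(3)
        other = "".join(rng.choice(SENSE_CODONS) for _ in range(100))
        models = [_toy_model("g0", "c1", 0), _toy_model("g1", "c1", 5000)]
        proteins = {"g0": self.prot, "g1": str(Seq(other).translate())}
        cds = {"g0": self.cds, "g1": other}
        assert w.find_duplicate_pairs(models, proteins, cds) == []

    def test_planted_divergence_pair_dated(self):
        a, b, _ = w.gen_duplicate_pair(150, 0.3, 0.05, seed=5)
        models = [_toy_model("g0", "c1", 0, len(a)), _toy_model("g1", "c2", 0, len(b))]
        proteins = {"g0": str(Seq(a).translate()), "g1": str(Seq(b).translate())}
        (pair,) = w.find_duplicate_pairs(models, proteins, {"g0": a, "g1": b})
        assert pair.regime == "purifying"
        assert pair.t_mya == pytest.approx(pair.ks / (2 * 6.1e-9) / 1e6)


class TestOrthologyAndCollinearity:
    def test_identical_single_gene_proteomes(self):
        pairs = w.reciprocal_best_hits({"a": "MKTAYIAKQRQISFVK"}, {"b": "MKTAYIAKQRQISFVK"})
        assert len(pairs) == 1 and pairs[0].reciprocal

    def test_non_mutual_best_hits_yield_no_pair(self):
        # x's best is y, but y's best is z
        pa = {"x": "AAAAAAAAAA"}
        pb = {"y": "AAAAAAAAAA", "z": "AAAAAAAAAA"}
        assert w.reciprocal_best_hits(pa, pb) == []  # tie for x -> no call

    def test_planted_orthologs_all_recovered(self):
        pa, pb, mapping = w.gen_ortholog_proteomes(8, seed=12)
        pairs = w.reciprocal_best_hits(pa, pb)
        assert {(p.gene_a, p.gene_b) for p in pairs} == set(mapping.items())

    def test_matching_order_gives_one_block(self):
        pairs = [w.OrthologPair(f"a{i}", f"b{i}", 10.0, True) for i in range(5)]
        blocks = w.collinear_blocks(
            pairs, {"cA": [f"a{i}" for i in range(5)]}, {"cB": [f"b{i}" for i in range(5)]})
        assert [(b.orientation, len(b)) for b in blocks] == [("+", 5)]

    def test_inverted_segment_detected_with_minus_orientation(self):
        pairs = [w.OrthologPair(f"a{i}", f"b{i}", 10.0, True) for i in range(4)]
        blocks = w.collinear_blocks(
            pairs, {"cA": [f"a{i}" for i in range(4)]},
            {"cB": [f"b{i}" for i in reversed(range(4))]})
        assert [(b.orientation, len(b)) for b in blocks] == [("-", 4)]

    def test_scrambled_order_below_min_chain_yields_nothing(self, rng):
        # brute-force longest monotone subsequence confirms max chain < 3
        order_b = [2, 0, 3, 1]
        while True:
            ok = True
            for combo in itertools.combinations(range(4), 3):
                sub = [order_b[i] for i in combo]
                if sub == sorted(sub) or sub == sorted(sub, reverse=True):
                    ok = False
            if ok:
                break
        pairs = [w.OrthologPair(f"a{i}", f"b{order_b[i]}", 10.0, True) for i in range(4)]
        blocks = w.collinear_blocks(
            pairs, {"cA": [f"a{i}" for i in range(4)]}, {"cB": [f"b{i}" for i in range(4)]})
        assert blocks == []
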