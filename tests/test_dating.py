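"""Age classes, Fitch reconstruction, amr and Kimura dating."""

import itertools
import math

import numpy as np
import pytest

from numt_atlas.config import RateConfig
from numt_atlas.dating import (
    AgeClass,
    Fragment,
    age_from_amr,
    age_from_kimura,
    assign_age_class,
    compute_amr,
    compute_vmt,
    date_region,
    fitch_ancestral,
    kimura_insertion_point,
    kimura_k80,
    threeway_align,
)
from numt_atlas.synthio import (
    HostSpec, InsertionSpec, plant_numts, simulate_mtdna_set,
)


# hand-written rule table over (scrofa, other_sus, warthog, bovid)
EXPECTED_CLASSES = {
    (0, 0, 0, 0): AgeClass.UNDETERMINED,
    (1, 0, 0, 0): AgeClass.LE_3P5,
    (0, 1, 0, 0): AgeClass.LE_3P5,
    (0, 0, 1, 0): AgeClass.MYA_10_3P5,     # warthog-lineage-private, < 10 Mya
    (0, 0, 0, 1): AgeClass.UNDETERMINED,   # bovid without any Suinae copy
    (1, 1, 0, 0): AgeClass.MYA_10_3P5,
    (1, 0, 1, 0): AgeClass.MYA_55_10,
    (0, 1, 1, 0): AgeClass.MYA_55_10,
    (1, 1, 1, 0): AgeClass.MYA_55_10,
    (1, 0, 0, 1): AgeClass.GT_55,
    (0, 1, 0, 1): AgeClass.GT_55,
    (0, 0, 1, 1): AgeClass.GT_55,
    (1, 1, 0, 1): AgeClass.GT_55,
    (1, 0, 1, 1): AgeClass.GT_55,
    (0, 1, 1, 1): AgeClass.GT_55,
    (1, 1, 1, 1): AgeClass.GT_55,
}


class TestAgeClass:
    def test_exhaustive_sixteen_patterns(self):
        for pattern in itertools.product((0, 1), repeat=4):
            got = assign_age_class(*(bool(x) for x in pattern))
            assert got is EXPECTED_CLASSES[pattern], pattern

    def test_paper_rule_examples(self):
        assert assign_age_class(True, True, False, False) is AgeClass.MYA_10_3P5
        assert assign_age_class(True, True, True, True) is AgeClass.GT_55


class TestFitch:
    TOPOLOGY = "(((A,B)ab,C)abc,D)root;"

    def test_identical_taxa_identical_ancestor(self):
        aln = {t: "ACGTACGT" for t in "ABCD"}
        seq, amb = fitch_ancestral(aln, self.TOPOLOGY, "ab")
        assert seq == "ACGTACGT"
        assert not amb.any()

    def test_hand_worked_single_site_cases(self):
        # A=T, B=T, C=G, D=G: ab = {T} unambiguous
        seq, amb = fitch_ancestral(
            {"A": "T", "B": "T", "C": "G", "D": "G"}, self.TOPOLOGY, "ab"
        )
        assert seq == "T" and not amb[0]
        # A=T, B=G, C=G, D=G: up(ab) = {T,G}; final(ab) = {G} via parent
        seq, amb = fitch_ancestral(
            {"A": "T", "B": "G", "C": "G", "D": "G"}, self.TOPOLOGY, "ab"
        )
        assert seq == "G" and not amb[0]
        # A=T, B=G, C=A, D=C: everything unions -> ambiguous at ab
        seq, amb = fitch_ancestral(
            {"A": "T", "B": "G", "C": "A", "D": "C"}, self.TOPOLOGY, "ab"
        )
        assert seq == "N" and amb[0]

    def test_mismatched_taxa_rejected(self):
        with pytest.raises(ValueError):
            fitch_ancestral({"A": "T", "B": "T", "X": "G", "D": "G"},
                            self.TOPOLOGY, "ab")

    def test_recovers_simulated_ancestor(self, outgroup_tree):
        """>= 95% of unambiguous sites match the recorded true ancestor."""
        accs = []
        for seed in range(20):
            panel = simulate_mtdna_set(outgroup_tree, seed=seed)
            seq, amb = fitch_ancestral(
                panel.species, outgroup_tree.newick_topology, "sus"
            )
            truth = panel.ancestors["sus"]
            ok = [a == b for a, b, m in zip(seq, truth, amb) if not m]
            accs.append(np.mean(ok))
        assert np.mean(accs) >= 0.95


class TestAmr:
    def test_identical_to_modern_gives_age_zero(self):
        r = compute_amr("ACGT", "ACGA", "ACGT")
        assert r.amr == 1.0
        assert age_from_amr(r.amr, 3.5) == 0.0

    def test_identical_to_ancestral_gives_age_T(self):
        r = compute_amr("ACGA", "ACGA", "ACGT")
        assert r.amr == 0.0
        assert age_from_amr(r.amr, 3.5) == 3.5

    def test_direct_arithmetic(self):
        """8 informative columns, NUMT matches modern at 3 of them."""
        anc = "AAAAAAAA" + "C" * 12
        mod = "GGGGGGGG" + "C" * 12
        numt = "GGGAATAA" + "C" * 12  # matches modern at cols 0,1,2
        r = compute_amr(numt, anc, mod)
        assert (r.numt_vs_modern, r.ancestral_vs_modern) == (3, 8)
        assert r.amr == 0.375
        assert age_from_amr(r.amr, 3.5) == pytest.approx(2.1875)

    def test_gap_and_ambiguous_columns_excluded(self):
        r = compute_amr("A-GN", "AAGA", "AGGT")
        assert r.ancestral_vs_modern == 0
        assert r.amr is None

    def test_out_of_range_amr_rejected(self):
        with pytest.raises(ValueError):
            age_from_amr(1.2, 3.5)

    def test_age_from_amr_midpoint(self):
        assert age_from_amr(0.5, 10.0) == 5.0

    def test_threeway_align_handles_deletion(self):
        numt = "ACGTGT"          # 2-bp deletion relative to modern
        modern = "ACGTACGT"
        anc = "ACGAACGA"
        gn, ga, gm = threeway_align(numt, anc, modern)
        assert len(gn) == len(ga) == len(gm) == 8
        assert gn.count("-") == 2


class TestKimura:
    def test_identical_zero(self):
        assert kimura_k80("ACGT" * 50, "ACGT" * 50) == 0.0

    def test_closed_form_spot_check(self):
        """P=0.1, Q=0.05 -> K = -0.5 ln(0.75 sqrt(0.9)) ~ 0.170191."""
        n = 200
        a = list("A" * n)
        b = list("A" * n)
        for i in range(20):        # 10% transitions (A->G)
            b[i] = "G"
        for i in range(20, 30):    # 5% transversions (A->C)
            b[i] = "C"
        k = kimura_k80("".join(a), "".join(b))
        expected = -0.5 * math.log((1 - 0.2 - 0.05) * math.sqrt(1 - 0.1))
        assert k == pytest.approx(expected, abs=1e-4)
        assert k == pytest.approx(0.1702, abs=1e-4)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a = "".join(rng.choice(list("ACGT"), 500))
        b = list(a)
        for i in rng.choice(500, 60, replace=False):
            b[i] = "ACGT"[(("ACGT".index(b[i])) + int(rng.integers(1, 4))) % 4]
        b = "".join(b)
        assert kimura_k80(a, b) == kimura_k80(b, a) > 0

    def test_saturation_returns_nan(self):
        a = "A" * 100
        b = "G" * 100  # all transitions: 1 - 2P - Q < 0
        assert math.isnan(kimura_k80(a, b))


class TestVmtAndKimuraAge:
    def test_vmt_arithmetic(self):
        v = compute_vmt({("A", "B"): 0.14}, {("A", "B"): 3.5})
        assert v == pytest.approx(0.14 / (2 * 3.5e6))  # 2.0e-8

    def test_zero_matrix_guards_division(self):
        v = compute_vmt({("A", "B"): 0.0}, {("A", "B"): 3.5})
        assert v == 0.0

    def test_age_arithmetic(self):
        t = age_from_kimura(0.25, 2.0e-8, 2.2e-9)
        assert t == pytest.approx(11.26, abs=0.01)
        assert age_from_kimura(0.0, 2.0e-8, 2.2e-9) == 0.0

    def test_zero_rates_rejected(self):
        with pytest.raises(ValueError):
            age_from_kimura(0.1, 0.0, 0.0)

    def test_rate_ordering_monotone(self):
        """Fixed K and V_mt: age strictly decreases in V_numt, so the slow
        pedigree rate pushes regions into older classes."""
        ages = [age_from_kimura(0.3, 1e-8, v)
                for v in (1.2e-9, 2.2e-9, 2.48e-9)]
        assert ages[0] > ages[1] > ages[2]

    def test_insertion_point_clade_selection(self):
        dists = {"scrofa": 0.10, "cebifrons": 0.12, "warthog": 0.30,
                 "bovid": 1.0}
        div = {"scrofa": 0.0, "cebifrons": 3.5, "warthog": 10.0, "bovid": 55.0}
        closest, K = kimura_insertion_point(dists, "scrofa", div)
        assert closest == "scrofa"
        assert K == pytest.approx(0.10)
        # alternative strictly-by-distance rule behind the flag
        closest2, K2 = kimura_insertion_point(dists, "scrofa", div,
                                              clade_rule="distance")
        assert K2 == pytest.approx(0.10)


@pytest.fixture(scope="module")
def dated_fixture(outgroup_tree):
    tree = outgroup_tree
    pair_times = {}
    for i, a in enumerate(tree.species):
        for b in tree.species[i + 1:]:
            pair_times[(a, b)] = tree.divergence(a, b)
    div_host = {sp: tree.divergence("scrofa", sp) for sp in tree.species}
    return tree, pair_times, div_host


class TestDateRegion:
    def _run(self, tree, pair_times, div_host, age, cls, length=2000,
             identity=0.99, seed=0, dloop=None, mt_start=3000):
        host = HostSpec(contigs={"c": 30_000}, species=["scrofa"])
        ins = InsertionSpec("x", "c", 10_000, mt_start, mt_start + length,
                            age, genotypes={"s1": "hom_ins"})
        res = plant_numts(host, [ins], tree, seed=seed)
        anc, _ = fitch_ancestral(res.panel.species, tree.newick_topology,
                                 "sus")
        frag = Fragment(res.truth[0].inserted_seq["scrofa"], mt_start,
                        mt_start + length, identity)
        return date_region("r", cls, [frag], res.panel.species, anc,
                           "scrofa", div_host, pair_times, dloop=dloop)

    def test_short_region_class_only(self, dated_fixture):
        tree, pt, dh = dated_fixture
        est = self._run(tree, pt, dh, 1.0, AgeClass.LE_3P5, length=140)
        assert est.method == "class_only"
        assert est.age is None

    def test_dloop_region_class_only(self, dated_fixture):
        tree, pt, dh = dated_fixture
        est = self._run(tree, pt, dh, 1.0, AgeClass.LE_3P5,
                        mt_start=3000, dloop=(2900, 5200))
        assert est.method == "class_only"

    def test_low_identity_routes_to_kimura(self, dated_fixture):
        tree, pt, dh = dated_fixture
        est = self._run(tree, pt, dh, 6.0, AgeClass.MYA_10_3P5,
                        identity=0.76)
        assert est.method == "kimura"

    def test_young_high_identity_routes_to_amr(self, dated_fixture):
        tree, pt, dh = dated_fixture
        est = self._run(tree, pt, dh, 1.75, AgeClass.LE_3P5)
        assert est.method == "amr"
        assert 0.0 <= est.age <= 3.5

    def test_multi_fragment_counts_are_summed(self, dated_fixture):
        tree, pt, dh = dated_fixture
        host = HostSpec(contigs={"c": 40_000}, species=["scrofa"])
        ins = InsertionSpec("x", "c", 10_000, 3000, 5000, 1.75,
                            genotypes={"s1": "hom_ins"})
        res = plant_numts(host, [ins], tree, seed=1)
        anc, _ = fitch_ancestral(res.panel.species, tree.newick_topology,
                                 "sus")
        whole = res.truth[0].inserted_seq["scrofa"]
        frags = [Fragment(whole[:1000], 3000, 4000, 0.99),
                 Fragment(whole[1000:], 4000, 5000, 0.99)]
        est_split = date_region("r", AgeClass.LE_3P5, frags,
                                res.panel.species, anc, "scrofa", dh, pt)
        est_whole = date_region("r", AgeClass.LE_3P5,
                                [Fragment(whole, 3000, 5000, 0.99)],
                                res.panel.species, anc, "scrofa", dh, pt)
        assert est_split.amr.ancestral_vs_modern == \
            est_whole.amr.ancestral_vs_modern
        assert est_split.age == pytest.approx(est_whole.age)

    def test_method1_age_bounded_by_T(self, dated_fixture):
        tree, pt, dh = dated_fixture
        for seed in range(5):
            est = self._run(tree, pt, dh, 3.0, AgeClass.LE_3P5, seed=seed)
            assert 0.0 <= est.age <= 3.5

    def test_vmt_recovered_within_20_percent(self, dated_fixture):
        tree, pt, dh = dated_fixture
        vmts = []
        for seed in range(10):
            est = self._run(tree, pt, dh, 30.0, AgeClass.MYA_55_10,
                            identity=0.7, seed=seed)
            vmts.append(est.kimura.v_mt)
        assert abs(np.mean(vmts) - tree.mito_rate) / tree.mito_rate < 0.20
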