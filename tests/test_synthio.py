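"""Ground-truth generator: mtDNA evolution, NUMT planting, read simulation."""

import numpy as np
import pytest
from scipy.stats import binomtest, chisquare

from numt_atlas.dating import kimura_k80
from numt_atlas.synthio import (
    HostSpec,
    InsertionSpec,
    SpeciesTreeSpec,
    default_tree,
    plant_numts,
    simulate_mtdna_set,
    simulate_reads,
)


def _hom(sample="s1"):
    return {sample: "hom_ins"}


class TestMtdnaSimulation:
    def test_zero_time_limit_identical_sequences(self, two_species_tree):
        tree = two_species_tree(T=1e-12)
        panel = simulate_mtdna_set(tree, seed=0)
        assert panel.species["A"] == panel.species["B"]
        assert kimura_k80(panel.species["A"], panel.species["B"]) == 0.0

    def test_pairwise_distance_matches_closed_form(self, two_species_tree):
        """Mean K80 distance ~ 2 * rate * T over 20 replicate panels."""
        tree = two_species_tree(T=3.5, mito_rate=2e-8)
        dists = [
            kimura_k80(*simulate_mtdna_set(tree, seed=s).species.values())
            for s in range(20)
        ]
        expected = 2 * 2e-8 * 3.5e6  # 0.14
        assert abs(np.mean(dists) - expected) / expected < 0.15

    def test_kappa_one_transition_transversion_symmetry(self, two_species_tree):
        """At kappa=1 each substitution type is equally likely, so observed
        transitions are ~half the transversions (two transversion targets)."""
        tree = two_species_tree(T=2.0, mito_rate=2e-8, kappa=1.0)
        ts = tv = 0
        purine = set("AG")
        for s in range(20):
            panel = simulate_mtdna_set(tree, seed=s)
            a, b = panel.species["A"], panel.species["B"]
            for x, y in zip(a, b):
                if x == y:
                    continue
                if (x in purine) == (y in purine):
                    ts += 1
                else:
                    tv += 1
        total = ts + tv
        stat, p = chisquare([ts, tv], [total / 3, 2 * total / 3])
        assert p > 0.01

    def test_non_ultrametric_rejected(self):
        with pytest.raises(ValueError):
            SpeciesTreeSpec(
                newick_topology="((A,B)inner,C)root;",
                divergence_times={"inner": 12.0, "root": 10.0},
            )

    def test_ancestors_recorded_at_every_internal_node(self, tree):
        panel = simulate_mtdna_set(tree, seed=1)
        assert set(panel.ancestors) == {"root", "suinae", "sus"}
        assert all(len(s) == tree.mt_length for s in panel.ancestors.values())


class TestPlanting:
    def test_zero_age_insertion_identical_to_modern(self, tree):
        host = HostSpec(contigs={"c": 30_000}, species=["scrofa"])
        ins = InsertionSpec("n", "c", 10_000, 2000, 3000, 0.0,
                            genotypes=_hom())
        res = plant_numts(host, [ins], tree, seed=0)
        modern_seg = res.panel.species["scrofa"][2000:3000]
        assert res.truth[0].inserted_seq["scrofa"] == modern_seg

    def test_full_branch_age_gives_near_zero_amr(self, two_species_tree):
        """Inserted at the divergence time, the copy matches the ancestor;
        the truth amr stays below 0.15 for 2-kb fragments."""
        tree = two_species_tree(T=3.5, mito_rate=2e-8)
        host = HostSpec(contigs={"c": 30_000}, species=["A"])
        amrs = []
        for s in range(20):
            ins = InsertionSpec("n", "c", 10_000, 2000, 4000, 3.5,
                                host_species="A", genotypes=_hom())
            res = plant_numts(host, [ins], tree, seed=s)
            amrs.append(res.truth[0].true_amr)
        assert np.mean(amrs) < 0.15

    def test_genotype_semantics(self, tree):
        host = HostSpec(contigs={"c": 30_000}, species=["scrofa"])
        ins = InsertionSpec("n", "c", 10_000, 2000, 2500, 0.5,
                            genotypes={"s1": "hom_ins", "s2": "absent"})
        res = plant_numts(host, [ins], tree, seed=1)
        background = res.reference["c"]
        assert res.sample_haplotypes["s2"][0]["c"] == background
        assert res.sample_haplotypes["s2"][1]["c"] == background
        for hap in res.sample_haplotypes["s1"]:
            assert len(hap["c"]) == 30_500

    def test_het_one_haplotype_carries(self, tree):
        host = HostSpec(contigs={"c": 30_000}, species=["scrofa"])
        ins = InsertionSpec("n", "c", 10_000, 2000, 2500, 0.5,
                            genotypes={"s1": "het"})
        res = plant_numts(host, [ins], tree, seed=1)
        lens = sorted(len(h["c"]) for h in res.sample_haplotypes["s1"])
        assert lens == [30_000, 30_500]

    def test_wraparound_interval_needs_flag(self, tree):
        host = HostSpec(contigs={"c": 30_000}, species=["scrofa"])
        bad = InsertionSpec("n", "c", 10_000, tree.mt_length - 100,
                            tree.mt_length + 80, 0.5, genotypes=_hom(),
                            wraparound=False)
        with pytest.raises(ValueError):
            plant_numts(host, [bad], tree, seed=0)
        ok = InsertionSpec("n", "c", 10_000, tree.mt_length - 100,
                           tree.mt_length + 80, 0.0, genotypes=_hom(),
                           wraparound=True)
        res = plant_numts(host, [ok], tree, seed=0)
        assert res.truth[0].length == 180

    def test_fragmentation_plan_applied(self, tree):
        host = HostSpec(contigs={"c": 30_000}, species=["scrofa"])
        ins = InsertionSpec(
            "n", "c", 10_000, 2000, 3000, 0.0, genotypes=_hom(),
            fragmentation_plan=[("del", 100, 300), ("inv", 400, 600)],
        )
        res = plant_numts(host, [ins], tree, seed=2)
        assert res.truth[0].length == 800
        mt = res.panel.species["scrofa"]
        seq = res.truth[0].inserted_seq["scrofa"]
        assert seq[:100] == mt[2000:2100]          # before deletion
        assert seq[100:400] == mt[2300:2600]       # deletion removed 200
        comp = str.maketrans("ACGT", "TGCA")
        assert seq[400:600] == mt[2600:2800].translate(comp)[::-1]

    def test_overlapping_deletions_rejected(self):
        with pytest.raises(ValueError):
            InsertionSpec(
                "n", "c", 0, 0, 100, 0.0,
                fragmentation_plan=[("del", 10, 50), ("del", 40, 80)],
            )

    def test_identity_decreases_with_age(self, tree):
        """Mean NUMT-vs-modern identity is strictly age-monotone."""
        host = HostSpec(contigs={"c": 40_000}, species=["scrofa"])
        means = []
        for age in (0.0, 3.5, 10.0, 30.0):
            idents = []
            for s in range(20):
                ins = InsertionSpec("n", "c", 10_000, 2000, 4000, age,
                                    genotypes=_hom())
                res = plant_numts(host, [ins], tree, seed=s)
                numt = res.truth[0].inserted_seq["scrofa"]
                modern = res.panel.species["scrofa"][2000:4000]
                idents.append(np.mean([a == b for a, b in zip(numt, modern)]))
            means.append(np.mean(idents))
        assert all(a > b for a, b in zip(means, means[1:]))


def _sim(tree, genotypes, depth=20, error_rate=0.0, seed=0, length=500,
         contig_len=40_000, read_len=100):
    host = HostSpec(contigs={"c": contig_len}, species=["scrofa"])
    ins = InsertionSpec("n", "c", 20_000, 3000, 3000 + length, 0.1,
                        genotypes=genotypes)
    res = plant_numts(host, [ins], tree, seed=seed)
    sample = sorted(genotypes)[0]
    rs = simulate_reads(
        res.sample_haplotypes[sample], res.reference,
        res.haplotype_layout(sample), depth=depth, read_len=read_len,
        insert_size=300, error_rate=error_rate, seed=seed + 7,
        sample_name=sample,
    )
    return res, rs


def _parse_sam(sam_text):
    recs = []
    for line in sam_text.splitlines():
        if line.startswith("@"):
            continue
        f = line.split("\t")
        recs.append({"name": f[0], "flag": int(f[1]), "pos": int(f[3]),
                     "cigar": f[5], "seq": f[9]})
    return recs


def _cigar_ops(cigar):
    out, n = [], ""
    for ch in cigar:
        if ch.isdigit():
            n += ch
        else:
            out.append((int(n), ch))
            n = ""
    return out


class TestReadSimulation:
    def test_clean_sample_has_no_soft_clips(self, tree):
        res, rs = _sim(tree, {"s1": "absent"})
        recs = _parse_sam(rs.sam_text)
        assert all("S" not in r["cigar"] for r in recs)
        assert rs.expected_breakpoints == []

    def test_hom_insertion_clips_match_placement_oracle(self, tree):
        """Every junction-crossing read is soft-clipped exactly at the
        breakpoint; verified against an independent re-placement of each
        read in the known haplotype."""
        res, rs = _sim(tree, {"s1": "hom_ins"}, depth=20)
        hap = res.sample_haplotypes["s1"][0]["c"]
        t = res.truth[0]
        r_start, r_end = t.realised["scrofa"]
        recs = [r for r in _parse_sam(rs.sam_text) if not r["flag"] & 0x4]
        n_clipped_sam = sum("S" in r["cigar"] for r in recs)
        n_crossing = 0
        for r in recs:
            seq = r["seq"]
            # independent placement: locate the read in the haplotype
            s = hap.find(seq)
            assert s >= 0, "read must re-locate in its haplotype"
            e = s + len(seq)
            crosses = s < r_start < e or s < r_end < e
            if crosses:
                n_crossing += 1
                assert "S" in r["cigar"], (s, e, r["cigar"])
                # clip position is the breakpoint
                ops = _cigar_ops(r["cigar"])
                if ops[0][1] == "S":
                    assert r["pos"] - 1 == t.ref_position
                else:
                    m = sum(n for n, op in ops if op == "M")
                    assert r["pos"] - 1 + m == t.ref_position
        assert n_clipped_sam == n_crossing

    def test_het_clip_support_is_binomial_half_of_hom(self, tree):
        """Heterozygous samples draw junction reads from one haplotype of
        two, so clip support is Binomial(n_hom, 1/2) relative to a
        homozygous sample at the same depth."""
        _res, rs_hom = _sim(tree, {"s1": "hom_ins"}, depth=30, seed=3)
        _res2, rs_het = _sim(tree, {"s1": "het"}, depth=30, seed=3)
        n_hom = sum("S" in r["cigar"] for r in _parse_sam(rs_hom.sam_text))
        n_het = sum("S" in r["cigar"] for r in _parse_sam(rs_het.sam_text))
        ci = binomtest(n_het, n_hom, 0.5).proportion_ci(0.999)
        assert ci.low <= 0.5 <= ci.high

    def test_mean_coverage_close_to_requested(self, tree):
        res, rs = _sim(tree, {"s1": "absent"}, depth=25)
        recs = [r for r in _parse_sam(rs.sam_text) if not r["flag"] & 0x4]
        aligned = sum(
            sum(n for n, op in _cigar_ops(r["cigar"]) if op == "M")
            for r in recs
        )
        cov = aligned / len(res.reference["c"])
        assert abs(cov - 25) / 25 < 0.10

    def test_coverage_conservation(self, tree):
        """Aligned plus clipped bases equal read_len for every mapped read."""
        res, rs = _sim(tree, {"s1": "hom_ins"}, depth=10)
        for r in _parse_sam(rs.sam_text):
            if r["flag"] & 0x4:
                continue
            total = sum(n for n, op in _cigar_ops(r["cigar"]) if op in "MS")
            assert total == 100

    def test_reproducibility_byte_identical(self, tree):
        _res, rs1 = _sim(tree, {"s1": "het"}, error_rate=0.01, seed=5)
        _res2, rs2 = _sim(tree, {"s1": "het"}, error_rate=0.01, seed=5)
        assert rs1.sam_text == rs2.sam_text
        assert rs1.fastq1 == rs2.fastq1
        assert rs1.fastq2 == rs2.fastq2

    def test_read_len_longer_than_contig_rejected(self, tree):
        host = HostSpec(contigs={"c": 2_000}, species=["scrofa"])
        res = plant_numts(host, [], tree, seed=0)
        with pytest.raises(ValueError):
            simulate_reads([{"c": "ACGT" * 10}], res.reference,
                           [{"c": []}], depth=5, read_len=100)

    def test_pooled_mode_mixes_haplotypes(self, tree):
        """A 1:3 pool of carrier and background haplotypes yields ~25%
        of the homozygous clip support."""
        host = HostSpec(contigs={"c": 40_000}, species=["scrofa"])
        ins = InsertionSpec("n", "c", 20_000, 3000, 3500, 0.1,
                            genotypes={"s1": "hom_ins", "s2": "absent"})
        res = plant_numts(host, [ins], tree, seed=2)
        carrier = res.sample_haplotypes["s1"][0]
        background = res.sample_haplotypes["s2"][0]
        lay_c = res.haplotype_layout("s1")[0]
        lay_b = res.haplotype_layout("s2")[0]
        rs = simulate_reads(
            [carrier, background], res.reference, [lay_c, lay_b],
            depth=40, seed=9, weights=[0.25, 0.75], sample_name="pool",
        )
        rs_hom = simulate_reads(
            [carrier], res.reference, [lay_c], depth=40, seed=9,
            sample_name="hom",
        )
        n_pool = sum("S" in r["cigar"] for r in _parse_sam(rs.sam_text))
        n_hom = sum("S" in r["cigar"] for r in _parse_sam(rs_hom.sam_text))
        ci = binomtest(n_pool, n_hom, 0.25).proportion_ci(0.999)
        assert ci.low <= 0.25 <= ci.high
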