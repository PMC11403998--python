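"""Soft-clip breakpoint calling, filters, genotyping and assembly."""

import numpy as np
import pytest

from numt_atlas.assembly_scan import NumtHit, build_regions
from numt_atlas.synthio import HostSpec, InsertionSpec, default_tree, plant_numts, simulate_reads
from numt_atlas.wgs_scan import (
    Breakpoint,
    GenotypeCall,
    InsertionLocus,
    SampleAlignment,
    assemble_insertion,
    call_insertions,
    classify_novel,
    depth_filter,
    detect_breakpoints,
    finalize_novel,
    group_loci,
    match_clips,
)
from conftest import random_dna
from sam_fixtures import build_cascade_fixture, brute_force_r1_r2


@pytest.fixture(scope="module")
def hom_sample(tmp_path_factory):
    tree = default_tree()
    host = HostSpec(contigs={"c": 50_000}, species=["scrofa"])
    ins = InsertionSpec("n", "c", 20_000, 2000, 2400, 0.1,
                        genotypes={"s1": "hom_ins"})
    res = plant_numts(host, [ins], tree, seed=3)
    rs = simulate_reads(res.sample_haplotypes["s1"], res.reference,
                        res.haplotype_layout("s1"), depth=20, seed=5,
                        sample_name="s1")
    p = tmp_path_factory.mktemp("sam") / "s1.sam"
    rs.write(sam_path=p)
    return res, SampleAlignment(p, "s1")


class TestDetectBreakpoints:
    def test_hom_insertion_gives_left_and_right_breakpoints(self, hom_sample):
        res, sample = hom_sample
        bps = detect_breakpoints(sample)
        truth_pos = res.truth[0].ref_position
        sides = {(b.clip_side, b.position) for b in bps}
        assert any(s == "left" and abs(p - truth_pos) <= 1 for s, p in sides)
        assert any(s == "right" and abs(p - truth_pos) <= 1 for s, p in sides)
        assert all(b.n_clip_reads >= 3 for b in bps)

    def test_two_supporting_reads_insufficient(self, tmp_path):
        ref_len = 5_000
        rng = np.random.default_rng(0)
        ref = random_dna(rng, ref_len)
        lines = ["@HD\tVN:1.6", f"@SQ\tSN:c\tLN:{ref_len}"]
        for i in range(2):
            lines.append(f"r{i}\t0\tc\t{1000 - 60 + 1}\t60\t60M40S\t*\t0\t0\t"
                         f"{ref[940:1000] + 'A' * 40}\t{'I' * 100}")
        p = tmp_path / "two.sam"
        p.write_text("\n".join(lines) + "\n")
        assert detect_breakpoints(SampleAlignment(p, "s")) == []

    def test_clean_genome_no_breakpoints(self, tmp_path, tree):
        host = HostSpec(contigs={"c": 20_000}, species=["scrofa"])
        res = plant_numts(host, [], tree, seed=0)
        rs = simulate_reads([res.reference], res.reference, [{"c": []}],
                            depth=10, seed=1)
        p = tmp_path / "clean.sam"
        rs.write(sam_path=p)
        assert detect_breakpoints(SampleAlignment(p, "s")) == []

    def test_missing_sq_header_rejected(self, tmp_path):
        p = tmp_path / "nosq.sam"
        p.write_text("@HD\tVN:1.6\nr0\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tIIII\n")
        with pytest.raises(ValueError):
            SampleAlignment(p, "s")


class TestMatchClips:
    def test_clips_reconstruct_mt_segment(self):
        rng = np.random.default_rng(1)
        mt = random_dna(rng, 2_000)
        clips = [(f"r{i}", mt[2000 - 300 + 50 * i : 2000 - 300 + 50 * i + 60])
                 for i in range(5)]
        matches, seq = match_clips(clips, mt)
        assert len(matches) == 5
        assert seq == mt[1700:1760 + 200]

    def test_random_clip_rejected(self):
        rng = np.random.default_rng(2)
        mt = random_dna(rng, 2_000)
        matches, seq = match_clips([("r", random_dna(rng, 50))], mt)
        assert matches == []
        assert seq == ""

    def test_identity_exactly_75_percent_rejected(self):
        """Strict reading: identity must exceed 0.75, equality fails.

        64-bp clip: 15-bp exact anchors at both ends, middle alternating
        mismatch/match, 48/64 matches total -- the full-length alignment is
        the unique optimum and its identity is exactly 0.75.
        """
        rng = np.random.default_rng(3)
        mt = random_dna(rng, 2_000)
        seg = list(mt[600:664])
        positions = [15 + 2 * k for k in range(16)]  # 16 middle mismatches
        for p in positions:
            seg[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seg[p]]
        clip = "".join(seg)
        matches, _seq = match_clips([("r", clip)], mt)
        assert matches == []
        # control: 10 middle mismatches (identity 54/64 = 0.84) passes
        seg2 = list(mt[600:664])
        for p in positions[:10]:
            seg2[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seg2[p]]
        matches2, _ = match_clips([("r", "".join(seg2))], mt)
        assert len(matches2) == 1
        assert matches2[0].identity > 0.75


class TestDepthFilter:
    def _bp(self, pos=500):
        return Breakpoint("c", pos, "right", 5, "s")

    def test_md_formula_upper_bound(self):
        depth = np.full(1000, 33, dtype=np.int32)
        assert depth_filter(self._bp(), depth, d=16.0) is False  # MD = 32
        depth[:] = 32
        assert depth_filter(self._bp(), depth, d=16.0) is True

    def test_lower_bound_six(self):
        depth = np.full(1000, 5, dtype=np.int32)
        assert depth_filter(self._bp(), depth, d=16.0) is False
        depth[:] = 6
        assert depth_filter(self._bp(), depth, d=16.0) is True

    def test_requires_positive_mean_depth(self):
        with pytest.raises(ValueError):
            depth_filter(self._bp(), np.zeros(10), d=0.0)


class TestGroupLoci:
    def _bp(self, pos, sample):
        return Breakpoint("c", pos, "right", 3, sample)

    def test_within_100bp_grouped(self):
        loci = group_loci([self._bp(1000, "s1"), self._bp(1099, "s2")])
        assert len(loci) == 1
        assert loci[0].position == 1049

    def test_beyond_100bp_split(self):
        loci = group_loci([self._bp(1000, "s1"), self._bp(1101, "s2")])
        assert len(loci) == 2

    def test_single_sample_locus_counts_one_dataset(self):
        (locus,) = group_loci([self._bp(1000, "s1")])
        assert {b.sample_id for b in locus.breakpoints} == {"s1"}


class TestClassifyNovel:
    def _regions(self):
        h = NumtHit("g", "c", 5_000, 5_400, 0, 400, "+", 400, 1.0, 400)
        return build_regions([h])

    def _locus(self, pos, contig="c"):
        return InsertionLocus("x", contig, pos, [])

    def test_inside_region_known(self):
        assert classify_novel(self._locus(5_200), self._regions()) is False

    def test_within_slop_known(self):
        assert classify_novel(self._locus(5_450), self._regions()) is False
        assert classify_novel(self._locus(4_950), self._regions()) is False

    def test_far_away_or_other_contig_novel(self):
        assert classify_novel(self._locus(8_000), self._regions()) is True
        assert classify_novel(self._locus(5_200, "c2"), self._regions()) is True


class TestAssembleInsertion:
    def test_error_free_tiling_reconstructs_sequence(self):
        rng = np.random.default_rng(4)
        truth = random_dna(rng, 300)
        reads = [truth[i : i + 80] for i in range(0, 221, 20)]
        contigs = assemble_insertion(reads)
        assert contigs[0][0] == truth
        assert contigs[0][1] is False

    def test_two_loci_give_two_contigs(self):
        rng = np.random.default_rng(5)
        a, b = random_dna(rng, 200), random_dna(rng, 200)
        reads = ([a[i : i + 80] for i in range(0, 121, 40)]
                 + [b[i : i + 80] for i in range(0, 121, 40)])
        contigs = assemble_insertion(reads)
        assert sorted(c for c, _f in contigs) == sorted([a, b])

    def test_lonely_read_flagged_fragmentary(self):
        rng = np.random.default_rng(6)
        frag = random_dna(rng, 90)
        tiling = random_dna(rng, 200)
        reads = [tiling[i : i + 80] for i in range(0, 121, 30)] + [frag]
        contigs = dict(assemble_insertion(reads))
        assert contigs[frag] is True

    def test_too_few_reads_rejected(self):
        with pytest.raises(ValueError):
            assemble_insertion(["ACGT" * 20] * 4)


class TestFinalizeNovel:
    def _locus(self, pos, r1, r2, length, n_datasets, contig="c"):
        locus = InsertionLocus(f"c:{pos}", contig, pos, [])
        locus.numt_seq = "A" * length
        locus.n_datasets_present = n_datasets
        locus.per_sample = {
            "s1": GenotypeCall(r1=r1, r2=r2, genotype=None, depth_ok=True,
                               d=20.0, md=37.9)
        }
        return locus

    def test_each_rejection_reason(self):
        survivors = finalize_novel([
            self._locus(1000, r1=0.5, r2=0.9, length=100, n_datasets=2),
            self._locus(3000, r1=1.0, r2=0.1, length=100, n_datasets=2),
            self._locus(5000, r1=1.0, r2=0.9, length=20, n_datasets=2),
            self._locus(7000, r1=1.0, r2=0.9, length=100, n_datasets=1),
            self._locus(9000, r1=1.0, r2=0.9, length=100, n_datasets=2),
        ])
        assert [l.position for l in survivors] == [9000]
        assert survivors[0].region_id == "c_REGION_1"

    def test_pool_r2_waived(self):
        locus = self._locus(1000, r1=1.0, r2=0.05, length=100, n_datasets=2)
        assert finalize_novel([locus], pool_ids={"s1"}) == [locus]
        locus2 = self._locus(1000, r1=1.0, r2=0.05, length=100, n_datasets=2)
        assert finalize_novel([locus2]) == []

    def test_region_ids_continue_per_contig_ordinals(self):
        known = build_regions([
            NumtHit("g", "c", 100_000, 100_400, 0, 400, "+", 400, 1.0, 400)
        ])
        locus = self._locus(1000, r1=1.0, r2=0.9, length=100, n_datasets=2)
        (out,) = finalize_novel([locus], known_regions=known)
        assert out.region_id == "c_REGION_2"


@pytest.fixture(scope="module")
def cascade(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("cascade")
    paths, reference, mt, design = build_cascade_fixture(tmp)
    samples = [SampleAlignment(paths[s], s) for s in sorted(paths)]
    accepted, loci = call_insertions(samples, mt)
    return paths, mt, design, accepted, loci


class TestCascadeFixture:
    """The engineered two-sample SAM fixture drives the whole cascade."""

    def test_exactly_designed_survivors(self, cascade):
        _paths, _mt, design, accepted, _loci = cascade
        assert sorted(l.position for l in accepted) == [
            design.SURVIVOR_A, design.SURVIVOR_B
        ]

    def test_rejection_reasons_match_design(self, cascade):
        _paths, _mt, design, _accepted, loci = cascade
        by_pos = {l.position: l for l in loci}
        for pos, reason in design.expected_rejections.items():
            assert by_pos[pos].rejection == reason, (pos, by_pos[pos])
        for pos in design.expected_missing:
            assert pos not in by_pos

    def test_r1_r2_equal_brute_force_counts(self, cascade):
        paths, mt, design, _accepted, loci = cascade
        from numt_atlas.mito_align import circularize, local_align

        def mt_matched(clip):
            hits = local_align(clip, circularize(mt), min_score=10,
                               exact_dp_cells=2_000_000)
            if not hits:
                return False
            best = max(hits, key=lambda h: h.score)
            from numt_atlas.mito_align import karlin_evalue
            ev = karlin_evalue(best.score, len(clip), len(mt))
            return best.identity > 0.75 and ev < 1e-4

        by_pos = {l.position: l for l in loci}
        for pos in (design.R2_FAIL, design.SURVIVOR_A, design.SURVIVOR_B):
            locus = by_pos[pos]
            for sid, path in paths.items():
                call = locus.per_sample[sid]
                r1, r2 = brute_force_r1_r2(path, "ref", pos, mt_matched)
                if call.r1 is not None or r1 is not None:
                    assert call.r1 == pytest.approx(r1)
                if call.r2 is not None:
                    assert call.r2 == pytest.approx(r2)
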