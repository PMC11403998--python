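"""Hand-designed SAM fixtures for the soft-clip filter cascade.

``build_cascade_fixture`` constructs two WGS datasets over one reference
contig with candidate insertion sites engineered to trip each rejection
rule exactly once, plus two designed survivors.  Every quantity (support,
R1, R2, depth, putative length, dataset count) is enumerable by hand, so
the caller can compare the pipeline against brute-force counts.
"""

from __future__ import annotations

import numpy as np

from conftest import random_dna

READ_LEN = 100
BASELINE_STEP = 5  # tiling step -> baseline depth = READ_LEN / 5 = 20x


def _rec(name, flag, contig, pos0, cigar, seq):
    return (f"{name}\t{flag}\t{contig}\t{pos0 + 1}\t60\t{cigar}\t*\t0\t0\t"
            f"{seq}\t{'I' * len(seq)}")


class CascadeDesign:
    """Positions and expected outcomes of the engineered loci."""

    SUPPORT_FAIL = 5_000        # 2 clipped reads: never becomes a breakpoint
    R1_FAIL = 7_000             # clips do not match mtDNA
    DEPTH_FAIL = 9_000          # window depth above MD = d + 4 sqrt(d)
    R2_FAIL = 11_000            # clipped fraction far below 0.30
    LENGTH_FAIL = 13_000        # putative sequence of 20 bp (< 30)
    SINGLE_DATASET = 15_000     # good locus present in one dataset only
    SURVIVOR_A = 20_000
    SURVIVOR_B = 25_000

    expected_accepted = ("SURVIVOR_A", "SURVIVOR_B")
    expected_rejections = {
        R1_FAIL: "r1",
        R2_FAIL: "r2",
        LENGTH_FAIL: "length",
        SINGLE_DATASET: "datasets",
    }
    expected_missing = (SUPPORT_FAIL, DEPTH_FAIL)


def build_cascade_fixture(tmp_path):
    """Write sA.sam / sB.sam and return (paths, reference, mt, design)."""
    rng = np.random.default_rng(42)
    ref_len = 40_000
    reference = random_dna(rng, ref_len, gc=0.42)
    mt = random_dna(rng, 2_000)
    d = CascadeDesign

    def clip_reads(sample, pos, n, clip_seq, side, start_name):
        """n reads clipped at pos; anchor is perfect reference sequence."""
        out = []
        for i in range(n):
            name = f"{sample}:{start_name}:{i}"
            if side == "right":
                anchor = reference[pos - 60 : pos]
                cigar = f"60M{len(clip_seq)}S"
                out.append(_rec(name, 0, "ref", pos - 60, cigar,
                                anchor + clip_seq))
            else:
                anchor = reference[pos : pos + 60]
                cigar = f"{len(clip_seq)}S60M"
                out.append(_rec(name, 0, "ref", pos, cigar,
                                clip_seq + anchor))
        return out

    def spanning_reads(sample, pos, n, start_name):
        out = []
        for i in range(n):
            s = pos - 50
            out.append(_rec(f"{sample}:{start_name}:{i}", 0, "ref", s,
                            f"{READ_LEN}M", reference[s : s + READ_LEN]))
        return out

    # clip payloads
    good_left = mt[800:840]     # right-side clip: insertion prefix
    good_right = mt[920:960]    # left-side clip: insertion suffix
    surv_b_clip = mt[1200:1240]
    short_clip = mt[500:520]    # 20 bp -> putative NUMT below 30 bp
    junk = random_dna(np.random.default_rng(7), 40)

    samples = {"sA": [], "sB": []}
    for sample, lines in samples.items():
        # uniform baseline coverage
        for k, s in enumerate(range(0, ref_len - READ_LEN + 1, BASELINE_STEP)):
            lines.append(_rec(f"{sample}:base:{k}", 0, "ref", s,
                              f"{READ_LEN}M", reference[s : s + READ_LEN]))
        # support-fail: only two clipped reads
        lines += clip_reads(sample, d.SUPPORT_FAIL, 2, good_left, "right", "sup")
        # R1-fail: five clips of non-mitochondrial sequence
        lines += clip_reads(sample, d.R1_FAIL, 5, junk, "right", "r1")
        # depth-fail: good clips drowned in excess coverage
        lines += clip_reads(sample, d.DEPTH_FAIL, 5, good_left, "right", "dep")
        lines += spanning_reads(sample, d.DEPTH_FAIL, 120, "depx")
        # R2-fail: five good clips + 45 extra spanning reads
        lines += clip_reads(sample, d.R2_FAIL, 5, good_left, "right", "r2")
        lines += spanning_reads(sample, d.R2_FAIL, 45, "r2x")
        # length-fail: ten clips containing a 20-bp mt segment
        lines += clip_reads(sample, d.LENGTH_FAIL, 10, short_clip, "right",
                            "len")
        # survivors: both junction sides, both samples
        lines += clip_reads(sample, d.SURVIVOR_A, 6, good_left, "right", "svL")
        lines += clip_reads(sample, d.SURVIVOR_A, 6, good_right, "left", "svR")
        lines += clip_reads(sample, d.SURVIVOR_B, 10, surv_b_clip, "right",
                            "svB")
    # single-dataset locus: sA only
    samples["sA"] += clip_reads("sA", d.SINGLE_DATASET, 10, good_left,
                                "right", "one")

    header = ["@HD\tVN:1.6\tSO:unsorted", f"@SQ\tSN:ref\tLN:{ref_len}"]
    paths = {}
    for sample, lines in samples.items():
        p = tmp_path / f"{sample}.sam"
        p.write_text("\n".join(header + lines) + "\n")
        paths[sample] = p
    return paths, reference, mt, d


def brute_force_r1_r2(sam_path, contig, pos, mt_matched, min_clip_len=7):
    """Independent R1/R2 recount straight off the SAM text."""
    eligible = matched = clipped_at = overlapping = 0
    seen = set()
    for line in open(sam_path):
        if line.startswith("@"):
            continue
        f = line.split("\t")
        if f[2] != contig or int(f[1]) & 0x4:
            continue
        key = (f[0], f[1])
        if key in seen:
            continue
        seen.add(key)
        start = int(f[3]) - 1
        cigar = f[5]
        ops, n = [], ""
        for ch in cigar:
            if ch.isdigit():
                n += ch
            else:
                ops.append((int(n), ch))
                n = ""
        m_len = sum(k for k, op in ops if op == "M")
        end = start + m_len
        left = ops[0][0] if ops[0][1] == "S" else 0
        right = ops[-1][0] if ops[-1][1] == "S" else 0
        seq = f[9]
        lclip = seq[:left]
        rclip = seq[len(seq) - right:] if right else ""
        is_clipped_at = (left and start == pos) or (right and end == pos)
        if start <= pos <= end or is_clipped_at:
            overlapping += 1
            if is_clipped_at:
                clipped_at += 1
        if left >= min_clip_len and start == pos:
            eligible += 1
            matched += mt_matched(lclip)
        if right >= min_clip_len and end == pos:
            eligible += 1
            matched += mt_matched(rclip)
    r1 = matched / eligible if eligible else None
    r2 = clipped_at / overlapping if overlapping else None
    return r1, r2
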