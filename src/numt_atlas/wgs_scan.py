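"""Non-reference NUMT detection from soft-clipped reads in SAM alignments.

Filter cascade, applied to candidate insertion loci:

1. a breakpoint needs >= 3 soft-clipped reads (clips >= 7 nt);
2. mean depth in a +-200 bp window must lie in [6, d + 4*sqrt(d)] where d is
   the sample's average depth (copy-number / collapsed-repeat guard);
3. breakpoints within 100 bp across samples are grouped into one locus;
4. clipped bases must align to the circularised mtDNA with identity > 0.75
   and E-value < 1e-4; surviving mtDNA intervals are union-merged and
   concatenated into the putative NUMT sequence;
5. R1 (fraction of >= 7 nt clips that match mtDNA) must reach 0.75 at some
   breakpoint in some sample; R2 (fraction of breakpoint-overlapping reads
   that are clipped) genotypes each sample -- > 0.80 homozygous insertion,
   [0.30, 0.80] heterozygous, < 0.30 absent -- and must reach 0.30 somewhere
   unless the sample is a pool;
6. the putative sequence must be >= 30 bp and the locus present in >= 2
   datasets to be accepted as a novel NUMT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam
from scipy.stats import trim_mean

from .config import ScoringScheme, Thresholds
from ._seq import revcomp
from .mito_align import circularize, karlin_evalue, local_align, normalize_circular_hits

__all__ = [
    "SampleAlignment",
    "Breakpoint",
    "ClipMatch",
    "GenotypeCall",
    "InsertionLocus",
    "detect_breakpoints",
    "match_clips",
    "depth_filter",
    "group_loci",
    "genotype_locus",
    "classify_novel",
    "assemble_insertion",
    "finalize_novel",
    "call_insertions",
]


@dataclass
class _Read:
    name: str
    flag: int
    contig: str
    start: int
    end: int
    left_clip: str
    right_clip: str
    seq: str


class SampleAlignment:
    """One WGS dataset: parsed SAM, per-contig depth, mean-depth estimate."""

    def __init__(self, sam_path, sample_id: str, is_pool: bool = False,
                 seed: int = 0):
        self.sample_id = sample_id
        self.is_pool = is_pool
        self.reads: list[_Read] = []
        self.contig_lengths: dict[str, int] = {}
        seen: set[tuple[str, int]] = set()
        with pysam.AlignmentFile(str(sam_path), "r", check_sq=True) as fh:
            if not fh.header.get("SQ"):
                raise ValueError("SAM header lacks @SQ lines")
            for sq in fh.header["SQ"]:
                self.contig_lengths[sq["SN"]] = sq["LN"]
            for rec in fh:
                if rec.is_unmapped:
                    continue
                key = (rec.query_name, rec.flag)
                if key in seen:  # duplicate guard: one record per (name, flag)
                    continue
                seen.add(key)
                left = right = ""
                ct = rec.cigartuples or []
                if ct and ct[0][0] == 4:
                    left = rec.query_sequence[: ct[0][1]]
                if ct and ct[-1][0] == 4:
                    right = rec.query_sequence[len(rec.query_sequence) - ct[-1][1]:]
                self.reads.append(
                    _Read(
                        name=rec.query_name,
                        flag=rec.flag,
                        contig=rec.reference_name,
                        start=rec.reference_start,
                        end=rec.reference_end,
                        left_clip=left,
                        right_clip=right,
                        seq=rec.query_sequence,
                    )
                )
        self.depth: dict[str, np.ndarray] = {
            c: np.zeros(l + 1, dtype=np.int32)
            for c, l in self.contig_lengths.items()
        }
        for r in self.reads:
            self.depth[r.contig][r.start] += 1
            self.depth[r.contig][r.end] -= 1
        for c in self.depth:
            self.depth[c] = np.cumsum(self.depth[c])[:-1]
        self._seed = seed
        self._arr_cache: dict[str, tuple] = {}

    def _arrays(self, contig: str):
        """Per-contig numpy views over reads for fast interval counting."""
        if contig not in self._arr_cache:
            idx = [i for i, r in enumerate(self.reads) if r.contig == contig]
            self._arr_cache[contig] = (
                idx,
                np.array([self.reads[i].start for i in idx], dtype=np.int64),
                np.array([self.reads[i].end for i in idx], dtype=np.int64),
                np.array([len(self.reads[i].left_clip) for i in idx],
                         dtype=np.int32),
                np.array([len(self.reads[i].right_clip) for i in idx],
                         dtype=np.int32),
            )
        return self._arr_cache[contig]

    def mean_depth(self, n_windows: int = 1000, window: int = 1000) -> float:
        """Trimmed mean depth over random windows (10% trimmed each side)."""
        rng = np.random.default_rng(self._seed)
        vals = []
        for contig, arr in sorted(self.depth.items()):
            if len(arr) < window:
                vals.append(arr.mean())
                continue
            n = min(n_windows, max(1, len(arr) // window))
            starts = rng.integers(0, len(arr) - window, size=n)
            for s in starts:
                vals.append(arr[s : s + window].mean())
        if not vals:
            return 0.0
        return float(trim_mean(np.array(vals), 0.1))


@dataclass
class Breakpoint:
    contig: str
    position: int
    clip_side: str  # "left": clipped bases precede the alignment start
    n_clip_reads: int
    sample_id: str
    clips: list[tuple[str, str]] = field(default_factory=list)  # (read, seq)
    depth_ok: bool | None = None


@dataclass(frozen=True)
class ClipMatch:
    read_id: str
    clip_seq: str
    mt_start: int
    mt_end: int
    identity: float
    e_value: float


@dataclass
class GenotypeCall:
    r1: float | None
    r2: float | None
    genotype: str | None  # hom_ins / het / absent / carrier / non_carrier
    depth_ok: bool
    d: float
    md: float


@dataclass
class InsertionLocus:
    locus_id: str
    contig: str
    position: int
    breakpoints: list[Breakpoint]
    numt_seq: str = ""
    mt_intervals: list[tuple[int, int]] = field(default_factory=list)
    novel: bool | None = None
    per_sample: dict[str, GenotypeCall] = field(default_factory=dict)
    n_datasets_present: int = 0
    region_id: str | None = None
    rejection: str | None = None

    @property
    def length(self) -> int:
        return len(self.numt_seq)


# ---------------------------------------------------------------------------
# breakpoints
# ---------------------------------------------------------------------------

def detect_breakpoints(
    sample: SampleAlignment,
    min_support: int = 3,
    min_clip_len: int = 7,
) -> list[Breakpoint]:
    """Soft-clip pileups with >= ``min_support`` clipped reads.

    Left clips mark the alignment start, right clips the alignment end; one
    breakpoint is emitted per (contig, position, side).
    """
    piles: dict[tuple[str, int, str], list[tuple[str, str]]] = {}
    for r in sample.reads:
        if len(r.left_clip) >= min_clip_len:
            piles.setdefault((r.contig, r.start, "left"), []).append(
                (r.name, r.left_clip)
            )
        if len(r.right_clip) >= min_clip_len:
            piles.setdefault((r.contig, r.end, "right"), []).append(
                (r.name, r.right_clip)
            )
    out = []
    for (contig, pos, side), clips in sorted(piles.items()):
        if len(clips) < min_support:
            continue
        out.append(
            Breakpoint(
                contig=contig,
                position=pos,
                clip_side=side,
                n_clip_reads=len(clips),
                sample_id=sample.sample_id,
                clips=clips,
            )
        )
    return out


# ---------------------------------------------------------------------------
# clip-to-mtDNA matching
# ---------------------------------------------------------------------------

def match_clips(
    clips: list[tuple[str, str]],
    mt_seq: str,
    scoring: ScoringScheme | None = None,
    min_identity: float = 0.75,
    max_evalue: float = 1e-4,
    karlin_k: float = 0.1,
) -> tuple[list[ClipMatch], str]:
    """Align clipped sequences to circular mtDNA; return survivors + sequence.

    Identity must be strictly greater than ``min_identity`` and E-value
    strictly below ``max_evalue``.  Surviving mtDNA intervals are
    union-merged and their sequence concatenated (the putative NUMT).
    """
    sc = scoring or ScoringScheme()
    mt_len = len(mt_seq)
    circ = circularize(mt_seq)
    matches: list[ClipMatch] = []
    cache: dict[str, ClipMatch | None] = {}
    seed_k = 11
    for read_id, clip in clips:
        norm = clip.upper()
        if len(norm) < seed_k:
            # too short to reach the E-value bar (score >= ~16 needed)
            continue
        if norm in cache:
            hit = cache[norm]
        else:
            hits = local_align(norm, circ, sc, seed_k=seed_k, min_score=10,
                               target_contig="mt", exact_dp_cells=0)
            hit = None
            if hits:
                best = max(hits, key=lambda h: h.score)
                ev = karlin_evalue(best.score, len(norm), mt_len, sc, karlin_k)
                if best.identity > min_identity and ev < max_evalue:
                    ts, te = best.target_start, best.target_end
                    if ts >= mt_len:
                        ts, te = ts - mt_len, te - mt_len
                    hit = ClipMatch(
                        read_id="", clip_seq=norm, mt_start=ts, mt_end=te,
                        identity=best.identity, e_value=ev,
                    )
            cache[norm] = hit
        if hit is not None:
            matches.append(
                ClipMatch(read_id, hit.clip_seq, hit.mt_start, hit.mt_end,
                          hit.identity, hit.e_value)
            )
    intervals = _union([(m.mt_start, m.mt_end) for m in matches])
    doubled = circ
    seq = "".join(doubled[s:e] for s, e in intervals)
    return matches, seq


def _union(intervals):
    merged = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


# ---------------------------------------------------------------------------
# depth filter
# ---------------------------------------------------------------------------

def depth_filter(
    breakpoint: Breakpoint,
    depth: np.ndarray,
    d: float,
    window: int = 200,
    low: float = 6.0,
) -> bool:
    """True when mean depth around the breakpoint is within [low, d+4*sqrt(d)].

    Both bounds are inclusive; MD = d + 4*sqrt(d) guards against collapsed
    repeats and copy-number gains that mimic insertion breakpoints.
    """
    if d <= 0:
        raise ValueError("sample mean depth must be positive")
    md = d + 4.0 * np.sqrt(d)
    s = max(0, breakpoint.position - window)
    e = min(len(depth), breakpoint.position + window)
    mean = float(depth[s:e].mean()) if e > s else 0.0
    return bool(low <= mean <= md)


# ---------------------------------------------------------------------------
# locus grouping and genotyping
# ---------------------------------------------------------------------------

def group_loci(
    breakpoints: list[Breakpoint],
    window: int = 100,
) -> list[InsertionLocus]:
    """Single-linkage grouping of breakpoints <= ``window`` bp apart."""
    by_contig: dict[str, list[Breakpoint]] = {}
    for b in breakpoints:
        by_contig.setdefault(b.contig, []).append(b)
    loci = []
    for contig, group in sorted(by_contig.items()):
        group = sorted(group, key=lambda b: b.position)
        cluster = [group[0]]
        clusters = [cluster]
        for b in group[1:]:
            if b.position - cluster[-1].position <= window:
                cluster.append(b)
            else:
                cluster = [b]
                clusters.append(cluster)
        for members in clusters:
            pos = int(np.median([b.position for b in members]))
            loci.append(
                InsertionLocus(
                    locus_id=f"{contig}:{pos}",
                    contig=contig,
                    position=pos,
                    breakpoints=members,
                )
            )
    return loci


def genotype_locus(
    locus: InsertionLocus,
    sample: SampleAlignment,
    mt_matched: dict[str, bool],
    min_clip_len: int = 7,
    r2_absent: float = 0.30,
    r2_hom: float = 0.80,
    depth_ok: bool = True,
    d: float = 0.0,
) -> GenotypeCall:
    """R1/R2 ratios and genotype for one sample at one locus.

    R1 and R2 are taken as the maximum over the locus's breakpoints present
    in this sample.  Pools are genotyped carrier / non-carrier only.
    """
    positions = sorted({
        b.position for b in locus.breakpoints
    })
    best_r1 = None
    best_r2 = None
    idx, starts, ends, lclip, rclip = sample._arrays(locus.contig)
    for pos in positions:
        lc = (starts == pos) & (lclip >= 1)
        rc = (ends == pos) & (rclip >= 1)
        clipped_mask = lc | rc
        overlap_mask = ((starts <= pos) & (ends >= pos)) | clipped_mask
        overlapping = int(overlap_mask.sum())
        clipped_at = int(clipped_mask.sum())
        eligible = []
        for i in np.nonzero((starts == pos) & (lclip >= min_clip_len))[0]:
            r = sample.reads[idx[i]]
            eligible.append((r.name, r.left_clip))
        for i in np.nonzero((ends == pos) & (rclip >= min_clip_len))[0]:
            r = sample.reads[idx[i]]
            eligible.append((r.name, r.right_clip))
        if eligible:
            matched = sum(
                1 for _name, clip in eligible
                if mt_matched.get(clip.upper(), False)
            )
            r1 = matched / len(eligible)
            best_r1 = r1 if best_r1 is None else max(best_r1, r1)
        if overlapping:
            r2 = clipped_at / overlapping
            best_r2 = r2 if best_r2 is None else max(best_r2, r2)
    genotype = None
    if sample.is_pool:
        if best_r2 is not None or best_r1 is not None:
            carrier = any(
                b.sample_id == sample.sample_id for b in locus.breakpoints
            )
            genotype = "carrier" if carrier else "non_carrier"
    elif best_r2 is not None:
        if best_r2 > r2_hom:
            genotype = "hom_ins"
        elif best_r2 >= r2_absent:
            genotype = "het"
        else:
            genotype = "absent"
    md = d + 4.0 * np.sqrt(d) if d > 0 else float("nan")
    return GenotypeCall(r1=best_r1, r2=best_r2, genotype=genotype,
                        depth_ok=depth_ok, d=d, md=md)


def classify_novel(locus: InsertionLocus, known_regions, slop: int = 100) -> bool:
    """Novel iff the locus position misses every known region span +- slop."""
    for r in known_regions:
        if r.contig != locus.contig:
            continue
        if r.start - slop <= locus.position < r.end + slop:
            return False
    return True


# ---------------------------------------------------------------------------
# insertion assembly (greedy overlap-layout-consensus)
# ---------------------------------------------------------------------------

def _best_overlap(a: str, b: str, min_overlap: int, min_identity: float):
    """Longest suffix(a)/prefix(b) overlap passing the identity bar."""
    max_o = min(len(a), len(b))
    for o in range(max_o, min_overlap - 1, -1):
        sa, pb = a[-o:], b[:o]
        mism = sum(x != y for x, y in zip(sa, pb))
        if mism <= (1 - min_identity) * o:
            return o
    return 0


def assemble_insertion(
    reads: list[str],
    min_overlap: int = 20,
    min_identity: float = 0.90,
    min_reads: int = 5,
) -> list[tuple[str, bool]]:
    """Greedy overlap-layout-consensus of clip/discordant read sequences.

    Returns (contig, fragmentary) pairs; fragmentary means the contig is a
    single read that overlapped nothing.  Raises when fewer than
    ``min_reads`` sequences are supplied.
    """
    if len(reads) < min_reads:
        raise ValueError(f"need >= {min_reads} reads to assemble")
    seqs = sorted({r.upper() for r in reads}, key=lambda s: (-len(s), s))
    support: dict[str, int] = {}
    kept: list[str] = []
    for s in seqs:  # absorb exact substrings into their container
        host = next((t for t in kept if s in t), None)
        if host is None:
            kept.append(s)
            support[s] = 1
        else:
            support[host] += 1
    seqs = kept
    while True:
        best = (0, None, None)
        for i, a in enumerate(seqs):
            for j, b in enumerate(seqs):
                if i == j:
                    continue
                o = _best_overlap(a, b, min_overlap, min_identity)
                if o > best[0]:
                    best = (o, i, j)
        o, i, j = best
        if o == 0:
            break
        a, b = seqs[i], seqs[j]
        new = a + b[o:]
        support[new] = support.pop(a) + support.pop(b)
        seqs = [s for k, s in enumerate(seqs) if k not in (i, j)]
        seqs.append(new)
        seqs.sort(key=lambda s: (-len(s), s))
    return [(s, support[s] <= 1) for s in seqs]


# ---------------------------------------------------------------------------
# final filter cascade
# ---------------------------------------------------------------------------

def finalize_novel(
    loci: list[InsertionLocus],
    known_regions=(),
    thresholds: Thresholds | None = None,
    pool_ids: set[str] | frozenset = frozenset(),
) -> list[InsertionLocus]:
    """Apply the acceptance rules and assign region ids to survivors.

    A locus is rejected when every breakpoint in every sample has
    R1 < 0.75, or every non-pool sample has R2 < 0.30, or the putative
    sequence is shorter than 30 bp, or it is present in fewer than two
    datasets.  Survivors continue the per-contig region ordinals.
    """
    t = thresholds or Thresholds()
    next_ordinal: dict[str, int] = {}
    for r in known_regions:
        k = int(r.region_id.rsplit("_", 1)[1])
        next_ordinal[r.contig] = max(next_ordinal.get(r.contig, 0), k)
    accepted = []
    for locus in sorted(loci, key=lambda l: (l.contig, l.position)):
        calls = locus.per_sample
        r1s = [c.r1 for c in calls.values() if c.r1 is not None]
        if not r1s or all(r1 < t.r1_min for r1 in r1s):
            locus.rejection = "r1"
            continue
        non_pool_r2 = [
            c.r2 for sid, c in calls.items()
            if sid not in pool_ids and c.r2 is not None
        ]
        if non_pool_r2 and all(r2 < t.r2_absent for r2 in non_pool_r2):
            locus.rejection = "r2"
            continue
        if locus.length < t.min_length:
            locus.rejection = "length"
            continue
        if locus.n_datasets_present < t.min_datasets:
            locus.rejection = "datasets"
            continue
        n = next_ordinal.get(locus.contig, 0) + 1
        next_ordinal[locus.contig] = n
        locus.region_id = f"{locus.contig}_REGION_{n}"
        accepted.append(locus)
    return accepted


def call_insertions(
    samples: list[SampleAlignment],
    mt_seq: str,
    known_regions=(),
    thresholds: Thresholds | None = None,
    scoring: ScoringScheme | None = None,
    karlin_k: float = 0.1,
) -> tuple[list[InsertionLocus], list[InsertionLocus]]:
    """Full WGS cascade over several datasets.

    Returns (accepted_novel, all_loci); the second element keeps rejected
    loci with their rejection reason for inspection.
    """
    t = thresholds or Thresholds()
    sc = scoring or ScoringScheme()
    depths = {s.sample_id: s.mean_depth() for s in samples}
    all_bps: list[Breakpoint] = []
    for s in samples:
        bps = detect_breakpoints(s, t.clip_support, t.clip_length)
        for b in bps:
            b.depth_ok = depth_filter(
                b, s.depth[b.contig], depths[s.sample_id],
                t.depth_window, t.depth_min,
            )
        all_bps.extend(b for b in bps if b.depth_ok)
    loci = group_loci(all_bps, t.group_window)
    sample_map = {s.sample_id: s for s in samples}
    pool_ids = {s.sample_id for s in samples if s.is_pool}
    for locus in loci:
        clips = [c for b in locus.breakpoints for c in b.clips]
        matches, seq = match_clips(
            clips, mt_seq, sc, t.clip_identity, t.clip_evalue, karlin_k
        )
        matched_set = {m.clip_seq for m in matches}
        mt_matched = {c[1].upper(): c[1].upper() in matched_set for c in clips}
        locus.numt_seq = seq
        locus.mt_intervals = _union(
            [(m.mt_start, m.mt_end) for m in matches]
        )
        for sid, s in sorted(sample_map.items()):
            locus.per_sample[sid] = genotype_locus(
                locus, s, mt_matched, t.clip_length,
                t.r2_absent, t.r2_hom, True, depths[sid],
            )
        locus.n_datasets_present = len({
            b.sample_id for b in locus.breakpoints
        })
        locus.novel = classify_novel(locus, known_regions, t.group_window)
    novel = [l for l in loci if l.novel]
    accepted = finalize_novel(novel, known_regions, t, pool_ids)
    return accepted, loci
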