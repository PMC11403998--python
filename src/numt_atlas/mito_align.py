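"""Consensus mtDNA, circularisation and local alignment of mtDNA to nuclear
sequence.

The aligner reports every local alignment reaching the configured score
threshold under the distant-homology scheme (+1 match, -1 mismatch, affine
gaps 7 + 1/base).  Two execution paths share one scoring engine:

* small problems (``len(query) * len(target) <= exact_dp_cells``) run a full
  affine local dynamic program and peel off non-overlapping alignments in
  score order, so the best hit is guaranteed optimal;
* genome-scale problems seed with exact k-mers, chain seeds into candidate
  regions, and rescore each region with the same dynamic program on a
  padded window (an X-drop-bounded extension).

``N`` bases never seed and score as mismatches during extension.  The score
threshold itself can be calibrated from alignments of the *reversed*
(not complemented) mtDNA, which cannot be homologous and therefore bound
the spurious score distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy.optimize import brentq

from ._seq import revcomp

__all__ = [
    "ScoringScheme",
    "AlignmentHit",
    "build_consensus",
    "circularize",
    "normalize_circular_hits",
    "local_align",
    "smith_waterman_score",
    "calibrate_score_threshold",
    "mask_low_complexity",
    "low_complexity_mask",
    "karlin_lambda",
    "karlin_evalue",
]

from .config import ScoringScheme

# encoding that tolerates N (code 4, never matches anything)
_CODE_N = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("AGCTN"):
    _CODE_N[ord(_b)] = _i
    _CODE_N[ord(_b.lower())] = _i


def _encode_n(seq: str) -> np.ndarray:
    arr = _CODE_N[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("sequence contains characters outside {A,C,G,T,N}")
    return arr


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment of (circularised) mtDNA against nuclear sequence.

    Intervals are 0-based half-open; ``query_*`` refer to the mtDNA query in
    its own forward orientation, ``strand`` tells which genome strand the
    mtDNA matched.  ``identity`` counts gap columns as non-identical.
    """

    target_contig: str
    target_start: int
    target_end: int
    query_start: int
    query_end: int
    strand: str
    score: int
    identity: float
    aligned_length: int


# ---------------------------------------------------------------------------
# consensus / circularisation
# ---------------------------------------------------------------------------

def build_consensus(aligned: list[str]) -> str:
    """Plurality consensus of equal-length gapped sequences.

    A column is dropped when the gap character outnumbers every base; base
    ties break alphabetically (A < C < G < T).
    """
    if len(aligned) < 2:
        raise ValueError("need at least two sequences")
    lengths = {len(s) for s in aligned}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    mat = np.array([list(s.upper()) for s in aligned])
    out = []
    for col in mat.T:
        bases, counts = np.unique(col, return_counts=True)
        tally = dict(zip(bases.tolist(), counts.tolist()))
        gap = tally.pop("-", 0)
        if not tally:
            continue
        best = max(tally.values())
        if gap > best:
            continue
        out.append(min(b for b, c in tally.items() if c == best))
    return "".join(out)


def circularize(seq: str) -> str:
    """Concatenate two copies so alignments may span the circular origin."""
    if not seq:
        raise ValueError("empty sequence")
    return seq + seq


def normalize_circular_hits(hits: list[AlignmentHit], length: int) -> list[AlignmentHit]:
    """Map hits on a doubled sequence back to [0, L) and drop duplicates.

    Hits starting in the second copy are shifted by -L; a hit that starts
    before L and ends after it spans the circular junction and keeps its
    raw end (end may exceed L, meaning wraparound).  A hit whose target
    interval is essentially contained (>= 90%) in a stronger hit's target
    interval is a doubled-query artifact of the same genomic copy and is
    dropped.
    """
    seen = set()
    out = []
    for h in sorted(hits, key=lambda h: (-h.score, h.target_start)):
        qs, qe = h.query_start, h.query_end
        if qs >= length:
            qs, qe = qs - length, qe - length
        key = (h.target_contig, h.target_start, h.target_end, qs, qe, h.strand)
        if key in seen:
            continue
        span = max(1, h.target_end - h.target_start)
        contained = any(
            k.target_contig == h.target_contig
            and (min(k.target_end, h.target_end)
                 - max(k.target_start, h.target_start)) >= 0.9 * span
            and (k.target_end - k.target_start) > span
            for k in out
        )
        if contained:
            continue
        seen.add(key)
        out.append(replace(h, query_start=qs, query_end=qe))
    return out


# ---------------------------------------------------------------------------
# affine local DP engine (Gotoh with traceback), numba-compiled
# ---------------------------------------------------------------------------

@njit(cache=True)
def _affine_local_dp(a, b, match, mismatch, gap_open, gap_ext):  # pragma: no cover
    n, m = len(a), len(b)
    NEG = -(10 ** 9)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in a (consumes b)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in b (consumes a)
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            sub = match if (ai == b[j - 1] and ai < 4) else -mismatch
            e = E[i, j - 1] - gap_ext
            e2 = H[i, j - 1] - gap_open - gap_ext
            E[i, j] = e if e > e2 else e2
            f = F[i - 1, j] - gap_ext
            f2 = H[i - 1, j] - gap_open - gap_ext
            F[i, j] = f if f > f2 else f2
            h = H[i - 1, j - 1] + sub
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best, bi, bj = h, i, j
    return H, E, F, best, bi, bj


@njit(cache=True)
def _traceback(a, b, H, E, F, bi, bj, match, mismatch, gap_open, gap_ext):  # pragma: no cover
    """Walk back from (bi, bj); returns (qs, qe, ts, te, ops).

    ops (alignment order): 0 match, 1 mismatch, 2 gap in a (consumes b),
    3 gap in b (consumes a).
    """
    i, j = bi, bj
    ops_rev = np.empty(bi + bj, dtype=np.int8)
    k = 0
    state = 0  # 0 = H, 1 = E (gap in a), 2 = F (gap in b)
    while i > 0 or j > 0:
        if state == 0:
            if H[i, j] == 0:
                break
            sub = match if (i > 0 and j > 0 and a[i - 1] == b[j - 1] and a[i - 1] < 4) else -mismatch
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + sub:
                if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                    ops_rev[k] = 0
                else:
                    ops_rev[k] = 1
                k += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            elif H[i, j] == F[i, j]:
                state = 2
            else:
                break
        elif state == 1:
            ops_rev[k] = 2
            k += 1
            if E[i, j] == H[i, j - 1] - gap_open - gap_ext:
                j -= 1
                state = 0
            else:
                j -= 1
        else:
            ops_rev[k] = 3
            k += 1
            if F[i, j] == H[i - 1, j] - gap_open - gap_ext:
                i -= 1
                state = 0
            else:
                i -= 1
    return i, bi, j, bj, ops_rev[:k][::-1].copy()


def _op_scores(ops: np.ndarray, sc: ScoringScheme) -> np.ndarray:
    """Per-column score contributions (gap open charged on first gap column)."""
    contrib = np.empty(len(ops), dtype=np.int32)
    prev_gap = False
    for i, op in enumerate(ops):
        if op == 0:
            contrib[i] = sc.match
            prev_gap = False
        elif op == 1:
            contrib[i] = -sc.mismatch
            prev_gap = False
        else:
            contrib[i] = -sc.gap_extend - (0 if prev_gap else sc.gap_open)
            prev_gap = True
    return contrib


def _trim_weak_ends(ops: np.ndarray, sc: ScoringScheme,
                    max_frac: float = 1 / 3, max_cols: int = 30):
    """Trim terminal segments scoring at most half the perfect rate.

    The local-DP optimum happily extends through marginal flank segments
    (e.g. net +1 over nine columns of random flank); such ends inflate hit
    intervals past the true homology boundary.  From each end, the longest
    terminal segment (up to ``max_cols`` and a fraction of the alignment)
    whose net score is below half the perfect score for its length is
    removed.
    Returns (lo, hi): the retained column slice.
    """
    n = len(ops)
    contrib = _op_scores(ops, sc)
    limit = min(max_cols, int(n * max_frac))

    def cut(scores) -> int:
        # cut point minimising the terminal segment's excess over half rate
        best_k, best_excess, run = 0, 0, 0
        for k in range(1, limit + 1):
            run += scores[k - 1]
            excess = 2 * run - k * sc.match
            if excess < best_excess:
                best_k, best_excess = k, excess
        return best_k

    lo = cut(contrib)
    hi = n - cut(contrib[::-1])
    if hi <= lo:
        return 0, n
    return lo, hi


def _best_local(a: np.ndarray, b: np.ndarray, sc: ScoringScheme):
    """Optimal local alignment of encoded arrays; None when score is 0.

    The returned score is the DP optimum; the interval and identity refer
    to the weak-end-trimmed alignment (see _trim_weak_ends).
    """
    H, E, F, best, bi, bj = _affine_local_dp(
        a, b, sc.match, sc.mismatch, sc.gap_open, sc.gap_extend
    )
    if best <= 0:
        return None
    qs, qe, ts, te, ops = _traceback(
        a, b, H, E, F, bi, bj, sc.match, sc.mismatch, sc.gap_open, sc.gap_extend
    )
    lo, hi = _trim_weak_ends(ops, sc)
    if lo or hi < len(ops):
        head, core, tail = ops[:lo], ops[lo:hi], ops[hi:]
        qs += int((head == 0).sum() + (head == 1).sum() + (head == 3).sum())
        qe -= int((tail == 0).sum() + (tail == 1).sum() + (tail == 3).sum())
        ts += int((head == 0).sum() + (head == 1).sum() + (head == 2).sum())
        te -= int((tail == 0).sum() + (tail == 1).sum() + (tail == 2).sum())
        ops = core
    matches = int((ops == 0).sum())
    cols = len(ops)
    return int(best), int(qs), int(qe), int(ts), int(te), matches, cols


def smith_waterman_score(query: str, target: str, scoring: ScoringScheme) -> int:
    """Optimal affine local alignment score (exact DP, any input size)."""
    a, b = _encode_n(query.upper()), _encode_n(target.upper())
    if len(a) == 0 or len(b) == 0:
        return 0
    _, _, _, best, _, _ = _affine_local_dp(
        a, b, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    return int(best)


# ---------------------------------------------------------------------------
# seed / chain / extend
# ---------------------------------------------------------------------------

# reusing a target index across calls matters when many short queries hit
# the same target (clip-to-mtDNA matching); keyed by target text hash
_INDEX_CACHE: dict[tuple, dict] = {}


def _cached_kmer_index(target: str, codes: np.ndarray, k: int) -> dict:
    key = (hash(target), len(target), k)
    if key not in _INDEX_CACHE:
        if len(_INDEX_CACHE) > 8:
            _INDEX_CACHE.clear()
        _INDEX_CACHE[key] = _kmer_index(codes, k)
    return _INDEX_CACHE[key]


def _kmer_index(codes: np.ndarray, k: int) -> dict:
    index: dict[int, list[int]] = {}
    if len(codes) < k:
        return index
    valid = codes < 4
    val = 0
    run = 0
    mask = (1 << (2 * k)) - 1
    for i, c in enumerate(codes):
        if valid[i]:
            val = ((val << 2) | int(c)) & mask
            run += 1
        else:
            run = 0
            val = 0
        if run >= k:
            index.setdefault(val, []).append(i - k + 1)
    return index


def _seed_positions(q: np.ndarray, index: dict, k: int):
    seeds = []
    if len(q) < k:
        return seeds
    valid = q < 4
    val = 0
    run = 0
    mask = (1 << (2 * k)) - 1
    for i, c in enumerate(q):
        if valid[i]:
            val = ((val << 2) | int(c)) & mask
            run += 1
        else:
            run = 0
            val = 0
        if run >= k:
            qpos = i - k + 1
            for tpos in index.get(val, ()):
                seeds.append((qpos, tpos))
    return seeds


def _cluster_seeds(seeds, k: int, chain_gap: int = 100, diag_band: int = 50):
    """Chain seeds into candidate regions: same diagonal +- diag_band, close."""
    by_diag: dict[int, list[tuple[int, int]]] = {}
    for qpos, tpos in seeds:
        by_diag.setdefault((tpos - qpos) // diag_band, []).append((qpos, tpos))
    clusters = []
    for band in sorted(by_diag):
        pts = sorted(by_diag[band])
        cur = [pts[0]]
        for p in pts[1:]:
            if p[0] - cur[-1][0] <= chain_gap + k:
                cur.append(p)
            else:
                clusters.append(cur)
                cur = [p]
        clusters.append(cur)
    regions = []
    for cl in clusters:
        qs = min(p[0] for p in cl)
        qe = max(p[0] for p in cl) + k
        ts = min(p[1] for p in cl)
        te = max(p[1] for p in cl) + k
        regions.append((qs, qe, ts, te))
    return _merge_regions(regions)


def _merge_regions(regions, slop: int = 50):
    regions = sorted(regions)
    merged = []
    for r in regions:
        for i, m in enumerate(merged):
            if (r[0] <= m[1] + slop and r[1] >= m[0] - slop
                    and r[2] <= m[3] + slop and r[3] >= m[2] - slop):
                merged[i] = (min(m[0], r[0]), max(m[1], r[1]),
                             min(m[2], r[2]), max(m[3], r[3]))
                break
        else:
            merged.append(r)
    return merged


def _hit_from_alignment(res, q_off, t_off, q_len, strand, contig) -> AlignmentHit:
    best, qs, qe, ts, te, matches, cols = res
    qs += q_off
    qe += q_off
    ts += t_off
    te += t_off
    if strand == "-":
        qs, qe = q_len - qe, q_len - qs
    return AlignmentHit(
        target_contig=contig,
        target_start=ts,
        target_end=te,
        query_start=qs,
        query_end=qe,
        strand=strand,
        score=best,
        identity=matches / cols if cols else 0.0,
        aligned_length=cols,
    )


def _exact_hits(q, t, sc, min_score, strand, contig, q_len, max_hits=64):
    """Peel non-overlapping local alignments from a full DP, best first."""
    hits = []
    t_work = t.copy()
    for _ in range(max_hits):
        res = _best_local(q, t_work, sc)
        if res is None or res[0] < min_score:
            break
        hits.append(_hit_from_alignment(res, 0, 0, q_len, strand, contig))
        _, _, _, ts, te, _, _ = res
        t_work[ts:te] = 4  # mask as N so the region cannot re-align
        if te == ts:
            break
    return hits


def local_align(
    query: str,
    target: str,
    scoring: ScoringScheme | None = None,
    seed_k: int = 11,
    xdrop: int = 20,
    min_score: int | None = None,
    target_contig: str = "target",
    exact_dp_cells: int = 250_000,
    both_strands: bool = True,
) -> list[AlignmentHit]:
    """All local alignments of ``query`` to ``target`` scoring >= threshold.

    Searches both strands unless ``both_strands`` is False; hit multiplicity
    is unlimited.  Raises when ``seed_k`` exceeds either sequence length on
    the seeded path.
    """
    sc = scoring or ScoringScheme()
    if min_score is None:
        min_score = sc.min_score_threshold
    query = query.upper()
    target = target.upper()
    t_codes = _encode_n(target)
    exact = len(query) * len(target) <= exact_dp_cells
    if not exact and seed_k > min(len(query), len(target)):
        raise ValueError("seed_k exceeds sequence length")

    hits: list[AlignmentHit] = []
    strands = ("+", "-") if both_strands else ("+",)
    index = None if exact else _cached_kmer_index(target, t_codes, seed_k)
    for strand in strands:
        qseq = query if strand == "+" else revcomp(query)
        q_codes = _encode_n(qseq)
        if exact:
            hits.extend(
                _exact_hits(q_codes, t_codes, sc, min_score, strand,
                            target_contig, len(query))
            )
            continue
        seeds = _seed_positions(q_codes, index, seed_k)
        if not seeds:
            continue
        base_pad = xdrop + seed_k + 10
        for qs, qe, ts, te in _cluster_seeds(seeds, seed_k):
            # X-drop-style extension: rescore on a padded window, growing the
            # window while the optimal alignment presses against its border
            # (diverged copies extend far beyond any fixed pad)
            pad = base_pad
            res = None
            q0 = t0 = 0
            while True:
                q0, q1 = max(0, qs - pad), min(len(q_codes), qe + pad)
                t0, t1 = max(0, ts - pad), min(len(t_codes), te + pad)
                res = _best_local(q_codes[q0:q1], t_codes[t0:t1], sc)
                if res is None:
                    break
                _score, aqs, aqe, ats, ate, _m, _c = res
                edge = 3
                touches = (
                    (aqs <= edge and q0 > 0)
                    or (aqe >= (q1 - q0) - edge and q1 < len(q_codes))
                    or (ats <= edge and t0 > 0)
                    or (ate >= (t1 - t0) - edge and t1 < len(t_codes))
                )
                next_pad = pad * 4
                cells = (min(len(q_codes), qe - qs + 2 * next_pad)
                         * (te - ts + 2 * next_pad))
                if not touches or next_pad > 16_384 or cells > 3e7:
                    break
                pad = next_pad
            if res is None or res[0] < min_score:
                continue
            hits.append(
                _hit_from_alignment(res, q0, t0, len(query), strand, target_contig)
            )
    return _dedup_hits(hits)


def _overlap_frac(a0, a1, b0, b1) -> float:
    inter = min(a1, b1) - max(a0, b0)
    if inter <= 0:
        return 0.0
    return inter / max(1, min(a1 - a0, b1 - b0))


def _dedup_hits(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    kept: list[AlignmentHit] = []
    for h in sorted(hits, key=lambda h: (-h.score, h.target_start, h.query_start)):
        dup = any(
            k.strand == h.strand
            and k.target_contig == h.target_contig
            and _overlap_frac(k.target_start, k.target_end, h.target_start, h.target_end) > 0.5
            and _overlap_frac(k.query_start, k.query_end, h.query_start, h.query_end) > 0.5
            for k in kept
        )
        if not dup:
            kept.append(h)
    return sorted(kept, key=lambda h: (h.target_contig, h.target_start, h.query_start))


# ---------------------------------------------------------------------------
# score-threshold calibration by sequence reversal
# ---------------------------------------------------------------------------

def calibrate_score_threshold(
    mt_seq: str,
    genome: dict[str, str] | str,
    scoring: ScoringScheme | None = None,
    seed_k: int = 11,
    floor: int = 30,
) -> int:
    """Score threshold from spurious alignments of the reversed mtDNA.

    The mtDNA is reversed *without* complementation -- such matches cannot
    be homologous -- and aligned to the genome; the threshold is one more
    than the best spurious score, floored at the configured default so the
    pipeline never becomes more permissive than the published setting.
    """
    sc = scoring or ScoringScheme()
    if isinstance(genome, str):
        genome = {"genome": genome}
    reversed_mt = mt_seq[::-1]
    best = 0
    for contig, seq in genome.items():
        for h in local_align(
            reversed_mt, seq, sc, seed_k=seed_k, min_score=10,
            target_contig=contig,
        ):
            best = max(best, h.score)
    return max(best + 1, floor)


# ---------------------------------------------------------------------------
# low-complexity masking
# ---------------------------------------------------------------------------

def low_complexity_mask(seq: str, max_period: int = 6, min_run: int = 12) -> np.ndarray:
    """Boolean mask of positions inside short-period tandem repeats.

    A position is masked when it lies in a stretch where ``s[i] == s[i-p]``
    for some period p <= max_period sustained over at least ``min_run``
    repeat-matching positions (homopolymers are period 1).
    """
    codes = _CODE_N[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    n = len(codes)
    mask = np.zeros(n, dtype=bool)
    for p in range(1, max_period + 1):
        if n <= p:
            break
        eq = codes[p:] == codes[:-p]
        # run-length scan over eq
        i = 0
        while i < len(eq):
            if not eq[i]:
                i += 1
                continue
            j = i
            while j < len(eq) and eq[j]:
                j += 1
            if j - i >= min_run:
                mask[i : j + p] = True
            i = j
    return mask


def mask_low_complexity(
    hits: list[AlignmentHit],
    target_seqs: dict[str, str],
    max_covered: float = 0.5,
) -> list[AlignmentHit]:
    """Drop hits whose target interval is mostly low-complexity sequence."""
    masks: dict[str, np.ndarray] = {}
    out = []
    for h in hits:
        if h.target_contig not in masks:
            masks[h.target_contig] = low_complexity_mask(target_seqs[h.target_contig])
        m = masks[h.target_contig][h.target_start : h.target_end]
        frac = float(m.mean()) if len(m) else 0.0
        if frac <= max_covered:
            out.append(h)
    return out


# ---------------------------------------------------------------------------
# Karlin-Altschul style E-values (ungapped, uniform base frequencies)
# ---------------------------------------------------------------------------

def karlin_lambda(scoring: ScoringScheme | None = None) -> float:
    """Positive root of 0.25 e^(lambda*match) + 0.75 e^(-lambda*mismatch) = 1."""
    sc = scoring or ScoringScheme()
    if 0.25 * sc.match - 0.75 * sc.mismatch >= 0:
        raise ValueError("expected score must be negative for a valid lambda")

    def f(lam):
        return 0.25 * np.exp(lam * sc.match) + 0.75 * np.exp(-lam * sc.mismatch) - 1.0

    return float(brentq(f, 1e-9, 50.0))


def karlin_evalue(
    score: float,
    query_len: int,
    db_len: int,
    scoring: ScoringScheme | None = None,
    k_param: float = 0.1,
) -> float:
    """Expected count of alignments with >= score: E = K m n exp(-lambda S).

    ``k_param`` is calibrated once from shuffled-sequence simulation and kept
    in configuration; only the monotone structure of E matters downstream.
    """
    lam = karlin_lambda(scoring)
    return float(k_param * query_len * db_len * np.exp(-lam * score))
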