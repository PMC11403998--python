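"""Insertion dating: presence/absence age classes and two quantitative methods.

Age classes come from the species presence pattern (which lineages carry an
orthologous copy): shared with a bovid means the insertion predates the
Suidae/Ruminantia split (~55 Mya); shared with the warthog but no bovid,
10-55 Mya; shared within the genus but not the warthog, 3.5-10 Mya; private
to one lineage, <= 3.5 Mya.

Quantitative method 1 (allele matching ratio, for insertions <= 10 Mya):
among alignment sites where the ancestral and modern mtDNA differ, the
fraction ``amr`` at which the NUMT carries the modern allele measures how
far down the branch the insertion happened: ``age = (1 - amr) * T``.
The ancestral sequence is reconstructed with Fitch parsimony; ambiguous
sites are excluded from the counts.

Quantitative method 2 (Kimura distance, for older insertions or degraded
sequence): with per-region mitochondrial rate ``V_mt = avg(K_pair / 2 T_pair)``
over species pairs and a configured nuclear rate ``V_numt``,
``t = K / (V_mt + V_numt)`` where K averages NUMT-to-mtDNA distances over
the clade below the insertion point (the species closest to the NUMT).
D-loop-derived sequence is excluded from both methods.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import dendropy
import edlib
import numpy as np

from .config import DivergenceTimes, RateConfig

__all__ = [
    "AgeClass",
    "AmrResult",
    "KimuraResult",
    "AgeEstimate",
    "Fragment",
    "assign_age_class",
    "fitch_ancestral",
    "threeway_align",
    "compute_amr",
    "age_from_amr",
    "kimura_k80",
    "compute_vmt",
    "age_from_kimura",
    "kimura_insertion_point",
    "date_region",
]


class AgeClass(enum.Enum):
    GT_55 = "> 55"
    MYA_55_10 = "55-10"
    MYA_10_3P5 = "10-3.5"
    LE_3P5 = "< 3.5"
    UNDETERMINED = "undetermined"


def assign_age_class(
    scrofa: bool,
    other_sus: bool,
    warthog: bool,
    bovid: bool,
) -> AgeClass:
    """Presence pattern -> age class.

    Sharing with a bovid dates the insertion before ~55 Mya; with the
    warthog (no bovid) to 10-55 Mya; within the genus only to 3.5-10 Mya;
    a single-lineage copy (including a warthog-private copy, which arose on
    the warthog lineage after the ~10 Mya split) is the youngest class.
    A bovid copy with no Suinae copy contradicts the single-origin model.
    """
    suinae = scrofa or other_sus or warthog
    if bovid:
        return AgeClass.GT_55 if suinae else AgeClass.UNDETERMINED
    if warthog:
        if scrofa or other_sus:
            return AgeClass.MYA_55_10
        return AgeClass.MYA_10_3P5
    if scrofa and other_sus:
        return AgeClass.MYA_10_3P5
    if scrofa or other_sus:
        return AgeClass.LE_3P5
    return AgeClass.UNDETERMINED


# ---------------------------------------------------------------------------
# Fitch parsimony ancestral reconstruction
# ---------------------------------------------------------------------------

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_FULL = 15
_BIT_BASE = {1: "A", 2: "C", 4: "G", 8: "T"}


def fitch_ancestral(
    alignment: dict[str, str],
    topology: str,
    node_label: str,
) -> tuple[str, np.ndarray]:
    """Fitch parsimony ancestor at a labelled internal node.

    ``alignment`` maps taxon name to equal-length sequence (gaps/N treated
    as missing); ``topology`` is a rooted newick whose internal nodes carry
    labels.  Returns the reconstructed sequence with ``N`` at sites whose
    final state set is ambiguous, plus the ambiguity mask.
    """
    if len(alignment) < 3:
        raise ValueError("need at least three taxa")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment sequences must have equal length")
    n_sites = lengths.pop()
    tree = dendropy.Tree.get(data=topology, schema="newick")

    def leaf_mask(name: str) -> np.ndarray:
        if name not in alignment:
            raise ValueError(f"taxon {name!r} missing from alignment")
        seq = alignment[name].upper()
        return np.array(
            [_BASE_BIT.get(c, _FULL) for c in seq], dtype=np.uint8
        )

    up: dict[int, np.ndarray] = {}
    labels: dict[int, str | None] = {}

    def bottom_up(node) -> np.ndarray:
        children = node.child_nodes()
        if not children:
            name = node.taxon.label if node.taxon else node.label
            m = leaf_mask(str(name).replace(" ", "_"))
        else:
            masks = [bottom_up(c) for c in children]
            inter = masks[0]
            union = masks[0]
            for m2 in masks[1:]:
                inter = inter & m2
                union = union | m2
            m = np.where(inter != 0, inter, union).astype(np.uint8)
        up[id(node)] = m
        labels[id(node)] = node.label or (
            node.taxon.label if node.taxon else None
        )
        return m

    bottom_up(tree.seed_node)

    final: dict[int, np.ndarray] = {id(tree.seed_node): up[id(tree.seed_node)]}

    def top_down(node) -> None:
        for child in node.child_nodes():
            inter = up[id(child)] & final[id(node)]
            final[id(child)] = np.where(
                inter != 0, inter, up[id(child)]
            ).astype(np.uint8)
            top_down(child)

    top_down(tree.seed_node)

    target = None
    for node in tree.preorder_node_iter():
        if labels[id(node)] == node_label:
            target = node
            break
    if target is None:
        raise ValueError(f"node {node_label!r} not found in topology")
    mask = final[id(target)]
    ambiguous = np.array([bin(int(m)).count("1") != 1 for m in mask])
    seq = "".join(
        "N" if amb else _BIT_BASE[int(m)] for m, amb in zip(mask, ambiguous)
    )
    return seq, ambiguous


# ---------------------------------------------------------------------------
# allele matching ratio (method 1)
# ---------------------------------------------------------------------------

@dataclass
class AmrResult:
    numt_vs_modern: int
    ancestral_vs_modern: int
    amr: float | None
    T: float | None = None
    age: float | None = None


def threeway_align(numt: str, ancestral: str, modern: str):
    """Gapped three-way alignment of a NUMT with ancestral and modern mtDNA.

    Ancestral and modern are coordinate-matched segments of the circular
    mtDNA (equal length); the NUMT is anchored to the modern segment by a
    global pairwise alignment, and the resulting gap pattern is propagated.
    """
    if len(ancestral) != len(modern):
        raise ValueError("ancestral and modern segments must be equal length")
    if len(numt) == len(modern):
        return numt, ancestral, modern
    res = edlib.align(numt, modern, task="path", mode="NW")
    g_numt, g_anc, g_mod = [], [], []
    qi = ti = 0
    for n, op in _parse_cigar(res["cigar"]):
        for _ in range(n):
            if op in ("=", "X", "M"):
                g_numt.append(numt[qi]); g_anc.append(ancestral[ti])
                g_mod.append(modern[ti]); qi += 1; ti += 1
            elif op == "I":  # base in numt absent from modern
                g_numt.append(numt[qi]); g_anc.append("-"); g_mod.append("-")
                qi += 1
            elif op == "D":
                g_numt.append("-"); g_anc.append(ancestral[ti])
                g_mod.append(modern[ti]); ti += 1
    return "".join(g_numt), "".join(g_anc), "".join(g_mod)


def _parse_cigar(cigar: str):
    n = ""
    for ch in cigar:
        if ch.isdigit():
            n += ch
        else:
            yield int(n), ch
            n = ""


def compute_amr(numt: str, ancestral: str, modern: str) -> AmrResult:
    """Allele matching ratio over sites where ancestral and modern differ.

    Inputs are the three aligned (equal-length, possibly gapped) sequences;
    gap and ambiguous (N) columns are excluded.  When ancestral and modern
    never differ the ratio is undefined and the region is undatable by this
    method.
    """
    if not (len(numt) == len(ancestral) == len(modern)):
        raise ValueError("sequences must be aligned to equal length")
    denom = num = 0
    for x, a, m in zip(numt.upper(), ancestral.upper(), modern.upper()):
        if "-" in (x, a, m) or "N" in (x, a, m):
            continue
        if a == m:
            continue
        denom += 1
        if x == m:
            num += 1
    amr = num / denom if denom else None
    return AmrResult(numt_vs_modern=num, ancestral_vs_modern=denom, amr=amr)


def age_from_amr(amr: float, T: float) -> float:
    """Insertion age in Mya: (1 - amr) * T."""
    if not 0.0 <= amr <= 1.0:
        raise ValueError("amr must be within [0, 1]")
    return (1.0 - amr) * T


# ---------------------------------------------------------------------------
# Kimura two-parameter distance (method 2)
# ---------------------------------------------------------------------------

def kimura_k80(seq_a: str, seq_b: str) -> float:
    """K80 distance with pairwise deletion of gap/N columns.

    K = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)) with P/Q the transition and
    transversion fractions.  Returns NaN at saturation (log argument <= 0).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    a = np.frombuffer(seq_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.upper().encode(), dtype=np.uint8)
    code = np.full(256, -1, dtype=np.int8)
    for i, base in enumerate(b"AGCT"):
        code[base] = i  # A,G purines (0,1); C,T pyrimidines (2,3)
    ca, cb = code[a], code[b]
    valid = (ca >= 0) & (cb >= 0)
    n = int(valid.sum())
    if n == 0:
        return float("nan")
    diff = valid & (ca != cb)
    same_class = (ca // 2) == (cb // 2)
    ts = int((diff & same_class).sum())
    tv = int((diff & ~same_class).sum())
    P, Q = ts / n, tv / n
    arg1 = 1.0 - 2.0 * P - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0 or arg2 <= 0:
        return float("nan")
    return float(-0.5 * np.log(arg1 * np.sqrt(arg2)))


def compute_vmt(
    distances: dict[tuple[str, str], float],
    divergence_times: dict[tuple[str, str], float],
) -> float:
    """Per-region mitochondrial rate: mean over pairs of K / (2 T).

    ``divergence_times`` are in Mya; pairs lacking a time (either key
    order accepted) are skipped.  Result is per site per year.
    """
    vals = []
    for (a, b), k in sorted(distances.items()):
        t = divergence_times.get((a, b), divergence_times.get((b, a)))
        if t is None or not np.isfinite(k):
            continue
        vals.append(k / (2.0 * t * 1e6))
    return float(np.mean(vals)) if vals else 0.0


def kimura_insertion_point(
    numt_distances: dict[str, float],
    host_species: str,
    divergence_of_host: dict[str, float],
    clade_rule: str = "divergence",
) -> tuple[str, float]:
    """Closest species and averaged K below the inferred insertion point.

    The species with the smallest NUMT distance marks the insertion point;
    K averages the distances to all species that diverged from the host no
    earlier than that species ("divergence" rule) or, alternatively, to the
    minimum-distance species only ("distance" rule).
    """
    finite = {s: d for s, d in numt_distances.items() if np.isfinite(d)}
    if not finite:
        return "", float("nan")
    closest = min(sorted(finite), key=lambda s: finite[s])
    if clade_rule == "distance":
        clade = [s for s, d in finite.items() if d <= finite[closest]]
    else:
        t_star = divergence_of_host.get(closest, 0.0)
        clade = [
            s for s in finite
            if divergence_of_host.get(s, float("inf")) <= t_star
            or s == host_species
        ]
    K = float(np.mean([finite[s] for s in sorted(clade)]))
    return closest, K


def age_from_kimura(K: float, v_mt: float, v_numt: float) -> float:
    """Insertion age in Mya: t = K / (V_mt + V_numt) (rates per site/year)."""
    if v_mt + v_numt <= 0:
        raise ValueError("V_mt + V_numt must be positive")
    if not np.isfinite(K):
        return float("nan")
    return float(K / (v_mt + v_numt) / 1e6)


@dataclass
class KimuraResult:
    distances: dict[str, float]
    insertion_species: str
    K: float
    v_mt: float
    v_numt: float
    t: float
    ages_by_rate: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# method dispatch per region
# ---------------------------------------------------------------------------

@dataclass
class Fragment:
    """One NUMT sequence of a region, with its source mtDNA interval."""

    seq: str
    mt_start: int
    mt_end: int
    identity: float = 1.0


@dataclass
class AgeEstimate:
    region_id: str
    age_class: AgeClass
    method: str                     # "amr" | "kimura" | "class_only"
    age: float | None = None
    amr: AmrResult | None = None
    kimura: KimuraResult | None = None
    note: str = ""


def _dloop_fraction(frag: Fragment, dloop: tuple[int, int] | None) -> float:
    if dloop is None:
        return 0.0
    s, e = dloop
    inter = max(0, min(frag.mt_end, e) - max(frag.mt_start, s))
    return inter / max(1, frag.mt_end - frag.mt_start)


def date_region(
    region_id: str,
    age_class: AgeClass,
    fragments: list[Fragment],
    species_mt: dict[str, str],
    ancestral_mt: str | None,
    host_species: str,
    divergence_of_host: dict[str, float],
    pair_times: dict[tuple[str, str], float],
    rates: RateConfig | None = None,
    divergence: DivergenceTimes | None = None,
    dloop: tuple[int, int] | None = None,
    min_summed_len: int = 150,
    min_identity: float = 0.80,
    clade_rule: str = "divergence",
) -> AgeEstimate:
    """Dispatch a region to the appropriate dating method.

    Method 1 (amr) applies to the two youngest classes when the summed
    fragment length exceeds 150 bp, mean identity exceeds 80% and the
    region is not D-loop derived; otherwise method 2 runs on the longest
    non-D-loop fragment > 150 bp; failing both, the class alone is
    reported.  mtDNA sequences are indexed in circular coordinates; the
    ancestral sequence (method 1) must cover the same coordinate system.
    """
    rates = rates or RateConfig()
    divergence = divergence or DivergenceTimes()
    usable = [f for f in fragments if _dloop_fraction(f, dloop) <= 0.5]
    summed = sum(len(f.seq) for f in usable)
    total = sum(len(f.seq) for f in fragments)
    mean_identity = (
        sum(f.identity * len(f.seq) for f in fragments) / total if total else 0.0
    )

    young = age_class in (AgeClass.LE_3P5, AgeClass.MYA_10_3P5)
    if (young and usable and summed > min_summed_len
            and mean_identity > min_identity and ancestral_mt is not None):
        T = divergence.sus if age_class is AgeClass.LE_3P5 else divergence.suinae
        modern = species_mt[host_species]
        num = denom = 0
        for f in usable:
            mod_seg = _circular_slice(modern, f.mt_start, f.mt_end)
            anc_seg = _circular_slice(ancestral_mt, f.mt_start, f.mt_end)
            gn, ga, gm = threeway_align(f.seq, anc_seg, mod_seg)
            r = compute_amr(gn, ga, gm)
            num += r.numt_vs_modern
            denom += r.ancestral_vs_modern
        if denom:
            amr = num / denom
            res = AmrResult(num, denom, amr, T=T, age=age_from_amr(amr, T))
            return AgeEstimate(region_id, age_class, "amr", res.age, amr=res)
        return AgeEstimate(region_id, age_class, "class_only",
                           note="ancestral and modern mtDNA identical")

    candidates = [f for f in usable if len(f.seq) > min_summed_len]
    if candidates:
        frag = max(candidates, key=lambda f: len(f.seq))
        distances = {}
        species_dist = {}
        names = sorted(species_mt)
        for sp in names:
            seg = _circular_slice(species_mt[sp], frag.mt_start, frag.mt_end)
            gn, _ga, gm = threeway_align(frag.seq, seg, seg)
            distances[sp] = kimura_k80(gn, gm)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                sa = _circular_slice(species_mt[a], frag.mt_start, frag.mt_end)
                sb = _circular_slice(species_mt[b], frag.mt_start, frag.mt_end)
                species_dist[(a, b)] = kimura_k80(sa, sb)
        v_mt = compute_vmt(species_dist, pair_times)
        if v_mt <= 0:
            return AgeEstimate(region_id, age_class, "class_only",
                               note="V_mt not estimable")
        closest, K = kimura_insertion_point(
            distances, host_species, divergence_of_host, clade_rule
        )
        if not np.isfinite(K):
            return AgeEstimate(region_id, age_class, "class_only",
                               note="Kimura distance saturated")
        v_numt = rates.default_rate
        ages = {
            name: age_from_kimura(K, v_mt, getattr(rates, name))
            for name in ("mammalian", "ruminant", "pig_pedigree")
        }
        res = KimuraResult(
            distances=distances, insertion_species=closest, K=K,
            v_mt=v_mt, v_numt=v_numt, t=ages[rates.default],
            ages_by_rate=ages,
        )
        return AgeEstimate(region_id, age_class, "kimura", res.t, kimura=res)

    return AgeEstimate(region_id, age_class, "class_only",
                       note="no datable fragment")


def _circular_slice(seq: str, start: int, end: int) -> str:
    if end <= len(seq):
        return seq[start:end]
    doubled = seq + seq
    return doubled[start:end]
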