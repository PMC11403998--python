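"""NUMT discovery in assembled genomes.

Pipeline per genome: circularise the consensus mtDNA, align it locally to
every contig on both strands, drop low-complexity matches, apply the score
threshold (default 30), exclude hits within 1 kb of contig ends, normalise
circular coordinates, then merge hits closer than 20 kb into NUMT regions
attributed to single insertion events.  Regions containing duplicated or
inverted mtDNA structure are flagged complex.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

from .config import ScoringScheme
from .mito_align import (
    AlignmentHit,
    circularize,
    local_align,
    mask_low_complexity,
    normalize_circular_hits,
)

__all__ = [
    "NumtHit",
    "NumtRegion",
    "scan_assembly",
    "build_regions",
    "flag_complex",
    "summarize_regions",
    "write_hits_bed",
    "write_regions_bed",
]


@dataclass(frozen=True)
class NumtHit:
    """An mtDNA local alignment retained as a putative NUMT fragment."""

    genome_id: str
    target_contig: str
    target_start: int
    target_end: int
    query_start: int
    query_end: int
    strand: str
    score: int
    identity: float
    aligned_length: int
    region_id: str | None = None

    @property
    def length(self) -> int:
        return self.target_end - self.target_start


@dataclass
class NumtRegion:
    """One or more NUMT fragments < 20 kb apart: a single insertion event."""

    region_id: str
    genome_id: str
    contig: str
    start: int
    end: int
    hits: list[NumtHit]
    total_numt_bp: int
    mean_identity: float
    n_fragments: int
    complex: bool = False
    inversion_present: bool = False
    unplaced: bool = False

    @property
    def span(self) -> int:
        return self.end - self.start


def scan_assembly(
    genome: dict[str, str],
    consensus_mt: str,
    scoring: ScoringScheme | None = None,
    threshold: int | None = None,
    genome_id: str = "genome",
    min_length: int = 30,
    end_exclusion: int = 1000,
    seed_k: int = 11,
    xdrop: int = 20,
) -> list[NumtHit]:
    """All NUMT hits of the circularised mtDNA in one assembled genome."""
    sc = scoring or ScoringScheme()
    if threshold is None:
        threshold = sc.min_score_threshold
    mt_len = len(consensus_mt)
    circ = circularize(consensus_mt)
    all_hits: list[AlignmentHit] = []
    for contig, seq in sorted(genome.items()):
        if not seq:
            continue
        hits = local_align(
            circ, seq, sc, seed_k=seed_k, xdrop=xdrop,
            min_score=threshold, target_contig=contig,
        )
        hits = mask_low_complexity(hits, {contig: seq})
        for h in hits:
            if h.target_end - h.target_start < min_length:
                continue
            if h.target_start < end_exclusion:
                continue
            if h.target_end > len(seq) - end_exclusion:
                continue
            all_hits.append(h)
    all_hits = normalize_circular_hits(all_hits, mt_len)
    return [
        NumtHit(
            genome_id=genome_id,
            target_contig=h.target_contig,
            target_start=h.target_start,
            target_end=h.target_end,
            query_start=h.query_start,
            query_end=h.query_end,
            strand=h.strand,
            score=h.score,
            identity=h.identity,
            aligned_length=h.aligned_length,
        )
        for h in sorted(
            all_hits, key=lambda h: (h.target_contig, h.target_start)
        )
    ]


def build_regions(
    hits: list[NumtHit],
    merge_gap: int = 20_000,
    unplaced_contigs: set[str] | None = None,
) -> list[NumtRegion]:
    """Single-linkage merge of same-contig hits with gaps < ``merge_gap``.

    Region ids follow the CONTIG_REGION_k convention, ordinal per contig in
    coordinate order; mean identity is length-weighted over member hits.
    """
    unplaced_contigs = unplaced_contigs or set()
    by_contig: dict[tuple[str, str], list[NumtHit]] = {}
    for h in hits:
        by_contig.setdefault((h.genome_id, h.target_contig), []).append(h)
    regions = []
    for (genome_id, contig), group in sorted(by_contig.items()):
        group = sorted(group, key=lambda h: (h.target_start, h.target_end))
        clusters: list[list[NumtHit]] = [[group[0]]]
        cluster_end = group[0].target_end
        for h in group[1:]:
            if h.target_start - cluster_end < merge_gap:
                clusters[-1].append(h)
                cluster_end = max(cluster_end, h.target_end)
            else:
                clusters.append([h])
                cluster_end = h.target_end
        for k, members in enumerate(clusters, start=1):
            start = min(h.target_start for h in members)
            end = max(h.target_end for h in members)
            total = sum(h.length for h in members)
            mean_id = (
                sum(h.identity * h.length for h in members) / total
                if total else 0.0
            )
            region_id = f"{contig}_REGION_{k}"
            members = [
                NumtHit(**{**h.__dict__, "region_id": region_id})
                for h in members
            ]
            regions.append(
                flag_complex(
                    NumtRegion(
                        region_id=region_id,
                        genome_id=genome_id,
                        contig=contig,
                        start=start,
                        end=end,
                        hits=members,
                        total_numt_bp=total,
                        mean_identity=mean_id,
                        n_fragments=len(members),
                        unplaced=contig in unplaced_contigs,
                    )
                )
            )
    return regions


def _mt_overlap(a: NumtHit, b: NumtHit) -> int:
    return min(a.query_end, b.query_end) - max(a.query_start, b.query_start)


def flag_complex(region: NumtRegion) -> NumtRegion:
    """Set duplication/inversion flags from member-hit mtDNA structure.

    Complex: two members re-use the same mtDNA interval (> 50 bp overlap on
    normalised mtDNA coordinates), or mixed strands whose mtDNA intervals
    overlap.  An inversion alone (mixed strands, disjoint mtDNA intervals)
    sets only ``inversion_present``.
    """
    strands = {h.strand for h in region.hits}
    region.inversion_present = len(strands) > 1
    complex_flag = False
    for i, a in enumerate(region.hits):
        for b in region.hits[i + 1 :]:
            ov = _mt_overlap(a, b)
            if ov > 50:
                complex_flag = True
            if a.strand != b.strand and ov > 0:
                complex_flag = True
    region.complex = complex_flag
    return region


def summarize_regions(
    regions: list[NumtRegion], genome_bp: int | None = None
) -> dict:
    """Headline statistics plus dot-plot coordinates per region."""
    if not regions:
        return {
            "n_regions": 0, "n_sequences": 0, "n_singletons": 0,
            "total_numt_bp": 0, "min_length": 0, "median_length": 0,
            "mean_length": 0.0, "sd_length": 0.0, "genome_fraction": 0.0,
            "n_complex": 0, "dotplot": {},
        }
    lengths = [r.total_numt_bp for r in regions]
    total = sum(lengths)
    return {
        "n_regions": len(regions),
        "n_sequences": sum(r.n_fragments for r in regions),
        "n_singletons": sum(1 for r in regions if r.n_fragments == 1),
        "total_numt_bp": total,
        "min_length": min(lengths),
        "median_length": statistics.median(lengths),
        "mean_length": statistics.mean(lengths),
        "sd_length": statistics.stdev(lengths) if len(lengths) > 1 else 0.0,
        "genome_fraction": total / genome_bp if genome_bp else 0.0,
        "n_complex": sum(1 for r in regions if r.complex),
        "dotplot": {
            r.region_id: [
                (h.target_start, h.target_end, h.query_start, h.query_end,
                 h.strand)
                for h in r.hits
            ]
            for r in regions
        },
    }


def write_hits_bed(hits: list[NumtHit], path) -> None:
    with open(path, "w") as fh:
        for h in sorted(hits, key=lambda h: (h.target_contig, h.target_start)):
            name = f"mt:{h.query_start}-{h.query_end}"
            fh.write(
                f"{h.target_contig}\t{h.target_start}\t{h.target_end}\t"
                f"{name}\t{h.score}\t{h.strand}\n"
            )


def write_regions_bed(regions: list[NumtRegion], path) -> None:
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.contig, r.start)):
            fh.write(
                f"{r.contig}\t{r.start}\t{r.end}\t{r.region_id}\t"
                f"{r.n_fragments}\t+\n"
            )
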