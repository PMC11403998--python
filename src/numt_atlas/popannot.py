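"""Population-level summaries and genomic annotation of NUMT regions.

Carrier frequencies per breed/group feed three analyses: a false-negative
control (ancient, pre-speciation insertions must be present in every
genome, so their missing calls measure the detection error rate), the
polymorphism call (species-wide carrier frequency below 1 - that error
rate), and UPGMA clustering of groups by their carrier-frequency vectors
(Euclidean distance), which should recover known population structure.

Annotation places each region relative to gene features (precedence
exon > UTR > intron > intergenic), finds the closest gene, collects repeat
classes within 1 kb, computes flank GC, and tests repeat enrichment of the
flanks against the genome background with Fisher's exact test on
nucleotide counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.stats import fisher_exact

__all__ = [
    "CarrierTable",
    "GffFeature",
    "AnnotationRecord",
    "EnrichmentResult",
    "carrier_frequencies",
    "estimate_false_negative_rate",
    "call_polymorphic",
    "upgma_cluster",
    "read_gff3",
    "annotate_regions",
    "repeat_enrichment",
    "export_gff",
]

CARRIER_STATES = {"het", "hom_ins", "carrier", "CORRESPONDING",
                  "COMPATIBLE_SEQUENCE"}
NON_CARRIER_STATES = {"absent", "non_carrier", "PRIVATE"}
# UNALIGNED / empty / None are excluded from denominators


@dataclass
class CarrierTable:
    frequencies: pd.DataFrame   # regions x groups, carrier fraction
    n_datasets: pd.DataFrame    # regions x groups, informative datasets

    def eligible_groups(self, min_datasets: int = 10) -> list[str]:
        ok = (self.n_datasets.max(axis=0) >= min_datasets)
        return [g for g in self.frequencies.columns if ok[g]]


def carrier_frequencies(
    matrix: pd.DataFrame,
    group_map: dict[str, str],
) -> CarrierTable:
    """Carrier fraction per region and group from a status/genotype matrix.

    ``matrix`` is regions x datasets with genotype or orthology-status
    strings; datasets missing from ``group_map`` are ignored, undetermined
    cells are excluded from denominators, empty groups are skipped.
    """
    groups = sorted(set(group_map.values()))
    freqs = {}
    counts = {}
    for g in groups:
        cols = [c for c in matrix.columns if group_map.get(c) == g]
        if not cols:
            continue
        sub = matrix[cols]
        carrier = sub.isin(CARRIER_STATES).sum(axis=1)
        informative = carrier + sub.isin(NON_CARRIER_STATES).sum(axis=1)
        with np.errstate(invalid="ignore"):
            freqs[g] = (carrier / informative.replace(0, np.nan)).astype(float)
        counts[g] = informative
    return CarrierTable(
        frequencies=pd.DataFrame(freqs, index=matrix.index),
        n_datasets=pd.DataFrame(counts, index=matrix.index),
    )


def estimate_false_negative_rate(
    ancient_region_ids: list[str],
    matrix: pd.DataFrame,
) -> float | None:
    """Detection error from ancient regions that every genome must carry.

    Returns 1 - mean carrier fraction of the given regions across all
    informative datasets, or None when no ancient region is available
    (callers then fall back to a configured polymorphism threshold).
    """
    rows = [r for r in ancient_region_ids if r in matrix.index]
    if not rows:
        return None
    fracs = []
    for r in rows:
        row = matrix.loc[r]
        carrier = row.isin(CARRIER_STATES).sum()
        informative = carrier + row.isin(NON_CARRIER_STATES).sum()
        if informative:
            fracs.append(carrier / informative)
    if not fracs:
        return None
    return float(1.0 - np.mean(fracs))


def call_polymorphic(
    species_freq: pd.Series,
    fn_rate: float,
) -> list[str]:
    """Regions with species-wide carrier frequency strictly below 1 - fn_rate."""
    cut = 1.0 - fn_rate
    return [r for r, f in species_freq.items() if pd.notna(f) and f < cut]


# ---------------------------------------------------------------------------
# UPGMA clustering of groups
# ---------------------------------------------------------------------------

def upgma_cluster(
    table: CarrierTable | pd.DataFrame,
    min_datasets: int = 10,
) -> tuple[str, np.ndarray, list[str]]:
    """UPGMA dendrogram of groups by Euclidean carrier-frequency distance.

    Returns (newick, scipy linkage matrix, leaf labels).  Groups observed in
    fewer than ``min_datasets`` datasets are excluded; NaN frequencies are
    mean-imputed per region.  Node heights in the newick are half the
    cophenetic distance (ultrametric convention); ties break by label order
    through deterministic input ordering.
    """
    if isinstance(table, CarrierTable):
        cols = table.eligible_groups(min_datasets)
        df = table.frequencies[cols]
    else:
        df = table
    if df.shape[1] < 3:
        raise ValueError("need at least three groups to cluster")
    filled = df.apply(lambda row: row.fillna(row.mean()), axis=1)
    filled = filled.dropna(how="any")  # regions with no informative group
    if filled.empty:
        raise ValueError("no regions with informative frequencies")
    labels = list(filled.columns)
    data = filled.T.to_numpy(dtype=float)
    Z = linkage(data, method="average", metric="euclidean")
    newick = _linkage_to_newick(Z, labels)
    return newick, Z, labels


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}

    def node(i: int) -> str:
        if i < n:
            return labels[i]
        a, b, dist, _cnt = Z[i - n]
        h = dist / 2.0
        heights[i] = h
        left, right = int(a), int(b)
        return (
            f"({node(left)}:{h - heights[left]:.6g},"
            f"{node(right)}:{h - heights[right]:.6g})"
        )

    return node(n + len(Z) - 1) + ";"


# ---------------------------------------------------------------------------
# GFF3 I/O (minimal: the fields this pipeline reads and writes)
# ---------------------------------------------------------------------------

@dataclass
class GffFeature:
    contig: str
    source: str
    type: str
    start: int          # 1-based inclusive
    end: int
    score: str = "."
    strand: str = "."
    phase: str = "."
    attributes: dict[str, str] = field(default_factory=dict)

    def attr_string(self) -> str:
        return ";".join(f"{k}={v}" for k, v in self.attributes.items())


def read_gff3(path) -> list[GffFeature]:
    feats = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            feats.append(GffFeature(f[0], f[1], f[2], int(f[3]), int(f[4]),
                                    f[5], f[6], f[7], attrs))
    return feats


def _write_gff3(features: list[GffFeature]) -> str:
    lines = ["##gff-version 3"]
    for f in features:
        lines.append(
            f"{f.contig}\t{f.source}\t{f.type}\t{f.start}\t{f.end}\t"
            f"{f.score}\t{f.strand}\t{f.phase}\t{f.attr_string()}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

@dataclass
class AnnotationRecord:
    region_id: str
    feature_class: str              # exon | UTR | intron | intergenic
    closest_gene: str | None
    gene_distance: int | None       # signed; 0 when overlapping
    repeat_classes: list[str]
    flank_gc: float
    flank_clipped: bool = False


_UTR_TYPES = {"five_prime_UTR", "three_prime_UTR", "UTR"}


def annotate_regions(
    regions,
    gff_features: list[GffFeature],
    repeat_table: list[tuple[str, int, int, str]],
    genome: dict[str, str],
    flank: int = 1000,
) -> list[AnnotationRecord]:
    """Feature class, closest gene, nearby repeats and flank GC per region.

    Precedence when a region overlaps several feature types:
    exon > UTR > intron (inside a gene but outside exon/UTR) > intergenic.
    The closest gene is by signed distance from the region to the gene
    span (negative when the gene is upstream of the region start).
    """
    genes = [f for f in gff_features if f.type == "gene"]
    exons = [f for f in gff_features if f.type == "exon"]
    utrs = [f for f in gff_features if f.type in _UTR_TYPES]
    out = []
    for r in regions:
        s, e = r.start, r.end  # 0-based half-open region coordinates

        def overlaps(f: GffFeature) -> bool:
            return f.contig == r.contig and f.start - 1 < e and f.end > s

        if any(overlaps(f) for f in exons):
            cls = "exon"
        elif any(overlaps(f) for f in utrs):
            cls = "UTR"
        elif any(overlaps(f) for f in genes):
            cls = "intron"
        else:
            cls = "intergenic"

        closest, dist = None, None
        for g in (f for f in genes if f.contig == r.contig):
            gs, ge = g.start - 1, g.end
            if ge <= s:
                d = -(s - ge)      # gene upstream: negative distance
            elif gs >= e:
                d = gs - e
            else:
                d = 0
            if dist is None or abs(d) < abs(dist):
                closest = g.attributes.get("ID", g.attributes.get("Name", "?"))
                dist = d

        rep_classes = sorted({
            cls_ for contig, rs, re_, cls_ in repeat_table
            if contig == r.contig and rs < e + flank and re_ > s - flank
        })

        seq = genome[r.contig]
        lo, hi = s - flank, e + flank
        clipped = lo < 0 or hi > len(seq)
        flank_seq = seq[max(0, lo):s] + seq[e:min(len(seq), hi)]
        gc = (
            sum(1 for b in flank_seq.upper() if b in "GC") / len(flank_seq)
            if flank_seq else 0.0
        )
        out.append(AnnotationRecord(
            region_id=r.region_id,
            feature_class=cls,
            closest_gene=closest,
            gene_distance=dist,
            repeat_classes=rep_classes,
            flank_gc=gc,
            flank_clipped=clipped,
        ))
    return out


# ---------------------------------------------------------------------------
# repeat enrichment (Fisher's exact test on nucleotide counts)
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    repeat_class: str
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float


def repeat_enrichment(
    flank_cov: dict[str, int],
    flank_total: int,
    genome_cov: dict[str, int],
    genome_total: int,
) -> list[EnrichmentResult]:
    """Two-sided Fisher test per repeat class: flank vs genome nucleotides.

    Each 2x2 table is (bases in class, bases not) for flanks vs genome;
    zero-margin tables give p = 1.  No multiplicity correction is applied;
    raw per-class p-values are reported.
    """
    out = []
    for cls in sorted(set(flank_cov) | set(genome_cov)):
        a = flank_cov.get(cls, 0)
        b = flank_total - a
        c = genome_cov.get(cls, 0)
        d = genome_total - c
        tbl = ((a, b), (c, d))
        if a + c == 0 or b + d == 0 or a + b == 0 or c + d == 0:
            out.append(EnrichmentResult(cls, tbl, 1.0, 1.0))
            continue
        orr, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        out.append(EnrichmentResult(cls, tbl, float(orr), float(p)))
    return out


# ---------------------------------------------------------------------------
# GFF export of regions
# ---------------------------------------------------------------------------

def export_gff(regions, path=None, source: str = "numt-atlas") -> str:
    """Regions and their fragments as GFF3 (1-based inclusive coordinates).

    Each region becomes a NUMT_region row; member hits become NUMT_fragment
    children with Parent attributes.  Output is canonical: writing the
    parsed features again reproduces the text byte for byte.
    """
    feats = []
    for r in sorted(regions, key=lambda r: (r.contig, r.start)):
        feats.append(GffFeature(
            contig=r.contig, source=source, type="NUMT_region",
            start=r.start + 1, end=r.end, score=".", strand=".",
            attributes={"ID": r.region_id},
        ))
        for i, h in enumerate(getattr(r, "hits", []) or [], start=1):
            feats.append(GffFeature(
                contig=r.contig, source=source, type="NUMT_fragment",
                start=h.target_start + 1, end=h.target_end,
                score=str(h.score), strand=h.strand,
                attributes={
                    "ID": f"{r.region_id}.{i}",
                    "Parent": r.region_id,
                    "mt_interval": f"{h.query_start}-{h.query_end}",
                },
            ))
    text = _write_gff3(feats)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
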