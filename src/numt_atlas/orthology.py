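"""Cross-genome orthology of NUMT regions.

Given one-to-one whole-genome alignment blocks (MAF), each NUMT region of
genome A is projected onto genome B and classified:

* CORRESPONDING        -- the projection overlaps a NUMT region called in B;
* COMPATIBLE_SEQUENCE  -- the region aligns fully and gaplessly onto B
  sequence where no region was called: treated as a detection false
  negative in B and promoted to a region there;
* PRIVATE              -- the region projects onto gaps only: the insertion
  is absent in B (a presence/absence polymorphism);
* UNALIGNED            -- no block covers the region.

For distantly related species, where whole-genome alignment is unreliable,
orthology is decided from shared synteny of the five up- and downstream
flanking genes plus reciprocal overlap of the source mtDNA intervals.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OrthologyStatus",
    "AlignmentBlock",
    "SyntenyContext",
    "PresenceMatrix",
    "read_maf",
    "map_region_status",
    "promote_compatible",
    "distant_orthology",
    "build_presence_matrix",
]


class OrthologyStatus(enum.Enum):
    CORRESPONDING = "CORRESPONDING"
    COMPATIBLE_SEQUENCE = "COMPATIBLE_SEQUENCE"
    PRIVATE = "PRIVATE"
    UNALIGNED = "UNALIGNED"


@dataclass
class AlignmentBlock:
    """One pairwise MAF block (both strands +; one-to-one after filtering)."""

    genome_a: str
    contig_a: str
    start_a: int
    size_a: int
    text_a: str
    genome_b: str
    contig_b: str
    start_b: int
    size_b: int
    text_b: str
    strand: str = "+"
    mismap: float = 0.0


def read_maf(path, max_mismap: float = 1e-5) -> list[AlignmentBlock]:
    """Parse pairwise MAF; blocks with mismap above the cutoff are dropped."""
    blocks = []
    with open(path) as fh:
        cur_attrs: dict[str, str] = {}
        rows: list[tuple] = []

        def flush():
            if len(rows) == 2:
                mismap = float(cur_attrs.get("mismap", 0.0))
                if mismap <= max_mismap:
                    (ga, ca, sa, za, ta), (gb, cb, sb, zb, tb) = rows
                    blocks.append(AlignmentBlock(
                        ga, ca, sa, za, ta, gb, cb, sb, zb, tb,
                        mismap=mismap,
                    ))
            rows.clear()

        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("a"):
                flush()
                cur_attrs = dict(
                    kv.split("=", 1) for kv in line.split()[1:] if "=" in kv
                )
            elif line.startswith("s"):
                _s, src, start, size, strand, _src_size, text = line.split()
                genome, _, contig = src.partition(".")
                rows.append((genome, contig, int(start), int(size), text))
            elif not line.strip():
                flush()
        flush()
    return blocks


def _project(region: tuple[int, int], block: AlignmentBlock):
    """Columns of the block inside the region: (covered, aligned, b_lo, b_hi).

    ``covered`` counts region bases present in the A row, ``aligned`` those
    whose B column is a base (not a gap); b_lo/b_hi bound the projected
    interval on B (half-open), or None when nothing aligns.
    """
    s, e = region
    a = np.frombuffer(block.text_a.encode(), dtype=np.uint8)
    b = np.frombuffer(block.text_b.encode(), dtype=np.uint8)
    gap = ord("-")
    a_base = a != gap
    b_base = b != gap
    a_pos = np.cumsum(a_base) - 1 + block.start_a  # A coordinate per column
    b_pos = np.cumsum(b_base) - 1 + block.start_b
    in_region = a_base & (a_pos >= s) & (a_pos < e)
    covered = int(in_region.sum())
    aligned_cols = in_region & b_base
    aligned = int(aligned_cols.sum())
    if aligned:
        bp = b_pos[aligned_cols]
        return covered, aligned, int(bp.min()), int(bp.max()) + 1
    return covered, aligned, None, None


def map_region_status(
    region,
    blocks: list[AlignmentBlock],
    other_regions,
) -> tuple[OrthologyStatus, tuple[int, int] | None]:
    """Classify one region of genome A against genome B.

    ``region`` needs .contig/.start/.end (a NumtRegion works); ``blocks``
    must already be mismap-filtered with genome A as the first row;
    ``other_regions`` are the NUMT regions called in genome B.
    """
    s, e = region.start, region.end
    covered = aligned = 0
    b_lo, b_hi = None, None
    b_contig = None
    for blk in blocks:
        if blk.contig_a != region.contig:
            continue
        if blk.start_a + blk.size_a <= s or blk.start_a >= e:
            continue
        c, a, lo, hi = _project((s, e), blk)
        covered += c
        aligned += a
        if lo is not None:
            b_lo = lo if b_lo is None else min(b_lo, lo)
            b_hi = hi if b_hi is None else max(b_hi, hi)
            b_contig = blk.contig_b
    if covered == 0:
        return OrthologyStatus.UNALIGNED, None
    if aligned == 0:
        return OrthologyStatus.PRIVATE, None
    projected = (b_lo, b_hi)
    for r in other_regions:
        if r.contig == b_contig and r.start < b_hi and r.end > b_lo:
            return OrthologyStatus.CORRESPONDING, projected
    region_len = e - s
    gapless = aligned == region_len and (b_hi - b_lo) == region_len
    if covered == region_len and gapless:
        return OrthologyStatus.COMPATIBLE_SEQUENCE, projected
    # partial, gappy projection without a matching region: insertion absent
    return OrthologyStatus.PRIVATE, projected


@dataclass
class _PromotedRegion:
    region_id: str
    contig: str
    start: int
    end: int
    promoted: bool = True


def promote_compatible(statuses: dict, regions_by_genome: dict) -> dict:
    """Add COMPATIBLE_SEQUENCE projections as regions of the other genome.

    ``statuses`` maps (region_id, genome) -> (status, projected interval,
    contig).  Promotion is idempotent: a second pass finds the promoted
    region and reports CORRESPONDING.
    """
    out = dict(regions_by_genome)
    for (region_id, genome), (status, proj, contig) in sorted(statuses.items()):
        if status is not OrthologyStatus.COMPATIBLE_SEQUENCE or proj is None:
            continue
        existing = out.get(genome, [])
        if any(r.contig == contig and r.start < proj[1] and r.end > proj[0]
               for r in existing):
            continue
        out[genome] = existing + [
            _PromotedRegion(f"{region_id}@{genome}", contig, proj[0], proj[1])
        ]
    return out


# ---------------------------------------------------------------------------
# distant-species synteny
# ---------------------------------------------------------------------------

@dataclass
class SyntenyContext:
    """Flanking-gene context of a region: up to 5 genes each side, in order."""

    region_id: str
    genes: list[str]            # upstream then downstream, genomic order
    mt_interval: tuple[int, int]
    truncated: bool = False     # fewer than 10 genes (contig end)


def distant_orthology(
    ctx_a: SyntenyContext,
    ctx_b: SyntenyContext,
    ortholog_map: dict[str, str],
    min_syntenic: float = 0.50,
    min_mt_overlap: float = 0.40,
) -> bool | None:
    """Synteny + mtDNA-interval test for distantly related genomes.

    Requires >= 50% of comparable flanking genes syntenic (orthologs present
    in the partner context, in consistent order) and reciprocal mtDNA
    overlap strictly above 40% (smaller interval as denominator).  Returns
    None (undetermined) with fewer than 4 comparable genes.
    """
    mapped = [(g, ortholog_map[g]) for g in ctx_a.genes if g in ortholog_map]
    comparable = len(mapped)
    if comparable < 4:
        return None
    pos_b = {g: i for i, g in enumerate(ctx_b.genes)}
    present = [(i, pos_b[ob]) for i, (_g, ob) in enumerate(mapped) if ob in pos_b]
    syntenic = 0
    if present:
        order = [j for _i, j in present]
        forward = all(b >= a for a, b in zip(order, order[1:]))
        reverse = all(b <= a for a, b in zip(order, order[1:]))
        syntenic = len(present) if (forward or reverse) else max(
            _longest_monotone(order), _longest_monotone(order[::-1])
        )
    if syntenic / comparable < min_syntenic:
        return False
    (a0, a1), (b0, b1) = ctx_a.mt_interval, ctx_b.mt_interval
    inter = max(0, min(a1, b1) - max(a0, b0))
    denom = min(a1 - a0, b1 - b0)
    if denom <= 0:
        return False
    return inter / denom > min_mt_overlap


def _longest_monotone(seq: list[int]) -> int:
    best = [1] * len(seq)
    for i in range(len(seq)):
        for j in range(i):
            if seq[j] <= seq[i]:
                best[i] = max(best[i], best[j] + 1)
    return max(best, default=0)


# ---------------------------------------------------------------------------
# presence matrix
# ---------------------------------------------------------------------------

@dataclass
class PresenceMatrix:
    table: pd.DataFrame          # rows: region ids (coordinate order)
    upset: pd.Series             # counts per unique presence pattern
    conflicts: list = field(default_factory=list)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")

    def to_json(self, path) -> None:
        import json

        payload = {
            "regions": self.table.index.tolist(),
            "columns": self.table.columns.tolist(),
            "cells": self.table.values.tolist(),
            "upset": {k: int(v) for k, v in self.upset.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def build_presence_matrix(
    statuses: dict,
    region_order: list[str],
    wgs_genotypes: dict | None = None,
) -> PresenceMatrix:
    """Regions x genomes/datasets status table with UpSet-style summaries.

    ``statuses`` maps (region_id, genome) -> OrthologyStatus (duplicates
    conflict-resolved keeping CORRESPONDING); ``wgs_genotypes`` maps
    (region_id, dataset) -> genotype string.
    """
    cells: dict[tuple[str, str], str] = {}
    conflicts = []
    for (region_id, genome), status in sorted(
        statuses.items(), key=lambda kv: str(kv)
    ):
        key = (region_id, genome)
        val = status.value if isinstance(status, OrthologyStatus) else str(status)
        if key in cells and cells[key] != val:
            conflicts.append((key, cells[key], val))
            if OrthologyStatus.CORRESPONDING.value in (cells[key], val):
                cells[key] = OrthologyStatus.CORRESPONDING.value
            continue
        cells[key] = val
    for (region_id, dataset), gt in (wgs_genotypes or {}).items():
        cells[(region_id, dataset)] = str(gt)
    columns = sorted({g for _r, g in cells})
    rows = [r for r in region_order if any((r, g) in cells for g in columns)]
    table = pd.DataFrame(
        [[cells.get((r, g), "") for g in columns] for r in rows],
        index=rows,
        columns=columns,
    )
    present_vals = {
        OrthologyStatus.CORRESPONDING.value,
        OrthologyStatus.COMPATIBLE_SEQUENCE.value,
        "hom_ins", "het", "carrier",
    }
    patterns = table.apply(
        lambda row: "|".join(g for g in columns if row[g] in present_vals),
        axis=1,
    )
    upset = patterns.value_counts()
    return PresenceMatrix(table=table, upset=upset, conflicts=conflicts)
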