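"""End-to-end demo pipeline: simulate -> scan -> wgs-scan -> orthology ->
dating -> population/annotation, with a provenance manifest.

The demo design plants NUMT of every age class into a synthetic host
genome, sequences three samples with genotype variation at the young
insertions, and runs every downstream stage on the simulated data.  All
randomness flows from the single configured seed; rerunning with the same
seed reproduces every output byte for byte (the manifest digests prove it).
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._seq import write_fasta
from .config import PipelineConfig
from .assembly_scan import (
    build_regions, scan_assembly, summarize_regions, write_hits_bed,
    write_regions_bed,
)
from .dating import (
    AgeClass, Fragment, assign_age_class, date_region, fitch_ancestral,
)
from .orthology import (
    OrthologyStatus, build_presence_matrix, map_region_status, read_maf,
)
from .popannot import (
    annotate_regions, call_polymorphic, carrier_frequencies,
    estimate_false_negative_rate, export_gff, read_gff3, upgma_cluster,
    GffFeature, _write_gff3,
)
from .synthio import (
    HostSpec, InsertionSpec, default_tree, plant_numts, simulate_reads,
    write_pairwise_maf,
)
from .wgs_scan import SampleAlignment, call_insertions

STAGES = ["simulate", "scan", "wgs-scan", "orthology", "date", "popannot"]

# demo insertion ages (Mya): every age class is represented
_DEMO_AGES = [0.2, 1.75, 6.0, 30.0, 55.0, 2.5, 8.0, 45.0]


def _demo_insertions(rng: np.random.Generator, contig: str, contig_len: int,
                     mt_len: int, samples: list[str]) -> list[InsertionSpec]:
    n = len(_DEMO_AGES)
    slots = np.linspace(30_000, contig_len - 30_000, n).astype(int)
    jitter = rng.integers(-5000, 5000, size=n)
    insertions = []
    for i, age in enumerate(_DEMO_AGES):
        length = int(rng.integers(300, 2000))
        mt_start = int(rng.integers(0, mt_len - 1))
        young = age < 3.5
        if young:
            gts = {}
            options = ["hom_ins", "het", "absent"]
            for j, s in enumerate(samples):
                gts[s] = options[(i + j) % 3]
            if all(g == "absent" for g in gts.values()):
                gts[samples[0]] = "het"
        else:
            gts = {s: "hom_ins" for s in samples}
        insertions.append(InsertionSpec(
            name=f"numt{i + 1}",
            host_contig=contig,
            host_position=int(slots[i] + jitter[i]),
            mt_start=mt_start,
            mt_end=mt_start + length,
            insertion_age=age,
            host_species="scrofa",
            wraparound=mt_start + length > mt_len,
            genotypes=gts,
        ))
    return insertions


def _demo_gff(contig: str, contig_len: int) -> list[GffFeature]:
    feats = []
    k = 0
    for gs in range(50_000, contig_len - 120_000, 200_000):
        k += 1
        ge = gs + 60_000
        gid = f"gene{k}"
        feats.append(GffFeature(contig, "demo", "gene", gs + 1, ge,
                                strand="+", attributes={"ID": gid}))
        feats.append(GffFeature(contig, "demo", "exon", gs + 1, gs + 2000,
                                strand="+",
                                attributes={"ID": f"{gid}.e1", "Parent": gid}))
        feats.append(GffFeature(contig, "demo", "exon", ge - 1999, ge,
                                strand="+",
                                attributes={"ID": f"{gid}.e2", "Parent": gid}))
    return feats


def run(
    config: PipelineConfig,
    out_dir,
    stages: list[str] | None = None,
    contig_len: int = 1_000_000,
    depth: float = 20.0,
    read_len: int = 100,
    error_rate: float = 0.002,
    log=print,
) -> dict:
    """Execute the pipeline stages in dependency order; return the manifest."""
    stages = stages or STAGES
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(
            f"unknown stage(s) {unknown}; valid stages: {STAGES}"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    rng = np.random.default_rng(seed)
    samples = ["s1", "s2", "s3"]
    contig = "chr1"
    tree = default_tree()
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "stages": [],
        "outputs": {},
        "python": sys.version.split()[0],
    }

    # --- simulate -----------------------------------------------------------
    sim_dir = out / "simulate"
    sim_dir.mkdir(exist_ok=True)
    host = HostSpec(contigs={contig: contig_len},
                    species=["scrofa", "cebifrons", "warthog", "bovid"])
    insertions = _demo_insertions(rng, contig, contig_len, tree.mt_length,
                                  samples)
    result = plant_numts(host, insertions, tree, seed)
    read_sets = {}
    for i, s in enumerate(samples):
        rs = simulate_reads(
            result.sample_haplotypes[s], result.reference,
            result.haplotype_layout(s), depth=depth, read_len=read_len,
            insert_size=3 * read_len, error_rate=error_rate,
            seed=seed + 1000 + i, sample_name=s,
        )
        read_sets[s] = rs
    if "simulate" in stages:
        log("stage simulate: planting %d NUMT" % len(insertions))
        write_fasta(sim_dir / "reference.fasta",
                    sorted(result.reference.items()))
        for sp in host.species:
            result.write_genome_fasta(sim_dir / f"{sp}.fasta", sp)
        write_fasta(sim_dir / "mtdna.fasta",
                    sorted(result.panel.species.items()))
        result.write_truth_tsv(sim_dir / "truth.tsv")
        result.write_truth_bed(sim_dir / "truth.bed", "scrofa")
        for s in samples:
            read_sets[s].write(
                sam_path=sim_dir / f"{s}.sam",
                fq1_path=sim_dir / f"{s}_R1.fastq",
                fq2_path=sim_dir / f"{s}_R2.fastq",
            )
        for other in ("cebifrons", "warthog", "bovid"):
            write_pairwise_maf(result, "scrofa", other,
                               sim_dir / f"scrofa_{other}.maf")
        manifest["stages"].append("simulate")

    mt_consensus = result.panel.species["scrofa"]

    # --- scan (assembled genomes) ------------------------------------------
    scan_dir = out / "scan"
    regions_by_genome = {}
    hits_by_genome = {}
    for sp in host.species:
        hits = scan_assembly(
            result.species_genomes[sp],
            result.panel.species.get(sp, mt_consensus),
            config.scoring,
            threshold=config.thresholds.score,
            genome_id=sp,
            min_length=config.thresholds.min_length,
            end_exclusion=config.thresholds.end_exclusion,
            seed_k=config.seed_k,
            xdrop=config.xdrop,
        )
        hits_by_genome[sp] = hits
        regions_by_genome[sp] = build_regions(
            hits, merge_gap=config.thresholds.merge_gap
        )
    if "scan" in stages:
        scan_dir.mkdir(exist_ok=True)
        log("stage scan: %d regions in host genome"
            % len(regions_by_genome["scrofa"]))
        for sp in host.species:
            write_hits_bed(hits_by_genome[sp], scan_dir / f"{sp}.hits.bed")
            write_regions_bed(regions_by_genome[sp],
                              scan_dir / f"{sp}.regions.bed")
        summary = summarize_regions(regions_by_genome["scrofa"], contig_len)
        summary.pop("dotplot")
        (scan_dir / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True) + "\n"
        )
        manifest["stages"].append("scan")

    host_regions = regions_by_genome["scrofa"]

    # --- wgs-scan -----------------------------------------------------------
    wgs_dir = out / "wgs-scan"
    aligned = []
    for i, s in enumerate(samples):
        sam_path = sim_dir / f"{s}.sam"
        if not sam_path.exists():
            sam_path = wgs_dir / f"{s}.sam"
            wgs_dir.mkdir(exist_ok=True)
            read_sets[s].write(sam_path=sam_path)
        aligned.append(SampleAlignment(sam_path, s, seed=seed + i))
    accepted, all_loci = call_insertions(
        aligned, mt_consensus, host_regions,
        thresholds=config.thresholds, scoring=config.scoring,
        karlin_k=config.karlin_k,
    )
    if "wgs-scan" in stages:
        wgs_dir.mkdir(exist_ok=True)
        log("stage wgs-scan: %d loci, %d accepted novel"
            % (len(all_loci), len(accepted)))
        rows = []
        for l in all_loci:
            rows.append({
                "locus": l.locus_id, "contig": l.contig, "pos": l.position,
                "length": l.length, "novel": l.novel,
                "region_id": l.region_id or "",
                "rejection": l.rejection or "",
                "n_datasets": l.n_datasets_present,
                **{f"gt_{sid}": (c.genotype or "")
                   for sid, c in sorted(l.per_sample.items())},
            })
        pd.DataFrame(rows).to_csv(wgs_dir / "loci.tsv", sep="\t", index=False)
        manifest["stages"].append("wgs-scan")

    # --- orthology ----------------------------------------------------------
    orth_dir = out / "orthology"
    statuses = {}
    for r in host_regions:
        statuses[(r.region_id, "scrofa")] = OrthologyStatus.CORRESPONDING
    for other in ("cebifrons", "warthog", "bovid"):
        maf_path = sim_dir / f"scrofa_{other}.maf"
        if not maf_path.exists():
            orth_dir.mkdir(exist_ok=True)
            maf_path = orth_dir / f"scrofa_{other}.maf"
            write_pairwise_maf(result, "scrofa", other, maf_path)
        blocks = read_maf(maf_path, config.thresholds.mismap)
        for r in host_regions:
            status, _proj = map_region_status(
                r, blocks, regions_by_genome[other]
            )
            statuses[(r.region_id, other)] = status
    genotype_cells = {}
    for l in all_loci:
        rid = l.region_id
        if rid is None:
            for r in host_regions:
                if r.start - 100 <= l.position < r.end + 100 and \
                        r.contig == l.contig:
                    rid = r.region_id
                    break
        if rid is None:
            continue
        for sid, c in l.per_sample.items():
            if c.genotype:
                genotype_cells[(rid, sid)] = c.genotype
    order = [r.region_id for r in sorted(host_regions,
                                         key=lambda r: (r.contig, r.start))]
    order += [l.region_id for l in accepted if l.region_id not in order]
    matrix = build_presence_matrix(statuses, order, genotype_cells)
    if "orthology" in stages:
        orth_dir.mkdir(exist_ok=True)
        log("stage orthology: %d x %d presence matrix" % matrix.table.shape)
        matrix.to_tsv(orth_dir / "presence.tsv")
        matrix.to_json(orth_dir / "presence.json")
        manifest["stages"].append("orthology")

    # --- dating -------------------------------------------------------------
    date_dir = out / "date"
    pair_times = {}
    for a in tree.species:
        for b in tree.species:
            if a < b:
                pair_times[(a, b)] = tree.divergence(a, b)
    div_of_host = {sp: tree.divergence("scrofa", sp) for sp in tree.species}
    anc_sus, _ = fitch_ancestral(
        result.panel.species, tree.newick_topology, "sus"
    )
    anc_suinae, _ = fitch_ancestral(
        result.panel.species, tree.newick_topology, "suinae"
    )
    estimates = []
    for r in host_regions:
        pattern = {
            sp: statuses.get((r.region_id, sp)) in (
                OrthologyStatus.CORRESPONDING,
                OrthologyStatus.COMPATIBLE_SEQUENCE,
            )
            for sp in ("scrofa", "cebifrons", "warthog", "bovid")
        }
        cls = assign_age_class(pattern["scrofa"], pattern["cebifrons"],
                               pattern["warthog"], pattern["bovid"])
        genome_seq = result.species_genomes["scrofa"][r.contig]
        frags = [
            Fragment(
                seq=genome_seq[h.target_start:h.target_end],
                mt_start=h.query_start, mt_end=h.query_end,
                identity=h.identity,
            )
            for h in r.hits
        ]
        anc = anc_sus if cls is AgeClass.LE_3P5 else anc_suinae
        estimates.append(date_region(
            r.region_id, cls, frags, result.panel.species, anc, "scrofa",
            div_of_host, pair_times, config.rates, config.divergence,
        ))
    if "date" in stages:
        date_dir.mkdir(exist_ok=True)
        log("stage date: %d regions dated" % len(estimates))
        rows = []
        for est in estimates:
            row = {"region": est.region_id, "class": est.age_class.value,
                   "method": est.method,
                   "age_mya": "" if est.age is None else round(est.age, 3)}
            if est.kimura:
                row.update(K=round(est.kimura.K, 5),
                           v_mt=f"{est.kimura.v_mt:.3e}",
                           **{f"age_{k}": round(v, 2)
                              for k, v in est.kimura.ages_by_rate.items()})
            if est.amr and est.amr.amr is not None:
                row["amr"] = round(est.amr.amr, 4)
            rows.append(row)
        pd.DataFrame(rows).to_csv(date_dir / "ages.tsv", sep="\t", index=False)
        manifest["stages"].append("date")

    # --- population + annotation -------------------------------------------
    pop_dir = out / "popannot"
    if "popannot" in stages:
        pop_dir.mkdir(exist_ok=True)
        group_map = {s: f"grp_{s}" for s in samples}
        table = carrier_frequencies(matrix.table[samples].replace("", np.nan)
                                    if set(samples) <= set(matrix.table.columns)
                                    else matrix.table, group_map)
        ancient = [e.region_id for e in estimates
                   if e.age_class is AgeClass.GT_55]
        fn_rate = estimate_false_negative_rate(ancient, matrix.table[samples]
                                               if set(samples) <= set(matrix.table.columns)
                                               else matrix.table)
        if fn_rate is None:
            fn_rate = 1.0 - config.thresholds.polymorphic
        species_freq = table.frequencies.mean(axis=1)
        polymorphic = call_polymorphic(species_freq, fn_rate)
        newick, _Z, _labels = upgma_cluster(table, min_datasets=1)
        gff_feats = _demo_gff(contig, contig_len)
        (pop_dir / "genes.gff3").write_text(_write_gff3(gff_feats))
        ann = annotate_regions(host_regions,
                               read_gff3(pop_dir / "genes.gff3"), [],
                               result.species_genomes["scrofa"])
        log("stage popannot: fn_rate=%.3f, %d polymorphic"
            % (fn_rate, len(polymorphic)))
        table.frequencies.to_csv(pop_dir / "carrier_freq.tsv", sep="\t")
        (pop_dir / "polymorphic.txt").write_text(
            "\n".join(polymorphic) + ("\n" if polymorphic else "")
        )
        (pop_dir / "fn_rate.txt").write_text(f"{fn_rate:.6f}\n")
        (pop_dir / "upgma.nwk").write_text(newick + "\n")
        export_gff(host_regions, pop_dir / "regions.gff3")
        pd.DataFrame([a.__dict__ for a in ann]).to_csv(
            pop_dir / "annotation.tsv", sep="\t", index=False
        )
        manifest["stages"].append("popannot")

    # --- manifest -----------------------------------------------------------
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            digest = hashlib.sha256(p.read_bytes()).hexdigest()
            manifest["outputs"][str(p.relative_to(out))] = digest
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return manifest
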