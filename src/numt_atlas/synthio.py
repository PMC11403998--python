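"""Synthetic genomes with planted NUMT of known age, and reads thereof.

The generator emulates the study design the pipeline is built for:

* a small ultrametric species tree (divergences at ~3.5, ~10 and ~55 Mya by
  default) along which a circular mtDNA evolves under Kimura's two-parameter
  model at a fast mitochondrial rate;
* nuclear genomes (i.i.d. background at a configurable GC) that evolve at a
  much slower nuclear rate and carry planted NUMT: each insertion copies the
  *ancestral* mtDNA segment as it existed ``age`` Mya on the host lineage and
  then evolves it at the nuclear rate, so sequence degradation is exactly
  age-proportional;
* paired-end reads emitted with an analytic SAM against the reference
  *without* the insertions, so reads crossing an insertion junction carry
  soft-clips whose clipped bases come from the inserted sequence.

Every stochastic choice flows from one integer seed; identical seeds give
byte-identical FASTA/FASTQ/SAM.  A truth table records realised coordinates,
breakpoints, true ages, true allele-matching ratios and per-sample genotypes
for every insertion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from ._seq import decode, encode, revcomp, write_fasta

__all__ = [
    "SpeciesTreeSpec",
    "InsertionSpec",
    "HostSpec",
    "MtPanel",
    "TruthRecord",
    "SimulationResult",
    "ReadSet",
    "default_tree",
    "simulate_mtdna_set",
    "plant_numts",
    "simulate_reads",
    "write_pairwise_maf",
]


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass
class SpeciesTreeSpec:
    """Ultrametric species tree with per-clade divergence times (Mya)."""

    newick_topology: str
    divergence_times: dict[str, float]
    mito_rate: float = 2.0e-8
    nuclear_rate: float = 2.2e-9
    kappa: float = 4.0
    mt_length: int = 16_600

    def __post_init__(self) -> None:
        if self.mito_rate <= 0 or self.nuclear_rate <= 0:
            raise ValueError("rates must be positive")
        if self.mt_length <= 1000:
            raise ValueError("mt_length must exceed 1000 bp")
        self._root = _parse_tree(self.newick_topology, self.divergence_times)

    @property
    def root(self) -> "_Node":
        return self._root

    @property
    def root_age(self) -> float:
        return self._root.age

    @property
    def species(self) -> list[str]:
        return [leaf.name for leaf in self._root.leaves()]

    def path_to(self, species: str) -> list["_Node"]:
        path = self._root.find_path(species)
        if path is None:
            raise KeyError(f"unknown species {species!r}")
        return path

    def divergence(self, a: str, b: str) -> float:
        """Age (Mya) of the most recent common ancestor of two species."""
        if a == b:
            return 0.0
        pa = {id(n): i for i, n in enumerate(self.path_to(a))}
        for node in reversed(self.path_to(b)):
            if id(node) in pa:
                return node.age
        raise KeyError((a, b))


class _Node:
    __slots__ = ("name", "age", "children")

    def __init__(self, name: str, age: float, children: list["_Node"]):
        self.name = name
        self.age = age
        self.children = children

    def leaves(self):
        if not self.children:
            yield self
        for c in self.children:
            yield from c.leaves()

    def find_path(self, leaf_name: str):
        if not self.children:
            return [self] if self.name == leaf_name else None
        for c in self.children:
            sub = c.find_path(leaf_name)
            if sub is not None:
                return [self] + sub
        return None


def _parse_tree(newick: str, times: dict[str, float]) -> _Node:
    tree = dendropy.Tree.get(data=newick, schema="newick")

    def build(node) -> _Node:
        children = [build(c) for c in node.child_nodes()]
        if not children:
            name = node.taxon.label if node.taxon else node.label
            return _Node(str(name).replace(" ", "_"), 0.0, [])
        label = node.label or (node.taxon.label if node.taxon else None)
        if label is None or label not in times:
            raise ValueError(
                f"internal node {label!r} missing from divergence_times"
            )
        age = float(times[label])
        if age <= 0:
            raise ValueError("divergence times must be strictly positive")
        n = _Node(label, age, children)
        for c in children:
            if c.age >= age:
                raise ValueError(
                    f"non-ultrametric tree: node {c.name} (age {c.age}) under "
                    f"{label} (age {age})"
                )
        return n

    return build(tree.seed_node)


def default_tree(
    mito_rate: float = 1.0e-8,
    nuclear_rate: float = 2.2e-9,
    kappa: float = 4.0,
    mt_length: int = 16_600,
) -> SpeciesTreeSpec:
    """Four-taxon scaffold: pig-like, close congener, warthog-like, bovid."""
    return SpeciesTreeSpec(
        newick_topology="(((scrofa,cebifrons)sus,warthog)suinae,bovid)root;",
        divergence_times={"sus": 3.5, "suinae": 10.0, "root": 55.0},
        mito_rate=mito_rate,
        nuclear_rate=nuclear_rate,
        kappa=kappa,
        mt_length=mt_length,
    )


@dataclass
class InsertionSpec:
    """A planted NUMT: where, which mtDNA piece, how old, who carries it."""

    name: str
    host_contig: str
    host_position: int
    mt_start: int
    mt_end: int
    insertion_age: float
    host_species: str = "scrofa"
    wraparound: bool = False
    fragmentation_plan: list[tuple[str, int, int]] = field(default_factory=list)
    genotypes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.insertion_age < 0:
            raise ValueError("insertion_age must be >= 0")
        if self.mt_start < 0:
            raise ValueError("mt_start must be >= 0")
        for g in self.genotypes.values():
            if g not in ("hom_ins", "het", "absent"):
                raise ValueError(f"unknown genotype {g!r}")
        dels = sorted(
            (s, e) for op, s, e in self.fragmentation_plan if op == "del"
        )
        for (s1, e1), (s2, e2) in zip(dels, dels[1:]):
            if s2 < e1:
                raise ValueError("fragmentation deletions overlap")

    def validate_against(self, mt_length: int) -> None:
        if self.mt_start >= mt_length:
            raise ValueError("mt_start beyond mtDNA length")
        if self.mt_end > mt_length and not self.wraparound:
            raise ValueError(
                "mt interval exceeds circular length without wraparound flag"
            )
        if not self.wraparound and self.mt_end <= self.mt_start:
            raise ValueError("empty mt interval")


@dataclass
class HostSpec:
    """Nuclear genome scaffold: contig sizes, base composition, decorations."""

    contigs: dict[str, int]
    gc: float = 0.416
    species: list[str] = field(default_factory=lambda: ["scrofa"])
    repeat_cassettes: list[tuple[str, int, str, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# K80 evolution
# ---------------------------------------------------------------------------

def _k80_probs(rate: float, kappa: float, years: float):
    """(p_transition, p_each_transversion) after ``years`` at total rate."""
    beta = rate / (kappa + 2.0)
    alpha = kappa * beta
    e4b = np.exp(-4.0 * beta * years)
    e2ab = np.exp(-2.0 * (alpha + beta) * years)
    p_ts = 0.25 + 0.25 * e4b - 0.5 * e2ab
    p_tv = 0.25 - 0.25 * e4b
    return p_ts, p_tv


def _evolve(codes: np.ndarray, years: float, rate: float, kappa: float,
            rng: np.random.Generator) -> np.ndarray:
    if years <= 0:
        return codes.copy()
    p_ts, p_tv = _k80_probs(rate, kappa, years)
    u = rng.random(len(codes))
    out = codes.copy()
    out[u < p_ts] ^= 1                                   # transition partner
    out[(u >= p_ts) & (u < p_ts + p_tv)] ^= 2            # transversion 1
    out[(u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)] ^= 3  # transversion 2
    return out


# ---------------------------------------------------------------------------
# mtDNA panel
# ---------------------------------------------------------------------------

@dataclass
class MtPanel:
    """Simulated circular mtDNA per species plus every ancestral sequence."""

    species: dict[str, str]
    ancestors: dict[str, str]
    snapshots: dict[tuple[str, float], str]
    length: int

    def segment(self, seq: str, start: int, end: int, wrap: bool) -> str:
        if wrap or end > self.length:
            end = end if end > start else end + self.length
            doubled = seq + seq
            return doubled[start:end]
        return seq[start:end]


def simulate_mtdna_set(
    tree: SpeciesTreeSpec,
    seed: int | np.random.Generator,
    snapshots: dict[str, list[float]] | None = None,
) -> MtPanel:
    """Evolve one circular mtDNA down the species tree under K80.

    ``snapshots`` requests intermediate sequences at given ages (Mya) on the
    lineage leading to a species; these become available through
    ``MtPanel.snapshots[(species, age)]`` and are what planted NUMT copy.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    snapshots = snapshots or {}
    # assign each requested (species, age) to its branch (parent node id)
    branch_marks: dict[int, list[tuple[str, float]]] = {}
    for sp, ages in snapshots.items():
        path = tree.path_to(sp)
        for age in ages:
            if age > tree.root_age:
                raise ValueError("snapshot age exceeds root age")
            for parent, child in zip(path, path[1:]):
                if child.age < age <= parent.age:
                    branch_marks.setdefault(id(parent), []).append((sp, age))
                    break

    root_codes = rng.integers(0, 4, size=tree.mt_length).astype(np.uint8)
    species: dict[str, str] = {}
    ancestors: dict[str, str] = {tree.root.name: decode(root_codes)}
    snaps: dict[tuple[str, float], str] = {}
    # snapshots exactly at a node age resolve to the node sequence
    node_ages = {}

    def walk(node: _Node, codes: np.ndarray) -> None:
        node_ages[node.name] = node.age
        for child in node.children:
            marks = [
                (sp, age)
                for sp, age in branch_marks.get(id(node), [])
                if tree.path_to(sp)[tree.path_to(sp).index(node) + 1] is child
            ]
            cur = codes
            cur_age = node.age
            for age in sorted({a for _, a in marks}, reverse=True):
                cur = _evolve(cur, (cur_age - age) * 1e6, tree.mito_rate,
                              tree.kappa, rng)
                cur_age = age
                for sp, a in marks:
                    if a == age:
                        snaps[(sp, a)] = decode(cur)
            cur = _evolve(cur, (cur_age - child.age) * 1e6, tree.mito_rate,
                          tree.kappa, rng)
            if child.children:
                ancestors[child.name] = decode(cur)
                walk(child, cur)
            else:
                species[child.name] = decode(cur)

    if not tree.root.children:  # single-taxon degenerate tree
        species[tree.root.name] = decode(root_codes)
    walk(tree.root, root_codes)
    # node-age snapshots requested exactly at a divergence time
    for sp, ages in snapshots.items():
        path = tree.path_to(sp)
        for age in ages:
            if (sp, age) in snaps:
                continue
            for node in path:
                if node.age == age:
                    name = node.name
                    snaps[(sp, age)] = (
                        ancestors[name] if name in ancestors else species[name]
                    )
    return MtPanel(species=species, ancestors=ancestors, snapshots=snaps,
                   length=tree.mt_length)


# ---------------------------------------------------------------------------
# NUMT planting
# ---------------------------------------------------------------------------

@dataclass
class TruthRecord:
    name: str
    contig: str
    ref_position: int
    mt_start: int
    mt_end: int
    wraparound: bool
    age: float
    host_species: str
    length: int
    realised: dict[str, tuple[int, int]]          # species -> nuclear interval
    inserted_seq: dict[str, str]                  # species -> realised sequence
    genotypes: dict[str, str]
    true_amr: float | None


@dataclass
class SimulationResult:
    tree: SpeciesTreeSpec
    panel: MtPanel
    reference: dict[str, str]                     # host background, no NUMT
    species_genomes: dict[str, dict[str, str]]
    sample_haplotypes: dict[str, list[dict[str, str]]]
    truth: list[TruthRecord]
    _sample_layouts: dict[str, list[dict[str, list[tuple[int, int]]]]]

    def haplotype_layout(self, sample: str):
        """Per haplotype, per contig: sorted (ref_position, length) pairs."""
        return self._sample_layouts[sample]

    def write_truth_tsv(self, path) -> None:
        cols = ["name", "contig", "ref_position", "mt_start", "mt_end",
                "age_mya", "host_species", "length", "true_amr", "genotypes",
                "realised"]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for t in self.truth:
                gt = ",".join(f"{k}:{v}" for k, v in sorted(t.genotypes.items()))
                rc = ",".join(
                    f"{sp}:{s}-{e}" for sp, (s, e) in sorted(t.realised.items())
                )
                amr = "NA" if t.true_amr is None else f"{t.true_amr:.4f}"
                fh.write(
                    f"{t.name}\t{t.contig}\t{t.ref_position}\t{t.mt_start}\t"
                    f"{t.mt_end}\t{t.age}\t{t.host_species}\t{t.length}\t"
                    f"{amr}\t{gt}\t{rc}\n"
                )

    def write_truth_bed(self, path, species: str) -> None:
        with open(path, "w") as fh:
            for t in sorted(self.truth, key=lambda t: (t.contig, t.ref_position)):
                if species not in t.realised:
                    continue
                s, e = t.realised[species]
                fh.write(f"{t.contig}\t{s}\t{e}\t{t.name}\t0\t+\n")

    def write_genome_fasta(self, path, species: str) -> None:
        write_fasta(path, sorted(self.species_genomes[species].items()))


def _apply_fragmentation(seq_codes: np.ndarray, mt_coords: np.ndarray,
                         orient: np.ndarray, plan):
    seq, coords, ori = seq_codes, mt_coords, orient
    for op, s, e in plan:
        if not (0 <= s < e <= len(seq)):
            raise ValueError(f"fragmentation interval ({s},{e}) out of range")
        if op == "del":
            keep = np.ones(len(seq), dtype=bool)
            keep[s:e] = False
            seq, coords, ori = seq[keep], coords[keep], ori[keep]
        elif op == "inv":
            seq = seq.copy()
            seq[s:e] = (seq[s:e] ^ np.uint8(3))[::-1]  # reverse complement
            coords = coords.copy()
            coords[s:e] = coords[s:e][::-1]
            ori = ori.copy()
            ori[s:e] = ~ori[s:e]
        else:
            raise ValueError(f"unknown fragmentation op {op!r}")
    return seq, coords, ori


def plant_numts(
    host_spec: HostSpec,
    insertions: list[InsertionSpec],
    tree: SpeciesTreeSpec,
    seed: int,
) -> SimulationResult:
    """Build nuclear genomes carrying the requested NUMT, plus ground truth.

    An insertion of age ``a`` on the host lineage appears in every species
    whose divergence from the host is <= ``a`` (shared ancestor carried it);
    after each divergence the copies evolve independently at the nuclear
    rate.  Per-sample genotypes control which haplotypes of the host-species
    WGS samples carry the insertion.
    """
    ss = np.random.SeedSequence(seed)
    mt_rng, bg_rng, ins_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    for ins in insertions:
        ins.validate_against(tree.mt_length)
        if ins.insertion_age > tree.root_age:
            raise ValueError("insertion age exceeds root age")
        if ins.host_contig not in host_spec.contigs:
            raise KeyError(ins.host_contig)

    snapshots: dict[str, list[float]] = {}
    for ins in insertions:
        snapshots.setdefault(ins.host_species, []).append(ins.insertion_age)
    panel = simulate_mtdna_set(tree, mt_rng, snapshots)

    # nuclear background: root i.i.d. then K80 at the nuclear rate per branch
    gc = host_spec.gc
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A G C T
    root_bg: dict[str, np.ndarray] = {}
    for name, length in sorted(host_spec.contigs.items()):
        root_bg[name] = bg_rng.choice(4, size=length, p=probs).astype(np.uint8)
    for contig, pos, motif, ncopy in host_spec.repeat_cassettes:
        cassette = encode((motif * ncopy))
        root_bg[contig][pos : pos + len(cassette)] = cassette[: max(
            0, len(root_bg[contig]) - pos)]

    species_bg: dict[str, dict[str, np.ndarray]] = {}

    def walk_bg(node: _Node, genome: dict[str, np.ndarray]) -> None:
        for child in node.children:
            years = (node.age - child.age) * 1e6
            evolved = {
                c: _evolve(g, years, tree.nuclear_rate, tree.kappa, bg_rng)
                for c, g in sorted(genome.items())
            }
            if child.children:
                walk_bg(child, evolved)
            else:
                species_bg[child.name] = evolved

    if tree.root.children:
        walk_bg(tree.root, root_bg)
    else:
        species_bg[tree.root.name] = root_bg

    # per-insertion realised sequences per carrier species
    carrier_sets: dict[str, list[str]] = {}
    ins_seqs: dict[str, dict[str, np.ndarray]] = {}
    ins_meta: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for ins in insertions:
        snap = panel.snapshots[(ins.host_species, ins.insertion_age)]
        seg = panel.segment(snap, ins.mt_start, ins.mt_end, ins.wraparound)
        codes = encode(seg)
        coords = (np.arange(ins.mt_start, ins.mt_start + len(codes))
                  % tree.mt_length)
        orient = np.zeros(len(codes), dtype=bool)  # False = forward
        codes, coords, orient = _apply_fragmentation(
            codes, coords, orient, ins.fragmentation_plan
        )
        carriers = [
            sp for sp in host_spec.species
            if sp == ins.host_species
            or tree.divergence(ins.host_species, sp) <= ins.insertion_age
        ]
        carrier_sets[ins.name] = carriers
        ins_meta[ins.name] = (coords, orient)
        # evolve down the host subtree below the insertion age
        per_species: dict[str, np.ndarray] = {}
        path = tree.path_to(ins.host_species)
        # node just below the insertion point on the host path
        sub = next(n for n in path if n.age <= ins.insertion_age)

        def walk_ins(node: _Node, codes_in: np.ndarray, top_age: float) -> None:
            cur = _evolve(codes_in, (top_age - node.age) * 1e6,
                          tree.nuclear_rate, tree.kappa, ins_rng)
            if not node.children:
                if node.name in carriers:
                    per_species[node.name] = cur
                return
            for child in node.children:
                walk_ins(child, cur, node.age)

        walk_ins(sub, codes, ins.insertion_age)
        ins_seqs[ins.name] = per_species

    # realised genomes
    species_genomes: dict[str, dict[str, str]] = {}
    realised: dict[str, dict[str, tuple[int, int]]] = {i.name: {} for i in insertions}
    by_contig = sorted(insertions, key=lambda i: (i.host_contig, i.host_position))
    for sp in host_spec.species:
        genome = {}
        for contig in sorted(host_spec.contigs):
            parts = []
            cursor = 0
            offset = 0
            bg = species_bg[sp][contig]
            for ins in by_contig:
                if ins.host_contig != contig or sp not in carrier_sets[ins.name]:
                    continue
                parts.append(bg[cursor : ins.host_position])
                seq = ins_seqs[ins.name][sp]
                start = ins.host_position + offset
                realised[ins.name][sp] = (start, start + len(seq))
                parts.append(seq)
                offset += len(seq)
                cursor = ins.host_position
            parts.append(bg[cursor:])
            genome[contig] = decode(np.concatenate(parts)) if parts else ""
        species_genomes[sp] = genome

    # per-sample haplotypes (host species background + genotype-dependent NUMT)
    samples = sorted({s for ins in insertions for s in ins.genotypes})
    sample_haps: dict[str, list[dict[str, str]]] = {}
    sample_layouts: dict[str, list[dict[str, list[tuple[int, int]]]]] = {}
    for sample in samples:
        haps = []
        layouts = []
        for hap_i in (0, 1):
            genome = {}
            layout: dict[str, list[tuple[int, int]]] = {}
            for contig in sorted(host_spec.contigs):
                parts = []
                cursor = 0
                lay = []
                host_sp = None
                for ins in by_contig:
                    if ins.host_contig != contig:
                        continue
                    gt = ins.genotypes.get(sample, "absent")
                    carried = gt == "hom_ins" or (gt == "het" and hap_i == 0)
                    if not carried:
                        continue
                    host_sp = ins.host_species
                    bg = species_bg[host_sp][contig]
                    parts.append(bg[cursor : ins.host_position])
                    seq = ins_seqs[ins.name][host_sp]
                    parts.append(seq)
                    lay.append((ins.host_position, len(seq)))
                    cursor = ins.host_position
                if host_sp is None:
                    host_sp = insertions[0].host_species if insertions else (
                        host_spec.species[0])
                bg = species_bg[host_sp][contig]
                parts.append(bg[cursor:])
                genome[contig] = decode(np.concatenate(parts))
                layout[contig] = lay
            haps.append(genome)
            layouts.append(layout)
        sample_haps[sample] = haps
        sample_layouts[sample] = layouts

    # truth records (amr against the nearest ancestral node above the age)
    truth = []
    host0 = insertions[0].host_species if insertions else host_spec.species[0]
    reference = {c: decode(species_bg[host0][c]) for c in sorted(host_spec.contigs)}
    for ins in by_contig:
        coords, orient = ins_meta[ins.name]
        h = ins.host_species
        amr = None
        if h in ins_seqs[ins.name]:
            path = tree.path_to(h)
            anc_node = None
            for node in reversed(path[:-1]):
                if node.age >= ins.insertion_age:
                    anc_node = node
                    break
            if anc_node is not None:
                anc = panel.ancestors[anc_node.name]
                modern = panel.species[h]
                numt = decode(ins_seqs[ins.name][h])
                denom = num = 0
                for i, (c, o) in enumerate(zip(coords, orient)):
                    if o:
                        continue  # skip inverted positions
                    a_b, m_b = anc[c], modern[c]
                    if a_b == m_b:
                        continue
                    denom += 1
                    if numt[i] == m_b:
                        num += 1
                amr = num / denom if denom else None
        seq_len = len(coords)
        truth.append(
            TruthRecord(
                name=ins.name,
                contig=ins.host_contig,
                ref_position=ins.host_position,
                mt_start=ins.mt_start,
                mt_end=ins.mt_end,
                wraparound=ins.wraparound,
                age=ins.insertion_age,
                host_species=h,
                length=seq_len,
                realised=realised[ins.name],
                inserted_seq={
                    sp: decode(s) for sp, s in sorted(ins_seqs[ins.name].items())
                },
                genotypes=dict(ins.genotypes),
                true_amr=amr,
            )
        )

    return SimulationResult(
        tree=tree,
        panel=panel,
        reference=reference,
        species_genomes=species_genomes,
        sample_haplotypes=sample_haps,
        truth=truth,
        _sample_layouts=sample_layouts,
    )


# ---------------------------------------------------------------------------
# read simulation with analytic SAM
# ---------------------------------------------------------------------------

@dataclass
class ReadSet:
    sam_text: str
    fastq1: str
    fastq2: str
    expected_breakpoints: list[tuple[str, int]]
    n_pairs: int

    def write(self, sam_path=None, fq1_path=None, fq2_path=None) -> None:
        if sam_path:
            open(sam_path, "w").write(self.sam_text)
        if fq1_path:
            open(fq1_path, "w").write(self.fastq1)
        if fq2_path:
            open(fq2_path, "w").write(self.fastq2)


def _segments(ref_len: int, layout: list[tuple[int, int]]):
    """Alternating (hap_start, hap_end, is_insertion, ref_pos) segments."""
    segs = []
    cursor_ref = 0
    cursor_hap = 0
    for ref_pos, length in sorted(layout):
        if ref_pos > cursor_ref:
            segs.append((cursor_hap, cursor_hap + ref_pos - cursor_ref,
                         False, cursor_ref))
            cursor_hap += ref_pos - cursor_ref
            cursor_ref = ref_pos
        segs.append((cursor_hap, cursor_hap + length, True, ref_pos))
        cursor_hap += length
    if cursor_ref < ref_len:
        segs.append((cursor_hap, cursor_hap + ref_len - cursor_ref,
                     False, cursor_ref))
    return segs


def _map_read(s: int, e: int, segs):
    """Map haplotype interval [s, e) to (ref_start, cigar) or None.

    The longest reference-matching piece anchors the alignment; haplotype
    bases outside it (inserted sequence or past a junction) are soft-clipped.
    """
    pieces = []
    for hs, he, is_ins, ref_pos in segs:
        if he <= s or hs >= e:
            continue
        ps, pe = max(hs, s), min(he, e)
        pieces.append((ps, pe, is_ins, ref_pos + (ps - hs) if not is_ins else -1))
    ref_pieces = [p for p in pieces if not p[2]]
    if not ref_pieces:
        return None
    anchor = max(ref_pieces, key=lambda p: (p[1] - p[0], -p[0]))
    left = anchor[0] - s
    mid = anchor[1] - anchor[0]
    right = e - anchor[1]
    cigar = ""
    if left:
        cigar += f"{left}S"
    cigar += f"{mid}M"
    if right:
        cigar += f"{right}S"
    return anchor[3], cigar, left, mid, right


_ERR_SUB = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}


def simulate_reads(
    haplotypes: list[dict[str, str]],
    reference: dict[str, str],
    layouts: list[dict[str, list[tuple[int, int]]]],
    depth: float,
    read_len: int = 100,
    insert_size: int = 300,
    error_rate: float = 0.0,
    seed: int = 0,
    sample_name: str = "s",
    weights: list[float] | None = None,
) -> ReadSet:
    """Paired-end reads from haplotypes, mapped analytically to ``reference``.

    ``weights`` (default uniform) set the haplotype mixing proportions, which
    is how pooled samples and heterozygous genotypes are represented.  The
    SAM is emitted against the reference *without* insertions, so junction
    reads carry soft-clips.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    ref_total = sum(len(s) for s in reference.values())
    for hap in haplotypes:
        for contig, seq in hap.items():
            if read_len > len(seq):
                raise ValueError("read_len exceeds contig length")
    if insert_size < read_len:
        raise ValueError("insert_size must be >= read_len")

    rng = np.random.default_rng(seed)
    n_pairs = int(round(depth * ref_total / (2 * read_len)))
    w = np.asarray(weights if weights is not None else [1.0] * len(haplotypes),
                   dtype=float)
    w = w / w.sum()
    contigs = sorted(reference)
    clens = np.array([len(reference[c]) for c in contigs], dtype=float)
    cprob = clens / clens.sum()

    header = ["@HD\tVN:1.6\tSO:unsorted"]
    for c in contigs:
        header.append(f"@SQ\tSN:{c}\tLN:{len(reference[c])}")
    sam_lines = list(header)
    fq1, fq2 = [], []
    segs_cache: dict[tuple[int, str], list] = {}

    hap_idx = rng.choice(len(haplotypes), size=n_pairs, p=w)
    contig_idx = rng.choice(len(contigs), size=n_pairs, p=cprob)
    u_start = rng.random(n_pairs)

    for i in range(n_pairs):
        hi = int(hap_idx[i])
        contig = contigs[int(contig_idx[i])]
        hap_seq = haplotypes[hi][contig]
        span = len(hap_seq) - insert_size
        if span <= 0:
            frag_start = 0
            frag_end = len(hap_seq)
        else:
            frag_start = int(u_start[i] * span)
            frag_end = frag_start + insert_size
        key = (hi, contig)
        if key not in segs_cache:
            segs_cache[key] = _segments(
                len(reference[contig]), layouts[hi].get(contig, [])
            )
        segs = segs_cache[key]

        name = f"{sample_name}:{i}"
        r1_ival = (frag_start, frag_start + read_len)
        r2_ival = (frag_end - read_len, frag_end)
        recs = []
        for mate, (s, e) in enumerate((r1_ival, r2_ival)):
            fwd = hap_seq[s:e]
            if error_rate > 0:
                errs = np.nonzero(rng.random(read_len) < error_rate)[0]
                if len(errs):
                    lst = list(fwd)
                    for p in errs:
                        lst[p] = _ERR_SUB[lst[p]][int(rng.integers(3))]
                    fwd = "".join(lst)
            m = _map_read(s, e, segs)
            recs.append((mate, s, e, fwd, m))

        mapped = [r for r in recs if r[4] is not None]
        both = len(mapped) == 2
        for mate, s, e, fwd, m in recs:
            other = recs[1 - mate]
            flag = 0x1 | (0x40 if mate == 0 else 0x80)
            if mate == 1:
                flag |= 0x10
            else:
                flag |= 0x20
            if m is None:
                flag |= 0x4
            if other[4] is None:
                flag |= 0x8
            if both:
                flag |= 0x2
            rname = contig
            rnext = "="
            if m is not None:
                ref_start, cigar, left, mid, right = m
                pos = ref_start + 1
            elif other[4] is not None:
                # unmapped read placed at its mapped mate's coordinate
                cigar = "*"
                pos = other[4][0] + 1
            else:
                cigar = "*"
                pos = 0
                rname = rnext = "*"
            pnext = other[4][0] + 1 if other[4] is not None else pos
            tlen = 0
            if both:
                a0 = recs[0][4][0]
                a1 = recs[1][4][0] + recs[1][4][3]
                tlen = (a1 - a0) if mate == 0 else -(a1 - a0)
            seq_out = fwd  # SAM stores the forward-reference orientation
            sam_lines.append(
                f"{name}\t{flag}\t{rname}\t{pos}\t"
                f"{0 if m is None else 60}\t{cigar}\t{rnext}\t{pnext}\t{tlen}\t"
                f"{seq_out}\t{'I' * read_len}"
            )
            read_seq = fwd if mate == 0 else revcomp(fwd)
            fq = fq1 if mate == 0 else fq2
            fq.append(f"@{name}/{mate + 1}\n{read_seq}\n+\n{'I' * read_len}")

    breakpoints = sorted({
        (contig, ref_pos)
        for hi, layout in enumerate(layouts)
        for contig, lay in layout.items()
        for ref_pos, _len in lay
    })
    return ReadSet(
        sam_text="\n".join(sam_lines) + "\n",
        fastq1="\n".join(fq1) + ("\n" if fq1 else ""),
        fastq2="\n".join(fq2) + ("\n" if fq2 else ""),
        expected_breakpoints=breakpoints,
        n_pairs=n_pairs,
    )


# ---------------------------------------------------------------------------
# exact pairwise MAF for genome pairs
# ---------------------------------------------------------------------------

def write_pairwise_maf(
    result: SimulationResult,
    species_a: str,
    species_b: str,
    path,
    unaligned_intervals: dict[str, list[tuple[int, int]]] | None = None,
) -> None:
    """Emit the exact whole-genome alignment of two simulated genomes.

    Shared background columns align one-to-one; an insertion present in only
    one genome appears as a gap run in the other row.  ``unaligned_intervals``
    (reference background coordinates) punch holes in block coverage to
    emulate unalignable regions; blocks are split around them.
    """
    unaligned = unaligned_intervals or {}
    ga, gb = result.species_genomes[species_a], result.species_genomes[species_b]

    def ins_events(contig):
        ev = []
        for t in result.truth:
            if t.contig != contig:
                continue
            in_a = species_a in t.realised
            in_b = species_b in t.realised
            if not (in_a or in_b):
                continue
            la = t.realised[species_a][1] - t.realised[species_a][0] if in_a else 0
            lb = t.realised[species_b][1] - t.realised[species_b][0] if in_b else 0
            ev.append((t.ref_position, t.name, la, lb, in_a, in_b))
        return sorted(ev)

    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for contig in sorted(result.reference):
            ref_len = len(result.reference[contig])
            holes = sorted(unaligned.get(contig, []))
            cuts = [0]
            for s, e in holes:
                cuts.extend([s, e])
            cuts.append(ref_len)
            events = ins_events(contig)
            for seg_i in range(0, len(cuts) - 1, 2):
                seg_s, seg_e = cuts[seg_i], cuts[seg_i + 1]
                if seg_e <= seg_s:
                    continue
                rows_a, rows_b = [], []
                # coordinates of seg_s in each genome
                off_a = sum(la for p, _n, la, lb, ia, ib in events
                            if p <= seg_s and ia)
                off_b = sum(lb for p, _n, la, lb, ia, ib in events
                            if p <= seg_s and ib)
                a_start, b_start = seg_s + off_a, seg_s + off_b
                cursor = seg_s
                pos_a, pos_b = a_start, b_start
                for p, _name, la, lb, in_a, in_b in events:
                    if p <= seg_s or p >= seg_e:
                        continue
                    rows_a.append(ga[contig][pos_a : pos_a + (p - cursor)])
                    rows_b.append(gb[contig][pos_b : pos_b + (p - cursor)])
                    pos_a += p - cursor
                    pos_b += p - cursor
                    cursor = p
                    if in_a:
                        rows_a.append(ga[contig][pos_a : pos_a + la])
                        pos_a += la
                    if in_b:
                        rows_b.append(gb[contig][pos_b : pos_b + lb])
                        pos_b += lb
                    if in_a and not in_b:
                        rows_b.append("-" * la)
                    if in_b and not in_a:
                        rows_a.append("-" * lb)
                    if in_a and in_b and la != lb:
                        # shared insertion evolved only by substitution keeps
                        # equal length; unequal lengths arise only from
                        # per-genome fragmentation, not modelled here
                        raise ValueError("shared insertion length mismatch")
                rows_a.append(ga[contig][pos_a : pos_a + (seg_e - cursor)])
                rows_b.append(gb[contig][pos_b : pos_b + (seg_e - cursor)])
                pos_a += seg_e - cursor
                pos_b += seg_e - cursor
                text_a = "".join(rows_a)
                text_b = "".join(rows_b)
                size_a = pos_a - a_start
                size_b = pos_b - b_start
                fh.write("a score=0\n")
                fh.write(
                    f"s {species_a}.{contig} {a_start} {size_a} + "
                    f"{len(ga[contig])} {text_a}\n"
                )
                fh.write(
                    f"s {species_b}.{contig} {b_start} {size_b} + "
                    f"{len(gb[contig])} {text_b}\n\n"
                )
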