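# Methods

This note records the models, parameter choices and numerical decisions
behind numt-atlas, in the spirit of a methods supplement: what is computed,
under which assumptions, and what the synthetic validation does and does
not demonstrate.

## Local alignment of mtDNA to nuclear sequence

NUMT detection rests on local alignment of the circularised mtDNA (the
sequence concatenated with itself, so homology crossing the origin is one
match) against nuclear contigs under a distant-homology scheme: match +1,
mismatch −1, affine gaps costing 7 to open plus 1 per base. These weights
deliberately tolerate the ~40–50% divergence of ancient insertions, where
steeper schemes truncate alignments.

Two execution paths share one scoring engine (a Gotoh dynamic program,
numba-compiled):

* for small problems (≤ 250k matrix cells) the full DP runs and
  non-overlapping local alignments are peeled off in score order, so the
  best hit is provably optimal — this is exercised directly by tests that
  compare against an independently written Smith–Waterman;
* at genome scale, exact 11-mers seed candidate regions (seeds chained
  within 100 bp on ±50-diagonal bands), and each region is rescored by the
  same DP on a padded window. The window grows geometrically while the
  optimal alignment touches its border, bounded by an absolute pad of
  16 kb and 3·10⁷ cells; this makes heavily diverged copies (55 Mya,
  ~55% identity) extend to their full length, which a fixed X-drop pad
  would truncate.

**End trimming.** The local-DP optimum happily wanders into flanking
sequence through marginal segments (e.g. net +1 over nine random columns);
symmetrically, it can end mid-way through a mismatch-dense but genuine
terminal region. Reported hit *intervals* are therefore trimmed: from each
end, the terminal segment (up to 30 columns and a third of the alignment)
whose cumulative score stays furthest below half the perfect-match rate is
removed (the cut point minimises 2·net(k) − k·match). The hit *score*
remains the untrimmed DP optimum — thresholding and the optimality
invariant refer to the optimum, coordinates to the trimmed core. On
simulated insertions this keeps boundary error within ±2 bp for
high-identity (≲ 2 Mya) copies; ends of older copies are intrinsically
ambiguous by a few bases because terminal mismatches make any boundary
choice arbitrary.

**Threshold calibration.** Aligning the reversed-without-complementation
mtDNA — which cannot be homologous to anything — bounds the spurious score
distribution; the threshold is one more than the best spurious score,
floored at the default 30 so the pipeline never becomes more permissive
than the published protocol. On a random 1-Mb genome the calibrated value
is 30 (spurious maxima sit near 20–26).

**Low-complexity masking** drops hits whose target interval is > 50%
covered by short-period tandem repeats (period ≤ 6 sustained ≥ 12
repeat-matching positions, homopolymers included). This is a deterministic
approximation of DUST/postmask-style filtering; it removes poly-A and
(AT)n artifacts without touching shuffled-sequence controls.

**E-values** use the ungapped Karlin–Altschul form E = K·m·n·e^(−λS) with λ
solved from 0.25e^λ + 0.75e^(−λ) = 1 (λ = ln 3 for the ±1 scheme) and K a
configured constant (default 0.1). Only the monotone structure matters
downstream (the clip filter threshold at 1e-4); the E-values are not
calibrated to any particular aligner's statistics.

## Region building

Hits < 20 kb apart on one contig merge into a region (single-linkage),
reflecting the interpretation that nearby fragments descend from one
insertion later fragmented by rearrangement. Regions are labelled
`CONTIG_REGION_k` in coordinate order. A region is *complex* when two
member hits re-use the same mtDNA interval (> 50 bp overlap — a
duplication) or when mixed strands coincide with overlapping mtDNA
intervals; mixed strands alone set an inversion flag. Mean region identity
is length-weighted so short noisy fragments do not dominate. Hits within
1 kb of contig ends are excluded (assembly quality), as are hits < 30 bp.

## WGS insertion calling

Breakpoints are read directly from CIGAR soft-clips: a left clip marks the
alignment start, a right clip the alignment end; both junctions of a
non-reference insertion collapse onto (nearly) the same reference
coordinate. Support requires ≥ 3 reads clipped by ≥ 7 nt. The depth guard
accepts breakpoints whose mean depth over a ±200 bp window (about one
insert size; the published description names no width) lies within
[6, d + 4√d], d being the sample's trimmed-mean depth over up to 1000
random 1-kb windows. Both bounds are inclusive; R1 rejection is strict
(< 0.75), homozygosity strict (> 0.80), heterozygosity the closed band
[0.30, 0.80] — the endpoint conventions are choices where the published
wording is ambiguous. Reads are deduplicated by (name, flag) before any
counting. Clips shorter than the 11-bp seed are skipped during
mtDNA matching: a clip that short cannot reach the E-value bar
(score ≥ ~16 needed at E < 1e-4) regardless.

Note a consequence of both junctions sharing one coordinate: for a
heterozygous insertion longer than the read length, the expected R2 is
2/3 rather than 1/2 (the carrier haplotype contributes clipped reads from
*two* junctions into one pileup, the reference haplotype spanning reads
from one locus). The published genotype bands accommodate this; simulated
genotype accuracy at 20–30× exceeds 0.9.

Pooled samples are genotyped carrier/non-carrier only, and the R2
rejection is waived for them, since a pool mixes many genotypes.

Insertion sequence assembly is a greedy overlap-layout-consensus (minimum
overlap 20 bp at ≥ 90% identity, substring absorption first); a contig that
absorbed no other read is flagged fragmentary.

## Orthology and the presence matrix

Whole-genome alignment is consumed, not computed: blocks arrive as
pairwise MAF (the simulator emits exact MAF for its genome pairs) and are
filtered at mismap ≤ 1e-5. A region's columns are projected through the
blocks: overlap with a called region in the partner genome ⇒
CORRESPONDING; complete, gapless projection onto uncalled sequence ⇒
COMPATIBLE_SEQUENCE, promoted to a region (the detection false-negative
correction; promotion is idempotent); gap-only projection ⇒ PRIVATE
(insertion absent — polymorphism candidate); no covering block ⇒
UNALIGNED. Partial gappy projections without a region match are reported
PRIVATE, the conservative reading.

For distant species, orthology requires ≥ 50% of the up-to-ten flanking
genes to be syntenic (orthologs present in the partner context in a
consistent order — measured as the longest monotone run of mapped
positions) and reciprocal mtDNA-interval overlap strictly above 40%
(smaller interval as denominator); fewer than four comparable genes is
undetermined.

## Insertion dating

**Age classes** follow the presence pattern: sharing with a bovid ⇒
> 55 Mya; with the warthog but no bovid ⇒ 10–55; within the genus but not
the warthog ⇒ 3.5–10; single-lineage ⇒ ≤ 3.5. A copy private to the
warthog lineage arose there after the ~10 Mya split and is assigned the
3.5–10 class. A bovid copy with no Suinae copy contradicts the
single-origin premise and is reported undetermined.

**Method 1 (allele matching ratio)** applies to the two youngest classes
when the summed fragment length exceeds 150 bp and mean identity exceeds
80%. The ancestral mtDNA is reconstructed by Fitch parsimony on the fixed
species topology (sites whose final state set is ambiguous are excluded
from the counts). Among alignment columns where ancestral and modern
differ, amr is the fraction where the NUMT sides with the modern allele;
age = (1 − amr)·T with T = 3.5 or 10 Mya. Multi-fragment regions sum the
counts across fragments before forming the ratio. Parsimony is a
deliberate simplification of likelihood reconstruction; on simulated
panels it recovers ≥ 95% of unambiguous ancestral sites at the 3.5-Mya
node, and its residual bias is absorbed in the recovery tolerances below.

**Method 2 (Kimura distance)** serves older or degraded regions, on the
longest fragment > 150 bp. K80 distance K = −½ ln((1−2P−Q)√(1−2Q)) with
pairwise deletion; a non-positive logarithm argument means saturation and
the region is undatable. The species with the smallest NUMT distance marks
the insertion point; K averages distances to the clade of species whose
divergence from the host does not exceed that species' (an alternative
minimum-distance-only rule is available behind `clade_rule="distance"`,
since the published clade wording admits both readings). The per-region
mitochondrial rate is V_mt = mean over species pairs of K_pair/(2·T_pair)
— the printed form of this average is typographically ambiguous
(K/2·T vs K/(2T)); the implementation uses K/(2T), the only reading with
rate units. Ages are reported under three nuclear rates (mammalian
2.2e-9, ruminant 2.48e-9, pig-pedigree 1.2e-9 per site/year; the mammalian
rate is the default for calculated ages). Saturated pairs are skipped in
the V_mt average, which matters for deep outgroup pairs.

D-loop-derived fragments (mtDNA interval > 50% inside the annotated
control region) are excluded from both methods, because ancestral D-loop
states are unreliable.

## Population statistics and annotation

Carrier frequency is the fraction of informative datasets carrying the
insertion (genotypes het/hom/carrier; undetermined cells leave the
denominator). Assembled genomes enter the combined matrix with
CORRESPONDING/COMPATIBLE_SEQUENCE as carriers, PRIVATE as non-carriers,
UNALIGNED excluded. Ancient (> 55 Mya) regions predate all speciations, so
every dataset must carry them; 1 − their mean carrier fraction estimates
the detection false-negative rate, and a region is polymorphic when its
species-wide frequency is strictly below 1 − that rate (fallback: the
configured 0.97). UPGMA clustering uses scipy's average-linkage on
Euclidean distances between group frequency vectors (groups with < 10
datasets excluded; per-region mean imputation of missing cells; newick
heights are half the cophenetic distance).

Annotation classifies regions against GFF3 with precedence exon > UTR >
intron > intergenic (exon outranking UTR is a documented choice; the
source protocol leaves it implicit), reports the closest gene by signed
distance, repeat classes within 1 kb, and GC over ±1 kb flanks. Repeat
enrichment is a two-sided Fisher exact test on nucleotide counts (flanks
vs genome), per repeat class, with raw p-values (no multiplicity
correction, matching the original single pooled report).

## The synthetic-data generator

`synthio` is first-class, tested code, and defines the validation
conditions:

* **Species tree**: ultrametric, default four taxa with divergences at 3.5
  (congener), 10 (warthog) and 55 Mya (bovid); dating studies add an
  outgroup at 75 Mya so insertions up to 60 Mya lie on an internal branch.
* **Substitution model**: Kimura two-parameter with κ = 4 (a typical
  mammalian mtDNA transition bias), no indels; mitochondrial rate
  1e-8 substitutions/site/year (whole-molecule phylogenetic scale),
  nuclear rate 2.2e-9. Keeping the mtDNA indel-free makes the truth
  allele-matching ratio exactly countable by column comparison;
  rearrangement enters only through explicit fragmentation plans
  (deletions and inversions of the inserted copy).
* **NUMT planting**: an insertion of age a copies the mtDNA snapshot at a
  on the host lineage and evolves at the nuclear rate; every species that
  diverged from the host no earlier than a inherits the copy and continues
  independently. Per-sample genotypes (hom/het/absent) control the two
  haplotypes of each WGS individual.
* **Nuclear background**: i.i.d. bases at 41.6% GC (pig-like), evolved
  along the tree at the nuclear rate, with optional overwritten repeat
  cassettes for annotation tests.
* **Reads**: fixed-length paired-end fragments placed uniformly,
  substitution errors only, and an *analytic* SAM against the
  insertion-free reference: each read maps by its longest
  reference-matching piece, the rest soft-clipped — exactly the signal the
  caller consumes, without an external mapper. Mates are emitted in the
  conventional FR orientation; fully-inserted reads are unmapped records
  placed at the mate.

What passing tests therefore show: the *logic* of every stage — scoring,
filtering, thresholds, grouping, projection, dating algebra — is correct
against enumerable truth. What they do not show: robustness to real-data
phenomena the generator omits — site-rate heterogeneity and selection on
mtDNA (which make real ancient NUMT far more alignable than uniform-rate
theory predicts), indels and sequencing-machine error profiles, mapping
artifacts of a real aligner, target-site duplications at insertion
junctions, and repeat landscapes beyond planted cassettes.

## Problem sizes and reproducibility

The shipped validation runs at desk scale: genomes of 0.1–1 Mb, mtDNA of
16.6 kb, 20× coverage, 2–3 samples, 8–20 replicate seeds per recovery
study — sizes at which every stage's behaviour is already asymptotic while
a full run stays in minutes on one core. All randomness flows from
explicit integer seeds through numpy Generators (per-stage streams derived
by SeedSequence spawning); rerunning any stage or the full demo pipeline
with one seed reproduces every output byte for byte, which the manifest's
SHA-256 digests certify.

## Known limitations

* The aligner's reported intervals are heuristically end-trimmed (see
  above); scores are exact optima but boundaries of diverged hits carry a
  few bases of uncertainty.
* Fitch parsimony underestimates ancestral states in regions of high rate
  or deep divergence; method-1 dating is accordingly restricted to young,
  high-identity regions.
* E-values are scheme-level approximations, not calibrated to LAST or
  BLAST statistics.
* The complex-region rule is purely structural (duplication/inversion of
  mtDNA coordinates); no visual dot-plot judgement is emulated, though
  dot-plot coordinates are exported.
* Pooled-sample support is carrier/non-carrier only; allele frequencies
  within pools are not modelled.
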