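# Methods

`allcll` re-creates, as an open and testable pipeline, the analysis workflow
of an integrated capture-NGS assay for chronic lymphocytic leukemia (CLL):
full-length IGH/IGL V(D)J rearrangement reconstruction with somatic
hypermutation (SHM) status, stereotyped-subset and IGLV3-21 R110 calling,
log2-ratio copy-number calling of the four recurrent CLL lesions, and
VAF-tiered somatic variant filtering. This note records the models, the
parameters that matter, the numerical conventions, and the known limits.

## V(D)J reconstruction from soft-clipped reads

Capture panels tile both sides of an IG rearrangement junction at high depth
(2×300 bp paired ends, ~1500× on target), so an aligner maps junction-spanning
reads to the germline V or J segment and soft-clips the bases from the joined
partner. Reconstruction proceeds in four steps:

1. **Soft-clip harvest.** Every soft clip of ≥ `min_clip` (10 nt) on a read
   with MAPQ ≥ 20 over an IG target becomes junction evidence, with the clip
   coordinate converted to a segment-local offset in reading orientation
   (minus-strand segments flip the clip side and reverse-complement the clip).
2. **Breakpoint clustering.** Single-linkage clustering of evidence sharing
   segment and clip side within a ±5 nt window; clusters below `min_support`
   (3 reads) are discarded; the modal breakpoint breaks ties to the smallest
   offset.
3. **Two-sided consensus.** The V-side sequence is the germline V up to the
   breakpoint, overwritten by the per-column majority vote of aligned read
   bases wherever covered (this is what carries SHM into the assembly), plus
   the column-aligned vote over the right-clip bases. The J side is the vote
   over left-clip bases plus germline J from its breakpoint. Voting ties are
   resolved deterministically (A<C<G<T) and flagged.
4. **Placement join.** The J-side consensus is placed at the offset within
   the V-side consensus that maximizes the overlap subject to a Hamming
   mismatch rate ≤ 5% over ≥ 20 nt. V-side clip consensus extending past the
   J 3′ end (reads running into downstream germline flank) is discarded.
   If no placement qualifies, no candidate is produced; V-only/J-only
   clusters are reported as unjoined counts, never as a clonal result.

Candidates are ranked by `support × log2(1 + length) × mean_MAPQ/60`, ties
lexicographic by (V, J) name; the top candidate is the clonal rearrangement.

With 300-nt reads over a ~350–400 nt rearrangement plus 400-nt flanks, the
two consensi always overlap by far more than 20 nt, which is why a mate-pair
bridge path is not needed on this geometry.

## Germline assignment and percent identity

Allele assignment uses an affine-gap local alignment (match +1, mismatch −2,
gap of length k costs 6 + k; Bio.Align.PairwiseAligner) of every candidate
allele against the assembled sequence. The aligned span is then extended
1:1, without gaps, to the query 5′ start and to the allele 3′ end for V
(anchoring the evaluated span at FR1 and treating the allele body as global),
and to the shared 3′ end for J. The best allele is chosen by alignment
score — identity alone is degenerate, because a wrong allele can produce a
short 100 %-identity core under local alignment — with ties broken by
identity, fewest gapped columns, then name.

Percent identity is `100 · matches / (matches + mismatches + gap columns)`
over the evaluated span, each inserted or deleted base counting as one
column, rounded **half-up to two decimals** before any classification. The
98.00 % cutoff separates unmutated (≥ 98.00, adverse prognosis) from mutated;
97.00–97.99 % is flagged borderline. Rounding before classification is what
makes the borderline band well-defined at its upper edge.

When a rearrangement has trimmed the V 3′ end, a few untemplated junction
bases may be attributed to V by the allele-global convention — an inherent
ambiguity of junction analysis shared by all annotators, since a mutated
breakpoint-adjacent base and an untemplated base are indistinguishable. The
simulator's default V 3′ trim is therefore 0 (V exonucleolytic trimming is
small and uncommon relative to D/J trimming), keeping simulated truth
identity well-defined; D and J trims and N-insertions default to 0–4/0–6 and
0–10 nt.

D genes are assigned by the best ungapped match (both orientations) within
the junction, reported only at ≥ 5 nt and ≥ 80 % identity — junction-analysis
practice, since short junction matches are otherwise noise.

## CDR3, productivity, subsets, R110

The junction runs from the conserved Cys-104 codon (an annotated offset on
each V allele) through the Trp/Phe-118 codon of the J, both mapped through
the alignment; CDR3 is the junction minus both anchors. A rearrangement is
productive iff the anchor-to-anchor length is ≡ 0 mod 3, both anchor residues
are intact, and the V-through-J translation is stop-free. An anchor mapped
into a gap or mutated away yields `missing_anchor`; an out-of-frame junction
still reports the nucleotide CDR3.

Stereotyped subsets are matched against a user-supplied definitions table
(subset id, allowed V genes allele-agnostic, exact CDR3 amino-acid length,
position-indexed motif with wildcards and alternative sets, mismatch budget).
Length and V-gene gates are necessary conditions; among passing definitions
the fewest motif mismatches wins. The bundled table contains synthetic test
definitions only — canonical subset definitions are a curated external
resource and must be supplied for real data; the file's version string is
echoed into every report.

R110 is the arginine-creating point mutation at IMGT position 110 of the
IGLV3-21 λ junction. The position-110 codon is carried as an annotated
offset on IGLV3-21 alleles (avoiding a full IMGT-numbering implementation);
after IGL reconstruction and allele assignment the codon is translated from
the assembly. A codon that is truncated, gapped, or covered by fewer than 10
reads is `indeterminate` — the gate is deliberately asymmetric so low
coverage can never produce a false negative. A best V hit other than
IGLV3-21 reports `not_IGLV3-21` and skips the analysis.

## Copy-number calling

Per-target mean depths (duplicates and MAPQ < 20 excluded) are divided by
the per-target median of a panel of normals when one is given. Centring is
robust and two-pass: first on the median of per-region medians, then on the
pooled targets of regions whose provisional median ratio is within ±0.1
log2 of that centre. Plain global-median centring is biased when a clonal
lesion spans a fifth of the backbone and would erode the margin to the
calling threshold; the two-pass scheme keeps log2 ratios unbiased for up to
two lesioned regions per sample (with three or more simultaneous deletions
the centring degrades — a known limitation).

Calls use the median log2 ratio per region with ≥ 3 informative targets:
deletion at ≤ −0.2 for del(17p)/del(11q)/del(13q), gain at ≥ +0.15 for
trisomy 12; a direction gate forbids the opposite state per region. Clonal
fraction inverts the expected single-copy ratios: `f = 2(1 − 2^m)` for
deletions and `f = 2(2^m − 1)` for trisomy, clipped to [0, 1], so a full
clonal deletion sits at log2 −1.0 and a full trisomy at +0.585.

The uniformity QC gate is the IQR of backbone log2 ratios after subtracting
each region's own median (a spread-not-shift statistic in the spirit of
derivative-log-ratio spread); samples above 0.5 yield no CNA calls at all,
mirroring assays that withhold CNA results below a coverage-uniformity
confidence threshold. The numeric threshold of the commercial comparator is
unpublished; 0.5 on this metric is this package's stated substitute.

## Variant calling and VAF tiers

The pileup caller is a reference implementation whose role is to make the
filter tiers and the end-to-end pipeline testable: per-position allele
counts from bases with quality ≥ 20 on MAPQ ≥ 20 reads over driver targets,
SNVs and simple CIGAR indels emitted at ≥ 5 alternate reads, VAF = alt/depth.
Externally produced VCFs can be fed directly to the filter stage. Tiers:
VAF < 2 % → filtered (`below_vaf_cutoff`); 2–3 % → `low_confidence`
(cross-run reproducibility is only complete at ≥ 3 %); ≥ 3 % → pass.
Qualifying depth < 100 forces filtered status. Defaults reflect ~1500×
panel coverage. Pathogenicity classification and manual review are out of
scope.

## The synthetic-data generator

The simulator is the package's test bed and defines the conditions under
which every property is measured:

- **Reference world.** Synthetic germline segments with realistic geometry —
  V 300–312 nt in frame 0 with the Cys anchor at the FR3 end, D 12–27 nt
  (generated stop-free in all frames so forced-productive junctions are
  satisfiable), J 48 nt with the W/F anchor at offset 9; IGLV3-21*04/*02
  differ at two diagnostic positions and carry the annotated position-110
  codon (germline GGG). These are not IMGT-licensed sequences. The panel
  has 200 probe-sized (120 nt) backbone targets per CNA region plus 200
  neutral ones — the density at which a 200-target median resolves f = 0.3
  lesions at the default thresholds — and 5 driver targets.
- **Rearrangements.** V(D)J concatenation with seeded trims and N-insertions,
  SHM as uniform substitutions over the V portion at the closest achievable
  count ≥ the identity target, junction frame-padding and bounded retries
  for forced productivity. Truth (segments, trims, mutations, junction
  coordinates) is recorded and reconstructable.
- **Reads.** Pre-aligned paired 2×300 bp SAM records over the rearranged
  molecule (400 nt germline flanks), soft-clipped analytically at the
  junction; substitution-only errors at a constant rate with flat Q30
  qualities; fragment length N(500, 50); coverage calibrated so the interior
  plateau matches the requested depth. Identical seed and parameters give
  byte-identical SAM.
- **CNAs and variants.** Per-target depth multipliers 1 − f/2 (deletion) and
  1 + f/2 (trisomy) with mean-1 lognormal noise of the requested CV; variant
  spiking flips each overlapping read independently with probability VAF
  (SNVs, insertions and deletions via CIGAR surgery) and records the
  realized fraction.

What the simulator does **not** model — and what passing tests therefore do
not establish for real data: alignment artifacts of a real aligner
(mismapping, chimeric splits, supplementary alignments), indel sequencing
errors and quality-dependent error profiles, PCR duplicates and UMI
structure, GC- and capture-efficiency bias beyond per-target noise,
subclonal rearrangement mixtures, and real IGHV gene-family cross-similarity
(synthetic V alleles are mutually random, so allele discrimination is easier
than in the true IGHV locus). Cohort-level concordance with FISH/Sanger is
not reproducible here; the test suite instead pins operating
characteristics on this generator.

## Problem sizes and numerical conventions

Property checks run at desk scale: 100 seeded rearrangement simulations per
recovery property (depth 35–100), 50 for R110, 100 profiles per CNA
operating point, 200 pairs for the identity-oracle equivalence, with all
seeds fixed. Reports serialize with sorted keys; every tie-break in the
pipeline (cluster modal breakpoint, consensus votes, allele and subset
selection, candidate ranking) is deterministic, so a rerun on identical
input is byte-identical. Coordinates are 0-based half-open internally;
1-based coordinates appear only in VCF export.
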