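# Methods

## Model and procedure

The pipeline treats a small-RNA library as a set of collapsed read
sequences, each carried as one record per genomic mapping with two integer
attributes: `count` (total abundance of the sequence in the library) and
`n_mappings` (number of genomic loci the sequence maps to). All interval
arithmetic is 0-based half-open; GFF input is converted at the boundary.
Sequences are stored uppercase as RNA (T and U equivalent on input).

Processing order:

1. **Multimapper filter.** Reads with `n_mappings` > 50 are removed. A
   parallel "unique" subset (`n_mappings` == 1) is kept so that all
   downstream analyses can be run on the all-read and unique-read
   populations independently. The filter is idempotent.
2. **rRNA exclusion.** Any read overlapping an annotated rRNA interval by
   ≥1 nt is removed. The overlap is strand-agnostic by default (the most
   permissive removal is the conservative choice for downstream classes);
   `stranded=True` restricts removal to same-strand overlap.
3. **Clustering.** Single-linkage merge per scaffold: consecutive mappings
   at most 150 nt apart (gap, not centre distance) join one cluster,
   strand-agnostically, since sense and antisense products of one precursor
   belong together. Retained clusters need ≥3 distinct
   (scaffold, start, end, strand, sequence) tuples that are not all
   perfectly overlapping, and a span ≥51 bp. "Span" is interpreted as
   cluster extent, not summed read coverage (configurable elsewhere would
   add little: at ≥3 non-identical reads the two rarely disagree). When the
   distinct-read minimum is explicitly lowered to 1, the
   non-perfect-overlap clause is vacuous and single-read clusters are
   allowed.
4. **Uniformity index.** UI = total count / distinct reads, ≥1 by
   construction, equal to 1 exactly when every distinct read is a
   singleton. UI grows with sequencing depth, so UI / library depth is
   reported alongside; depth counts each distinct sequence once however
   many loci it maps to. The HU/LU threshold defaults to raw UI ≥ 3.0,
   chosen so the two reference examples (UI 5.3 vs 1.3) fall on opposite
   sides with margin; a quantile mode (top q of the library's UI
   distribution) is available when depth varies strongly across libraries.
5. **Classification.** Clusters overlapping known miRNA, tRNA or snoRNA
   annotation by ≥1 nt are labelled by overlap, with precedence
   known_miRNA > tRNA > snoRNA, and bypass length-peak rules. Otherwise the
   modal read length L (count-weighted; ties to the shorter length) is
   looked up in the preset peak sets, and the class is assigned only when
   the summed abundance over L−1..L+1 strictly exceeds the summed abundance
   of every other length — equality leaves the cluster unclassified. The
   halo always uses L±1 even when L±1 falls outside the class's peak set.
   In the mnemiopsis preset, L = 26 is eligible for both piRNA (26-28) and
   25-mer (24-26); the class whose full peak set carries more summed
   abundance wins, ties to piRNA. This disambiguation is this package's own
   rule and is flagged as such. HU clusters at Dicer lengths become
   `miRNA_candidate_HU`: high-uniformity 20-22 nt loci are dominated by
   miRNA, tRNA, snoRNA and rDNA loci and deserve review, not a silent
   endo-siRNA call.
6. **Signatures.** Bias matrices anchor reads at the 5' end; position p
   holds each base's percentage among reads covering p (count-weighted by
   default; a distinct-read mode exists because either convention is
   defensible). Positions with no covering read are missing, not zero.
   Ping-pong: positive iff U is modal at position 1 with ≥40% and A modal
   at position 10 with ≥35%. Downstream-G: positive iff mean G% beyond
   position 25 exceeds 1.25× the mean G% over positions 2-25; if no read
   extends past position 25 the result is indeterminate. These numeric
   thresholds replace what is usually a visual read of bias plots; they
   were set to recover clearly planted signatures while keeping the
   simulated uniform null below a 5% false-positive rate, and all three are
   configurable.
7. **Structure.** The cluster span is folded on the strand(s) its reads come
   from; mixed clusters fold both strands and keep the lower MFE, with ties
   going deterministically to the plus strand. The folding engine is a
   contract: the ViennaRNA thermodynamic folder (max base-pair span 150,
   matching the cluster window) when its bindings import, else a built-in
   Nussinov-style minimiser over proxy energies (−1.0 GC, −0.7 AU, −0.5 GU,
   minimum hairpin loop 3, same span cap) accelerated with numba. MFE is
   clamped to ≤0 (the open chain is always available). Whichever engine is
   active scores both the native sequence and its shuffles. Significance:
   dinucleotide-preserving shuffles (Altschul-Erickson Eulerian-walk;
   dinucleotide rather than mononucleotide shuffling preserves stacking
   statistics, the standard null for RNA MFE) and
   p = (1 + #{shuffle MFE ≤ native}) / (N + 1), N = 100 by default. The
   add-one convention bounds p in [1/(N+1), 1]; ties count against
   significance, which makes the test slightly conservative on the
   discrete energy grid of the built-in engine.
8. **Genomic context.** Exon/intron/UTR intervals overlapping a predicted
   transposon by ≥1 nt are masked out first. A cluster is attributed to
   every element class whose interval union covers ≥51% of the cluster
   span (union, not single interval — the stricter single-interval reading
   would split credit across adjacent exons arbitrarily); clusters meeting
   no class are intergenic. Multi-assignment is deliberate: per-class
   percentages may total slightly over 100 where the genome encodes
   overlapping element types. Single-label summaries use the precedence
   exon > utr5 > utr3 > intron > transposon_known > transposon_unknown.
   Overlap enrichment against a reference locus set is a permutation test:
   cluster intervals are re-placed uniformly within their scaffolds with
   lengths preserved, and the add-one empirical p-value is reported.
9. **cis-NATs and co-expression.** A gene is cis-NAT iff it overlaps a gene
   on the opposite strand by ≥1 nt (symmetric). For co-expression, clusters
   are called per stage and loci matched across stages by ≥1-nt span
   overlap; a locus expressed at ≥`min_expression` (default 1) in k stages
   yields C(k,2) links, by default only when the same class (endo-siRNA or
   piRNA) is expressed in both stages.

## Synthetic data

The generator emulates the statistical structure that separates the
classes, not the biology that produces it:

* scaffolds are i.i.d. uniform DNA (3 × 50 kb by default) with cassettes
  placed at randomised gaps;
* miRNA loci are 75-nt hairpins whose 3' arm is an imperfect (15% mutated)
  reverse complement, emitting one dominant 22-mer (Poisson mean 120), a
  rarer star read from the other arm, and five ±2-nt variants of count 1.
  The star read is what carries the cluster span past the 51-bp minimum —
  as in real miRNA clusters, where mature and star reads map across the
  hairpin. Expected UI is far above the HU threshold;
* endo-siRNA loci are 120-nt hairpins emitting 30 distinct 20-22-nt reads
  from both strands, counts 1-2 (UI near 1.2, structured precursor);
* piRNA loci are unstructured 400-nt regions with T/A/G anchor positions
  every 7 nt (read-relative positions 1, 10, 26-27); read starts are drawn
  from anchors with probability 0.6, other T positions up to a cumulative
  0.8, else uniformly, yielding ~85% 1U and ~75% 10A with a downstream-G
  tail. Lengths 26-28;
* 25-mer loci are 300-nt regions with T anchors only (~85% 1U, no 10A, no
  structure), lengths 24-26;
* two transposon families (one piRNA-type, one endo-siRNA-type) are pasted
  verbatim at 4 loci each, so every read from them occurs at exactly 4
  genomic sites and `n_mappings` is computed by literal occurrence
  counting — no aligner involved;
* genes have UTR/exon/intron structure; cis-NAT pairs are opposite-strand
  single-exon genes overlapping by 200 nt with an endo-siRNA hairpin inside
  the overlap; tRNA loci emit high-uniformity fragments and rRNA loci emit
  degradation-like fragments destined for the rRNA filter;
* each locus is expressed in a random subset of 4 stages (p = 0.7 per
  stage, at least one).

What passing tests on this generator do **not** show: robustness to
sequencing error, untemplated 3' tailing, partial mappability, repeat
families with internal divergence, or annotation noise — planted reads are
exact genome substrings and planted signals are strong by construction.
The generator demonstrates that the rules recover the classes they define
when the class-separating signal is present, and that the statistical
tests are calibrated under their nulls.

## Numerical choices and degenerate inputs

* Peak-length ties break toward the shorter length (deterministic).
* UI is stored at full precision; reports round to 2 dp (1 dp where a
  reference value is quoted to 1 dp).
* Empty length histograms, empty read sets, zero library depth and folding
  of non-ACGU sequences raise immediately rather than propagating NaNs.
* Homopolymers shuffle to themselves, so their shuffle-test p is exactly 1.
* A cluster longer than its scaffold is skipped (with a warning) by the
  permutation test, which cannot place it.
* Per-cluster shuffle seeds are derived as `seed × 1000003 + index` modulo
  2³¹ over position-sorted clusters, so runs are reproducible and
  independent of dict ordering.
* Clusters longer than `max_fold_span` (default 2000 nt) are not folded;
  their fold columns are NA.

## Problem sizes

Default test and demonstration runs use 3 × 50 kb genomes with ~56 planted
loci and four stages (~1,000-1,600 read records per stage), 100 shuffles
for significance, 1,000 permutations for enrichment, and 200-replicate
calibration loops. These sizes give stable pass/fail behaviour for every
statistical property tested while keeping a full run on one CPU in the
minutes range; all are parameters, not constants.

## Known limitations

* The built-in folding engine maximises weighted base pairs; it is a
  consistent ranking device for native-vs-shuffle comparison, not a
  thermodynamic model. Absolute MFEs are only comparable within one engine.
* Known-locus annotation is any-overlap (≥1 nt); a long cluster clipping
  the edge of a tRNA is labelled tRNA even if most of its mass lies
  elsewhere.
* The 25-mer/piRNA disambiguation at 26 nt and the HU threshold are
  package conventions (documented above), not field standards.
* Cross-stage locus identity is by span overlap after per-stage calling;
  a joint-calling mode would merge ragged stage-specific boundaries
  differently.
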