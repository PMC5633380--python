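# Methods

This note documents the models behind `ecckit`, the parameters that matter,
the design choices made where the method description left room, and what the
simulation-based tests do and do not demonstrate about real data.

## Tn5 tagmentation model

Tn5 transposase cuts double-stranded DNA leaving a 9-nt staggered overhang;
fill-in during the first PCR cycle copies those 9 bases to both sides of the
insertion. We model cut sites as a homogeneous Poisson process along each
molecule with rate `cut_rate` (per bp, default 1/500 — a 500-bp mean
fragment in the standard regime). Real Tn5 has sequence-dependent insertion
bias; modeling it is out of scope, and the homogeneous process is the
simplest defensible null.

For a linear molecule, a cut at position p produces a left fragment ending
at p + d and a right fragment starting at p (d = `dup_len`, default 9), so
consecutive fragments share exactly d terminal bases and total fragment
length is L + d·cuts. Cut positions are restricted to [1, L − d] so the
duplicated segment always fits. For a circular molecule the cut count is
Poisson conditioned on ≥ 1 (an uncut circle is never sequenced); a single
cut linearizes the circle into one molecule of length L + d whose first d
bases equal its last d bases. The laboratory "attenuated" tagmentation
(short incubation) is modeled as exactly one cut per circle rather than as
a shorter exposure time, because the duplication signature is defined for
the single-cut case; the multi-cut regime remains reachable through
`cut_rate` with `attenuated=False`.

Reads are error-free by default (R1 = first `read_length` bases of the top
strand, R2 = same from the bottom strand read inward); an optional uniform
substitution rate exists for robustness experiments but is off everywhere
signature detection is validated, keeping the 4⁻⁹ chance-positive bound
analytic.

## Signature detection

A pair is evidence for a singly tagmented circle iff
`R1[0:d] == revcomp(R2[0:d])`. The inward orientation follows from standard
paired-end chemistry; a `same`-orientation switch exists for nonstandard
preps. Exact matching is the default; a ≤ k-mismatch mode exists for
error-bearing data but voids the analytic false-positive bound. The
signature fraction uses *all* input pairs as its denominator. Detection is
deliberately alignment-free: the statistic is computable straight from
FASTQ, before any mapping decisions.

## Enrichment-pool model

Biochemical circle enrichment (exoV digestion, CsCl banding) is reduced to
one parameter: linear molecules are destroyed with probability ε
(`linear_removal`), covalently closed circles always survive. Nicked or
relaxed circles are not distinguished from closed ones — that split is
biochemical, not computational — and no published calibration ties ε to
residual linear DNA after digestion, so ε is a free simulation parameter
(ε = 0 is the total-genomic control; ε → 1 a strongly enriched fraction).
Reads are allocated multinomially across sources by molecular mass
(length × copies, linear sources down-weighted by 1 − ε). Linear background
pairs sequence the two ends of a random genomic fragment (fixed fragment
length, default 400 bp) and therefore carry no shared duplication; circle
pairs sequence the ends of a singly cut linearization and always do. A
declared mitochondrion is a small chromosome marked circular, sampled like
any other circle at `mito_copies` relative abundance.

## k-mer placement and classification

The index stores every position of every canonical k-mer (lexicographic min
of the k-mer and its reverse complement); k defaults to 31, a standard odd
choice that avoids reverse-complement-palindromic k-mers. k-mers containing
N are skipped. A read's placement set is recovered by anchoring on its
first k-mer and verifying the full read against the genome at each implied
position — equivalent to exact full-read matching on both strands, which is
what makes the brute-force oracle equivalence provable. A
fraction-of-consistent-k-mers relaxation for error-bearing reads is
deliberately not the default.

Classification is a pure function of the placement set and the focal range
(default 300 kb): one placement → unique; several on one chromosome with
outermost-start span ≤ range → focal repeat; span > range →
intrachromosomal repeat; multiple chromosomes → dispersed repeat; empty →
unplaceable. Growing the focal range can only reclassify intrachromosomal
as focal, never anything else. For positional tracks, unique reads count at
their placement and focal reads at their span midpoint (deterministic and
unbiased within the family); intrachromosomal and dispersed reads appear in
composition summaries only, having no single defensible location. A read
*pair* is classified by its more-repetitive placeable mate
(unique < focal < intrachromosomal < dispersed), the conservative choice.
Positional deduplication of aligned pairs keys on both mates' start/stop
coordinates and, by default, strands; strand-awareness is a switch since
conventions differ between pipelines.

## Enrichment statistics

Given bin counts s_i (sample, total S) and c_i (control, total C):

* **Fold**: `(s_i/S)/(c_i/C)`; a pseudocount (0.5, on both counts) enters
  only when c_i = 0, keeping folds finite while preserving monotonicity.
  Bins with s_i = c_i = 0 are untestable and skipped.
* **Robustness**: "enrichment robust to binomial sampling noise" is
  operationalized as the fold recomputed from the Wilson 95% lower limit of
  s_i/S and the Wilson upper limit of c_i/C. This bound is ≤ the point fold,
  is 0 when s_i = 0, and converges to the point fold as depth grows. The
  minimum-fold threshold (default 4) is applied to this lower bound — the
  stricter of the two possible readings.
* **Significance**: exact two-tailed binomial p with the minimum-likelihood
  tail construction (sum of all outcome probabilities ≤ that of the
  observation), null p₀ = c_i/C (pseudocount-adjusted when c_i = 0). For
  large S the summation runs over a ±60 SD window with explicit tail
  corrections; the result matches `scipy.stats.binomtest` to 10⁻⁶ relative
  (scipy remains the independent cross-check in the tests, not the
  implementation, and the windowed form is vastly faster on large grids).
* **Correction**: Bonferroni familywise control, α divided by the number of
  tested bins, is the default; a per-gene variant with per-test threshold
  α/(2·n_genes) is available for gene-centric maps. The alternative fold
  threshold of 2 used with the per-gene policy is selectable. A doubled
  smaller-tail p-value variant was considered and rejected in favor of the
  single minimum-likelihood definition to keep one canonical number per bin.

Bin sizes: 1 kb suits a ~100-Mb (worm-scale) genome and is the default;
25 kb suits human-scale genomes. Replicate agreement is the Pearson
correlation of log₁₀(count + 1) across bins; the mitochondrial internal
control is the fold enrichment of the whole mitochondrial chromosome as a
single interval.

## Simulation study sizes

Desk-scale problem sizes used throughout the test suite, chosen once as
realistic miniatures of a whole-genome experiment:

* Recovery study: 2 × 500 kb nuclear chromosomes + 14 kb circular
  mitochondrion; three 2-kb circles planted at 10 copies; enriched library
  ε = 0.999 at 3×10⁴ pairs vs control ε = 0 at 10⁵ pairs; 1-kb bins. Under
  these conditions every planted circle bin is called, no distant bin is,
  and the mitochondrial fold exceeds 10.
* Null calibration: sample and control drawn from the same uniform
  multinomial (1,000 bins, 10⁵ reads each, 200 replicates); the familywise
  false-call rate under (fourfold, Bonferroni α = 0.05) stays within the
  α = 0.05 budget.
* Replicate agreement: two independently seeded ε = 0.999 libraries of
  6×10⁴ pairs, 10-kb bins (the 100-kb bins appropriate for a 3-Gb genome,
  scaled to the ~1-Mb simulated one); r > 0.9.
* Classification oracle equivalence: 100 seeded 10-kb genomes with planted
  families of every category, using a proportionally reduced focal range
  (2 kb) so that intrachromosomal repeats exist at this scale; the 300-kb
  default is exercised directly in the rule-level tests.

## What the simulations do and do not show

The simulator emulates the *topological and combinatorial* structure of a
circle-enrichment experiment: duplication mechanics, mixture composition,
exoV-style depletion, repeat architecture. It does not emulate sequencing
error profiles, PCR duplication beyond copy numbers, adapter read-through,
Tn5 insertion bias, chimeric molecules, or partially degraded circles.
Passing tests therefore demonstrate correctness of the statistics and the
detection logic under the stated model — not robustness to every artifact
of real libraries. For real data, alignment is expected to come from an
external aligner (the built-in exact mapper is a test oracle, not an
aligner), and the mismatch-tolerant switches exist precisely because exact
matching is optimistic there.

## Degenerate inputs and numerical notes

Empty read sets raise undefined-statistic errors rather than returning 0.
Circular molecules store an explicit rotation; rotation-invariant equality
lives only in test helpers so serialization stays deterministic. Reads from
a circle that span the circle junction have no linear-genome placement and
are counted unplaceable — a known, small (~read_length/circle_length)
coverage loss at planted-circle edges. All randomness flows through
explicit seeds; every simulator output is byte-identical under a fixed
seed. p-values are clamped to [0, 1]; ties in the minimum-likelihood tail
are resolved with a 1 + 10⁻⁷ relative tolerance, matching common practice.

## Known limitations

Junction-spanning reads are discarded rather than split-mapped, so circle
boundaries are resolved only to bin resolution; no merging of adjacent
significant bins beyond simple adjacency, and no per-base breakpoint
refinement. The fold saturates at the library-composition ratio when a
circle is abundant in the control, so very-high-copy circles in weakly
enriched samples can fall below the fourfold gate — an inherent property of
ratio-based calling, not an implementation artifact.
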