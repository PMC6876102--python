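# Methods

This note records the models implemented in `plexsig`, the parameters
that matter, what the synthetic data emulate (and do not), and the
numerical choices made where the design was genuinely open.

## Data model

A complex is an ordered set of fragments (0-based, half-open BED
coordinates) on one chromosome. Parsing groups fragments by barcode,
splits barcodes spanning several chromosomes into per-chromosome
sub-complexes (all tests are intra-chromosomal), and merges overlapping
or book-ended fragments. Neighboring distances are floored at 1 bp so
the probability vector `p = x / d_tot` is always defined; the floor only
matters for degenerate inputs that bypassed parse-time merging.

## Distance test

* **Null.** Per chromosome, every neighboring distance goes into a
  bucket *B*; a class-*j* expected complex is *j−1* draws from *B* with
  replacement. Only the sorted totals and the mean normalized entropy
  per class are stored. `sample_size` defaults to 100,000 (10,000 in
  SPRITE mode, whose complexes reach 500 fragments). One RNG stream is
  derived per (chromosome, class) from the base seed, so per-chromosome
  parallelism cannot change results.
* **Raw p-value.** The proportion (count / sample size) of expected
  complexes with strictly smaller total distance. Zero p-values are
  allowed; no pseudo-count is added.
* **Multiplicity.** BH step-up per (chromosome, fragment class), FDR
  0.1. Significance is `adjusted p ≤ FDR`.
* **First-pass routing.** Significant → `pass1`; insignificant `F_2` →
  `fail1` (a two-fragment complex cannot be a split candidate);
  optionally complexes above `max_frags_fail` fragments → `fail1`
  (100 in SPRITE mode); the rest → `defer`.
* **Entropy filter.** Threshold = mean normalized entropy of the class's
  expected complexes, recomputed per chromosome — in clean data the
  threshold is high and the filter aggressive; in noisy data the null
  itself is low-entropy and the filter conservative. Cuts: left-most
  largest gap; second cut at the second-largest gap when
  `second ≥ largest/τ` (τ default 2). Sub-complexes keep the parent ID
  with `.k` suffixes; singletons are recorded but never tested. A
  sub-complex falling into a class with no observed member draws its
  null from the same bucket on demand.
* **Behavioral note.** The test is *relative*: it asks whether a complex
  is compact compared to the dataset's own distance mixture. Under a
  mixture of compact complexes and all-large-gap noise, a class-*j*
  compact complex has raw p ≈ φ^(j−1)·U with φ the small-gap share of
  the bucket and U uniform; per-class BH therefore admits a class
  essentially entirely or not at all, at 2·φ^(j−1) ≤ FDR (φ = 1/2 at a
  50/50 mix ⇒ j ≥ 6 at FDR 0.1). Conversely, in homogeneous data with
  little long-range contamination almost nothing is "significantly
  compact" — matching the intuition that significance requires noise to
  stand out from.

## TAD calling

* Complexes are first cut at gaps > `max_gap` (100 kb for *Drosophila*;
  1 Mb preset for mouse/human), then each complex adds its fragment
  count *n* to every bin its span overlaps (1-kb bins by default). This
  keeps high-fragment complexes linear rather than quadratic
  contributors.
* Smoothing: multilevel DWT (`bior1.1`, level 3, symmetric extension),
  detail coefficients zeroed, reconstruction cropped to the input length
  and clamped at 0. Tracks too short for the requested level fall back
  to the maximal level with a warning.
* Segmentation: maximal runs above a signal floor (default 5% of the
  positive-bin median) become TAD candidates; candidates shorter than
  `min_tad_bins` are dropped; regions between consecutive TADs are
  explicit gaps (TADs and gaps interleave by construction).
* **Edge refinement.** The Haar-like level-3 approximation is
  block-constant over ~8-bin blocks, so thresholding the smoothed track
  places edges up to 2^level bins off. Each candidate edge is therefore
  snapped to the raw-track support — the outermost bin above a tenth of
  the floor within ±2^level bins. Genuine domain edges ramp up from
  zero, so the support boundary is the better coordinate estimate; the
  lower refinement floor matters because the ramp crosses the full floor
  several bins inside the domain.
* The caller is intended to run on *de-noised* (significant) complexes;
  on raw noisy input the uniform background lifts gap bins above any
  relative floor.

## Inter-TAD binomial test

Combinations are counted per complex ("occurrence-weighted"); `a` counts
pair appearances within the class including the combination itself, `b`
counts strict supersets with their occurrence multiplicities. The trial
count `k` is the class-wise sum of `x`, the null success probability
`1/|G_j|` with `|G_j|` the number of distinct combinations in the class,
and the alternative one-sided (greater). BH at FDR 0.1 is pooled across
all combinations. No normalization for TAD distance or size is applied —
closer and larger TADs are expected to interact more, and that bias is
accepted as a known limitation.

## Enrichment test

Coverage is binned (10 bp): a bin's value is the coverage-weighted mean
of overlapping bedGraph intervals with uncovered base pairs contributing
zero. A fragment's score is the simple mean over the bins it overlaps (a
deliberate lookup approximation; the binned score deviates from exact
integration by at most the signal variation within one bin). Placements
of the shifted complex are restricted so the whole complex stays
in-bounds — unrestricted shifts could push fragments past the chromosome
end. Ties use the strict `>` of the indicator, so constant coverage
degenerates to p = 0 for every complex (a warning is emitted for
all-zero tracks rather than silent significance). Repeat-masked
fragments can be removed beforehand; complexes left with fewer than two
fragments are dropped.

## SPRITE pre-processing

Reads on the target chromosome are de-duplicated with a greedy
left-to-right sweep against the previously *retained* read (≥10 kb),
matching the intent of removing PCR-duplicate pileups, then extended to
1-kb fragments; clusters outside 2–500 fragments are dropped. The
cluster-file dialect is configurable because released formats vary.

## Synthetic data: study conditions

The generator emulates droplet/barcode data with known truth; defaults
are fixed once:

* fragment count per complex `n = 2 + Poisson(8)` (mean 10). High-count
  complexes carry the structural signal, and the per-class admission
  bound above means discrimination experiments are only informative in
  classes j ≥ 6; a mean of 10 places most complexes there while keeping
  a realistic spread down to n = 2;
* fragment length Normal(500, 100) bp floored at 100 bp (typical mapped
  ChIA-Drop fragment scale);
* intra-complex gaps log-uniform over one decade from 1 kb, giving
  non-degenerate probability vectors with entropies well above typical
  null thresholds;
* default chromosome 20 Mb with eight planted TADs of 100–500 kb
  separated by 60–200 kb gaps (fly-arm scale);
* multiplets concatenate complete, independently drawn singlets from
  TADs separated by ≥ 20× the largest intra-complex gap (co-encapsulation
  produces whole spurious complexes, not stray fragments);
* enrichment tracks: gamma-distributed baseline (mean 1) plus Gaussian
  peaks (default 10 peaks, width 2 kb, height 30); peak-bound complexes
  anchor every fragment near peak centers, background complexes have
  compact geometry at uniform positions. The noisy baseline keeps the
  placement null continuous — on a noise-free flat background every
  background complex ties the null and the strict indicator would let
  all of them pass.

What the generator does **not** emulate: mappability/GC bias, chromatin-
state-dependent contact decay, inter-chromosomal contacts, barcode
collision structure beyond whole-complex multiplets, or read-level
artifacts. Recovery rates on these fixtures demonstrate algorithmic
correctness under the stated conditions, not performance on real
libraries.

Problem sizes used by the acceptance script: 10,000 complexes (30%
doublets) for the entropy-filter rates; 20,000 complexes (50% uniform
noise, null sample size 10,000) for distance-test discrimination; 4,000
complexes on a 5-Mb chromosome with five planted TADs for TAD recovery;
2,000 complexes with 1,000 placements each on a 2-Mb chromosome for the
enrichment rates. These sizes give stable rates (Monte-Carlo spread
well under the margins asserted) at a few seconds of runtime.

## Known limitations

* The distance test assumes intra-class independence for BH and treats
  the per-chromosome bucket as exchangeable; strong regional coverage
  gradients violate both.
* Entropy-based splitting can only produce 1–3 sub-complexes; ≥4-plets
  are split at most once per pass.
* TAD calls have no hierarchy/nesting and no insulation-style score.
* The inter-TAD test does not model distance or TAD size.
* The enrichment null is computationally heavy on large genomes
  (linear in complexes × placements), by design of the empirical
  approach.
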