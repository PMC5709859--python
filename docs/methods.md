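# Methods

## Problem and scope

Polytene chromosomes of *Drosophila* salivary glands carry two kinds of
H3K27me3-enriched domains distinguished by their response to loss of the
SUUR (Suppressor of Under-Replication) protein: *SuUR*-sensitive regions
(SSRs), whose moderate wild-type signal collapses in the mutant and which
are essentially free of Polycomb, and *SuUR*-non-sensitive regions
(SNRs), which keep a high signal in both genotypes and coincide with
Polycomb (Pc) binding. chromoshift re-implements the computational side
of that comparison as a reusable, tested pipeline: signal normalization,
joint two-genotype HMM segmentation, DamID-seq fragment scoring with FDR
peak calling, and region-level statistics, validated end-to-end on a
synthetic genome with planted domains.

Coordinates are 0-based half-open (BED-native) everywhere; the
`GenomicInterval` constructor is the single shared validator. bedGraph is
the track interchange format (line-oriented, diffable); missing bins are
explicit NaN, never zero-filled, because 0 is a meaningful log-ratio.

## Synthetic-data generator

The generator defines the study conditions; every acceptance check runs
against it.

* **Genome**: 2 chromosomes × 10 Mb, 100-bp bins (default).
* **Domains**: 20 SSRs and 15 SNRs with log-normal lengths (shape 0.4)
  around class means of 214 kb (SSR, the published average) and 120 kb
  (SNR — a free choice; the source analysis states only that SNRs carry
  "high" signal, and ~100-kb Pc domains are typical). Lengths are clipped
  below at 30 kb so every planted domain is callable under the span rule,
  snapped to the bin grid, placed without overlap and with at least one
  background bin between domains, assigned to chromosomes proportionally
  to free space.
* **ChIP tracks**: per-bin class mean plus i.i.d. Gaussian noise
  (σ = 0.3), two replicates per genotype. Class means: SSR 0.41 (wt) /
  −0.06 (mut) — the published characterization; SNR 1.5 in both
  genotypes (free parameter, "high" signal); background 0. σ = 0.3 is a
  calibration choice making recovery nontrivial but feasible; no probe
  noise SD is published. No spatial autocorrelation is simulated — the
  HMM transition structure supplies persistence, and the planted means
  are identifiable under the i.i.d. model.
* **GATC fragments**: exponential inter-site spacing, mean 256 bp,
  tiling each chromosome exactly. (When a real FASTA is supplied,
  `damid.gatc_fragment` scans the sequence exactly instead; GATC is its
  own reverse complement, so forward-strand scanning is exhaustive.)
* **DamID counts**: Dam-only ~ Poisson(depth · length / mean_spacing),
  depth 20 reads per fragment. Fusion samples multiply the rate by a
  fold-enrichment at *binding sites*: a seeded Bernoulli subset
  (site_frac = 0.5) of the fragments inside a bound domain. Pc binds SNRs
  only (fold 8); SUUR binds SNRs (fold 6) and SSRs (fold 2.5). Punctate
  sites rather than uniform domain-wide enrichment are essential for peak
  *density* to be meaningful: with uniform enrichment every fragment in a
  domain is significant and adjacency merging collapses each domain into
  a single peak, inverting the density comparison; discrete sites also
  match how Pc actually distributes inside broad domains. Setting
  site_frac = 1 restores uniform enrichment.
* **Determinism**: every random draw comes from a named SHA-256-derived
  substream of (seed, purpose), so outputs are pure functions of
  (config, seed) and fixture files are byte-identical across reruns.

What the generator does **not** emulate: mappability and GC biases,
spatially correlated probe noise, copy-number (under-replication) effects
on coverage, fragment-length–dependent amplification bias, and boundary
fuzziness of real domains. Passing recovery tests therefore demonstrate
the correctness of the pipeline's inference machinery under the stated
noise model, not its performance on real arrays/libraries.

## Normalization

Tracks are quantile normalized (classic rank-mean dialect; ties share the
mean of their tied ranks' reference values; rows with any missing cell
pass through unchanged and are flagged) and replicates averaged
afterwards, one profile per genotype. The pipeline normalizes
**within genotype** by default (`qnorm_scope: genotype`). Cross-genotype
quantile normalization forces both genotypes onto one value distribution,
but the mutant genuinely loses signal over ~20 % of the genome — the very
effect being measured — so normalizing across genotypes would shrink the
planted wild-type SSR mean by ≈ 0.07 (analytic estimate from the quantile
map between the two mixture distributions). The generator emulates
already-normalized signal, making within-genotype normalization the
consistent default; `scope="all"` is available when the assumption of a
shared distribution is justified. Smoothing (1-kb window, 100-bp step,
unweighted mean of intersecting bins) is applied after the log2 ratio
when starting from coverage tracks; the simulated tracks are generated
directly at the smoothed granularity.

## Segmentation

A standard first-order HMM replaces the hidden semi-Markov model of the
original analysis: with the explicit >30-kb span filter the long-domain
regime is reproduced without duration distributions, and every component
(forward-backward, Viterbi, EM updates) is exactly testable against
enumeration oracles. Design choices, all open in the source description:

* K = 3 states (SSR, SNR, background), joint bivariate emissions over
  (wt, mut) rather than a difference track — the two-genotype mean vector
  is what distinguishes SSR (0.41, −0.06) from SNR (high, high).
* Initialization: seeded Lloyd k-means on the observation vectors,
  centers sorted for determinism; transitions start at 0.99 self-loop
  (domain persistence); uniform start probabilities.
* EM stops when the total log-likelihood gains < 0.01 (absolute) or at
  50 iterations; the per-iteration log-likelihood is recorded and tested
  for monotonicity. Missing bins contribute emission likelihood 1.
* A starving state keeps its previous parameters with a warning;
  a degenerate covariance is floored at 1e-4·I.
* Viterbi ties break toward the lower state index (first-argmax).
  An all-missing sequence decodes to state 0 with a warning.
* State labeling: SSR = argmax(wt − mut) provided the contrast ≥ δ = 0.2;
  SNR = the remaining state with the largest min(wt, mut) provided it
  clears the background level by δ; otherwise background. δ = 0.2 sits
  between the background fluctuation scale (σ/√n per region) and the
  smallest planted contrast (0.41 − (−0.06) = 0.47).
* Region calling: maximal same-label runs, no gap bridging by default
  (max_gap = 0; the source analysis mentions none), discarded unless
  length > 30 kb.

## DamID scoring

Reads must begin with GATC; retained reads are summed per GATC fragment.
Replicates are pooled (summed) per sample before testing — common DamID
practice — with per-replicate Pearson correlation reported as QC.
Each fragment is tested two-sided by Fisher's exact test against the
rest-of-library totals; the profile unit is −log10(P) signed positive for
fusion enrichment (the sign convention is this package's; "log10(P)
units" alone leaves it ambiguous). P is clamped to ≥ 1e-300, capping
scores at 300. Benjamini–Hochberg adjustment runs across all fragments;
peaks are fragments with q ≤ 0.05 on the enrichment side, merged when
bookended. The 5% threshold is the calling default; 0.5 can be passed for
display-style profiles. Identical (k_fus, k_dam) pairs share one Fisher
computation since the library totals are fixed.

## Region statistics

* Catalog UNION: per-base union with bookended merging, idempotent and
  order-invariant.
* Overlap classification: a query overlaps when it shares ≥ 1 bp
  (configurable `min_bp`) with any single reference region; half-open,
  so bookended regions do not overlap.
* Per-region means use the bin-midpoint rule — the same midpoint
  convention assigns fragments to domains and peaks to regions.
* Paired t-test: classical d = wt − mut, df = n − 1, two-sided; raw P,
  no multiple-testing adjustment across the handful of region-class
  contrasts (the source reports raw P). Zero-variance differences are
  reported degenerate.
* Random controls: 1000 regions, lengths resampled with replacement from
  the query set (length-matching is this package's choice; whether the
  original controls were length-matched is unstated), chromosome chosen
  proportional to length, uniform start, overlaps permitted.
* Chromatin composition: fraction of (unioned) region bases covered by
  each of the five Kc167 chromatin colors, plus an unannotated remainder
  summing to 1; assumes the color annotation partitions the genome.
  The synthetic annotation paints SSRs BLACK, SNRs BLUE, background
  YELLOW, mirroring the expected composition qualitatively.

## Problem sizes and numerics

The default study is 2 × 10 Mb (200k bins, ~78k GATC fragments) — large
enough that base-level recovery, effect-size and density statistics are
stable, while a full pipeline run completes in well under a minute of
simulation plus a few seconds of EM (numba-compiled forward-backward;
first call pays a one-time JIT cost). The FDR calibration uses 20
independent 1-Mb null genomes. Determinism checks run on a 2 × 2 Mb
configuration; determinism is size-independent. Emission stabilization
subtracts the per-bin max log-density before exponentiation; the scaled
forward pass accumulates log normalizers, so likelihoods are finite for
any parameter values the fit can reach.

## Known limitations

* The i.i.d. noise model understates boundary uncertainty relative to
  autocorrelated array noise; recovery numbers on real data would be
  lower.
* The HMM has no duration model; domains shorter than the span filter
  are unreachable by construction, and the 30-kb rule is a hard
  post-filter rather than a prior.
* Fisher's exact test on pooled replicates ignores replicate-level
  overdispersion; the FDR calibration therefore holds under the Poisson
  generator, not necessarily under biological replicate variance.
* Quantile normalization across genotypes is available but interacts
  with genuine global signal differences (see Normalization); use with
  care in differential designs.
* BAM/SAM alignment parsing, bigWig output and liftover are out of
  scope; the pipeline starts from binned tracks and fragment counts.
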