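# Methods

## Model

The scan treats gene-level differential-expression P-values as given (any
upstream test may produce them) and asks whether nominally significant
genes cluster positionally. Fix a per-gene threshold α; call a gene
*dysregulated* when its nominal P ≤ α (the comparison is inclusive). Under
the null hypothesis that dysregulation carries no positional signal, the
dysregulated count among the `n` genes inside a genomic window is
`K ~ Binomial(n, p)` with a per-gene success probability `p` set to α
itself: by construction of a P-value, each gene is significant at α with
probability at most α, so the binomial tail with `p = α` is conservative.
Each window is scored by the exact upper tail `P(K ≥ k)`, multiplied by
the number `M` of tested windows genome-wide (Bonferroni), clamped to 1,
and reported as `score = min(cap, log₁₀(1/p_corr))`.

Assumptions worth stating:

- **Independence across genes.** The binomial null treats genes within a
  window as independent Bernoulli trials. Co-regulated neighboring genes
  (shared enhancers, read-through, copy-number differences) violate this;
  that is precisely the alternative the scan is designed to flag, but it
  also means the null is approximate for genuinely correlated expression
  with no genetic cause.
- **One record per gene.** Probeset redundancy must be curated away first
  (below), or a single gene measured twice would be counted twice.
- **Positions are points.** A gene is in a window iff its span midpoint
  is; gene length is otherwise ignored.

## Window geometry

Centers sit at integer multiples of the step starting at 0 and extend
while `center − radius < chromosome length`; membership is half-open,
`center − radius ≤ midpoint < center + radius`. With the default
radius = step, these choices make the staggered-overlap property exact:
every non-negative position belongs to exactly two windows, so the window
counts genome-wide sum to exactly twice the number of dysregulated genes,
and a cluster straddling one window's breakpoint falls in the interior of
a neighbor. The grid origin and edge convention are internal conventions;
any fixed choice gives the same coverage properties.

`M` counts only windows holding at least `min_genes` assayed genes
(default 1): a window with no genes carries no test, so it contributes no
multiple-comparison burden. Windows below `min_genes` are still reported
(counts intact) with raw and corrected probability 1, score 0, and
`tested = 0`.

## Parameters

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| `step_bp` | 1,250,000 | bp | window spacing; ≈ 2.5 cM in the mouse, narrow enough to act like a linkage-scan partition |
| `radius_bp` | 1,250,000 | bp | half-width; equal to the step so windows overlap 50% (must be ≥ step) |
| `alpha_gene` | 0.01 | – | per-gene nominal threshold; inclusive comparison |
| `success_prob` | 0.01 | – | binomial null success probability; fixed at α, conservative by the P-value guarantee |
| `score_cap` | 9 | log₁₀ units | corrected probabilities below 10⁻⁹ are collapsed for display and reporting |
| `min_genes` | 1 | genes | minimum window occupancy to be tested |
| `threshold` | 3 | score | significance line; corrected probability 1/1,000, the positional analogue of LOD 3 |

`use_empirical_rate` substitutes the observed genome-wide dysregulated
fraction for `success_prob` as a sensitivity analysis (off by default: the
fixed-α null is the defined statistic; the empirical rate mixes the
alternative into the null when real clusters exist).

## Curation

Expression platforms measure many genes with several probesets. For each
gene the probeset with the smallest nominal P is retained and the rest are
deleted; ties are broken by larger |t|, then lexicographically smallest
probeset id, making the output deterministic. Probesets with no gene
assignment are dropped and counted in the log. Genes with more than one
genomic placement are rejected as an annotation error rather than guessed
at. Keeping the *minimum* P per gene is deliberately anti-conservative at
the gene level but uniform across the genome, so it does not bias any
particular window.

## Region merging

Windows at or above the threshold whose spans overlap on one chromosome
are merged into maximal intervals `[min(center − r), max(center + r))`,
each reporting its peak score, peak center, and the number of windows
merged. With radius = step, two consecutive significant centers always
merge.

## Permutation test

The behavioral comparison uses a two-sample permutation test: statistic
`mean(x) − mean(y)`, two-sided via absolute value, `B` random relabelings
of the pooled sample, p estimated with the add-one rule `(b+1)/(B+1)` (so
p is never 0 and the test is slightly conservative), and a Z value
standardizing the observed statistic against the Monte Carlo null moments.
The mean difference is the canonical two-sample statistic; the sign
convention is first group minus second. For `C(n_x+n_y, n_x) ≤ 10⁶` an
exhaustive mode enumerates every assignment and returns the exact
proportion instead.

## Synthetic data

The generators produce what the statistics assume, with known ground
truth:

- **Annotation**: genes on `n_chrom` chromosomes, placement uniform
  (probability proportional to chromosome length) or clustered around a
  few hotspots (half the genes, normal jitter with 300 kb sd); gene
  lengths uniform on 1–50 kb. Default scale 20 chromosomes × 100 Mb with
  20,000 genes — the order of a genome-wide expression platform.
- **Null P-values**: i.i.d. uniform(0, 1], so the dysregulated fraction at
  α = 0.01 is exactly the binomial null rate.
- **Planted clusters**: a chosen number of genes inside an interval get P
  resampled uniformly on (0, p_max] with p_max ≤ α — resampled rather
  than set to a constant to avoid degenerate ties.
- **Behavioral samples**: one group from a two-component normal location
  mixture (bimodal, e.g. an animal cycling between activity states), the
  control from a single normal; a null mode draws both groups from the
  control distribution.

All generators are bit-reproducible given (spec, seed).

What the fixtures do *not* emulate: probe-level intensities and
normalization artifacts, correlated expression among neighbors, uneven
assay coverage, or annotation errors. Passing tests demonstrate the
statistical machinery — error control and power under the stated model —
not robustness to those real-data features.

## Validation conditions

The simulation-based checks run at fixed, seeded conditions chosen to
make their guarantees sharp:

- **Null calibration**: 100 null genomes at the default scale (20 × 100 Mb,
  20,000 genes). Bonferroni bounds the family-wise error at threshold 3 by
  0.001 per genome, so even 2 flagged genomes out of 100 would be
  extreme; the check allows ≤ 2 for Monte Carlo slack.
- **Planted recovery**: 5 chromosomes × 50 Mb with 5,000 genes
  (20 genes/Mb) and 10 genes planted at P ≤ 0.009 in a 2 Mb interval
  contained in a single window. The covering window then holds ≈ 50
  genes with k ≥ 10, giving an analytic corrected tail around 10⁻⁸ —
  far below the 10⁻³ needed for score 3 — while the interval holds ≥ 10
  genes with overwhelming probability at that gene density. Recovery is
  required in 100/100 seeded replicates.

## Numerical choices

- The binomial upper tail is computed through the regularized incomplete
  beta identity `P(K ≥ k) = I_p(k, n − k + 1)` (relative error ~10⁻¹³
  across the tested grid). Below 10⁻²⁴⁰, where double-precision special
  functions lose relative accuracy, the tail is recomputed exactly in
  big-integer arithmetic on the binary rational `p = a/2^m`, with a
  certified truncation bound below 2⁻⁶⁰ relative; the division is
  correctly rounded. Probabilities are floored at 10⁻³⁰⁰ so they remain
  strictly positive; tails smaller than that are not representable in
  IEEE doubles anyway, and everything below 10⁻⁹ is reported at the score
  cap regardless.
- Corrected probabilities above 1 are clamped to 1 (score 0); only the
  lower collapse at `10^-cap` affects reporting.
- Chromosome lengths come from a lengths file when supplied, else are
  inferred as max(gene end) per chromosome and logged.
- TSV floats are serialized at full precision (repr-style), so
  write-then-read round-trips are exact and re-runs are byte-identical.
- Monte Carlo permutations are generated by row-wise argsort of uniform
  keys from a seeded generator, in chunks of 10⁵; results are invariant
  to the chunk size and deterministic per (x, y, B, seed).

## Limitations

- The binomial null ignores local correlation of expression noise;
  corrected probabilities are accurate under the stated model only.
- Bonferroni across overlapping windows is conservative (neighboring
  windows share half their genes, so the tests are positively
  correlated).
- The double-coverage accounting assumes radius = step; wider radii are
  allowed (every position then falls in ≥ 2 windows) but the
  exactly-two-windows property and the Σk = 2·total identity hold only at
  the default geometry.
- The synteny step reports interval overlap with user-supplied homology
  blocks; it does not establish orthology itself, and both inputs must be
  on the same assembly.
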