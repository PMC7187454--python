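# Methods

## The chromatin-state model

The genome is divided into fixed-width bins (default 200 bp) per
chromosome. Observations are binary vectors `x_t ∈ {0,1}^M`, one bit
per histone mark. The generative model is a hidden Markov chain over K
chromatin states with product-Bernoulli emissions:

- initial distribution `π` (each chromosome restarts from `π`),
- row-stochastic transition matrix `A` (K×K),
- emission matrix `E` (K×M): `P(x_tm = 1 | z_t = k) = E_km`,
  independent across marks given the state.

Assumptions worth stating: mark calls are conditionally independent
given the state (the standard chromatin-state assumption; real mark
co-variation beyond the state is absorbed into extra states);
transition dynamics are homogeneous along the genome; chromosomes are
independent chains.

### Training and inference

Baum–Welch EM with *scaled* forward–backward recursions: at every
position the forward vector is normalized and the scale factor stored;
the total log-likelihood is the sum of log scale factors, and the
backward recursion reuses the same factors, so `γ_t = α_t · β_t` is
directly the posterior. Per-iteration log-likelihood is monotone
non-decreasing (asserted in tests with 1e-8 slack). The inner
recursions are numba-compiled; everything around them is vectorized
numpy.

- **Initialization**: emissions from k-means centroids on a random bin
  subsample (≤ 10,000 bins, 3 k-means restarts) plus ±0.02 jitter,
  clipped to [0.02, 0.98]; transitions uniform with 0.9 self-weight;
  initial distribution uniform. Fully determined by `random_state`.
  An explicit `(π, A, E)` triple can be supplied instead
  (`init_params`), e.g. for warm-started nested fits.
- **Stopping**: `tol = 1e-4` total log-likelihood improvement or
  `max_iter = 200`, whichever first — comparable to the convergence
  behavior of standard chromatin-state tools.
- **Numerical floors**: emissions are clipped to
  [1e-10, 1 − 1e-10] after each M-step so frame probabilities never
  underflow to exactly zero; a forward scale factor of zero (impossible
  observation under a user-supplied degenerate model) is floored at
  1e-300.
- **Viterbi**: log-space; ties broken toward the smallest state index
  (strict `>` comparisons), making decoding deterministic.

### State labelling

Rules fire in priority order on the emission row: promoter
(`e(H3K4me3) ≥ 0.5`), strong enhancer (`e(H3K4me1) ≥ 0.5` and
`e(H3K27ac) ≥ 0.5`), weak enhancer (`e(H3K4me1) ≥ 0.5`), transcription
(`e(H3K36me3) ≥ 0.5`), Polycomb-repressed (`e(H3K27me3) ≥ 0.5`),
quiescent (all emissions < 0.2), else "Mixed". Labels carry a 1-based
index prefix (`13_EnhS` style). The ruleset is replaceable; rules
referencing marks absent from the model raise.

### Choosing K

`select_state_count` trains one model per candidate K and scores each
by *redundancy* — the maximum Pearson correlation between any two
emission rows — recommending the largest K whose redundancy stays at or
below 0.95 (threshold exposed). This operationalizes "increase K until
states stop separating". Two caveats, documented deliberately:
Pearson correlation is scale-invariant, so a near-zero (quiescent)
emission row can correlate ≈1 with a single-dominant-mark row of much
larger magnitude; and with noisy Bernoulli marks a single-restart EM
often spends surplus states on genuine finite-sample noise
sub-patterns whose rows correlate only ~0.6–0.9 with their parent
state. The procedure is therefore advisory: reliable when emission
profiles are crisp, but inspect the per-K report rather than trusting
the single recommended number.

## Binarization

`call = 1` iff the Poisson upper tail `P(X ≥ obs | λ) ≤ p` with default
`p = 1e-4`. With an input control, `λ_i = c_i · (Σs / Σc)` (global
depth matching, floored at 1e-8); without, `λ` is the flat mean signal
count. This is a single-scale variant of the usual chromatin-state
binarization: no local background windows, a declared simplification.
Calls are monotone in the observed count and monotone in `p`.

## Interval algebra and similarity

Intervals are 0-based half-open; `merge` coalesces overlapping *and
abutting* records (bp-coverage semantics); `intersect`/`union`/`jaccard`
are exact sorted sweeps validated against a per-bp membership oracle
and against pyranges. The Jaccard of two empty sets is defined 0 (not
NaN) so downstream clustering stays finite; an empty sample similarly
gets similarity 0 to everything including itself, with a warning.

Clustering converts the similarity matrix to distances as the Euclidean
distance between matrix *rows* (similarity profiles) — consequently two
samples with identical profiles are at distance 0 even if their
interval sets differ; `d = 1 − J` is available via `metric="one_minus"`.
Linkage defaults to average (UPGMA), via scipy; leaf order and the
Newick serialization come from the scipy dendrogram/tree.

## Methylation integration

CpG positions are 1-based at ingest (array convention) and converted
exactly once: site `pos` lives in bin `(pos−1) // bin_size`. Sites on
chromosomes outside the layout are flagged unassigned and excluded from
tables rather than erroring. The enrichment test is the Pearson
chi-square on the states × {significant, not} table; its null
distribution permutes significance flags across sites. Because only
per-state significant counts enter the statistic, a flag permutation is
distributionally identical to one multivariate hypergeometric draw with
the fixed margins, which is what is sampled (numpy Generator; bit-wise
reproducible per seed). The p-value is the add-one estimator
`(1 + #{perm ≥ obs}) / (1 + n_perm)`, so the attainable minimum is
`1/(n_perm+1)` and p is never 0. The default permutation count is
1,000; the 500-replicate calibration study uses 200 to keep runtime
proportionate, which only coarsens the p-grid, not the test.

## Overlap and motif statistics

The hypergeometric upper tail is summed in log space (log-gamma terms,
logsumexp), keeping full relative precision at p ~ 1e-90; `log10_p` is
reported alongside for output files. Two tail conventions are exposed:
`"geq"` (`P(X ≥ k)`, the standard p-value and the default) and `"gt"`
(`P(X > k)`, the complement convention of R's `phyper`), since
published overlap p-values computed the latter way are reproducible
only under it. Overlap counting is per-query-interval (≥ `min_bp`
overlap with the merged reference counts once).

PWM scanning scores `Σ log2((p_ib + ε·bg_b)/bg_b)` per window (default
pseudocount ε = 0.01), both strands (minus strand via the
reverse-complemented matrix, which makes scanning exactly
strand-symmetric even for asymmetric backgrounds), skipping windows
containing non-ACGT characters. The default hit threshold is 60% of
the maximal achievable score. Enrichment between sequence classes uses
sequence-level presence (≥ 1 hit) in a one-sided Fisher exact test,
with Haldane's 0.5 correction on the odds ratio when a cell is zero —
the canonical statistic family of AME-style relative enrichment.

## The synthetic-data generator

One global seed fans out into independent substreams per stage
(SeedSequence spawn keys derived from a CRC32 of the stage label), so
regenerating one artifact never shifts another. Defaults define the
package's standard study conditions:

- **Genome**: 4 chromosomes × 10 Mb at 200 bp bins (2×10⁵ bins) —
  desk-scale but large enough for parameter recovery; tests shrink it
  where less suffices.
- **States/marks**: six states (TssS, EnhS, EnhW, Tx, ReprPC, Quies)
  over the five canonical marks, with a sticky transition matrix (0.9
  self-weight) and block-like emission profiles.
- **Condition pair**: per-bin resampling from a flow matrix that keeps
  states mostly stable (0.90/0.82 self) and routes 10% of quiescent and
  repressed bins into the strong enhancer state — the
  differentiation-driven enhancer gain the dynamics stage must detect.
- **Methylation**: site density 0.5/kb (denser than a real 450K array
  so a toy genome still yields ≥10⁴ sites per state); baseline betas
  from a bimodal Beta(0.5,5)/Beta(5,0.5) mixture (array marginals are
  U-shaped); demethylation probability 0.40 in EnhS vs 0.01–0.05
  elsewhere, effect size 0.3, plus a 0.002 state-independent
  hypermethylation rate (real differential methylation here is ~94%
  hypo). The beta noise model is a labelled stand-in, not fit to data.
- **Sequences**: uniform-background ACGT; planting inserts the PWM
  *consensus* at a uniform offset (so every planted instance is
  detectable — planting rates, not detection noise, carry the signal),
  at per-class rates 0.6 (new) vs 0.1 (constant). The bundled
  SOX9-like PWM (AACAATG core, 0.97 consensus weight) is sharp enough
  that at the default 60%-of-max threshold only exact consensus windows
  hit; background presence in 500 bp is ~0.1 per class.
- **Replicate maps**: two groups of enhancer maps built from a slot
  tiling — 5% of slots shared between groups, the rest split into
  disjoint group cores, each replicate keeping core slots with
  probability 0.9 — giving high within-group and low between-group
  Jaccard.

What the generator does *not* emulate: read-level noise (mappability,
duplicates, fragment-size effects), correlated mark noise beyond the
state, spatially clustered CpGs (islands), probe-design bias, or
sequence composition structure. Passing recovery tests therefore
demonstrates correctness of the algorithms under the model's own
assumptions, not robustness to real-data artifacts.

## Problem sizes used in the standard checks

HMM exactness is verified against explicit enumeration of all hidden
paths on instances up to 8 bins × 3 states; parameter recovery uses
K=4, M=5 at 2×10⁵ bins (emission MAE ≤ 0.03, transition MAE ≤ 0.05
after Hungarian state matching); flow recovery uses 10⁶ bins (MAE ≤
0.01 row-normalized); the permutation-test calibration uses 500 null
replicates of 2,000 sites; motif power and clustering recovery use 100
seeded runs each. These sizes are the package's standard study
conditions and are what `scripts/acceptance.py` re-runs.

## Known limitations

- Joint multi-condition training is by concatenation (chains grouped
  per condition and chromosome); there is no parameter tying across
  cell types beyond sharing one model.
- The binarization omits local background smoothing; heavily uneven
  input coverage would be better served by windowed backgrounds.
- `select_state_count` is advisory (see above).
- Differential-methylation significance is consumed as an input flag;
  no FDR machinery is included.
- No plotting: riverplots, heatmaps and browser tracks are out of
  scope; all outputs are flat text files meant to feed standard tools.
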