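# chromstate

Chromatin-state segmentation and enhancer-dynamics analysis for
paired-condition histone ChIP-seq, with ground-truth simulators for
every stage.

## The problem

During differentiation — the motivating system is human mesenchymal
stem cells (hMSCs) differentiating into chondrocytes — the combinatorial
pattern of histone modifications (H3K4me3, H3K4me1, H3K27ac, H3K27me3,
H3K36me3) reorganizes genome-wide. Analyzing that reorganization
requires a chain of methods:

1. **Binarization** — binned ChIP-seq counts become per-bin 0/1 mark
   calls via a Poisson upper-tail test against an input-control
   background: call 1 iff `P(X ≥ obs | λ) ≤ p`, with `λ` the
   depth-scaled control count (default `p = 1e-4`, 200 bp bins).
2. **Chromatin-state learning** — a hidden Markov model with K states
   and product-Bernoulli emissions: in state *k*, mark *m* is present
   with probability `e_km`, independently across marks and bins. Chains
   run per chromosome; training is Baum–Welch EM with scaled
   forward–backward recursions; decoding is Viterbi. States get
   semantic labels (`TssS`, `EnhS`, `EnhW`, `Tx`, `ReprPC`, `Quies`)
   from thresholded emission profiles — e.g. a strong enhancer state is
   high H3K4me1 *and* H3K27ac without H3K4me3.
3. **State dynamics** — the flow matrix `F_ij` counts bins in state *i*
   before and *j* after differentiation (the riverplot matrix); bins
   that become strong enhancers are classified by origin as **new**
   (from quiescent/Polycomb-repressed chromatin), **constant** (already
   enhancers), or a residual other-gain class.
4. **Cross-epigenome similarity** — one state's territory per sample,
   compared pairwise by bp-level Jaccard `|A∩B|/|A∪B|`, then clustered
   hierarchically on the Euclidean distance between similarity-matrix
   rows.
5. **Methylation integration** — CpG sites (450K-array-style beta
   values with differential-methylation flags) intersected with the
   state map; a Pearson chi-square on the state × {demethylated, not}
   table with a Monte-Carlo permutation null tests whether
   demethylation concentrates in enhancer states.
6. **Enrichment statistics** — an upper-tail hypergeometric test for
   region-set overlap (evaluated in log space, exact even at p ~ 1e-90)
   and AME-style relative motif enrichment: PWM log-odds scanning of
   both strands, sequence-level presence, one-sided Fisher exact test
   between new and constant enhancer sequences.

Every stage can be exercised on synthetic data with known ground truth
(`chromstate.simulate`), so recovery is testable end to end without any
external download.

## Worked example

```python
import numpy as np
from chromstate import (
    default_config, GenomeLayout, simulate_state_chain, simulate_marks,
    simulate_condition_pair, stack_tracks, fit_model, label_states,
    match_states, classify_enhancers, simulate_methylation, assign_cpgs,
    summarize_states, permutation_chisq, hypergeom_upper_tail,
)

layout = GenomeLayout(("chr1", "chr2"), (4_000_000, 4_000_000), 200)
config = default_config(seed=0, layout=layout)

seg_a = simulate_state_chain(config)               # stem-cell state map
seg_b = simulate_condition_pair(seg_a, config)     # differentiated map
obs_a, marks = stack_tracks(simulate_marks(seg_a, config))

model = label_states(fit_model(obs_a, 6, lengths=layout.chain_lengths(),
                               seed=0, mark_names=marks))
perm = match_states(config.emission_truth, model.emission)
print("emission recovery MAE:",
      round(float(np.abs(config.emission_truth - model.emission[perm]).mean()), 4))

cls = classify_enhancers(seg_a, seg_b)
print("new enhancer bp:", cls.new_enhancers.covered_bp(),
      "constant bp:", cls.constant_enhancers.covered_bp())

cpgs = simulate_methylation(seg_b, config)
assign = assign_cpgs(cpgs, seg_b)
row = summarize_states(cpgs, assign, seg_b).set_index("state").loc["2_EnhS"]
print(f"EnhS share of CpGs: {row['pct_all']:.1f}%  "
      f"share of demethylated CpGs: {row['pct_demeth']:.1f}%")
res = permutation_chisq(assign, cpgs.hypo_flags(), n_perm=1000, seed=0)
print(f"chi-square={res.statistic:.1f}  permutation p={res.p_perm:.6f}")

ht = hypergeom_upper_tail(77_655, 14_954, 3_797, 1_239, tail="gt")
print(f"overlap test p={ht.p_upper:.3e} (expected overlap {ht.expected:.0f})")
```

prints

```
emission recovery MAE: 0.0028
new enhancer bp: 268200 constant bp: 1193400
EnhS share of CpGs: 19.2%  share of demethylated CpGs: 75.2%
chi-square=970.8  permutation p=0.000999
overlap test p=3.747e-90 (expected overlap 731)
```

Reading the output: the learned emission matrix matches the planted one
to within 0.003 per entry (after optimal state matching); the
differentiated map contains both newly gained and pre-existing enhancer
territory; demethylated CpGs concentrate in the strong enhancer state
far beyond its share of all sites, and the permutation p-value sits at
the attainable floor `1/(n_perm+1)`; the final line is a pure-count
overlap test — drawing 3,797 regions from a universe of 77,655 of which
14,954 are marked, observing 1,239 marked is astronomically beyond the
~731 expected.

## Command line

`chromstate` exposes each stage as a subcommand over flat BED/TSV/FASTA
files: `simulate`, `binarize`, `learn`, `segment`, `flows`,
`classify-enhancers`, `methylation`, `similarity`, `overlap-test`,
`motif-enrich`, and `demo`. The demo runs the full chain on a small
synthetic genome, writes a checksummed manifest, asserts recovery gates
and exits nonzero if any fail:

```bash
chromstate demo --seed 1 --out-dir demo_out
```

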