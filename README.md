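# ppinpipe

Stagewise protein–protein interaction network (PPIN) inference and
comparison from expression data, built for studying how molecular
interactions reorganize across the early stages of a disease — the motivating
setting is early cardioembolic stroke, with blood expression profiles at four
stages (pre-stroke control C, and ≤3 h, 5 h, 24 h post-stroke: I, II, III).

## What it does

For each stage, every protein *i* is modeled by a linear interaction model
over its candidate interactors:

    y_i(m) = Σ_k α_ik · y_k(m) + β_i + ε_i(m),    β_i ≥ 0,  α_ii = 0

where `y_i(m)` is the expression of protein *i* in sample *m*, `α_ik` is the
interaction activity of interactor *k* on target *i*, `β_i` is a nonnegative
basal level and `ε_i(m)` is noise. The pipeline:

1. **Preprocessing** — quantile normalization, Tukey median-polish
   probe→gene summarization, and a Bonferroni-corrected Welch-test DEG
   fraction between stages.
2. **Network identification** — per target, constrained least squares
   (`β ≥ 0`, active-set closed form) over the candidate interactors; model
   order chosen by minimizing `AIC(L) = log(RSS/M) + 2L/M` with greedy
   forward selection and interleaved backward elimination; retained
   activities tested against zero with a Student t-test and deleted at
   p ≥ 0.05. The per-target coefficients assemble into the weighted directed
   stage network `N[i,k] = α_ik`.
3. **Functional networks** — hypergeometric over-representation (BH-controlled)
   selects enriched functions from a GMT catalog; the activity between two
   functions is the signed sum of member-pair interaction activities.
4. **Principal network projection** — SVD `N = U Σ Vᵀ`; the right singular
   vectors are *eigen-interactions* with energy fractions
   `r_i = σ_i²/Σσ_j² × 100%`; the smallest K modes reaching 85% cumulative
   energy are kept, proteins are scored by the magnitude of their interaction
   row's projection onto them, and proteins scoring above a threshold
   (default > 6, scale-dependent) form the **core network**.
5. **Differential networks** — edge-wise (and, for core networks, node-wise
   Δβ) differences between consecutive stages; large Δβ proteins are
   partitioned into miRNA-regulation candidates (present in a user-supplied
   miRNA–target table) and methylation-regulation candidates (the rest).

Everything is exercised end-to-end on synthetic data with known ground truth
(the `synthetic` module is first-class, tested code): a generic closed-loop
generator, and a layered identifiable design used for the recovery
benchmarks. Real data enter as plain TSV/GMT files.

## Worked example

```python
import numpy as np
from ppinpipe import *

# ground truth for the control stage; stage I perturbs 20% of edges and basal levels
truth_C = generate_identifiable_truth(n_proteins=40, true_degree=2,
                                      candidate_excess=1.0, seed=7, noise_sd=0.05)
truth_I = perturb_truth(truth_C, edge_change_frac=0.2, beta_change_frac=0.2, seed=8)

cand = assemble_candidate_network(truth_C.candidate_edges, truth_C.protein_ids)
nets = {}
for label, truth in [("C", truth_C), ("I", truth_I)]:
    expr = simulate_expression(truth, n_samples=23, seed=9, stage=label)
    nets[label] = build_stage_network(expr, cand)

eig = eigen_decompose(nets["C"], energy_threshold=85.0)
sim = protein_similarity(nets["C"], eig)
core = select_core(sim, threshold=1.0)   # similarity scale tracks network scale
diff = differential_network(nets["I"], nets["C"])
```

Output (with per-stage precision/recall against the known truth added):

```
stage C: 40 proteins, 94 directed interactions, precision 0.86, recall 1.00
stage I: 40 proteins, 80 directed interactions, precision 0.76, recall 0.98
principal modes K = 4 of 40 (top energy fractions: [47.3 22.8 12.7] %)
core network: 8 proteins
differential network C -> I: 42 up-regulated, 49 down-regulated interactions
largest basal-level changes: {'P0010': 1.48, 'P0007': -1.18, 'P0009': -1.11}
```

Reading: at 23 samples per stage the identified networks recover the true
interactions almost completely, with some decoy candidate pairs surviving
(precision < 1). Four eigen-interactions carry 85% of the control network's
energy; eight proteins project strongly onto them and form the core. The
stage C→I comparison shows which interactions strengthened or weakened and
which proteins changed basal level — the quantities used to nominate
miRNA/methylation regulation candidates (`flag_regulation_candidates`).

A command-line interface mirrors the library
(`ppinpipe simulate|preprocess|build|funcnet|corenet|diff|run-all`); `run-all`
drives the full pipeline from a YAML config and writes TSV/GraphML outputs
plus a JSON manifest of node/edge counts per stage.

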