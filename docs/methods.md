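# Methods

## The interaction model

Expression of a target protein *i* in sample *m* is modeled as

    y_i(m) = Σ_k α_ik y_k(m) + β_i + ε_i(m),    β_i ≥ 0,  α_ii = 0.

`α_ik` (interaction activity) quantifies how interactor *k*'s level
associates with target *i*'s level; `β_i` is a nonnegative basal level; `ε`
absorbs environmental noise and model mismatch. The model is directional in
form (each protein has its own regression) but the candidate pairs feeding it
are undirected database interactions, so both orientations of a pair are
candidate terms in their respective target models and are estimated
independently. No self-regulation terms are allowed.

Stacking M samples gives `y_i = Φ_i θ_i + ε_i` with
`θ_i = (α_i1 … α_iL, β_i)ᵀ`, estimated by least squares under the single
inequality constraint `β_i ≥ 0`. With one constraint the active-set solution
is closed-form: take the unconstrained minimizer, and if its intercept is
negative clamp it to zero and re-solve for the activities — exact for a
convex quadratic with one inequality. Rank-deficient designs fall back to
the minimum-norm solution with a warning.

## Model-order detection

The number of real interactors L is unknown; it is chosen by minimizing

    AIC(L) = log(RSS/M) + 2L/M      (natural log)

with greedy forward selection (add the candidate that most decreases AIC),
interleaved with backward elimination after every addition beyond the first
(remove any selected candidate whose removal does not increase AIC).
Numerical conventions:

* Comparisons use the lexicographic key (AIC, L), so a removal that leaves
  AIC unchanged is taken, and among perfect fits the smaller model wins.
* A perfect fit is undefined under the log, so RSS below a relative
  tolerance `1e-12 · (‖y‖² + 1)` is clamped to zero and assigned AIC = −∞.
  Without this clamp, AIC differences in the numerically-zero regime are
  dominated by floating-point noise and the search overfits.
* Ties between candidates with equal keys resolve to the lexicographically
  smallest identifier (the scan runs in sorted order), making per-target
  fits deterministic and independent of evaluation order.
* The order is capped at M − 2 so the coefficient t-test always keeps at
  least one residual degree of freedom. With M = 23 samples per stage — the
  study design this package targets — the cap binds at L ≤ 21.

After selection, each retained activity is tested against zero with a
two-sided Student t-test (standard OLS covariance `σ̂²(XᵀX)⁻¹`,
`σ̂² = RSS/(M−L−1)`; only activities are tested since the constraint binds on
the intercept alone). Coefficients with p ≥ 0.05 are deleted and the model
is refit once on the survivors, without further selection. A threshold ≥ 1
records p-values but deletes nothing.

Per-target fits are embarrassingly independent; the assembled stage network
`N[i,k] = α_ik` does not depend on the order in which targets are processed.

## Synthetic data: two generative designs

**Closed-loop (generic).** `generate_truth` draws a random sparse network
(each protein receives `true_degree` incoming edges, activities Gaussian
with random sign, rescaled so the spectral radius of A stays ≤ 0.8) and
half-normal basal levels. Expression solves the fixed point
`y(m) = (I − A)⁻¹(β + ε(m))` per sample — the only self-consistent joint
reading of the per-protein model — with i.i.d. Gaussian noise (the noise
distribution is an assumption of this package, not a claim about data).
Candidate lists add `candidate_excess × (number of true pairs)` decoy pairs
drawn uniformly from non-edges, emulating database false positives.

**Layered identifiable (benchmark).** In the closed loop, noise is the only
source of sample-to-sample variation: with ε = 0 every sample equals the
same fixed point and nothing is identifiable. More fundamentally, a dataset
in which *every* structural equation holds exactly with varying profiles
must be constant (`(I−A)y = β` forces `y = (I−A)⁻¹β`), so exact noiseless
recovery requires variation to enter through dedicated nodes whose own
equations are allowed to carry it. `generate_identifiable_truth` therefore
builds a layered DAG:

* *Driver* proteins carry exogenous per-sample fluctuations (empirically
  centered, scale `driver_sd`), arranged in groups of size d = `true_degree`.
* Each group feeds d+1 *layer-1* children whose parents are exactly the
  group's drivers, with negative activities and basal levels chosen so each
  child's mean level is exactly zero.
* Every *deeper* protein takes d parents among earlier non-driver proteins;
  its equation holds exactly in the noiseless limit, so its activities and
  basal level are recovered to machine precision.

The layer-1 zero-mean construction makes driver basal levels exactly
identifiable too: a driver's own equation carries the fluctuation, so its
fit latches onto its children (a perfect fit exists because each group's
children jointly span the group's fluctuation space), and the intercept of
that fit equals `β_driver − Σ_j c_j · mean(y_child_j) = β_driver` when the
children's means vanish. Recovered driver edges point child→driver, i.e.
the reverse orientation of the truth — undirected support is still exact,
which is why the benchmark compares support as undirected pairs.

Three further choices keep the benchmark identifiable *by the greedy search
itself*: the ambient variation dimension (d × groups, ≥ 10 by default) stays
above typical candidate degrees, else any large-enough candidate subset fits
any target exactly; deep parent sets must straddle at least two driver
groups and never repeat, else alternate exact representations of a target
exist inside its own candidate set; and parent duty is spread evenly with
driver→child couplings (0.6–1.0) stronger than deep couplings (0.3–0.7), so
forward selection is drawn to a target's parents rather than its children.
These are structural identifiability conditions, not tuning: violating any
of them makes "recover the planted network" an ill-posed request.

**Stage perturbation.** `perturb_truth` removes exactly
`⌊frac · |edges|⌋` true directed edges (removal, not rescaling, so the
symmetric difference of edge sets equals the requested count) and shifts
exactly `⌊frac · P⌋` basal levels (guaranteed changed, kept ≥ 0), leaving
the candidate set untouched so all stages share one search space.

**What the generator does not emulate.** Probe-level/array noise, batch
effects, realistic pathway topology, heavy-tailed expression, and
correlated (non-diagonal) noise. Passing the benchmarks shows the estimator
recovers its own model's parameters under these idealized conditions; it
does not certify edge-level accuracy on real arrays, where model mismatch
and confounding dominate.

## Functional networks and enrichment

The enrichment statistic behind the functional networks is a stand-in (the
field offers no single convention): one-sided hypergeometric
over-representation of each catalog function among the network's proteins
against a user-chosen background, Benjamini–Hochberg controlled at 0.05 by
default. A user-supplied enriched-function list bypasses the test.

Function-level activity sums the *signed* activities over member pairs —
preserving up/down direction — with
`activity(f,g) = Σ α_ik over (i∈f, k∈g) + (i∈g, k∈f)` for f ≠ g and edges
with both endpoints in f for `activity(f,f)`. A protein in both functions
contributes once per ordered containment (so an edge inside f ∩ g counts
twice toward (f,g)); this is the documented contract and what the
brute-force oracle in the tests checks. Aggregation is linear in the
underlying network.

## Principal network projection

SVD of the dense stage matrix N (rows = target profiles, absent entries 0);
energy fractions `r_i = σ_i²/Σσ_j² × 100`; K = smallest count with
cumulative energy ≥ 85% (the usual PCA convention; the threshold is
exposed). Proteins are scored by projecting their interaction *rows* onto
the K right singular vectors — matching the row-vector notation of the
model — and aggregating the K coefficients by their 2-norm, which reduces
to ‖a_i‖₂ when K = P (a clean Parseval contract); the largest absolute
single-mode inner product is available as `mode="max"` since the
aggregation rule across several modes is genuinely open. Core proteins are
those with similarity strictly above the threshold (default 6). The score
scales linearly with the network (c·N gives c·similarity), so the absolute
threshold is data-scale-dependent and should be re-chosen per dataset — the
default mirrors a choice made by node-count inspection on one dataset, not
a universal constant. Dense SVD is used throughout; the intended problem
sizes (≤ a few thousand proteins) are well within its reach.

## Differential comparison and regulation candidates

Differential networks subtract activities edge-wise over the union of edges
(absent = 0) and, for core networks, basal levels node-wise; the operation
is antisymmetric under stage swap. Proteins with |Δβ| above a user
threshold split into miRNA-regulation candidates (those with entries in a
supplied miRNA–target table) and methylation-regulation candidates (the
rest) — a screening heuristic, not a causal claim.

## Preprocessing conventions

Quantile normalization maps each column through its ranks to the
cross-column mean of order statistics; ties take the mean of the reference
values across tied ranks (average-rank dialect); the operation is
idempotent on tie-free data. Median polish runs at most 10 alternating
row/column sweeps or until the total absolute residual stalls (relative
1e-6); gene expression = overall + sample effect, probe effects discarded
(RMA-style). The alternating sweeps stall with row/column medians small
(~1e-3 on unit-scale data) but not exactly zero — the documented "near
zero" contract. The DEG fraction uses Welch's t-test per gene (no
equal-variance assumption) with Bonferroni correction at p ≤ 0.05; the
upstream study reports only that a test was used, so this choice is a
stand-in.

## Problem sizes and known limitations

The test and acceptance benchmarks run at P = 30–100 proteins, 23–100
samples and ≤ 1,000 replicate fits — sizes chosen so the whole suite
completes in seconds while still exercising every code path; the estimator
itself scales to thousands of proteins since targets are independent.

Two limitations are measured, not hidden:

* **Post-selection inflation.** The procedure tests coefficients *after*
  AIC selection picked them, so under a global null the per-coefficient
  false-retention rate exceeds the nominal 0.05 once candidates are many
  and mutually correlated (≈ 0.065–0.075 with 5 i.i.d. Gaussian candidates
  at M = 23, growing with candidate count). The pruning test in isolation
  is calibrated (≈ 0.05 with a single candidate or near-orthogonal
  designs). Selective-inference corrections are out of scope.
* **Endogeneity under self-consistent noise.** When noise enters the
  structural equations (the closed-loop simulation), a target's noise
  propagates into its descendants' profiles, so decoy pairs between related
  proteins carry genuine partial correlations and survive the t-test. On
  the layered benchmark at 10% noise this caps undirected edge precision
  around 0.75–0.8 at perfect recall; the surviving false pairs are
  predominantly ancestor/descendant or shared-ancestry pairs. This is a
  property of regression-based network identification on equilibrium data,
  not of the implementation.
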