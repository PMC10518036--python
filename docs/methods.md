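# Methods

## Model

A sample's observed SBS96 spectrum v (96 non-negative integer counts) is
modeled as a non-negative mixture of K reference signature profiles, the
columns of W (each a probability vector over the 96 trinucleotide-context
channels): v ≈ W h with h ≥ 0.  Assignment estimates h for every sample of
a catalog V; stacking the per-sample solutions gives the activity matrix H.
The model assumes signature profiles are fixed and known (no de novo
extraction), mutations are independent draws given the mixture, and
channels are exchangeable across samples.  Activities are reported both as
proportions of the sample's assigned mass (hᵢ/Σh) and as counts
(proportion × burden), with an explicit Unassigned row so that proportion
columns always sum to 1 and count columns to the sample burden.

## Engines

All four optimizers solve the same per-sample problem under different
objectives, mirroring the algorithm families used by published assignment
tools.

* **nnls** — Lawson–Hanson active set (`scipy.optimize.nnls`); the exact
  Euclidean minimizer.
* **fcnnls** — the fast combinatorial NNLS scheme for many right-hand
  sides: columns sharing a passive set are solved with one factorization of
  the normal equations; infeasible iterates are repaired with
  Lawson–Hanson feasibility steps.  Solutions agree with per-column NNLS to
  < 1e-8 (tested against it, and against subset enumeration); a per-column
  Lawson–Hanson fallback guards the rare degenerate-cycling case.
* **qp** — the simplex-constrained least-squares problem on the proportion
  spectrum p = v/Σv (the equality Σh = 1 is meaningless on raw counts).
  Solved by a primal active-set method: on the passive set, the
  equality-constrained KKT system is solved exactly (lstsq, so duplicate
  signatures degrade gracefully); blocking constraints trigger a step to
  the boundary.  The iterate stays on the simplex throughout.  Verified
  against a 1e-6-resolution grid oracle for K = 2.
* **mu** — multiplicative updates h ← h ∘ (Wᵀ(v ⊘ Wh)) ⊘ (Wᵀ1) minimizing
  the generalized Kullback–Leibler divergence D(v ‖ Wh).  Initialization is
  uniform (deterministic) by default; a seeded random start is available.
  Convergence: relative divergence change < 1e-8 (or divergence < 1e-12,
  which catches the perfect-fit limit where the relative criterion never
  fires), capped at 10,000 iterations with the convergence flag reported
  rather than an error.  The divergence is asserted non-increasing at every
  step.

Engines return one of the equivalent optima when W contains (near-)
duplicate columns; downstream comparisons in that regime should use the
reconstruction W h, not h itself.

## Strategies

The activity threshold t (default 0.05) is a proportion of each sample's
*assigned* mass, since every emulated tool thresholds engine output.

* **Regular** fits the full reference.  An optional `regular_floor`
  (default 0; 1e-4 emulates a 0.01% trace floor) zeroes trace activities
  and renormalizes the rest, so utilization stays exactly 1.
* **Remove** zeroes activities < t and moves their combined proportion to
  the Unassigned row *without* renormalizing the survivors — this
  preserves the utilization semantics (utilization = 1 − removed mass) and
  lets the removed spectrum W·(removed activities) be reported per channel.
  A sample losing every signature reports utilization 0 and a missing RvO.
* **Refit** keeps the signatures ≥ t and re-runs the engine on the subset.
  `single_pass` (default) applies the selection once; `iterative` repeats
  selection + re-fit until the retained set is stable or one signature
  remains (terminates in ≤ K rounds since the set only shrinks or fixes).
  Single-pass may leave post-refit activities below t; this is documented
  behavior, not suppressed.  An empty selection falls back to the single
  strongest signature and flags the sample.

## Ensembles

Members are aligned to the union of signature ids (missing entries are
zero) and the intersection of samples.  The Unassigned row never votes and
is excluded from averaging, because the intended ensemble inputs are Refit
outputs, which carry no unassigned mass.  Majority is strict (> M/2; ≥ 3
of 5 for five members).  Ensemble-Mean draws, per signature and sample,
n = 500 bootstrap samples of size M with replacement from the member
proportions, averages each, takes the mean of bootstrap means, and then
standardizes each sample's vector to sum to 1.  The bootstrap unit is the
member value (tool/engine), not the sample; with n = 500 the estimate sits
within Monte-Carlo noise of the arithmetic mean, whose RMSE against truth
is provably no worse than the average member RMSE (triangle inequality of
the Euclidean norm), so the ensemble can lose to the single best member
but never to the member average.

## Metrics

RvO is the cosine similarity between the observed spectrum and the
reconstruction from retained signatures (scale-invariant, so it reflects
spectral shape, not mutation loss).  Kendall tau-b uses the standard tie
correction; it is missing when either vector is constant.  Sample-wise
concordance declares a sample valid only if every member assigns it ≥ 2
signatures (so all pairwise correlations are computable on one global
valid set); within a pair, double-zero signatures are dropped.
Signature-wise concordance scores a signature per member pair across the
samples where at least one of the two assigns it (≥ 2 such samples
required), then averages pairs with equal weight — including when pairs
differ in how many valid samples they contribute, a deliberate choice.
Shannon diversity uses the natural log, so the flatness ceiling for an
SBS96 profile is ln 96 ≈ 4.564.  RMSE against simulated truth is pooled
over all (signature, sample) entries with positive truth activity —
restricting to truly active entries means the metric measures quantitative
accuracy, not the qualitative false-positive rate, which the confusion
metrics (PPV/NPV/accuracy) cover instead.  Missing values are excluded
from means and counted.

## Simulator

The generator is a parametric surrogate for activity-resampling
simulators: it reproduces the features that matter for assignment
benchmarking (sparse per-sample signature sets, skewed activity sizes,
order-of-magnitude burden heterogeneity, counting noise) without copying
any specific tool's internal distributions.  A verbatim/bootstrap pathway
(`resample_from_reference`) accepts a real activity matrix as truth when
faithful cohort replication is wanted.

Defaults, chosen once as realistic for WGS cohorts: per-signature
prevalence 0.5 with ≥ 2 active signatures per sample; carrier magnitudes
Gamma(shape 1.5) normalized to the simplex (shape < 1 produces many
sub-threshold nuisance activities, used to stress the strategies); burdens
log-uniform over 1,000–50,000 mutations; multinomial noise (conserves the
burden exactly; Poisson optional; a noise-free rounded mode for recovery
tests).  Synthetic spiky signatures put Dirichlet mass on 3–8 channels
(diversity < ln 8); flat signatures are Dirichlet(α = 2) over all 96
channels, keeping diversity above 4 while letting pairwise cosines stay
below the 0.9 rejection bound — a near-uniform perturbation would make any
two flat profiles nearly collinear and the bound unsatisfiable.  All
randomness derives from one cohort seed via `numpy.random.SeedSequence`
spawning.

What passing synthetic tests does *not* show: real tumor catalogs have
correlated signature co-occurrence, cancer-type structure, sequencing
artifacts and reference-signature misspecification that the surrogate does
not emulate; results on it bound algorithmic behavior, not biological
accuracy.

## Problem sizes and numerical choices

Cohort-scale tests use 10–100 samples, 5–8 signatures and burdens
500–50,000 — large enough for the distributional checks (3-standard-error
bands) to be meaningful while keeping the default suite fast.  The
ensemble-convexity and rank properties use 10–20 independent cohorts of 15
samples with half-flat signature sets and low burdens (500–5,000), the
regime where engines disagree enough for ensembling to matter.  Load-time
tolerances: signature columns renormalized (zero-sum rejected); activity
proportion columns must sum to 1 within 1e-6 internally, 1e-4 on external
files (warn + renormalize, or error in strict mode).  Ties in dominant-
signature calls break lexicographically and are flagged.  File round-trips
write 12 significant digits.

## Known limitations

Only SBS96 catalogs (no indel/doublet/SV classes, no strand-aware SBS192);
no a-priori cancer-type signature subsetting; no significance testing on
concordance statistics; engines emulate optimizer families, not any
specific published tool's exact heuristics, so tool-bit-exact replication
is out of scope.  The simplex-QP active-set solver targets K up to a few
hundred signatures; it is not tuned for larger references.
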