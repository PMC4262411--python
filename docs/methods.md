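# Methods

## The calibration model

The property of interest y is modelled as an affine function of a
subset S of the instrument channels:

    y = β₀ + Σ_{k ∈ S} β_k x_k + ε.

Coefficients are the minimum-norm least-squares solution of the
intercept-augmented system `[1 | X_S] b ≈ y`, i.e. the Moore–Penrose
pseudoinverse solution. This keeps the fit defined even when |S|
exceeds the number of calibration samples, a routine situation in
spectroscopy. Singular values below `eps · max(m, n) · s_max` are
treated as zero.

Model quality on a held-out split with N samples is summarised by

* RMSEP = √(Σ (y − ŷ)² / N) — root mean squared error of prediction;
* MAPE = 100 · mean |(y − ŷ)/y| — relative error in percent (an error is
  raised if any reference value is zero; silently dropping such samples
  would bias comparisons);
* PRESS = Σ (y − ŷ)² — computed from the held-out residuals directly,
  not by leave-one-out cross-validation;
* AIC = N ln(σ̂²) + 2p and BIC = N ln(σ̂²) + p ln N with
  σ̂² = PRESS/N (maximum-likelihood variance) and p = |S| + 1 (the
  intercept counts as a parameter). Smaller is better. A perfect fit
  (PRESS = 0) has no defined information criteria; `aic_bic` raises,
  while the search-internal evaluation maps the degenerate case to −∞
  so a noiseless run cannot crash.

## Sample splitting and preprocessing

Samples are partitioned into calibration, validation and prediction
sets with the Kennard–Stone max–min rule: the calibration set starts
from the two most mutually distant samples (Euclidean distance on the
rows of X, after any preprocessing) and greedily adds the sample whose
minimum distance to the selected ones is largest; the validation and
prediction sets are grown the same way over the remaining samples.
Ties are broken by the lowest sample index, so splits are deterministic
and permutation-equivariant. Undersubscribed splits leave the surplus
samples unassigned.

Savitzky–Golay first-derivative preprocessing (default: order-2
polynomial, 11-point window) removes baseline offsets from raw
spectra. The (window−1)/2 edge channels on each side, where the
centred window does not fit, are dropped rather than padded — padding
invents data at the spectrum ends.

For robustness studies, `inject_noise` adds zero-mean white Gaussian
noise per column with standard deviation `factor × sd(column)`, where
`sd` is the sample standard deviation (n−1 denominator) of the data
being contaminated. The model is fixed; only the prediction-set
spectra are perturbed. Since E[(ŷ_noisy − y)²] ≥ (ŷ_clean − y)² in
expectation for a fixed linear model, mean noisy RMSEP above the clean
RMSEP is the expected signature; the ratio measures noise
amplification by the selected channel set (collinear channel sets
amplify more).

## The search

Each firefly holds a position in [0, 1]^K; channels whose component
strictly exceeds the threshold (default 0.5) are selected. The
objective vector of a firefly is (validation RMSEP of its subset model,
number of selected channels), both minimised; light intensity is the
negative error, so the brightest firefly has the smallest RMSEP. A
firefly with an empty mask is infeasible and carries an infinite-error
sentinel (dominated by every feasible solution, never archived); it
remains in the population and can be rescued by later moves.

Each iteration scans ordered pairs (i, j) in ascending index order.
When j's objectives Pareto-dominate i's, firefly i moves by

    xᵢ ← clip( xᵢ + β₀ e^{−γ r²}(xⱼ − xᵢ) + α(rand − ½), 0, 1 )

with one fresh uniform draw per component, and is re-evaluated
immediately if the move changed its mask (objectives are mask-pure, so
an unchanged mask needs no refit). Updates are in place: later
comparisons in the same scan see the new state.

A firefly that no other firefly dominates takes an exploration step
instead, as in multiobjective firefly formulations where non-dominated
fireflies walk around a randomly chosen Pareto-front member: an
archive entry is drawn uniformly, and the firefly adopts that
position with one random selected channel reflected across the
threshold with probability ½ (a drop) and, independently, one random
unselected channel reflected with probability ½ (an add). The
subset-neighbourhood form replaces a full-width uniform perturbation
deliberately: in [0, 1]^K a full-width walk flips a number of channels
that grows with K, which makes sparse solutions unreachable — the
population equilibrates near K/10 selected channels and the front never
extends into the sparse region. One-channel add/drop steps explore
Hamming neighbours of archived solutions, so the front ratchets toward
parsimony at a K-independent rate. The walk is part of the stochastic
component of the dynamics and is disabled at α = 0, in which case a
firefly that nothing dominates is a fixed point.

Every feasible evaluation updates a non-dominated archive (one entry
per objective pair/mask; dominated entries are evicted), so the best
archived error is non-increasing by construction. After the final
iteration the decision maker picks one archive member: objectives are
min–max normalised over the front (a degenerate zero range normalises
to 0) and the member with the smallest Euclidean distance to the
normalised utopian point wins, with ties broken by fewer channels, then
lower error, then first occurrence. The chosen subset is re-fitted on
the calibration set and all five metrics are reported on the prediction
set, which plays no role during the search.

Determinism: one seeded generator drives population initialisation,
movement noise and exploration draws in scan order, so identical
configurations (including the seed) reproduce identical results
byte-for-byte.

## Parameters

| parameter | default | meaning and guidance |
|---|---|---|
| `n_fireflies` | 250 (`RunConfig`); 100 used in the bundled studies | swarm size; larger swarms cover more subsets per iteration |
| `max_iterations` | 100 (`RunConfig`); 300 used at K = 200 | the archive frontier needs roughly K iterations to descend from ~K/2-channel masks to a sparse model; watch `trace` and stop when the front stabilises |
| `alpha` | 0.2 | randomisation scale in [0, 1]; 0 switches all stochastic movement off |
| `beta0` | 1.0 | attractiveness at distance zero |
| `gamma` | 1.0 | light absorption. Random positions in [0, 1]^K sit at r² ≈ K/6 apart, so attraction is only effective when γ·K/6 ≲ 1. Use the dimension-scaled value γ = 6/K (which reduces to the conventional 1.0 at K = 6); the `RunConfig` default keeps the small-K convention |
| `threshold` | 0.5 | encoding cut; strict inequality, so a component exactly at the threshold deselects its channel |
| `objective_set` | validation | split on which the search objective is computed |

## The synthetic-data generator

`synthetic.generate` draws X with i.i.d. uniform [0, 1] entries,
plants a support set of columns with weights drawn uniform on
[0.5, 1.5] (so every planted channel is materially informative; a
near-zero weight would make recovery ill-posed), and sets
y = X[:, support]·w + ε with Gaussian ε whose standard deviation is
`noise_frac` times the sample standard deviation of the noiseless
response. The preconfigured scenarios plant 5 or 10 of K = 200
channels over 775 samples — matching a 389/193/193
calibration/validation/prediction split — with `noise_frac` = 0.05,
a level at which the support stays identifiable while RMSEP remains
non-degenerate.

What the generator emulates: the planted-support recovery task on
which subset-selection methods are conventionally benchmarked — a known
ground truth, independent uninformative channels, and homoscedastic
response noise. What it does not emulate: real spectra are smooth and
strongly collinear across neighbouring wavelengths, baselines drift,
and noise enters X as well as y. Passing the recovery tests therefore
demonstrates that the search machinery finds sparse generating sets
under controlled conditions; it does not by itself certify performance
on instrument data, where channel collinearity makes the "correct"
subset ill-defined.

A structural property worth noting: with the validation set guiding
selection, dense masks can noise-fit the validation samples and reach a
*lower* validation RMSEP than the true support. The error objective
alone therefore never prefers the sparse truth — the size objective and
the decision maker are what pull the answer back to the support. This
is by design and mirrors why the multiobjective formulation exists at
all.

## Numerical choices

* Subset fits inside the search reuse a precomputed calibration Gram
  matrix (X'X, X'y, column sums): the normal equations of the
  intercept-augmented subset system are assembled by indexing and solved
  by Cholesky. This equals the pseudoinverse solution whenever the
  system is comfortably overdetermined and well conditioned (agreement
  ~1e−12, an order of magnitude tighter than any tolerance used here)
  at roughly a tenth of the cost; rank-deficient or ill-conditioned
  subsets (Cholesky failure, or a factor-diagonal ratio below √1e−10)
  fall back to the full SVD path. `fit_mlr` itself uses the same
  Cholesky-then-SVD strategy without the precomputed Gram.
* `batch_evaluate` deliberately routes through `evaluate_subset` so its
  output is bit-identical to sequential evaluation, as its contract
  promises.
* Kennard–Stone and the decision maker break all ties deterministically
  (lowest index / fewest channels / lowest error / first occurrence).
* Empty masks, zero reference values in MAPE, and exact fits in the
  information criteria are all explicit, documented edge cases rather
  than silent NaNs.

## Known limitations

* The decision maker (normalised distance to utopia) is one standard
  choice among several; it is isolated behind `moo.decision_maker` so an
  alternative ranking can be swapped in.
* With very short archives (e.g. a front of two points) the min–max
  normalisation makes the knee sensitive to the front's extremes.
* The search cost is dominated by subset refits; it scales roughly with
  `n_fireflies² × max_iterations` in the worst case, mitigated in
  practice by mask-level caching.
* GPU or multi-process evaluation is out of scope; `batch_evaluate`
  defines the backend-neutral contract (a pure, order-preserving map)
  that a parallel implementation would have to satisfy.
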