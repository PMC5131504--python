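# Methods

## Problem

Binary classification of imbalanced biomedical tabular data: the target
(minority) class — deaths, positive tests, rare diagnoses — is outnumbered
by the ordinary (majority) class at ratios from roughly 5:1 to 40:1.  A
classifier trained on such data tends to predict the majority class almost
everywhere and still posts high accuracy ("pseudo-accuracy"), while its
chance-corrected agreement, Cohen's kappa, stays near zero.  This package
treats kappa as a first-class objective alongside accuracy and rebalances
the data so that both can be high at once.

## Metrics

All statistics are computed from the binary confusion matrix with the
minority class on the positive axis:

- accuracy = (TP + TN) / (P + N);
- kappa = (Po − Pc) / (1 − Pc), with Po the observed agreement (accuracy)
  and Pc the chance agreement from the marginals.  When Pc = 1 (all mass in
  one cell) kappa is defined as 0: agreement equals chance in the only
  realizable sense.  Kappa ≤ accuracy whenever Pc < 1, which the test suite
  verifies as a property;
- G-mean = √(sensitivity × specificity), F1 = 2TP / (2TP + FP + FN) — the
  standard textbook forms;
- reliable accuracy = kappa × accuracy, the scalar used to pick one
  solution from a Pareto archive.

Which class F1 scores is configurable (`fmeasure_positive`): the default is
the minority class (the imbalanced-learning convention), but published
benchmark tables in this area are sometimes only consistent with a
majority-positive F1 (near-perfect F1 next to near-zero kappa), so both
conventions are exposed and neither is asserted as canonical.

Kappa maps to qualitative bands on two scales: six bands
(< 0 less-than-chance, then slight/fair/moderate/substantial/almost-perfect
with cut points 0.20/0.40/0.60/0.80, right-closed) and four credibility
bands with cut points 0/0.4/0.75.  The printed six-band bins start at 0.01;
the unassigned sliver [0, 0.01) is folded into "slight agreement".

`sweep_confusion(m, n)` enumerates the (m+1)(n+1) lattice of matrices with
TP + FP = m and TN + FN = n, walking from the all-wrong to the all-correct
matrix; it exists to illustrate how kappa reacts along that trajectory far
more sharply than accuracy (for m = 100, n = 5 the walk has 606 states).

## SMOTE core

Synthetic minority samples are linear interpolations
x_new = x_i + (x_t − x_i)·v_rand with v_rand ~ U[0,1], x_t drawn uniformly
from the k nearest minority neighbours of x_i (Euclidean, self excluded,
distance ties broken by lower row index).  N, the oversampling rate, is the
integer number of synthetic samples per minority sample, so augmentation
multiplies the minority by (1 + N).  A one-sample minority fails loudly
rather than silently duplicating the lone point.  Features enter the
neighbour search as-is; standardise first if the columns have incomparable
scales.

Baselines built on this core:

- **full-balance SMOTE** appends exactly (majority − minority) rows,
  cycling base samples round-robin so per-sample synthesis counts differ by
  at most one — integer N alone cannot land on an exact 1:1 ratio;
- **Random-SMOTE** draws (N, k) uniformly from bounds and applies SMOTE
  once; the harness averages over repeated draws.

Default search bounds: N ∈ [1, 2·⌈imbalance ratio⌉] — deliberately allowing
the minority to overshoot the majority, because exact parity is not where
the best models live — and k ∈ [1, min(10, minority − 1)].

## The swarm search (DMSMOTE / SDMRA)

(N, k) are tuned per sub-dataset by PSO: velocity update
v ← ωv + c1·r1·(pbest − x) + c2·r2·(gbest − x), position clamped to bounds,
with ω = 0.7298 and c1 = c2 = 1.49618 (standard constriction-equivalent
constants; not specified by the protocol we follow, fully exposed in
config), velocities clamped to 20 % of each bound's range.  Particles carry
a continuous 2-D position decoded to integers by rounding and clamping (k
additionally clamped to minority − 1).

Both objectives (kappa, accuracy) are kept: every evaluation streams
through a non-inferior archive (candidates dominated by no member enter,
members they dominate leave), and the global best fed to the velocity
update is drawn uniformly at random from the archive each iteration.  A
particle's personal best is replaced when (i) the new evaluation is better
on both objectives, or (ii) strictly better on one and within `tolerance`
(default 0.05; named but never valued in the protocol) on the other, or
(iii) the old personal best's kappa sits below the current credibility
threshold.  Otherwise the particle is "randomly removed": position and
velocity re-drawn uniformly, personal best reset — literal removal would
shrink the swarm.  Reading criterion (iii) against the old particle (rather
than the new) is an interpretation: displacing stagnant low-credibility
bests is productive, rewarding low-kappa newcomers would not be; a
`keep_old_on_fail` flag preserves the alternative reading of the removal
clause.

The threshold ladder 0.2 → 0.4 → 0.6 → 0.8 escalates when every particle's
personal-best kappa exceeds the current rung at the end of an iteration,
and never descends (the escalation trigger is unstated in the protocol;
this rule is the package's choice).  At termination the archive member with
the highest reliable accuracy wins.  An optional early stop fires once an
archive member reaches kappa ≥ 0.999 and accuracy ≥ 0.999 (disable for
fully protocol-faithful runs).

The predecessor **SRA** is the single-objective control: plain PSO on
accuracy in which personal/global bests only update when kappa > 0.4 and
accuracy strictly improves; if nothing is ever feasible the best-kappa
evaluation is returned flagged.

Because the inner evaluation is a pure function of (N, k) — synthesis draw
and holdout split are both derived from a per-sub seed and the parameters —
evaluations are cached on the decoded integer pair; this changes nothing
about the search trajectory and avoids re-training on revisited parameters.

## Majority decomposition

The majority class of real biomedical data mixes latent sub-populations.
k-means over the majority, with the centre configuration searched by PSO
(fitness = SSE after ≤ 5 Lloyd refinement steps of the decoded centres;
the winning centres get a full refinement), avoids poor local optima of
random-init Lloyd.  Lloyd refinement stops when the SSE change drops below
1e-8 or after 300 iterations; an emptied cluster is re-seeded at the sample
farthest from its assigned centre.

The cluster count is chosen adaptively under two termination conditions:
k must exceed 1, and the minimum screening kappa over the resulting
sub-datasets (each = one majority cluster + the full minority class) must
exceed 0.2.  k is searched ascending from 2 — the smallest qualifying k
fragments the majority least — up to
k_max = min(8, ⌊maj/(2·min)⌋ + 2, ⌊maj/10⌋); a k producing a cluster of
fewer than 5 samples is skipped.  Screening uses a seeded stratified 70/30
holdout, not full CV: it runs inside a loop.  If no k qualifies, the k with
the best minimum kappa is returned flagged `fallback` (the protocol does
not say what happens in this case).

## Pipeline and evaluation

Per sub-dataset: if the minority already outnumbers the sub-majority the
classifier is applied directly (skip rule, recorded as such); otherwise the
swarm search runs.  The final result is the component-wise arithmetic mean
of the per-sub metrics — sub-classifiers are never ensembled at prediction
time, only their metrics are averaged.

The verification classifier is a pluggable contract; the default is a
standardiser followed by a single-hidden-layer MLP
(hidden = max(5, ⌈(d+2)/2⌉), adam, learning rate 1e-3, 200 epochs, seeded).
This default deliberately represents the practitioner's network, not an
oracle: on raw 15:1 data its fate depends on initialization — some seeds
learn the minority, others collapse to majority-voting with near-zero kappa
— which is precisely the instability the rebalancer removes.  Reported
numbers therefore come from repeated stratified ten-fold cross-validation
in which **each repeat re-initializes the network** as well as reshuffling
folds; single-repeat numbers on raw imbalanced data are not stable and
should not be quoted.

Two CV modes: `paper_faithful` (default) rebalances once and
cross-validates the augmented data — the protocol of the benchmark this
package reproduces.  Note what that implies: synthetic points are
interpolations of minority points that also appear in training folds, so
test folds are easier than truly unseen data and every oversampler's
numbers are flattered.  `within_fold` synthesizes only from each training
fold's minority rows and is the methodologically clean mode; it is provided
for the non-swarm methods (none / smote / random_smote), where the
leakage question actually arises in practice — running a full swarm search
inside every fold of every repeat is out of proportion to the mode's
diagnostic purpose, so `sra`/`ascb_dmsmote` raise a clear error there.
Fold records carry synthetic-row provenance so tests can assert test folds
stay clean.

Inner fitness evaluation uses a stratified 70/30 holdout of the rebalanced
sub-dataset rather than CV: at population 20 × 100 iterations × several
sub-datasets, nested ten-fold CV would multiply classifier trainings by an
order of magnitude for no change in the selection mechanics.

## Synthetic data

The generator plants the structure the method assumes: the majority is a
mixture of `majority_subclusters` spherical unit-σ Gaussians at the
vertices of a regular simplex with edge `cluster_separation`·σ; the
minority has its own component at exactly that separation from the nearest
majority mean; a `minority_overlap` fraction of minority points is
relocated into randomly chosen majority components.  Relocation, not
variance widening, keeps class counts exact and the clean minority geometry
interpretable.  Class counts and the imbalance ratio are exact by
construction; everything is seed-deterministic.  Default dimensionality is
2 — the smallest that admits a 3-vertex simplex, and the hardest for the
classifier since higher dimensions only increase Gaussian separability.

Frozen fixtures: `easy` (450:30, separation 8σ, no overlap — every stage
should succeed cleanly), `hard` (450:30, separation 4σ, 30 % overlap — the
regime where the direct classifier's kappa is unstable and rebalancing
pays), `extreme` (420:10, separation 6σ, 10 % overlap — the 42:1 edge of
the benchmark regime).  Seeds 11/23/37.

What the generator does not emulate: correlated or categorical features,
non-Gaussian cluster shapes, label noise, and the covariance structure of
real benchmark sets.  Passing tests on these fixtures show the machinery is
correct and that the method behaves as designed on data matching its
assumptions; they do not certify performance on any real dataset.

## Scale of the shipped experiments

Unit and acceptance tests run the swarm at reduced scale (populations 4-10,
5-25 iterations, 1-10 repeats) and the fixtures at a few hundred samples;
these sizes were chosen so the full suite completes in about two minutes on
one CPU while still exercising every code path at the documented study
conditions.  The protocol-scale settings (population 20, 100 iterations,
ten-fold CV × 10 repeats) are the library defaults and run fine; they are
simply not what the tests spin in a loop.

## Known limitations

- `paper_faithful` CV inherits the leakage described above; treat its
  absolute numbers as protocol-comparable, not deployment estimates.
- The archive is unpruned; with two objectives on small integer grids it
  stays tiny, but a future many-objective variant would need crowding.
- Only binary problems; only numeric features.
- The SRA fallback (nothing feasible) and decomposition fallback (no k
  clears the screening bar) are flagged, not silent; downstream code should
  check the flags.
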