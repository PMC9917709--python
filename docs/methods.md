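# Methods

This note documents the models and procedures implemented in
`musksynth`, the parameters that matter, the synthetic-data conditions,
and the design decisions taken where the procedure was genuinely open.

## Positive-unlabeled bagging

**Setting.** 11 molecules are positive (synthesized, commercialized
musks); 77 are unlabeled designed derivatives. No negatives exist.

**Procedure** (`musksynth.pulearn`). For t = 1..T: draw a uniform random
subset U_t of the unlabeled molecules, |U_t| = K, *without* replacement
(a with-replacement flag exists); train the base learner on
positives ∪ U_t with provisional labels 1/0; record the predicted class-1
probability of every molecule outside the training set. The
synthesizability of an unlabeled molecule is the mean of its out-of-bag
predictions; positives, which are in every training set, are scored by
the mean over all T classifiers. The *evaluation score* is the fraction
of molecules whose thresholded averaged prediction matches its training
label. "Relabeling per iteration" is exactly the random draw of U_t;
labels are never mutated persistently. A molecule that is never
out-of-bag is a hard error (raise T or lower K), not a silent NaN.

**Defaults and why.** T = 23 and K = |positives| follow the screening
protocol this package reimplements; τ = 0.5 with an *inclusive*
comparison (score ≥ 0.5 counts as synthesizable), because the published
per-model synthesizable sets include molecules printed at exactly 0.50 —
a strict comparison cannot reproduce them. Reports carry both the
inclusive and strict counts.

**Random streams.** One master seed; iteration t uses the substream
`SeedSequence(entropy=seed, spawn_key=(t,))`, so increasing T extends a
run without reshuffling earlier iterations.

**Base learners.**

* *rf*: scikit-learn `RandomForestClassifier` (bootstrap, √d features,
  Gini), 100 trees — a well-tested implementation of a standard
  component.
* *ert*: implemented in-repo. Trees are grown on the full training
  sample; at each node k = ⌈√d⌉ candidate features receive one
  uniform-random cut point each and the best Gini reduction wins; the
  ensemble probability is the arithmetic mean of leaf class frequencies.
* *gbc*: implemented in-repo from the update equations. F0 is the prior
  log-odds; each stage fits a least-squares regression tree (exhaustive
  axis-aligned split search over midpoints of consecutive distinct
  values) to the pseudo-residuals y − σ(F) and replaces each leaf value
  with the Newton step Σr / Σ(y−r)(1−y+r); the denominator equals
  Σ p(1−p) for 0/1 labels and is clamped to ±1e−6 in degenerate
  (saturated pure) leaves, with a logged warning. Defaults M = 100,
  depth 3, shrinkage ν = 0.1; ν = 1 reproduces the unshrunk update
  equations exactly, which is how the staged-oracle test checks the
  implementation to 1e−10.

## Descriptor reduction

`reduce_descriptors` scans columns left to right and drops a column iff
its |Pearson r| with an already-retained column exceeds the threshold
(default 0.6). Keeping the *earlier* member of a violating pair makes the
scan deterministic; the alternative (keep the higher-variance member) is
noted but not default. The retained set can depend on column order — the
test suite demonstrates this rather than hiding it. Correlation of a
constant column is an explicit error; cleaning (drop any column with
missing values, then any constant column) must run first. The 16
descriptor names retained in the original study ship as a fixture for
naming downstream objects, not as a reproduction target — the raw matrix
they were computed from is not public.

## Screening and endpoints

Threshold sets per model, exact intersection for the consensus, and the
search-space reduction 100·(n_unlabeled − n_kept)/n_unlabeled. Change
rates are 100·(derivative − parent)/parent, rounded half-up to two
decimals (half-up, not banker's: 26 109.375 must print as 26 109.38).
Verdicts combine the sign with the endpoint direction: receptor and
keratin docking scores are better lower (less abortion risk, less
bioaccumulation), olfactory binding and fish LC50 are better higher.
Cross-model deviations use 100·|a−b|/a with the first model's score as
denominator. Some published change rates do not recompute from the
printed inputs (they were evidently computed from unrounded sources);
only the recomputable ones are asserted.

## Sensitivity analysis

Descriptors are ranked by |Pearson r| with the synthesizability scores
(the univariate filter criterion; |r| is monotone in the univariate F
statistic at fixed n), the top 50% enter an OLS fit (statsmodels), and
the fitted linear model is probed one descriptor at a time:
SC_i = |ΔY/Y_den| / δ with x_i inflated by δ ∈ {10%, …, 50%} of its
baseline. The evaluation point is the per-descriptor sample mean — the
original study never states its evaluation point, and the mean is the
natural center. Two denominator conventions are first-class:

* **base** (Y_den = unperturbed prediction): SC is δ-invariant for a
  linear model, with closed form |b_i·X̄_i / Y(X̄)| — used as an exact
  invariant in the tests;
* **perturbed** (Y_den = perturbed prediction, the default): SC drifts
  with δ, which is the only convention under which growth rates of |SC|
  across the grid are non-trivial; since the growth-rate analysis is the
  point of the exercise, this is the default. Signed SC values are
  reported alongside the absolute ones, since the published analysis
  does not state which it used.

The three published linear models (one per base learner) ship as JSON
fixtures and drive the sensitivity engine and the parameter-recovery
test; their printed growth-rate tables are not asserted because they
require the unavailable real descriptor baselines.

## Hydrogen bonds

A contact is a hydrogen bond iff the H···A distance is strictly below
3.2 Å. E_HB is estimated from the bond-critical-point electron density
by a *fitted* least-squares line rather than hard-coded constants; on the
packaged 26-bond table the fit gives ≈ −223.0·ρ + 0.73 kcal/mol, matching
the published neutral-system relation, with all residuals ≤ 0.12
kcal/mol — the bound implied by ρ being printed at 3 decimals
(±0.0005 a.u. × slope ≈ 0.11). Density outside (0, 0.05] a.u. triggers an
extrapolation warning. Strength classes: very weak above −2.5 kcal/mol,
weak-to-medium in (−14, −2.5], strong at or below −14 (absent from the
data but included for completeness). The −2.5 boundary is assigned to
weak-to-medium: the published prose is garbled at the boundary, and all
26 printed labels are consistent with this choice. Formation rate =
percent of a molecule group with ≥ 1 bond; weak-bond fraction = percent
of the group's bonds classified weak-to-medium.

## Synthetic data

`generate_descriptor_table` emulates the unpublished matrix:

* 88 molecules, 11 positives, 200 descriptors by default (the full-width
  1471-descriptor configuration with 449 all-missing columns,
  `FULL_SCALE_CONFIG`, reproduces the 1471 → 1022 cleaning step; 200
  keeps routine runs fast without changing the structure);
* exchangeable-correlation blocks: all columns of a block share a latent
  factor, so within-block pairwise correlation equals `block_rho`
  (default 0.7, above the 0.6 pruning threshold, so pruning collapses
  each block);
* `n_signal` = 8 descriptors carry a standardized mean shift
  `effect_size` = 2.0 between the truly synthesizable and
  non-synthesizable groups, placed one per block as the block's first
  column so that pruning retains the signal-bearing representative. The
  first four signal columns follow the direction pattern observed for
  the four key descriptors: synthesizable molecules get higher
  energy-gap-like and E_HOMO-like values and lower qH⁺-like and
  dipole-like values;
* the truly synthesizable fraction is 0.35 (11 positives plus roughly a
  quarter of the 77 unlabeled, the order suggested by the screening
  outcome), and positives are sampled only from that group;
* hidden truth labels are returned separately and never enter the table.

What the generator does **not** emulate: realistic quantum-chemistry
value ranges and units, heavy-tailed or discrete descriptor
distributions, label noise among the positives, and any structure
linking descriptors to the endpoint or hydrogen-bond tables. Passing
recovery tests therefore show the pipeline extracts a class signal
embedded in correlated noise at realistic sample sizes — not that the
published biological conclusions follow.

The endpoint generator writes parent/derivative rows with exact
fractional shifts per endpoint (zero shift ⇒ all change rates exactly
0%). The hydrogen-bond generator draws densities uniformly from a range
inside the calibration's validity window and applies the linear map plus
bounded Gaussian noise (clipped at 3σ so no bond flips to a positive
energy); with zero noise, classification and calibration-recovery are
exact by construction.

## Problem sizes and runtime

Routine tests use 200-descriptor tables and 10-seed replicates; the
truth-recovery check (10 seeds × full pipeline with the RF learner) and
the acceptance script each complete in well under a minute on one CPU.
The full-width 1471-descriptor configuration is exercised once for the
cleaning-step count.

## Known limitations

* The published evaluation scores (0.705/0.727/0.770), the 10.13%
  cross-model deviation bound and the CoMSIA statistics depend on the
  unpublished descriptor matrix and commercial software; they are not
  reproduction targets. Generic q²/R²/SEE/r²_pred statistics are
  provided as reusable operations instead.
* PU scores are not calibrated probabilities; no class-prior correction
  (e.g. Elkan–Noto) is applied, matching the protocol being
  reimplemented.
* The greedy pruning is order-dependent by design; a different column
  order can retain a different (equally valid) representative set.
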