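# Methods

## Model

The classifier is a sparse weighted sum of interval-conjunction rules,

    f(x) = Σ_{j=1}^{M} a_j h_j(x) + b,

where the implicit rule space H = {h_1, …, h_M} contains every conjunction
of one-dimensional closed intervals over a discretized feature grid, and
only the rules with nonzero weight are ever materialized. A rule such as
`I(1.0 ≤ x3 ≤ 2.0) I(x5 ≥ 0.5) I(x6 ≤ 0.8)` is the model's unit of
explanation: it is either satisfied by a subject or not, and the subject's
score decomposes exactly into the bias plus the weights of the satisfied
rules.

### Discretization

Each continuous feature is cut at its interior B-quantiles (default
B = 10), deduplicated, with cuts at the feature's extremes dropped
(they separate nothing) and constant features contributing no cuts.
Quantile cuts are robust to the skewed distributions typical of biomarker
concentrations. Every cut `c` on feature `j` spawns two *items*,
`x_j ≤ c` and `x_j ≥ c`; a conjunction of items reduces per feature to an
interval (lower bound = max of ≥-thresholds, upper = min of ≤-thresholds,
empty if they cross), so the rule space is exactly the itemset lattice
over the catalogue and can be searched by itemset mining. Bounds are
closed on both sides; a value lying exactly on a cut satisfies both
directions. Missing values are rejected at load time — imputation is the
caller's responsibility.

### Training objective

With labels y ∈ {+1, −1} and per-sample margin z_i = y_i f(x_i), training
minimizes

    Σ_j |a_j| + C⁺ Σ_{y_i=+1} φ(z_i) + C⁻ Σ_{y_i=−1} φ(z_i),

where φ is the double hinge with rejection cost d ∈ (0, 0.5]:

    φ(z) = max(0, 1 − z, 1 − k z),   k = (1 − d)/d.

φ is convex, piecewise linear, nonincreasing; at d = 0.5 it is the
ordinary hinge, and as d decreases the negative-domain slope −k steepens,
reflecting that misclassification grows relatively more expensive than
abstention. d = 0 is rejected as an invalid configuration (the steep
branch's slope diverges).

Class imbalance is handled by separate costs. The single-knob default is
C⁺ = C·n/(2n⁺), C⁻ = C·n/(2n⁻) (balanced weighting); both costs can also
be set explicitly.

### Linear program and column generation

Splitting a_j = a_j⁺ − a_j⁻ (a_j± ≥ 0) and introducing slack ξ_i ≥ 0 with

    ξ_i ≥ 1 − z_i,   ξ_i ≥ 1 − k z_i,

the objective becomes the LP

    min Σ_j (a_j⁺ + a_j⁻) + Σ_i C_{y_i} ξ_i,

exact because φ(z) = max(0, 1 − z, 1 − k z). The bias b is free and
unregularized (standard LP-boosting convention). The LP over all M rules
is intractable to materialize, so a restricted master problem over the
columns found so far is solved with HiGHS (via
`scipy.optimize.linprog`), and new columns are priced in from the duals:
with multipliers α_i, β_i on the two slack constraints, the *effective
mining weight* is u_i = α_i + k β_i ≥ 0, and dual feasibility for any
rule h reads |Σ_i y_i u_i h(x_i)| ≤ 1 (with Σ_i y_i u_i = 0 from the free
bias and u_i ≤ k C_{y_i} from the box constraints). This derivation is
verified numerically in the test suite by checking the returned duals
against all of these constraints and against strong duality on random
instances.

Each iteration adds the single most-violated rule, found by the pricing
oracle below; generation stops when the best gain is ≤ 1 + ε (ε = 1e−6)
or after `max_iterations` (default 100). Because the full problem is one
convex LP, termination implies global optimality over the entire rule
space — asserted in the tests by comparison with a fully enumerated LP on
small instances.

### Pricing by branch-and-bound weighted itemset mining

The pricing problem — maximize g(S) = |Σ_{i ∈ cover(S)} y_i u_i| over
itemsets S with |S| ≤ `max_rule_order` (default 3) — is solved by
depth-first search over the item catalogue in its canonical order
(feature index, ≤ before ≥, threshold ascending). At a node with cover V
the bound max(Σ_{i∈V, w_i>0} w_i, −Σ_{i∈V, w_i<0} w_i), w_i = y_i u_i, is
anti-monotone under cover shrinkage, so subtrees whose bound cannot beat
the incumbent are pruned without ever cutting the optimum (the tests
compare against exhaustive enumeration on hundreds of random instances).
Empty covers are pruned; a second item with the same feature and
direction as one already chosen is skipped (it cannot change the optimal
gain and would only enlarge the itemset). The incumbent is replaced only
on strict improvement, which breaks ties deterministically toward the
first (smallest, in catalogue/DFS order) maximizer.

## Rejection and calibration

Scores are mapped to posteriors η(x) = P(y = +1 | x) by isotonic
regression (pool-adjacent-violators, via scikit-learn), fitted on
*out-of-fold* scores: the model is refitted on each of `folds` (default
5) stratified fold-complements with the same configuration, and the
pooled held-out (score, label) pairs are regressed. Training scores are
optimistically biased, which would shift the calibrated band. The map is
piecewise linear between PAV breakpoints, constant beyond the fitted
range, clipped to [1e−6, 1 − 1e−6]; it depends on score ranks only.

With misclassification cost 1 and rejection cost d, the decision with
smallest expected cost is +1 if η > 1 − d, −1 if η < d, and reject inside
the band [d, 1 − d]; boundary values reject. The band shrinks to {0.5} as
d → 0.5 and is nested across d.

Because practitioners usually quote operating points as a rejection
*rate* rather than a cost, `decide_at_rejection_rate` abstains on the
round(RR·n) samples whose η is closest to 0.5 (the empirical analogue of
the symmetric band; the rejected count is the nearest-integer realization
of the target, ties in |η − 0.5| broken by sample order). Classified
subsets are therefore nested along an increasing RR grid, and SN/SP/ACC/
AUC at an operating point are computed on the classified subset only.

## Two-stage screening cost model

A `CostPolicy` holds two stages (e.g. plasma at 1 unit, CSF at 10 units)
with the referral rule "stage-1 reject → stage-2". A two-stage policy
costs n·c1 + n_rejected·c2 against n·c2 for the expensive single stage;
correctness counts final decisions equal to the label, with stage-2
abstentions (possible only if the second model also rejects) counted as
incorrect and flagged. Costs are abstract units; the worked 47-subject
example with 12 referrals (167 vs. 470 units) is kept as a fixed
regression test.

## Synthetic cohorts and recovery scoring

The generator draws X iid per feature (uniform [0, 1] by default, or
standard Gaussian), plants a small rule ensemble, labels by
sign(Σ_k w_k r_k(x) + b0) with sign(0) → −1, and flips each label
independently with probability ρ < 0.5 — so the Bayes accuracy is 1 − ρ
by construction and fitted models cannot legitimately beat it. The
default profile mirrors a plasma-proteomics panel: p = 14 features,
n = 151, two planted order-2 rules combined as an OR (either firing makes
the subject positive), ρ = 0.05, ≈64% positives. Planted boundaries are
placed on multiples of 1/8 (0.25/0.625 and 0.375/0.375) so that, at the
recovery experiment's B = 8, the truth is representable on the quantile
grid in expectation: a recovery experiment should measure recovery, not
discretization error. What the generator deliberately does *not* emulate:
correlated features (real protein panels are strongly correlated),
covariate shift, measurement batch effects — so green recovery tests
certify the optimizer and scoring pipeline, not clinical performance.

Recovery is scored per planted rule as the best item-level Jaccard
similarity against any fitted rule, after snapping each truth boundary to
the model's cut grid. A truth boundary strictly between two cuts accepts
*either* bracketing cut as a match: discretization bounds recovery
resolution to one bin width, and nearest-value snapping would arbitrarily
demand half-bin agreement. A rule counts as recovered at Jaccard ≥ 0.5.

### Validation experiment sizes

The exhaustive references dictate small instances: pricing exactness uses
200 random instances with n ≤ 30, p ≤ 4, B = 3, order ≤ 3 (enumeration
over ~700 itemsets each); column-generation optimality uses 50 instances
with n ≤ 25, p ≤ 3, B = 3, order 2 (every itemset materialized as an LP
column). The recovery experiment fits five cohorts of n = 500 with the
protocol C = 0.3, d = 0.5, B = 8, order cap 2 (the planted order),
60 iterations — moderate L1 pressure so the planted rules carry the bulk
of the weight — and evaluates AUC on an independent n = 2000 draw. The
whole validation battery runs in about a minute on one CPU.

## Numerical choices and edge cases

* LP tolerance 1e−7; dual marginals from HiGHS are clipped at 0 before
  forming u. HiGHS is deterministic on a fixed problem, so fits are
  reproducible bit-for-bit for a fixed dataset and configuration.
* Stored model weights keep |a_j| > 1e−12; zero-weight columns generated
  along the way are dropped from the final model.
* Degenerate inputs fail loudly: single-class labels and all-constant
  feature matrices are unfittable; specs whose planted rules label every
  sample identically are rejected; all-rejected decision vectors make
  metrics undefined.
* Repeated pricing of an already-added itemset (possible only through
  dual degeneracy at numerical tolerance) terminates generation rather
  than looping.
* Serialization is versioned JSON; scores of a round-tripped model are
  bitwise identical because weights, cuts and calibration breakpoints are
  stored as exact binary64 values.

## Known limitations

* Rule search cost grows with the item catalogue (p·2·(B−1) items);
  pruning keeps realistic panels (p ≲ 50, B ≤ 10) fast, but adversarial
  dual-weight patterns can approach the combinatorial worst case.
* Isotonic calibration needs enough out-of-fold score diversity; on tiny
  cohorts the posterior map is step-like and the rejection band coarse.
* Only binary classification, two screening stages, and numeric features
  are supported.
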