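# Methods

## Model and estimand

`anchorq` works inside the deterministic-input noisy-gate family of
cognitive diagnosis models.  Each of N examinees carries a binary mastery
profile α over K attributes; each item *j* carries a binary q-vector
q_j of required attributes.  The deterministic ("ideal") response is

* conjunctive gate (DINA): η = 1 iff every required attribute is mastered;
* disjunctive gate (DINO): w = 1 iff at least one required attribute is
  mastered.

Observed responses add item-level noise: P(correct) = 1 − s_j when the
gate fires, g_j otherwise, with slip s_j and guess g_j in [0, 1).  An item
with an all-zero q-vector has η = 1 and w = 0 for every profile (the
empty-product convention of the two gate definitions); such items are
excluded from reduced Q-matrices but the convention matters for validation
paths that see zero columns.

The estimand is the Q-matrix of the test's unlabelled items.  The expert
input is restricted to K anchor items whose q-vectors are the columns of a
reachability matrix R = (A + I)^K (Boolean powers of the attribute
prerequisite adjacency matrix); under the independent structure studied
throughout, R = I_K.

## The subset-search estimator

Every column of a reduced Q-matrix is the entrywise OR of a subset of
reachability columns, and — for independent attributes — that subset
relationship transfers exactly to the latent response matrix: q_j is the
OR of columns {r_l : l ∈ S} iff the latent column of item j is the AND
(conjunctive) or OR (disjunctive) of the anchor latent columns in S.
These are if-and-only-if statements, verified in the test suite by
exhaustive enumeration over all 2^K profiles and all non-empty subsets for
K ≤ 5.  The estimator transplants the identity from latent to observed
data: for each unknown item it enumerates all 2^K − 1 non-empty subsets S,
combines the observed anchor columns with AND (DINA) or OR (DINO), and
keeps the subset minimising the Hamming distance to the item's observed
column; the q-vector estimate is the OR-expansion of the winner.  Items
are estimated independently; nothing is shared across unknown columns.

Numerical choices:

* **Loss.**  The binary quadratic form (Y − c)ᵀ(Y − c) equals the Hamming
  count for 0/1 vectors, so the loss is computed as an exact integer;
  no floating point enters the argmin.
* **Enumeration order and ties.**  Subsets are enumerated by cardinality
  and then lexicographically, and the first minimum wins.  The argmin can
  be genuinely non-unique (with duplicate anchor columns, or under
  hierarchies where e.g. η₄ = η₂∧η₃ = η₁∧η₂∧η₃), so ties resolve to the
  smallest, lexicographically earliest subset: parsimonious and
  deterministic.  Under the independent structure with noise-free data the
  tied subsets expand to the same q-vector, so the tie-break never changes
  a noiseless estimate.
* **Enumeration cap.**  The search is O(2^K); K > 20 raises unless the cap
  is overridden explicitly.
* **Anchor blocks with repeated q-vectors** (possible for hierarchical R)
  are allowed: the search runs over item-column subsets, which is what the
  observed-data loss is defined on.
* **No loss-gap filtering.**  The margin between the best and second-best
  subset is reported as a per-item diagnostic but never used to veto an
  estimate.

Behaviour under a non-identity (hierarchical) R is exposed but carries no
accuracy guarantee: the subset/column biconditional is proved only for the
independent structure, and the package tests hierarchies only through
their Boolean column identities.

## Sampling designs

Two examinee-profile designs are implemented, both i.i.d. with
replacement:

* **random** — uniform over all 2^K mastery patterns;
* **optimal** — uniform over the K patterns that drive the
  identifiability proofs: 1 − e_k (all attributes but one) for DINA,
  e_k (exactly one attribute) for DINO.  Over these K profiles, distinct
  anchor subsets produce distinct noiseless predictions, so the noiseless
  minimiser is unique; this is what makes the design "optimal" for
  discriminating q-vectors.

No stratification or balancing is applied to the random design; at N = 30
some of the 32 patterns are necessarily absent from any sample, which is
visible as the lower recovery at the smallest sample size.

## The simulation study

The Monte-Carlo grid crosses sample size N ∈ {30, 60, …, 300}, anchor-item
slip/guess level and unknown-item slip/guess level ∈ {0, 0.05, …, 0.45},
model ∈ {DINA, DINO} and design ∈ {random, optimal}, with K = 5
independent attributes and 30 replications per condition.  A noise
"level" x sets s_j = g_j = x for every item in its block — the anchor
block and the unknown block each get one scalar level; slip and guess are
never varied separately.  Each replication simulates responses on the test
Q-matrix [I₅ | Q_r] with Q_r the full 31-column reduced Q-matrix, then
estimates all 31 unknown q-vectors from the anchor block and scores the
correct recovery rate CRR (fraction of matching entries among the
5 × 31 = 155 cells).

Summary conventions:

* CRR is computed per replication and then averaged; the per-condition SD
  is the sample SD (ddof = 1) of the 30 replication values.
* The per-sample-size summary pools the raw replication CRR values of all
  100 parameter combinations at that N (not the per-condition SDs, and not
  an SD of condition means); this pooled convention is what yields
  across-grid SDs of roughly 0.15.  Marginal rows/columns of the
  level × level tables are unweighted means of their cells, which equals
  the pooled replication mean because every cell has the same replication
  count.

### Randomness discipline

One master seed governs a run.  Replication r of a condition draws from
`SeedSequence([master, model, design, N, anchor_level, unknown_level, r])`,
so every cell of every table is reproducible in isolation, grids can be
subset or re-ordered without changing any value, and parallel scheduling
cannot affect results.  Parameter combinations use independent streams
(no common random numbers across conditions).  Response generation keeps
the u ≤ P convention (a uniform draw exactly equal to the success
probability counts as correct) — irrelevant for a continuous generator but
fixed for determinism of the contract.

## What the generator does and does not emulate

The simulator reproduces the study conditions exactly: independent
attributes, equal slip and guess within a block, i.i.d. profile sampling,
and conditionally independent Bernoulli responses.  Real assessments
violate most of these — attributes correlate, item parameters vary by
item, populations are not uniform over patterns, and responses can carry
dependence beyond the latent class (testlets, speededness).  Passing the
recovery benchmarks therefore demonstrates correctness of the algorithm
under its stated model, not robustness to model misspecification.  In
particular, items requiring attributes absent from R are out of scope: the
estimator can only return OR-combinations of reachability columns.

## File formats and conventions

Matrices are exchanged as strict 0/1 integer CSV with labels.  In-memory
Q-matrices are attributes × items (the traditional orientation); files
default to rows = items and columns = attributes, the now-common layout,
with an `attributes_in_rows` flag for the transposed layout, because both
conventions circulate and silent transposition is a classic source of
error.  Attribute subsets are 0-based in the API and 1-based (A1…AK) in
CLI output and diagnostics.  Student/reduced-matrix columns are ordered by
binary counting with attribute 1 as the least significant bit (attribute 1
toggles fastest), matching how the classical worked examples print these
matrices.

One wrinkle in those worked examples: the disjunctive-gate latent matrix
of the K = 2 example is sometimes printed identically to the conjunctive
one, which contradicts the OR-gate definition (a profile mastering either
attribute answers the q = (1,1) item correctly).  The fixture bundle
exposes both the recomputed matrix (`W`) and the printed variant
(`W_printed`); all computation follows the gate definition.

## Problem sizes used in the checks

The acceptance script and the end-to-end tests run the study at its full
published scale — K = 5, 31 unknown items, N up to 300, the complete
10 × 10 noise grid and 30 replications per condition — for the DINA arm,
and at N = 300 for the cross-model comparisons; a single condition takes
on the order of a tenth of a second, the full DINA/random grid about a
minute.  Tolerances on reproduced table values follow the Monte-Carlo
noise of a 30-replication mean: ±0.03 on single cells, ±0.02 on
grid-pooled means.
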