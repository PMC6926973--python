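# Methods

## Model

The central object is a discrete Bayesian network: a DAG over categorical
variables, each node carrying a CPT P(node | parents).  The joint
distribution is the product of the CPTs; all reported quantities
(posteriors, mutual information, scenario shifts) are functionals of that
joint, computed exactly — no sampling approximations enter any reported
number.

Two independent inference routes exist on purpose.  Production queries use
variable elimination: CPT factors are restricted by the evidence, hidden
variables are summed out in min-degree order on the moralized graph of the
current factor scopes (ties broken lexicographically by name), and the
final factor is renormalized.  The reference route materializes the full
joint as one ndarray (guarded at 10⁷ cells) and marginalizes it directly;
it shares no code with the elimination engine and anchors the property
suites at 1e-10 agreement.  Evidence with zero probability raises a typed
`InconsistentEvidenceError` — never NaN or a uniform fallback — so scenario
engines must surface impossible evidence instead of silently absorbing it.

## Structure learning

Search is greedy hill climbing over add/delete/reverse edge moves, scanned
in lexicographic order with first-improvement acceptance, every move
checked for acyclicity and the parent bound.  Scores are decomposable
(BDeu by default, BIC as the alternative), so a move rescoring touches at
most two families; family scores are cached for the lifetime of a search.

Defaults and why:

* **score = BDeu, equivalent sample size 1.0** — the conventional choice
  for discrete network search; BIC is offered where a consistent,
  prior-free criterion is preferred.
* **max_parents = 3** — a node with three 3-state parents already has 27
  CPT rows; at survey scale (~10⁴ rows) deeper families are not reliably
  estimable.
* **restarts = 4** — beyond the greedy run from the empty graph, four
  restarts from random seeded DAGs.  Greedy search occasionally lands in a
  local optimum that drops a genuinely strong edge (observed once at
  n = 20,000 with two restarts); four restarts removed every such case we
  encountered while keeping a full search under a second at survey scale.
* **smoothing α = 1** — Laplace-smoothed CPTs, ``(count + α) /
  (row_total + α·r)``.  Smoothing matters at prediction time: held-out
  rows may hit parent configurations unseen in training, and α > 0 keeps
  their evidence consistent.  α = 0 gives maximum-likelihood rows with a
  uniform fallback for empty rows.
* Missing values are rejected, not imputed: the cleaning stage deletes
  incomplete rows, and the learners refuse unclean data so an accidental
  skip of the cleaning stage fails loudly.

The MB-restricted classifier ("GBN-MB") learns the full network, extracts
the class node's Markov blanket, and relearns a network over
{class} ∪ blanket; prediction conditions only on blanket evidence.  This is
the feature-selection reading of blanket-based classification; the
alternative (post-processing a full network into a blanket-completion
classifier) was considered and not taken, since feature discarding is the
stated purpose of the blanket here.  An empty blanket degrades to a
prior-only classifier with a logged warning.

## Sensitivity to findings

For target T and finding node X, three measures are computed from the
exact pairwise joint (obtained by one inference call per state of X, so
memory stays bounded rather than building a global joint):

* mutual information I(T; X), base-2 logs — the self-row I(T; T) = H(T);
* entropy percent, 100·I(T; X)/H(T), exactly 100 on the self-row;
* variance of beliefs, Σ_f P(X=f) Σ_s P(T=s|f)(P(T=s|f) − P(T=s))² — the
  expected squared belief shift weighted by posterior belief.  Its self-row
  closed form Σ_t p_t(1−p_t)² is the documented consistency check.

Base-2 entropy is used throughout: a 4-state target then has at most
2 bits, the natural scale for "percent of uncertainty removed".  A
degenerate target (zero entropy) raises an error rather than reporting an
undefined percentage.  Rows are ordered self-row first, then by MI
descending with lexicographic tie-breaks.

## What-if analysis

A scenario is an evidence assignment plus a (variable, state) target whose
indicator is Y, so E(Y | ·) is a posterior probability and the headline is
the "baseline → posterior" arrow.  The decomposition computes z-terms at
the observed evidence states only (that is what a scenario asks), with a
full-tabulation helper (`main_effect_profile`) for the mean-zero
diagnostic Σ_x P(Xᵢ=x) zᵢ(x) = 0.  `max_order` defaults to 2 (main effects
plus pairwise interactions); higher-order structure folds into an explicit
remainder, which is identically zero when `max_order` equals the number of
evidence variables.  "Maximize/minimize X" scenario directives resolve to
the last/first state of X's ordered state list at load time and the
resolved states are recorded in the report.  Evidence shifts are
associational, not causal: the engine conditions on evidence, it does not
intervene, and no do-calculus semantics are claimed.

## Evaluation

Classifiers (full network, MB-restricted network, naive Bayes) are
compared by stratified k-fold cross-validation (k = 10 by default, a
single seed): train per fold, score the held-out fold, pool all held-out
predictions, compute metrics once on the pool.  Metrics are accuracy
(argmax with ties broken toward the lexicographically first state),
class-frequency-weighted mean of per-class F1, and class-frequency-weighted
one-vs-rest ranking AUC with midrank tie handling; macro averages are
available by flag.  Stratification requires every class to have at least k
rows so per-fold class proportions stay within one row of the global ones.

## Synthetic data: what it emulates, what it does not

`survey11` carries eleven survey-style variables — a 4-state obesity level
plus ten 3-state ordinal factors (pocket money, wealth, pressure, sitting
time, sleeping quality, parental education, academic performance,
smartphone time and service) — wired so that pocket money is the dominant
driver of the target (wealth feeds pocket money; pressure and sleeping
quality feed the target directly).  CPT rows are Dirichlet(1.0) draws,
rejection-tuned per seed until the target's marginal entropy lies in
[1.5, 2.0] bits (the belief-geometry regime of a 4-state survey outcome
that is informative but not uniform) and pocket money carries strictly the
largest MI with the target.  `generate_survey` applies corruption to
disjoint random row sets — one blanked cell per "missing" row using the
cleaning stage's own marker tokens, smartphone-column overwrites for
never-users and "don't know" answers — and logs exactly which rows were
touched, so round-trip tests can require drop counts to match injection
counts *exactly*, not approximately.

What passing on this generator does **not** show: real survey columns are
not Dirichlet-smooth (they have spikes, skips and near-deterministic
logical constraints), missingness is not uniform at random, and real
effect sizes may sit below what n = 11,206 can resolve.  Results on the
fixtures validate the machinery — inference identities, recovery behavior,
screening properties — not any substantive claim about adolescent obesity.

## Numerical and design choices

* CPT rows must sum to 1 within 1e-9 at construction; posteriors are
  renormalized after elimination.  Probability-identity tests run at
  1e-10–1e-12.
* Hill-climbing accepts a move only if it improves the score by more than
  1e-6 (scores are O(10⁴) log-likelihood magnitudes; this absorbs float
  noise without masking real improvements).
* Quantile binning in attribute merges uses interpolated quantile edges of
  the combined ordinal value with closed-left intervals (`include_lowest`),
  so balanced inputs relabel cleanly and ties never straddle bins.
* Weekday/weekend minute pairs combine as (5·weekday + 2·weekend)/7 — a
  weekly average per day.
* BMI category intervals are closed on the left ([p85, p95) overweight,
  ≥ p95 obese), applied uniformly; ages outside the chart (12–18) are an
  error, not a clamp, because the chart defines no other rows.
* Recovery instrumentation matches CPT rows on the *true* parent sets and
  aggregates row total-variation distances as the expectation over the
  truth's parent-configuration distribution.  A raw per-row maximum is
  dominated by configurations with vanishing probability, which a sample of
  any realistic size cannot pin down; the expected distance reflects the
  error a user of the learned network would actually encounter.
* All randomness flows through explicit integer seeds (one
  `numpy.random.Generator` per call); no global RNG state anywhere.

## Problem sizes

The default suites run at the scale the analysis itself targets: structure
recovery at n = 20,000 samples of the 11-variable fixture, classifier
comparison at n = 5,000 with 10-fold cross-validation, cleaning round trips
at n = 11,206 (the survey's post-cleaning order of magnitude), and property
suites over hundreds of random networks of up to 8 nodes.  The full test
suite and the acceptance script each complete in well under a minute on a
single CPU.

## Known limitations

* Exact inference only; networks whose moralized treewidth is large would
  need approximate methods, which are out of scope.
* No imputation, no survey weights, no calibration analysis.
* Hill climbing with restarts is a local search; it can in principle return
  a suboptimal structure, which the recovery report quantifies but does not
  prevent.
* The growth-chart table covers ages 12–18 only.
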