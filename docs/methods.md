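# Methods

This note documents the models, conventions, numerical choices and known
limitations of the package. Units throughout: ages in Myr before present
(tips at 0), all rates in events·lineage⁻¹·Myr⁻¹.

## Tree model and branching times

A `Tree` is a rooted phylogeny wrapping a dendropy tree; when flagged dated
it must be ultrametric within a relative tolerance of 1e-6 × crown age
(beyond that it is rejected rather than rescaled — dating error should be
explicit, not silently absorbed). Zero-length terminal branches are allowed;
zero-length internal branches are not collapsed automatically. Branching
times are internal-node ages sorted non-increasingly, with polytomies
counted by multiplicity (a node with c children contributes c−1 entries), so
an N-tip tree always yields N−1 ages. Node identity across trees is the
bipartition (descendant tip set), which is how per-tree ancestral-state
reconstructions are averaged onto a reference topology.

## Diversification likelihoods

All six models use one additive-constant convention — the conditioned
reconstructed-process likelihood with no (N−1)! term — chosen so that every
nesting route back to pure birth (BD at a=0, DDX at x=0, DDL at K→∞,
multi-rate Yule with equal rates) reproduces the PB value identically, and
AICs are comparable across models:

- **PB**: `lnL = (N−2)·ln λ − λ·G`, `G = 2t_2 + Σ_{i≥3} t_i`; closed-form
  MLE `λ̂ = (N−2)/G`.
- **BD** (net rate r, extinction fraction a = μ/λ ∈ [0, 1)):
  `lnL = (N−2)·ln r + N·ln(1−a) + r·Σ_{i≥3} t_i − 2·Σ_{i≥2} ln(e^{r t_i} − a)`,
  evaluated in the overflow-safe form `r·t + ln(1 − a·e^{−r t})`. The a
  parameterisation keeps the boundary fit a=0 representable, and that fit
  collapses exactly onto PB.
- **DDX/DDL**: per-lineage rate `λ_k` while k lineages exist;
  `lnL = Σ_{k=2}^{N−1} ln λ_k − Σ_{k=2}^{N} k·λ_k·τ_k` with τ_k the duration
  spent at k lineages (τ_N ending at the present).
- **Y2R/Y3R**: piecewise PB. Shift ages are profiled over the observed
  branching times (an event exactly at a shift belongs to the younger
  regime); given shifts, the per-regime rate MLE is closed-form
  (`λ̂_j = events_j / exposure_j`), which makes the whole fit deterministic
  and lets the Y3R pair search be fully vectorised.

Free-parameter counts: PB 1, BD/DDX/DDL 2, Y2R 3, Y3R 5 (shift ages count);
AIC = 2k − 2lnL. These conventions reproduce the printed AICs of the study
this package re-implements from its printed log-likelihoods.

Optimisation (BD/DDX/DDL): bounded L-BFGS-B on log-rate (plus a, x, or
ln(K−N)) with analytic gradients and three fixed starting points; tolerance
1e-12 on the objective. Determinism was preferred over stochastic restarts.

**ΔAIC_RC test.** The observed statistic is AIC(best of PB, BD) − AIC(best of
DDX, DDL, Y2R, Y3R); the null simulates pure-birth branching times at the
data's PB MLE and refits all six models. Because every profile likelihood
shifts by the same constant under a time rescaling, the statistic is exactly
scale-invariant: its null law depends only on N, so a single null sample may
be shared across replicates (`daicrc_test(..., null=...)`), which is how the
calibration check keeps its runtime down without changing the test.

## Simulators

All simulators consume a numpy `Generator` (or integer seed); a fixed seed
reproduces output byte-for-byte.

- **Yule**: two crown lineages at time 0; waiting time at k lineages is
  Exponential(kλ). By default the interval from the n-th lineage's origin to
  the present is drawn as the waiting time to the next (unobserved) event,
  Exponential(nλ) — coherent with the conditioned fitting likelihood; a flag
  stops exactly at the n-th birth instead.
- **BD/BiSSE**: per-lineage Gillespie (speciation, extinction, state flip at
  the state's rates), stopped at the first passage of the extant count to n
  plus the same Exponential final segment; whole-clade extinction triggers
  reject-and-retry (cap 10,000). Extinct lineages are pruned; the returned
  tree is the reconstructed tree, with the true state recorded at every
  surviving node (the state of the parent lineage at that speciation). The
  first-passage stopping is the simple conditioning; no correction is made
  for histories that pass n, dip, and return.
- **Mk2 on a fixed tree**: child states drawn from the exact 2-state
  transition probabilities branch by branch.
- **Clade-C-like dataset**: one base tree simulated under the irreversible
  extinction-free regime (λ_O = 0.68, q_OS = 0.21 — the regime the study
  system's model ranking favours) conditioned on 30 tips with exactly 8 in
  the derived state, rescaled to crown age 5.3 Myr; the posterior-style
  sample multiplies the crown by a lognormal factor (σ = 0.05) and jitters
  internal node ages (σ = 0.05) preserving topology and ultrametricity; two
  ancestral-state tips are masked as missing, mirroring the real data's two
  unknown species. What this emulates: topology/branch-length uncertainty of
  a dating posterior around one tree. What it does not: topological
  variation across the sample, dating error correlated across nodes, or
  sampling gaps — so passing recovery tests here says the estimators work
  under idealised posterior spread, not that they overcome real
  phylogenetic error.

## Mk2

Likelihood is Felsenstein pruning with the closed-form 2×2 transition matrix
(`P(0→0) = (q10 + q01·e^{−st})/s`, s = q01+q10), per-node renormalisation
for underflow safety, missing tips contributing (1,1) and never being
dropped. Root prior default is equal (0.5, 0.5); stationary and fixed priors
are available. The ML fit runs L-BFGS-B on log rates from five fixed starts.

**MCMC.** Metropolis–Hastings over (q01, q10) across a tree sample: each
generation draws one tree uniformly and evaluates current and proposed rates
on it. Moves: (i) a joint uniform sliding window of half-width
`proposal_width` on both rates (negative proposals rejected), (ii) with
probability 0.1 an independence refresh drawn from the conditional prior
Exp(m) — its Hastings ratio is the likelihood ratio — without which the
window chain mixes too slowly across the prior's magnitude range, and
(iii) a window move on the hyperparameter m. The prior is hierarchical:
q01, q10 ~ iid Exponential(mean m), m ~ Uniform(0, `hyper_mean_max`).
Defaults: `hyper_mean_max` 30 (the scale used by the BayesTraits-style
analysis this emulates, appropriate when branch lengths are in
substitutions/site) and `proposal_width` 3.0 (tuned on the clade-C-like
fixture to a window-move acceptance of ~0.5). On Myr-scaled chronograms,
where plausible rates are ~0.1–1, that prior is informative upward; analyses
on chronograms should set `hyper_mean_max` near the expected rate scale (the
credible-interval calibration test uses 2.0). Only the two-rate model is
sampled; a one-rate constraint is a separate fit, and no trans-model jumps
are made.

**Marginal ASR** uses the standard up–down (inside–outside) pass,
renormalised per node, and matches brute-force enumeration to 1e-10 on small
trees. Averaging across a tree sample is per bipartition with a support
count; trees lacking a node are skipped by default, or counted as
probability zero of the derived state behind a flag.

## BiSSE

Along each branch (time increasing rootward) the kernel integrates

    dE_i/dt = μ_i − (λ_i+μ_i+q_i)E_i + λ_i E_i² + q_i E_j
    dD_i/dt = −(λ_i+μ_i+q_i)D_i + q_i D_j + 2λ_i E_i D_i

with tip conditions D = state indicator (both f_i if missing) and
E = 1 − sampling fraction (default fraction 1 per state, since the study
this mirrors made no sampling correction even though 30 of 32 species were
sampled); at internal nodes D_i ← λ_i·D_left,i·D_right,i. The D vector is
renormalised per branch with exact log compensation (the likelihood is
linear in D). Root treatment, both togglable: weighting of the two states
proportional to the root D values ("obs", default; "flat" and "given"
available) and survival conditioning ON by default, dividing by the weighted
survival term Σ w_i·λ_i·(1−E_i)². The weighted (rather than per-state) form
is used so that models with a zero speciation rate in one state — including
the best-fitting irreversible model — remain well-defined.

Integration: an embedded Dormand–Prince 5(4) stepper (rtol 1e-8, atol 1e-10)
compiled with numba; a plain-numpy fixed-step RK4 integrator lives in the
test suite as the independent cross-check (agreement ≤ 1e-6 in lnL). The
closed-form two-tip values (lnL = −1.6931 unconditioned, −1.0 conditioned at
λ = 0.5, t = 1) pin the absolute constant, and with state-independent rates,
zero extinction and flat root weighting the likelihood equals the PB
branching-time likelihood plus ln ½ exactly.

**Fitting.** Free parameters (after equality ties and zero fixes) are
optimised on log scale in [1e-9, 1e2] by L-BFGS-B with three deterministic
restarts jittered (±0.7 in log space) around the heuristic start: a
state-independent BD fit replicated to both states, with transition rates
started at the Fitch parsimony change count divided by total tree length.
Zero-fixed parameters never enter the optimiser. Per-tree fits across a
sample are summarised by medians (and 2.5/50/97.5 percentiles with O/S
overlap indicators); AIC is computed per tree and then medianed, so
AIC = 2k − 2lnL holds per tree, not necessarily between median columns. The
model suite is the fixed 13-model set; ΔAIC is reported as best − model
(≤ 0), and each constrained model carries the percentage of trees whose LRT
against the per-tree full-model fit rejects at α = 0.05 (χ² with Δdf equal
to the difference in free parameters).

**Marginal ASR** constrains each node to each state in turn, recomputes the
likelihood, and normalises the two values — O(nodes) recomputations, fast
enough with the compiled kernel and exactly the definition of the marginal.

## Transition counting and Bayes factors

Modal states: internal nodes take state 1 iff P(1) > 0.5 (exact ties resolve
to the ancestral state 0 and are flagged); tips take their observed state;
missing tips inherit their parent's modal state by default (their pendant
edge then cannot contribute) or have their pendant edges excluded in strict
mode. Gains (0→1) and losses (1→0) are counted over parent→child edges.

The Bayes-factor statistic is the plain difference of marginal log tree
likelihoods (unconstrained − constrained), which is the arithmetic that
reproduces the printed comparisons this package ships as reference inputs;
the textbook 2×Δln form is available behind a flag. Bands: ≤2 none, (2,6]
positive, (6,10] strong, >10 very strong. Marginal likelihoods themselves
are consumed as supplied numbers — estimating them is out of scope.

## Problem sizes

The test suite and the acceptance script run everything at sizes a laptop
CPU handles in minutes, chosen as the package's own defaults: recovery
checks use 200–500 Yule/BD replicates at n = 30, BiSSE model-selection
recovery 50 replicates × 13 models, the ΔAIC_RC calibration 200 datasets
against one shared 200-replicate null (valid by the exact scale invariance
above), and the fixture workflow 8–50 trees of the 1,000-tree-style sample.
The BD λ/μ recovery check runs at n = 100 because extinction estimates from
reconstructed trees carry a large upward bias at n ≈ 30 — a genuine property
of the estimator, not a defect, and one reason extinction-rate conclusions
on small clades deserve caution.

## Known limitations

- BiSSE on 30-tip trees with 8/30 derived tips has low power, especially for
  extinction; the package reproduces the method, not a remedy.
- The Mk2 sampler's hierarchical prior is informative on chronogram scales
  (see above); posterior summaries under the default scale should be read as
  prior-influenced.
- The BD/BiSSE simulators condition on n by first passage; distributional
  checks against the exact conditioned process are approximate to that
  choice.
- Only binary characters; no multi-state, covarion, HiSSE-style hidden
  states, time-varying rates, or terminally-unresolved-clade likelihoods.
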