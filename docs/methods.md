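# Methods

## The AEq metric

AEq quantifies how hard a subpopulation is to learn. For a *scope* — the
examples of one sensitive group under one outcome, or a group-balanced
joint pool — we append a small compressive autoencoder to the (frozen)
feature representation and trace its validation reconstruction loss as a
function of training-set size. The loss follows a decaying learning
curve; the sample size at which that curve's curvature vanishes is the
scope's data requirement, and

    AEq = log2(n*)

where `n*` is that convergence size. A higher AEq means the scope needs
more data before a model generalises to it — because it is more
heterogeneous, more complex, or structurally unusual.

Relations between AEq values drive a bias taxonomy:

- **Label (performance-invariant) bias.** For each candidate outcome,
  compare the groups' AEq within each label stratum. If the same label
  selects structurally different populations from different groups, the
  label does not mean the same thing for both; the outcome with the
  smallest summed between-group difference is the least distorted.
- **Sampling bias.** Groups share a distribution but one is
  under-collected: group AEqs agree, and the joint AEq sits at or below
  the over-represented group's value. Mitigation: balanced collection.
- **Complexity bias.** One group is intrinsically harder: its AEq is
  higher, and the joint AEq exceeds every group or is pulled toward the
  higher group's value. Mitigation: prioritise collecting that group.

## Learning-curve estimation

**Autoencoder head.** One tanh bottleneck layer (width
`max(2, d/4)`, always `< d` so the head is compressive), linear output,
MSE loss, full-batch Adam (lr 0.02), at most 150 epochs with early
stopping on validation loss (checked every 2 epochs, patience 10
checks). The reported loss is the best validation loss seen — checkpoint
semantics without storing weights. Training is float32 and fully batched
across bootstrap replicates, which is what makes 50-replicate audits
cheap on one CPU. A narrow bottleneck is deliberate: it is the probe's
sensitivity. Wider bottlenecks reconstruct everything well and stop
discriminating between scope structures.

**Sampling protocol.** Each scope is audited on an equalised subset
size (the smallest scope among those being compared): comparing scopes
of unequal size otherwise confounds AEq with pool size. Each bootstrap
replicate resamples the *whole scope* with replacement; the first 60% of
the resample is its training pool and the next 20% its validation set
(capped at 256 rows), mirroring a 60/20/20 convention with the held-out
20% never touched. Grid sizes are nested prefixes of the replicate's
training pool, so cross-size noise is shared within a replicate and each
replicate's curve is internally smooth. Resampling at the scope level
makes the replicate spread an honest estimate of scope-level
uncertainty, which the CIs and t tests below rely on. At grid sizes
≤ 96 the loss is dominated by initialisation noise, so 2–4 independent
initialisations are averaged there.

**Grid.** Default audit grid is half-octave spaced,
16 … 512 (the classic doubling grid 16 … 1024 remains the library
default for single curves). Half-octave spacing roughly doubles the
points per decade and materially stabilises the decay-rate estimate.
Pipelines trim the grid to fit `0.6 × scope size`.

**Curve family and fit.** `L(n) = a + b·n^(−c)` with bounds `a ≥ 0`,
`b ≥ 0`, `c ∈ [0.05, 5]`, fitted by bounded least squares with
multi-start over a fixed ladder of decay rates. Fits are weighted by the
inverse replicate standard deviation per grid size (small-n losses are
intrinsically noisier and would otherwise dominate). Two numerical
choices matter:

- *Replicate refits anchor the floor.* A free 3-parameter fit on one
  replicate's dozen noisy points lets the floor, amplitude and rate
  trade off freely and swamps the decay-rate signal. Each replicate is
  therefore refitted with `a` pinned to the scope's pooled floor
  estimate shifted by the replicate's own tail offset (its bootstrapped
  validation set sits at a slightly different asymptote).
- *The pooled floor is profile-marginalised.* For each decay rate on a
  dense grid the conditional (a, b) fit is closed-form; the floor is the
  likelihood-weighted average of `a(c)`. Where the full fit is bistable
  between near-tied decay rates — which flips the fitted floor
  discontinuously — this estimator varies smoothly.

**Convergence.** With `u = log2 n`, the fitted loss is
`ℓ(u) = a + b·2^(−c·u)` and `ℓ''(u) = b (c ln2)² 2^(−c·u)`. The
convergence point is the smallest `u ≥ log2(min grid)` with
`|ℓ''(u)| ≤ ε`, located by a dense scan (step 0.01) plus bisection. The
derivative is taken in log2 of the sample size, consistent with
reporting AEq in log2 units. The default tolerance is relative,
`ε = 0.01·b`, because absolute curvature scales with the loss magnitude;
an absolute `ε` can be configured. Degenerate flat curves (`b ≈ 0`)
convergence at the grid floor and are flagged. Points beyond the grid are
flagged `extrapolated`.

**Statistics.** Each scope is bootstrapped 50 times by default; the
reported AEq is the mean of replicate values and the 95% CI is
mean ± 1.96 SE across replicates. Two-scope differences use Welch t
tests on the replicate values with paired-by-index SE intervals;
multi-scope families use one-way ANOVA; all p values are
Bonferroni-adjusted over the family of comparisons performed in a call.
Treating bootstrap replicates as independent samples is anticonservative
— every report carries a machine-readable caveat flag. Decision rules
(complexity vs sampling, label flagging, residual unfairness) fire only
on significant comparisons (adjusted p < 0.05 *and* CI excluding zero).
The "joint pulled toward the higher group" test uses the statistic
`|AEq_joint − AEq_hi| − |AEq_joint − AEq_lo|` with a percentile CI from
resampling replicate triples.

## Guided collection

A diagnosis maps to a plan under a fixed budget N: sampling → balanced
collection (equal per-group counts, lexicographic tie-break on odd
budgets); complexity → all incremental capacity to the higher-AEq group
until its pool is exhausted, then spill to balanced; no bias →
prevalence-proportional; mixed → prioritise, with a warning. Plans are
feasibility-checked against per-group pools (greedy waterfall; spill is
recorded in the plan's notes). Test subjects are frozen by subject id
before any curation and can never re-enter a curated cohort. The
balanced-ERM baseline is the identical machinery pinned to the balanced
mode; when the diagnosis is sampling, the guided plan and balanced ERM
coincide exactly.

## Fairness evaluation

Per group: AUROC (Mann–Whitney rank statistic, midrank ties — identical
to the trapezoidal ROC area) and the threshold panel TPR/FNR/TNR/FPR/
PPV/FDR at a configurable threshold (default 0.5). Degenerate groups
yield explicit nulls with reasons. Bootstrap CIs resample subjects, not
rows. Bias for a metric is the signed difference under a configured
group order; bias reduction between two models is
`100 · (|bias_pre| − |bias_post|) / |bias_pre|`, negative when bias
increased, null (with a reason) when the pre-intervention bias is zero.
AUROC gaps are reported as plain differences (×100 when displayed in
percentage points).

## The synthetic study conditions

The generator produces two-group tabular cohorts (default 8 000 per
group, 10 features) from Gaussian mixtures with a logistic outcome link.
Scenario geometry — cluster directions, the signal direction — is drawn
once from a fixed generator, so a scenario is the same data-generating
process at every cohort seed; the seed drives sampling only. Cluster
assignments are exact-proportion (stratified), because multinomial
weight fluctuations between groups would inject genuine learnability
differences into scenarios meant to be exchangeable.

- **none** — both groups i.i.d. from a single Gaussian; outcome from a
  shared logistic link (signal 2.0 along the diagonal direction).
- **sampling** — one shared distribution, drawn 4:1 (majority:minority)
  at a fixed total, so the minority is purely under-collected.
- **complexity** — group B carries 4 latent subclusters (separation 3.0,
  within-cluster SD 1) against A's one, and B's outcome direction is
  rotated 60° from A's with attenuated strength (0.8 vs 2.0). The
  rotation-plus-attenuation is what makes the harm *data-addressable*: a
  pooled model is dominated by the majority's stronger gradients and
  fits the majority's direction; only re-weighting the training mix
  toward B moves the fit toward B's optimum. A capacity-limited harm
  (e.g. label shifts no feature can explain) would not respond to data
  collection at all.
- **label** — six severity bands along one axis, each with its own
  orthogonal offset (bands on a single axis would be a trivially
  compressible 1-D manifold and band count would not affect
  learnability). True need = band ≥ 2 for both groups (1% label noise);
  group B's proxy fires only at band ≥ 5. At equal proxy label, B's
  positive stratum is one tight severity band while A's spans four — the
  cost-style distortion in which equally-labelled members of the
  disadvantaged group are systematically sicker. The audit accordingly
  scans *both* label strata per outcome (per-risk-category style) and
  scores each outcome by the summed |ΔAEq| across strata.
- **mixed** — complexity structure plus a score-shift proxy distortion,
  for the synergy experiment (label selection + prioritised collection).

What the generator does *not* emulate: covariate measurement error,
missingness, temporal drift, many-valued sensitive attributes,
survey weights, or image-like structure. Passing tests show the audit
recovers *planted* mechanisms of realistic effect size under clean
tabular conditions; they do not certify behaviour on real clinical data,
where mechanisms mix and effect sizes may be smaller.

## Problem sizes and runtime choices

The packaged experiments use: audit grids to 512 (724 for label-stratum
scans), 20–40 bootstrap replicates depending on the experiment, cohorts
of 4 000–8 000 per group, and 10–40 repetitions per reported rate.
These are the package's standard desk-scale settings: large enough for
the reported rates to be stable, small enough that the full validation
suite runs on a single CPU in tens of minutes. The library default
remains 50 bootstrap replicates.

## Known limitations

- AEq values depend on the encoder, head architecture, grid and
  tolerance; only *comparisons under one configuration* are meaningful.
  The config fingerprint is enforced across compared scopes.
- The t tests inherit the anticonservatism of treating bootstrap
  replicates as independent; borderline significance should be read
  with that in mind (the caveat flag is attached to every comparison).
- Scope-level AEq noise (≈0.1–0.2 in log2 units at these sizes) sets a
  floor on detectable between-group differences; differences below
  ~0.3 are unreliable at default replicate counts.
- The sampling-vs-no-bias distinction is not identifiable from AEq
  relations alone (both present equal group AEqs with a joint at or
  below them); both map to balanced/prevalence collection, which is the
  correct action in either case.
- Curation assumes fixed-total-budget semantics (prioritised collection
  replaces capacity that would have gone to the majority), and
  feasibility is limited by per-group pools.
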