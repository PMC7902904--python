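# Methods

## The behavioural model

The package analyses an immersive object-copying task. A participant
stands between three areas: a **Model** (an arrangement of 8 objects on
a grid), a **Resource** pool (those 8 objects plus 16 distractors, drawn
from a 60-object pool), and a **Workspace** where the arrangement is
reproduced. One object can be carried at a time. The Model's angular
separation from the Workspace (0°, 45°, 90° or 135°, varied run-wise)
sets the *locomotive effort* of re-inspecting the Model.

The unit of analysis is the **sequence**: from one gaze sample on the
Model to the next qualifying gaze on the Model. The **features in
memory** used in a sequence is the number of object features acted on
before gaze returned: +1 *identity* per non-corrective pickup of a model
object, +1 *location* per non-corrective correct placement. Each of the
8 objects carries exactly two features, so a completed display without
errors always sums to 16 — a conservation law the test suite enforces.
Zero-feature sequences (a Model-Resource round trip with no action) are
tallied separately and excluded from the probability tables by default;
a switch includes them.

## Sequence qualification and timing rules

- A Model re-view closes the open sequence only if a **Resource** visit
  occurred since it opened. Workspace glances mid-placement do not split
  an encoding episode. A configuration switch additionally accepts
  Workspace visits, since the verbal definition of the rule admits both
  readings; the default follows the canonical encode → search → return
  narrative.
- Sequence spans are half-open `(start, end]` on event time; the
  boundary Model visit closes one sequence and opens the next, and its
  dwell counts only toward the *next* sequence's initial viewing time.
  This makes summed sequence durations exactly equal the display span.
- **Initial Model viewing time** sums Model-AOI time from the sequence's
  opening sample until its first Resource visit; Workspace/OTHER
  interludes neither end nor count toward it. Whether multi-block
  initial viewings should be summed is not externally fixed; summing is
  this package's documented choice.
- The viewing-time analysis uses the closed interval **[50, 2000] ms**
  ("below 50" / "above 2000" excluded — the literal reading) and
  sequences with 1–4 features. On simulator output this excludes well
  under 1% of sequences.
- **Display completion time** is the sum of the display's sequence
  durations; displays cut by the 45 s timeout are flagged and excluded
  by default.
- Corrective actions (re-pickup and re-placement of a misplaced object)
  and distractor pickups earn no features but set per-sequence error
  flags; error-flagged sequences are excluded from the feature-
  probability tables by default because a forced correction truncates
  the sequence's credited count (switch provided). The 16-feature
  conservation law holds exactly only when corrections are excluded
  from crediting, which motivates the rule.

## The synthetic agent

The simulator emits AOI labels directly at 90 Hz — no 3D geometry or
ray casting; the analysis consumes labels, and geometry enters only
through travel times. Its policy is parameterized by:

- **features_per_visit_pmf** — per condition, the distribution of
  features encoded per Model visit. Defaults (0°: 60/27/12/1%,
  45°: 50/36/12/2%, 90°: 40/44/11/5%, 135°: 29/50/11/10% over
  k = 1..4) reproduce the reported per-condition shares: one-feature
  use falls from 60% to below 30% across conditions, four-feature use
  rises from ~1% to 10%, mean use from ~1.5 to ~2.
- **Durations** — encoding dwell mean 0.20 + 0.22·k s, scaled by
  (1 + 0.10·rank) across conditions; travel 0.30 + 0.12·rank s per leg;
  search 0.70 s per pickup; placement 0.60 s. All draws are log-normal
  with σ = 0.3 on the log scale (positive, right-skewed — consistent
  with the log transforms the analysis applies). These means are
  calibrated qualitatively: they put completion times at roughly
  26–32 s per display, monotone in angle and safely inside the 45 s
  timeout, so that every participant completes 28 displays (224 objects)
  per condition. Dwell magnitudes sit inside the 50–2000 ms analysis
  window with a realistic tail.
- **Error injection** — per sequence, an identity error (pick up a
  distractor, notice, drop it; rate 1.8%) or a location error (place in
  a wrong cell; rate 2.9%). A location error forces the scripted
  correction: immediate re-gaze at the Model (which closes the erroring
  sequence), corrective re-pickup and re-placement at the start of the
  next span. Location-error draws landing on a sequence with no
  placement slot are deferred to the next placing sequence, keeping the
  realized per-sequence rate equal to the configured rate.
- **zero_feature_rate** (default 5%) — probability of inserting an
  unproductive Model-Resource-Model round trip before an action
  sequence starts empty-handed.

**Exact-sum compositions.** A display needs exactly 16 features, so
per-sequence draws cannot be literally i.i.d. Naive rejection sampling
(accept i.i.d. draws iff they sum to 16) length-biases the pooled
per-sequence distribution by about +2 points on the one-feature share.
The generator therefore draws from a *tilted* pmf, computed once per
policy by a dynamic-programming fixed point, whose exact-sum
compositions have pooled part marginals equal to the configured pmf to
<1e-10. Totals not reachable from the pmf support (e.g. a pure
3-feature policy) fall back to truncating the final draw, flagged in
the ledger. After the final placement the agent gives the Model a short
verification glance so the last sequence closes.

Every emitted sequence includes at least one Resource visit (pickups
happen there; placement-only walks pass the Resource area), so the
ledger's sequence inventory matches what the default qualification rule
will segment — with noise off, scorer-vs-ledger agreement is exactly
100%, and the optional flicker-noise layer degrades it monotonically.

**What the simulator does not emulate:** saccade/fixation
microstructure, gaze-position noise within an AOI, visual search
difficulty differences between objects, learning or fatigue across
runs, and any principled encoding-time/working-memory-load theory — the
dwell model is purely phenomenological. Passing tests therefore
validate the *pipeline's bookkeeping and statistics*, not claims about
human cognition; recovering the configured policy from simulated logs
shows the measurement chain is faithful, no more.

## Statistical procedures

- **Box-Cox**: profile likelihood over λ ∈ [−2, 2] (401-point grid);
  recommend log iff 0 lies in the χ²(1)-based 95% CI. Applied to dwell
  (ms) and completion time (s); simulator responses are mixtures of
  log-normals, so the profile maximum sits at λ ≈ 0 and the log member
  of the power family is the appropriate transform. No additive
  constants: inputs are strictly positive after filtering.
- **Locomotion predictors**: conditions are ranked 1–4 (log of 0° would
  be undefined on the raw scale), then exponential/log transforms or
  orthogonal polynomials (QR over the realized design) are taken and
  z-scaled. Higher-order models include lower orders.
- **Poisson GLMM** (own implementation): log-link, by-participant
  random intercept + slope on the linear locomotion term, ML via the
  Laplace approximation. The conditional mode is found by penalized
  IRLS over (β, u) jointly with block-wise Schur elimination (β is
  profiled, the strategy lme4 uses at nAGQ = 0 — exact at zero
  random-effect variance); the 2×2 covariance Cholesky factor is
  optimized by bounded L-BFGS-B with 5 jittered, seeded restarts,
  inner convergence 1e-13 relative on the penalized deviance and a
  1e-5 finite-difference step (a loose inner tolerance leaks noise
  into the numeric gradients and visibly inflates null likelihood-ratio
  statistics). Wald z from the profiled information; AIC/BIC from
  k = #fixed + #covariance parameters, so the identities
  AIC = 2k − 2ℓ and BIC = k·ln n − 2ℓ hold exactly.
- **Model ladder**: exponential → logarithmic → linear → quadratic →
  cubic, identical observations and random structure, each row compared
  to the previous by likelihood ratio. Adjacent single-predictor models
  have equal parameter counts, hence no LR degrees of freedom: the
  default output marks them "compare by AIC" with p = NaN; a
  compatibility mode prints the df-0 point-mass convention (p = 1 at
  χ² = 0, p = 0 otherwise) used in some published tables.
- **LMMs** (statsmodels MixedLM, ML): log viewing time and log
  completion time on orthogonal linear + quadratic feature terms
  crossed with locomotion, maximal by-participant random structure.
  Reported t statistics are Wald with normal-approximation p values and
  are labelled as such — Satterthwaite degrees of freedom are
  deliberately out of scope, so p values differ slightly from
  lmerTest-style output; β and SE are the comparable quantities.
  Random-structure simplification removes a slope only when a PCA of
  the fitted random-effect covariance shows a component below 0.1% of
  total variance (MixedLM reports near-boundary variances as small
  positive numbers, never exact zeros, so a machine-epsilon threshold
  would never fire) *and* an LRT against the reduced model is
  non-significant; every decision is recorded in an audit trail and the
  intercept is never removed.
- **Paired tests**: within-subject t tests for all neighboring-condition
  pairs within each feature level 1–4 (12 comparisons), df = n−1,
  Cohen's d = mean difference / SD of differences, 95% t-CI.

## Problem sizes and reproducibility

All randomness flows from a single master seed through
`numpy.random.SeedSequence.spawn`, one stream per participant, so
adding participants never perturbs earlier ones and identical
configurations are byte-identical on disk. The test suite validates the
scorer against an independent frame-level recount on >1000 displays,
the GLMM against statsmodels' Poisson GLM (zero-variance limit,
|Δβ| < 1e-4) and R lme4 on a shared dataset, and runs the full
study-scale recovery (24 participants, ~26k sequences) plus a
50-replicate ladder simulation at 24 × 100 observations each; the whole
suite completes in a few minutes on one CPU.

## Known limitations

- The Laplace approximation (and profiled β) biases variance components
  slightly for very small counts; fixed effects at this design's sizes
  agree with lme4 to well within one standard error.
- The per-sequence feature distribution inside a fixed-total display
  cannot be exactly i.i.d.; the tilt removes the pooled-marginal
  discrepancy, but higher-order composition statistics (e.g. runs of
  equal k) still differ from an unconstrained process.
- Excluding error-flagged sequences from the probability tables selects
  slightly against placement-containing sequences (~+0.5 points on the
  0° one-feature share); with ~3% error rates this stays inside the
  binomial sampling band at study scale.
- The deposited-data adapter maps foreign schemas onto the canonical
  dialect, but a real deposit's column mapping must be supplied by the
  analyst; no deposit ships with the package.
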