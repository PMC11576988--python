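# Methods

## The decomposition model

The model treats every reaction time as the sum of an answer time — the
portion spent on the targeted cognitive process — and a participant-level
delay time capturing device latency, visuomotor speed and cognition that is
not specific to the task:

    RT(i, t) = AT(i, t) + DT(i).

Its premise is that a trial's difficulty can be defined from the group's
performance on that trial, while a participant's performance depends on the
difficulty of what they were shown — a circularity resolved by two
fixed-point iterations.

**Stage 1 (difficulty).** Performance on a presentation is
`P = (1 − RT/RT_max) · acc · D(t)`, where `acc` is the 0/1 correctness
indicator (binary tasks) or a graded score in [0, 1] (continuous tasks), and
a wrong answer scores 0 outright — the RT of a wrong answer carries no
information about ability. `RT_max` is the maximum RT across all retained
trials and participants; it is a global scaling constant, so it affects the
scale but not the ranking of the estimates. `D(t)` is the mean of `1 − P`
over every presentation of label `t` (repeat presentations by the same
participant count separately). Starting from `D = 1`, the per-label update
is affine, `D ← 1 − m_t·D`, with `m_t` the label mean of
`acc · (1 − RT/RT_max)`; it converges geometrically to `1/(1 + m_t)`, which
bounds converged difficulties to [0.5, 1]. The closed form is exposed as
`closed_form_difficulty` and used as an independent oracle in the tests; the
iteration is kept because its trace is a diagnostic output. If `m_t = 1`
exactly (every answer correct at zero RT) the iteration alternates between 0
and 1; such labels are pinned to the analytic fixed point 0.5 with a
warning.

**Stage 2 (ability and delay).** With `D` fixed, answer times are modelled
as `AT(i,t) = (1 − A(i)) · D(t) · (RT(i,t) − DT_max(i))`, where
`DT_max(i) = RT_min(i)` is the participant's smallest retained RT — the
largest delay consistent with their data. Performance is re-expressed as
`P = (1 − AT/RT_max − DT(i)/RT_max) · acc · D(t)`, clamped to [0, 1]
(extreme RT/DT combinations can push the raw expression outside the unit
interval; P is a proportion). The ability `A(i)` is the average of the
cumulative means of `P` in presentation order: with performances
`P_1..P_Q`, `A = (1/Q) Σ_N (1/N) Σ_{t≤N} P_t`. This weights early trials
more, keeps `A` in [0, 1], and reduces to the single `P` when `Q = 1`; it
is the reading of the cumulative-performance definition consistent with
ability being a unit fraction. Consequently `A` and `AS` depend on each
participant's presentation order, which is therefore a required input (file
row order is the documented fallback). The stage starts from
`AT = RT − DT_max` (ability treated as maximal) and `DT = DT_max`, which
makes its first performance equal the converged Stage-1 performance, and
iterates `DT → P → A → AT` until the mean absolute change in `A` falls
below tolerance. `DT(i)` is the participant mean of `RT − AT`; it is
bounded by `[DT_max(i), mean RT(i)]` and is *not* clamped below `DT_max`
(the update equations place it at or above that bound by construction).

**Specific ability.** `PA = (1 − AT/AT_max) · acc · D(t)` replaces the raw
speed term with the delay-corrected one; `AT_max` is the maximum answer time
over all retained presentations, by analogy with `RT_max` (it has no other
natural definition). `AS(i)` is the cumulative-mean average of `PA`. If all
answer times are zero (degenerate: every participant at their own fastest
RT), the `AT` term is dropped with a warning.

**Scaled difficulty.** `DS(t)` pre-scales as `D(t)` times the mean `AS` of
the *distinct* participants who saw label `t`, then is affinely mapped onto
`[min D, max D]`. The affine min–max map is the simplest rescaling
consistent with "scaled to the original range": it leaves `D` exactly
invariant when all abilities are equal, and a single-label task (rescaling
undefined) returns the pre-scale value with a warning. Under adaptive
sampling, hard trials are seen mostly by able participants and look
spuriously easy under `D`; weighting by the viewers' `AS` pushes them back
up the scale.

## Iteration controls

`FitConfig(max_iter=10, tol=1e-6)` by default: ten iterations is the depth
at which both stages stabilise on population-scale data (mean absolute
changes below 1e-3), and the tolerance allows early exit when a stage
converges sooner. Runs that hit `max_iter` above tolerance are flagged
(`converged=False`, warning, residual recorded in the trace), never raised:
a fixed-depth fit is a legitimate operating mode. The difficulty stage's
contraction factor is `m_t`, so labels answered fast and correctly by almost
everyone (`m_t` near 1) converge slowly; analyses that need the exact fixed
point should raise `max_iter` (the tests run with 5000) or read the closed
form. All accumulations are in float64, and estimates are independent of the
order in which participants appear in the file (only within-participant
presentation order matters).

## Preprocessing

Three cleaning rules, each returning a reconciling count report: RT
thresholds (defaults 200–60000 ms — placeholders to be overridden per task;
too-fast responses suggest random keying, too-slow disengagement),
removal of participants observed at more than one timepoint (avoids learning
effects), and span caps for sequence-memory tasks (target lengths above the
design maximum indicate writing the sequence down). The pipeline applies
the repeat-participant filter first: whether someone repeated the task
should not depend on which of their records survive the RT thresholds. The
RT and span filters are idempotent and commute with each other
unconditionally; commutation with the repeat filter holds unless a
threshold erases one of a participant's timepoints entirely, which is why
the order is fixed. Continuous difficulty dimensions (e.g. distance from
the previous target) are binned into equal-width bins (default 20) to form
labels.

## Synthetic-data generator

The generator inverts the model: abilities `a_i ~ Beta(5, 2)` (mean 0.71,
negative skew), delays `DT_i ~ Gamma(25, 30)` ms (mean 750 ms, SD 150 ms,
positive skew), difficulties evenly spaced at `t/(L+1)`. Answer times are
`AT = (1 − a_i) · d_t · τ · ε` with `τ = 700` ms and mean-one lognormal
noise `ε` (σ = 0.15); `RT = AT + DT_i`. Correctness is Bernoulli with
probability `logistic(κ(a_i − d_t))`, κ = 10; continuous mode draws a
0–3 rubric score as `Binomial(3, p)/3`, normalised to [0, 1]. The defaults
were chosen once so that the standard 1000 × 50 balanced task reproduces
the operating regime the estimator is documented in: group-mean performance
`m_t ≈ 0.35` (so both stages converge within about ten iterations), a
negatively skewed `AS` distribution and a positively skewed `DT`
distribution, and reliable recovery of difficulty, delay and ability.

The staircase design implements span-task semantics: start at the lowest
level, move up on success, repeat on failure, stop after three consecutive
failures (configurable) or after success at the top level.

What the generator does *not* emulate: heavy-tailed RT distributions
(real online data contain extreme slow responses; the preprocessing
thresholds exist precisely to trim them before fitting), within-participant
ability drift or learning, device or demographic covariates, and
multi-task correlation structure (tests induce it by sharing abilities
across generator calls). Passing recovery tests therefore show the
estimator is consistent with its own generative assumptions at realistic
sizes — not that those assumptions exhaust real data.

Raw ability `A` is contaminated by delay by construction (its performance
term contains `DT`), so recovery is assessed against `AS` for ability, `DT`
for delay and `D`/`DS` for difficulty; `recovery_metrics` reports `A` too.

## Psychometric layer

Task score matrices are sparse (participants skip tasks), so correlations
are pairwise-complete with a minimum-overlap guard (default 3; pairs under
it are reported missing, not fatal). Clustering is agglomerative with
complete linkage on `1 − r`, tasks pre-sorted by name for deterministic
tie-breaking. Factor count uses the strict Kaiser criterion (eigenvalues
> 1, so an identity matrix yields zero factors). Extraction is
minimum-residual (L-BFGS-B over uniquenesses, SMC start), with
principal-axis as an option; varimax follows the standard Kaiser-normalised
SVD algorithm with the conventional relative-improvement stopping rule
(verified against a frozen R `stats::varimax` oracle), and factor signs are
fixed so each column's largest loading is positive. The Schmid–Leiman path
uses a promax (oblique) first-order rotation — the transformation requires
correlated first-order factors even though first-order loadings are
reported under varimax — factors the factor-correlation matrix at second
order with one general factor, and orthogonalises: g loadings are the
first-order pattern times the second-order loadings, `ss_g` their sum of
squares, and the g variance share is `100 · ss_g / n_tasks` reported at
full precision (integer percentages elsewhere are rounded from this).
Sign fixes are applied jointly to the pattern and the factor correlation
matrix so the implied covariance (and hence `pct_g`) is invariant to task
order and consistent sign flips.

Cohen's f² is implemented as printed in the source convention,
`(1 − R²)/R²`; the conventional `R²/(1 − R²)` is available via
`conventional=True`. Demographic regressions themselves are left to
standard statistical tooling; only the effect-size arithmetic (f², beta/SD)
is provided here.

## Problem sizes

The standard simulation is 1000 participants × 50 labels (50 000 records);
the subsample-stability experiment uses 2000 × 30 with 30 subsamples of
100, and the staircase-correction experiment 50 replicates of 200 × 10.
These sizes give stable estimates of every property the suite asserts while
keeping a full test run in seconds on one CPU.

## Known limitations

- Difficulty is one-dimensional per task; trials engaging several distinct
  processes are summarised by a single `D`.
- `DT` does not separate device latency from visuomotor or unspecific
  cognitive components.
- Ability estimates depend on presentation order (early trials weigh more);
  two datasets differing only in order yield different `A`/`AS`.
- For labels answered fast and correctly by nearly everyone, the default
  ten-iteration difficulty fit is short of the fixed point; use the closed
  form or raise `max_iter` when exact values matter.
- The pairwise-complete correlation matrix is not guaranteed positive
  semi-definite under heavy missingness; factor routines warn on
  near-singular structures but do not smooth the matrix.
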