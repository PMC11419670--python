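# Methods

`stndecide` re-implements, as a tested pipeline on synthetic data, the
analysis chain of a primate subthalamic-nucleus (STN) decision-making
experiment: a collapsing-bound drift-diffusion model (DDM) of choice and
reaction time (RT) with additive microstimulation effects and AIC-based
variant selection; lapse-logistic psychometric and per-choice linear
chronometric fits with permutation bootstrap tests; window-wise
spike-count regressions; and model-seeded k-means clustering of 30-D
neural activity profiles with Rand-index stability and silhouette
quality metrics.

## The decision model

Momentary evidence is accumulated into a decision variable (DV)
`dX = k (C + me) dt + sigma dW`, where `C` is signed motion coherence
(positive toward the contralateral choice target), `k` the drift scale,
`me` a momentary-evidence bias, and `sigma = 1` by the standard DDM
scaling convention. The DV starts at offset `z` and is absorbed at
symmetric collapsing bounds `+/-B(t)` with

    B(t) = a                                  for t <= b_t
    B(t) = a exp(-b_collapse (t - b_t))       for t >  b_t

(a plateau followed by exponential decay; `b_t` is the collapse onset in
seconds, `b_collapse` the decay rate in 1/s). The upper bound maps to
the contralateral choice. RT is the absorption time plus a per-choice
non-decision time (`t0_contra`, `t0_ipsi`). Microstimulation enters as
additive deltas on all eight parameters, applied on stimulated trials
only. Eight model variants control which of the six parameter groups
{a}, {b_collapse, b_t}, {k}, {me}, {z}, {t0_contra, t0_ipsi} may have
nonzero deltas: Full (all), None (none), and NoA/NoCollapse/NoK/NoME/
NoZ/NoT (all but one group).

### First-passage solver

The joint choice/RT likelihood needs the defective first-passage
densities at each bound. We integrate the forward Kolmogorov equation
with a Crank–Nicolson scheme (Rannacher start-up for the delta initial
condition) in *bound-normalized coordinates* `y = x / B(t)`: the
absorbing boundaries then sit at the fixed nodes `y = +/-1`, and the
collapse reappears as an outward linear drift `y b_collapse` (active
past the onset, time-averaged within each step so the solution is smooth
in `b_t`) plus a growing effective diffusion `sigma / B(t)`. The
decisive property of this formulation is smoothness of the likelihood in
all parameters: a moving absorbing-node boundary on a fixed grid makes
the likelihood a staircase function of `(a, b_collapse, b_t)`, which
defeats finite-difference quasi-Newton optimization. Absorbed
probability per step is split between the bounds in proportion to the
one-sided second-order diffusive boundary fluxes, so total mass
(upper + lower + surviving) is conserved to machine precision. When
`B(t)` falls below 2.5% of `a`, the bound is treated as fully collapsed
and the remaining mass is absorbed by side.

Grids (time step, spatial nodes over `[-1, 1]`): default 1 ms / 513 for
stand-alone solves; 5 ms / 121 for single-session fitting; 15 ms / 41
inside the eight-variant comparison, where ~10^6 solves are needed per
session and only same-grid AIC *differences* matter (the residual
discretization bias largely cancels between variants). Accuracy against
the constant-bound closed form is ~1e-6 on the default grid and the
fitting grids alter choice probabilities by <~1e-3; parameter recovery
at the comparison grid shows 2–8% median relative errors.

### Path simulator

Synthetic sessions are simulated by Euler–Maruyama at 0.5 ms steps with
the Brownian-bridge crossing correction: between step endpoints that
both lie inside the bounds, a crossing is drawn with probability
`exp(-2 d_old d_new / (sigma^2 dt))`. Without this correction the
O(sqrt(dt)) boundary bias of the plain Euler scheme is visible as a
~0.011 Kolmogorov–Smirnov distance between simulated and solved RT
distributions; with it the distance drops to ~1e-3. Trials not absorbed
by 10 s are resampled (up to 5 attempts, then an error — a signal of
pathological parameters). Stimulated and control trials are interleaved
1:1; the default coherence ladder is {0.032, 0.064, 0.128, 0.256,
0.512}, the canonical five-level random-dot set.

### MAP fitting and model comparison

Each variant is fit by maximizing log-likelihood plus log-prior over the
eight base parameters and the variant's free deltas. Weakly-informative
priors anchor the weakly identified directions of the collapsing-bound
likelihood surface (bound height trades against collapse speed and
non-decision time): log-normal on `a` (median 1, log-SD 0.5) and `k`
(median 6, log-SD 0.6), half-normal(1.0) on `b_collapse`, uniform[0, 2] s
on `b_t`, normal(0, 0.2) on `me` and `z`, normal(0.3, 0.12) s truncated
to [0.08, 0.8] on the non-decision times, and zero-centered normals on
all deltas. Five runs per fit start from independent prior draws
(invalid draws resampled); each run is a short bounded L-BFGS-B
exploration in prior-scaled coordinates, and the best run by
log-posterior is polished to convergence. Per-trial likelihoods are
floored at 1e-10 (also covering RT below the fitted non-decision time),
and invalid parameter combinations return a finite penalty rather than
raising, so the optimizer can recover.

`compare_models` chains warm starts (None → Full → each reduced variant,
with the fixed group's deltas zeroed) as one of the five runs, shares
one solve cache across variants, and repairs nesting explicitly: if a
reduced fit beats Full, Full is re-polished from that solution. AIC is
`2 n_free - 2 loglik` with the log-likelihood taken at the MAP point
(`n_free` = 8 base + free deltas). A session shows a stimulation effect
when `AIC_None - AIC_Full > 3`; parameter group X is flagged when
additionally `AIC_NoX - AIC_Full > 3`.

## Psychometrics and chronometrics

Three logistic variants model the probability of a contralateral choice
as a function of signed coherence with stimulation offsets on slope and
bias: no-lapse, symmetric-lapse, and asymmetric-lapse (separate ipsi-
and contra-side lapses), each lapse with its own stimulation offset on
stimulated trials. Lapses are box-bounded at 0.45 (per arm, sums
included) to keep probabilities proper; fits pinned at a bound are
flagged rather than rejected (the bounded-fit contract under complete
separation). Variants are compared by AIC, ties toward fewer
parameters. Significance of the stimulation terms uses a permutation
bootstrap: stimulation labels are shuffled within session (200 sets by
default), the model is refit on each (warm-started from the observed
fit with stimulation terms zeroed), and the one-tailed p-value is the
fraction of null values whose magnitude is at least as large as the
observed one, floored at 1/(n+1). (Choosing the tail from the observed
sign instead would make the nominal 5% criterion reject 10% of null
sessions; the magnitude form is calibrated, which the test suite
verifies on 500 null sessions.) Chronometric fits are ordinary least squares of RT
on unsigned coherence per choice, with stimulation offsets on intercept
and slope and two-sided coefficient t-tests (statsmodels).

## Neural-activity analysis

Firing rates are computed in running windows (300 ms by default)
aligned to motion or saccade onset. Truncation rules prevent
cross-event leakage: motion-aligned windows overlapping the last 100 ms
before saccade onset, and saccade-aligned windows overlapping the first
200 ms after motion onset, are masked and excluded from every regression
and summary. Two multiple regressions are fit per window on spike
counts (not rates): one with choice (+1 contra / -1 ipsi) and one-sided
coherence regressors (coherence on own-choice trials, else 0), one with
choice and one-sided RT regressors (seconds). Coefficients are tested
at p < 0.05 (two-sided t); per-window fractions of significant neurons
are reported against the 0.05 chance line, optionally stratified by
whether the neuron's choice coefficient is itself significant at that
window. The regression is a hand-vectorized OLS batched across neurons
sharing a validity pattern (the design depends only on trials);
correctness is pinned by exact noiseless-recovery tests and type-I
calibration on unmodulated populations. No multiple-testing correction
is applied across windows; the fractions are descriptive.

## Activity vectors and clustering

Each neuron is summarized by a 30-D vector: mean rate in three 200 ms
epochs (early motion viewing 100–300 ms, late 300–500 ms, peri-saccade
+/-100 ms) for 2 choices x 5 coherences, z-scored by the mean and SD of
the 300 ms pre-motion baseline across trials (correct trials only by
default; zero-variance baselines exclude the neuron with a log entry).
Choices are relabeled preferred/other by peri-saccade average so
mirror-image neurons group together. Ordering is epoch-major
(epoch x choice x ascending coherence), frozen and serialized.

k-means supports squared-Euclidean, cosine, and correlation distances;
for the latter two, members are normalized (centered for correlation)
and a centroid is the mean of its normalized members, making
correlation-distance clustering invariant to per-vector affine
rescaling. Random initialization uses k-means++ seeding, best of 100
repetitions by within-cluster distance; model-seeded runs start from
four fixed 30-D seed vectors encoding the three theorized STN activity
patterns — choice- and coherence-dependent ramping
(pooling/normalization), an early choice-independent rise that decays
(early brake), and choice-free coherence ramping with a peri-saccade
choice burst (nonlinear gating) — plus an arbitrary fourth seed, a
fixed oscillatory pattern projected out of the span of the three.
Empty clusters are re-seeded at the worst-fit member. Stability is the
mean pairwise Rand index over 50 runs (pair-counting via the
contingency table); quality is the silhouette
`(D_inter - D_intra)/max(D_inter, D_intra)` with singleton and
zero-distance members scored 0. Site assignment uses the
highest-Pearson-correlation centroid. Spatial mixing of clusters is the
Euclidean silhouette of anatomical (AP, ML, depth) coordinates grouped
by activity-cluster labels. A fixed-seed t-SNE provides 2-D plots only.

## The synthetic data generators

The generators define the study conditions under which every test runs.

Behavioral sessions come from the DDM above with base parameters
`a=1.1, b_collapse=1.5 /s, b_t=0.35 s, k=6, me=z=0, t0=0.32/0.30 s` —
a regime producing ~55–100% accuracy across the ladder and mean RTs of
0.6–1.1 s, typical of trained macaques on this task. Recovery and
operating-characteristic harnesses use 3000-trial sessions and a pure
drift-scale effect `d_k = -0.5 k`.

Neural populations draw one of four template families
(2 choices x 5 coherences x 3 epochs mean rates over a log-normal
baseline, median 12 spikes/s, log-SD 0.6 — matching the reported STN
baseline distribution): (1) preferred-choice coherence-dependent
ramping to a common peri-saccade level; (2) an early
choice/coherence-free rise (14 spikes/s above baseline) decaying to
near baseline; (3) choice-free coherence ramping with a one-sided
peri-saccade burst; (4) a weak mixed pattern — the arbitrary seed's
shape, choice-symmetrized, at roughly half the amplitude of the others.
Deriving family 4 from the fourth seed keeps the four basins
well-separated under correlation distance (a generic weak ramp is
shape-confusable with families 1 and 3, and any choice-asymmetric weak
pattern is mirrored by noise in the preferred-side relabeling, creating
spurious substructure). Each neuron applies a log-normal gain (log-SD
0.3) to its modulation plus Gaussian jitter (SD 0.6 spikes/s) per
(coherence, epoch) cell, shared across choices so that the
choice-independence of families 2–4 during motion viewing is preserved.
A `separation` factor scales mean modulation (1.0 = default conditions).
Spike counts are Poisson draws from a piecewise-linear rate profile
through the epoch values; trial RTs come from the behavioral generator
in a slower parameter regime so analysis epochs rarely overlap.
Anatomical locations are uniform in a 4 x 4 x 5 mm box, independent of
cluster — the intermingled regime, under which the spatial silhouette is
expected near zero.

What the generators do *not* emulate: continuous spike times or
autocorrelated rate fluctuations (counts are conditionally independent
Poisson), session-to-session learning, motivational-state drift,
across-trial drift/starting-point variability in the DDM, and real STN
heterogeneity beyond four discrete families. Passing tests therefore
demonstrate correctness of the analysis chain under its own model
assumptions, not robustness to the messiness of recorded data.

## Numerical and design choices

- Correctness of a synthetic trial: choice sign matches coherence sign;
  at zero coherence (not in the default ladder) a fair coin.
- Simulation step 0.5 ms, horizon 10 s, retry cap 5.
- Optimizer space is prior-scaled; forward-difference step 1e-3 in
  scaled units; validity violations return a smoothly increasing
  penalty.
- Test and harness problem sizes (20 sessions per arm for operating
  characteristics, 500 reduced sessions for bootstrap calibration, 1000
  neurons for regression calibration, 50 runs x 100 repetitions for
  stability) mirror the stated study conditions while keeping the suite
  practical on a single CPU.
- On this generator, best-of-100 k-means is perfectly stable (mean Rand
  1.0) for several cluster counts at once, so the stability-based
  choice of k degenerates to the silhouette tie-break; the package
  reports the full setting table rather than insisting on a unique
  winner. With real, noisier data the Rand index discriminates between
  cluster counts, which is the regime the selection rule is designed
  for.

## Known limitations

- AIC uses the likelihood at the MAP point; with informative priors
  this is not the maximum-likelihood AIC (documented caveat of the
  mixed MAP + AIC recipe).
- The collapse form is plateau-then-exponential; Weibull-style
  collapses are an extension point, not implemented.
- No hierarchical (shared-prior multi-session) fitting.
- The bootstrap refits use the same psychometric variant as the
  observed fit (selected on the observed data).
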