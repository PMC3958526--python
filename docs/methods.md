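# Methods

## Model

A single mESC is described by four protein concentrations (arbitrary
units, a.u.): the Oct4-Sox2 heterodimer `OS`, Nanog `N`, Rex1 `R` and
Erk activity `E`.  Time is in minutes throughout.  Transcription is
modelled directly as protein production (no separate mRNA stage, no
delays), with activating Hill terms `H(x) = xⁿ/(kⁿ + xⁿ)` sharing one
binding constant `k` and Hill coefficient `n = 2`, motivated by the
dimeric action of Oct4-Sox2 and of Nanog in their autoregulatory loops.
Oct4-Sox2 activates itself (`s12`), Nanog (`s3`), Rex1 (`s5`) and — via
FGF4 — Erk (`s7`); Nanog activates itself (`s4`) and Rex1 (`s6`).  Erk
represses Nanog transcription multiplicatively, `G_p(E) = 1/(1+p·H(E))`,
applied to the whole Nanog production term (basal plus autoregulatory;
the split is not determined by the available evidence, and repressing
both is the simpler choice).  Degradation is first order with rates
`d_j`.

An extrinsic differentiation signal `Y` is transmitted into the cell
through a Nanog-controlled gate,

    Y_in(N) = Y · k_Y^h / (k_Y^h + N^h),

which is *decreasing* in Nanog: `Y_in(0) = Y`, `Y_in → 0` for `N ≫ k_Y`.
High Nanog therefore shields the pluripotency network; once a cell sits
in the Nanog-low state the gate opens and `Y_in` multiplies the
degradation rates of OS, N and R by `(1 + i_j·Y_in)` (linear
enhancement, the minimal increasing form).  Erk is not a `Y_in` target
and carries no noise.  `k_Y` tunes the steepness/position of the gate
but not its range.

Transcriptional noise enters multiplicatively: each of OS, N, R receives
an independent zero-mean Gaussian increment scaled by `σ_j · X · √dt`.
The multiplicative form is chosen because reporter distributions are
roughly equally wide per mode on the log scale; additive small-number
noise cannot reproduce that at the measured abundances.

Culture conditions are parameter mappings, not structural changes:
LIF/serum keeps Erk repression active (`p = 15` in the reference set,
`Y = 0` for the self-renewal analyses), 2i sets `p = 0`, and 2i
withdrawal (N2B27) ramps `p` per cell from 0 to `p_max` while exposing
the cells to `Y > 0` with reduced Rex1 turnover (below).

## Integration

Euler–Maruyama with post-update clamping at zero: the noise term is
evaluated at the pre-update concentration, the full update is applied,
and any negative result is set to 0 (whether clamping happens before or
after the noise is an unreported detail of the original procedure; the
choice is recorded in run metadata).  `E` is integrated deterministically
inside the same stepper.  Default `dt = 0.1` min, small against the
fastest relaxation time (1/d = 10 min).  The 3-day population snapshot
is insensitive to halving the step (NL fraction moves < 1 percentage
point between dt 0.1 and 0.05); the *rare-event* statistics are more
step-sensitive (coarse steps of 0.2 min measurably accelerate basin
escapes), which is why the calibration and all reported long-run
statistics use dt = 0.1 min.

Per-cell random streams derive from `SeedSequence((master_seed,
cell_id))`, so populations are bit-reproducible and independent of
execution order.  The inner loop is numba-compiled; the identical
pure-Python code path (`_integrate.py_func`) serves as a slow reference
and is asserted bit-identical in the tests.

## Steady states and bifurcation structure

With `Y = 0` the drift has a feed-forward structure: the OS equation is
autonomous (positive roots of a quadratic for n = 2), `E* = s7·H(OS*)/d_E`,
Nanog solves a 1-D problem on each OS branch, and Rex1 is slaved.
`find_fixed_points` nevertheless solves the full 4-D system by
multi-start damped (Powell-hybrid) root iteration from a deterministic
log-spaced lattice (5 points per axis spanning twice each species'
production/degradation ratio, plus the origin), deduplicating at
relative distance 1e-6 and requiring drift norm < 1e-8.  Stability is
classified from the central-difference Jacobian (relative step 1e-6);
eigenvalues within 1e-9 of zero are flagged marginal.  The 1-D
reduction (`reduced_nanog_rhs`) is kept as an independent brute-force
oracle; fixed points on the self-sustained OS branch must match its
sign-change roots to 1e-4 relative, and do so on randomized parameter
sets in the tests.  Bifurcation scans re-solve per grid value and report
the maximal contiguous range with two stable OS-positive states; the
continuation is deliberately naive (branches are well separated in N).

Besides the pluripotency attractors the system has fixed points with
`OS = 0` (including, for strong autoregulation, a Nanog-positive state
on the OS-free branch).  These are reported with branch label `other`
and are dynamically irrelevant for the scenarios studied here: with the
reference noise levels the OS basin boundary is ~10 log-standard
deviations away.

## Attractor-basin statistics

The NH/NL boundary is the Nanog coordinate of the saddle separating the
two attractors.  A boundary crossing is a **valid transition** only if
the cell then remains on the destination side continuously for at least
60 min; shorter excursions are ignored and do not reset the basin.
Basin membership during the validation window uses the raw N(t) without
smoothing — the residence rule itself is the filter.  Residence
intervals are delimited by valid transitions; only intervals bounded by
two transitions count as uncensored.  Note a sampling property of this
estimator: restricting to completed intervals inside a window of length
T biases the mean of exponential sojourns low by roughly a factor
(1 − 2τ/T); at the 100-day window used for the headline statistics this
is a 15–20% effect for ~10-day residences.  Transition rates are total
valid events per cell-day, with a bootstrap CI resampling cells (1000
replicates, seeded).

The NL-fraction sweep classifies cells by the instantaneous boundary
side at the snapshot time, recomputing the boundary per `s4`; monostable
grid columns classify by proximity to the single attractor.  Its default
initial condition mixes NL/NH at the share of the log-Nanog interval
below the saddle (configurable; the original initialization is
unreported).

## Reference parameter set and calibration

No numeric parameter table is distributed with the model's published
description, so the packaged reference set
(`src/mescnet/data/reference_params.yaml`) was recovered by the
calibration module from the stated constraints:

* structure — bistable Nanog at the LIF/serum repression strength
  (p = 15) and at `s4` ∈ {30, 40, 50}; monostable NH at p = 0;
* 3-day LIF/serum culture seeded in the NH state: ~20% NL cells, NH/NL
  Nanog medians ~2 decades apart, homogeneous OS (CV ≤ 0.3), bimodal
  Rex1 (two-component log-normal mixture beats one by ≥ 10 BIC with
  ≥ 5% weights);
* rare transitions: ~0.05 valid transitions per cell per 24 h (within a
  factor of 2 — the published figure is an estimate), NL/NH mean
  residences ≈ 9/11 days (±30%).

`calibrate` is staged and budget-bounded: a Latin-hypercube sample over
the search box is screened structurally (cheap, deterministic), the
survivors are ranked by a stochastic score from short fixed-seed
population runs, and the most sensitive knobs (`σ_N`, `s4`) are refined
by greedy coordinate steps.  Everything is deterministic given the
master seed, and a failed search returns the best candidate with the
failing constraints enumerated rather than silently accepting it.

Two consistency remarks about those targets.  First, a two-state Markov
caricature with residences (9, 11) days started in NH reaches ≈ 20% NL
after exactly 3 days, so the snapshot and residence targets cohere under
an all-NH initial condition, which the pipeline therefore uses for the
snapshot experiments (it also mirrors sorting experiments in which
purified NH cells re-establish the minority NL population).  Second, the
same caricature implies a *two-directional* long-run event rate of
2/(9+11) = 0.1 per cell-day; 0.05/day corresponds to one direction of
switching.  The transition-rate contract here counts all valid events,
and the measured ~0.09/day sits within the factor-2 tolerance attached
to that target.

Reference values: s12 = 12, s3 = 0.4, s4 = 43, s5 = 0.2, s6 = 15,
s7 = 2, k = 50, n = 2, p = 15, all d_j = 0.1/min, i_OS = i_N = i_R = 1,
σ_OS = 0.05, σ_N = 0.1875, σ_R = 0.1 (1/√min), k_Y = 20, h = 2.  With
these, NL ≈ 1.5 a.u., NH ≈ 172 a.u., saddle ≈ 12.9 a.u., 2i NH ≈ 397 a.u.

## Differentiation experiments

*Signal-response (fraction vs Y).*  LIF/serum populations run 3 days at
each Y; a cell is scored differentiated when its OS stays below 10% of
the NH level for ≥ 60 min (the same persistence logic as the transition
rule), and the classification is absorbing.  At Y = 0 nothing
differentiates; increasing Y converts NL residence into commitment, so
the differentiated fraction rises monotonically and intermediate Y
leaves a mixture of Nanog-regain and chance differentiation.  Absolute
differentiated fractions should not be over-interpreted: the model has
no proliferation or death, which would reshape them in culture.

*2i withdrawal.*  Cells start at the 2i NH attractor.  Erk reaccumulation
is modelled as a per-cell logistic ramp `p_i(t) = p_max/(1+exp(−slope·(t −
t_mid,i)))` with lognormal midpoints (median `t_mid_median`, natural-log
sd `log_sd`) — the minimal smooth, positive, unimodal choice for an
unreported functional form; the midpoint spread stands for cell-to-cell
variation in autocrine FGF4 transduction.  Defaults: p_max = 30,
t_mid_median = 480 min, log_sd = 0.5, slope = 0.02/min, Y = 1,
`rex1_turnover_scale` = 0.005.  Matching the delayed Rex1 kinetics
requires slowing the Rex1 turnover relative to LIF/serum; the scale
multiplies (s5, s6, d_R) — leaving the Rex1 steady state unchanged — and
additionally multiplies σ_R by √scale.  The latter is a package design
choice: the stationary log-variance of Rex1 is σ_R²/(2d_R), so scaling
the turnover alone would inflate the Rex1 spread by 1/scale and turn the
population mean into outlier-dominated noise; √scale keeps the
stationary width turnover-invariant.  With these defaults the population
Nanog mean halves ~8 h after withdrawal while Rex1 holds until ~20–30 h,
and the across-cell dispersion of Nanog peaks hours before that of Rex1
— the asynchronous two-step sequence (Nanog loss, then Rex1 decay, then
abrupt OS collapse).

## Ramp fitting

`fit_ramp` estimates the withdrawal kinetics from a population mRNA
table (t in hours, Nanog and Rex1 relative to t = 0, points every 3 h).
Stage 1 fits (p_max, t_mid_median, slope, log_sd) to the Nanog curve;
stage 2 fits `rex1_turnover_scale` ∈ (0, 1] to the Rex1 curve with the
ramp frozen.  Residuals are taken on log10 expression with a 0.05
relative-expression floor (a detection-limit surrogate that also keeps
the noisy late-time plateau from dominating).  The simulated forward
model uses *stratified* ramp midpoints (lognormal quantiles instead of
random draws), removing the dominant Monte-Carlo noise source, and fixed
seeds per evaluation so the objective is deterministic.  Optimization is
a coarse global grid over (p_max, t_mid_median) followed by Nelder–Mead
with a wide initial simplex and a polish restart — the objective has a
long, nearly flat valley trading p_max against ramp timing, and a purely
local search stalls in it.

Identifiability: `t_mid_median`, `slope`, `log_sd` and the Rex1 scale
are well determined; `p_max` is only weakly identified by a population
mean curve.  Above the saddle-node in p (~38 for the reference set) only
the time at which the ramp crosses the threshold matters, and below it
the escape kinetics respond exponentially but finite-population noise
between data and model tilts the flat valley by ~±20%.  The recovery
test therefore checks self-consistency — data generated and fitted with
the same fixed stochastic realization — where the objective's global
minimum provably sits at the true parameters; recovery of p_max from
independently noisy population data to better than ~±20% should not be
expected at realistic population sizes.

## Synthetic observed data

The generators emulate the *shapes* of the two relevant measurement
types, not any particular measured values: log-normal mixture intensity
samples for Rex1GFPd2-like flow cytometry (LIF/serum default: 20%/80%
weights, modes two decades apart, 0.25 log10-sd per mode; 2i default:
one high mode), and delayed-exponential qRT-PCR time courses with a 3-h
grid, multiplicative measurement noise and a shorter Nanog than Rex1
delay.  `distribution_distance` is the two-sample empirical-CDF max
distance on log10 intensities.  Passing tests against these surrogates
demonstrates that the pipeline reproduces the *statistical structure*
the analysis assumes (bimodality, mode separation, decay ordering); it
does not validate the model against real cytometry or PCR data, which
the generators do not replace (no autofluorescence, gating, compensation,
amplification-efficiency or batch effects).

## Problem sizes

The packaged analyses use 1000 cells × 3 days (dt 0.1 min) for snapshot
phenotypes and transition rates, 500 cells × 100 days for residence
statistics, 150–300 cells for response surfaces and withdrawal kinetics,
and 300-cell populations in the ramp-fit objective — sizes at which the
reported statistics are stable to a few percent while a full analysis
runs in minutes on one CPU.

## Known limitations

No proliferation, death, cell-cycle or spatial/paracrine coupling; mRNA
and protein are collapsed into one stage without delays; the Erk branch
is deterministic; degradation enhancement by Y_in is linear by
assumption; the reference set is one constraint-satisfying point, not a
posterior; the transitions-vs-noise peak position (σ_N ≈ 0.35 here for
s4 = 40) depends on that set, and only its qualitative shape (rise,
interior maximum, decline; higher s4 needs more noise) is a robust
statement.  Euler–Maruyama's first-order treatment of rare escapes makes
long-residence estimates dt-sensitive; statistics intended for
comparison should be computed at dt = 0.1 min.
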