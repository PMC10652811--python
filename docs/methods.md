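# Methods

This note documents the models, the synthetic-data design, the numerical
choices and the known limitations of `cycletrial`.

## The cell-cycle model

Tumor-cell proliferation is modeled as a multistage (Erlang-stage) chain.
Each cell-cycle phase — G0–G1, S, G2–M — is split into `m` memoryless
subphases, so the time spent in a phase is Erlang(m)-distributed rather than
exponential; `m` is a per-cell-line property selected from data. The
population state `X(t)` is the vector of expected cell counts per subphase
(length 3m) evolving as the linear system `dX/dt = A·X`, where `A` encodes

- within-G1 progression at rate `λ_α` (the first m−1 steps),
- the final G1→S exit at rate `λ̃` — the only treatment-sensitive rate,
- S-phase steps at `λ_β`, G2–M steps at `λ_γ` (per-subphase rates, used raw;
  any m-scaling convention is the caller's responsibility),
- division at the end of G2–M returning two daughters to the first G1
  subphase.

There is no carrying capacity, no death compartment and no stochastic
branching: untreated populations grow exponentially at the Perron eigenvalue
of `A`. For `m = 1`, `λ_α` drops out of the dynamics entirely and is excluded
from the inference parameter vector.

Whether a multistage chain should apply `λ_α` or the drug-dependent rate to
the intermediate G1 steps is a genuine design choice; we use the standard
multistage reading — constant `λ_α` within G1, drug dependence confined to
the single G1→S exit step — and treat it as a model assumption.

## The drug-interaction layer

Fulvestrant (F) and palbociclib (P) jointly set the G1→S exit rate through a
Bliss extension with effective doses:

    d_F,eff = d_F / (1 + a_FP · d_P / C_P),   d_P,eff = d_P
    E_i(d)  = e_inf,i + (1 − e_inf,i) / (1 + (d / C_i)^(h_i))
    λ̃(d_F, d_P) = λ_ctrl · E_F(d_F,eff) · E_P(d_P,eff)

`a_FP < 0` is synergy (the partner inflates the effective dose), `a_FP > 0`
antagonism, `a_FP = 0` recovers exact Bliss factorization. The reciprocal
interaction `a_PF` is fixed to zero — a standard one-parameter reduction of
the two-parameter effective-dose model with negligible loss of flexibility.

Two numerical choices:

- **Denominator clamp.** For `a_FP < 0` the denominator `1 + a_FP·d_P/C_P`
  crosses zero at large partner dose. It is clamped below at 0.05, keeping
  the effective dose finite and monotone over the whole nonnegative dose
  orthant while leaving the assay's dose range untouched. Clamping is logged.
- **Response floors.** The Hill curves are parameterized by the control rate
  `λ_ctrl` with optional floors `e_inf ∈ [0, 1)` (default 0); the rate at
  infinite dose is then `λ_ctrl · e_inf`. This reconciles a "maximum-effect
  rate" reading with curves normalized to 1 at zero dose.

**Metrics.** The G1–S TR50 is the dose at which `λ̃/λ_ctrl` crosses 1/2,
found by bracketing bisection to 1e-10 relative (equal to `C` exactly for a
pure single-drug Hill curve); an unattainable half-response returns an
explicit no-result rather than raising. The IC50 is operational: monotone
piecewise-linear interpolation of day-5 count/control against log dose, with
extrapolation refused. GR is the normalized growth-rate inhibition
`2^(k/k_ctrl) − 1`.

## Synthetic assay designs

No public dataset accompanies the assay designs, so the package generates
both from documented ground-truth fixtures:

- **Synergy assay** — 5×5 dose matrix (palbociclib 0/12.5/25/50/100 nmol/L ×
  fulvestrant 0/0.65/1.3/2.6/5.2 nmol/L), days 0–5, 3 replicates,
  2000–3000 cells/well seeded at the stationary phase distribution (cells
  were in free growth before treatment). Only total counts are observed.
- **Cell-cycle assay** — fulvestrant ladder F1–F4 (1.25–10 nmol/L),
  palbociclib ladder P1–P4 (12.5–100 nmol/L) and matched combinations,
  days 0–4, 3 replicates, 500 cells/well starting synchronized (all cells
  in the first G1 subphase, emulating serum-starvation release). Per-phase
  counts are observed; a binomial 10% of cells is thinned uniformly across
  phases into an "unassigned" row, mimicking the S/G2–M ambiguity of
  EdU-based phase calling.

Observation noise is multiplicative log-normal (`exp(σ·z)` per observation):
counts span orders of magnitude and their measured uncertainty behaves
multiplicatively. Default log-scale standard deviations are 0.10 (synergy)
and 0.20 (cell-cycle) — the phase-resolved readout is substantially noisier
than bulk counting. The inference likelihood uses the same observation
model, so parameter recovery is well-posed by construction (self-consistency
is the testable claim; the noise model of the original assays is not
published).

**Fixtures.** Two sensitive profiles are shipped: a wild-type-ER-like line
(`m = 8`, half-max doses `C_P = 7.7`, `C_F = 1.47e−5` nmol/L,
`a_FP = −0.113`) and an ESR1-mutant-like line (`m = 2`, `C_P = 18`,
`C_F = 1.49` nmol/L, `a_FP = −0.1`); the mutant's nmol/L-scale `C_F`
encodes its relative fulvestrant resistance. Chain rates target a ~1.1–1.2
day doubling time; the control exit rates and fulvestrant slopes were
calibrated once so the operational day-5 IC50s land near 58/0.2 nmol/L
(wild-type-like) and 41/5 nmol/L (mutant-like) while the TR50s equal the
half-max doses exactly. A `palbo_resistant` profile scales `C_P` tenfold.
The `recovery_small` fixture used by the inference experiments is the
mutant-like line with `a_FP = −0.113` and deliberately distinct chain rates
(a diagonalizable 6-state system keeps the likelihood cheap).

## Bayesian inference

All kinetic parameters, the interaction term, one day-0 count per assay and
the two noise SDs are estimated jointly. Sampling coordinates are logs of
the positive parameters and the raw `a_FP`. Priors are normal on the
sampling coordinates — weakly informative, centered at fixture-scale
magnitudes with chain-rate centers proportional to `m`, and day-0 centers
taken from the observed day-0 means — with Half-Cauchy(1) priors on the
noise SDs (log-transform Jacobian included).

The likelihood is log-normal around the deterministic trajectory; zero
counts and zero predictions are floored at 0.5 cell before logging (rare,
synchronized day-0 S/G2–M rows). Phase-unassigned rows are dropped from
the likelihood, but their mass is modeled: phase-count predictions are
scaled by (1−u) and the binomial thinning's second-order mean shift
(−u/2(1−u)c) and extra variance (u/(1−u)c) enter the phase-count density
(delta method, with u the generator's unassigned fraction, default 0.10).
The extra-variance term is negligible for large counts but doubles the
effective noise on few-cell observations — which are exactly the early
synchronized-wave S/G2–M counts that identify λ_β and λ_γ; without it the
fit is overconfident there (we measured ~80% instead of 90% interval
coverage for λ_γ). A mixture treatment of the unassigned rows themselves
is a possible extension, not implemented.

The sampler is an ensemble MCMC (emcee; 80% differential-evolution, 20%
snooker moves), initialized in a tight ball around the prior locations. The
convergence contract is checked, not assumed: max R-hat and min bulk ESS
(arviz, walkers treated as chains) ship with every posterior and a
`converged` flag is set at R-hat < 1.01 and ESS > 400; unconverged runs are
returned flagged, never silently accepted. Model choice over `m` fits each
candidate and ranks by LOOIC (−2·elpd, Pareto-smoothed importance-sampling
leave-one-out from the stored pointwise log-likelihood matrix, with per-
observation Pareto-k diagnostics).

**Recovery validation (simulation-based calibration).** Whether the
inference machinery recovers what the generator produced is validated
with 10 seeded repeats in which each repeat's generating parameter set
is *drawn* from a documented, fixture-centered recovery prior
(log-normal spread 0.25 around the fixture values; interaction term
normal around −0.113) and the fit uses that same prior. With truth
drawn from the fitting prior, exact inference covers at exactly the
nominal rate, so the observed counts test the sampler and likelihood
implementation. A fixed-truth variant is *not* calibrated here: in this
nonlinear model at desk-scale n, credible intervals are systematically
~10–20% narrower than the frequentist scatter of their centers
(a Bernstein–von Mises finite-sample gap we measured explicitly — the
residual z-scores are N(0,1) and the MCMC matches the MAP/Laplace
summaries, so it is a property of the statistics, not a defect), which
caps fixed-truth per-parameter coverage near 85%. The experiment asserts
each of `C_P`, `h_P`, `λ_β`, `λ_γ` covered by its 90% interval in ≥8/10
repeats — counted per parameter, since the all-four-jointly rate of even
a perfectly calibrated posterior is well below 90% by the union bound.

**Problem sizes.** Both inference experiments use the reduced design
(4×3 synergy grid with palbociclib doses bracketing the half-max, a
2-level cell-cycle ladder, duplicate wells; ~420 observations). Sampler
budgets are 32 walkers × 1400 steps (recovery, thinned ×2 — interval
endpoints need the effective sample size) and × 400 steps per candidate
(m-selection over {1, 2, 4}, fixed truth m = 2 — the LOOIC ranking is
robust to short chains); these sit below the convergence-contract
thresholds by design and are calibrated for interval coverage and LOOIC
ranking, which tolerate moderate autocorrelation.

## Pharmacokinetics

**Palbociclib** follows linear absorption kinetics per dose: a linear rise
to `C_max` over `t_max` (default 5.5 h) then exponential decay with
half-life 29 h; regimens are superpositions of per-dose profiles. `C_max`
is stored per dose level, not assumed dose-proportional: under this model
the steady-state mean concentration is proportional to the summed per-dose
`C_max`, so strict proportionality would force the once-daily/split-dose
mean ratios to 1. The shipped mapping (125→42.4, 100→35.8, 75→25.43,
50→15.98, 25→11.23 ng/mL single-dose) is calibrated so those ratios equal
the reported clinical values — 1.12 for 100 mg QD vs 50 mg BID and 1.07 for
50/25 mg BID vs 75 mg QD — while the 125 mg steady-state peak lands near
97 ng/mL. Twice-daily doses are 12 h apart.

**Fulvestrant** (500 mg IM on days 1, 15, 29, then every 28 days —
"monthly" is read as the 28-day cycle) follows a three-state linear system:
slow depot → central absorption with central⇄peripheral distribution and
first-order elimination, solved in closed form by eigendecomposition.
Absorption is rate-limiting ("flip-flop"), and the defaults are package
calibrations to the clinical profile shape: single-dose time-to-peak ≈ 7
days, terminal half-life ≈ 40 days, peak ≈ 8.5 ng/mL.

Inter-patient variability is log-normal per parameter (default log-SD 0.2,
0.25 on volumes/C_max; palbociclib `C_max` varies through one shared scale
factor so the calibrated dose-level ratios are preserved within a patient).
Plasma concentrations map to the in vitro nmol/L axis by molecular weight
(palbociclib 447.5, fulvestrant 606.8 g/mol) times a configurable scale
factor (default 1 — no protein-binding or penetration adjustment).

## The in silico trial

Each virtual patient joins an independent PK draw, a PD posterior row (a
synthetic posterior built by jittering a fixture is used where a fitted one
is not supplied; the class is labelled synthetic) and a day-0 tumor count.
For every schedule, concentrations are evaluated at the midpoints of a
0.05-day grid, mapped to the G1→S rate, and propagated by midpoint-frozen
matrix exponentials (unconditionally stable and nonnegativity-preserving on
this Metzler system; second-order in the step; step-halving changes day-100
totals by <0.1%). Heterogeneous tumors are two non-interacting
subpopulations whose totals add; the mixture fraction interpolates the
homogeneous endpoints monotonically.

Comparisons are patient-matched (every patient runs every schedule), with
unpaired two-sided Wilcoxon rank-sum tests across arms (the paired
signed-rank variant is available), 2.5/50/97.5% trajectory-ratio bands, a
descending day-100 waterfall over a 150-patient subsample (dedicated
sub-seed recorded in the output), and the share of patients below ¼ of
their matched standard-schedule count. The packaged trial experiment uses
100-patient cohorts (50 for the resistance sweep over C_P multipliers
{1, 10, 100}) — scaled down from a 1500-patient design, which the engine
also supports.

## Reproducibility

Every stochastic entry point takes an explicit seed; the pipeline expands
one global seed into per-stage seeds via `SeedSequence` spawning, and
identical configurations produce byte-identical outputs. All serialization
is plain text (tidy CSV + JSON manifests).

## Limitations

- The synthetic generator emulates design, dynamics range, multiplicative
  noise and phase-unassignment of the real assays, but not plate spatial
  effects, pipetting error, counting saturation or model misspecification;
  passing recovery tests demonstrates internal consistency of the
  inference, not accuracy on any laboratory dataset.
- Fixture parameter values are calibrated anchors, not fitted posteriors;
  trial-level percentages (e.g. the resistance progression) depend on them
  and should be read qualitatively.
- PK defaults are literature-shaped calibrations supplied via config, not a
  population-PK fit; no food effects, absorption-site physiology, or
  adaptive dose-reduction rules.
- No toxicity model: schedule rankings weigh efficacy only.
- The deterministic ODE tracks expected counts; stochastic extinction and
  clonal variability are out of scope.
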