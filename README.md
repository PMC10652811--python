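# cycletrial

Cell-cycle–explicit PK/PD modeling of CDK4/6-inhibitor + endocrine-therapy
combinations, with an in silico clinical-trial engine for ranking
palbociclib dosing schedules in ER+ breast cancer.

## The problem

Palbociclib is approved as a pulsed schedule — 125 mg daily, 3 weeks on /
1 week off — combined with fulvestrant. Whether continuous lower-dose
schedules would suppress tumor growth better cannot be explored exhaustively
in clinical trials. `cycletrial` provides the modeling chain to ask that
question quantitatively: a mechanistic cell-cycle model parameterized from
in vitro assays, coupled to clinical pharmacokinetics, simulated over
virtual patient cohorts.

## The model

Proliferation follows a multistage cell-cycle chain: each phase (G0–G1, S,
G2–M) is split into *m* memoryless subphases (phase durations are
Erlang(m)), giving a linear ODE system dX/dt = A·X over 3m subphase counts,
with division feeding two daughters back into G1. The only
treatment-sensitive rate is the G1→S exit λ̃, set by both drugs through a
Bliss-extension effective-dose model with Hill responses:

    λ̃(d_F, d_P) = λ_ctrl · E_F(d_F / (1 + a_FP·d_P/C_P)) · E_P(d_P),
    E(d) = e_inf + (1 − e_inf) / (1 + (d/C)^h)

with a_FP < 0 indicating synergy. Parameters (chain rates, half-max doses,
Hill slopes, a_FP, day-0 counts, noise scales) are estimated by ensemble
MCMC from two synthetic assay designs — a 5-day dose-matrix growth assay
and a 4-day phase-resolved cell-cycle assay — and the subphase count m is
selected by PSIS-LOO (LOOIC). The package defines the **G1–S TR50** (dose
halving the G1→S rate) alongside the conventional day-5 IC50 and GR
metrics. A PK layer (linear-absorption palbociclib, two-compartment IM
fulvestrant, log-normal inter-patient variability) drives 100-day
virtual-cohort trials comparing five dosing schedules.

## Worked example

A scaled in silico trial on the ESR1-mutant-like fixture
(`examples/06_in_silico_trial.py`, 60 patients):

```
ranking by median day-100 tumor cells:
 schedule  median_day100  rank
daily_100    7996.865601     1
bid_50_50   10452.433474     2
bid_50_25   15850.296678     3
 daily_75   19893.379045     4
 standard   94729.711725     5

% of patients below 1/4 of their matched standard-schedule count:
  standard       0.0%
  daily_100     88.3%
  daily_75      50.0%
  bid_50_50     85.0%
  bid_50_25     68.3%

pulsed-standard regrowth during the first treatment holiday: day-27/day-21
median ratio 1.76
```

Every continuous schedule outperforms the pulsed standard at day 100 (about
12-fold fewer cells for continuous 100 mg); the pulsed arm rebounds toward
exponential growth during each 7-day washout (the 1.76 ratio); and
splitting 75 mg into 50/25 mg twice daily beats the flat 75 mg once-daily
dose because it holds a higher steady-state mean plasma concentration.
`examples/` contains one script per capability (chain simulation, response
metrics, assay synthesis, Bayesian fitting, PK profiles, trials), each
printing and explaining its numbers.

A pipeline CLI wraps the same machinery for shell use:

```bash
cycletrial pipeline --outdir runs/demo --seed 7 --profile sensitive_plusDOX
```

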