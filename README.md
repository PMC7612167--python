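# scblock

Stochastically curtailed block-randomised two-arm phase II trial designs
for binary outcomes.

## The problem

Single-arm phase II trials compare a response rate against a historical
control and are fragile when that historical rate is wrong. Randomised
two-arm trials remove that fragility but roughly double the sample size,
which matters most in small phase II settings. `scblock` implements a
two-arm design that claws much of that sample size back through
*stochastic curtailment*: the trial is block-randomised (blocks of 2B
participants, B per arm, so the arms are balanced at every interim look),
and after every block the design may stop for futility or efficacy based
on conditional power. It is intended for statisticians designing
randomised phase II trials with a binary endpoint.

## The design

With true response rates p_T (treatment) and p_C (control), define a
*success* as a response on the treatment arm or a non-response on the
control arm. After m participants per arm the success count is

    S(m) = X_T(m) + m − X_C(m),

where X_T, X_C are the arms' response counts. At the final analysis
(N/2 per arm) the null hypothesis p_T = p_C is rejected when
X_T − X_C > r, i.e. S(N/2) ≥ N/2 + r + 1. *Conditional power* (CP) at an
interim state (S, m) is the probability, computed at the anticipated
rates (p_0, p_1), of ultimately rejecting H_0 given the data so far; it
satisfies a backward recursion over the block success distribution (the
convolution of Binomial(B, p_1) and Binomial(B, 1 − p_0)). The design
stops at a block end with a no-go when CP < θ_F, with a go when
CP > θ_E; θ_F = 0, θ_E = 1 gives non-stochastic curtailment (stop only
when the final decision is already certain).

A design realisation is the tuple (r, N, B, θ_F, θ_E). Its exact
operating characteristics — type I error α*, power, and the expected
sample size ESS(p_C, p_T) over both arms — follow from a forward
first-passage recursion over the same state space, with no simulation.
The search enumerates (r, N), takes candidate thresholds from the
attainable CP grid, keeps feasible realisations (α* ≤ α,
power ≥ 1 − β), and Pareto-filters on (ESS(p_0,p_0), ESS(p_0,p_1), N) to
produce the admissible set, tagging the p_0-/p_1-optimal and minimax
members.

The package also evaluates, exactly, the standard comparators — Simon's
single-arm two-stage design, Jung's randomised two-stage design, and the
curtailed designs of Carsten & Chen and Chen et al — and compares
approaches through the weighted loss
L = w_0·ESS(p_0,p_0) + w_1·ESS(p_0,p_1) + (1 − w_0 − w_1)·N over the
weight simplex, and through rejection-probability surfaces under
misspecified true rates.

## Worked example

Evaluate the minimax block-size-two realisation for
(α, β, p_0, p_1) = (0.15, 0.20, 0.30, 0.50) — r = 4, N = 80, thresholds
θ_F = 0.0428, θ_E = 0.9842 (`--snap` moves the truncated printed
thresholds onto the attainable CP grid):

```
$ cat design.json
{
  "r": 4, "N": 80, "B": 1, "theta_f": 0.0428, "theta_e": 0.9842,
  "p0": 0.3, "p1": 0.5, "alpha": 0.15, "beta": 0.2
}
$ scblock evaluate --design design.json --snap
r: 4
N_arm: 40
N: 80
B: 1
ESS00: 57.275881117023104
ESS01: 52.676943291149286
alpha_star: 0.14979761515292775
power: 0.801638031186733
theta_F: 0.042767812499999995
theta_E: 0.9841904016400533
min_stop: 10
```

The design controls the type I error rate at α* = 0.1498 ≤ 0.15 with
power 0.8016 ≥ 0.80; although up to 80 participants may be enrolled, on
average only 57.3 are needed when the treatment is ineffective
(p_C = p_T = 0.3) and 52.7 when it works as anticipated
(p_C, p_T) = (0.3, 0.5); the earliest possible stop is after 10
participants. A seeded Monte-Carlo cross-check of the same design agrees
with the exact values within simulation error:

```
$ scblock simulate --design design.json --pc 0.3 --pt 0.5 --reps 100000 --seed 1 --snap
reject_prob: 0.8009 (se 0.0013)
ess: 52.72 (se 0.067)
```

A restricted search over the threshold grid at fixed (r, N) recovers an
admissible realisation and writes the design table:

```
$ scblock search --p0 0.3 --p1 0.5 --block-size 1 --max-n 80 --n 80 --r 4 \
      --max-combos 100 --out adm.csv
1 admissible design(s) written to adm.csv
```

Unrestricted `--max-combos` (default 10^6) searches the full attainable
grid; other commands are `scblock compare` (exact comparator evaluation)
and `scblock misspec` (rejection surface over true response rates). See
`docs/methods.md` for the model, conventions and numerical choices.

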