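# Methods

This note documents the models, conventions and numerical choices behind
`scblock`. Everything stated here is computed by the test suite or the
acceptance script; nothing is asserted beyond what the code verifies.

## Model and state space

A block-randomised two-arm trial with binary outcomes allocates
participants in blocks of 2B (B per arm), so the arms are balanced after
every block. With per-arm response counts X_T(m), X_C(m) after m
participants per arm, the scalar state is the success count

    S(m) = X_T(m) + m − X_C(m)  ∈  {0, ..., 2m},

which increments per block by the convolution of Binomial(B, p_T) and
Binomial(B, 1 − p_C). The block success distribution is computed by
`block_success_pmf` as that convolution (numpy `convolve` of two scipy
binomial pmfs); it is validated to sum to 1 within 1e−12.

### Final decision boundary

The null p_T = p_C is rejected at the final analysis (n = N/2 per arm)
iff X_T − X_C **strictly exceeds** r, equivalently S(n) ≥ n + r + 1
(`BlockDesign.go_bound`). This strict convention is the one under which
the package's exact computations reproduce the published operating
characteristics of every tabulated block realisation and keep them
feasible; the non-strict reading (≥ r) makes them all infeasible. A
no-go before the final analysis is certain once
S(m) + 2(n − m) < go_bound (the difference can no longer exceed r).

## Conditional power and curtailment

Conditional power (CP) at a block-end state (S, m) is the probability of
final rejection given the state, evaluated at the anticipated rates
(p_0, p_1). It satisfies the backward recursion

    CP(S, m) = Σ_i  P(block adds i successes | p_0, p_1) · CP(S + i, m + B),

with base case CP(S, n) = 1{S ≥ go_bound}. Stochastic curtailment (SC)
rounds interim CP values: a state with CP < θ_F becomes a no-go (CP := 0)
and CP > θ_E a go (CP := 1), **strict** comparisons in both directions —
a state whose CP exactly equals a threshold continues. Rounded values
propagate backwards, so earlier CP values account for later curtailment.
θ_F = 0, θ_E = 1 reduces the SC recursion exactly to the non-stochastic
(NSC) one; the test suite checks the reduction and checks both
recursions against brute-force path enumeration on small designs at
1e−12.

### Threshold snapping

Operating characteristics change only when a threshold crosses an
attainable CP value, so meaningful thresholds live on the finite grid of
interior NSC CP values. Printed thresholds truncated to 3–4 decimal
places can fall on the wrong side of a grid value whose decision is
"continue on equality"; `snap_thresholds` moves each threshold to the
nearest attainable CP value. Evaluation of published realisations in
tests and the acceptance script applies this snap; for most realisations
it is a no-op at the reported precision, but it is what makes the
block-size-two p_0-optimal realisation reproduce its printed expected
sample sizes exactly.

## Exact operating characteristics

The probability of first reaching each block-end state under true rates
(p_C, p_T) follows a forward first-passage recursion: mass enters at the
first block with the block pmf (at the *true* rates) and propagates only
out of continue states. ESS is Σ 2m × (stop mass at m); the rejection
probability is the total go mass; the stopping distribution must sum to
1 within 1e−9 (enforced at construction). `min_stopping_size` is
structural (boolean reachability, independent of rates). Rejection
surfaces under misspecified rates reuse the CP table built at the
anticipated rates and re-run only the forward pass per (p_C, p_T) pair.

## Admissible design search

For each (r, N) on the grid, candidate (θ_F, θ_E) pairs are all ordered
pairs of attainable interior CP values with θ_F ≤ θ_F_MAX (default p_1),
θ_E ≥ θ_E_MIN (default 0.7). If the pair count exceeds `max_combos`
(default 10^6) the sorted value list is repeatedly halved (keeping
indices 0, 2, 4, ...) until it fits. Two cheap bounds prune hopeless
(r, N) cells: the maximum attainable power (no futility stopping,
maximal go-curtailment) and the minimum attainable type I error (maximal
futility stopping, no go-curtailment). Remaining pairs are evaluated
exactly in vectorised batches (all pairs share the NSC structure; only
the thresholding differs), with batch sizes tuned to stay cache-resident
(~2·10^6 state-entries per batch). Feasible pairs are Pareto-thinned
within each batch — exact, since N is constant within a cell and
dominance is transitive — and the survivors are Pareto-filtered globally
on (ESS(p_0,p_0), ESS(p_0,p_1), N). Ties on all three criteria are all
retained. Optimal/minimax tags break ties by smaller N, then the other
ESS, then larger θ_E. The full threshold grid of the largest tabulated
cell (about 6·10^5 pairs at N = 116) evaluates in about 90 s on one CPU;
the test suite's search tests use restricted grids and the acceptance
suite runs the one full-grid search.

## Comparator designs

All four comparators are evaluated exactly; a seeded Monte-Carlo mode
exists as an independent cross-check (the original comparator tables
were published as 10,000-replicate estimates, so agreement with those is
asserted within ±1.0 ≈ 3 standard errors). Conventions, fixed by
calibration against the published tables:

- **Simon** (single-arm two-stage): stop after n1 patients iff
  responses ≤ r1; reject at n iff responses > r. The single response
  rate is passed through the `pt` slot of `evaluate(pc, pt)`.
- **Jung** (randomised two-stage): continue past the interim (n1 per
  arm) iff X_T1 − X_C1 > r1; reject at the final analysis iff
  X_T − X_C ≥ r. Evaluated by double-binomial convolution over both
  stages.
- **Carsten & Chen** (paired, curtailed): pair success probability
  p_T(1 − p_C); go the moment successes reach r; no-go as soon as r1
  successes by pair n1, or r by pair n_arm, become unreachable
  (continuing at the interim requires successes ≥ r1). Markov chain
  over (pair index, success count).
- **Chen et al** (per-patient, curtailed): patients alternate T, C, ...;
  a "success" is a treatment response (prob p_T) or a control
  non-response (prob 1 − p_C); n1 is per arm (interim after 2·n1
  patients); continue iff X_T − X_C ≥ r1 there, reject iff ≥ r at the
  end, with go/no-go curtailment the moment the final decision is
  certain. Per-patient dynamic programme.

One published table's Jung rows (and one Chen row) at the second
parameter set are only consistent with the interim boundary shifted by
one; the package freezes the convention calibrated on the first
parameter set. The Carsten realisations quoted in the two published
misspecification figure captions are infeasible under the calibrated
Carsten model (their power is far below the design requirement), so
misspecification reproduction is asserted for the block designs only.

## Loss comparison

The loss of a realisation with criteria (ESS00, ESS01, N) at weights
(w_0, w_1 ≥ 0, w_0 + w_1 ≤ 1) is
L = w_0·ESS00 + w_1·ESS01 + (1 − w_0 − w_1)·N. `omni_admissible_map`
evaluates, on a triangular weight grid (default step 0.01), each
approach's minimum loss over its admissible set and reports the winning
approach per grid point (ties within 1e−9 reported jointly);
`area_fractions` splits tied points equally.

## Simulation

`simulate_trial` / `estimate_chars` draw block outcomes at the true
rates and apply the precomputed decision table; decisions depend only on
block-end states. Replicates are driven by a generator spawned from the
master seed, so results are reproducible. Standard errors are binomial
(rejection) and empirical (ESS). Test-suite problem sizes — 10^5
replicates per published realisation for the consistency sweep, 2–3·10^4
for goodness-of-fit — are the package's own choices balancing resolution
(3 SE ≈ 0.4 participants at 10^5 replicates) against runtime.

## Numerical choices and limitations

- All probabilities are computed in double precision with convolutions
  of exact binomial pmfs; no logs or approximations. Mass-conservation
  checks at 1e−9–1e−12 guard the recursions.
- Interim analyses happen only at block ends; within-block outcomes are
  never inspected. N must be even and N/2 divisible by B.
- The search is exact but exhaustive per (r, N) cell; full searches over
  maxN = 120 with the 10^6-combo grid across many rate pairs are
  compute-heavy and are exercised at reduced scale in the tests.
- ESS is counted over both arms everywhere. Anticipated rates enter the
  CP table; true rates enter only the forward pass.
- The package designs trials; it does not analyse trial data beyond the
  designed decision rule.
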