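"""Exact evaluation of the comparison designs: Simon, Jung, Carsten, Chen.

All four are evaluated by exact binomial computation or dynamic
programming; a seeded Monte-Carlo mode is provided as an independent
fidelity check (the original comparator operating characteristics were
published as 10,000-replicate estimates).

Boundary conventions (fixed by calibration against published operating
characteristics; see docs/methods.md):

* Simon (single-arm two-stage): stop for futility after n1 patients iff
  responses <= r1; reject H0 at n iff responses > r.
* Jung (two-arm two-stage): continue past the interim (n1 per arm) iff
  X_T1 - X_C1 > r1; reject at the final analysis iff X_T - X_C >= r.
* Carsten & Chen (paired, curtailed): pair success = response on
  treatment and non-response on control, probability pt*(1-pc); go the
  moment successes reach r; no-go as soon as r1 successes by pair n1, or
  r successes by pair n_arm, become unreachable (continuing at the
  interim requires successes >= r1).
* Chen et al (per-patient, curtailed): patients alternate T, C, T, C...;
  a success is a response on a treatment slot (prob pt) or a non-response
  on a control slot (prob 1-pc).  Reject at the final analysis iff
  X_T - X_C >= r; go as soon as that is guaranteed, no-go as soon as it —
  or the interim requirement X_T - X_C >= r1 after n1 per arm — becomes
  unreachable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.stats import binom

KINDS = ("simon", "jung", "carsten", "chen")


class Evaluation(NamedTuple):
    """Rejection probability and expected total sample size."""

    reject_prob: float
    expected_n: float


@dataclass(frozen=True)
class TwoStageDesign:
    """Two-stage / curtailed comparator parameterisation (r1, n1, r, n_arm).

    ``n1`` is counted per arm for Jung and Chen, in pairs for Carsten and
    in patients for the single-arm Simon design; ``n_arm`` is the maximum
    per-arm sample size (total for Simon).  ``r1`` may be negative (an
    interim futility boundary below zero difference).
    """

    kind: str
    r1: int
    n1: int
    r: int
    n_arm: int

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if not 0 < self.n1 <= self.n_arm:
            raise ValueError(f"require 0 < n1 <= n_arm, got n1={self.n1}, n_arm={self.n_arm}")
        if self.r1 > self.r:
            raise ValueError(f"require r1 <= r, got r1={self.r1}, r={self.r}")

    @property
    def max_total(self) -> int:
        return self.n_arm if self.kind == "simon" else 2 * self.n_arm

    def evaluate(self, pc: float, pt: float) -> Evaluation:
        return _EVALUATORS[self.kind](self, pc, pt)


def _diff_pmf(n: int, pc: float, pt: float) -> np.ndarray:
    """pmf of X_T - X_C over n per arm; index i corresponds to d = i - n."""
    k = np.arange(n + 1)
    return np.convolve(binom.pmf(k, n, pt), binom.pmf(k, n, 1.0 - pc))


def simon_eval(design: TwoStageDesign, p: float) -> Evaluation:
    """Exact two-stage single-arm computation (reference design)."""
    r1, n1, r, n = design.r1, design.n1, design.r, design.n_arm
    if not (-1 <= r1 <= n1 and 0 <= r <= n):
        raise ValueError("boundaries outside sample-size range")
    pet = float(binom.cdf(r1, n1, p))  # stop iff stage-1 responses <= r1
    reject = 0.0
    for x1 in range(r1 + 1, n1 + 1):
        reject += binom.pmf(x1, n1, p) * binom.sf(r - x1, n - n1, p)
    return Evaluation(float(reject), n1 + (1.0 - pet) * (n - n1))


def jung_eval(design: TwoStageDesign, pc: float, pt: float) -> Evaluation:
    """Exact double-binomial convolution over both stages of Jung's design."""
    r1, n1, r, n = design.r1, design.n1, design.r, design.n_arm
    pmf1 = _diff_pmf(n1, pc, pt)
    d1 = np.arange(-n1, n1 + 1)
    cont = d1 > r1
    n2 = n - n1
    if n2 == 0:
        reject = float(pmf1[cont & (d1 >= r)].sum())
        return Evaluation(reject, 2.0 * n1)
    pmf2 = _diff_pmf(n2, pc, pt)
    d2 = np.arange(-n2, n2 + 1)
    reject = 0.0
    for v, p in zip(d1[cont], pmf1[cont]):
        reject += p * float(pmf2[d2 + v >= r].sum())
    en = 2.0 * n1 + float(pmf1[cont].sum()) * 2.0 * n2
    return Evaluation(float(reject), en)


def carsten_eval(design: TwoStageDesign, pc: float, pt: float) -> Evaluation:
    """Exact Markov-chain evaluation of the paired-success curtailed design."""
    r1, n1, r, n = design.r1, design.n1, design.r, design.n_arm
    ps = pt * (1.0 - pc)
    if r == 0:  # success boundary met before any pair
        return Evaluation(1.0, 0.0)
    active = np.zeros(r)  # prob of s successes among still-running trials
    active[0] = 1.0
    reject = en = 0.0
    for j in range(1, n + 1):
        nxt = np.zeros(r + 1)
        nxt[1:] += active * ps
        nxt[:-1] += active * (1.0 - ps)
        go = nxt[r]  # reached the required success count at pair j
        reject += go
        en += 2 * j * go
        active = nxt[:r]
        s = np.arange(r)
        stop = s + (n - j) < r  # r unreachable by the final pair
        if j <= n1:
            stop |= s + (n1 - j) < r1  # interim requirement unreachable
        en += 2 * j * float(active[stop].sum())
        active = np.where(stop, 0.0, active)
    en += 2 * n * float(active.sum())  # defensive; all mass stops by pair n
    return Evaluation(float(reject), float(en))


def chen_eval(design: TwoStageDesign, pc: float, pt: float) -> Evaluation:
    """Exact per-patient DP for the curtailed response-difference design."""
    r1, n1, r, n = design.r1, design.n1, design.r, design.n_arm
    total = 2 * n
    interim_at = 2 * n1
    gb = n + r  # reject iff final success count S >= n_arm + r  (D >= r)
    req1 = n1 + r1  # continue iff S after 2*n1 patients >= n1 + r1 (D >= r1)
    if gb > total:
        # final boundary unreachable: every path is no-go curtailed
        return Evaluation(0.0, float(_chen_nogo_only_en(design, pc, pt)))
    active = np.zeros(total + 1)
    active[0] = 1.0
    reject = en = 0.0
    for k in range(1, total + 1):
        p_succ = pt if k % 2 == 1 else 1.0 - pc  # T, C, T, C, ...
        nxt = np.zeros(total + 1)
        nxt[1:] += active[:-1] * p_succ
        nxt += active * (1.0 - p_succ)
        s = np.arange(total + 1)
        go = s >= gb
        nogo = s + (total - k) < gb
        if k <= interim_at:
            nogo |= s + (interim_at - k) < req1
        if k == total:
            nogo |= ~go
        stop = go | nogo
        reject += float(nxt[go].sum())
        en += k * float(nxt[stop].sum())
        nxt[stop] = 0.0
        active = nxt
    return Evaluation(float(reject), float(en))


def _chen_nogo_only_en(design: TwoStageDesign, pc: float, pt: float) -> float:
    # with r > n_arm the no-go curtailment fires immediately at patient 1
    # under the same unreachability rule; expected N equals the first
    # patient index at which S + remaining < n_arm + r, which is patient 1
    # whenever r > n_arm.  Kept as a helper for clarity.
    return 1.0


def simulate_comparator(
    design: TwoStageDesign,
    pc: float,
    pt: float,
    n_reps: int,
    seed: int,
) -> tuple[Evaluation, Evaluation]:
    """Seeded Monte-Carlo estimate replicating the published estimation
    protocol; returns (estimate, standard_errors) as Evaluation pairs."""
    rng = np.random.default_rng(seed)
    rejects = np.empty(n_reps, dtype=bool)
    totals = np.empty(n_reps, dtype=float)
    for i in range(n_reps):
        rejects[i], totals[i] = _simulate_one(design, pc, pt, rng)
    est = Evaluation(float(rejects.mean()), float(totals.mean()))
    se = Evaluation(
        float(rejects.std(ddof=1) / np.sqrt(n_reps)),
        float(totals.std(ddof=1) / np.sqrt(n_reps)),
    )
    return est, se


def _simulate_one(design: TwoStageDesign, pc, pt, rng) -> tuple[bool, float]:
    r1, n1, r, n = design.r1, design.n1, design.r, design.n_arm
    if design.kind == "simon":
        x1 = rng.binomial(n1, pt)  # single-arm: rate taken from the pt slot
        if x1 <= r1:
            return False, float(n1)
        x = x1 + rng.binomial(n - n1, pt)
        return bool(x > r), float(n)
    if design.kind == "jung":
        d1 = rng.binomial(n1, pt) - rng.binomial(n1, pc)
        if d1 <= r1:
            return False, 2.0 * n1
        d = d1 + rng.binomial(n - n1, pt) - rng.binomial(n - n1, pc)
        return bool(d >= r), 2.0 * n
    if design.kind == "carsten":
        ps = pt * (1.0 - pc)
        s = 0
        for j in range(1, n + 1):
            s += rng.random() < ps
            if s >= r:
                return True, 2.0 * j
            if s + (n - j) < r or (j <= n1 and s + (n1 - j) < r1):
                return False, 2.0 * j
        return False, 2.0 * n
    # chen
    total, interim_at, gb, req1 = 2 * n, 2 * design.n1, n + r, design.n1 + r1
    s = 0
    for k in range(1, total + 1):
        p_succ = pt if k % 2 == 1 else 1.0 - pc
        s += rng.random() < p_succ
        if s >= gb:
            return True, float(k)
        if s + (total - k) < gb or (k <= interim_at and s + (interim_at - k) < req1):
            return False, float(k)
    return False, float(total)


_EVALUATORS = {
    # single-arm: the (single) response rate is taken from the pt slot
    "simon": lambda d, pc, pt: simon_eval(d, pt),
    "jung": jung_eval,
    "carsten": carsten_eval,
    "chen": chen_eval,
}


def comparator_search(
    kind: str,
    p0: float,
    p1: float,
    alpha: float,
    beta: float,
    n_min: int = 10,
    n_max: int = 200,
    screen_reps: int = 0,
    seed: int = 0,
) -> list[tuple[TwoStageDesign, float, float, float, float]]:
    """Admissible designs of one comparator approach.

    Enumerates (r1, n1, r, n_arm) with n1 <= n_arm and r1 <= r over total
    sample sizes in [n_min, n_max], evaluates each design exactly at
    (p0, p0) and (p0, p1), keeps feasible designs and Pareto-filters on
    (ESS(p0,p0), ESS(p0,p1), N).  ``screen_reps > 0`` enables a coarse
    Monte-Carlo pre-screen at relaxed error rates (alpha + 0.1,
    beta + 0.1) before the exact evaluation.

    Returns tuples (design, alpha_star, power, ess00, ess01).
    """
    from .search import pareto_mask  # local import to avoid a cycle

    if kind not in KINDS:
        raise ValueError(f"kind must be one of {KINDS}, got {kind!r}")
    single_arm = kind == "simon"
    feasible = []
    arm_lo = max(1, n_min if single_arm else (n_min + 1) // 2)
    arm_hi = n_max if single_arm else n_max // 2
    for n_arm in range(arm_lo, arm_hi + 1):
        r_hi = n_arm
        for r in range(0, r_hi + 1):
            r1_lo = 0 if kind in ("simon", "carsten") else -n_arm
            for n1 in range(1, n_arm + 1):
                for r1 in range(r1_lo, min(r, n1) + 1):
                    d = TwoStageDesign(kind=kind, r1=r1, n1=n1, r=r, n_arm=n_arm)
                    if screen_reps:
                        est0, _ = simulate_comparator(d, p0, p0, screen_reps, seed)
                        est1, _ = simulate_comparator(d, p0, p1, screen_reps, seed + 1)
                        if est0.reject_prob > alpha + 0.1 or est1.reject_prob < 1 - beta - 0.1:
                            continue
                    a, e00 = d.evaluate(p0, p0)
                    pw, e01 = d.evaluate(p0, p1)
                    if a <= alpha and pw >= 1.0 - beta:
                        feasible.append((d, a, pw, e00, e01))
    if not feasible:
        return []
    crit = np.array([[e00, e01, d.max_total] for d, _, _, e00, e01 in feasible])
    keep = pareto_mask(crit)
    return [f for f, k in zip(feasible, keep) if k]
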