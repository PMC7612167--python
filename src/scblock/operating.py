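"""Exact operating characteristics via forward first-passage recursion.

Given a conditional-power table, the probability of *first* reaching each
block-end state (S, m) under true rates (pC, pT) satisfies a forward
recursion: mass enters at the first block with the block pmf and
propagates only out of continue states, convolved with the block pmf.
Stop states (CP in {0, 1}) absorb.  Expected sample size is the stop-state
mass weighted by 2m (both arms), and the rejection probability is the
total mass absorbed in go states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conditional_power import CONTINUE, GO, NOGO, CPTable, block_success_pmf, cp_table_sc
from .design import BlockDesign


@dataclass(frozen=True)
class RateEvaluation:
    """Exact behaviour of a fixed design under one pair of true rates."""

    pc: float
    pt: float
    reject_prob: float
    ess: float
    stop_dist: pd.DataFrame  # columns (m, decision, prob); sums to 1

    def __post_init__(self) -> None:
        total = float(self.stop_dist["prob"].sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"stopping distribution mass {total!r} != 1")


@dataclass(frozen=True)
class OperatingChars:
    """Operating characteristics of a design realisation.

    ``ess_null``/``ess_alt`` are ESS(p0,p0) and ESS(p0,p1) counted over
    both arms; ``min_stop`` is the smallest total sample size at which the
    trial can terminate (a structural property of the boundaries).
    """

    alpha_star: float
    power: float
    ess_null: float
    ess_alt: float
    max_n: int
    min_stop: int
    null_eval: RateEvaluation
    alt_eval: RateEvaluation

    def feasible(self, alpha: float, beta: float) -> bool:
        return self.alpha_star <= alpha and self.power >= 1.0 - beta


def reach_probabilities(
    table: CPTable, pc: float, pt: float
) -> dict[int, np.ndarray]:
    """First-passage probability of every block-end state (S, m).

    ``out[m][S]`` is the probability that the trial is still running after
    m - B participants per arm and then moves to state (S, m).  Mass in a
    stop state is absorbed there; the total over all stop states is 1.
    """
    design = table.design
    pmf = block_success_pmf(design.block, pc, pt).probs
    reach: dict[int, np.ndarray] = {design.block: pmf.copy()}
    for m in design.block_ends:
        if m == design.block:
            continue
        prev = reach[m - design.block].copy()
        prev[table.decisions(m - design.block) != CONTINUE] = 0.0
        reach[m] = np.convolve(prev, pmf)
    return reach


def rate_characteristics(table: CPTable, pc: float, pt: float) -> RateEvaluation:
    """Exact rejection probability, ESS and stopping distribution at (pc, pt)."""
    design = table.design
    reach = reach_probabilities(table, pc, pt)
    ess = 0.0
    reject = 0.0
    rows = []
    for m in design.block_ends:
        dec = table.decisions(m)
        mass = reach[m]
        p_go = float(mass[dec == GO].sum())
        p_nogo = float(mass[dec == NOGO].sum())
        reject += p_go
        ess += 2 * m * (p_go + p_nogo)
        if p_go:
            rows.append((m, "go", p_go))
        if p_nogo:
            rows.append((m, "no-go", p_nogo))
    dist = pd.DataFrame(rows, columns=["m", "decision", "prob"])
    return RateEvaluation(pc=pc, pt=pt, reject_prob=reject, ess=ess, stop_dist=dist)


def min_stopping_size(table: CPTable) -> int:
    """Smallest total sample size at which the trial can terminate.

    Uses structural reachability (every block outcome 0..2B treated as
    possible), so the result does not depend on the true response rates.
    """
    design = table.design
    b = design.block
    reachable = np.ones(2 * b + 1, dtype=bool)
    for m in design.block_ends:
        dec = table.decisions(m)
        if np.any(reachable & (dec != CONTINUE)):
            return 2 * m
        cont = reachable & (dec == CONTINUE)
        nxt = np.zeros(2 * (m + b) + 1, dtype=bool)
        for i in range(2 * b + 1):
            nxt[i : i + 2 * m + 1] |= cont
        reachable = nxt
    return design.n_total  # unreachable in practice: final states all stop


def operating_characteristics(
    design: BlockDesign, table: CPTable | None = None
) -> OperatingChars:
    """Exact operating characteristics at the anticipated rates.

    Evaluates the design at (p0, p0) for the type I error rate and
    ESS(p0,p0), and at (p0, p1) for power and ESS(p0,p1).
    """
    if table is None:
        table = cp_table_sc(design)
    ctx = design.context
    null_eval = rate_characteristics(table, ctx.p0, ctx.p0)
    alt_eval = rate_characteristics(table, ctx.p0, ctx.p1)
    return OperatingChars(
        alpha_star=null_eval.reject_prob,
        power=alt_eval.reject_prob,
        ess_null=null_eval.ess,
        ess_alt=alt_eval.ess,
        max_n=design.n_total,
        min_stop=min_stopping_size(table),
        null_eval=null_eval,
        alt_eval=alt_eval,
    )


def chars_to_row(design: BlockDesign, chars: OperatingChars) -> dict:
    """Flatten a design and its characteristics into a table row."""
    return {
        "r": design.r,
        "N_arm": design.n_arm,
        "N": design.n_total,
        "B": design.block,
        "ESS00": chars.ess_null,
        "ESS01": chars.ess_alt,
        "alpha_star": chars.alpha_star,
        "power": chars.power,
        "theta_F": design.theta_f,
        "theta_E": design.theta_e,
        "min_stop": chars.min_stop,
    }
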