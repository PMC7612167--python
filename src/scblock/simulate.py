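"""Seeded Monte-Carlo trial simulation.

The simulator draws block outcomes sequentially and applies the
precomputed conditional-power stopping boundaries, serving as an
independent oracle for every exact computation in the package.  Decisions
depend only on block-end states, never on within-block partial data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conditional_power import CONTINUE, GO, NOGO, CPTable, cp_table_sc
from .design import BlockDesign


@dataclass(frozen=True)
class TrialResult:
    decision: str  # "go" or "no-go"
    total_n: int  # participants enrolled over both arms
    trajectory: list[tuple[int, int]]  # (m, S) after each completed block


@dataclass(frozen=True)
class MonteCarloChars:
    """Plug-in estimates of the operating characteristics with standard errors."""

    pc: float
    pt: float
    n_reps: int
    reject_prob: float
    reject_se: float
    ess: float
    ess_se: float
    stop_dist: pd.DataFrame  # empirical (m, decision, prob)


def simulate_trial(
    design: BlockDesign,
    pc: float,
    pt: float,
    seed: int | np.random.Generator,
    table: CPTable | None = None,
) -> TrialResult:
    """Simulate a single trial; identical seeds give identical outcomes."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if table is None:
        table = cp_table_sc(design)
    b = design.block
    s = 0
    trajectory = []
    for m in design.block_ends:
        xt = rng.binomial(b, pt)
        xc = rng.binomial(b, pc)
        s += xt + b - xc
        trajectory.append((m, s))
        d = table.decisions(m)[s]
        if d != CONTINUE:
            return TrialResult("go" if d == GO else "no-go", 2 * m, trajectory)
    raise RuntimeError("trial reached final analysis without a decision")  # pragma: no cover


def estimate_chars(
    design: BlockDesign,
    pc: float,
    pt: float,
    n_reps: int,
    seed: int,
    table: CPTable | None = None,
) -> MonteCarloChars:
    """Monte-Carlo operating characteristics from ``n_reps`` replicates.

    Replicates are driven by substreams spawned deterministically from the
    master seed, so estimates are reproducible and parallelisable.  All
    replicates are advanced block-by-block in a vectorised sweep.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if table is None:
        table = cp_table_sc(design)
    root = np.random.default_rng(seed)
    rng = root.spawn(1)[0]
    b = design.block
    s = np.zeros(n_reps, dtype=np.int64)
    alive = np.ones(n_reps, dtype=bool)
    total_n = np.zeros(n_reps, dtype=np.int64)
    rejected = np.zeros(n_reps, dtype=bool)
    stop_counts: dict[tuple[int, str], int] = {}
    for m in design.block_ends:
        n_alive = int(alive.sum())
        if n_alive == 0:
            break
        draw = rng.binomial(b, pt, size=n_alive) + b - rng.binomial(b, pc, size=n_alive)
        s[alive] += draw
        dec = table.decisions(m)[s[alive]]
        idx = np.flatnonzero(alive)
        for code, label in ((GO, "go"), (NOGO, "no-go")):
            hit = idx[dec == code]
            if hit.size:
                total_n[hit] = 2 * m
                rejected[hit] = code == GO
                alive[hit] = False
                stop_counts[(m, label)] = stop_counts.get((m, label), 0) + hit.size
    reject = float(rejected.mean())
    ess = float(total_n.mean())
    dist = pd.DataFrame(
        [(m, lab, c / n_reps) for (m, lab), c in sorted(stop_counts.items())],
        columns=["m", "decision", "prob"],
    )
    reject_se = float(np.sqrt(reject * (1 - reject) / n_reps))
    ess_se = float(total_n.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else float("nan")
    return MonteCarloChars(
        pc=pc, pt=pt, n_reps=n_reps,
        reject_prob=reject, reject_se=reject_se,
        ess=ess, ess_se=ess_se, stop_dist=dist,
    )
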