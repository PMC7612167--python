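"""Exact conditional-power recursions for the curtailed block design.

Conditional power CP(S, m) is the probability of ultimately rejecting H0
given S successes after m participants per arm, always computed at the
anticipated rates (p0, p1) — there is no re-estimation of response rates.
The recursion runs backwards over block ends m = N/2, N/2-B, ..., B:

* CP = 1 when rejection is already certain (S >= N/2 + r + 1, since the
  success count never decreases);
* CP = 0 when rejection has become impossible (even 2B successes per
  remaining block cannot reach the boundary);
* otherwise CP(S, m) = D = sum_i P(i, B | p0, p1) CP(S+i, m+B).

Under stochastic curtailment, interior D below theta_f is rounded down to
zero (no-go) and interior D above theta_e is rounded up to one (go); the
rounded values feed the D sums of earlier blocks, so downstream operating
characteristics are exact.  Threshold comparisons are strict — D equal to
theta_f or theta_e continues — because thresholds are drawn from the
attainable CP grid itself, where equality marks the state that defines the
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import binom

from .design import BlockDesign

# decision codes
GO = 1
CONTINUE = 0
NOGO = -1

_DECISION_LABEL = {GO: "go", CONTINUE: "continue", NOGO: "no-go"}


@dataclass(frozen=True)
class BlockPMF:
    """Distribution of block successes S(B) = X_T(B) + B - X_C(B)."""

    block: int
    pc: float
    pt: float
    probs: np.ndarray  # length 2B+1, index i = successes in the block

    def __post_init__(self) -> None:
        total = float(self.probs.sum())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"block pmf does not sum to 1 (sum={total!r})")

    @property
    def mean(self) -> float:
        return float(np.arange(2 * self.block + 1) @ self.probs)


def block_success_pmf(block: int, pc: float, pt: float) -> BlockPMF:
    """Exact pmf of the number of successes in one block.

    A success is a response on treatment or a non-response on control, so
    S(B) = X_T + (B - X_C) with X_T ~ Binom(B, pt) and X_C ~ Binom(B, pc)
    independent; B - X_C ~ Binom(B, 1 - pc) and S(B) is the convolution of
    the two binomials.
    """
    if block < 1:
        raise ValueError(f"block must be >= 1, got {block}")
    for name, p in (("pc", pc), ("pt", pt)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    k = np.arange(block + 1)
    probs = np.convolve(binom.pmf(k, block, pt), binom.pmf(k, block, 1.0 - pc))
    return BlockPMF(block=block, pc=pc, pt=pt, probs=probs)


@dataclass
class CPTable:
    """Conditional power and stop/continue classification at block ends.

    ``cp[m]`` is an array of length 2m+1 giving CP(S, m) for S = 0..2m.
    A state is a *go* state iff CP = 1, a *no-go* state iff CP = 0, and a
    *continue* state otherwise; at the final analysis every state stops.
    """

    design: BlockDesign
    cp: dict[int, np.ndarray]
    curtailed: bool  # True when built with the (theta_f, theta_e) thresholds

    _decisions: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def block_ends(self) -> range:
        return self.design.block_ends

    def decisions(self, m: int) -> np.ndarray:
        """Decision codes (GO / CONTINUE / NOGO) for every S at block end m."""
        if m not in self._decisions:
            v = self.cp[m]
            d = np.full(v.shape, CONTINUE, dtype=np.int8)
            d[v == 1.0] = GO
            d[v == 0.0] = NOGO
            self._decisions[m] = d
        return self._decisions[m]

    def interior_values(self) -> np.ndarray:
        """Sorted unique interior CP values (strictly between 0 and 1),
        pooled over all block ends."""
        vals = np.concatenate([v[(v > 0.0) & (v < 1.0)] for v in self.cp.values()])
        return np.unique(vals)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns (m, S, cp, decision)."""
        rows = []
        for m in self.block_ends:
            dec = self.decisions(m)
            for s, (v, d) in enumerate(zip(self.cp[m], dec)):
                rows.append((m, s, v, _DECISION_LABEL[int(d)]))
        return pd.DataFrame(rows, columns=["m", "S", "cp", "decision"])


def _backward(design: BlockDesign, theta_f: float, theta_e: float) -> dict[int, np.ndarray]:
    n_arm = design.n_arm
    gb = design.go_bound
    pmf = block_success_pmf(design.block, design.context.p0, design.context.p1).probs
    cp: dict[int, np.ndarray] = {}
    cp[n_arm] = (np.arange(2 * n_arm + 1) >= gb).astype(float)
    for m in range(n_arm - design.block, 0, -design.block):
        s = np.arange(2 * m + 1)
        # D(S) = sum_i pmf[i] * CP(S+i, m+B), a correlation with the block pmf
        d = np.convolve(cp[m + design.block], pmf[::-1], mode="valid")
        vals = d.copy()
        go = s >= gb
        nogo = s + 2 * (n_arm - m) < gb  # boundary unreachable even if all succeed
        interior = ~go & ~nogo
        vals[go] = 1.0
        vals[nogo] = 0.0
        vals[interior & (d < theta_f)] = 0.0
        vals[interior & (d > theta_e)] = 1.0
        cp[m] = vals
    return cp


def cp_table_nsc(design: BlockDesign) -> CPTable:
    """Conditional-power table under non-stochastic curtailment only.

    The trial stops only when the final decision is logically certain;
    interior states always continue.
    """
    return CPTable(design=design, cp=_backward(design, 0.0, 1.0), curtailed=False)


def cp_table_sc(design: BlockDesign) -> CPTable:
    """Conditional-power table under stochastic curtailment.

    Interior D < theta_f is rounded down to 0 (no-go) and interior
    D > theta_e is rounded up to 1 (go) during the backward pass, so the
    rounded values propagate into earlier states' expectations.  With
    theta_f=0 and theta_e=1 this reduces exactly to :func:`cp_table_nsc`.
    """
    return CPTable(
        design=design,
        cp=_backward(design, design.theta_f, design.theta_e),
        curtailed=True,
    )


def snap_thresholds(design: BlockDesign) -> BlockDesign:
    """Snap (theta_f, theta_e) to the nearest attainable interior CP values.

    Threshold grids are drawn from the interior CP values of the design's
    NSC table, where equality with a threshold means *continue*.  A
    threshold printed to a few decimal places can therefore land just
    below the CP value that defined it and silently flip that state from
    continue to stop.  Snapping to the nearest attainable value restores
    the intended classification; designs whose thresholds already sit on
    grid values are returned unchanged.
    """
    vals = cp_table_nsc(design).interior_values()
    if vals.size == 0:
        return design
    tf = float(vals[np.abs(vals - design.theta_f).argmin()])
    te = float(vals[np.abs(vals - design.theta_e).argmin()])
    if te <= tf:
        raise ValueError("snapped thresholds collapsed: theta_f >= theta_e")
    return replace(design, theta_f=tf, theta_e=te)
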