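"""Design parameterisations for two-arm binary-outcome phase II trials.

A trial is framed by a :class:`DesignContext` — the anticipated control and
treatment response rates (p0, p1) and the error constraints (alpha, beta)
for testing H0: pT <= pC.  A :class:`BlockDesign` is a concrete realisation
of the stochastically curtailed block design: participants are randomised
in blocks of 2B (B per arm), the trial is inspected at the end of every
block, and stopping is governed by conditional-power thresholds
(theta_f for futility / no-go, theta_e for efficacy / go) together with the
final boundary r on the response difference X_T - X_C.

The null hypothesis is rejected at the final analysis when the difference
in responses exceeds r, i.e. X_T(N/2) - X_C(N/2) > r.  In terms of the
success count S(m) = X_T(m) + m - X_C(m), rejection at the final analysis
corresponds to S(N/2) >= N/2 + r + 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class DesignContext:
    """Hypothesis-test frame: anticipated rates and error constraints.

    Parameters
    ----------
    p0 : float
        Anticipated control-arm response rate, in [0, 1).
    p1 : float
        Anticipated treatment-arm response rate, in (p0, 1].
    alpha : float
        Maximum type I error P(reject H0 | p0, p0), in (0, 1).
    beta : float
        Maximum type II error 1 - P(reject H0 | p0, p1), in (0, 1).
    """

    p0: float
    p1: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 < self.p1 <= 1.0:
            raise ValueError(
                f"require 0 <= p0 < p1 <= 1, got p0={self.p0}, p1={self.p1}"
            )
        for name in ("alpha", "beta"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass(frozen=True)
class BlockDesign:
    """A stochastically curtailed block-design realisation.

    Parameters
    ----------
    r : int
        Final stopping boundary: H0 is rejected iff X_T - X_C > r at the
        final analysis.
    n_total : int
        Maximum total sample size N over both arms (even, divisible by 2B).
    block : int
        Participants per arm per block (B); the block size is 2B.
    theta_f : float
        Lower conditional-power threshold; interior CP below theta_f stops
        the trial with a no-go decision.
    theta_e : float
        Upper conditional-power threshold; interior CP above theta_e stops
        the trial with a go decision.
    context : DesignContext
        Anticipated rates and error constraints the design was built for.

    Setting ``theta_f=0, theta_e=1`` disables stochastic curtailment and
    leaves only non-stochastic (certain-outcome) curtailment.
    """

    r: int
    n_total: int
    block: int
    theta_f: float
    theta_e: float
    context: DesignContext

    def __post_init__(self) -> None:
        if self.n_total <= 0 or self.n_total % 2:
            raise ValueError(f"n_total must be a positive even integer, got {self.n_total}")
        if self.block < 1 or (self.n_total // 2) % self.block:
            raise ValueError(
                f"block must divide n_total/2: block={self.block}, n_total={self.n_total}"
            )
        if not 0 <= self.r <= self.n_total // 2:
            raise ValueError(f"require 0 <= r <= N/2, got r={self.r}, N={self.n_total}")
        if not 0.0 <= self.theta_f < self.theta_e <= 1.0:
            raise ValueError(
                f"require 0 <= theta_f < theta_e <= 1, got ({self.theta_f}, {self.theta_e})"
            )

    @property
    def n_arm(self) -> int:
        """Maximum participants per arm, N/2."""
        return self.n_total // 2

    @property
    def n_blocks(self) -> int:
        """Number of blocks, N / 2B."""
        return self.n_arm // self.block

    @property
    def block_ends(self) -> range:
        """Per-arm sample sizes at which the trial is inspected."""
        return range(self.block, self.n_arm + 1, self.block)

    @property
    def go_bound(self) -> int:
        """Success count S guaranteeing rejection: S >= N/2 + r + 1."""
        return self.n_arm + self.r + 1

    def without_sc(self) -> "BlockDesign":
        """The same (r, N, B) design with stochastic curtailment disabled."""
        return replace(self, theta_f=0.0, theta_e=1.0)
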