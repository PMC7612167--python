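"""Independent brute-force oracles used by the unit tests.

Everything here enumerates outcome paths directly (no dynamic
programming, no convolutions) so that it cannot share a bug with the
package's recursive implementations.
"""

from __future__ import annotations

from scipy.stats import binom


def joint_block_probs(block: int, pc: float, pt: float):
    """All (xt, xc) block outcomes with their probabilities."""
    out = []
    for xt in range(block + 1):
        for xc in range(block + 1):
            out.append((xt, xc, binom.pmf(xt, block, pt) * binom.pmf(xc, block, pc)))
    return out


def cp_by_enumeration(design, s: int, m: int) -> float:
    """P(final success count >= go bound | S=s after m per arm), walking
    every remaining block outcome explicitly (NSC: no early stopping)."""
    if m == design.n_arm:
        return 1.0 if s >= design.go_bound else 0.0
    total = 0.0
    for xt, xc, p in joint_block_probs(design.block, design.context.p0, design.context.p1):
        nxt = s + xt + design.block - xc
        total += p * cp_by_enumeration(design, nxt, m + design.block)
    return total


def walk_all_sequences(table, pc: float, pt: float):
    """Enumerate every complete block-outcome sequence and record where
    the trial stops according to the table's decisions.

    Returns (reject_prob, ess, first_passage) where first_passage maps
    (m, S) to the probability of first reaching that state.
    """
    from scblock.conditional_power import CONTINUE, GO

    design = table.design
    outcomes = joint_block_probs(design.block, pc, pt)
    ends = list(design.block_ends)
    reject = ess = 0.0
    first: dict[tuple[int, int], float] = {}

    def walk(idx: int, s: int, prob: float) -> None:
        nonlocal reject, ess
        m = ends[idx]
        first[(m, s)] = first.get((m, s), 0.0) + prob
        decision = table.decisions(m)[s]
        if decision != CONTINUE or m == design.n_arm:
            if decision == GO:
                reject += prob
            ess += 2 * m * prob
            return
        for xt, xc, p in outcomes:
            walk(idx + 1, s + xt + design.block - xc, prob * p)

    for xt, xc, p in outcomes:
        walk(0, xt + design.block - xc, p)
    return reject, ess, first


def carsten_by_enumeration(design, pc: float, pt: float):
    """Recursively walk every success/failure pair prefix of a Carsten design."""
    ps = pt * (1.0 - pc)
    n, n1, r, r1 = design.n_arm, design.n1, design.r, design.r1
    reject = en = 0.0

    def walk(j: int, s: int, prob: float) -> None:
        nonlocal reject, en
        for y, p_y in ((1, ps), (0, 1.0 - ps)):
            p = prob * p_y
            if p == 0.0:
                continue
            s2, j2 = s + y, j + 1
            if s2 >= r:
                reject += p
                en += 2 * j2 * p
            elif s2 + (n - j2) < r or (j2 <= n1 and s2 + (n1 - j2) < r1):
                en += 2 * j2 * p
            elif j2 == n:
                en += 2 * n * p
            else:
                walk(j2, s2, p)

    walk(0, 0, 1.0)
    return reject, en


def chen_by_enumeration(design, pc: float, pt: float):
    """Recursively walk every per-patient success prefix of a Chen design."""
    n, r, r1 = design.n_arm, design.r, design.r1
    total, interim_at = 2 * n, 2 * design.n1
    gb, req1 = n + r, design.n1 + r1
    reject = en = 0.0

    def walk(k: int, s: int, prob: float) -> None:
        nonlocal reject, en
        k2 = k + 1
        p_succ = pt if k2 % 2 == 1 else 1.0 - pc  # T, C, T, C, ...
        for y, p_y in ((1, p_succ), (0, 1.0 - p_succ)):
            p = prob * p_y
            if p == 0.0:
                continue
            s2 = s + y
            if s2 >= gb:
                reject += p
                en += k2 * p
            elif (s2 + (total - k2) < gb
                  or (k2 <= interim_at and s2 + (interim_at - k2) < req1)):
                en += k2 * p
            elif k2 == total:
                en += total * p
            else:
                walk(k2, s2, p)

    walk(0, 0, 1.0)
    return reject, en
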