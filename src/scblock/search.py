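"""Admissible-design search for the curtailed block design.

For each (r, N) on the grid the candidate conditional-power thresholds
are the interior CP values of that design's NSC table (pooled over all
block ends): operating characteristics only change when a threshold
crosses an attainable CP value, so nothing is lost by searching the
attainable grid instead of a uniform one.  Every candidate (theta_f,
theta_e) pair is evaluated exactly; feasible realisations (alpha* <=
alpha, power >= 1-beta) are kept and Pareto-filtered on
(ESS(p0,p0), ESS(p0,p1), N).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .conditional_power import cp_table_nsc, cp_table_sc
from .design import BlockDesign, DesignContext
from .operating import OperatingChars, operating_characteristics

logger = logging.getLogger(__name__)

#: labels attached to selected members of an admissible set
TAGS = ("p0-optimal", "p1-optimal", "p0-minimax", "p1-minimax")


@dataclass(frozen=True)
class SearchConfig:
    """Search-space bounds.

    Defaults mirror the reference search settings: thresholds bounded by
    theta_f <= p1 (no futility stop while CP exceeds the single-patient
    response probability on treatment) and theta_e >= 0.7, and at most
    10^6 threshold pairs per (r, N) (the attainable-value grid is halved
    until the pair count fits).
    """

    block: int
    max_n: int
    r_values: tuple[int, ...] | None = None  # default {0, ..., ceil(N*p1)} per N
    n_values: tuple[int, ...] | None = None  # default {2B, 4B, ..., max_n}
    theta_f_max: float | None = None  # default p1
    theta_e_min: float = 0.7
    max_combos: int = 10**6

    def __post_init__(self) -> None:
        if self.block < 1:
            raise ValueError("block must be >= 1")
        if self.max_n < 2 * self.block or self.max_n % 2:
            raise ValueError("max_n must be even and >= 2*block")
        if self.max_combos < 1:
            raise ValueError("max_combos must be >= 1")
        if not 0.0 < self.theta_e_min <= 1.0:
            raise ValueError("theta_e_min must lie in (0, 1]")


@dataclass
class AdmissibleSet:
    """Feasible, non-dominated design realisations with optimality tags."""

    context: DesignContext
    designs: list[tuple[BlockDesign, OperatingChars]] = field(default_factory=list)
    labels: dict[str, int] = field(default_factory=dict)  # tag -> index into designs

    def __len__(self) -> int:
        return len(self.designs)

    def tagged(self, tag: str) -> tuple[BlockDesign, OperatingChars]:
        return self.designs[self.labels[tag]]

    def criteria(self) -> np.ndarray:
        """(ESS00, ESS01, N) rows for every member."""
        return np.array(
            [[c.ess_null, c.ess_alt, c.max_n] for _, c in self.designs], dtype=float
        )


def pareto_mask(criteria: np.ndarray) -> np.ndarray:
    """Boolean mask of non-dominated rows (smaller is better everywhere).

    A row is dominated when some other row is <= in every criterion and
    strictly < in at least one; exact ties on all criteria are all kept.
    The filter is idempotent and independent of row order.
    """
    c = np.asarray(criteria, dtype=float)
    n = len(c)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        better_eq = (c <= c[i]).all(axis=1)
        strictly = (c < c[i]).any(axis=1)
        if np.any(better_eq & strictly):
            keep[i] = False
    return keep


def _pair_count(values: np.ndarray, f_max: float, e_min: float) -> int:
    f_cand = values[values <= f_max]
    e_all = values[values >= e_min]
    if f_cand.size == 0 or e_all.size == 0:
        return 0
    # for each f, number of e-candidates strictly greater than f
    idx = np.searchsorted(e_all, f_cand, side="right")
    return int((e_all.size - idx).sum())


def candidate_thresholds(
    nsc_table, cfg: SearchConfig, p1: float | None = None
) -> list[tuple[float, float]]:
    """Candidate (theta_f, theta_e) pairs for one (r, N, B).

    Candidates are the unique interior CP values of the NSC table, filtered
    by theta_f <= theta_f_max, theta_e >= theta_e_min and theta_f < theta_e.
    If the pair count exceeds ``cfg.max_combos``, the sorted value list is
    thinned by deleting every other value (keeping indices 0, 2, 4, ...)
    until the count fits.
    """
    f_max = cfg.theta_f_max
    if f_max is None:
        if p1 is None:
            p1 = nsc_table.design.context.p1
        f_max = p1
    values = nsc_table.interior_values()
    while _pair_count(values, f_max, cfg.theta_e_min) > cfg.max_combos:
        values = values[::2]
    f_cand = values[values <= f_max]
    e_all = values[values >= cfg.theta_e_min]
    return [(float(f), float(e)) for f in f_cand for e in e_all if f < e]


def _evaluate_lean(
    n_arm: int,
    block: int,
    gb: int,
    theta_f: float,
    theta_e: float,
    pmf_alt: np.ndarray,
    pmf_null: np.ndarray,
) -> tuple[float, float, float, float]:
    """(alpha*, power, ESS00, ESS01) without the bookkeeping of the full
    evaluator; used only inside the threshold search loop."""
    # backward pass at the anticipated rates
    cp: dict[int, np.ndarray] = {n_arm: (np.arange(2 * n_arm + 1) >= gb).astype(float)}
    rev = pmf_alt[::-1]
    for m in range(n_arm - block, 0, -block):
        s = np.arange(2 * m + 1)
        d = np.convolve(cp[m + block], rev, mode="valid")
        go = s >= gb
        nogo = s + 2 * (n_arm - m) < gb
        interior = ~go & ~nogo
        d[go] = 1.0
        d[nogo] = 0.0
        d[interior & (d < theta_f)] = 0.0
        d[interior & (d > theta_e)] = 1.0
        cp[m] = d
    out = []
    for pmf in (pmf_null, pmf_alt):
        reach = pmf
        reject = ess = 0.0
        for m in range(block, n_arm + 1, block):
            v = cp[m]
            stop = (v == 0.0) | (v == 1.0)
            p_stop = reach[stop]
            ess += 2 * m * p_stop.sum()
            reject += reach[v == 1.0].sum()
            if m < n_arm:
                nxt = np.where(stop, 0.0, reach)
                reach = np.convolve(nxt, pmf)
        out.append((float(reject), float(ess)))
    (alpha, ess00), (power, ess01) = out
    return alpha, power, ess00, ess01


def _evaluate_lean_batch(
    n_arm: int,
    block: int,
    gb: int,
    tfs: np.ndarray,
    tes: np.ndarray,
    pmf_alt: np.ndarray,
    pmf_null: np.ndarray,
) -> np.ndarray:
    """Vectorised form of :func:`_evaluate_lean` over many threshold pairs.

    Returns an array of shape (n_pairs, 4) with columns
    (alpha*, power, ESS00, ESS01).
    """
    n_pairs = len(tfs)
    width_final = 2 * n_arm + 1
    cp = np.broadcast_to(
        (np.arange(width_final) >= gb).astype(float), (n_pairs, width_final)
    ).copy()
    ms = list(range(block, n_arm + 1, block))
    decisions: dict[int, np.ndarray] = {n_arm: None}  # filled below
    dec_final = np.where(np.arange(width_final) >= gb, np.int8(1), np.int8(-1))
    decisions[n_arm] = np.broadcast_to(dec_final, (n_pairs, width_final))
    tf_col = tfs[:, None]
    te_col = tes[:, None]
    for m in ms[-2::-1]:
        width = 2 * m + 1
        d = np.zeros((n_pairs, width))
        for i in range(2 * block + 1):
            d += pmf_alt[i] * cp[:, i : i + width]
        s = np.arange(width)
        go = s >= gb
        nogo = s + 2 * (n_arm - m) < gb
        interior = ~(go | nogo)
        d[:, go] = 1.0
        d[:, nogo] = 0.0
        di = d[:, interior]
        di[di < tf_col] = 0.0
        di[di > te_col] = 1.0
        d[:, interior] = di
        dec = np.zeros((n_pairs, width), dtype=np.int8)
        dec[d == 1.0] = 1
        dec[d == 0.0] = -1
        decisions[m] = dec
        cp = d
    out = np.empty((n_pairs, 4))
    for j, pmf in enumerate((pmf_null, pmf_alt)):
        reach = np.tile(pmf, (n_pairs, 1))
        reject = np.zeros(n_pairs)
        ess = np.zeros(n_pairs)
        for m in ms:
            dec = decisions[m]
            stop = dec != 0
            ess += 2 * m * np.where(stop, reach, 0.0).sum(axis=1)
            reject += np.where(dec == 1, reach, 0.0).sum(axis=1)
            if m < n_arm:
                cont = np.where(stop, 0.0, reach)
                width = reach.shape[1]
                nxt = np.zeros((n_pairs, width + 2 * block))
                for i in range(2 * block + 1):
                    nxt[:, i : i + width] += pmf[i] * cont
                reach = nxt
        out[:, j] = reject
        out[:, 2 + j] = ess
    return out


def _n_grid(cfg: SearchConfig) -> list[int]:
    if cfg.n_values is not None:
        for n in cfg.n_values:
            if n % 2 or (n // 2) % cfg.block:
                raise ValueError(f"N={n} incompatible with block={cfg.block}")
        return sorted(cfg.n_values)
    return list(range(2 * cfg.block, cfg.max_n + 1, 2 * cfg.block))


def find_admissible(context: DesignContext, cfg: SearchConfig) -> AdmissibleSet:
    """Enumerate, evaluate and Pareto-filter curtailed block designs.

    Returns the admissible set with p0-/p1-optimal and p0-/p1-minimax
    members tagged.  An empty feasible region yields an empty set (with a
    logged warning), not an error.
    """
    from .conditional_power import block_success_pmf

    feasible: list[tuple[BlockDesign, tuple[float, float, float, float]]] = []
    f_max = cfg.theta_f_max if cfg.theta_f_max is not None else context.p1
    for n in _n_grid(cfg):
        n_arm = n // 2
        pmf_alt = block_success_pmf(cfg.block, context.p0, context.p1).probs
        pmf_null = block_success_pmf(cfg.block, context.p0, context.p0).probs
        r_values = (
            cfg.r_values
            if cfg.r_values is not None
            else range(0, math.ceil(n * context.p1) + 1)
        )
        for r in r_values:
            if r > n_arm:
                continue
            gb = n_arm + r + 1
            # cheap bounds: max power over the grid is attained with no
            # futility stopping and maximal go-curtailment; min alpha with
            # maximal futility stopping and no go-curtailment.
            _, hi_power, _, _ = _evaluate_lean(
                n_arm, cfg.block, gb, 0.0, cfg.theta_e_min - 1e-12,
                pmf_alt, pmf_null)
            if hi_power < 1.0 - context.beta:
                continue
            lo_alpha, _, _, _ = _evaluate_lean(
                n_arm, cfg.block, gb, f_max, 1.0, pmf_alt, pmf_null)
            if lo_alpha > context.alpha:
                continue
            base = BlockDesign(r=r, n_total=n, block=cfg.block,
                               theta_f=0.0, theta_e=1.0, context=context)
            pairs = candidate_thresholds(cp_table_nsc(base), cfg, p1=context.p1)
            logger.info("search r=%d N=%d: %d threshold pairs", r, n, len(pairs))
            if not pairs:
                continue
            tfs = np.array([p[0] for p in pairs])
            tes = np.array([p[1] for p in pairs])
            chunk = max(1, 2_000_000 // (n_arm * n_arm + 1))
            for lo in range(0, len(pairs), chunk):
                sl = slice(lo, lo + chunk)
                res = _evaluate_lean_batch(
                    n_arm, cfg.block, gb, tfs[sl], tes[sl], pmf_alt, pmf_null)
                ok = np.flatnonzero(
                    (res[:, 0] <= context.alpha)
                    & (res[:, 1] >= 1.0 - context.beta))
                if ok.size == 0:
                    continue
                # thin within the chunk before accumulating: members
                # dominated here are dominated globally too (N is shared),
                # so discarding them cannot change the final Pareto set.
                crit = np.column_stack(
                    [res[ok, 2], res[ok, 3], np.full(ok.size, float(n))])
                for i in ok[pareto_mask(crit)]:
                    a, pw, e00, e01 = res[i]
                    d = BlockDesign(r=r, n_total=n, block=cfg.block,
                                    theta_f=float(tfs[sl][i]),
                                    theta_e=float(tes[sl][i]),
                                    context=context)
                    feasible.append((d, (a, pw, e00, e01)))
            if len(feasible) > 10_000:
                crit = np.array(
                    [[e00, e01, d.n_total]
                     for d, (_, _, e00, e01) in feasible])
                keep = pareto_mask(crit)
                feasible = [f for f, k in zip(feasible, keep) if k]
    if not feasible:
        logger.warning("no feasible design found for %s with %s", context, cfg)
        return AdmissibleSet(context=context)
    crit = np.array([[e00, e01, d.n_total] for d, (_, _, e00, e01) in feasible])
    keep = pareto_mask(crit)
    members = [
        (d, operating_characteristics(d))
        for (d, _), k in zip(feasible, keep) if k
    ]
    out = AdmissibleSet(context=context, designs=members)
    out.labels = label_admissible(members)
    return out


def label_admissible(
    members: list[tuple[BlockDesign, OperatingChars]]
) -> dict[str, int]:
    """Tag p0-/p1-optimal and p0-/p1-minimax members.

    Ties on the target criterion prefer smaller N, then smaller ESS under
    the other rate pair, then larger theta_e.
    """

    def key(target: str):
        def k(item):
            d, c = members[item]
            primary = c.ess_null if target == "p0" else c.ess_alt
            other = c.ess_alt if target == "p0" else c.ess_null
            return (primary, d.n_total, other, -d.theta_e)
        return k

    idx = range(len(members))
    labels = {
        "p0-optimal": min(idx, key=key("p0")),
        "p1-optimal": min(idx, key=key("p1")),
    }
    min_n = min(d.n_total for d, _ in members)
    small = [i for i in idx if members[i][0].n_total == min_n]
    labels["p0-minimax"] = min(small, key=key("p0"))
    labels["p1-minimax"] = min(small, key=key("p1"))
    return labels
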