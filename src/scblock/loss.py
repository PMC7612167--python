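"""Loss-score comparison of design approaches over the weight simplex.

The loss of a design with characteristics (ESS(p0,p0), ESS(p0,p1), N) at
weights (w0, w1) is

    L = w0 * ESS(p0,p0) + w1 * ESS(p0,p1) + (1 - w0 - w1) * N,

with w0, w1 >= 0 and w0 + w1 <= 1.  At each weight point each approach
contributes its minimum-loss realisation; the approach attaining the
overall minimum is the omni-admissible design there.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["loss_score", "omni_admissible_map", "area_fractions"]


def _check_weights(w0: float, w1: float) -> None:
    if w0 < 0 or w1 < 0 or w0 + w1 > 1 + 1e-12:
        raise ValueError(f"weights must satisfy w0, w1 >= 0 and w0 + w1 <= 1, got ({w0}, {w1})")


def loss_score(ess00: float, ess01: float, n: float, w0: float, w1: float) -> float:
    """Weighted-sum loss of one design realisation."""
    _check_weights(w0, w1)
    return w0 * ess00 + w1 * ess01 + (1.0 - w0 - w1) * n


def omni_admissible_map(
    criteria_by_type: dict[str, np.ndarray],
    grid_step: float = 0.01,
    tie_tol: float = 1e-9,
) -> pd.DataFrame:
    """Winning design approach at every point of the weight simplex.

    Parameters
    ----------
    criteria_by_type : dict
        Maps an approach label to an (n_designs, 3) array of
        (ESS00, ESS01, N) rows — typically ``AdmissibleSet.criteria()``.
    grid_step : float
        Weight grid resolution; the grid covers {(w0, w1): w0 + w1 <= 1}.

    Returns
    -------
    DataFrame with columns (w0, w1, winner, loss_<type>...), where
    ``winner`` holds the minimum-loss approach (ties joined with '|').
    """
    if not criteria_by_type:
        raise ValueError("at least one admissible set is required")
    types = list(criteria_by_type)
    steps = int(round(1.0 / grid_step))
    rows = []
    for i in range(steps + 1):
        w0 = i * grid_step
        for j in range(steps + 1 - i):
            w1 = j * grid_step
            losses = {}
            for t in types:
                c = np.asarray(criteria_by_type[t], dtype=float)
                losses[t] = float(
                    (w0 * c[:, 0] + w1 * c[:, 1] + (1 - w0 - w1) * c[:, 2]).min()
                )
            best = min(losses.values())
            winners = [t for t in types if losses[t] <= best + tie_tol]
            rows.append((w0, w1, "|".join(winners), *[losses[t] for t in types]))
    return pd.DataFrame(rows, columns=["w0", "w1", "winner", *[f"loss_{t}" for t in types]])


def area_fractions(omni: pd.DataFrame) -> pd.Series:
    """Fraction of weight-grid points won by each approach (ties split equally)."""
    counts: dict[str, float] = {}
    for winner in omni["winner"]:
        tied = winner.split("|")
        for t in tied:
            counts[t] = counts.get(t, 0.0) + 1.0 / len(tied)
    total = float(len(omni))
    return pd.Series({t: c / total for t, c in sorted(counts.items())}, name="fraction")
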