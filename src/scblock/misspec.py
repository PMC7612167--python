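"""Rejection-probability surfaces under misspecified true response rates.

A design's boundaries are fixed at the anticipated rates (p0, p1); the
surface evaluates P(reject H0 | pC, pT) exactly over a grid of true rates,
exposing how sensitive the realised error rates are to misspecification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .comparators import TwoStageDesign
from .conditional_power import CPTable, cp_table_sc
from .design import BlockDesign
from .operating import rate_characteristics


def rejection_surface(
    design: BlockDesign | TwoStageDesign,
    p_grid: np.ndarray | list[float] | None = None,
    table: CPTable | None = None,
) -> pd.DataFrame:
    """Exact P(reject H0) at every (pC, pT) grid combination.

    Rows are indexed by pC, columns by pT (matrix layout ready for a
    heatmap export).  For a block design the conditional-power table is
    built once at the anticipated rates and the forward recursion re-run
    at each pair of true rates; comparator designs use their exact DP.
    """
    grid = np.round(np.arange(0.0, 1.0001, 0.1), 10) if p_grid is None else np.asarray(
        p_grid, dtype=float
    )
    if np.any((grid < 0) | (grid > 1)):
        raise ValueError("grid probabilities must lie in [0, 1]")
    if isinstance(design, BlockDesign):
        if table is None:
            table = cp_table_sc(design)
        def reject(pc, pt):
            return rate_characteristics(table, pc, pt).reject_prob
    else:
        def reject(pc, pt):
            return design.evaluate(pc, pt).reject_prob
    mat = np.array([[reject(pc, pt) for pt in grid] for pc in grid])
    return pd.DataFrame(mat, index=pd.Index(grid, name="pC"),
                        columns=pd.Index(grid, name="pT"))
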