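"""Climate-novelty diagnostics: MESS maps and correlation-structure shifts.

Projecting a fitted niche onto past or future climates risks extrapolating
into environments never seen during fitting.  The multivariate
environmental similarity surface (MESS) quantifies this per cell: for each
variable the projected value is scored against the reference distribution
(values at the model-fitting points) on a percentile scale, and the
aggregate map is the cell-wise minimum; negative values flag novel
climate.  A complementary diagnostic compares the Pearson correlation
matrix of the predictor layers between scenarios, revealing variable
combinations that exist in one climate but not another.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import GridSurface, PredictorStack
from .predictors import predictor_columns

__all__ = ["mess_variable", "mess_map", "MessMap", "correlation_shift"]


def mess_variable(reference: np.ndarray, p) -> np.ndarray:
    """Percentile similarity of value(s) ``p`` to a reference sample.

    With ``f`` the percentage of reference values strictly below p:

    * f = 0    -> (p - min) / (max - min) * 100   (negative below the range)
    * f <= 50  -> 2 f
    * f < 100  -> 2 (100 - f)
    * f = 100  -> (max - p) / (max - min) * 100   (negative above the range)

    Piecewise linear, maximal (100) at the reference median.
    """
    reference = np.sort(np.asarray(reference, dtype=float))
    if len(reference) == 0:
        raise ValueError("empty reference")
    lo, hi = reference[0], reference[-1]
    if hi <= lo:
        raise ValueError("constant reference (max == min)")
    p_arr = np.atleast_1d(np.asarray(p, dtype=float))
    f = 100.0 * np.searchsorted(reference, p_arr, side="left") / len(reference)
    sim = np.where(
        f == 0,
        (p_arr - lo) / (hi - lo) * 100.0,
        np.where(
            f <= 50,
            2.0 * f,
            np.where(f < 100, 2.0 * (100.0 - f), (hi - p_arr) / (hi - lo) * 100.0),
        ),
    )
    sim = np.where(np.isfinite(p_arr), sim, np.nan)
    return sim if np.ndim(p) else float(sim[0])


class MessMap:
    """Per-variable similarity rasters plus their cell-wise minimum."""

    def __init__(self, grid, variable_maps: dict[str, np.ndarray]):
        self.grid = grid
        self.variable_maps = variable_maps
        stacked = np.stack(list(variable_maps.values()))
        self.aggregate = np.min(stacked, axis=0)

    def variable_surface(self, name: str) -> GridSurface:
        return GridSurface(self.grid, self.variable_maps[name])

    def aggregate_surface(self) -> GridSurface:
        return GridSurface(self.grid, self.aggregate)

    @property
    def novel_fraction(self) -> float:
        """Fraction of (finite) cells with negative aggregate similarity."""
        finite = np.isfinite(self.aggregate)
        if not finite.any():
            return float("nan")
        return float((self.aggregate[finite] < 0).mean())


def mess_map(reference_table: pd.DataFrame, stack: PredictorStack) -> MessMap:
    """MESS of a scenario stack against the model-fitting reference values.

    ``reference_table`` holds raw (unstandardised) predictor values at the
    fitting points (presences + pseudo-absences); every reference column
    must exist in the stack.
    """
    cols = predictor_columns(reference_table)
    missing = [c for c in cols if c not in stack]
    if missing:
        raise KeyError(f"stack lacks reference predictors: {missing}")
    maps = {}
    for c in cols:
        ref = reference_table[c].to_numpy(dtype=float)
        vals = stack[c].ravel()
        maps[c] = mess_variable(ref, vals).reshape(stack.grid.shape)
    return MessMap(stack.grid, maps)


def correlation_shift(
    stack_a: PredictorStack, stack_b: PredictorStack
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations over cells for two scenario stacks.

    Returns (corr_a, corr_b, corr_a - corr_b) as named DataFrames;
    correlations use cells valid in the respective stack.
    """
    if set(stack_a.names) != set(stack_b.names):
        raise ValueError("stacks must share layer names")
    names = stack_a.names

    def corr(stack: PredictorStack) -> pd.DataFrame:
        table = stack.as_table(names)
        table = table[np.all(np.isfinite(table), axis=1)]
        sds = table.std(axis=0)
        if np.any(sds == 0):
            bad = [n for n, s in zip(names, sds) if s == 0]
            raise ValueError(f"constant layer(s): {bad}")
        return pd.DataFrame(np.corrcoef(table, rowvar=False), index=names, columns=names)

    ca, cb = corr(stack_a), corr(stack_b)
    return ca, cb, ca - cb
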