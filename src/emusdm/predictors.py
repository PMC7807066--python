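"""Predictor extraction, collinearity screening (VIF), and standardisation.

The variance inflation factor of predictor j is ``1 / (1 - R^2_j)`` where
``R^2_j`` comes from regressing predictor j on all the others (labels are
ignored).  Stepwise screening repeatedly removes the single predictor with
the largest VIF until every remaining VIF is at or below the threshold
(default 10), the usual rule of thumb for "collinearity worth worrying
about".

Standardisation parameters (per-column mean and sd) are estimated once on
the model-fitting table and re-applied verbatim to every projection stack:
a scenario's climate must be expressed in the fitted model's coordinate
system, never re-centred on itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import PredictorStack

__all__ = [
    "extract",
    "build_sample_table",
    "vif",
    "vif_stepwise",
    "VifReport",
    "scale_centre",
    "StandardizationParams",
]

LABEL_COLUMN = "label"
_NON_PREDICTOR = {LABEL_COLUMN, "weight"}


def extract(stack: PredictorStack, points: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Layer values at the cell containing each point.

    Points on nodata cells are dropped; the count of dropped points is
    returned alongside the table.  Points outside the grid extent are an
    error.
    """
    row, col = stack.grid.cell_of(
        points["lon"].to_numpy(dtype=float), points["lat"].to_numpy(dtype=float)
    )
    table = pd.DataFrame(
        {name: stack[name][row, col] for name in stack.names}, index=points.index
    )
    ok = np.all(np.isfinite(table.to_numpy()), axis=1)
    return table.loc[ok], int((~ok).sum())


def build_sample_table(
    stack: PredictorStack,
    presences: pd.DataFrame,
    pseudoabsences: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Points x predictors matrix with a binary label (1 presence, 0 PA)."""
    pres, dropped_p = extract(stack, presences)
    absn, dropped_a = extract(stack, pseudoabsences)
    pres = pres.assign(**{LABEL_COLUMN: 1})
    absn = absn.assign(**{LABEL_COLUMN: 0})
    table = pd.concat([pres, absn], ignore_index=True)
    if table[LABEL_COLUMN].nunique() < 2:
        raise ValueError("sample table must contain both classes")
    return table, {"dropped_presences": dropped_p, "dropped_pseudoabsences": dropped_a}


def predictor_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in _NON_PREDICTOR]


def _r_squared(y: np.ndarray, X: np.ndarray) -> float:
    """R^2 of y ~ X with intercept, via least squares."""
    design = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        raise ValueError("constant predictor column")
    return 1.0 - (resid**2).sum() / ss_tot


def vif(table: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor column (labels ignored)."""
    cols = predictor_columns(table)
    if len(cols) < 2:
        raise ValueError("VIF needs at least 2 predictors")
    X = table[cols].to_numpy(dtype=float)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("VIF needs more rows than predictors")
    out = {}
    for j, name in enumerate(cols):
        r2 = _r_squared(X[:, j], np.delete(X, j, axis=1))
        out[name] = np.inf if r2 >= 1.0 - 1e-15 else 1.0 / (1.0 - r2)
    return pd.Series(out)


@dataclass
class VifReport:
    steps: list[dict] = field(default_factory=list)  # {"vifs": {...}, "removed": name|None}
    removed_order: list[str] = field(default_factory=list)
    retained: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "steps": [
                {"vifs": {k: float(v) for k, v in s["vifs"].items()}, "removed": s["removed"]}
                for s in self.steps
            ],
            "removed_order": list(self.removed_order),
            "retained": list(self.retained),
        }


def vif_stepwise(table: pd.DataFrame, threshold: float = 10.0) -> VifReport:
    """Iteratively drop the max-VIF predictor while any VIF exceeds threshold.

    Ties in the maximum are broken by column order.  The retained set's
    VIFs are all <= threshold.
    """
    report = VifReport()
    cols = predictor_columns(table)
    current = table[cols + ([LABEL_COLUMN] if LABEL_COLUMN in table else [])].copy()
    while True:
        vifs = vif(current)
        worst = vifs.idxmax()  # first occurrence wins ties (column order)
        if vifs[worst] > threshold and len(predictor_columns(current)) > 2:
            report.steps.append({"vifs": vifs.to_dict(), "removed": worst})
            report.removed_order.append(worst)
            current = current.drop(columns=[worst])
        else:
            removed = None
            if vifs[worst] > threshold:  # only 2 predictors left but still collinear
                report.removed_order.append(worst)
                removed = worst
                current = current.drop(columns=[worst])
            report.steps.append({"vifs": vifs.to_dict(), "removed": removed})
            report.retained = predictor_columns(current)
            return report


@dataclass
class StandardizationParams:
    """Fitting-era per-column means and sds, re-applied to any projection."""

    means: pd.Series
    sds: pd.Series

    def apply_to_table(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for c in self.means.index:
            out[c] = (out[c] - self.means[c]) / self.sds[c]
        return out

    def apply_to_stack(self, stack: PredictorStack) -> PredictorStack:
        names = [n for n in self.means.index if n in stack]
        missing = [n for n in self.means.index if n not in stack]
        if missing:
            raise KeyError(f"stack lacks fitted predictors: {missing}")
        return PredictorStack(
            stack.grid,
            {n: (stack[n] - self.means[n]) / self.sds[n] for n in names},
        )

    def to_dict(self) -> dict:
        return {
            "means": {k: float(v) for k, v in self.means.items()},
            "sds": {k: float(v) for k, v in self.sds.items()},
        }


def scale_centre(table: pd.DataFrame) -> tuple[pd.DataFrame, StandardizationParams]:
    """Standardise every predictor column to mean 0, sd 1."""
    cols = predictor_columns(table)
    X = table[cols].to_numpy(dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    if np.any(sds == 0):
        bad = [c for c, s in zip(cols, sds) if s == 0]
        raise ValueError(f"constant predictor column(s): {bad}")
    params = StandardizationParams(pd.Series(means, index=cols), pd.Series(sds, index=cols))
    return params.apply_to_table(table), params
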