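"""Skill-gated, TSS-weighted ensembling, projection, and range change.

Candidate models enter the ensemble only if they clear all three skill
gates (TSS >= 0.7, AUC >= 0.9, Kappa >= 0.7 by default); survivors are
averaged with weights proportional to their TSS, so stronger models steer
the consensus.  Projections over scenario stacks are binarized at a max-TSS
threshold and compared cell-by-cell to give range change under two
dispersal bounds: *unlimited* (the whole projected range counts) and *no
dispersal* (only the overlap with the current range counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import max_tss_threshold
from .grids import BinaryRangeMap, GridSurface, PredictorStack
from .models import FittedModel
from .predictors import LABEL_COLUMN

__all__ = [
    "GateThresholds",
    "EmptyEnsembleError",
    "select_members",
    "EnsembleModel",
    "build_ensemble",
    "ensemble_predict",
    "uncertainty_map",
    "binarize",
    "range_change",
    "RangeChangeReport",
]


@dataclass(frozen=True)
class GateThresholds:
    tss_min: float = 0.7
    auc_min: float = 0.9
    kappa_min: float = 0.7


class EmptyEnsembleError(RuntimeError):
    """No candidate model cleared the skill gates."""


def select_members(
    models: list[FittedModel], gates: GateThresholds = GateThresholds()
) -> tuple[list[FittedModel], list[dict]]:
    """Inclusive (>=) gating on TSS, AUC and Kappa; returns survivors + report.

    The report lists every candidate with its scores, pass/fail, and the
    reasons it failed (failed gates, or a fitting error).
    """
    members: list[FittedModel] = []
    report: list[dict] = []
    for m in models:
        entry = m.metadata()
        reasons: list[str] = []
        if not m.ok:
            reasons.append(f"fit failed: {m.error}")
        else:
            s = m.scores
            if s.tss < gates.tss_min:
                reasons.append(f"TSS {s.tss:.3f} < {gates.tss_min}")
            if s.auc < gates.auc_min:
                reasons.append(f"AUC {s.auc:.3f} < {gates.auc_min}")
            if s.kappa < gates.kappa_min:
                reasons.append(f"Kappa {s.kappa:.3f} < {gates.kappa_min}")
        entry["passed"] = not reasons
        entry["exclusion_reasons"] = reasons
        report.append(entry)
        if not reasons:
            members.append(m)
    return members, report


@dataclass
class EnsembleModel:
    members: list[FittedModel]
    weights: np.ndarray
    gates: GateThresholds = field(default_factory=GateThresholds)

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise EmptyEnsembleError("ensemble has no members")
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1")

    @property
    def feature_names(self) -> list[str]:
        return self.members[0].feature_names

    def member_predictions(self, X: np.ndarray) -> np.ndarray:
        """(n_members, n_rows) member suitabilities."""
        return np.vstack([m.predict(X) for m in self.members])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.weights @ self.member_predictions(X)


def build_ensemble(
    models: list[FittedModel], gates: GateThresholds = GateThresholds()
) -> tuple[EnsembleModel, list[dict]]:
    """Gate candidates and weight survivors by TSS (normalised to sum 1)."""
    members, report = select_members(models, gates)
    if not members:
        raise EmptyEnsembleError(
            "no model passed the TSS/AUC/Kappa gates; cannot build an ensemble"
        )
    tss = np.array([m.scores.tss for m in members], dtype=float)
    weights = tss / tss.sum()
    return EnsembleModel(members=members, weights=weights, gates=gates), report


def _stack_predictions(
    ensemble: EnsembleModel, stack: PredictorStack
) -> tuple[np.ndarray, np.ndarray]:
    """Member predictions over valid stack cells: (matrix, flat valid mask)."""
    missing = [n for n in ensemble.feature_names if n not in stack]
    if missing:
        raise KeyError(f"stack lacks fitted predictors: {missing}")
    table = stack.as_table(ensemble.feature_names)
    valid = np.all(np.isfinite(table), axis=1)
    preds = ensemble.member_predictions(table[valid])
    return preds, valid


def ensemble_predict(ensemble: EnsembleModel, stack: PredictorStack) -> GridSurface:
    """TSS-weighted mean suitability per cell (NaN on nodata cells).

    The stack must already be standardised with the fitting-era parameters.
    """
    preds, valid = _stack_predictions(ensemble, stack)
    out = np.full(stack.grid.n_cells, np.nan)
    out[valid] = ensemble.weights @ preds
    return GridSurface(stack.grid, out.reshape(stack.grid.shape))


def uncertainty_map(ensemble: EnsembleModel, stack: PredictorStack) -> GridSurface:
    """Cell-wise coefficient of variation (sample sd / mean) across members."""
    if len(ensemble.members) < 2:
        raise ValueError("coefficient of variation needs >= 2 members")
    preds, valid = _stack_predictions(ensemble, stack)
    mean = preds.mean(axis=0)
    sd = preds.std(axis=0, ddof=1)
    cv = np.where(mean == 0, 0.0, sd / np.where(mean == 0, 1.0, mean))
    out = np.full(stack.grid.n_cells, np.nan)
    out[valid] = cv
    return GridSurface(stack.grid, out.reshape(stack.grid.shape))


def ensemble_threshold(ensemble: EnsembleModel, table: pd.DataFrame) -> float:
    """Max-TSS binarization threshold from the ensemble's own predictions."""
    X = table[ensemble.feature_names].to_numpy(dtype=float)
    y = table[LABEL_COLUMN].to_numpy(dtype=int)
    threshold, _ = max_tss_threshold(ensemble.predict(X), y)
    return threshold


def binarize(surface: GridSurface, threshold: float, scenario: str = "") -> BinaryRangeMap:
    """Presence where suitability >= threshold (NaN cells are absent)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    vals = surface.values
    present = np.where(np.isfinite(vals), vals >= threshold, False)
    return BinaryRangeMap(surface.grid, present, threshold, scenario)


@dataclass
class RangeChangeReport:
    cells_current: int
    cells_other: int
    cells_overlap: int
    pct_change_unlimited: float
    pct_change_no_dispersal: float
    transitions: np.ndarray  # 0 absent-both, 1 stable, 2 gain, 3 loss
    scenario: str = ""

    TRANSITION_CODES = {0: "absent", 1: "stable", 2: "gain", 3: "loss"}

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "cells_current": self.cells_current,
            "cells_other": self.cells_other,
            "cells_overlap": self.cells_overlap,
            "pct_change_unlimited": float(self.pct_change_unlimited),
            "pct_change_no_dispersal": float(self.pct_change_no_dispersal),
        }

    def summary(self) -> str:
        return (
            f"range change ({self.scenario or 'scenario'} vs current): "
            f"{self.cells_current} -> {self.cells_other} cells "
            f"(overlap {self.cells_overlap}); "
            f"{self.pct_change_unlimited:+.2f}% with unlimited dispersal, "
            f"{self.pct_change_no_dispersal:+.2f}% with no dispersal"
        )


def range_change(current: BinaryRangeMap, other: BinaryRangeMap) -> RangeChangeReport:
    """Cell-count range change between two binary maps, both dispersal bounds.

    Unlimited dispersal treats the whole projected range as occupied:
    ``(cells_other - cells_current) / cells_current * 100``.  No dispersal
    keeps only the overlap: ``(overlap - cells_current) / cells_current *
    100`` (always <= the unlimited figure).
    """
    current.grid.require_same(other.grid, "range maps")
    n_cur = current.n_present
    if n_cur == 0:
        raise ValueError("current range is empty; percentage change undefined")
    n_oth = other.n_present
    overlap = int(np.sum(current.present & other.present))
    trans = np.zeros(current.grid.shape, dtype=np.int8)
    trans[current.present & other.present] = 1
    trans[~current.present & other.present] = 2
    trans[current.present & ~other.present] = 3
    return RangeChangeReport(
        cells_current=n_cur,
        cells_other=n_oth,
        cells_overlap=overlap,
        pct_change_unlimited=(n_oth - n_cur) / n_cur * 100.0,
        pct_change_no_dispersal=(overlap - n_cur) / n_cur * 100.0,
        transitions=trans,
        scenario=other.scenario,
    )
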