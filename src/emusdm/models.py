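"""Multi-algorithm fitting, holdout evaluation, permutation importance.

The candidate pool is ``n_repeats`` independent 70/30 calibration/holdout
splits x every algorithm in the roster (defaults: 6 repeats x 9 algorithms
= 54 candidate models).  Each model is scored on its own holdout with AUC,
TSS and Kappa (the latter two at the model's max-TSS threshold).  Variable
importance is permutational: one minus the Pearson correlation between
predictions on the intact table and on the table with one column shuffled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import EvaluationScores, score_predictions
from .learners import DEFAULT_ROSTER, SdmLearner, make_learner
from .predictors import LABEL_COLUMN, predictor_columns

__all__ = ["FittedModel", "fit_all", "permutation_importance"]


@dataclass
class FittedModel:
    algorithm: str
    repeat: int
    learner: SdmLearner | None
    feature_names: list[str]
    calib_idx: np.ndarray
    holdout_idx: np.ndarray
    scores: EvaluationScores | None
    seed: int
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None and self.scores is not None

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.learner is None:
            raise RuntimeError(f"model {self.algorithm}#{self.repeat} failed to fit")
        return np.clip(self.learner.predict_suitability(np.asarray(X, dtype=float)), 0.0, 1.0)

    def metadata(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "repeat": self.repeat,
            "seed": self.seed,
            "n_calibration": int(len(self.calib_idx)),
            "n_holdout": int(len(self.holdout_idx)),
            "scores": self.scores.to_dict() if self.scores else None,
            "error": self.error,
        }


def _stratified_split(
    y: np.ndarray, calib_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random split so both classes appear on both sides."""
    calib, holdout = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls} has fewer than 2 rows")
        idx = rng.permutation(idx)
        n_cal = int(round(calib_fraction * len(idx)))
        n_cal = min(max(n_cal, 1), len(idx) - 1)
        calib.append(idx[:n_cal])
        holdout.append(idx[n_cal:])
    return np.sort(np.concatenate(calib)), np.sort(np.concatenate(holdout))


def fit_all(
    table: pd.DataFrame,
    roster: list[str] | None = None,
    n_repeats: int = 6,
    calib_fraction: float = 0.7,
    seed: int = 0,
) -> list[FittedModel]:
    """Fit every roster algorithm on each of ``n_repeats`` random splits.

    Splits and learner seeds derive deterministically from ``seed``; a
    learner that raises is recorded with its error, not fatal.
    """
    if not 0.0 < calib_fraction < 1.0:
        raise ValueError("calib_fraction must be in (0, 1)")
    roster = list(DEFAULT_ROSTER) if roster is None else list(roster)
    cols = predictor_columns(table)
    X = table[cols].to_numpy(dtype=float)
    y = table[LABEL_COLUMN].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("sample table must contain both classes")
    rng = np.random.default_rng(seed)
    models: list[FittedModel] = []
    for rep in range(n_repeats):
        calib_idx, holdout_idx = _stratified_split(y, calib_fraction, rng)
        for algorithm in roster:
            learner_seed = int(rng.integers(2**31))
            learner = None
            scores = None
            error = None
            try:
                learner = make_learner(algorithm, seed=learner_seed)
                learner.fit(X[calib_idx], y[calib_idx])
                preds = np.clip(
                    learner.predict_suitability(X[holdout_idx]), 0.0, 1.0
                )
                scores = score_predictions(preds, y[holdout_idx])
            except Exception as exc:  # recorded, not fatal
                error = f"{type(exc).__name__}: {exc}"
            models.append(
                FittedModel(
                    algorithm=algorithm,
                    repeat=rep,
                    learner=learner if error is None else None,
                    feature_names=cols,
                    calib_idx=calib_idx,
                    holdout_idx=holdout_idx,
                    scores=scores,
                    seed=learner_seed,
                    error=error,
                )
            )
    return models


def permutation_importance(
    model: FittedModel,
    table: pd.DataFrame,
    n_shuffles: int = 3,
    seed: int = 0,
) -> pd.Series:
    """Importance of each predictor: 1 - corr(original, column-shuffled).

    Averaged over ``n_shuffles`` shuffles and clipped to [0, 1].  A model
    whose predictions are constant gets all-zero importances (degenerate,
    there is nothing to correlate against).
    """
    cols = model.feature_names
    X = table[cols].to_numpy(dtype=float)
    base = model.predict(X)
    rng = np.random.default_rng(seed)
    out = {}
    if np.std(base) == 0:
        return pd.Series({c: 0.0 for c in cols})
    for j, c in enumerate(cols):
        vals = []
        for _ in range(n_shuffles):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            pred = model.predict(Xp)
            if np.std(pred) == 0:
                vals.append(1.0)  # shuffling destroyed all signal
                continue
            r = np.corrcoef(base, pred)[0, 1]
            vals.append(1.0 - r)
        out[c] = float(np.clip(np.mean(vals), 0.0, 1.0))
    return pd.Series(out)
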