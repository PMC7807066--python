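"""The suitability-model roster.

Nine registered algorithms mirror the usual consensus-modelling line-up for
presence/pseudo-absence data: a climate-envelope model (BIOCLIM), logistic
GLM with quadratic terms, a smooth additive logistic model (spline basis),
a single classification tree, random forest, gradient-boosted trees, a
one-hidden-layer neural network, shrinkage discriminant analysis, and an
adaptive regression-splines learner (forward hinge-basis selection).  A
tenth slot accepts any user-registered learner.

Every learner exposes ``fit(X, y)`` and ``predict_suitability(X)`` with
outputs in [0, 1], and is deterministic given its seed.  Inputs are assumed
standardised (mean 0 / sd 1 per column) by the predictors stage.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import SplineTransformer
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "SdmLearner",
    "BioclimLearner",
    "bioclim_score",
    "HingeSplineLearner",
    "NoiseLearner",
    "make_learner",
    "register_learner",
    "DEFAULT_ROSTER",
    "LEARNER_FACTORIES",
]


class SdmLearner:
    """Base class: binary classifier emitting habitat suitability in [0, 1]."""

    algorithm_id: str = "base"

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SdmLearner":
        raise NotImplementedError

    def predict_suitability(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# BIOCLIM climate envelope
# ---------------------------------------------------------------------------

def bioclim_score(presence_env: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Percentile-envelope suitability of rows ``x`` given presence rows.

    Per variable, ``p`` is the fraction of presence values <= x; the
    per-variable score is ``2 * min(p, 1 - p)`` (1 at the presence median,
    falling linearly to 0 at the envelope edges) and 0 outside the presence
    min-max; the overall score is the minimum over variables.
    """
    presence_env = np.asarray(presence_env, dtype=float)
    if presence_env.ndim != 2 or len(presence_env) < 5:
        raise ValueError("BIOCLIM needs >= 5 presence rows")
    X = np.atleast_2d(np.asarray(x, dtype=float))
    n = len(presence_env)
    scores = np.ones(len(X))
    for j in range(presence_env.shape[1]):
        col = np.sort(presence_env[:, j])
        p = np.searchsorted(col, X[:, j], side="right") / n
        var_score = 2.0 * np.minimum(p, 1.0 - p)
        inside = (X[:, j] >= col[0]) & (X[:, j] <= col[-1])
        var_score = np.where(inside, var_score, 0.0)
        scores = np.minimum(scores, var_score)
    return scores


class BioclimLearner(SdmLearner):
    algorithm_id = "bioclim"

    def __init__(self, seed: int = 0):
        self.presence_env_: np.ndarray | None = None

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.presence_env_ = X[y == 1]
        if len(self.presence_env_) < 5:
            raise ValueError("BIOCLIM needs >= 5 presence rows")
        return self

    def predict_suitability(self, X):
        return bioclim_score(self.presence_env_, X)


# ---------------------------------------------------------------------------
# Adaptive regression splines (forward hinge-basis selection)
# ---------------------------------------------------------------------------

class HingeSplineLearner(SdmLearner):
    """MARS-style additive model: greedy forward selection of hinge pairs.

    Candidate knots sit at per-variable quantiles; at each step the hinge
    pair max(x - k, 0) / max(k - x, 0) that most reduces the residual sum of
    squares joins the basis, until the relative improvement stalls or the
    term budget is reached.  Predictions are least-squares fits on the 0/1
    labels, clipped to [0, 1].
    """

    algorithm_id = "mars"

    def __init__(self, seed: int = 0, max_terms: int = 15, n_knots: int = 8, rel_tol: float = 1e-4):
        self.max_terms = max_terms
        self.n_knots = n_knots
        self.rel_tol = rel_tol
        self.terms_: list[tuple[int, float, int]] = []  # (var, knot, sign)
        self.beta_: np.ndarray | None = None

    @staticmethod
    def _hinge(X: np.ndarray, var: int, knot: float, sign: int) -> np.ndarray:
        d = X[:, var] - knot
        return np.maximum(sign * d, 0.0)

    def _design(self, X: np.ndarray) -> np.ndarray:
        cols = [np.ones(len(X))]
        cols += [self._hinge(X, v, k, s) for v, k, s in self.terms_]
        return np.column_stack(cols)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        qs = np.linspace(0.1, 0.9, self.n_knots)
        candidates = [
            (v, float(k))
            for v in range(X.shape[1])
            for k in np.unique(np.quantile(X[:, v], qs))
        ]
        self.terms_ = []
        design = self._design(X)
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        sse = float(((y - design @ beta) ** 2).sum())
        used: set[tuple[int, float]] = set()
        while len(self.terms_) < self.max_terms:
            best = None
            for v, k in candidates:
                if (v, k) in used:
                    continue
                trial = np.column_stack(
                    [design, self._hinge(X, v, k, 1), self._hinge(X, v, k, -1)]
                )
                b, *_ = np.linalg.lstsq(trial, y, rcond=None)
                s = float(((y - trial @ b) ** 2).sum())
                if best is None or s < best[0]:
                    best = (s, v, k, trial, b)
            if best is None or best[0] > sse * (1.0 - self.rel_tol):
                break
            sse, v, k, design, beta = best[0], best[1], best[2], best[3], best[4]
            used.add((v, k))
            self.terms_ += [(v, k, 1), (v, k, -1)]
        self.beta_ = beta
        return self

    def predict_suitability(self, X):
        X = np.asarray(X, dtype=float)
        return np.clip(self._design(X) @ self.beta_, 0.0, 1.0)


# ---------------------------------------------------------------------------
# scikit-learn backed roster members
# ---------------------------------------------------------------------------

class _SkProbLearner(SdmLearner):
    """Wraps an sklearn classifier; suitability = P(class 1)."""

    def __init__(self, algorithm_id: str, estimator_factory: Callable, seed: int = 0, quadratic: bool = False):
        self.algorithm_id = algorithm_id
        self._factory = estimator_factory
        self.seed = seed
        self.quadratic = quadratic
        self.estimator_ = None

    def _features(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.column_stack([X, X**2]) if self.quadratic else X

    def fit(self, X, y):
        self.estimator_ = self._factory(self.seed)
        self.estimator_.fit(self._features(X), np.asarray(y).astype(int))
        return self

    def predict_suitability(self, X):
        proba = self.estimator_.predict_proba(self._features(X))
        class_index = list(self.estimator_.classes_).index(1)
        return np.clip(proba[:, class_index], 0.0, 1.0)


class NoiseLearner(SdmLearner):
    """Pure-noise control: seeded uniform scores, independent of the data.

    Useful for verifying that the ensemble's skill gates reject a learner
    with no predictive value.
    """

    algorithm_id = "noise"

    def __init__(self, seed: int = 0):
        self.seed = seed

    def fit(self, X, y):
        return self

    def predict_suitability(self, X):
        # Deterministic per (seed, row count): repeated calls agree.
        return np.random.default_rng(self.seed).uniform(size=len(np.atleast_2d(X)))


def _glm(seed):
    return LogisticRegression(C=np.inf, max_iter=2000)


def _gam(seed):
    return make_pipeline(
        SplineTransformer(n_knots=5, degree=3),
        LogisticRegression(C=10.0, max_iter=2000),
    )


def _cart(seed):
    return DecisionTreeClassifier(min_samples_leaf=10, random_state=seed)


def _rf(seed):
    return RandomForestClassifier(
        n_estimators=200, min_samples_leaf=2, random_state=seed, n_jobs=1
    )


def _gbm(seed):
    return GradientBoostingClassifier(random_state=seed)


def _ann(seed):
    return MLPClassifier(
        hidden_layer_sizes=(8,), max_iter=500, random_state=seed, alpha=1e-3
    )


def _fda(seed):
    return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")


LEARNER_FACTORIES: dict[str, Callable[[int], SdmLearner]] = {
    "bioclim": lambda seed: BioclimLearner(seed),
    "glm": lambda seed: _SkProbLearner("glm", _glm, seed, quadratic=True),
    "gam": lambda seed: _SkProbLearner("gam", _gam, seed),
    "cart": lambda seed: _SkProbLearner("cart", _cart, seed),
    "rf": lambda seed: _SkProbLearner("rf", _rf, seed),
    "gbm": lambda seed: _SkProbLearner("gbm", _gbm, seed),
    "ann": lambda seed: _SkProbLearner("ann", _ann, seed),
    "fda": lambda seed: _SkProbLearner("fda", _fda, seed),
    "mars": lambda seed: HingeSplineLearner(seed),
    "noise": lambda seed: NoiseLearner(seed),
}

DEFAULT_ROSTER = ["bioclim", "glm", "gam", "cart", "rf", "gbm", "ann", "fda", "mars"]


def register_learner(algorithm_id: str, factory: Callable[[int], SdmLearner]) -> None:
    """Register a user-supplied learner under a new id."""
    if algorithm_id in LEARNER_FACTORIES:
        raise ValueError(f"learner id {algorithm_id!r} already registered")
    LEARNER_FACTORIES[algorithm_id] = factory


def make_learner(algorithm_id: str, seed: int = 0) -> SdmLearner:
    if algorithm_id not in LEARNER_FACTORIES:
        raise KeyError(f"unknown learner id {algorithm_id!r}")
    return LEARNER_FACTORIES[algorithm_id](seed)
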