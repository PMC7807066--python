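"""Bias-aware pseudo-absence generation.

With presence-only data, absences must be invented.  The scheme here places
pseudo-absences (i) in environments unlike those where the species was
found, and (ii) preferentially where observers were active, so that the
presence/pseudo-absence contrast reflects the niche rather than the
sampling effort:

1. a *bias surface* is estimated by Gaussian point-density analysis of
   analogue-species sightings (large, conspicuous, commonly reported
   ground-foragers share the emu's observation process);
2. a *presence environmental kernel* is fitted: predictors are standardised
   over the whole grid, projected onto principal components, and a product
   Gaussian KDE (Scott bandwidth per component) is fitted to the presence
   scores;
3. pseudo-absence cells are drawn with weight proportional to
   ``(1 - density / density_max) * bias``, sequentially and without cell
   replacement, rejecting candidates closer than a minimum distance
   (default 30 km) to any presence or previously accepted pseudo-absence,
   until a 1:1 ratio with presences is reached.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .distances import pairwise_dist_km
from .grids import Grid, GridSurface, PredictorStack
from .synthetic import OCCURRENCE_COLUMNS

__all__ = [
    "InfeasibleSpacingError",
    "EnvKernel",
    "point_density",
    "build_bias_surface",
    "fit_env_kernel",
    "presence_density",
    "sample_pseudoabsences",
]


class InfeasibleSpacingError(RuntimeError):
    """Raised when the spacing constraint cannot accommodate the target count."""

    def __init__(self, requested: int, achieved: int):
        super().__init__(
            f"could only place {achieved} of {requested} pseudo-absences at the "
            "required spacing"
        )
        self.requested = requested
        self.achieved = achieved


def point_density(points: pd.DataFrame, grid: Grid, bandwidth_km: float) -> GridSurface:
    """Gaussian point density at cell centres (points per km^2).

    The surface integrates (cell sum x cell area) to the point count, up to
    kernel mass lying outside the grid.
    """
    if len(points) == 0:
        raise ValueError("point density needs at least one point")
    if not bandwidth_km > 0:
        raise ValueError("bandwidth must be positive")
    X, Y = grid.center_mesh()
    xy = points[["lon", "lat"]].to_numpy(dtype=float)
    h2 = bandwidth_km**2
    dens = np.zeros(grid.shape)
    norm = 1.0 / (2.0 * np.pi * h2)
    for px, py in xy:  # point count is modest; cells dominate the cost
        dens += norm * np.exp(-((X - px) ** 2 + (Y - py) ** 2) / (2.0 * h2))
    return GridSurface(grid, dens)


def build_bias_surface(
    analogue_points: pd.DataFrame, grid: Grid, bandwidth_km: float
) -> GridSurface:
    """Point-density bias layer rescaled so its maximum is 1."""
    dens = point_density(analogue_points, grid, bandwidth_km)
    peak = dens.values.max()
    if peak <= 0:
        raise ValueError("degenerate bias surface (zero density everywhere)")
    return GridSurface(grid, dens.values / peak)


@dataclass
class EnvKernel:
    """PCA transform + product-Gaussian KDE of presence environments."""

    means: np.ndarray            # grid-wide predictor means
    sds: np.ndarray              # grid-wide predictor sds
    components: np.ndarray       # (n_components, n_predictors) loadings
    pca_mean: np.ndarray         # mean of standardised values (PCA centring)
    bandwidths: np.ndarray       # Scott bandwidth per retained component
    presence_scores: np.ndarray  # (n_presences, n_components)
    layer_names: list[str]

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def transform(self, values: np.ndarray) -> np.ndarray:
        """Raw predictor rows -> retained principal-component scores."""
        z = (values - self.means) / self.sds
        return (z - self.pca_mean) @ self.components.T

    def density(self, values: np.ndarray, chunk: int = 4096) -> np.ndarray:
        """KDE density of the presence cloud at raw predictor rows."""
        scores = self.transform(np.atleast_2d(values))
        s = self.presence_scores
        h = self.bandwidths
        const = 1.0 / (len(s) * np.prod(np.sqrt(2 * np.pi) * h))
        out = np.empty(len(scores))
        for start in range(0, len(scores), chunk):
            block = scores[start : start + chunk]
            # (chunk, n_presence, n_comp)
            u = (block[:, None, :] - s[None, :, :]) / h
            out[start : start + chunk] = const * np.exp(-0.5 * (u**2).sum(axis=2)).sum(axis=1)
        return out


def _extract_values(stack: PredictorStack, points: pd.DataFrame) -> np.ndarray:
    row, col = stack.grid.cell_of(
        points["lon"].to_numpy(float), points["lat"].to_numpy(float)
    )
    return np.column_stack([stack[n][row, col] for n in stack.names])


def fit_env_kernel(
    presences: pd.DataFrame,
    stack: PredictorStack,
    n_components: int | None = None,
    variance_target: float = 0.95,
    seed: int = 0,
) -> EnvKernel:
    """Fit the presence kernel in the grid's principal-component space.

    PCA is fitted on standardised predictor values over every valid grid
    cell; by default the smallest component count explaining >= 95% of the
    variance is retained.  Bandwidths follow Scott's rule per component.
    """
    if len(presences) < 10:
        raise ValueError("need at least 10 presences to fit the kernel")
    if n_components is not None and n_components > len(stack.names):
        raise ValueError("n_components exceeds the number of predictors")
    table = stack.as_table()
    valid = np.all(np.isfinite(table), axis=1)
    table = table[valid]
    means = table.mean(axis=0)
    sds = table.std(axis=0)
    if np.any(sds == 0):
        bad = [n for n, s in zip(stack.names, sds) if s == 0]
        raise ValueError(f"constant predictor layer(s): {bad}")
    z = (table - means) / sds
    pca = PCA(n_components=len(stack.names), random_state=seed)
    scores_all = pca.fit_transform(z)
    if n_components is None:
        cum = np.cumsum(pca.explained_variance_ratio_)
        n_components = int(np.searchsorted(cum, variance_target) + 1)
        n_components = min(n_components, len(stack.names))
    kernel = EnvKernel(
        means=means,
        sds=sds,
        components=pca.components_[:n_components],
        pca_mean=np.zeros(len(stack.names)),  # z already centred grid-wide
        bandwidths=np.ones(n_components),
        presence_scores=np.empty((0, n_components)),
        layer_names=list(stack.names),
    )
    pres_scores = kernel.transform(_extract_values(stack, presences))
    n, d = pres_scores.shape
    scott = n ** (-1.0 / (d + 4))
    bw = scott * pres_scores.std(axis=0, ddof=1)
    bw[bw == 0] = 1e-6
    kernel.bandwidths = bw
    kernel.presence_scores = pres_scores
    return kernel


def presence_density(kernel: EnvKernel, stack: PredictorStack) -> GridSurface:
    """Presence-kernel density evaluated at every grid cell (NaN on nodata)."""
    table = stack.as_table(kernel.layer_names)
    valid = np.all(np.isfinite(table), axis=1)
    out = np.full(len(table), np.nan)
    out[valid] = kernel.density(table[valid])
    return GridSurface(stack.grid, out.reshape(stack.grid.shape))


def sample_pseudoabsences(
    kernel: "EnvKernel | GridSurface",
    bias: GridSurface,
    stack: PredictorStack,
    presences: pd.DataFrame,
    min_dist_km: float = 30.0,
    seed: int = 0,
    max_rejection_factor: int = 50,
) -> pd.DataFrame:
    """Draw pseudo-absences at a 1:1 ratio with presences.

    Cell weight is ``(1 - d/d_max) * bias`` with ``d`` the presence-kernel
    density; cells are drawn sequentially without replacement and a drawn
    point is rejected if it falls within ``min_dist_km`` of any presence or
    previously accepted pseudo-absence.  After ``max_rejection_factor * n``
    rejections the spacing problem is declared infeasible and the achieved
    count is reported in the raised error.

    ``kernel`` may be a fitted :class:`EnvKernel` or an already-evaluated
    density surface.
    """
    n_target = len(presences)
    if n_target < 1:
        raise ValueError("need at least one presence")
    bias.grid.require_same(stack.grid, "bias and predictor stack")
    if isinstance(kernel, GridSurface):
        kernel.grid.require_same(stack.grid, "density and predictor stack")
        dens = kernel.values
    else:
        dens = presence_density(kernel, stack).values
    if not np.nanmax(dens) > 0:
        raise ValueError("presence-kernel density is degenerate (all zero)")
    # Complement of the density's grid-wide ECDF: cells whose presence-kernel
    # density is in the top of the distribution get weight near 0, the least
    # presence-like cells weight near 1.  Rank-based rather than
    # max-normalised (1 - d/d_max) because a KDE in several components spans
    # orders of magnitude, which makes the linear complement ~1 almost
    # everywhere and lets pseudo-absences leak into presence-like habitat.
    flat = dens.ravel()
    valid = np.isfinite(flat)
    sorted_d = np.sort(flat[valid])
    complement = np.full(flat.shape, np.nan)
    complement[valid] = 1.0 - np.searchsorted(sorted_d, flat[valid], side="left") / len(sorted_d)
    weights = complement.reshape(dens.shape) * bias.values
    weights = np.where(np.isfinite(weights), np.clip(weights, 0.0, None), 0.0).ravel()
    if weights.sum() <= 0:
        raise ValueError("pseudo-absence weights are identically zero")

    grid = stack.grid
    rng = np.random.default_rng(seed)
    pres_xy = presences[["lon", "lat"]].to_numpy(dtype=float)
    accepted_xy: list[np.ndarray] = []
    accepted_cells: list[int] = []
    w = weights.copy()
    rejections = 0
    max_rejections = max_rejection_factor * n_target
    while len(accepted_xy) < n_target:
        total = w.sum()
        if total <= 0 or rejections >= max_rejections:
            raise InfeasibleSpacingError(n_target, len(accepted_xy))
        cell = rng.choice(grid.n_cells, p=w / total)
        row, col = np.unravel_index(cell, grid.shape)
        s = grid.cell_size_km
        x = grid.x_origin_km + (col + rng.uniform()) * s
        y = grid.y_origin_km + (grid.n_rows - row - 1 + rng.uniform()) * s
        cand = np.array([[x, y]])
        d_pres = pairwise_dist_km(cand, pres_xy)[0].min() if len(pres_xy) else np.inf
        d_pa = (
            pairwise_dist_km(cand, np.array(accepted_xy))[0].min()
            if accepted_xy
            else np.inf
        )
        if d_pres < min_dist_km or d_pa < min_dist_km:
            rejections += 1
            continue
        accepted_xy.append(cand[0])
        accepted_cells.append(int(cell))
        w[cell] = 0.0  # without replacement

    xy = np.array(accepted_xy)
    df = pd.DataFrame(
        {
            "lon": xy[:, 0],
            "lat": xy[:, 1],
            "year": np.nan,
            "coord_uncertainty_m": 0.0,
            "is_fossil": False,
            "is_absence_record": False,
            "source": "pseudoabsence",
        }
    )
    return df[OCCURRENCE_COLUMNS]
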