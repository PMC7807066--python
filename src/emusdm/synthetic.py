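"""Synthetic landscapes with a known true niche.

Every downstream stage of the pipeline (cleaning, pseudo-absence generation,
model fitting, ensembling, range change, MESS) is exercised against data
generated here, where the truth is known exactly:

* predictor layers are spatially autocorrelated Gaussian random fields
  (white noise convolved with a Gaussian kernel, then standardised);
* true habitat suitability is a logistic (linear + optional quadratic)
  function of the layers;
* presence records are sampled with probability proportional to
  suitability x observation bias, emulating opportunistic sightings
  concentrated where people are;
* analogue-species sightings follow the bias surface alone, providing the
  raw material for the sampling-effort bias layer;
* scenario stacks ("past"/"future" climates) are cell-wise affine shifts
  of the current layers.

All generators are pure functions of their arguments and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .grids import Grid, GridSurface, PredictorStack

__all__ = [
    "LandscapeSpec",
    "TrueNiche",
    "ScenarioShift",
    "generate_predictor_stack",
    "true_suitability",
    "sample_occurrences",
    "generate_analogue_sightings",
    "shift_climate",
    "make_hotspot_bias",
    "empty_occurrence_frame",
]

OCCURRENCE_COLUMNS = [
    "lon",
    "lat",
    "year",
    "coord_uncertainty_m",
    "is_fossil",
    "is_absence_record",
    "source",
]


@dataclass(frozen=True)
class LandscapeSpec:
    """Dimensions, naming, and autocorrelation of a synthetic landscape."""

    n_rows: int
    n_cols: int
    cell_size_km: float
    layer_names: tuple[str, ...]
    autocorr_length_km: tuple[float, ...] | float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.n_rows * self.n_cols < 4:
            raise ValueError("landscape needs at least 4 cells")
        if not self.cell_size_km > 0:
            raise ValueError("cell_size_km must be positive")
        names = tuple(self.layer_names)
        if len(names) == 0:
            raise ValueError("layer_names must be non-empty")
        if len(set(names)) != len(names):
            raise ValueError("layer_names must be unique")
        object.__setattr__(self, "layer_names", names)
        lengths = self.autocorr_length_km
        if np.isscalar(lengths):
            lengths = tuple(float(lengths) for _ in names)
        else:
            lengths = tuple(float(v) for v in lengths)
            if len(lengths) != len(names):
                raise ValueError("one autocorr length per layer required")
        if any(v < 0 for v in lengths):
            raise ValueError("autocorrelation lengths must be nonnegative")
        object.__setattr__(self, "autocorr_length_km", lengths)

    def grid(self) -> Grid:
        return Grid(self.n_rows, self.n_cols, self.cell_size_km)


@dataclass(frozen=True)
class TrueNiche:
    """Ground-truth logistic niche: logit(suitability) is linear-quadratic."""

    intercept: float
    coefficients: dict[str, float]
    quadratic_coefficients: dict[str, float] | None = None

    def required_layers(self) -> set[str]:
        names = set(self.coefficients)
        if self.quadratic_coefficients:
            names |= set(self.quadratic_coefficients)
        return names


@dataclass(frozen=True)
class ScenarioShift:
    """Cell-wise affine transform per layer: x -> factor * x + delta."""

    additive_delta: dict[str, float] = field(default_factory=dict)
    multiplicative_factor: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.multiplicative_factor.values()):
            raise ValueError("multiplicative factors must be positive")

    def layer_names(self) -> set[str]:
        return set(self.additive_delta) | set(self.multiplicative_factor)


def generate_predictor_stack(spec: LandscapeSpec) -> PredictorStack:
    """Smoothed-noise random fields, standardised to mean 0 / sd 1 per layer.

    Autocorrelation is imposed by convolving white noise with a Gaussian
    kernel whose sigma equals the requested length (in cells); the field is
    periodic (wrap-around convolution) so its statistics are stationary.
    Regeneration with the same spec is bit-identical.
    """
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid()
    layers: dict[str, np.ndarray] = {}
    for name, length_km in zip(spec.layer_names, spec.autocorr_length_km):
        noise = rng.standard_normal(grid.shape)
        if length_km > 0:
            sigma_cells = length_km / spec.cell_size_km
            noise = gaussian_filter(noise, sigma=sigma_cells, mode="wrap")
        sd = noise.std()
        if sd == 0:  # pragma: no cover - degenerate only for 1-cell grids
            raise ValueError(f"layer {name!r} is constant; enlarge the grid")
        layers[name] = (noise - noise.mean()) / sd
    return PredictorStack(grid, layers)


def true_suitability(stack: PredictorStack, niche: TrueNiche) -> GridSurface:
    """Inverse-logit of the niche's linear-quadratic score, per cell."""
    missing = niche.required_layers() - set(stack.names)
    if missing:
        raise KeyError(f"niche references unknown predictors: {sorted(missing)}")
    eta = np.full(stack.grid.shape, float(niche.intercept))
    for name, beta in niche.coefficients.items():
        eta = eta + beta * stack[name]
    for name, beta in (niche.quadratic_coefficients or {}).items():
        eta = eta + beta * stack[name] ** 2
    return GridSurface(stack.grid, expit(eta))


def empty_occurrence_frame() -> pd.DataFrame:
    return pd.DataFrame(columns=OCCURRENCE_COLUMNS)


def _sample_cells(weights: np.ndarray, grid: Grid, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw n jittered points with cell probability proportional to weights."""
    w = np.where(np.isfinite(weights), weights, 0.0).ravel()
    if w.min() < 0:
        raise ValueError("negative sampling weights")
    total = w.sum()
    if total <= 0:
        raise ValueError("sampling weights are identically zero")
    idx = rng.choice(grid.n_cells, size=n, replace=True, p=w / total)
    row, col = np.unravel_index(idx, grid.shape)
    s = grid.cell_size_km
    x = grid.x_origin_km + (col + rng.uniform(size=n)) * s
    y = grid.y_origin_km + (grid.n_rows - row - 1 + rng.uniform(size=n)) * s
    return pd.DataFrame({"lon": x, "lat": y})


def _inject_defects(
    df: pd.DataFrame,
    dirty_fraction: float,
    rng: np.random.Generator,
    outlier_clearance_km: float = 60.0,
) -> pd.DataFrame:
    """Make a fraction of records violate one cleaning rule each.

    Defect kinds cycle through: coordinate uncertainty above 5 km, missing
    year, fossil flag, absence flag, and far spatial outliers (relocated at
    least ``outlier_clearance_km`` from every other record, when the
    landscape leaves room).
    """
    n_dirty = int(round(dirty_fraction * len(df)))
    if n_dirty == 0:
        return df
    kinds = ["uncertainty", "missing_year", "fossil", "absence", "outlier"]
    dirty_idx = rng.choice(len(df), size=n_dirty, replace=False)
    xy = df[["lon", "lat"]].to_numpy()
    span_x = xy[:, 0].min(), xy[:, 0].max()
    span_y = xy[:, 1].min(), xy[:, 1].max()
    for k, i in enumerate(dirty_idx):
        kind = kinds[k % len(kinds)]
        if kind == "uncertainty":
            df.iat[i, df.columns.get_loc("coord_uncertainty_m")] = rng.uniform(6_000, 50_000)
        elif kind == "missing_year":
            df.iat[i, df.columns.get_loc("year")] = np.nan
        elif kind == "fossil":
            df.iat[i, df.columns.get_loc("is_fossil")] = True
        elif kind == "absence":
            df.iat[i, df.columns.get_loc("is_absence_record")] = True
        else:  # far outlier: try to find an isolated location
            others = np.delete(xy, i, axis=0)
            for _ in range(100):
                cand = np.array(
                    [rng.uniform(*span_x), rng.uniform(*span_y)]
                )
                d = np.sqrt(((others - cand) ** 2).sum(axis=1))
                if d.min() > outlier_clearance_km:
                    df.iat[i, df.columns.get_loc("lon")] = cand[0]
                    df.iat[i, df.columns.get_loc("lat")] = cand[1]
                    xy[i] = cand
                    break
    return df


def sample_occurrences(
    suit: GridSurface,
    bias: GridSurface,
    n: int,
    seed: int,
    dirty_fraction: float = 0.1,
    year_range: tuple[int, int] = (1975, 2020),
    source: str = "synthetic",
) -> pd.DataFrame:
    """Opportunistic presence records: cell probability ~ suitability x bias.

    Exactly ``n`` records are returned, each jittered uniformly within its
    cell. A ``dirty_fraction`` of them deliberately violate a cleaning rule
    (see :func:`_inject_defects`) so the cleaner has something to do.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    suit.grid.require_same(bias.grid, "suitability and bias")
    rng = np.random.default_rng(seed)
    df = _sample_cells(suit.values * bias.values, suit.grid, n, rng)
    df["year"] = rng.integers(year_range[0], year_range[1] + 1, size=n).astype(float)
    df["coord_uncertainty_m"] = rng.uniform(0, 4000, size=n)
    df["is_fossil"] = False
    df["is_absence_record"] = False
    df["source"] = source
    df = _inject_defects(df, dirty_fraction, rng)
    return df[OCCURRENCE_COLUMNS]


def generate_analogue_sightings(
    bias: GridSurface,
    n: int,
    seed: int,
    year_range: tuple[int, int] = (1975, 2020),
) -> pd.DataFrame:
    """Sightings of well-detected analogue species: probability ~ bias only."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    df = _sample_cells(bias.values, bias.grid, n, rng)
    df["year"] = rng.integers(year_range[0], year_range[1] + 1, size=n).astype(float)
    df["coord_uncertainty_m"] = rng.uniform(0, 4000, size=n)
    df["is_fossil"] = False
    df["is_absence_record"] = False
    df["source"] = "analogue"
    return df[OCCURRENCE_COLUMNS]


def shift_climate(stack: PredictorStack, shift: ScenarioShift) -> PredictorStack:
    """Apply the scenario's affine transform; untouched layers pass through."""
    unknown = shift.layer_names() - set(stack.names)
    if unknown:
        raise KeyError(f"shift references unknown layers: {sorted(unknown)}")
    layers = {}
    for name, arr in stack.items():
        factor = shift.multiplicative_factor.get(name, 1.0)
        delta = shift.additive_delta.get(name, 0.0)
        layers[name] = factor * arr + delta
    return PredictorStack(stack.grid, layers)


def make_hotspot_bias(
    grid: Grid,
    n_hotspots: int = 6,
    bandwidth_km: float | None = None,
    floor: float = 0.05,
    seed: int = 0,
) -> GridSurface:
    """Nonuniform observation-bias surface: Gaussian hotspots over a floor.

    Emulates sampling effort concentrated near population centres while
    leaving every cell observable with a small baseline probability.
    """
    rng = np.random.default_rng(seed)
    if bandwidth_km is None:
        bandwidth_km = 0.1 * grid.n_cols * grid.cell_size_km
    X, Y = grid.center_mesh()
    dens = np.zeros(grid.shape)
    width = grid.n_cols * grid.cell_size_km
    height = grid.n_rows * grid.cell_size_km
    cx = grid.x_origin_km + rng.uniform(0, width, size=n_hotspots)
    cy = grid.y_origin_km + rng.uniform(0, height, size=n_hotspots)
    for i in range(n_hotspots):
        d2 = (X - cx[i]) ** 2 + (Y - cy[i]) ** 2
        dens += np.exp(-d2 / (2 * bandwidth_km**2))
    dens /= dens.max()
    dens = np.maximum(dens, floor)
    return GridSurface(grid, dens / dens.max())
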