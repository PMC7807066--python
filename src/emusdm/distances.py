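"""Point distances on planar-km and geographic (WGS84) coordinates."""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between points given in decimal degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_dist_km(a: np.ndarray, b: np.ndarray, geographic: bool = False) -> np.ndarray:
    """Distance matrix (len(a), len(b)) between two (n, 2) [lon, lat] arrays.

    Planar coordinates are interpreted as kilometres (Euclidean distance);
    geographic coordinates as degrees (haversine on a spherical Earth).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if geographic:
        return haversine_km(
            a[:, 0][:, None], a[:, 1][:, None], b[None, :, 0], b[None, :, 1]
        )
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def nearest_neighbor_km(points: np.ndarray, geographic: bool = False) -> np.ndarray:
    """Distance from each point to its nearest other point."""
    d = pairwise_dist_km(points, points, geographic=geographic)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)
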