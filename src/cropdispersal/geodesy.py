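"""Great-circle geometry on the spherical Earth approximation.

All distances are in kilometres, all coordinates in decimal degrees
(longitude, latitude; WGS84 sphere approximation).
"""

from __future__ import annotations

import numpy as np

#: Mean Earth radius in km (IUGG mean radius).
EARTH_RADIUS_KM = 6371.0088


def great_circle_km(lon1, lat1, lon2, lat2):
    """Haversine great-circle distance in km between points (broadcasting).

    Parameters are in decimal degrees; scalars or array-likes accepted.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    # clip guards rounding for antipodal points
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def great_circle_matrix(lons, lats) -> np.ndarray:
    """Symmetric pairwise great-circle distance matrix (km), zero diagonal.

    Raises ``ValueError`` for latitudes outside [-90, 90].
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if lons.shape != lats.shape or lons.ndim != 1:
        raise ValueError("lons and lats must be equal-length 1-D sequences")
    if np.any(np.abs(lats) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    d = great_circle_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])
    np.fill_diagonal(d, 0.0)
    # enforce exact symmetry against floating-point asymmetry
    return (d + d.T) / 2.0


def lonlat_to_xyz(lons, lats) -> np.ndarray:
    """Unit-sphere Cartesian coordinates, shape (n, 3). Used for KD-tree queries."""
    lon = np.radians(np.asarray(lons, dtype=float))
    lat = np.radians(np.asarray(lats, dtype=float))
    return np.column_stack(
        (np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat))
    )


def chord_to_arc_km(chord: np.ndarray) -> np.ndarray:
    """Convert unit-sphere chord lengths to great-circle distances in km."""
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.clip(np.asarray(chord) / 2.0, 0.0, 1.0))
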