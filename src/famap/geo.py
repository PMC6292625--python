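"""Great-circle geometry on WGS84 geographic coordinates.

All public distances are in kilometres. Coordinates are (lon, lat) in
decimal degrees. A spherical earth with the WGS84 mean radius is used;
at the country scale of the mapping workflow the difference from a full
ellipsoidal geodesic is negligible relative to the 10-km analysis grid.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance between points, element-wise, in km."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def pairwise_distance_km(lons, lats, lons2=None, lats2=None):
    """Dense great-circle distance matrix (km).

    With one point set returns the symmetric n x n matrix; with two sets
    returns the n x m cross-distance matrix.
    """
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if lons2 is None:
        lons2, lats2 = lons, lats
    else:
        lons2 = np.asarray(lons2, dtype=float)
        lats2 = np.asarray(lats2, dtype=float)
    return haversine_km(lons[:, None], lats[:, None], lons2[None, :], lats2[None, :])


def destination_point(lons, lats, bearings_deg, distances_km):
    """Move each point along a given initial bearing by a great-circle distance.

    Parameters are broadcast together; returns (lon, lat) arrays in degrees.
    Bearing 0 is north, 90 east.
    """
    lam1 = np.radians(np.asarray(lons, dtype=float))
    phi1 = np.radians(np.asarray(lats, dtype=float))
    theta = np.radians(np.asarray(bearings_deg, dtype=float))
    delta = np.asarray(distances_km, dtype=float) / EARTH_RADIUS_KM

    sin_phi2 = np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(theta)
    phi2 = np.arcsin(np.clip(sin_phi2, -1.0, 1.0))
    lam2 = lam1 + np.arctan2(np.sin(theta) * np.sin(delta) * np.cos(phi1),
                             np.cos(delta) - np.sin(phi1) * sin_phi2)
    lon2 = np.degrees(lam2)
    # normalise to [-180, 180)
    lon2 = (lon2 + 180.0) % 360.0 - 180.0
    return lon2, np.degrees(phi2)
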