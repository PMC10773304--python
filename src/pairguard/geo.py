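"""Spherical geometry helpers.

All large-scale distances (the 500-km plausibility rule) use the haversine
great-circle formula; all sub-kilometre work (proximity thresholds, nest
radii, step lengths) happens on a local planar grid obtained from an
azimuthal equidistant projection centred on the study site.  At study-area
scale (a few km) the difference between the two metrics is far below GPS
noise.
"""

from __future__ import annotations

import numpy as np

#: mean Earth radius in metres (IUGG)
EARTH_RADIUS_M = 6_371_008.8

#: study-site centre used as the default projection origin (lon, lat),
#: open tundra near Utqiagvik, Alaska
DEFAULT_SITE = (-156.65, 71.32)


def haversine_m(lon1, lat1, lon2, lat2):
    """Great-circle distance in metres between points in degrees (vectorised)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


class LocalProjection:
    """Azimuthal equidistant projection on a sphere, centred at (lon0, lat0).

    Forward maps lon/lat degrees to planar x/y metres; inverse maps back.
    Distances from the origin are exact; distances between nearby points are
    accurate to O((d/R)^2), i.e. millimetres at study-area scale.
    """

    def __init__(self, lon0: float = DEFAULT_SITE[0], lat0: float = DEFAULT_SITE[1]):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self._lam0 = np.radians(self.lon0)
        self._phi0 = np.radians(self.lat0)

    def forward(self, lon, lat):
        lam = np.radians(np.asarray(lon, dtype=float))
        phi = np.radians(np.asarray(lat, dtype=float))
        dlam = lam - self._lam0
        cos_c = (np.sin(self._phi0) * np.sin(phi)
                 + np.cos(self._phi0) * np.cos(phi) * np.cos(dlam))
        c = np.arccos(np.clip(cos_c, -1.0, 1.0))
        # k = c / sin(c), with the removable singularity at c = 0
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
        x = EARTH_RADIUS_M * k * np.cos(phi) * np.sin(dlam)
        y = EARTH_RADIUS_M * k * (np.cos(self._phi0) * np.sin(phi)
                                  - np.sin(self._phi0) * np.cos(phi) * np.cos(dlam))
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float) / EARTH_RADIUS_M
        y = np.asarray(y, dtype=float) / EARTH_RADIUS_M
        rho = np.hypot(x, y)
        c = rho
        safe_rho = np.where(rho > 1e-12, rho, 1.0)
        sin_c, cos_c = np.sin(c), np.cos(c)
        phi = np.arcsin(np.clip(cos_c * np.sin(self._phi0)
                                + y * sin_c * np.cos(self._phi0) / safe_rho, -1.0, 1.0))
        lam = self._lam0 + np.arctan2(
            x * sin_c,
            safe_rho * np.cos(self._phi0) * cos_c - y * np.sin(self._phi0) * sin_c,
        )
        phi = np.where(rho > 1e-12, phi, self._phi0)
        lam = np.where(rho > 1e-12, lam, self._lam0)
        return np.degrees(lam), np.degrees(phi)


def planar_distance(x1, y1, x2, y2):
    """Euclidean distance on the local grid, metres."""
    return np.hypot(np.asarray(x2) - np.asarray(x1), np.asarray(y2) - np.asarray(y1))
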