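"""Local metric coordinate reference for small study areas.

All internal computation (hex areas, step lengths, transport costs) happens in
a local planar CRS with metre units. Input tracks arrive as geographic lon/lat;
a :class:`LocalProjection` centred on the study area maps them to planar x/y.
For domains a few tens of kilometres across the projection error of the
spherical transverse-Mercator formulas used here is far below GPS error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_M = 6_371_008.8


@dataclass(frozen=True)
class LocalProjection:
    """Spherical transverse Mercator centred on (``lon0``, ``lat0``).

    ``forward`` maps degrees lon/lat to metres x/y (x east, y north, origin at
    the reference point); ``inverse`` maps back. Round-trips are exact to
    floating point for points within the domain.
    """

    lon0: float
    lat0: float

    def forward(self, lon, lat):
        lam = np.radians(np.asarray(lon, dtype=float) - self.lon0)
        phi = np.radians(np.asarray(lat, dtype=float))
        phi0 = np.radians(self.lat0)
        B = np.cos(phi) * np.sin(lam)
        x = EARTH_RADIUS_M * np.arctanh(B)
        y = EARTH_RADIUS_M * (np.arctan2(np.tan(phi), np.cos(lam)) - phi0)
        return x, y

    def inverse(self, x, y):
        xr = np.asarray(x, dtype=float) / EARTH_RADIUS_M
        yr = np.asarray(y, dtype=float) / EARTH_RADIUS_M + np.radians(self.lat0)
        lam = np.arctan2(np.sinh(xr), np.cos(yr))
        phi = np.arcsin(np.cos(lam) * np.sin(yr))
        return self.lon0 + np.degrees(lam), np.degrees(phi)


def haversine_m(lon1, lat1, lon2, lat2):
    """Great-circle distance in metres between lon/lat points (degrees)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(h))
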