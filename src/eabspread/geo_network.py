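"""Locations and the pairwise great-circle distance matrix.

Distances between cities are computed on a sphere of mean Earth radius
(6371.0088 km by default) with the spherical law of cosines,

    d_ij = R * arccos( sin(lat_i) sin(lat_j)
                       + cos(lat_i) cos(lat_j) cos(lon_i - lon_j) ),

angles in radians.  The arccos argument is clamped to [-1, 1] so that
near-identical or near-antipodal coordinate pairs cannot produce NaN from
rounding.  No map projection is ever used for distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Mean Earth radius in km (IUGG mean radius R1).
EARTH_RADIUS_KM = 6371.0088


class ValidationError(ValueError):
    """Raised when input data violate a documented invariant."""


@dataclass(frozen=True)
class Location:
    """A city or transport hub with WGS84 coordinates.

    Parameters
    ----------
    id : str
        Unique token identifying the location within a network.
    name : str
        Human-readable name.
    country, region : str
        Free-text labels used for regional summaries.
    lat : float
        Latitude in decimal degrees, in [-90, 90].
    lon : float
        Longitude in decimal degrees, in (-180, 180].
    """

    id: str
    name: str
    country: str
    region: str
    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.lat) or not -90.0 <= self.lat <= 90.0:
            raise ValidationError(
                f"lat={self.lat!r} for location {self.id!r} outside [-90, 90]"
            )
        if not np.isfinite(self.lon) or not -180.0 < self.lon <= 180.0:
            raise ValidationError(
                f"lon={self.lon!r} for location {self.id!r} outside (-180, 180]"
            )


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise great-circle distances in km.

    ``ids`` fixes the row/column order; ``d`` is an n-by-n float array with
    zero diagonal.
    """

    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if d.shape != (n, n):
            raise ValidationError(f"distance matrix shape {d.shape} != ({n}, {n})")
        if not np.allclose(d, d.T, atol=1e-9):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0.0):
            raise ValidationError("distance matrix diagonal is not zero")
        if np.any(d < 0.0):
            raise ValidationError("negative distance entry")
        object.__setattr__(self, "d", d)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, location_id: str) -> int:
        try:
            return self.ids.index(location_id)
        except ValueError:
            raise KeyError(f"unknown location id {location_id!r}") from None

    def to_long_frame(self) -> pd.DataFrame:
        """Upper-triangle long format: columns id_i, id_j, distance_km."""
        iu, ju = np.triu_indices(self.n, k=1)
        return pd.DataFrame(
            {
                "id_i": [self.ids[i] for i in iu],
                "id_j": [self.ids[j] for j in ju],
                "distance_km": self.d[iu, ju],
            }
        )


def great_circle_distance(
    a: Location, b: Location, earth_radius_km: float = EARTH_RADIUS_KM
) -> float:
    """Great-circle distance between two locations in km.

    Spherical law of cosines on a sphere of radius ``earth_radius_km``;
    result lies in [0, pi*R].
    """
    if earth_radius_km <= 0:
        raise ValidationError(f"earth_radius_km={earth_radius_km!r} must be positive")
    la, lb = np.radians(a.lat), np.radians(b.lat)
    dlon = np.radians(a.lon) - np.radians(b.lon)
    cosang = np.sin(la) * np.sin(lb) + np.cos(la) * np.cos(lb) * np.cos(dlon)
    return float(earth_radius_km * np.arccos(np.clip(cosang, -1.0, 1.0)))


def pairwise_matrix(
    locations: Sequence[Location], earth_radius_km: float = EARTH_RADIUS_KM
) -> DistanceMatrix:
    """Pairwise great-circle distance matrix over ``locations``.

    Row/column order matches the input order.  Duplicate ids raise; distinct
    locations sharing identical coordinates are allowed but produce a
    warning, because a zero off-diagonal distance makes the two sites
    epidemiologically indistinguishable.
    """
    locations = list(locations)
    if len(locations) < 2:
        raise ValidationError("need at least 2 locations")
    ids = [loc.id for loc in locations]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate location ids: {dup}")

    lat = np.radians([loc.lat for loc in locations])
    lon = np.radians([loc.lon for loc in locations])
    cosang = np.sin(lat)[:, None] * np.sin(lat)[None, :] + np.cos(lat)[:, None] * np.cos(
        lat
    )[None, :] * np.cos(lon[:, None] - lon[None, :])
    d = earth_radius_km * np.arccos(np.clip(cosang, -1.0, 1.0))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against rounding

    coords = {}
    dup_pairs = []
    for k, loc in enumerate(locations):
        key = (loc.lat, loc.lon)
        if key in coords:
            dup_pairs.append((ids[coords[key]], ids[k]))
            d[coords[key], k] = d[k, coords[key]] = 0.0
        else:
            coords[key] = k
    if dup_pairs:
        warnings.warn(
            f"{len(dup_pairs)} pair(s) of distinct locations share identical "
            f"coordinates (zero distance), e.g. {dup_pairs[:5]}",
            stacklevel=2,
        )
    return DistanceMatrix(ids=tuple(ids), d=d)


def locations_to_frame(locations: Iterable[Location]) -> pd.DataFrame:
    """Location table with columns id,name,country,region,lat,lon."""
    return pd.DataFrame(
        [
            {
                "id": c.id,
                "name": c.name,
                "country": c.country,
                "region": c.region,
                "lat": c.lat,
                "lon": c.lon,
            }
            for c in locations
        ]
    )


def locations_from_frame(df: pd.DataFrame) -> list[Location]:
    """Build validated locations from a table with the standard columns."""
    required = ["id", "name", "country", "region", "lat", "lon"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"location table missing columns: {missing}")
    return [
        Location(
            id=str(row.id),
            name=str(row.name),
            country=str(row.country),
            region=str(row.region),
            lat=float(row.lat),
            lon=float(row.lon),
        )
        for row in df.itertuples(index=False)
    ]
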