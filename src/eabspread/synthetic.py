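"""Synthetic city networks and survey data for end-to-end testing.

Real invasion data for this model are a list of cities with coordinates
and binary survey outcomes.  This module generates networks with the same
statistical structure — clusters of cities concentrated around an invasion
epicenter, thinning with distance — and survey labels produced by running
the spread model under a *known* kernel, so calibration can be tested as a
parameter-recovery experiment with ground truth.

The generator is a cluster process: cluster centers drawn uniformly in a
box around the epicenter, cities scattered around the centers with Gaussian
displacement.  Defaults (173 cities, 8 clusters, 80 km scatter, centers
within ~500 km) mimic a dense national urban network around a capital.
One city is always placed exactly at the epicenter and serves as the seed.

Also bundles a small named-city fixture (epicenter Moscow plus ~20 real
cities with public-knowledge coordinates) for smoke tests and docs.  The
fixture is synthetic in the sense that coordinates are approximate and the
detection states are a coarse reading of the published invasion history,
not a survey dataset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from eabspread.calibration import SurveyRecord
from eabspread.geo_network import Location, ValidationError, pairwise_matrix
from eabspread.kernels import Kernel
from eabspread.spread_model import simulate

KM_PER_DEG_LAT = 111.32  # mean length of one degree of latitude


@dataclass(frozen=True)
class NetworkSpec:
    """Parameters of the clustered synthetic city network."""

    n_cities: int = 173
    epicenter: tuple[float, float] = (55.7558, 37.6173)  # lat, lon
    n_clusters: int = 8
    cluster_spread_km: float = 80.0
    extent_km: float = 500.0  # half-width of the box holding cluster centers
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cities < 2:
            raise ValidationError("n_cities must be >= 2")
        if self.cluster_spread_km <= 0 or self.extent_km <= 0:
            raise ValidationError("cluster_spread_km and extent_km must be positive")
        if self.n_clusters < 1:
            raise ValidationError("n_clusters must be >= 1")


def _km_offsets_to_degrees(lat0: float, dx_km, dy_km):
    """East/north displacements in km -> (lat, lon) degrees near lat0."""
    dlat = np.asarray(dy_km) / KM_PER_DEG_LAT
    dlon = np.asarray(dx_km) / (KM_PER_DEG_LAT * math.cos(math.radians(lat0)))
    return dlat, dlon


def generate_city_network(spec: NetworkSpec) -> list[Location]:
    """Deterministic clustered network; the first city is the seed.

    The seed city (id ``"seed"``) sits exactly at the epicenter in country
    "Homeland"; the rest are assigned to their cluster's region and to a
    country by east/west position (a crude stand-in for national borders so
    that regional summaries have something to group by).
    """
    rng = np.random.default_rng(spec.seed)
    lat0, lon0 = spec.epicenter

    centers_xy = rng.uniform(-spec.extent_km, spec.extent_km, size=(spec.n_clusters, 2))
    n_rest = spec.n_cities - 1
    assign = rng.integers(0, spec.n_clusters, size=n_rest)
    scatter = rng.normal(0.0, spec.cluster_spread_km, size=(n_rest, 2))
    xy = centers_xy[assign] + scatter

    dlat, dlon = _km_offsets_to_degrees(lat0, xy[:, 0], xy[:, 1])
    lats = np.clip(lat0 + dlat, -89.9, 89.9)
    lons = (lon0 + dlon + 180.0) % 360.0 - 180.0

    cities = [
        Location(
            id="seed",
            name="Epicenter",
            country="Homeland",
            region="Capital",
            lat=lat0,
            lon=lon0,
        )
    ]
    west_border = lon0 - 0.35 * spec.extent_km / (
        KM_PER_DEG_LAT * math.cos(math.radians(lat0))
    )
    for k in range(n_rest):
        country = "Homeland" if lons[k] >= west_border else "Neighborland"
        cities.append(
            Location(
                id=f"c{k:03d}",
                name=f"City {k:03d}",
                country=country,
                region=f"Cluster {assign[k]}",
                lat=float(lats[k]),
                lon=float(lons[k]),
            )
        )
    return cities


def simulate_survey_data(
    network: list[Location],
    kernel: Kernel,
    start_year: int,
    survey_year: int,
    rule: str = "threshold",
    p_star: float = 0.5,
    seed: int = 0,
    seed_id: str = "seed",
) -> list[SurveyRecord]:
    """Survey records labelled from a model run under a known kernel.

    Runs the spread model from ``seed_id`` and surveys every city at
    ``survey_year``.  With ``rule="threshold"`` a city is recorded as
    detected iff its probability exceeds ``p_star``; with
    ``rule="bernoulli"`` detection is drawn with probability P_j using
    ``seed``.  Warns if every label comes out identical (a degenerate set
    that cannot calibrate anything — resample or change the horizon).
    """
    if rule not in ("threshold", "bernoulli"):
        raise ValidationError(f"rule={rule!r} must be 'threshold' or 'bernoulli'")
    D = pairwise_matrix(network)
    traj = simulate(D, kernel, seed_id, start_year, survey_year)
    P = traj.at_year(survey_year)
    if rule == "threshold":
        detected = P > p_star
    else:
        detected = np.random.default_rng(seed).random(len(P)) < P
    records = [
        SurveyRecord(
            location_id=lid,
            year=survey_year,
            outcome="detected" if det else "not_detected",
        )
        for lid, det in zip(D.ids, detected)
    ]
    if detected.all() or not detected.any():
        warnings.warn(
            "degenerate survey labels (all identical); resample or adjust the "
            "kernel/horizon",
            stacklevel=2,
        )
    return records


#: Named cities with approximate public-knowledge coordinates.  ``detected``
#: reflects the coarse published invasion picture by 2017: detections inside
#: Russia out to roughly 460 km from Moscow, none in neighboring countries.
_REFERENCE_CITIES: list[tuple[str, str, str, float, float, bool]] = [
    ("Moscow", "Russia", "Moscow", 55.7558, 37.6173, True),
    ("Yaroslavl", "Russia", "Yaroslavl", 57.6261, 39.8845, True),
    ("Tver", "Russia", "Tver", 56.8587, 35.9176, True),
    ("Kaluga", "Russia", "Kaluga", 54.5293, 36.2754, True),
    ("Tula", "Russia", "Tula", 54.1931, 37.6173, True),
    ("Ryazan", "Russia", "Ryazan", 54.6296, 39.7412, True),
    ("Vladimir", "Russia", "Vladimir", 56.1290, 40.4070, True),
    ("Smolensk", "Russia", "Smolensk", 54.7826, 32.0453, True),
    ("Orel", "Russia", "Orel", 52.9703, 36.0635, True),
    ("Bryansk", "Russia", "Bryansk", 53.2434, 34.3642, True),
    ("Kursk", "Russia", "Kursk", 51.7304, 36.1926, True),
    ("Voronezh", "Russia", "Voronezh", 51.6615, 39.2003, True),
    ("Belgorod", "Russia", "Belgorod", 50.5955, 36.5873, False),
    ("St. Petersburg", "Russia", "St. Petersburg", 59.9343, 30.3351, False),
    ("Pskov", "Russia", "Pskov", 57.8194, 28.3318, False),
    ("Mogilev", "Belarus", "Mogilev", 53.9006, 30.3318, False),
    ("Vitebsk", "Belarus", "Vitebsk", 55.1904, 30.2049, False),
    ("Minsk", "Belarus", "Minsk", 53.9045, 27.5615, False),
    ("Sumy", "Ukraine", "Sumy", 50.9077, 34.7981, False),
    ("Kharkiv", "Ukraine", "Kharkiv", 49.9935, 36.2304, False),
    ("Kyiv", "Ukraine", "Kyiv", 50.4501, 30.5234, False),
    ("Riga", "Latvia", "Riga", 56.9496, 24.1052, False),
    ("Vilnius", "Lithuania", "Vilnius", 54.6872, 25.2797, False),
    ("Tallinn", "Estonia", "Tallinn", 59.4370, 24.7536, False),
]


def reference_fixture(
    survey_year: int = 2017,
) -> tuple[list[Location], list[SurveyRecord]]:
    """Small named-city fixture: locations plus survey records.

    Detected cities get a ``detected`` record at ``survey_year``;
    the others get a ``not_detected`` record.  Approximate, for smoke tests
    and documentation — not a survey dataset.
    """
    locations = [
        Location(
            id=name.lower().replace(" ", "_").replace(".", ""),
            name=name,
            country=country,
            region=region,
            lat=lat,
            lon=lon,
        )
        for name, country, region, lat, lon, _ in _REFERENCE_CITIES
    ]
    surveys = [
        SurveyRecord(
            location_id=loc.id,
            year=survey_year,
            outcome="detected" if det else "not_detected",
        )
        for loc, (*_, det) in zip(locations, _REFERENCE_CITIES)
    ]
    return locations, surveys
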