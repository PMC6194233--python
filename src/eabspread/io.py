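"""CSV loaders/writers and run configuration.

File dialects:

* location CSV — header ``id,name,country,region,lat,lon``, UTF-8,
  decimal point, one row per city;
* survey CSV — header ``location_id,year,outcome`` with outcome
  ``detected`` or ``not_detected`` (case-insensitive);
* distance export — long upper-triangle CSV ``id_i,id_j,distance_km``;
* trajectory export — long CSV ``id,year,probability,percent``.

Malformed rows are reported with their line number (header = line 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from eabspread.calibration import SurveyRecord
from eabspread.geo_network import (
    EARTH_RADIUS_KM,
    DistanceMatrix,
    Location,
    ValidationError,
    locations_to_frame,
)
from eabspread.reporting import DEFAULT_CUTS
from eabspread.spread_model import ProbabilityTrajectory


def load_locations(path: str | Path) -> list[Location]:
    df = pd.read_csv(path, dtype={"id": str, "name": str, "country": str, "region": str})
    required = ["id", "name", "country", "region", "lat", "lon"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    out = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                Location(
                    id=row.id,
                    name=row.name,
                    country=row.country,
                    region=row.region,
                    lat=float(row.lat),
                    lon=float(row.lon),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}:{pos}: {exc}") from exc
    return out


def save_locations(locations: Sequence[Location], path: str | Path) -> None:
    locations_to_frame(locations).to_csv(path, index=False)


def load_surveys(path: str | Path) -> list[SurveyRecord]:
    df = pd.read_csv(path, dtype={"location_id": str, "outcome": str})
    required = ["location_id", "year", "outcome"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    out = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                SurveyRecord(
                    location_id=row.location_id,
                    year=int(row.year),
                    outcome=row.outcome,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}:{pos}: {exc}") from exc
    return out


def save_surveys(surveys: Sequence[SurveyRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "location_id": [s.location_id for s in surveys],
            "year": [s.year for s in surveys],
            "outcome": [s.outcome for s in surveys],
        }
    ).to_csv(path, index=False)


def save_distances(D: DistanceMatrix, path: str | Path) -> None:
    D.to_long_frame().to_csv(path, index=False)


def save_trajectory(traj: ProbabilityTrajectory, path: str | Path) -> None:
    traj.to_long_frame().to_csv(path, index=False)


def save_geojson(collection: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(collection, indent=2), encoding="utf-8")


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=str), encoding="utf-8")


@dataclass
class RunConfig:
    """Configuration of a full model run.

    Years must be ordered start <= calibration <= verification <= forecast;
    the defaults follow the European EAB invasion timeline (first record
    2003, calibration surveys 2015, verification surveys 2017, five-year
    forecast horizon 2022).
    """

    locations: str = ""
    surveys: str = ""
    seed_id: str = ""
    kernel_family: str = "cauchy"
    kernel_theta: float | str = "calibrate"  # positive number or "calibrate"
    start_year: int = 2003
    calibration_year: int = 2015
    verification_year: int = 2017
    forecast_year: int = 2022
    band_cuts: tuple[float, ...] = DEFAULT_CUTS
    earth_radius_km: float = EARTH_RADIUS_KM
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        years = (
            self.start_year,
            self.calibration_year,
            self.verification_year,
            self.forecast_year,
        )
        if any(b < a for a, b in zip(years, years[1:])):
            raise ValidationError(
                f"years must satisfy start <= calibration <= verification <= "
                f"forecast, got {years}"
            )
        if self.kernel_theta != "calibrate":
            self.kernel_theta = float(self.kernel_theta)
            if self.kernel_theta <= 0:
                raise ValidationError("kernel theta must be positive or 'calibrate'")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Read a YAML/key-value config file; keyword overrides win."""
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: expected key: value mapping")
        kernel = raw.pop("kernel", None)
        if isinstance(kernel, dict):
            raw.setdefault("kernel_family", kernel.get("family", "cauchy"))
            raw.setdefault("kernel_theta", kernel.get("theta", "calibrate"))
        known = {f for f in cls.__dataclass_fields__ if f != "extras"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extras = {k: v for k, v in raw.items() if k not in known}
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        if "band_cuts" in kwargs:
            kwargs["band_cuts"] = tuple(float(c) for c in kwargs["band_cuts"])
        return cls(extras=extras, **kwargs)
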