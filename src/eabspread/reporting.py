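"""Probability bands, survey-based verification, and regional summaries.

Model output is presented in four probability bands — <15%, 15–40%, 40–85%
and >85% — the scheme used for pest-risk maps: a city above 85% is treated
as almost certainly infested, a city in the middle bands as a survey
priority, a city below 15% as probably still free of the pest.  A boundary
value belongs to the higher band's interval lower edge, i.e. intervals are
[0,15), [15,40), [40,85), [85,100].

Verification compares calculated probabilities against independent survey
outcomes: every negative survey should sit at a modest probability, and
confirmed detections far from the invasion epicenter discriminate between
kernel families (only a fat tail gives them non-negligible probability).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from eabspread.geo_network import DistanceMatrix, Location, ValidationError
from eabspread.spread_model import ProbabilityTrajectory

DEFAULT_CUTS = (15.0, 40.0, 85.0)


def round_half_up_percent(p) -> np.ndarray:
    """Probability (0..1) to whole percent, ties rounded up (0.215 -> 22)."""
    return np.floor(np.asarray(p, dtype=float) * 100.0 + 0.5).astype(int)


@dataclass(frozen=True)
class BandScheme:
    """Strictly increasing percent cut points defining probability bands."""

    cuts: tuple[float, ...] = DEFAULT_CUTS

    def __post_init__(self) -> None:
        cuts = tuple(float(c) for c in self.cuts)
        if not cuts or any(not 0 < c < 100 for c in cuts):
            raise ValidationError(f"cut points {cuts} must lie in (0, 100)")
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValidationError(f"cut points {cuts} must be strictly increasing")
        object.__setattr__(self, "cuts", cuts)

    @property
    def labels(self) -> tuple[str, ...]:
        cuts = [f"{c:g}" for c in self.cuts]
        inner = [f"{a}-{b}%" for a, b in zip(cuts, cuts[1:])]
        return tuple([f"<{cuts[0]}%"] + inner + [f">{cuts[-1]}%"])


def classify_bands(
    probabilities: Sequence[float], scheme: BandScheme = BandScheme()
) -> list[str]:
    """Band label for each probability (0..1).

    A value equal to a cut point falls in the band whose range starts
    there: 0.15 -> "15-40%".
    """
    p = np.asarray(probabilities, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValidationError("probabilities outside [0, 1]")
    idx = np.searchsorted(np.asarray(scheme.cuts), p * 100.0, side="right")
    labels = scheme.labels
    return [labels[i] for i in idx]


def verification_table(
    traj: ProbabilityTrajectory,
    survey_outcomes: Mapping[str, int],
    year: int,
    scheme: BandScheme = BandScheme(),
    D: DistanceMatrix | None = None,
    seed_id: str | None = None,
    remote_km: float = 200.0,
) -> dict:
    """Contingency of survey outcomes vs model probability bands.

    ``survey_outcomes`` maps location id -> 1 (detected) or 0 (negative
    survey).  Returns a dict with:

    ``table``
        DataFrame of counts, one row per band, columns ``detected`` and
        ``not_detected``.
    ``max_negative``
        Largest model probability among negative-survey cities (NaN if
        none) — a well-calibrated model keeps this moderate.
    ``remote_positive_range``
        (min, max) model probability among detected cities farther than
        ``remote_km`` from ``seed_id`` (requires ``D`` and ``seed_id``;
        (NaN, NaN) if none qualify).  Thin-tailed kernels collapse this
        range toward zero; a fat tail keeps it appreciable.
    """
    for lid in survey_outcomes:
        if lid not in traj.ids:
            raise ValidationError(f"survey at unknown location id {lid!r}")
    P = traj.at_year(year)
    bands = classify_bands(P, scheme)
    by_id = dict(zip(traj.ids, zip(P, bands)))

    counts = pd.DataFrame(
        0, index=list(scheme.labels), columns=["detected", "not_detected"]
    )
    neg_probs, pos_remote = [], []
    for lid, y in survey_outcomes.items():
        p, band = by_id[lid]
        counts.loc[band, "detected" if y else "not_detected"] += 1
        if not y:
            neg_probs.append(p)
        elif D is not None and seed_id is not None:
            if D.d[D.index_of(seed_id), D.index_of(lid)] > remote_km:
                pos_remote.append(p)
    return {
        "table": counts,
        "max_negative": float(max(neg_probs)) if neg_probs else float("nan"),
        "remote_positive_range": (
            (float(min(pos_remote)), float(max(pos_remote)))
            if pos_remote
            else (float("nan"), float("nan"))
        ),
    }


def regional_max(
    traj: ProbabilityTrajectory,
    locations: Sequence[Location],
    year: int,
    group_by: str = "region",
) -> pd.DataFrame:
    """Maximum detection probability per country or administrative region.

    Returns a DataFrame indexed by group with columns ``probability``
    (full precision) and ``percent`` (whole percent, round-half-up),
    sorted by descending probability.
    """
    if group_by not in ("country", "region"):
        raise ValidationError(f"group_by={group_by!r} must be 'country' or 'region'")
    P = traj.at_year(year)
    by_id = dict(zip(traj.ids, P))
    rows: dict[str, float] = {}
    for loc in locations:
        if loc.id not in by_id:
            raise ValidationError(f"location {loc.id!r} not in trajectory")
        g = getattr(loc, group_by)
        rows[g] = max(rows.get(g, 0.0), by_id[loc.id])
    out = pd.DataFrame(
        {"probability": pd.Series(rows)}
    ).sort_values("probability", ascending=False)
    out["percent"] = round_half_up_percent(out["probability"].to_numpy())
    out.index.name = group_by
    return out


def to_geojson(
    locations: Sequence[Location],
    traj: ProbabilityTrajectory,
    year: int,
    scheme: BandScheme = BandScheme(),
) -> dict:
    """RFC 7946 FeatureCollection of Point features (lon, lat order).

    Each feature carries name, country, region, probability, band and year
    properties, ready for any web map.
    """
    P = traj.at_year(year)
    by_id = dict(zip(traj.ids, P))
    bands = dict(zip(traj.ids, classify_bands(P, scheme)))
    features = []
    for loc in locations:
        if loc.id not in by_id:
            raise ValidationError(f"location {loc.id!r} not in trajectory")
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [loc.lon, loc.lat]},
                "properties": {
                    "id": loc.id,
                    "name": loc.name,
                    "country": loc.country,
                    "region": loc.region,
                    "probability": float(by_id[loc.id]),
                    "band": bands[loc.id],
                    "year": int(year),
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}
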