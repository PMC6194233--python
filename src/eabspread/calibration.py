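"""Least-squares calibration of the kernel parameter against survey labels.

Binary labels are built from presence/absence survey records at a reference
year: 1 where the pest had been detected by that year, 0 where at least one
survey up to that year was negative and no detection exists.  The kernel
parameter is then chosen to minimize the sum of squared differences between
the model's calculated detection probabilities at the reference year and
the assigned 0/1 labels.

The objective is one-dimensional and smooth in theta, so the optimizer is
deliberately simple and reproducible: a log-spaced grid scan followed by
bounded scalar refinement on the bracketing interval.  Boundary hits are
reported, never silently accepted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from eabspread.geo_network import DistanceMatrix, ValidationError
from eabspread.kernels import PARAM_SYMBOL, Kernel
from eabspread.spread_model import simulate

logger = logging.getLogger(__name__)

DETECTED = "detected"
NOT_DETECTED = "not_detected"

DEFAULT_BOUNDS = (1e-6, 1e3)
DEFAULT_GRID_POINTS = 200
DEFAULT_RTOL = 1e-6


@dataclass(frozen=True)
class SurveyRecord:
    """One survey outcome: a location, a year, detected or not."""

    location_id: str
    year: int
    outcome: str

    def __post_init__(self) -> None:
        out = self.outcome.strip().lower()
        if out not in (DETECTED, NOT_DETECTED):
            raise ValidationError(
                f"outcome {self.outcome!r} must be '{DETECTED}' or '{NOT_DETECTED}'"
            )
        object.__setattr__(self, "outcome", out)
        object.__setattr__(self, "year", int(self.year))


@dataclass(frozen=True)
class LabelSet:
    """Binary labels (id -> 0/1) at a reference year."""

    reference_year: int
    labels: dict[str, int]

    @property
    def n_pos(self) -> int:
        return sum(1 for v in self.labels.values() if v == 1)

    @property
    def n_neg(self) -> int:
        return sum(1 for v in self.labels.values() if v == 0)

    def positives(self) -> list[str]:
        return [k for k, v in self.labels.items() if v == 1]

    def negatives(self) -> list[str]:
        return [k for k, v in self.labels.items() if v == 0]


def build_labels(surveys: Sequence[SurveyRecord], reference_year: int) -> LabelSet:
    """Collapse survey records into 0/1 labels at ``reference_year``.

    A location is labelled 1 if it has any detection at or before the
    reference year; 0 if it has at least one negative survey at or before
    the reference year and no such detection; locations with no usable
    record are excluded.  A detection always overrides negative surveys,
    including a negative survey from the same year (a warning is logged for
    that conflict, since the pest often goes unnoticed for years).
    """
    det_years: dict[str, set[int]] = {}
    neg_years: dict[str, set[int]] = {}
    for rec in surveys:
        if rec.year > reference_year:
            continue
        bucket = det_years if rec.outcome == DETECTED else neg_years
        bucket.setdefault(rec.location_id, set()).add(rec.year)
    labels: dict[str, int] = {}
    for lid, years in det_years.items():
        clash = years & neg_years.get(lid, set())
        if clash:
            logger.warning(
                "location %s has both detected and not_detected records in "
                "year(s) %s; detection wins",
                lid,
                sorted(clash),
            )
        labels[lid] = 1
    for lid in neg_years:
        labels.setdefault(lid, 0)
    return LabelSet(reference_year=int(reference_year), labels=labels)


def sse_objective(
    theta: float,
    family: str,
    D: DistanceMatrix,
    labels: LabelSet | Mapping[str, int],
    seed_ids: Sequence[str] | str,
    start_year: int,
) -> float:
    """Sum of squared differences between model probabilities and labels.

    Runs the recursion from ``start_year`` to the label set's reference
    year with Kernel(family, theta) and sums (P_j - y_j)^2 over labelled
    locations.  Labelled locations missing from the network are an error —
    dropping them silently would corrupt the fit.
    """
    if isinstance(labels, LabelSet):
        ref_year, lab = labels.reference_year, labels.labels
    else:
        raise TypeError("labels must be a LabelSet (reference year is required)")
    traj = simulate(D, Kernel(family, theta), seed_ids, start_year, ref_year)
    P = traj.at_year(ref_year)
    idx = np.array([D.index_of(i) for i in lab], dtype=int)
    y = np.array([lab[i] for i in lab], dtype=float)
    return float(np.sum((P[idx] - y) ** 2))


@dataclass(frozen=True)
class FitResult:
    """Outcome of a kernel-parameter fit."""

    kernel: Kernel
    sse: float
    n_pos: int
    n_neg: int
    bounds: tuple[float, float]
    at_boundary: bool
    family: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", self.kernel.family)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "parameter": PARAM_SYMBOL[self.family],
            "theta": self.kernel.theta,
            "sse": self.sse,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "search_bounds": list(self.bounds),
            "at_boundary": self.at_boundary,
        }


def fit_kernel_parameter(
    family: str,
    D: DistanceMatrix,
    labels: LabelSet,
    seed_ids: Sequence[str] | str,
    start_year: int,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    grid_points: int = DEFAULT_GRID_POINTS,
    rtol: float = DEFAULT_RTOL,
) -> FitResult:
    """Least-squares fit of the kernel parameter for one family.

    Scans ``grid_points`` log-spaced thetas over ``bounds``, then refines
    the best bracket with bounded scalar minimization to relative tolerance
    ``rtol``.  Requires at least one positive and one negative label;
    otherwise the objective is unbounded toward a trivial kernel.
    """
    if labels.n_pos == 0 or labels.n_neg == 0:
        raise ValidationError(
            "degenerate label set; objective unbounded toward a trivial kernel "
            f"(n_pos={labels.n_pos}, n_neg={labels.n_neg})"
        )
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValidationError(f"invalid search bounds {bounds!r}")
    grid = np.logspace(np.log10(lo), np.log10(hi), grid_points)
    values = np.array(
        [sse_objective(t, family, D, labels, seed_ids, start_year) for t in grid]
    )
    if not np.all(np.isfinite(values)):
        raise ValidationError("objective not finite over the search grid")
    k = int(np.argmin(values))
    blo = grid[max(k - 1, 0)]
    bhi = grid[min(k + 1, grid_points - 1)]
    res = minimize_scalar(
        lambda t: sse_objective(t, family, D, labels, seed_ids, start_year),
        bounds=(blo, bhi),
        method="bounded",
        options={"xatol": rtol * grid[k]},
    )
    theta, sse = float(res.x), float(res.fun)
    if values[k] < sse:  # refinement should never lose to the grid
        theta, sse = float(grid[k]), float(values[k])
    at_boundary = k == 0 or k == grid_points - 1
    if at_boundary:
        warnings.warn(
            f"fitted {PARAM_SYMBOL[family]} = {theta:.6g} sits at the search "
            f"boundary of {bounds}; the objective may be monotone in theta",
            stacklevel=2,
        )
    logger.info(
        "fit %s: %s=%.6g sse=%.6g n_pos=%d n_neg=%d",
        family,
        PARAM_SYMBOL[family],
        theta,
        sse,
        labels.n_pos,
        labels.n_neg,
    )
    return FitResult(
        kernel=Kernel(family, theta),
        sse=sse,
        n_pos=labels.n_pos,
        n_neg=labels.n_neg,
        bounds=(lo, hi),
        at_boundary=at_boundary,
    )
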