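"""Recurrent yearly propagation of detection probability across the network.

Each year, every city j can receive the pest independently from every city
i with probability P_i(t) * f(d_ij), where P_i(t) is the current detection
probability at i and f the dispersal kernel.  The chance that at least one
of these independent introductions succeeds is a complement product:

    P_j(t+1) = 1 - prod_i ( 1 - P_i(t) * f(d_ij) )

The product runs over all i including i = j; because f(0) = 1 the self term
contributes (1 - P_j(t)), which makes establishment absorbing: once a city
is (probably) infested it stays so, and P_j is non-decreasing in time.  The
recursion is deterministic — it propagates probabilities, not realizations.

Products are accumulated as sums of log1p(-x) for numerical robustness,
with an exact-zero guard for any certain source (x = 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from eabspread.geo_network import DistanceMatrix, ValidationError
from eabspread.kernels import Kernel, evaluate


@dataclass(frozen=True)
class ProbabilityTrajectory:
    """Per-city detection probability over an inclusive span of years.

    ``P`` has one row per year (``years[0]`` first) and one column per
    location in ``ids`` order.
    """

    ids: tuple[str, ...]
    years: tuple[int, ...]
    P: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.shape != (len(self.years), len(self.ids)):
            raise ValidationError(
                f"trajectory shape {P.shape} != ({len(self.years)}, {len(self.ids)})"
            )
        if np.any(P < 0) or np.any(P > 1):
            raise ValidationError("trajectory probabilities outside [0, 1]")
        years = tuple(int(y) for y in self.years)
        if list(years) != list(range(years[0], years[-1] + 1)):
            raise ValidationError("years must be consecutive integers")
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "years", years)

    def at_year(self, year: int) -> np.ndarray:
        """Probability vector for one year (copy)."""
        if year not in self.years:
            raise ValidationError(
                f"year {year} outside trajectory span {self.years[0]}-{self.years[-1]}"
            )
        return self.P[year - self.years[0]].copy()

    def to_long_frame(self) -> pd.DataFrame:
        """Long format id,year,probability plus a rounded-percent column."""
        ny, n = self.P.shape
        return pd.DataFrame(
            {
                "id": np.tile(self.ids, ny),
                "year": np.repeat(self.years, n),
                "probability": self.P.ravel(),
                "percent": np.floor(self.P.ravel() * 100.0 + 0.5).astype(int),
            }
        )


def _transfer_complement_log(P_now: np.ndarray, F: np.ndarray) -> np.ndarray:
    """log prod_i (1 - P_i * F_ij) per column j, with -inf for certain sources."""
    X = P_now[:, None] * F
    with np.errstate(divide="ignore"):
        logs = np.log1p(-np.where(X >= 1.0, 1.0, X))
    return logs.sum(axis=0)


def annual_step(P_now: np.ndarray, D: DistanceMatrix, kernel: Kernel) -> np.ndarray:
    """One year of the complement-product recurrence.

    Returns P(t+1) aligned with ``D.ids``; elementwise >= P_now because the
    i = j self term (f(0) = 1) makes establishment absorbing.
    """
    P_now = np.asarray(P_now, dtype=float)
    if P_now.shape != (D.n,):
        raise ValidationError(f"probability vector shape {P_now.shape} != ({D.n},)")
    if np.any(P_now < 0) or np.any(P_now > 1):
        raise ValidationError("probabilities outside [0, 1]")
    F = evaluate(kernel, D.d)
    log_c = _transfer_complement_log(P_now, F)
    P_next = -np.expm1(log_c)  # 1 - exp(log complement)
    return np.clip(P_next, 0.0, 1.0)


def simulate(
    D: DistanceMatrix,
    kernel: Kernel,
    seed_ids: Sequence[str] | str,
    start_year: int,
    end_year: int,
) -> ProbabilityTrajectory:
    """Run the recursion from seed cities at probability 1.

    P(start_year) is 1 at every seed and 0 elsewhere; each later year
    applies :func:`annual_step` once, so reaching year start_year + k takes
    k steps.
    """
    if isinstance(seed_ids, str):
        seed_ids = [seed_ids]
    if int(end_year) < int(start_year):
        raise ValidationError(f"end_year {end_year} before start_year {start_year}")
    P0 = np.zeros(D.n)
    for sid in seed_ids:
        P0[D.index_of(sid)] = 1.0
    return _run(P0, D, kernel, int(start_year), int(end_year))


def _run(
    P0: np.ndarray, D: DistanceMatrix, kernel: Kernel, start_year: int, end_year: int
) -> ProbabilityTrajectory:
    years = range(start_year, end_year + 1)
    rows = [np.asarray(P0, dtype=float)]
    F = evaluate(kernel, D.d)
    for _ in range(start_year, end_year):
        log_c = _transfer_complement_log(rows[-1], F)
        rows.append(np.clip(-np.expm1(log_c), 0.0, 1.0))
    return ProbabilityTrajectory(ids=D.ids, years=tuple(years), P=np.vstack(rows))


def condition_on_detections(
    traj: ProbabilityTrajectory,
    detections: Iterable[str] | Mapping[str, int],
    at_year: int,
) -> np.ndarray:
    """The ``at_year`` probability vector with detected cities set to 1.

    ``detections`` is an iterable of detected location ids, or a mapping of
    id -> {0, 1} label from which the positives are taken.  Used before
    forecasting so that confirmed field detections override the model's own
    (possibly lower) calculated probabilities.
    """
    vec = traj.at_year(at_year)
    if isinstance(detections, Mapping):
        ids = [k for k, v in detections.items() if v]
    else:
        ids = list(detections)
    for sid in ids:
        i = traj.ids.index(sid) if sid in traj.ids else -1
        if i < 0:
            raise ValidationError(f"detection at unknown location id {sid!r}")
        vec[i] = 1.0
    return vec


def forecast(
    conditioned: np.ndarray,
    D: DistanceMatrix,
    kernel: Kernel,
    from_year: int,
    to_year: int,
) -> ProbabilityTrajectory:
    """Continue the recursion from an arbitrary (conditioned) start vector."""
    conditioned = np.asarray(conditioned, dtype=float)
    if conditioned.shape != (D.n,):
        raise ValidationError(
            f"conditioned vector shape {conditioned.shape} != ({D.n},)"
        )
    if np.any(conditioned < 0) or np.any(conditioned > 1):
        raise ValidationError("conditioned probabilities outside [0, 1]")
    if int(to_year) < int(from_year):
        raise ValidationError(f"to_year {to_year} before from_year {from_year}")
    return _run(conditioned, D, kernel, int(from_year), int(to_year))
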