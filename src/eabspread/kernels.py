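"""Single-parameter annual dispersal kernels.

A kernel maps the distance d (km) between two cities to the annual
probability that the pest is carried from an infested city to the other.
Three families are supported, each with one positive parameter:

    exponential:  f(d) = exp(-alpha * d)        alpha in 1/km
    normal:       f(d) = exp(-beta * d**2)      beta  in 1/km**2
    cauchy:       f(d) = 1 / (1 + (d/gamma)**2) gamma in km

All satisfy f(0) = 1, are strictly decreasing in d, and never reach zero.
The Cauchy kernel is fat-tailed: for large d it dominates any exponential
or Gaussian kernel, which is what lets the model reproduce rare very-long
human-mediated jumps.  Kernels are used directly as city-to-city transfer
probabilities (not as spatial densities), so no normalization over space
is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

FAMILIES = ("exponential", "normal", "cauchy")

#: Conventional parameter symbol per family, used in reports.
PARAM_SYMBOL = {"exponential": "alpha", "normal": "beta", "cauchy": "gamma"}


@dataclass(frozen=True)
class Kernel:
    """Dispersal kernel: a family tag plus its single positive parameter."""

    family: str
    theta: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}; choose from {FAMILIES}")
        if not np.isfinite(self.theta) or self.theta <= 0:
            raise ValueError(f"kernel parameter theta={self.theta!r} must be positive")

    def __call__(self, d):
        return evaluate(self, d)

    def half_distance(self) -> float:
        """Distance at which the annual transfer probability drops to 1/2."""
        if self.family == "exponential":
            return float(np.log(2.0) / self.theta)
        if self.family == "normal":
            return float(np.sqrt(np.log(2.0) / self.theta))
        return float(self.theta)  # cauchy: f(gamma) = 1/2 by construction


def evaluate(kernel: Kernel, d):
    """Annual transfer probability at distance ``d`` (km, scalar or array).

    Returns values in (0, 1]; raises on negative distances.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    if kernel.family == "exponential":
        out = np.exp(-kernel.theta * d)
    elif kernel.family == "normal":
        out = np.exp(-kernel.theta * d * d)
    else:
        out = 1.0 / (1.0 + (d / kernel.theta) ** 2)
    return out if out.ndim else float(out)


def tail_order(d: float, kernels: dict[str, Kernel] | list[Kernel]) -> list[str]:
    """Rank kernel families by transfer probability at distance ``d``.

    Returns family names sorted from the largest kernel value to the
    smallest.  For calibrated kernels and sufficiently large d the order is
    cauchy > exponential > normal — the fat tail dominates.
    """
    if isinstance(kernels, dict):
        items = list(kernels.items())
    else:
        items = [(k.family, k) for k in kernels]
    if len({fam for fam, _ in items}) != len(items):
        raise ValueError("duplicate kernel families in ranking")
    return [fam for fam, _ in sorted(items, key=lambda kv: evaluate(kv[1], d), reverse=True)]
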