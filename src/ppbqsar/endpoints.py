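"""Endpoint transformations for fraction-unbound (fu) data.

Plasma-protein-binding activity is usually reported as the fraction unbound
fu in (0, 1].  Raw fu is strongly right-skewed in drug-like collections
(highly bound compounds pile up below fu = 0.1), which makes it a poor
regression target.  Two standard transformations are provided:

* a pseudo-equilibrium constant ``logK = log10((1 - fu) / fu)``, the
  bound/free ratio on a log scale, with the convention that a fully
  unbound compound (fu = 1) is assigned logK = 2; and
* the square root of fu.

Both spread the low-fu mass and reduce the sample skewness gamma_1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TRANSFORMS",
    "EndpointVector",
    "to_logK",
    "invert_logK",
    "to_sqrt_fu",
    "skewness",
    "transform_endpoint",
]

#: Recognized endpoint scales.
TRANSFORMS = ("fu", "logK", "sqrt_fu")

#: Value assigned to logK when fu is exactly 1 (no measurable bound fraction).
LOGK_AT_FU_ONE = 2.0


def _check_fu(fu: float) -> None:
    if not (0.0 < fu <= 1.0):
        raise ValueError(f"fu must lie in (0, 1], got {fu!r}")


def to_logK(fu: float) -> float:
    """Pseudo-equilibrium constant log10((1 - fu)/fu).

    A compound that is 100% unbound has no bound fraction and the ratio is
    degenerate; by convention the transform returns exactly 2.0 there.
    """
    _check_fu(fu)
    if fu == 1.0:
        return LOGK_AT_FU_ONE
    return math.log10((1.0 - fu) / fu)


def invert_logK(logk: float) -> float:
    """Inverse of :func:`to_logK` for values not produced by the fu=1 rule."""
    return 1.0 / (1.0 + 10.0 ** logk)


def to_sqrt_fu(fu: float) -> float:
    """Square root of the fraction unbound."""
    _check_fu(fu)
    return math.sqrt(fu)


def skewness(values: Iterable[float]) -> float:
    """Adjusted Fisher--Pearson sample skewness gamma_1.

    Requires at least three observations with nonzero variance; a constant
    vector has undefined skewness and raises ``ValueError``.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 3:
        raise ValueError("skewness requires at least 3 observations")
    if np.ptp(arr) == 0 or np.std(arr) == 0:
        raise ValueError("skewness undefined for a constant vector")
    return float(stats.skew(arr, bias=False))


@dataclass
class EndpointVector:
    """Transformed activities aligned with their compound ids."""

    values: np.ndarray
    transform: str
    source_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.transform not in TRANSFORMS:
            raise ValueError(
                f"unknown transform {self.transform!r}; expected one of {TRANSFORMS}"
            )
        if len(self.source_ids) != len(self.values):
            raise ValueError("values and source_ids must be aligned")

    def __len__(self) -> int:
        return len(self.values)


def transform_endpoint(
    fu_values: Sequence[float], source_ids: Sequence, transform: str = "logK"
) -> EndpointVector:
    """Apply one of the registered transforms to a vector of fu values."""
    if transform == "fu":
        vals = [float(v) for v in fu_values]
        for v in vals:
            _check_fu(v)
    elif transform == "logK":
        vals = [to_logK(v) for v in fu_values]
    elif transform == "sqrt_fu":
        vals = [to_sqrt_fu(v) for v in fu_values]
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return EndpointVector(np.array(vals), transform, list(source_ids))
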