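"""Activity-stratified train/test splitting and the three-way sub-split.

The main split stratifies on the endpoint: values are binned into a fixed
number of equal-width intervals spanning the observed range, and each
non-empty bin is divided 80:20 (by default) into a training set (TS) and an
external validation set (EVS).  This keeps the activity distribution of the
two sets comparable even for strongly skewed endpoints.

For optimal-SMILES-descriptor modelling the TS is further partitioned at
random into a visible training set, an invisible training set (ITS) used to
monitor overfitting during the Monte-Carlo weight optimization, and a
calibration set (CS) on which the residual-balance index is computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .endpoints import EndpointVector

__all__ = ["SplitAssignment", "activity_binned_split", "coral_subsplit"]


@dataclass
class SplitAssignment:
    role: dict  # compound id -> "TS" | "EVS"
    subrole: dict = field(default_factory=dict)  # TS id -> "TS" | "ITS" | "CS"
    seed: int | None = None
    n_bins: int = 5
    ratio: float = 0.8

    def ids(self, role: str) -> list:
        return [i for i, r in self.role.items() if r == role]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def activity_binned_split(
    endpoint: EndpointVector,
    ratio: float = 0.8,
    n_bins: int = 5,
    seed: int | None = None,
    binning: str = "width",
) -> SplitAssignment:
    """Stratified TS/EVS split on fixed activity ranges.

    ``binning="width"`` uses equal-width intervals spanning [min, max];
    ``binning="count"`` uses quantile (equal-count) bins instead.  The
    overall TS size is round(ratio * n) (half-away-from-zero) and is
    apportioned over the non-empty bins proportionally to their sizes by
    the largest-remainder rule, so stratification is exact: each bin's TS
    fraction deviates from the ratio by less than one compound.  Members
    are drawn uniformly at random (seeded) within each bin.
    """
    n = len(endpoint)
    if n == 0:
        raise ValueError("empty endpoint")
    if n < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} compounds, got {n}")
    if not (0.0 < ratio <= 1.0):
        raise ValueError("ratio must lie in (0, 1]")
    values = np.asarray(endpoint.values, dtype=float)
    if np.ptp(values) == 0:
        raise ValueError("endpoint has zero range; cannot stratify")
    ids = np.asarray(endpoint.source_ids, dtype=object)

    if binning == "width":
        edges = np.linspace(values.min(), values.max(), n_bins + 1)
    elif binning == "count":
        edges = np.quantile(values, np.linspace(0, 1, n_bins + 1))
    else:
        raise ValueError(f"unknown binning mode {binning!r}")
    # rightmost edge inclusive
    bin_idx = np.clip(np.searchsorted(edges, values, side="right") - 1, 0, n_bins - 1)

    rng = np.random.default_rng(seed)
    bins = [np.where(bin_idx == b)[0] for b in range(n_bins)]
    bins = [m for m in bins if m.size > 0]  # skip empty bins silently
    total_ts = min(n, _round_half_away(ratio * n))
    quotas = [ratio * m.size for m in bins]
    n_ts = [int(math.floor(q)) for q in quotas]
    remainder = total_ts - sum(n_ts)
    order = sorted(
        range(len(bins)), key=lambda b: (quotas[b] - n_ts[b], -bins[b].size)
    )[::-1]
    for b in order:
        if remainder <= 0:
            break
        if n_ts[b] < bins[b].size:
            n_ts[b] += 1
            remainder -= 1
    role: dict = {}
    for members, k_ts in zip(bins, n_ts):
        perm = rng.permutation(members.size)
        for k, j in enumerate(perm):
            role[ids[members[j]]] = "TS" if k < k_ts else "EVS"
    return SplitAssignment(role=role, seed=seed, n_bins=n_bins, ratio=ratio)


def largest_remainder_sizes(n: int, fractions) -> list[int]:
    """Integer set sizes summing to n, proportional to fractions."""
    fractions = list(fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    raw = [f * n for f in fractions]
    sizes = [int(math.floor(r)) for r in raw]
    remainder = n - sum(sizes)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - sizes[i], reverse=True)
    for i in order[:remainder]:
        sizes[i] += 1
    return sizes


def coral_subsplit(
    ts_ids, fractions=(108 / 391, 140 / 391, 143 / 391), seed: int | None = None
) -> dict:
    """Random partition of the TS into sub-TS / ITS / CS.

    Sizes follow the fractions with largest-remainder rounding so they sum
    to ``len(ts_ids)``.  Default fractions follow the 108/140/143 pattern of
    a 391-compound training set.
    """
    ts_ids = list(ts_ids)
    if len(fractions) != 3:
        raise ValueError("fractions must be a triple")
    sizes = largest_remainder_sizes(len(ts_ids), fractions)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ts_ids))
    subrole = {}
    labels = ["TS"] * sizes[0] + ["ITS"] * sizes[1] + ["CS"] * sizes[2]
    for j, lab in zip(order, labels):
        subrole[ts_ids[j]] = lab
    return subrole
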