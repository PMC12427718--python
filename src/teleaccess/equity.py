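"""Equity and dispersion statistics over accessibility profiles.

Two spread measures drive the analysis: the absolute gap ``a_max - a_min``
and the equilibrium index ``(a_max - a_min) / (a_max + a_min)``, a Gini-like
ratio in [0, 1] that the allocation optimizer bounds from above.  A
population-weighted Gini coefficient is provided as a reporting companion.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from .core import AccessProfile

__all__ = [
    "EquityReport",
    "accessibility_gap",
    "equilibrium_index",
    "gini_coefficient",
    "compute_report",
]


def _totals(profile) -> np.ndarray:
    values = profile.a_total if isinstance(profile, AccessProfile) else profile
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty accessibility profile")
    return arr


@dataclass(frozen=True)
class EquityReport:
    """Summary statistics of one accessibility distribution."""

    mean: float
    a_min: float
    a_max: float
    gap: float
    equilibrium_index: float
    gini: float

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)


def accessibility_gap(profile) -> float:
    """Absolute spread a_max - a_min of the combined index."""
    a = _totals(profile)
    return float(a.max() - a.min())


def equilibrium_index(profile) -> float:
    """(a_max - a_min) / (a_max + a_min); 0 for an all-zero profile.

    Scale-invariant: rescaling every division's index leaves it unchanged.
    """
    a = _totals(profile)
    hi, lo = float(a.max()), float(a.min())
    if hi + lo == 0.0:
        return 0.0
    return (hi - lo) / (hi + lo)


def gini_coefficient(profile, weights: Sequence[float] | None = None) -> float:
    """Gini coefficient of accessibility, population-weighted by default.

    Equals sum_ij w_i w_j |a_i - a_j| / (2 W sum_i w_i a_i); 0 for an equal
    (or all-zero) distribution.  Pass ``weights=None`` with a plain array for
    the unweighted version.
    """
    a = _totals(profile)
    if np.any(a < 0):
        raise ValueError("accessibility values must be nonnegative")
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != a.shape or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive total, one per division")
    total = float(w @ a)
    if total == 0.0:
        return 0.0
    order = np.argsort(a, kind="stable")
    a, w = a[order], w[order]
    cw = np.cumsum(w)
    cs = np.cumsum(w * a)
    # sum over ordered pairs i<j of w_i w_j (a_j - a_i), doubled
    below_w = cw - w
    below_s = cs - w * a
    pairwise = 2.0 * float(np.sum(w * (a * below_w - below_s)))
    return pairwise / (2.0 * float(w.sum()) * total)


def compute_report(profile, weights: Sequence[float] | None = None) -> EquityReport:
    """Assemble an EquityReport (mean, extremes, gap, equilibrium index, Gini)."""
    a = _totals(profile)
    return EquityReport(
        mean=float(a.mean()),
        a_min=float(a.min()),
        a_max=float(a.max()),
        gap=accessibility_gap(a),
        equilibrium_index=equilibrium_index(a),
        gini=gini_coefficient(a, weights),
    )
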