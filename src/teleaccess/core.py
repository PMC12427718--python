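"""Domain types and the i2SFCA-TH accessibility equations.

The improved two-step floating catchment area method with tele-health
(i2SFCA-TH) scores each residential division k with a supply-per-demand
accessibility index built from three components:

* ``a_k^c`` — offline access to community hospitals (gravity 2SFCA with a
  power-law distance decay ``f(d) = d^-beta``),
* ``a_k^a`` — offline access to tertiary-A hospitals, reached through a
  hierarchical referral with rate ``r``,
* ``a_k^v`` — online (tele-health) access, distance-free, fed by the
  physician time ``V_i`` each tertiary hospital dedicates to online visits.

The combined index is

    a_k = (1 - Q_k) * [(1 - r) * a_k^c + r * a_k^a] + Q_k * a_k^v

where ``Q_k`` is the fraction of division k's chronic-disease demand that
prefers online service.  ``Q_k`` is two-tier: divisions whose purely offline
accessibility falls below the regional mean get the "poor-access" level
(default 0.35), the rest the "good-access" level (default 0.1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Tier",
    "DemandDivision",
    "SupplySite",
    "CostMatrix",
    "DecaySpec",
    "ModelParams",
    "Instance",
    "AccessProfile",
    "decay_weight",
    "supply_ratio",
    "offline_accessibility",
    "referral_accessibility",
    "online_accessibility",
    "combined_accessibility",
    "assign_online_preference",
    "compute_profile",
    "demand_vector",
]


class Tier(str, Enum):
    """Hospital tier: tertiary-A (referral + online) or community (first-line)."""

    tertiary_A = "tertiary_A"
    community = "community"


@dataclass(frozen=True)
class DemandDivision:
    """A residential division with its demand populations.

    ``coord`` is (lon, lat) or planar (x, y); it may be None when a cost
    matrix is supplied directly.  ``q_online`` is the online-preference
    fraction Q_k.
    """

    id: str
    pop_total: float
    pop_elderly: float
    pop_chronic: float
    coord: tuple[float, float] | None = None
    q_online: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pop_total", "pop_elderly", "pop_chronic"):
            if getattr(self, name) < 0:
                raise ValueError(f"division {self.id!r}: {name} must be >= 0")
        if not 0.0 <= self.q_online <= 1.0:
            raise ValueError(f"division {self.id!r}: q_online must lie in [0, 1]")


@dataclass(frozen=True)
class SupplySite:
    """A hospital: its tier, offline physician resource and online cap.

    ``resource_offline`` is measured in physician consultation-time units per
    day.  ``online_cap_fraction`` (rho_i) bounds the share of that resource a
    tertiary hospital may shift to online visits; community hospitals do not
    offer online consultations, so their cap is identically zero.
    """

    id: str
    tier: Tier
    resource_offline: float
    coord: tuple[float, float] | None = None
    online_cap_fraction: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "tier", Tier(self.tier))
        if self.resource_offline < 0:
            raise ValueError(f"site {self.id!r}: resource_offline must be >= 0")
        if not 0.0 <= self.online_cap_fraction <= 1.0:
            raise ValueError(f"site {self.id!r}: online_cap_fraction must lie in [0, 1]")
        if self.tier is Tier.community and self.online_cap_fraction != 0.0:
            raise ValueError(
                f"site {self.id!r}: community hospitals offer no online consultations "
                "(online_cap_fraction must be 0)"
            )


class CostMatrix:
    """Complete pairwise travel costs d_jk between sites (rows) and divisions (cols).

    Wraps a pandas DataFrame indexed by site id with division-id columns.
    Entries must be finite and nonnegative; the unit (km, minutes, ...) is
    recorded as metadata only.
    """

    def __init__(self, frame: pd.DataFrame, unit: str = "km") -> None:
        values = frame.to_numpy(dtype=float)
        if values.size and (not np.all(np.isfinite(values)) or np.any(values < 0)):
            raise ValueError("cost matrix entries must be finite and >= 0")
        if frame.index.has_duplicates or frame.columns.has_duplicates:
            raise ValueError("cost matrix has duplicate site or division ids")
        self.frame = frame.astype(float)
        self.unit = unit

    @classmethod
    def from_long(cls, records: pd.DataFrame, unit: str = "km") -> "CostMatrix":
        """Build from a tidy table with columns site_id, division_id, cost."""
        wide = records.pivot(index="site_id", columns="division_id", values="cost")
        if wide.isna().any().any():
            miss = next(
                (s, d)
                for s in wide.index
                for d in wide.columns
                if pd.isna(wide.at[s, d])
            )
            raise ValueError(f"cost matrix incomplete: missing pair {miss[0]!r} -> {miss[1]!r}")
        wide.index.name = None
        wide.columns.name = None
        return cls(wide, unit=unit)

    @property
    def site_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def division_ids(self) -> list[str]:
        return list(self.frame.columns)

    def value(self, site_id: str, division_id: str) -> float:
        return float(self.frame.at[site_id, division_id])

    def submatrix(self, site_ids: Sequence[str], division_ids: Sequence[str]) -> np.ndarray:
        """Dense (len(site_ids), len(division_ids)) cost block; KeyError if absent."""
        try:
            return self.frame.loc[list(site_ids), list(division_ids)].to_numpy(dtype=float)
        except KeyError as exc:
            raise ValueError(f"cost matrix missing entries: {exc}") from exc

    def to_long(self) -> pd.DataFrame:
        long = self.frame.rename_axis(index="site_id", columns="division_id").stack()
        return long.rename("cost").reset_index()


@dataclass(frozen=True)
class DecaySpec:
    """Power-law distance decay f(d) = max(d, d_floor)^(-beta).

    ``d0`` is an optional hard catchment cutoff (f = 0 beyond it); the default
    pipeline uses pure decay without a cutoff.  ``d_floor`` regularises the
    singularity at d = 0.
    """

    beta: float = 2.0
    d0: float | None = None
    d_floor: float = 0.1

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.d_floor <= 0:
            raise ValueError("d_floor must be > 0")
        if self.d0 is not None and self.d0 <= 0:
            raise ValueError("d0 must be > 0 when given")


_ONLINE_MODES = ("as_printed", "conserving")
_OFFLINE_MODES = ("resource_shift", "as_printed")
_STRATA = ("total", "elderly", "chronic")


@dataclass(frozen=True)
class ModelParams:
    """Behavioural parameters of the i2SFCA-TH combination.

    referral_rate
        Fraction r of chronic patients who, after a community visit, also
        visit a tertiary-A hospital.
    q_poor, q_good
        Two-tier online-preference levels assigned by baseline offline
        accessibility (below the regional mean -> q_poor).
    online_mode
        How the online component divides the pooled online resource:
        ``as_printed`` keeps the Q_k factor in the online term's numerator
        (so the combination carries Q_k twice); ``conserving`` drops it so
        that sum_k M_k Q_k a_k^v equals the total online resource.
    offline_mode
        ``resource_shift`` removes allocated online time V_i from tertiary
        offline supply (total resource conserved); ``as_printed`` leaves
        tertiary offline supply untouched.
    demand_stratum
        Which population column plays M_k: total, elderly or chronic.
    """

    referral_rate: float = 0.2
    q_poor: float = 0.35
    q_good: float = 0.1
    online_mode: str = "as_printed"
    offline_mode: str = "resource_shift"
    demand_stratum: str = "chronic"

    def __post_init__(self) -> None:
        if not 0.0 <= self.referral_rate <= 1.0:
            raise ValueError("referral_rate must lie in [0, 1]")
        for name in ("q_poor", "q_good"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.online_mode not in _ONLINE_MODES:
            raise ValueError(f"online_mode must be one of {_ONLINE_MODES}")
        if self.offline_mode not in _OFFLINE_MODES:
            raise ValueError(f"offline_mode must be one of {_OFFLINE_MODES}")
        if self.demand_stratum not in _STRATA:
            raise ValueError(f"demand_stratum must be one of {_STRATA}")


@dataclass
class Instance:
    """A study region: divisions, hospital sites and the travel-cost matrix."""

    divisions: list[DemandDivision]
    sites: list[SupplySite]
    costs: CostMatrix
    coord_mode: str = "lonlat"  # "lonlat" (haversine km) or "planar"

    def __post_init__(self) -> None:
        div_ids = [d.id for d in self.divisions]
        site_ids = [s.id for s in self.sites]
        if len(set(div_ids)) != len(div_ids):
            raise ValueError("duplicate division ids")
        if len(set(site_ids)) != len(site_ids):
            raise ValueError("duplicate site ids")
        missing_d = set(div_ids) - set(self.costs.division_ids)
        missing_s = set(site_ids) - set(self.costs.site_ids)
        if missing_d or missing_s:
            raise ValueError(
                f"cost matrix incomplete: missing sites {sorted(missing_s)}, "
                f"divisions {sorted(missing_d)}"
            )

    @property
    def division_ids(self) -> list[str]:
        return [d.id for d in self.divisions]

    def sites_by_tier(self, tier: Tier) -> list[SupplySite]:
        return [s for s in self.sites if s.tier is tier]

    @property
    def community_sites(self) -> list[SupplySite]:
        return self.sites_by_tier(Tier.community)

    @property
    def tertiary_sites(self) -> list[SupplySite]:
        return self.sites_by_tier(Tier.tertiary_A)

    def with_q(self, q: Sequence[float]) -> "Instance":
        """Copy of the instance with per-division online preference set."""
        q = np.asarray(q, dtype=float)
        if q.shape != (len(self.divisions),):
            raise ValueError("q must have one entry per division")
        divisions = [replace(d, q_online=float(qk)) for d, qk in zip(self.divisions, q)]
        return Instance(divisions, self.sites, self.costs, self.coord_mode)


@dataclass
class AccessProfile:
    """Per-division accessibility components and the combined index."""

    division_ids: list[str]
    a_comm: np.ndarray
    a_tert: np.ndarray
    a_online: np.ndarray
    a_total: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.division_ids)
        for name in ("a_comm", "a_tert", "a_online", "a_total"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per division")
            if np.any(arr < 0):
                raise ValueError(f"{name} must be nonnegative")
            setattr(self, name, arr)

    @classmethod
    def from_totals(cls, division_ids: Sequence[str], a_total: Sequence[float]) -> "AccessProfile":
        """Profile carrying only combined values (components zeroed); used for
        reporting on externally supplied accessibility indices."""
        a = np.asarray(a_total, dtype=float)
        z = np.zeros_like(a)
        return cls(list(division_ids), z, z, z, a)

    @property
    def mean(self) -> float:
        return float(np.mean(self.a_total))

    @property
    def min(self) -> float:
        return float(np.min(self.a_total))

    @property
    def max(self) -> float:
        return float(np.max(self.a_total))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "division_id": self.division_ids,
                "a_comm": self.a_comm,
                "a_tert": self.a_tert,
                "a_online": self.a_online,
                "a_total": self.a_total,
            }
        )


# ---------------------------------------------------------------------------
# accessibility operations
# ---------------------------------------------------------------------------


def demand_vector(divisions: Sequence[DemandDivision], stratum: str = "chronic") -> np.ndarray:
    """Population M_k for the configured demand stratum, ordered as given."""
    attr = {"total": "pop_total", "elderly": "pop_elderly", "chronic": "pop_chronic"}
    if stratum not in attr:
        raise ValueError(f"demand_stratum must be one of {tuple(attr)}")
    return np.array([getattr(d, attr[stratum]) for d in divisions], dtype=float)


def decay_weight(d, spec: DecaySpec = DecaySpec()):
    """Distance-decay weight f(d) = max(d, d_floor)^(-beta), 0 beyond d0.

    Accepts a scalar or array; negative travel costs are rejected.
    """
    arr = np.asarray(d, dtype=float)
    if np.any(arr < 0):
        raise ValueError("travel cost must be >= 0")
    w = np.maximum(arr, spec.d_floor) ** (-spec.beta)
    if spec.d0 is not None:
        w = np.where(arr > spec.d0, 0.0, w)
    return w if arr.ndim else float(w)


def supply_ratio(
    site: SupplySite,
    divisions: Sequence[DemandDivision],
    costs: CostMatrix,
    d0: float,
    demand_stratum: str = "chronic",
) -> float:
    """Physician-to-population ratio R_j = S_j / sum of M_k within the d0 catchment.

    An empty catchment yields 0 with a warning rather than an error, so that
    degenerate instances do not abort parameter sweeps.
    """
    d = costs.submatrix([site.id], [dv.id for dv in divisions])[0]
    m = demand_vector(divisions, demand_stratum)
    pop = float(m[d <= d0].sum())
    if pop == 0.0:
        warnings.warn(
            f"site {site.id!r}: no demand within catchment d0={d0}; ratio defined as 0",
            stacklevel=2,
        )
        return 0.0
    return site.resource_offline / pop


def offline_accessibility(
    sites: Sequence[SupplySite],
    divisions: Sequence[DemandDivision],
    costs: CostMatrix,
    spec: DecaySpec = DecaySpec(),
    demand_stratum: str = "chronic",
    resources: Sequence[float] | None = None,
) -> np.ndarray:
    """Gravity 2SFCA accessibility a_k = sum_j S_j f(d_jk) / sum_l M_l f(d_jl).

    ``sites`` is a single tier's supply; ``resources`` optionally overrides
    each site's offline resource (used when online time is shifted away).
    Conserves supply: sum_k M_k a_k = sum_j S_j whenever every site reaches
    some demand.
    """
    if not sites:
        return np.zeros(len(divisions))
    s = (
        np.asarray(resources, dtype=float)
        if resources is not None
        else np.array([x.resource_offline for x in sites], dtype=float)
    )
    if np.any(s < 0):
        raise ValueError("site resources must be >= 0")
    d = costs.submatrix([x.id for x in sites], [dv.id for dv in divisions])
    f = decay_weight(d, spec)  # (J, P)
    m = demand_vector(divisions, demand_stratum)
    denom = f @ m  # per-site weighted demand
    dead = denom == 0.0
    if np.any(dead & (s > 0)):
        warnings.warn(
            "site(s) with zero weighted demand contribute nothing: "
            + ", ".join(sites[j].id for j in np.flatnonzero(dead & (s > 0))),
            stacklevel=2,
        )
    ratio = np.divide(s, denom, out=np.zeros_like(s), where=~dead)
    return f.T @ ratio


def referral_accessibility(a_comm: np.ndarray, a_tert: np.ndarray, r: float) -> np.ndarray:
    """Referral-weighted offline index a_k = (1-r) a_k^c + r a_k^a."""
    a_comm = np.asarray(a_comm, dtype=float)
    a_tert = np.asarray(a_tert, dtype=float)
    if a_comm.shape != a_tert.shape:
        raise ValueError("component vectors must be on the same division set")
    if not 0.0 <= r <= 1.0:
        raise ValueError("referral rate must lie in [0, 1]")
    return (1.0 - r) * a_comm + r * a_tert


def online_accessibility(
    v_online: Sequence[float],
    divisions: Sequence[DemandDivision],
    mode: str = "as_printed",
    demand_stratum: str = "chronic",
    q: Sequence[float] | None = None,
) -> np.ndarray:
    """Distance-free online accessibility from pooled tele-health resource.

    as_printed:  a_k^v = (sum_i V_i) * Q_k / sum_l Q_l M_l
    conserving:  a_k^v = (sum_i V_i) / sum_l Q_l M_l
                 (so that sum_k M_k Q_k a_k^v equals sum_i V_i)

    With no online demand (all Q_l M_l = 0) the component is 0 everywhere.
    """
    if mode not in _ONLINE_MODES:
        raise ValueError(f"online mode must be one of {_ONLINE_MODES}")
    v = np.asarray(v_online, dtype=float)
    if np.any(v < 0):
        raise ValueError("online allocations must be >= 0")
    qv = (
        np.asarray(q, dtype=float)
        if q is not None
        else np.array([d.q_online for d in divisions], dtype=float)
    )
    m = demand_vector(divisions, demand_stratum)
    pool = float(v.sum())
    qm = float(qv @ m)
    if qm == 0.0:
        return np.zeros(len(divisions))
    if mode == "as_printed":
        return pool * qv / qm
    return np.full(len(divisions), pool / qm)


def combined_accessibility(
    a_comm: np.ndarray,
    a_tert: np.ndarray,
    a_online: np.ndarray,
    divisions: Sequence[DemandDivision],
    params: ModelParams = ModelParams(),
    q: Sequence[float] | None = None,
) -> AccessProfile:
    """Overall index a_k = (1-Q_k)[(1-r) a_k^c + r a_k^a] + Q_k a_k^v."""
    a_comm = np.asarray(a_comm, dtype=float)
    a_tert = np.asarray(a_tert, dtype=float)
    a_online = np.asarray(a_online, dtype=float)
    n = len(divisions)
    if not (a_comm.shape == a_tert.shape == a_online.shape == (n,)):
        raise ValueError("component vectors must be on the same division set")
    qv = (
        np.asarray(q, dtype=float)
        if q is not None
        else np.array([d.q_online for d in divisions], dtype=float)
    )
    if np.any((qv < 0) | (qv > 1)):
        raise ValueError("Q_k must lie in [0, 1]")
    offline = referral_accessibility(a_comm, a_tert, params.referral_rate)
    total = (1.0 - qv) * offline + qv * a_online
    return AccessProfile([d.id for d in divisions], a_comm, a_tert, a_online, total)


def assign_online_preference(
    baseline: AccessProfile, params: ModelParams = ModelParams()
) -> np.ndarray:
    """Two-tier Q_k from a purely offline baseline profile.

    Divisions with baseline accessibility strictly below the regional mean
    are classified poor-access and get ``q_poor``; all others (ties included)
    get ``q_good``.
    """
    if not baseline.division_ids:
        raise ValueError("empty division set")
    a = baseline.a_total
    return np.where(a < np.mean(a), params.q_poor, params.q_good)


def compute_profile(
    instance: Instance,
    spec: DecaySpec = DecaySpec(),
    params: ModelParams = ModelParams(),
    v_online: Sequence[float] | None = None,
    q: Sequence[float] | None = None,
) -> AccessProfile:
    """Full i2SFCA-TH pipeline on an instance.

    ``v_online`` is the per-tertiary-site online allocation (defaults to no
    online service); ``q`` overrides the divisions' stored Q_k.  In
    ``resource_shift`` offline mode the allocated time is removed from the
    tertiary offline supply before the gravity computation.
    """
    tert = instance.tertiary_sites
    if v_online is None:
        v = np.zeros(len(tert))
    else:
        v = np.asarray(v_online, dtype=float)
        if v.shape != (len(tert),):
            raise ValueError("v_online must have one entry per tertiary site")
    t_res = np.array([s.resource_offline for s in tert], dtype=float)
    if np.any(v > t_res + 1e-9):
        raise ValueError("online allocation exceeds a site's total resource")
    a_comm = offline_accessibility(
        instance.community_sites, instance.divisions, instance.costs, spec, params.demand_stratum
    )
    t_eff = np.clip(t_res - v, 0.0, None) if params.offline_mode == "resource_shift" else t_res
    a_tert = offline_accessibility(
        tert, instance.divisions, instance.costs, spec, params.demand_stratum, resources=t_eff
    )
    a_online = online_accessibility(
        v, instance.divisions, params.online_mode, params.demand_stratum, q=q
    )
    return combined_accessibility(a_comm, a_tert, a_online, instance.divisions, params, q=q)
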