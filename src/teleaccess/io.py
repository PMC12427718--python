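"""Readers, writers, config parsing and the end-to-end pipeline.

Tabular schemas (CSV):

* ``divisions.csv`` — id, lon, lat, pop_total, pop_elderly, pop_chronic
  [, q_online]
* ``sites.csv`` — id, tier, lon, lat, resource_offline [, online_cap_fraction]
* ``costs.csv`` — long form: site_id, division_id, cost

Coordinates may be omitted when a complete cost matrix is supplied; when no
cost matrix is given, costs are computed from coordinates (haversine km for
lon/lat, Euclidean for planar).  The same instances can be exchanged as
RFC 7946 GeoJSON Point FeatureCollections carrying identical properties.

All floats are serialized at 12 significant digits so that rerunning a
pipeline with the same config and seed reproduces every output byte for
byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import core
from .allocator import AllocationProblem, AllocationResult, solve_allocation
from .core import (
    AccessProfile,
    CostMatrix,
    DecaySpec,
    DemandDivision,
    Instance,
    ModelParams,
    SupplySite,
    Tier,
)
from .equity import compute_report
from .synthcity import haversine_km

__all__ = [
    "SchemaError",
    "InfeasibleError",
    "RunConfig",
    "load_config",
    "read_instance",
    "write_instance",
    "read_instance_geojson",
    "write_instance_geojson",
    "run_pipeline",
    "FLOAT_FORMAT",
]

log = logging.getLogger("teleaccess")

FLOAT_FORMAT = "%.12g"


class SchemaError(ValueError):
    """An input table, file or config violates the documented schema."""


class InfeasibleError(RuntimeError):
    """The allocation program has no feasible point under the equity bound."""


def _round12(x: float) -> float:
    return float(f"{float(x):.12g}")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return _round12(float(o))
    if isinstance(o, np.ndarray):
        return [_round12(v) for v in o.tolist()]
    raise TypeError(f"not JSON serializable: {type(o)}")


def _dump_json(obj, path: Path) -> None:
    def walk(x):
        if isinstance(x, float):
            return _round12(x)
        if isinstance(x, dict):
            return {k: walk(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [walk(v) for v in x]
        return x

    path.write_text(json.dumps(walk(obj), indent=2, default=_json_default) + "\n")


# ---------------------------------------------------------------------------
# table readers / writers
# ---------------------------------------------------------------------------

_DIV_REQUIRED = ["id", "pop_total", "pop_elderly", "pop_chronic"]
_SITE_REQUIRED = ["id", "tier", "resource_offline"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def _check_unique(ids: pd.Series, what: str) -> None:
    dup = ids[ids.duplicated()]
    if len(dup):
        raise SchemaError(f"{what}: duplicate id {dup.iloc[0]!r}")


def _coord(row, has_coords: bool):
    if not has_coords or pd.isna(row.get("lon")) or pd.isna(row.get("lat")):
        return None
    return (float(row["lon"]), float(row["lat"]))


def _divisions_from_frame(df: pd.DataFrame) -> list[DemandDivision]:
    _require_columns(df, _DIV_REQUIRED, "divisions")
    _check_unique(df["id"].astype(str), "divisions")
    has_coords = "lon" in df.columns and "lat" in df.columns
    out = []
    for _, row in df.iterrows():
        try:
            out.append(
                DemandDivision(
                    id=str(row["id"]),
                    pop_total=float(row["pop_total"]),
                    pop_elderly=float(row["pop_elderly"]),
                    pop_chronic=float(row["pop_chronic"]),
                    coord=_coord(row, has_coords),
                    q_online=float(row["q_online"]) if "q_online" in df.columns and not pd.isna(row.get("q_online")) else 0.0,
                )
            )
        except ValueError as exc:
            raise SchemaError(f"divisions: record {row['id']!r}: {exc}") from exc
    return out


def _sites_from_frame(df: pd.DataFrame) -> list[SupplySite]:
    _require_columns(df, _SITE_REQUIRED, "sites")
    _check_unique(df["id"].astype(str), "sites")
    has_coords = "lon" in df.columns and "lat" in df.columns
    out = []
    for _, row in df.iterrows():
        try:
            out.append(
                SupplySite(
                    id=str(row["id"]),
                    tier=Tier(str(row["tier"])),
                    resource_offline=float(row["resource_offline"]),
                    coord=_coord(row, has_coords),
                    online_cap_fraction=float(row["online_cap_fraction"])
                    if "online_cap_fraction" in df.columns and not pd.isna(row.get("online_cap_fraction"))
                    else 0.0,
                )
            )
        except ValueError as exc:
            raise SchemaError(f"sites: record {row['id']!r}: {exc}") from exc
    return out


def _costs_from_coords(
    sites: list[SupplySite], divisions: list[DemandDivision], coord_mode: str
) -> CostMatrix:
    if any(s.coord is None for s in sites) or any(d.coord is None for d in divisions):
        raise SchemaError("no cost matrix supplied and some records lack coordinates")
    sxy = np.array([s.coord for s in sites], dtype=float)
    dxy = np.array([d.coord for d in divisions], dtype=float)
    if coord_mode == "lonlat":
        dist = haversine_km(sxy[:, None, 0], sxy[:, None, 1], dxy[None, :, 0], dxy[None, :, 1])
        unit = "km"
    else:
        dist = np.sqrt(((sxy[:, None, :] - dxy[None, :, :]) ** 2).sum(axis=2))
        unit = "unit"
    return CostMatrix(
        pd.DataFrame(dist, index=[s.id for s in sites], columns=[d.id for d in divisions]),
        unit=unit,
    )


def read_instance(
    divisions_path: str | Path,
    sites_path: str | Path,
    costs_path: str | Path | None = None,
    coord_mode: str = "lonlat",
    unit: str = "km",
) -> Instance:
    """Load and validate an instance from CSV tables.

    When ``costs_path`` is omitted the cost matrix is computed from the
    coordinates.  Schema violations raise :class:`SchemaError` naming the
    offending column, record or missing cost pair.
    """
    for p in (divisions_path, sites_path, costs_path):
        if p is not None and not Path(p).exists():
            raise SchemaError(f"input file not found: {p}")
    divisions = _divisions_from_frame(pd.read_csv(divisions_path))
    sites = _sites_from_frame(pd.read_csv(sites_path))
    if costs_path is not None:
        costs_df = pd.read_csv(costs_path)
        _require_columns(costs_df, ["site_id", "division_id", "cost"], "costs")
        costs_df = costs_df.astype({"site_id": str, "division_id": str})
        try:
            costs = CostMatrix.from_long(costs_df, unit=unit)
        except ValueError as exc:
            raise SchemaError(str(exc)) from exc
        want = {(s.id, d.id) for s in sites for d in divisions}
        have = {(s, d) for s in costs.site_ids for d in costs.division_ids}
        missing = sorted(want - have)
        if missing:
            raise SchemaError(f"cost matrix incomplete: missing pair {missing[0][0]!r} -> {missing[0][1]!r}")
        # keep the declared record order rather than the pivot's sort order
        costs = CostMatrix(
            costs.frame.loc[[s.id for s in sites], [d.id for d in divisions]], unit=unit
        )
    else:
        costs = _costs_from_coords(sites, divisions, coord_mode)
    try:
        return Instance(divisions, sites, costs, coord_mode)
    except ValueError as exc:
        raise SchemaError(str(exc)) from exc


def write_instance(instance: Instance, outdir: str | Path) -> dict[str, Path]:
    """Write divisions.csv, sites.csv and costs.csv (12 significant digits)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    div = pd.DataFrame(
        {
            "id": [d.id for d in instance.divisions],
            "lon": [d.coord[0] if d.coord else np.nan for d in instance.divisions],
            "lat": [d.coord[1] if d.coord else np.nan for d in instance.divisions],
            "pop_total": [d.pop_total for d in instance.divisions],
            "pop_elderly": [d.pop_elderly for d in instance.divisions],
            "pop_chronic": [d.pop_chronic for d in instance.divisions],
            "q_online": [d.q_online for d in instance.divisions],
        }
    )
    site = pd.DataFrame(
        {
            "id": [s.id for s in instance.sites],
            "tier": [s.tier.value for s in instance.sites],
            "lon": [s.coord[0] if s.coord else np.nan for s in instance.sites],
            "lat": [s.coord[1] if s.coord else np.nan for s in instance.sites],
            "resource_offline": [s.resource_offline for s in instance.sites],
            "online_cap_fraction": [s.online_cap_fraction for s in instance.sites],
        }
    )
    paths = {
        "divisions": outdir / "divisions.csv",
        "sites": outdir / "sites.csv",
        "costs": outdir / "costs.csv",
    }
    div.to_csv(paths["divisions"], index=False, float_format=FLOAT_FORMAT)
    site.to_csv(paths["sites"], index=False, float_format=FLOAT_FORMAT)
    instance.costs.to_long().to_csv(paths["costs"], index=False, float_format=FLOAT_FORMAT)
    return paths


# ---------------------------------------------------------------------------
# GeoJSON (RFC 7946 Point features)
# ---------------------------------------------------------------------------


def _features(records: list[dict], coords: list[tuple[float, float] | None]) -> list[dict]:
    feats = []
    for props, coord in zip(records, coords):
        feats.append(
            {
                "type": "Feature",
                "geometry": None
                if coord is None
                else {"type": "Point", "coordinates": [_round12(coord[0]), _round12(coord[1])]},
                "properties": {
                    k: (_round12(v) if isinstance(v, float) else v) for k, v in props.items()
                },
            }
        )
    return feats


def write_instance_geojson(instance: Instance, outdir: str | Path) -> dict[str, Path]:
    """Write divisions.geojson / sites.geojson plus costs.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    div_feats = _features(
        [
            {
                "id": d.id,
                "pop_total": d.pop_total,
                "pop_elderly": d.pop_elderly,
                "pop_chronic": d.pop_chronic,
                "q_online": d.q_online,
            }
            for d in instance.divisions
        ],
        [d.coord for d in instance.divisions],
    )
    site_feats = _features(
        [
            {
                "id": s.id,
                "tier": s.tier.value,
                "resource_offline": s.resource_offline,
                "online_cap_fraction": s.online_cap_fraction,
            }
            for s in instance.sites
        ],
        [s.coord for s in instance.sites],
    )
    paths = {
        "divisions": outdir / "divisions.geojson",
        "sites": outdir / "sites.geojson",
        "costs": outdir / "costs.csv",
    }
    for key, feats in (("divisions", div_feats), ("sites", site_feats)):
        paths[key].write_text(
            json.dumps({"type": "FeatureCollection", "features": feats}, indent=2) + "\n"
        )
    instance.costs.to_long().to_csv(paths["costs"], index=False, float_format=FLOAT_FORMAT)
    return paths


def read_instance_geojson(
    divisions_path: str | Path,
    sites_path: str | Path,
    costs_path: str | Path | None = None,
    coord_mode: str = "lonlat",
) -> Instance:
    """Load an instance from GeoJSON FeatureCollections (plus optional costs.csv)."""

    def frame(path) -> pd.DataFrame:
        try:
            doc = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise SchemaError(f"cannot read GeoJSON {path}: {exc}") from exc
        if doc.get("type") != "FeatureCollection":
            raise SchemaError(f"{path}: not a GeoJSON FeatureCollection")
        rows = []
        for feat in doc.get("features", []):
            props = dict(feat.get("properties") or {})
            geom = feat.get("geometry")
            if geom and geom.get("type") == "Point":
                props["lon"], props["lat"] = geom["coordinates"][:2]
            rows.append(props)
        return pd.DataFrame(rows)

    divisions = _divisions_from_frame(frame(divisions_path))
    sites = _sites_from_frame(frame(sites_path))
    if costs_path is not None:
        costs_df = pd.read_csv(costs_path).astype({"site_id": str, "division_id": str})
        try:
            costs = CostMatrix.from_long(costs_df)
            costs = CostMatrix(
                costs.frame.loc[[s.id for s in sites], [d.id for d in divisions]]
            )
        except (ValueError, KeyError) as exc:
            raise SchemaError(str(exc)) from exc
    else:
        costs = _costs_from_coords(sites, divisions, coord_mode)
    try:
        return Instance(divisions, sites, costs, coord_mode)
    except ValueError as exc:
        raise SchemaError(str(exc)) from exc


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "divisions", "sites", "costs", "out_dir", "seed", "log_level",
    "beta", "d0", "d_floor", "referral_rate", "q_poor", "q_good",
    "demand_stratum", "online_mode", "offline_mode", "unit",
    "g_bound", "bounds_mode", "a_min", "a_max", "integrality", "optimize",
}


@dataclass
class RunConfig:
    """Validated parameters of one pipeline run.

    Defaults encode the reference tele-health scenario: gravity decay with
    beta = 2, two-tier online preference 0.35 / 0.1, online cap rho = 0.4
    (carried on the sites), equity bound G = 0.7.
    """

    divisions: str | None = None
    sites: str | None = None
    costs: str | None = None
    out_dir: str = "out"
    seed: int = 0
    log_level: str = "INFO"
    beta: float = 2.0
    d0: float | None = None
    d_floor: float = 0.1
    referral_rate: float = 0.2
    q_poor: float = 0.35
    q_good: float = 0.1
    demand_stratum: str = "chronic"
    online_mode: str = "as_printed"
    offline_mode: str = "resource_shift"
    unit: str = "km"
    g_bound: float = 0.7
    bounds_mode: str = "variable_extremes"
    a_min: float | None = None
    a_max: float | None = None
    integrality: str = "continuous"
    optimize: bool = True

    def decay_spec(self) -> DecaySpec:
        return DecaySpec(beta=self.beta, d0=self.d0, d_floor=self.d_floor)

    def model_params(self) -> ModelParams:
        return ModelParams(
            referral_rate=self.referral_rate,
            q_poor=self.q_poor,
            q_good=self.q_good,
            online_mode=self.online_mode,
            offline_mode=self.offline_mode,
            demand_stratum=self.demand_stratum,
        )

    def __post_init__(self) -> None:
        try:
            self.decay_spec()
            self.model_params()
        except ValueError as exc:
            raise SchemaError(str(exc)) from exc
        if not 0.0 < self.g_bound <= 1.0:
            raise SchemaError("g_bound must lie in (0, 1]")
        if self.bounds_mode not in ("variable_extremes", "fixed_bounds"):
            raise SchemaError("bounds_mode must be variable_extremes or fixed_bounds")
        if self.integrality not in ("continuous", "integer"):
            raise SchemaError("integrality must be continuous or integer")


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML (or JSON) run config; unknown keys are rejected."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise SchemaError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise SchemaError("config must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("divisions", "sites", "costs"):
        if raw.get(key) is not None:
            p = (path.parent / raw[key]).resolve() if not Path(raw[key]).is_absolute() else Path(raw[key])
            if not p.exists():
                raise SchemaError(f"config {key}: file not found: {raw[key]}")
            raw[key] = str(p)
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise SchemaError(str(exc)) from exc


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def _profile_csv(profile: AccessProfile, path: Path) -> None:
    profile.to_frame().to_csv(path, index=False, float_format=FLOAT_FORMAT)


def run_pipeline(config: RunConfig, instance: Instance | None = None) -> dict[str, Any]:
    """Baseline -> preference assignment -> tele-health profile -> allocation.

    Stages: (1) purely offline baseline profile (Q = 0 everywhere); (2)
    two-tier online-preference assignment from the baseline; (3) combined
    profile at zero allocation; (4) optionally the equity-constrained
    allocation.  Writes profile CSVs, equity JSON reports, the allocation
    JSON and a run log of all parameters; returns the artefact paths and
    in-memory results.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if instance is None:
        if config.divisions is None or config.sites is None:
            raise SchemaError("config must point at divisions and sites tables")
        instance = read_instance(
            config.divisions, config.sites, config.costs, unit=config.unit
        )
    spec = config.decay_spec()
    params = config.model_params()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    weights = core.demand_vector(instance.divisions, params.demand_stratum)
    baseline = core.compute_profile(instance, spec, params, q=np.zeros(len(instance.divisions)))
    log.info("baseline mean accessibility %.4f", baseline.mean)
    q = core.assign_online_preference(baseline, params)
    instance_q = instance.with_q(q)
    combined = core.compute_profile(instance_q, spec, params)

    artifacts: dict[str, Any] = {
        "baseline_profile": out / "baseline_profile.csv",
        "combined_profile": out / "combined_profile.csv",
        "equity_baseline": out / "equity_baseline.json",
        "run_log": out / "run_log.json",
        "baseline": baseline,
        "combined": combined,
        "q": q,
    }
    _profile_csv(baseline, artifacts["baseline_profile"])
    _profile_csv(combined, artifacts["combined_profile"])
    _dump_json(dataclasses.asdict(compute_report(baseline, weights)), artifacts["equity_baseline"])

    allocation: AllocationResult | None = None
    if config.optimize:
        problem = AllocationProblem(
            instance_q,
            spec,
            params,
            g_bound=config.g_bound,
            bounds_mode=config.bounds_mode,
            a_min_fixed=config.a_min,
            a_max_fixed=config.a_max,
            integrality=config.integrality,
        )
        allocation = solve_allocation(problem)
        artifacts["allocation"] = out / "allocation.json"
        artifacts["allocation_result"] = allocation
        alloc_doc = {
            "status": allocation.status,
            "objective": allocation.objective,
            "achieved_equilibrium_index": allocation.achieved_equilibrium_index,
            "solver_gap": allocation.solver_gap,
            "v": allocation.v_by_site,
            "diagnostics": allocation.diagnostics,
        }
        _dump_json(alloc_doc, artifacts["allocation"])
        if allocation.status == "optimal":
            artifacts["optimized_profile"] = out / "optimized_profile.csv"
            artifacts["equity_optimized"] = out / "equity_optimized.json"
            _profile_csv(allocation.profile, artifacts["optimized_profile"])
            _dump_json(
                dataclasses.asdict(compute_report(allocation.profile, weights)),
                artifacts["equity_optimized"],
            )
        elif allocation.status == "infeasible":
            raise InfeasibleError(
                "equity bound G=%g unreachable; minimal feasible G ~ %.4g"
                % (config.g_bound, allocation.diagnostics.get("min_feasible_g", float("nan")))
            )

    run_log = {k: v for k, v in dataclasses.asdict(config).items()}
    run_log["q_assigned"] = [float(x) for x in q]
    run_log["solver"] = {
        "engine": "scipy-highs",
        "feasibility_tol": 1e-6,
        "mip_rel_gap": 0.01,
    }
    _dump_json(run_log, artifacts["run_log"])
    return artifacts
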