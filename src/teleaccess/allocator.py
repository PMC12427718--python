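"""Equity-constrained allocation of tele-health capacity.

Chooses how much physician time ``V_i`` each tertiary-A hospital dedicates
to online visits so as to maximize the mean accessibility index over all
divisions, subject to

* a per-hospital cap  V_i <= rho_i * T_i,
* the equilibrium-index equity bound
  (a_max - a_min) / (a_max + a_min) <= G, linearized exactly as
  (1 - G) * a_max <= (1 + G) * a_min,
* optionally integral V_i.

Every accessibility index is linear in V, so the continuous problem is an
LP and the integral one a MIP; both are solved with the HiGHS engine behind
scipy.optimize.  A brute-force grid search over the feasible box serves as
an independent verification oracle on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import LinearConstraint, linprog, milp

from . import core
from .core import AccessProfile, DecaySpec, Instance, ModelParams
from .equity import equilibrium_index

__all__ = [
    "AllocationProblem",
    "AllocationResult",
    "LinearProgram",
    "build_program",
    "solve_allocation",
    "brute_force_allocation",
]

FEASIBILITY_TOL = 1e-6  # constraint violation / optimality tolerance
MIP_REL_GAP = 0.01


@dataclass
class AllocationProblem:
    """Instance plus optimization settings.

    ``g_bound`` is the equity bound G in (0, 1].  In ``variable_extremes``
    mode a_min/a_max are auxiliary decision variables squeezed onto the
    realized extremes by the constraints; ``fixed_bounds`` instead imposes
    user-chosen constants.  Per-site online caps rho_i live on the
    SupplySite records.
    """

    instance: Instance
    spec: DecaySpec = field(default_factory=DecaySpec)
    params: ModelParams = field(default_factory=ModelParams)
    g_bound: float = 0.7
    bounds_mode: str = "variable_extremes"
    a_min_fixed: float | None = None
    a_max_fixed: float | None = None
    integrality: str = "continuous"

    def __post_init__(self) -> None:
        if not 0.0 < self.g_bound <= 1.0:
            raise ValueError("equity bound G must lie in (0, 1]")
        if self.bounds_mode not in ("variable_extremes", "fixed_bounds"):
            raise ValueError("bounds_mode must be variable_extremes or fixed_bounds")
        if self.integrality not in ("continuous", "integer"):
            raise ValueError("integrality must be continuous or integer")
        if self.bounds_mode == "fixed_bounds":
            if self.a_min_fixed is None or self.a_max_fixed is None:
                raise ValueError("fixed_bounds mode requires a_min_fixed and a_max_fixed")
            if not 0.0 <= self.a_min_fixed <= self.a_max_fixed:
                raise ValueError("need 0 <= a_min_fixed <= a_max_fixed")


@dataclass
class AllocationResult:
    """Optimal online allocations with the resulting accessibility profile."""

    v: np.ndarray
    site_ids: list[str]
    profile: AccessProfile | None
    objective: float | None
    status: str  # optimal | infeasible | unbounded | error
    solver_gap: float
    achieved_equilibrium_index: float | None
    diagnostics: dict

    @property
    def v_by_site(self) -> dict[str, float]:
        return {s: float(x) for s, x in zip(self.site_ids, self.v)}


@dataclass
class LinearProgram:
    """Assembled LP in scipy form (min c @ x s.t. A_ub @ x <= b_ub, bounds)."""

    c: np.ndarray
    a_ub: np.ndarray
    b_ub: np.ndarray
    bounds: list[tuple[float, float | None]]
    integrality: np.ndarray
    var_names: list[str]
    objective_const: float  # mean accessibility at V = 0
    access_const: np.ndarray  # a_k(V) = access_const + access_coef @ V
    access_coef: np.ndarray


def _linearize(problem: AllocationProblem):
    """Express every a_k as an affine function of the allocation vector V."""
    inst, spec, params = problem.instance, problem.spec, problem.params
    tert = inst.tertiary_sites
    if not tert:
        raise ValueError("instance has no tertiary-A sites to allocate from")
    divisions = inst.divisions
    m = core.demand_vector(divisions, params.demand_stratum)
    q = np.array([d.q_online for d in divisions], dtype=float)
    r = params.referral_rate

    a_comm = core.offline_accessibility(
        inst.community_sites, divisions, inst.costs, spec, params.demand_stratum
    )
    t_res = np.array([s.resource_offline for s in tert], dtype=float)
    if np.any(t_res < 0):
        raise ValueError("negative tertiary resources")
    d_t = inst.costs.submatrix([s.id for s in tert], [d.id for d in divisions])
    f_t = np.atleast_2d(core.decay_weight(d_t, spec))  # (L, P)
    denom = f_t @ m
    # per-unit-of-resource contribution of site i to division k
    w = np.divide(f_t, denom[:, None], out=np.zeros_like(f_t), where=denom[:, None] > 0).T  # (P, L)

    a_tert_full = w @ t_res
    qm = float(q @ m)
    if qm > 0:
        online_per_unit = (q / qm) if params.online_mode == "as_printed" else np.full(len(q), 1.0 / qm)
    else:
        online_per_unit = np.zeros(len(q))

    access_const = (1.0 - q) * ((1.0 - r) * a_comm + r * a_tert_full)
    access_coef = np.outer(q * online_per_unit, np.ones(len(tert)))
    if params.offline_mode == "resource_shift":
        access_coef = access_coef - ((1.0 - q) * r)[:, None] * w

    v_upper = np.array([s.online_cap_fraction for s in tert]) * t_res
    return access_const, access_coef, v_upper, qm


def build_program(problem: AllocationProblem) -> LinearProgram:
    """Assemble the allocation LP/MIP.

    Variables are the L online allocations V_i, plus auxiliary a_min and
    a_max in ``variable_extremes`` mode.  The equity ratio is imposed in
    its exact linearization (1 - G) a_max <= (1 + G) a_min, equivalent to
    the ratio bound whenever a_max + a_min > 0.
    """
    access_const, access_coef, v_upper, _ = _linearize(problem)
    n_div, n_tert = access_coef.shape
    g = problem.g_bound
    tert_ids = [s.id for s in problem.instance.tertiary_sites]

    mean_coef = access_coef.mean(axis=0)
    if problem.bounds_mode == "variable_extremes":
        n_var = n_tert + 2
        c = np.concatenate([-mean_coef, [0.0, 0.0]])
        rows, rhs = [], []
        for k in range(n_div):
            row = np.zeros(n_var)  # a_min <= a_k
            row[:n_tert] = -access_coef[k]
            row[n_tert] = 1.0
            rows.append(row)
            rhs.append(access_const[k])
            row = np.zeros(n_var)  # a_k <= a_max
            row[:n_tert] = access_coef[k]
            row[n_tert + 1] = -1.0
            rows.append(row)
            rhs.append(-access_const[k])
        row = np.zeros(n_var)  # (1-G) a_max <= (1+G) a_min
        row[n_tert] = -(1.0 + g)
        row[n_tert + 1] = 1.0 - g
        rows.append(row)
        rhs.append(0.0)
        bounds = [(0.0, float(u)) for u in v_upper] + [(0.0, None), (0.0, None)]
        integrality = np.array(
            [1 if problem.integrality == "integer" else 0] * n_tert + [0, 0]
        )
        names = [f"V[{s}]" for s in tert_ids] + ["a_min", "a_max"]
    else:
        lo, hi = problem.a_min_fixed, problem.a_max_fixed
        if hi + lo > 0 and (hi - lo) / (hi + lo) > g + FEASIBILITY_TOL:
            raise ValueError("fixed a_min/a_max violate the equity bound G")
        c = -mean_coef
        rows, rhs = [], []
        for k in range(n_div):
            rows.append(-access_coef[k])  # a_k >= lo
            rhs.append(access_const[k] - lo)
            rows.append(access_coef[k])  # a_k <= hi
            rhs.append(hi - access_const[k])
        bounds = [(0.0, float(u)) for u in v_upper]
        integrality = np.array([1 if problem.integrality == "integer" else 0] * n_tert)
        names = [f"V[{s}]" for s in tert_ids]

    return LinearProgram(
        c=c,
        a_ub=np.array(rows),
        b_ub=np.array(rhs),
        bounds=bounds,
        integrality=integrality,
        var_names=names,
        objective_const=float(access_const.mean()),
        access_const=access_const,
        access_coef=access_coef,
    )


def _solve_lp(lp: LinearProgram, integer: bool):
    if integer:
        res = milp(
            c=lp.c,
            constraints=LinearConstraint(lp.a_ub, -np.inf, lp.b_ub),
            bounds=_milp_bounds(lp.bounds),
            integrality=lp.integrality,
            options={"mip_rel_gap": MIP_REL_GAP, "presolve": True},
        )
        status = {0: "optimal", 2: "infeasible", 3: "unbounded"}.get(res.status, "error")
        gap = float(getattr(res, "mip_gap", 0.0) or 0.0)
    else:
        res = linprog(lp.c, A_ub=lp.a_ub, b_ub=lp.b_ub, bounds=lp.bounds, method="highs")
        status = {0: "optimal", 2: "infeasible", 3: "unbounded"}.get(res.status, "error")
        gap = 0.0
    return res, status, gap


def _milp_bounds(bounds):
    from scipy.optimize import Bounds

    lo = [b[0] for b in bounds]
    hi = [np.inf if b[1] is None else b[1] for b in bounds]
    return Bounds(lo, hi)


def _min_feasible_g(problem: AllocationProblem, iters: int = 40) -> float:
    """Bisect for the smallest equity bound G under which the program is feasible."""

    def feasible(g: float) -> bool:
        trial = AllocationProblem(
            problem.instance,
            problem.spec,
            problem.params,
            g_bound=g,
            bounds_mode=problem.bounds_mode,
            a_min_fixed=problem.a_min_fixed,
            a_max_fixed=problem.a_max_fixed,
        )
        lp = build_program(trial)
        res = linprog(
            np.zeros_like(lp.c), A_ub=lp.a_ub, b_ub=lp.b_ub, bounds=lp.bounds, method="highs"
        )
        return res.status == 0

    lo, hi = problem.g_bound, 1.0
    if feasible(lo):
        return lo
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            hi = mid
        else:
            lo = mid
    return hi


def solve_allocation(problem: AllocationProblem) -> AllocationResult:
    """Solve the allocation program and recompute the profile from V.

    The returned profile is re-evaluated through the accessibility equations
    directly from the optimal V (not read off the solver), guarding against
    drift between the algebraic model and the engine.  When no division has
    any online demand the objective is flat in V; the solution is then
    canonicalized to V = 0.
    """
    inst = problem.instance
    tert_ids = [s.id for s in inst.tertiary_sites]
    lp = build_program(problem)
    _, _, _, qm = _linearize(problem)

    if qm == 0.0:
        v = np.zeros(len(tert_ids))
        profile = core.compute_profile(inst, problem.spec, problem.params, v_online=v)
        return AllocationResult(
            v=v,
            site_ids=tert_ids,
            profile=profile,
            objective=profile.mean,
            status="optimal",
            solver_gap=0.0,
            achieved_equilibrium_index=equilibrium_index(profile),
            diagnostics={"note": "no online demand; allocation canonicalized to 0"},
        )

    res, status, gap = _solve_lp(lp, problem.integrality == "integer")
    if status != "optimal":
        diagnostics = {"solver_message": getattr(res, "message", "")}
        if status == "infeasible":
            diagnostics["min_feasible_g"] = _min_feasible_g(problem)
        return AllocationResult(
            v=np.zeros(len(tert_ids)),
            site_ids=tert_ids,
            profile=None,
            objective=None,
            status=status,
            solver_gap=gap,
            achieved_equilibrium_index=None,
            diagnostics=diagnostics,
        )

    v = np.clip(np.asarray(res.x[: len(tert_ids)], dtype=float), 0.0, None)
    profile = core.compute_profile(inst, problem.spec, problem.params, v_online=v)
    return AllocationResult(
        v=v,
        site_ids=tert_ids,
        profile=profile,
        objective=profile.mean,
        status="optimal",
        solver_gap=gap,
        achieved_equilibrium_index=equilibrium_index(profile),
        diagnostics={"solver_message": getattr(res, "message", "")},
    )


def brute_force_allocation(problem: AllocationProblem, grid_steps: int = 20) -> AllocationResult:
    """Verification oracle: exhaustive grid search over the allocation box.

    Evaluates the mean-accessibility objective on a regular grid with
    ``grid_steps + 1`` points per tertiary site spanning [0, rho_i T_i],
    keeps the points whose realized profile satisfies the equity bound, and
    returns the best (ties broken by the lexicographically smallest V).
    Guarded to at most 4 sites and 50 steps; the accessibility algebra is
    re-derived here from the decay weights, independent of the LP assembly.
    """
    inst, spec, params = problem.instance, problem.spec, problem.params
    tert = inst.tertiary_sites
    if len(tert) > 4 or grid_steps > 50:
        raise ValueError("brute force guard: need <= 4 tertiary sites and <= 50 grid steps")
    if grid_steps < 1:
        raise ValueError("grid_steps must be >= 1")

    divisions = inst.divisions
    m = core.demand_vector(divisions, params.demand_stratum)
    q = np.array([d.q_online for d in divisions], dtype=float)
    r = params.referral_rate
    t_res = np.array([s.resource_offline for s in tert], dtype=float)

    a_comm = core.offline_accessibility(
        inst.community_sites, divisions, inst.costs, spec, params.demand_stratum
    )
    f_t = np.atleast_2d(
        core.decay_weight(inst.costs.submatrix([s.id for s in tert], [d.id for d in divisions]), spec)
    )
    denom = f_t @ m

    axes = [np.linspace(0.0, s.online_cap_fraction * s.resource_offline, grid_steps + 1) for s in tert]
    mesh = np.meshgrid(*axes, indexing="ij")
    v_grid = np.stack([g.ravel() for g in mesh], axis=1)  # (N, L)

    t_eff = (t_res[None, :] - v_grid) if params.offline_mode == "resource_shift" else np.broadcast_to(
        t_res, v_grid.shape
    )
    ratio = np.divide(t_eff, denom[None, :], out=np.zeros_like(t_eff), where=denom[None, :] > 0)
    a_tert = ratio @ f_t  # (N, P)

    qm = float(q @ m)
    pool = v_grid.sum(axis=1)
    if qm > 0:
        unit = q if params.online_mode == "as_printed" else np.ones_like(q)
        a_online = pool[:, None] * unit[None, :] / qm
    else:
        a_online = np.zeros_like(a_tert)

    a = (1.0 - q)[None, :] * ((1.0 - r) * a_comm[None, :] + r * a_tert) + q[None, :] * a_online
    hi, lo = a.max(axis=1), a.min(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ei = np.where(hi + lo > 0, (hi - lo) / (hi + lo), 0.0)
    if problem.bounds_mode == "variable_extremes":
        feas = ei <= problem.g_bound + FEASIBILITY_TOL
    else:
        feas = (lo >= problem.a_min_fixed - FEASIBILITY_TOL) & (
            hi <= problem.a_max_fixed + FEASIBILITY_TOL
        )

    tert_ids = [s.id for s in tert]
    if not np.any(feas):
        return AllocationResult(
            v=np.zeros(len(tert)),
            site_ids=tert_ids,
            profile=None,
            objective=None,
            status="infeasible",
            solver_gap=0.0,
            achieved_equilibrium_index=None,
            diagnostics={"grid_points": len(v_grid), "feasible_points": 0},
        )

    obj = a.mean(axis=1)
    obj_feas = np.where(feas, obj, -np.inf)
    best = obj_feas.max()
    tied = np.flatnonzero(obj_feas >= best - 1e-15)
    # lexicographically smallest V among ties
    order = np.lexsort(tuple(v_grid[tied, i] for i in reversed(range(v_grid.shape[1]))))
    pick = tied[order[0]]
    v = v_grid[pick]
    profile = core.compute_profile(inst, spec, params, v_online=v)
    return AllocationResult(
        v=v,
        site_ids=tert_ids,
        profile=profile,
        objective=float(obj[pick]),
        status="optimal",
        solver_gap=0.0,
        achieved_equilibrium_index=float(ei[pick]),
        diagnostics={"grid_points": len(v_grid), "feasible_points": int(feas.sum())},
    )
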