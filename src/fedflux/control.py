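"""Receding-horizon feeding optimization.

The controller chooses piecewise-linear profiles of three manipulated
variables (glucose feed concentration, inlet flow, outlet flow) on a knot
grid at control-interval boundaries, minimizing the integrated squared
deviation of realized specific fluxes from the FBA stage targets

    OF = int_0^T_opt  sum_j w_j (zbar_j(t) - z_target_j(t))^2 dt .

Case A tracks all extracellular metabolite fluxes plus biomass; Case B
tracks the glucose flux only.  Optional rate-of-change limits bound the
per-interval change of the glucose feed concentration (hard constraints by
default, with an optional soft quadratic penalty mode).

The optimization is a single-shooting NLP over the knot values, solved with
SLSQP on a fixed-step RK4 prediction model; starts are drawn from the
lower-bound feed, the mid-bound feed and (when available) the previous
solution shifted by one interval, and the returned policy never evaluates
worse than the best start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .fba import StageTargetTable
from .kinetics import KineticParameters
from .twin import FeedPolicy, ReactorState, SimulationTrajectory, simulate_fixed_step

__all__ = [
    "ControlConfig",
    "TrackingObjective",
    "HorizonSolution",
    "build_objective",
    "evaluate_objective",
    "optimize_horizon",
    "apply_rate_limit",
]

#: default manipulated-variable bounds; flows stated in L/min in configs and
#: converted (x60) at the I/O boundary — these are the internal L/h values.
DEFAULT_U_BOUNDS: dict[str, tuple[float, float]] = {
    "C_feed_glc": (0.0, 1000.0),     # mmol/L
    "F_in": (0.06, 60.0),            # L/h  (0.001 .. 1 L/min)
    "F_out": (0.0, 3.0),             # L/h  (0 .. 0.05 L/min)
}

_MANIPULATED = ("C_feed_glc", "F_in", "F_out")


@dataclass
class ControlConfig:
    case: str = "A"                                  # "A" or "B"
    control_interval: float = 8.0                    # h
    horizon: float = 72.0                            # h (T_opt)
    u_bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_U_BOUNDS)
    )
    rate_limit: float | None = None                  # mmol/L per interval
    rate_limit_mode: str = "hard"                    # "hard" | "soft"
    rate_penalty_weight: float = 1e-4                # soft mode only
    v_bounds: tuple[float, float] | None = None      # working volume (L), hard
    #: optional feed-volume allocation plan: (times, caps) piecewise-linear
    #: upper volume schedule over the batch; overrides v_bounds[1] pointwise
    v_cap_schedule: tuple[np.ndarray, np.ndarray] | None = None
    weights: dict[str, float] | None = None          # per-flux override
    output_dt: float = 2.0                           # quadrature grid, h
    model_dt: float = 0.5                            # RK4 step of the internal model, h
    maxiter: int = 40
    ftol: float = 1e-9
    seed: int = 0
    n_random_starts: int = 2
    n_polish: int = 2                                # SLSQP runs per cycle
    #: weak quadratic control-effort term on the normalized knot values;
    #: settles directions the tracking objective is flat in (keeps the
    #: solution deterministic) without influencing active tracking
    u_regularization: float = 1e-4

    def validate(self) -> None:
        if self.case not in {"A", "B"}:
            raise ValueError(f"case must be 'A' or 'B', got {self.case!r}")
        if not 0 < self.control_interval <= self.horizon:
            raise ValueError("need 0 < control_interval <= horizon")
        k = self.horizon / self.control_interval
        if abs(k - round(k)) > 1e-9:
            raise ValueError("horizon must be an integer multiple of control_interval")
        for name, (lo, hi) in self.u_bounds.items():
            if not lo < hi:
                raise ValueError(f"u_bounds[{name!r}]: need lb < ub")
        if self.rate_limit is not None and self.rate_limit < 0:
            raise ValueError("rate_limit must be nonnegative")
        if self.v_bounds is not None and not self.v_bounds[0] < self.v_bounds[1]:
            raise ValueError("v_bounds: need v_min < v_max")


@dataclass
class TrackingObjective:
    """Tracked flux ids, stage-resolved targets and weights over a horizon."""

    tracked: list[str]
    targets: StageTargetTable
    stage_of: "callable"          # t -> CultureStage
    weights: dict[str, float]

    def target_series(self, grid: np.ndarray) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        stages = [self.stage_of(float(t)) for t in grid]
        for fid in self.tracked:
            out[fid] = np.array(
                [self.targets.target_at(s, fid) for s in stages]
            )
        return out


DEFAULT_WEIGHT_EPS = 1e-6


def default_weights(targets: StageTargetTable, tracked: list[str]) -> dict[str, float]:
    """w_j = 1/max(|z_target_j|, eps)^2 with |z| the largest magnitude over
    stages, making residuals dimensionless across heterogeneous fluxes."""
    w = {}
    for fid in tracked:
        zmax = max(abs(targets.target_at(s, fid)) for s in targets.targets)
        w[fid] = 1.0 / max(zmax, DEFAULT_WEIGHT_EPS) ** 2
    return w


def build_objective(
    cfg: ControlConfig,
    targets: StageTargetTable,
    stage_of,
) -> TrackingObjective:
    tracked = list(targets.tracked) if cfg.case == "A" else ["glc"]
    weights = default_weights(targets, tracked)
    if cfg.weights:
        weights.update({k: v for k, v in cfg.weights.items() if k in weights})
    return TrackingObjective(
        tracked=tracked, targets=targets, stage_of=stage_of, weights=weights
    )


def _objective_from_traj(
    traj: SimulationTrajectory, obj: TrackingObjective
) -> float:
    grid = traj.grid
    target = obj.target_series(grid)
    total = 0.0
    for fid in obj.tracked:
        resid = traj.fluxes[fid].to_numpy() - target[fid]
        total += obj.weights[fid] * float(np.trapezoid(resid**2, grid))
    return total


def evaluate_objective(
    policy: FeedPolicy,
    x0: ReactorState,
    obj: TrackingObjective,
    p: KineticParameters,
    t_end: float | None = None,
    output_dt: float = 2.0,
    integrator: str = "adaptive",
    model_dt: float = 0.5,
) -> float:
    """OF for a policy: trapezoidal quadrature of the weighted squared flux
    deviations on the simulation output grid."""
    t_end = policy.t1 if t_end is None else t_end
    if integrator == "adaptive":
        from .twin import simulate

        traj = simulate(x0, policy, p, t_end, output_dt=output_dt)
    else:
        traj = simulate_fixed_step(x0, policy, p, t_end, dt=model_dt)
        step = max(1, int(round(output_dt / model_dt)))
        keep = np.arange(0, traj.grid.size, step)
        if keep[-1] != traj.grid.size - 1:
            keep = np.append(keep, traj.grid.size - 1)
        traj = SimulationTrajectory(
            grid=traj.grid[keep],
            states=[traj.states[i] for i in keep],
            fluxes=traj.fluxes.iloc[keep],
            glucose_fed=traj.glucose_fed[keep],
        )
    return _objective_from_traj(traj, obj)


@dataclass
class HorizonSolution:
    policy: FeedPolicy
    objective: float
    status: str                   # converged | max_iter | infeasible
    iterations: int
    feasibility_residual: float
    fluxes: "object" = None       # realized flux DataFrame over the horizon


def apply_rate_limit(
    cfg: ControlConfig, prev_value: float | None
) -> list[tuple[int, int, float]]:
    """Hard rate-of-change constraint set on the glucose-feed knot sequence.

    Returns (i, j, bound) triples meaning |u_i - u_j| <= bound on knot
    indices of C_feed_glc; index -1 stands for the previous implemented
    value.  Empty when no limit is configured.
    """
    if cfg.rate_limit is None or not np.isfinite(cfg.rate_limit):
        return []
    lo, hi = cfg.u_bounds["C_feed_glc"]
    out: list[tuple[int, int, float]] = []
    if prev_value is not None:
        if not (lo - 1e-9 <= prev_value <= hi + 1e-9):
            raise ValueError(
                f"previous glucose feed value {prev_value} outside bounds [{lo}, {hi}]"
            )
        out.append((0, -1, cfg.rate_limit))
    return out


def _knot_grid(t0: float, horizon: float, interval: float) -> np.ndarray:
    n = int(round(horizon / interval))
    return t0 + interval * np.arange(n + 1)


def _pack_bounds(cfg: ControlConfig, n_knots: int) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = [], []
    for name in _MANIPULATED:
        a, b = cfg.u_bounds[name]
        lo += [a] * n_knots
        hi += [b] * n_knots
    return np.array(lo), np.array(hi)


def _unpack(u: np.ndarray, n_knots: int) -> dict[str, np.ndarray]:
    return {
        name: u[i * n_knots : (i + 1) * n_knots]
        for i, name in enumerate(_MANIPULATED)
    }


def optimize_horizon(
    x0: ReactorState,
    cfg: ControlConfig,
    targets: StageTargetTable,
    schedule,
    p: KineticParameters,
    feed_concentrations: dict[str, float] | None = None,
    prev_glc_feed: float | None = None,
    prev_u: dict[str, float] | None = None,
    warm_start: FeedPolicy | None = None,
    t_end: float | None = None,
) -> HorizonSolution:
    """Single-shooting horizon optimization from the current state.

    ``schedule`` maps time to :class:`CultureStage` (see
    :class:`fedflux.loop.StageSchedule`).  The horizon is truncated at
    ``t_end`` (batch end) when given.  ``prev_u`` pins the first knot of
    each manipulated variable at its previously implemented value, keeping
    the concatenated closed-loop profile continuous (and hence exactly
    replayable as one piecewise-linear policy).
    """
    cfg.validate()
    x0.validate()
    horizon = cfg.horizon
    if t_end is not None:
        horizon = min(horizon, t_end - x0.t)
    if horizon <= 0:
        raise ValueError("horizon collapsed to zero; nothing to optimize")
    n_int = max(1, int(np.ceil(horizon / cfg.control_interval - 1e-9)))
    knots = x0.t + np.minimum(cfg.control_interval * np.arange(n_int + 1), horizon)
    n_knots = knots.size
    t1 = float(knots[-1])
    feed_other = dict(feed_concentrations or {})

    stage_of = schedule.stage_at if hasattr(schedule, "stage_at") else schedule
    obj = build_objective(cfg, targets, stage_of)

    lo, hi = _pack_bounds(cfg, n_knots)
    if prev_u is not None:
        for i, name in enumerate(_MANIPULATED):
            if name in prev_u:
                j = i * n_knots
                v = float(np.clip(prev_u[name], lo[j], hi[j]))
                lo[j] = hi[j] = v
    scale = hi - lo

    def to_policy(u: np.ndarray) -> FeedPolicy:
        vals = _unpack(np.clip(u, lo, hi), n_knots)
        return FeedPolicy(
            knots=knots,
            F_in=vals["F_in"],
            F_out=vals["F_out"],
            C_feed_glc=vals["C_feed_glc"],
            C_feed_other=feed_other,
        )

    rate_cons = apply_rate_limit(cfg, prev_glc_feed)
    has_rl = cfg.rate_limit is not None and np.isfinite(cfg.rate_limit)
    use_hard_rl = has_rl and cfg.rate_limit_mode == "hard"

    # precompute the fast-rollout inputs (identical numerics to
    # simulate_fixed_step + trapezoidal OF; asserted by the test suite)
    from . import _fastmodel as fm
    from .twin import SPECIES

    n_steps = max(1, int(round((t1 - x0.t) / cfg.model_dt)))
    step = max(1, int(round(cfg.output_dt / cfg.model_dt)))
    out_idx = np.arange(0, n_steps + 1, step)
    if out_idx[-1] != n_steps:
        out_idx = np.append(out_idx, n_steps)
    out_times = x0.t + (t1 - x0.t) * out_idx / n_steps
    flux_order = list(SPECIES) + ["biomass"]
    target_series = obj.target_series(out_times)
    tmat = np.zeros((out_idx.size, fm.N_FLUX))
    wvec = np.zeros(fm.N_FLUX)
    for f, fid in enumerate(flux_order):
        if fid in obj.tracked:
            tmat[:, f] = target_series[fid]
            wvec[f] = obj.weights[fid]
    y0 = x0.to_vector()
    f_other = np.array([feed_other.get(s, 0.0) for s in SPECIES])
    pp = fm.pack_params(p)

    def objective(u: np.ndarray) -> float:
        u = np.clip(u, lo, hi)
        vals = _unpack(u, n_knots)
        val = float(
            fm.rollout_objective(
                y0,
                x0.t,
                t1,
                n_steps,
                knots,
                vals["F_in"],
                vals["F_out"],
                vals["C_feed_glc"],
                f_other,
                pp,
                out_idx,
                tmat,
                wvec,
            )
        )
        if has_rl and cfg.rate_limit_mode == "soft":
            g = vals["C_feed_glc"]
            excess = np.maximum(np.abs(np.diff(g)) - cfg.rate_limit, 0.0)
            if prev_glc_feed is not None:
                excess = np.append(
                    excess, max(abs(g[0] - prev_glc_feed) - cfg.rate_limit, 0.0)
                )
            val += cfg.rate_penalty_weight * float(np.sum(excess**2))
        if cfg.u_regularization > 0.0:
            w_norm = np.where(scale > 0, (u - lo) / np.where(scale > 0, scale, 1.0), 0.0)
            val += cfg.u_regularization * float(np.mean(w_norm**2))
        return val

    # working-volume constraints: V(t) is an exact (piecewise-quadratic)
    # integral of the piecewise-linear net flow, so sampling knots and
    # interval midpoints bounds it everywhere; linear in the knot values
    refined = np.sort(np.concatenate([knots, 0.5 * (knots[:-1] + knots[1:])]))

    def volume_profile(fin: np.ndarray, fout: np.ndarray) -> np.ndarray:
        """V at the refined grid plus one virtual interval past the horizon
        with the terminal flows held, so a plan cannot park a volume spike
        just beyond its own lookahead (terminal feasibility)."""
        net = np.interp(refined, knots, fin) - np.interp(refined, knots, fout)
        dv = np.concatenate(
            ([0.0], np.cumsum(0.5 * (net[1:] + net[:-1]) * np.diff(refined)))
        )
        vols = x0.V + dv
        tail = vols[-1] + (fin[-1] - fout[-1]) * cfg.control_interval
        return np.append(vols, tail)

    constraints = []
    if cfg.v_bounds is not None:
        v_min, v_max = cfg.v_bounds
        cap_times = np.append(refined, refined[-1] + cfg.control_interval)
        if cfg.v_cap_schedule is not None:
            ts, caps = cfg.v_cap_schedule
            v_cap = np.minimum(np.interp(cap_times, ts, caps), v_max)
        else:
            v_cap = np.full(cap_times.size, v_max)

        def volume_residuals(u: np.ndarray) -> np.ndarray:
            vals = _unpack(u, n_knots)
            vols = volume_profile(vals["F_in"], vals["F_out"])
            return np.concatenate([v_cap - vols, vols - v_min])

        constraints.append({"type": "ineq", "fun": volume_residuals})
    if use_hard_rl:
        rl = cfg.rate_limit

        def rate_residuals(u: np.ndarray) -> np.ndarray:
            g = _unpack(u, n_knots)["C_feed_glc"]
            diffs = np.diff(g)
            if prev_glc_feed is not None:
                diffs = np.append(diffs, g[0] - prev_glc_feed)
            return rl - np.abs(diffs)

        constraints.append({"type": "ineq", "fun": rate_residuals})

    rng = np.random.default_rng(cfg.seed)
    starts: list[np.ndarray] = []
    starts.append(lo.copy())                       # minimal feed
    starts.append(lo + 0.5 * scale)                # mid-bounds
    starts.append(lo + 0.25 * scale)
    if prev_u is not None:                         # hold previous values
        hold = np.concatenate(
            [np.full(n_knots, prev_u.get(name, lo[i * n_knots]))
             for i, name in enumerate(_MANIPULATED)]
        )
        starts.append(np.clip(hold, lo, hi))
    if warm_start is not None:
        try:
            u_ws = np.concatenate(
                [
                    np.interp(knots, warm_start.knots, getattr(warm_start, name))
                    for name in _MANIPULATED
                ]
            )
            starts.insert(0, np.clip(u_ws, lo, hi))
        except Exception:
            pass
    for _ in range(cfg.n_random_starts):
        starts.append(lo + scale * rng.random(lo.size))

    def feasible(u: np.ndarray) -> np.ndarray:
        u = np.clip(u, lo, hi)
        vals = _unpack(u.copy(), n_knots)
        if use_hard_rl:
            # project the glucose-feed knots onto the rate-limit band
            g = vals["C_feed_glc"]
            if prev_glc_feed is not None:
                g[0] = np.clip(
                    g[0], prev_glc_feed - cfg.rate_limit, prev_glc_feed + cfg.rate_limit
                )
            for i in range(1, g.size):
                g[i] = np.clip(g[i], g[i - 1] - cfg.rate_limit, g[i - 1] + cfg.rate_limit)
            glo, ghi = cfg.u_bounds["C_feed_glc"]
            vals["C_feed_glc"] = np.clip(g, glo, ghi)
        if cfg.v_bounds is not None:
            # bisection repair: shrink the free F_in knots toward the lower
            # bound (then grow free F_out knots toward the upper bound) until
            # the volume band holds; pinned first knots stay untouched
            v_min, v_max = cfg.v_bounds
            nb = n_knots
            fin_lo = lo[nb : 2 * nb]
            fin_pinned = fin_lo == hi[nb : 2 * nb]
            fout_hi = hi[2 * nb : 3 * nb]
            fout_pinned = lo[2 * nb : 3 * nb] == fout_hi

            def ok(fin, fout):
                vols = volume_profile(fin, fout)
                return bool(
                    np.all(vols <= v_cap + 1e-9) and vols.min() >= v_min - 1e-9
                )

            fin, fout = vals["F_in"], vals["F_out"]
            if not ok(fin, fout):
                if volume_profile(fin, fout).min() < v_min:
                    fout = np.where(fout_pinned, fout, np.minimum(fout, fin))
                if not ok(fin, fout):
                    base = np.where(fin_pinned, fin, fin_lo)
                    if not ok(base, fout):
                        fout2 = np.where(
                            fout_pinned, fout, np.minimum(fout_hi, fout + fin)
                        )
                        if ok(base, fout2):
                            fout = fout2
                    s_lo, s_hi = 0.0, 1.0
                    for _ in range(50):
                        s = 0.5 * (s_lo + s_hi)
                        if ok(base + s * (fin - base), fout):
                            s_lo = s
                        else:
                            s_hi = s
                    fin = base + s_lo * (fin - base)
                vals["F_in"], vals["F_out"] = fin, fout
        u = np.concatenate([vals[name] for name in _MANIPULATED])
        return np.clip(u, lo, hi)

    starts = [feasible(u) for u in starts]
    ranked = sorted(starts, key=objective)
    best_u = ranked[0]
    best_val = objective(best_u)

    # solve in the unit box: the raw knot values span ~3 orders of magnitude
    # (mmol/L vs L/h), which SLSQP handles poorly unscaled
    span = np.where(scale > 0, scale, 1.0)

    def to_u(w: np.ndarray) -> np.ndarray:
        # pinned entries (scale == 0) stay at lo regardless of w
        return lo + np.clip(w, 0.0, 1.0) * scale

    def obj_w(w: np.ndarray) -> float:
        return objective(to_u(w))

    cons_w = [
        {"type": c["type"], "fun": (lambda f: lambda w: f(to_u(w)))(c["fun"])}
        for c in constraints
    ]

    status = "max_iter"
    u_opt, val_opt = best_u, best_val
    nit = 0
    for u0 in ranked[: max(1, cfg.n_polish)]:
        w0 = np.where(scale > 0, (u0 - lo) / span, 0.0)
        res = minimize(
            obj_w,
            w0,
            method="SLSQP",
            bounds=[(0.0, 1.0)] * w0.size,
            constraints=cons_w,
            options={"maxiter": cfg.maxiter, "ftol": cfg.ftol},
        )
        nit += int(res.nit)
        cand = feasible(to_u(res.x))
        val = objective(cand)
        if val < val_opt:                          # never worsen the best start
            u_opt, val_opt = cand, val
        if res.success:
            status = "converged"

    pol = to_policy(u_opt)
    resid = 0.0
    if rate_cons or use_hard_rl:
        g = pol.C_feed_glc
        diffs = list(np.abs(np.diff(g)))
        if prev_glc_feed is not None:
            diffs.append(abs(g[0] - prev_glc_feed))
        resid = max(0.0, max(diffs) - (cfg.rate_limit or np.inf))
    if cfg.v_bounds is not None:
        vols = volume_profile(pol.F_in, pol.F_out)
        resid = max(
            resid,
            float(vols.max() - cfg.v_bounds[1]),
            float(cfg.v_bounds[0] - vols.min()),
            0.0,
        )
    if resid > 1e-6:
        status = "infeasible"
    traj = simulate_fixed_step(x0, pol, p, t1, dt=cfg.model_dt)
    return HorizonSolution(
        policy=pol,
        objective=val_opt,
        status=status,
        iterations=nit,
        feasibility_residual=resid,
        fluxes=traj.fluxes,
    )
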